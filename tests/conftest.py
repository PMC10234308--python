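import logging
import warnings

import numpy as np
import pytest

from snoexpress import pipeline, predictor, synthetic_data

logging.getLogger("snoexpress").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smoke_cohort(tmp_path_factory):
    """Small (n=50) synthetic cohort shared across tests."""
    outdir = tmp_path_factory.mktemp("smoke_cohort")
    config = synthetic_data.SyntheticConfig(n_snornas=50, seed=20)
    paths, manifest = synthetic_data.generate_cohort(config, outdir)
    return paths, manifest


@pytest.fixture(scope="session")
def smoke_features(smoke_cohort):
    paths, _ = smoke_cohort
    return pipeline.compute_feature_table_for_cohort(paths)


@pytest.fixture(scope="session")
def medium_cohort(tmp_path_factory):
    """Mid-sized (n=200) cohort for protocol-level tests."""
    outdir = tmp_path_factory.mktemp("medium_cohort")
    config = synthetic_data.SyntheticConfig(n_snornas=200, seed=31)
    paths, manifest = synthetic_data.generate_cohort(config, outdir)
    return paths, manifest


@pytest.fixture(scope="session")
def medium_features(medium_cohort):
    paths, _ = medium_cohort
    return pipeline.compute_feature_table_for_cohort(paths)


@pytest.fixture(scope="session")
def medium_protocol(medium_features):
    return predictor.run_protocol(
        medium_features.table,
        seed=3,
        families=predictor.ENSEMBLE_FAMILIES,
    )
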