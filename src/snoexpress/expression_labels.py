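"""Binary expression labels from replicate TPM tables.

A gene is *expressed* when its abundance exceeds 1 TPM in at least one
average tissue (arithmetic mean over biological replicates), and *not
expressed* otherwise. The same rule, applied to host genes, yields the
three-way host status (host expressed / host not expressed / intergenic);
the host abundance table may come from an independent study.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .genome_io import INTERGENIC, HostAssignment

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.0  # TPM
EXPRESSED = "expressed"
NOT_EXPRESSED = "not_expressed"
HOST_EXPRESSED = "host_expressed"
HOST_NOT_EXPRESSED = "host_not_expressed"


def average_by_tissue(
    tpm: pd.DataFrame, design: Mapping[str, str]
) -> pd.DataFrame:
    """Average replicate samples into a genes x tissues matrix.

    `tpm` is genes x samples; `design` maps every sample column to its
    tissue. A sample without a tissue mapping is an error.
    """
    missing = [s for s in tpm.columns if s not in design]
    if missing:
        raise ValueError(f"samples without tissue mapping: {missing}")
    if (tpm.values < 0).any():
        raise ValueError("negative TPM values")
    tissues = pd.Series({s: design[s] for s in tpm.columns})
    return tpm.T.groupby(tissues).mean().T


def label_expression(
    tissue_means: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Label each gene from its tissue means (strict `> threshold` in at
    least one tissue). Returns columns `status` and `max_tissue_mean`."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    max_mean = tissue_means.max(axis=1)
    status = (max_mean > threshold).map({True: EXPRESSED, False: NOT_EXPRESSED})
    return pd.DataFrame({"status": status, "max_tissue_mean": max_mean})


def host_expression_status(
    host_labels: pd.DataFrame, assignments: Mapping[str, HostAssignment]
) -> pd.Series:
    """Three-way host status per snoRNA from host-gene labels.

    A hosted snoRNA whose host is absent from the abundance table is
    treated as host-not-expressed (absence from quantification read as
    non-detection), with a warning.
    """
    out = {}
    for sno_id, assignment in assignments.items():
        if assignment.is_intergenic:
            out[sno_id] = INTERGENIC
        elif assignment.host_id in host_labels.index:
            expressed = host_labels.loc[assignment.host_id, "status"] == EXPRESSED
            out[sno_id] = HOST_EXPRESSED if expressed else HOST_NOT_EXPRESSED
        else:
            logger.warning(
                "host %s of snoRNA %s absent from host abundance table; "
                "treated as not expressed",
                assignment.host_id,
                sno_id,
            )
            out[sno_id] = HOST_NOT_EXPRESSED
    return pd.Series(out, name="host_expression_status")


def read_tpm_table(path) -> pd.DataFrame:
    """Genes x samples TPM TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design(path) -> dict[str, str]:
    """Two-column TSV sample -> tissue."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
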