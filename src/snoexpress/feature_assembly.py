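"""Assembly of the model-ready feature matrix.

Numerical snoRNA features (box score, folding stabilities, genomic
context) and categorical metadata (snoRNA type and target, host biotype /
function / expression status, NMD susceptibility, promoter class) are
merged into one table, one-hot encoded with the redundant `intergenic`
indicator kept only once, imputed, and standardized. Scaling statistics
are always fit on a stated training set and re-applied to tuning/test or
cross-species rows, never re-fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_labels import EXPRESSED
from .genome_io import INTERGENIC, IntronContext, SnoRecord
from .motif_scoring import BoxScore

logger = logging.getLogger(__name__)

NUMERIC_FEATURES = [
    "sno_length",
    "box_score",
    "sno_stability",
    "terminal_stem_stability",
    "terminal_stem_length_score",
    "total_introns",
    "intron_length",
    "intron_rank_5p",
    "relative_intron_rank_3p",
    "dist_upstream_exon",
    "dist_downstream_exon",
    "dist_branchpoint",
]
CATEGORICAL_FEATURES = [
    "sno_type",
    "target",
    "host_biotype",
    "host_function",
    "host_expression_status",
    "nmd_susceptibility",
    "dual_initiation_promoter",
]
_INTRON_FEATURES = NUMERIC_FEATURES[5:]

#: The four features found to drive expression status (used for the
#: redundancy filter, the simplified models, and cross-species transfer).
TOP4_FEATURES = [
    "box_score",
    "sno_stability",
    "terminal_stem_stability",
    "host_expressed",
]
LABEL_COLUMN = "label"


@dataclass
class FeatureTable:
    """Encoded feature matrix plus labels, indexed by snoRNA id."""

    data: pd.DataFrame
    numeric_cols: list[str]
    onehot_cols: list[str]
    onehot_parent: dict[str, str] = field(default_factory=dict)

    @property
    def feature_cols(self) -> list[str]:
        return self.numeric_cols + self.onehot_cols

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.feature_cols]

    @property
    def y(self) -> pd.Series:
        return self.data[LABEL_COLUMN]


@dataclass(frozen=True)
class ScalingStats:
    """Per-column mean and population variance of a training set."""

    mean: pd.Series
    var: pd.Series
    training_id: str = ""

    def __post_init__(self) -> None:
        if (self.var < 0).any():
            raise ValueError("negative variance")
        if not self.mean.index.equals(self.var.index):
            raise ValueError("mean/var column mismatch")

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "training_id": self.training_id,
                "columns": list(self.mean.index),
                "mean": self.mean.tolist(),
                "var": self.var.tolist(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScalingStats":
        import json

        payload = json.loads(text)
        idx = pd.Index(payload["columns"])
        return cls(
            pd.Series(payload["mean"], index=idx),
            pd.Series(payload["var"], index=idx),
            payload["training_id"],
        )


def assemble_features(
    records: Sequence[SnoRecord],
    box_scores: Mapping[str, BoxScore],
    structure: pd.DataFrame,
    intron_contexts: Mapping[str, IntronContext | None],
    host_status: Mapping[str, str],
    labels: Mapping[str, str | int],
    metadata: pd.DataFrame,
    impute: str = "zero",
) -> pd.DataFrame:
    """Merge all feature sources into one raw (pre-encoding) table.

    `structure` carries sno_stability / terminal_stem_stability /
    terminal_stem_length_score per snoRNA id; `metadata` the categorical
    columns except host_expression_status, which comes from `host_status`.
    Intron features missing for intergenic or exonic snoRNAs are imputed
    (`impute="zero"` or `"median"`); the intergenic indicator carries the
    distinction. Ids present in one source but not another are an error.
    """
    ids = [r.id for r in records]
    for name, keys in [
        ("box_scores", set(box_scores)),
        ("structure", set(structure.index)),
        ("intron_contexts", set(intron_contexts)),
        ("host_status", set(host_status)),
        ("labels", set(labels)),
        ("metadata", set(metadata.index)),
    ]:
        diff = set(ids) ^ keys
        if diff:
            raise ValueError(f"id mismatch between records and {name}: {sorted(diff)}")

    rows = []
    for rec in records:
        ctx = intron_contexts[rec.id]
        row: dict[str, object] = {
            "sno_id": rec.id,
            "sno_length": rec.length,
            "box_score": box_scores[rec.id].total,
            "sno_stability": structure.loc[rec.id, "sno_stability"],
            "terminal_stem_stability": structure.loc[rec.id, "terminal_stem_stability"],
            "terminal_stem_length_score": structure.loc[
                rec.id, "terminal_stem_length_score"
            ],
            "sno_type": rec.sno_type,
            "host_expression_status": host_status[rec.id],
        }
        if ctx is not None:
            row.update(
                total_introns=ctx.total_introns,
                intron_length=ctx.intron_length,
                intron_rank_5p=ctx.rank_5p,
                relative_intron_rank_3p=ctx.relative_rank_3p,
                dist_upstream_exon=ctx.dist_upstream_exon,
                dist_downstream_exon=ctx.dist_downstream_exon,
                dist_branchpoint=ctx.dist_branchpoint,
            )
        label = labels[rec.id]
        row[LABEL_COLUMN] = int(label == EXPRESSED) if isinstance(label, str) else int(label)
        rows.append(row)

    table = pd.DataFrame(rows).set_index("sno_id")
    for col in metadata.columns:
        table[col] = metadata.loc[table.index, col]

    for col in _INTRON_FEATURES:
        if col not in table:
            table[col] = np.nan
        if table[col].isna().any():
            if impute == "zero":
                fill = 0.0
            elif impute == "median":
                med = table[col].median()
                fill = 0.0 if np.isnan(med) else med
            else:
                raise ValueError(f"unknown impute mode {impute!r}")
            table[col] = table[col].fillna(fill)

    ordered = NUMERIC_FEATURES + CATEGORICAL_FEATURES + [LABEL_COLUMN]
    return table[ordered]


def one_hot_encode(
    table: pd.DataFrame, categorical_cols: Sequence[str] | None = None
) -> FeatureTable:
    """One-hot encode the declared categorical columns.

    Each category becomes one binary column named after the category; the
    `intergenic` indicator, produced by every host-related parent, is
    collapsed into a single shared column. Category names clashing across
    parents (other than `intergenic`) are an error, as is an undeclared
    non-numeric column.
    """
    categorical_cols = list(categorical_cols or CATEGORICAL_FEATURES)
    numeric_cols = [
        c for c in table.columns if c not in categorical_cols and c != LABEL_COLUMN
    ]
    for col in numeric_cols:
        if not pd.api.types.is_numeric_dtype(table[col]):
            raise ValueError(f"column {col!r} is neither numeric nor declared categorical")

    data = table[numeric_cols].astype(float).copy()
    onehot_cols: list[str] = []
    parent_of: dict[str, str] = {}
    intergenic = pd.Series(False, index=table.index)
    has_intergenic = False
    for parent in categorical_cols:
        for cat in sorted(table[parent].astype(str).unique()):
            indicator = (table[parent].astype(str) == cat)
            if cat == INTERGENIC:
                intergenic |= indicator
                has_intergenic = True
                continue
            if cat in parent_of:
                raise ValueError(
                    f"category {cat!r} produced by both {parent_of[cat]!r} and {parent!r}"
                )
            data[cat] = indicator.astype(float)
            parent_of[cat] = parent
            onehot_cols.append(cat)
    if has_intergenic:
        data[INTERGENIC] = intergenic.astype(float)
        parent_of[INTERGENIC] = "shared"
        onehot_cols.append(INTERGENIC)

    if LABEL_COLUMN in table:
        data[LABEL_COLUMN] = table[LABEL_COLUMN].astype(int)
    return FeatureTable(data, numeric_cols, onehot_cols, parent_of)


def fit_scaler(training: pd.DataFrame, training_id: str = "") -> ScalingStats:
    """Column means and population variances of the training rows."""
    if len(training) < 2:
        raise ValueError("need at least 2 training rows to fit a scaler")
    return ScalingStats(training.mean(axis=0), training.var(axis=0, ddof=0), training_id)


def apply_scaler(stats: ScalingStats, rows: pd.DataFrame) -> pd.DataFrame:
    """Standardize rows with previously fitted statistics.

    Zero-variance columns scale to 0 (centered, not divided).
    """
    if list(rows.columns) != list(stats.mean.index):
        raise ValueError(
            f"column mismatch: {list(rows.columns)} vs {list(stats.mean.index)}"
        )
    sd = np.sqrt(stats.var)
    safe_sd = sd.replace(0.0, 1.0)
    return (rows - stats.mean) / safe_sd


def filter_redundant(
    table: pd.DataFrame, key_features: Sequence[str] = tuple(TOP4_FEATURES)
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop snoRNAs whose key-feature tuples are exact duplicates.

    Keeps the first representative in id order and returns the mapping of
    removed id -> kept id. Applied to cross-species cohorts to avoid large
    identical-copy families biasing accuracy.
    """
    missing = [k for k in key_features if k not in table.columns]
    if missing:
        raise ValueError(f"key features absent from table: {missing}")
    ordered = table.sort_index()
    keys = ordered[list(key_features)].apply(tuple, axis=1)
    first_of: dict[tuple, str] = {}
    keep: list[str] = []
    mapping: dict[str, str] = {}
    for sno_id, key in keys.items():
        if key in first_of:
            mapping[sno_id] = first_of[key]
        else:
            first_of[key] = sno_id
            keep.append(sno_id)
    return table.loc[keep], mapping
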