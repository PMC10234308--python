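"""Shapley-additive interpretation of the expression-status classifiers.

Per-feature signed contributions are computed against a background sample
of training rows on each model's decision score (log-odds margin for the
linear families, positive-class probability otherwise): closed form for
linear models, exact coalition enumeration for small feature counts, and
a seeded permutation-sampling approximation otherwise. All three routes
satisfy local accuracy: baseline + sum(contributions) equals the model
output for every row (exactly for the linear and exact routes, and by
telescoping construction for the sampling route).

Mean absolute contributions per (model, iteration) are turned into
predictive ranks (rank 1 = largest mean |contribution|) and aggregated
across models and iterations; per-snoRNA decision traces and motif-logo
entropy summaries complete the interpretability toolbox.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import factorial
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

RNA_ALPHABET = ("A", "C", "G", "U")


@dataclass
class AttributionMatrix:
    """Signed per-feature contributions for one model on a set of rows."""

    values: pd.DataFrame  # rows x features
    baseline: float  # expected model output over the background
    output: pd.Series  # model output per row

    def check_additivity(self, atol: float = 1e-6) -> None:
        resid = self.baseline + self.values.sum(axis=1) - self.output
        worst = float(np.abs(resid).max())
        if worst > atol:
            raise AssertionError(f"additivity violated: max residual {worst:.3g}")


@dataclass
class DecisionTrace:
    sno_id: str
    contributions: list[tuple[str, float]]  # ordered by |contribution| desc
    baseline: float
    output: float
    predicted_status: int


def _is_linear(model) -> bool:
    return isinstance(model, LogisticRegression) or (
        isinstance(model, SVC) and getattr(model, "kernel", None) == "linear"
    )


def score_function(model) -> Callable[[np.ndarray], np.ndarray]:
    """The monotone decision score attributed for a fitted model:
    decision_function margin where available, else positive-class
    probability."""
    if hasattr(model, "decision_function"):
        return lambda X: np.asarray(model.decision_function(X), dtype=float)
    pos = list(model.classes_).index(1)
    return lambda X: np.asarray(model.predict_proba(X)[:, pos], dtype=float)


def _linear_attribution(
    model, X: pd.DataFrame, background: pd.DataFrame
) -> AttributionMatrix:
    w = np.asarray(model.coef_).ravel()
    mu = background.to_numpy(dtype=float).mean(axis=0)
    contrib = (X.to_numpy(dtype=float) - mu) * w
    f = score_function(model)
    values = pd.DataFrame(contrib, index=X.index, columns=X.columns)
    baseline = float(f(pd.DataFrame([mu], columns=X.columns))[0])
    return AttributionMatrix(values, baseline, pd.Series(f(X), index=X.index))


def shapley_exact(
    f: Callable[[np.ndarray], np.ndarray], X: pd.DataFrame, background: pd.DataFrame
) -> AttributionMatrix:
    """Exact Shapley values by full coalition enumeration.

    The value of coalition S for row x is the mean of f over background
    rows with the S-features replaced by x's; cost is O(2^n_features).
    """
    Xv = X.to_numpy(dtype=float)
    bg = background.to_numpy(dtype=float)
    n_rows, n_feat = Xv.shape
    n_bg = bg.shape[0]
    fact = [factorial(k) for k in range(n_feat + 1)]

    # coalition value v(S) per row, for every subset bitmask
    v = np.empty((2**n_feat, n_rows))
    for mask in range(2**n_feat):
        sel = np.array([(mask >> j) & 1 for j in range(n_feat)], dtype=bool)
        z = np.repeat(bg[None, :, :], n_rows, axis=0)  # rows x bg x feat
        z[:, :, sel] = Xv[:, None, sel]
        v[mask] = f(z.reshape(n_rows * n_bg, n_feat)).reshape(n_rows, n_bg).mean(axis=1)

    phi = np.zeros((n_rows, n_feat))
    for j in range(n_feat):
        others = [k for k in range(n_feat) if k != j]
        for r in range(len(others) + 1):
            for combo in itertools.combinations(others, r):
                mask = sum(1 << k for k in combo)
                weight = fact[r] * fact[n_feat - r - 1] / fact[n_feat]
                phi[:, j] += weight * (v[mask | (1 << j)] - v[mask])

    values = pd.DataFrame(phi, index=X.index, columns=X.columns)
    baseline = float(v[0].mean()) if n_rows else float("nan")
    # v(empty) is row-independent; take row 0 defensively
    baseline = float(v[0, 0]) if n_rows else baseline
    return AttributionMatrix(values, baseline, pd.Series(v[-1], index=X.index))


def shapley_sampling(
    f: Callable[[np.ndarray], np.ndarray],
    X: pd.DataFrame,
    background: pd.DataFrame,
    n_samples: int = 16,
    seed: int = 0,
) -> AttributionMatrix:
    """Permutation-sampling Shapley approximation.

    Each sample draws one feature permutation and one background row,
    shared across all rows, and accumulates the marginal contribution of
    each feature along the permutation. The telescoping sum makes
    baseline + contributions equal f(x) exactly for every row.
    """
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(dtype=float)
    bg = background.to_numpy(dtype=float)
    n_rows, n_feat = Xv.shape
    phi = np.zeros((n_rows, n_feat))
    baseline_acc = 0.0
    for _ in range(n_samples):
        perm = rng.permutation(n_feat)
        b = bg[rng.integers(len(bg))]
        # walk the permutation: z_k has the first k features (perm order) from x
        z = np.repeat(b[None, None, :], n_rows, axis=0).repeat(n_feat + 1, axis=1)
        for k in range(1, n_feat + 1):
            z[:, k:, perm[k - 1]] = Xv[:, None, perm[k - 1]]
        vals = f(z.reshape(n_rows * (n_feat + 1), n_feat)).reshape(n_rows, n_feat + 1)
        phi[:, perm] += np.diff(vals, axis=1) / n_samples
        baseline_acc += vals[0, 0] / n_samples  # f(b), row-independent
    values = pd.DataFrame(phi, index=X.index, columns=X.columns)
    return AttributionMatrix(values, float(baseline_acc), pd.Series(f(Xv), index=X.index))


def attribute(
    model,
    X: pd.DataFrame,
    background: pd.DataFrame,
    seed: int = 0,
    n_samples: int = 16,
    exact_max_features: int = 8,
) -> AttributionMatrix:
    """Shapley-additive contributions of `model`'s decision score.

    Route: closed form for linear models; exact enumeration up to
    `exact_max_features` features; seeded permutation sampling beyond.
    """
    if list(X.columns) != list(background.columns):
        raise ValueError("feature mismatch between rows and background")
    if _is_linear(model):
        result = _linear_attribution(model, X, background)
    else:
        base = score_function(model)
        cols = list(X.columns)

        def f(arr):
            return base(pd.DataFrame(np.asarray(arr, dtype=float), columns=cols))

        if X.shape[1] <= exact_max_features:
            result = shapley_exact(f, X, background)
        else:
            result = shapley_sampling(f, X, background, n_samples, seed)
    result.check_additivity(1e-6)
    return result


def rank_features(
    matrices: Mapping[tuple[str, int], AttributionMatrix]
) -> pd.DataFrame:
    """Predictive ranks per (model family, iteration).

    Rank 1 is the feature with the largest mean absolute contribution;
    ties break by feature-name order. Returns a long-format, plot-ready
    frame (model, iteration, feature, mean_abs_contribution, rank).
    """
    rows = []
    for (family, iteration), matrix in sorted(matrices.items()):
        means = matrix.values.abs().mean(axis=0)
        order = sorted(means.index, key=lambda ft: (-means[ft], ft))
        ranks = {ft: r + 1 for r, ft in enumerate(order)}
        for ft in means.index:
            rows.append(
                {
                    "model": family,
                    "iteration": iteration,
                    "feature": ft,
                    "mean_abs_contribution": float(means[ft]),
                    "rank": ranks[ft],
                }
            )
    return pd.DataFrame(rows)


def aggregate_ranks(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate the rank distribution across models and iterations.

    Features are ordered by median rank, then mean rank, then name;
    `aggregate_rank` numbers that ordering from 1.
    """
    grouped = rank_table.groupby("feature")["rank"]
    summary = pd.DataFrame(
        {"median_rank": grouped.median(), "mean_rank": grouped.mean()}
    )
    summary = summary.sort_values(
        ["median_rank", "mean_rank", "feature"],
        key=lambda s: s if s.name != "feature" else s.astype(str),
    )
    summary["aggregate_rank"] = np.arange(1, len(summary) + 1)
    return summary


def decision_trace(
    model, row: pd.Series, background: pd.DataFrame, seed: int = 0, **kwargs
) -> DecisionTrace:
    """Per-snoRNA attribution trace, features ordered by |contribution|."""
    X = row.to_frame().T
    matrix = attribute(model, X, background, seed=seed, **kwargs)
    contribs = matrix.values.iloc[0]
    ordered = sorted(contribs.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    predicted = int(model.predict(X)[0])
    return DecisionTrace(
        sno_id=str(row.name),
        contributions=[(ft, float(val)) for ft, val in ordered],
        baseline=matrix.baseline,
        output=float(matrix.output.iloc[0]),
        predicted_status=predicted,
    )


@dataclass
class LogoStats:
    pfm: pd.DataFrame  # positions x alphabet, rows sum to 1
    entropy: pd.Series  # Shannon entropy (bits) per position
    cumulative_entropy: float
    proportion_found: float | None


def motif_logo_stats(
    instances: Sequence[str], n_total: int | None = None
) -> LogoStats:
    """Position frequency matrix and cumulative Shannon entropy of aligned
    motif instances; `n_total` (if given) yields the proportion of
    snoRNAs in which the motif was found."""
    if not instances:
        raise ValueError("no motif instances")
    lengths = {len(s) for s in instances}
    if len(lengths) > 1:
        raise ValueError(f"motif instances of unequal lengths: {sorted(lengths)}")
    (L,) = lengths
    counts = np.zeros((L, len(RNA_ALPHABET)))
    lookup = {nt: k for k, nt in enumerate(RNA_ALPHABET)}
    for seq in instances:
        for pos, nt in enumerate(seq):
            if nt not in lookup:
                raise ValueError(f"non-RNA character {nt!r} in motif instance")
            counts[pos, lookup[nt]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = pd.Series(-plogp.sum(axis=1), name="entropy_bits")
    pfm = pd.DataFrame(freqs, columns=list(RNA_ALPHABET))
    proportion = len(instances) / n_total if n_total else None
    return LogoStats(pfm, entropy, float(entropy.sum()), proportion)


def position_frequency_ks(
    instances_a: Sequence[str], instances_b: Sequence[str]
) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov comparison of per-position nucleotide
    distributions between two sets of aligned motif instances (nucleotides
    encoded on the fixed A<C<G<U ordinal scale; a coarse screen for
    position-wise composition shifts)."""
    la = {len(s) for s in instances_a} | {len(s) for s in instances_b}
    if len(la) != 1:
        raise ValueError("instances must share one length")
    lookup = {nt: k for k, nt in enumerate(RNA_ALPHABET)}
    rows = []
    for pos in range(la.pop()):
        a = np.array([lookup[s[pos]] for s in instances_a])
        b = np.array([lookup[s[pos]] for s in instances_b])
        stat, p = scipy_stats.ks_2samp(a, b)
        rows.append({"position": pos, "statistic": float(stat), "pvalue": float(p)})
    return pd.DataFrame(rows)
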