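"""Population-level admixture summaries from Bayesian-clustering output.

Consumes externally produced individual cluster-proportion matrices
(Q-matrices) and DIC-versus-K tables, and produces the quantity the
attribution models use as the admixture predictor: Simpson's diversity index
``D = 1 - sum q_k^2`` over a population's mean cluster proportions
(0 for a pure population, approaching ``1 - 1/K`` for even admixture).

Replicate clustering runs are assumed label-aligned upstream; a column
permutation check merely warns when replicates look misaligned.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "QMatrix",
    "population_mean_q",
    "average_replicates",
    "simpson_index",
    "select_k_plateau",
]


class QMatrix:
    """Individuals x clusters admixture proportions with population labels.

    Backed by a DataFrame with columns ``population``, ``individual`` and one
    ``q<k>`` column per cluster; every row sums to 1 (checked to 1e-6).
    """

    def __init__(self, df: pd.DataFrame):
        if "population" not in df.columns or "individual" not in df.columns:
            raise ValueError("QMatrix needs 'population' and 'individual' columns")
        q_cols = [c for c in df.columns if c.startswith("q")]
        if not q_cols:
            raise ValueError("QMatrix needs at least one q<k> column")
        q = df[q_cols].to_numpy(dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("admixture proportions must lie in [0, 1]")
        if np.any(np.abs(q.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("QMatrix rows must sum to 1 within 1e-6")
        self.df = df[["population", "individual", *q_cols]].reset_index(drop=True)
        self.q_cols = q_cols

    @property
    def k(self) -> int:
        return len(self.q_cols)

    @property
    def values(self) -> np.ndarray:
        return self.df[self.q_cols].to_numpy(dtype=float)


def population_mean_q(q: QMatrix) -> pd.DataFrame:
    """Mean cluster proportions per population (rows renormalised to sum 1).

    Returns a DataFrame indexed by population with the ``q<k>`` columns —
    the per-population cluster frequencies drawn as map pie charts.
    """
    means = q.df.groupby("population", sort=False)[q.q_cols].mean()
    sums = means.sum(axis=1)
    empty = sums <= 0
    if empty.any():
        warnings.warn(f"populations with no usable rows excluded: {list(means.index[empty])}")
        means = means[~empty]
        sums = sums[~empty]
    return means.div(sums, axis=0)


def _alignment_warning(q_runs: list[QMatrix]) -> None:
    """Warn when replicate columns look label-switched.

    For each run after the first, the column matching that maximises the mean
    correlation with the first run should be the identity permutation.
    """
    ref = q_runs[0].values
    for i, run in enumerate(q_runs[1:], start=2):
        cur = run.values
        k = ref.shape[1]
        corr = np.zeros((k, k))
        for a in range(k):
            for b in range(k):
                sa, sb = np.std(ref[:, a]), np.std(cur[:, b])
                if sa > 0 and sb > 0:
                    corr[a, b] = np.corrcoef(ref[:, a], cur[:, b])[0, 1]
        best = corr.argmax(axis=1)
        if not np.array_equal(best, np.arange(k)):
            warnings.warn(
                f"replicate {i} may be label-switched relative to replicate 1 "
                f"(best column matching {best.tolist()}); align replicates upstream"
            )


def average_replicates(q_runs: list[QMatrix], dic: list[float], top_m: int = 10) -> QMatrix:
    """Element-wise mean of the ``top_m`` lowest-DIC replicate Q-matrices."""
    if len(q_runs) != len(dic):
        raise ValueError("one DIC value per run required")
    if not q_runs:
        raise ValueError("no runs supplied")
    ks = {r.k for r in q_runs}
    if len(ks) > 1:
        raise ValueError(f"runs disagree on K: {sorted(ks)}")
    ids = {tuple(map(tuple, r.df[["population", "individual"]].to_numpy())) for r in q_runs}
    if len(ids) > 1:
        raise ValueError("runs do not share individuals")
    if len(q_runs) < top_m:
        warnings.warn(f"only {len(q_runs)} runs available; averaging all of them")
        top_m = len(q_runs)
    order = np.argsort(np.asarray(dic, dtype=float), kind="stable")[:top_m]
    chosen = [q_runs[i] for i in order]
    if len(chosen) > 1:
        _alignment_warning(chosen)
    mean = np.mean([r.values for r in chosen], axis=0)
    mean /= mean.sum(axis=1, keepdims=True)
    out = chosen[0].df.copy()
    out[chosen[0].q_cols] = mean
    return QMatrix(out)


def simpson_index(proportions) -> float:
    """Simpson's diversity index ``D = 1 - sum q_k^2`` of cluster proportions."""
    q = np.asarray(list(proportions), dtype=float)
    if np.any(q < 0):
        raise ValueError("proportions must be non-negative")
    if abs(q.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions must sum to 1 (got {q.sum():.6f})")
    return float(1.0 - np.sum(q**2))


def population_simpson(q: QMatrix) -> pd.Series:
    """Per-population Simpson index of the mean cluster proportions."""
    mean_q = population_mean_q(q)
    return mean_q.apply(lambda row: simpson_index(row.to_numpy()), axis=1).rename("simpson")


def select_k_plateau(dic_table: pd.DataFrame, epsilon: float = 0.05) -> int:
    """Choose the number of clusters where the mean DIC curve plateaus.

    ``dic_table`` has columns (K, replicate, dic).  Mean DIC is computed per
    K; the plateau K is the smallest K whose improvement to K+1 falls below
    ``epsilon * (max mean - min mean)``.  If the curve keeps declining
    steeply, the largest K is returned with a warning.
    """
    required = {"K", "dic"}
    if not required <= set(dic_table.columns):
        raise ValueError(f"DIC table needs columns {required}")
    means = dic_table.groupby("K")["dic"].mean().sort_index()
    if len(means) < 3:
        raise ValueError("plateau selection needs at least 3 distinct K values")
    spread = means.max() - means.min()
    if spread <= 0:
        return int(means.index[0])
    ks = means.index.to_numpy()
    vals = means.to_numpy()
    improvements = vals[:-1] - vals[1:]
    if np.any(improvements < 0):
        warnings.warn("mean DIC is not monotone decreasing in K")
    for i, imp in enumerate(improvements):
        if imp < epsilon * spread:
            return int(ks[i])
    warnings.warn("DIC declined steeply throughout; returning the largest K")
    return int(ks[-1])
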