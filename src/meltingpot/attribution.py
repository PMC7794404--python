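"""Attribution of diversity patterns: predictor table, Gaussian GLMs, AIC.

Given per-population diversity responses (rarefied allelic richness ``Ar``,
expected heterozygosity ``He``) and three candidate drivers — the Simpson
admixture index, distance to the nearest glacial refugium and distance to
the nearest stability area — this module fits the fixed set of Gaussian
GLMs (identity link, i.e. ordinary least squares)

    resp ~ stability + refugia + simpson
    resp ~ stability + simpson
    resp ~ refugia + simpson
    resp ~ stability
    resp ~ refugia
    resp ~ simpson

for each response, reports coefficient t-tests, sequential (Type I) ANOVA in
formula order, and ranks models by AIC.  AIC uses the convention that counts
the Gaussian variance parameter and keeps the additive constant:

    AIC = n * ln(2 * pi * RSS / n) + n + 2 * (k + 2)

with ``k`` slopes plus intercept, so rankings are comparable with standard
GLM software output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import BinaryMap, point_distance

__all__ = [
    "OLSFit",
    "ModelComparison",
    "nearest_distance",
    "build_predictor_table",
    "fit_gaussian_glm",
    "anova_sequential",
    "run_model_set",
    "subset_populations",
    "MODEL_SET",
]

PREDICTOR_ORDER = ["stability", "refugia", "simpson"]
MODEL_SET = [
    ["stability", "refugia", "simpson"],
    ["stability", "simpson"],
    ["refugia", "simpson"],
    ["stability"],
    ["refugia"],
    ["simpson"],
]


class RankDeficientDesignError(np.linalg.LinAlgError):
    pass


def nearest_distance(point: tuple[float, float], mask: BinaryMap) -> float:
    """Distance (km) from a point to the nearest cell marked 1 in the mask.

    Zero when the point's own cell is marked.  Planar on projected grids,
    great-circle on lon/lat grids.
    """
    geom = mask.geometry
    ones = np.argwhere(mask.mask & (mask.values == 1))
    if len(ones) == 0:
        raise ValueError("mask has no marked cells")
    x, y = point
    row, col = geom.cell_of(x, y)
    if 0 <= row < geom.rows and 0 <= col < geom.cols and mask.values[row, col] == 1:
        return 0.0
    cx, cy = geom.cell_center(ones[:, 0], ones[:, 1])
    return float(np.min(point_distance(x, y, cx, cy, geom.projected)))


def build_predictor_table(
    populations: pd.DataFrame,
    simpson: pd.Series,
    refugia_mask: BinaryMap,
    stability_mask: BinaryMap | None = None,
) -> pd.DataFrame:
    """Assemble the per-population design table.

    ``populations`` needs columns (population, x, y); ``simpson`` is indexed
    by population.  Output columns: population, simpson, refugia (km to the
    nearest refugium cell), stability (km to the nearest stability cell).
    """
    rows = []
    for _, rec in populations.iterrows():
        pop = rec["population"]
        entry = {
            "population": pop,
            "simpson": float(simpson.loc[pop]) if pop in simpson.index else np.nan,
            "refugia": nearest_distance((rec["x"], rec["y"]), refugia_mask),
        }
        if stability_mask is not None:
            entry["stability"] = nearest_distance((rec["x"], rec["y"]), stability_mask)
        rows.append(entry)
    return pd.DataFrame(rows)


@dataclass
class OLSFit:
    """A fitted Gaussian GLM: coefficients, tests, RSS, df and AIC."""

    formula: str
    response: str
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rss: float
    df_resid: int
    aic: float
    n: int
    anova: pd.DataFrame | None = None
    _design: np.ndarray | None = field(default=None, repr=False)
    _y: np.ndarray | None = field(default=None, repr=False)


def fit_gaussian_glm(y, X: pd.DataFrame, response_name: str = "y") -> OLSFit:
    """Ordinary least squares with intercept (Gaussian GLM, identity link).

    ``X`` holds the slope columns in formula order (no intercept column).
    Raises on rank-deficient designs, naming the aliased columns.
    """
    y = np.asarray(y, dtype=float)
    terms = list(X.columns)
    n = len(y)
    k = len(terms)
    if n <= k + 1:
        raise ValueError(f"n={n} observations cannot identify {k + 1} coefficients")
    zero_var = [c for c in terms if np.std(X[c].to_numpy(dtype=float)) == 0]
    if zero_var:
        raise RankDeficientDesignError(f"constant (zero-variance) predictors: {zero_var}")
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        aliased = []
        cols = [np.ones(n)]
        for name in terms:
            trial = np.column_stack(cols + [X[name].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                cols.append(X[name].to_numpy(dtype=float))
            else:
                aliased.append(name)
        raise RankDeficientDesignError(f"design is rank-deficient; aliased columns: {aliased}")

    import statsmodels.api as sm

    res = sm.OLS(y, design).fit()
    rss = float(res.ssr)
    df_resid = int(res.df_resid)
    # Gaussian AIC counting intercept, slopes and the variance parameter
    aic = n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (k + 2.0)
    names = ["intercept", *terms]
    formula = f"{response_name} ~ " + " + ".join(terms)
    return OLSFit(
        formula=formula,
        response=response_name,
        terms=terms,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        rss=rss,
        df_resid=df_resid,
        aic=float(aic),
        n=n,
        _design=design,
        _y=y,
    )


def anova_sequential(fit: OLSFit) -> pd.DataFrame:
    """Type I (sequential) ANOVA in formula order.

    Terms are added one at a time; each term's SS is the drop in residual sum
    of squares, tested against the full model's residual mean square.
    """
    if fit._design is None or fit._y is None:
        raise ValueError("fit does not carry its design matrix")
    y = fit._y
    design = fit._design
    n = len(y)

    def rss_of(cols: int) -> float:
        beta, _, _, _ = np.linalg.lstsq(design[:, :cols], y, rcond=None)
        resid = y - design[:, :cols] @ beta
        return float(resid @ resid)

    rows = []
    prev = rss_of(1)  # intercept-only
    mse = fit.rss / fit.df_resid
    for j, term in enumerate(fit.terms, start=2):
        cur = rss_of(j)
        ss = prev - cur
        f = (ss / 1.0) / mse
        p = float(stats.f.sf(f, 1, fit.df_resid))
        rows.append({"term": term, "df": 1, "df_resid": fit.df_resid, "F": f, "p": p})
        prev = cur
    return pd.DataFrame(rows)


@dataclass
class ModelComparison:
    """Per-response fits ranked by AIC."""

    fits: dict[str, list[OLSFit]]

    def best(self, response: str) -> OLSFit:
        return self.fits[response][0]

    def summary(self) -> pd.DataFrame:
        rows = []
        for response, fits in self.fits.items():
            for rank, fit in enumerate(fits, start=1):
                for name in fit.params.index:
                    rows.append(
                        {
                            "response": response,
                            "model": fit.formula,
                            "AIC": fit.aic,
                            "rank": rank,
                            "term": name,
                            "estimate": fit.params[name],
                            "p_t": fit.pvalues[name],
                        }
                    )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out: dict = {}
        for response, fits in self.fits.items():
            out[response] = [
                {
                    "model": f.formula,
                    "AIC": f.aic,
                    "coefficients": {
                        k: {
                            "estimate": float(f.params[k]),
                            "se": float(f.bse[k]),
                            "t": float(f.tvalues[k]),
                            "p": float(f.pvalues[k]),
                        }
                        for k in f.params.index
                    },
                    "anova": f.anova.to_dict(orient="records") if f.anova is not None else None,
                }
                for f in fits
            ]
        return out


def _with_interactions(terms: list[str], table: pd.DataFrame) -> tuple[list[str], pd.DataFrame]:
    X = table[terms].copy()
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            name = f"{terms[i]}:{terms[j]}"
            X[name] = table[terms[i]] * table[terms[j]]
    return list(X.columns), X


def run_model_set(
    responses: pd.DataFrame,
    predictors: pd.DataFrame,
    include_interactions: bool = False,
    response_names: tuple[str, ...] = ("Ar", "He"),
) -> ModelComparison:
    """Fit the fixed model set for each diversity response and rank by AIC.

    ``responses`` (population, Ar, He, ...) and ``predictors`` (population,
    simpson, refugia, stability) are joined on population; a join mismatch is
    an error listing the unmatched populations.  ``include_interactions``
    appends a model with all two-way interactions of the three predictors.
    """
    merged = responses.merge(predictors, on="population", how="outer", indicator=True)
    unmatched = merged.loc[merged["_merge"] != "both", "population"].tolist()
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    merged = merged.dropna(subset=[c for c in PREDICTOR_ORDER if c in merged.columns])
    if unmatched:
        raise ValueError(f"populations present in only one table: {unmatched}")
    if len(merged) < 8:
        raise ValueError(f"only {len(merged)} populations after joining; need >= 8")

    fits: dict[str, list[OLSFit]] = {}
    for response in response_names:
        sub = merged.dropna(subset=[response])
        model_fits = []
        for terms in MODEL_SET:
            fit = fit_gaussian_glm(sub[response], sub[terms], response_name=response)
            fit.anova = anova_sequential(fit)
            model_fits.append(fit)
        if include_interactions:
            terms, X = _with_interactions(MODEL_SET[0], sub)
            fit = fit_gaussian_glm(sub[response], X, response_name=response)
            fit.anova = anova_sequential(fit)
            model_fits.append(fit)
        model_fits.sort(key=lambda f: f.aic)
        fits[response] = model_fits
    return ModelComparison(fits)


def subset_populations(table: pd.DataFrame, include_ids) -> pd.DataFrame:
    """Row filter on population id, preserving order (geographic restriction)."""
    include = set(include_ids)
    missing = include - set(table["population"])
    if missing:
        warnings.warn(f"requested populations absent from the table: {sorted(missing)}")
    out = table[table["population"].isin(include)]
    if out.empty:
        raise ValueError("subset selection matched no populations")
    return out.reset_index(drop=True)
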