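"""Ensemble species-distribution modelling for refugia inference.

The workflow mirrors standard ensemble-forecasting practice for presence-only
data:

1. occurrence hygiene (duplicate and high-uncertainty records removed),
2. spatial thinning to a minimum nearest-neighbour distance, replicated to
   produce alternative calibration datasets,
3. variance-inflation-factor (VIF) pruning of collinear climate layers,
4. target-group background selection,
5. fitting several learner classes on every thinned replicate, validating
   each fit by AUC on the occurrences excluded by that replicate's thinning,
6. an AUC-weighted ensemble over all fits with AUC above a cutoff, and a
   maxTSS threshold to turn ensemble suitability into presence/absence.

Learners plug in through :class:`LearnerContract`; the built-in classes are a
binomial GLM with logit link (IRLS, optionally with quadratic terms) and a
gradient-boosted classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .grid import BinaryMap, EnvStack, Raster, point_distance

__all__ = [
    "OccurrenceSet",
    "LearnerContract",
    "LogisticLearner",
    "GradientBoostingLearner",
    "EnsembleModel",
    "clean_occurrences",
    "thin_occurrences",
    "vif_select",
    "target_group_background",
    "auc",
    "max_tss_threshold",
    "fit_ensemble",
    "project",
    "binarize",
]


@dataclass
class OccurrenceSet:
    """Presence points: columns x, y plus optional source and
    uncertainty_arcsec.  ``projected=True`` means x/y are km on a planar
    grid, otherwise lon/lat degrees."""

    points: pd.DataFrame
    projected: bool = True

    def __post_init__(self):
        df = self.points.copy()
        if not {"x", "y"} <= set(df.columns):
            raise ValueError("occurrence points need 'x' and 'y' columns")
        for col in ("source", "uncertainty_arcsec"):
            if col not in df.columns:
                df[col] = np.nan
        self.points = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        return self.points[["x", "y"]].to_numpy(dtype=float)


def clean_occurrences(raw: OccurrenceSet, max_uncertainty_arcsec: float = 30.0) -> OccurrenceSet:
    """Remove exact coordinate duplicates and records whose positional
    uncertainty is at or above ``max_uncertainty_arcsec``."""
    df = raw.points
    unc = df["uncertainty_arcsec"].to_numpy(dtype=float)
    keep = ~(np.isfinite(unc) & (unc >= max_uncertainty_arcsec))
    df = df[keep]
    df = df.drop_duplicates(subset=["x", "y"], keep="first")
    if df.empty:
        raise ValueError("no occurrence records survive cleaning")
    return OccurrenceSet(df.reset_index(drop=True), projected=raw.projected)


def _pairwise_distances(xy: np.ndarray, projected: bool) -> np.ndarray:
    n = len(xy)
    d = np.zeros((n, n))
    for i in range(n):
        d[i] = point_distance(xy[i, 0], xy[i, 1], xy[:, 0], xy[:, 1], projected)
    return d


def thin_occurrences(
    points: OccurrenceSet, d_min: float, n_datasets: int = 5, seed: int = 0
) -> list[tuple[OccurrenceSet, OccurrenceSet]]:
    """Spatially thin occurrences to a minimum nearest-neighbour distance.

    Greedy: while any pair is closer than ``d_min``, drop the point with the
    most conflicts, breaking ties at random (per replicate).  Returns
    ``n_datasets`` (retained, excluded) pairs; the excluded points are used
    downstream for validation.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    xy = points.xy
    dist = _pairwise_distances(xy, points.projected)
    np.fill_diagonal(dist, np.inf)
    conflict = dist < d_min
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_datasets):
        alive = np.ones(len(xy), dtype=bool)
        degree = conflict.sum(axis=1).astype(float)
        while True:
            deg_alive = np.where(alive, degree, -1.0)
            dmax = deg_alive.max()
            if dmax <= 0:
                break
            ties = np.flatnonzero(deg_alive == dmax)
            drop = int(rng.choice(ties))
            alive[drop] = False
            degree[conflict[drop]] -= 1
            degree[drop] = 0.0
        retained = points.points[alive].reset_index(drop=True)
        excluded = points.points[~alive].reset_index(drop=True)
        if len(retained) < 2:
            warnings.warn(f"thinning at d_min={d_min} left {len(retained)} point(s)")
        out.append(
            (
                OccurrenceSet(retained, projected=points.projected),
                OccurrenceSet(excluded, projected=points.projected),
            )
        )
    return out


def vif_select(env_values: pd.DataFrame, threshold: float = 5.0) -> list[str]:
    """Iteratively drop the variable with the largest variance inflation
    factor until every VIF is below ``threshold``; survivors keep input order.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing variable j (with intercept)
    on the remaining variables; perfect collinearity counts as infinite.
    """
    cols = list(env_values.columns)
    if len(cols) < 2:
        raise ValueError("VIF selection needs at least 2 variables")
    X_all = env_values.to_numpy(dtype=float)
    if X_all.shape[0] <= X_all.shape[1]:
        raise ValueError("VIF selection needs more rows than variables")
    active = cols.copy()
    while len(active) >= 2:
        vifs = {}
        for j, name in enumerate(active):
            others = [c for c in active if c != name]
            y = env_values[name].to_numpy(dtype=float)
            X = np.column_stack([np.ones(len(y))] + [env_values[c].to_numpy(dtype=float) for c in others])
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            ss_tot = np.sum((y - y.mean()) ** 2)
            if ss_tot == 0:
                vifs[name] = np.inf
                continue
            r2 = 1.0 - np.sum(resid**2) / ss_tot
            vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        # ties on VIF (e.g. a correlated pair) drop the later variable,
        # keeping the earliest-listed of the pair
        worst = max(vifs, key=lambda k: (vifs[k], active.index(k)))
        if vifs[worst] < threshold:
            break
        active.remove(worst)
    return active


def target_group_background(target_group: OccurrenceSet, region_mask: BinaryMap) -> OccurrenceSet:
    """Background points from target-group records inside the region mask,
    de-duplicated to one record per grid cell."""
    if len(target_group) == 0:
        raise ValueError("empty target group")
    geom = region_mask.geometry
    rows_cols = []
    keep_idx = []
    for idx, (x, y) in enumerate(target_group.xy):
        row, col = geom.cell_of(x, y)
        if 0 <= row < geom.rows and 0 <= col < geom.cols and region_mask.values[row, col] == 1:
            rows_cols.append((row, col))
            keep_idx.append(idx)
    if not keep_idx:
        raise ValueError("no target-group record falls inside the region mask")
    df = target_group.points.iloc[keep_idx].copy()
    df["_cell"] = rows_cols
    df = df.drop_duplicates(subset="_cell").drop(columns="_cell")
    return OccurrenceSet(df.reset_index(drop=True), projected=target_group.projected)


def auc(scores_presence, scores_background) -> float:
    """Rank AUC: probability a presence outscores a background point (ties 1/2)."""
    pres = np.asarray(list(scores_presence), dtype=float)
    back = np.asarray(list(scores_background), dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("both score groups must be non-empty")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pres, back]))
    r_pres = ranks[: pres.size].sum()
    u = r_pres - pres.size * (pres.size + 1) / 2.0
    return float(u / (pres.size * back.size))


def max_tss_threshold(scores_presence, scores_background) -> tuple[float, float]:
    """Threshold maximising the true skill statistic.

    Candidates are the unique observed scores; a point is predicted present
    iff its score >= threshold; ``TSS = sensitivity + specificity - 1``.
    Returns (smallest maximising threshold, its TSS).
    """
    pres = np.asarray(list(scores_presence), dtype=float)
    back = np.asarray(list(scores_background), dtype=float)
    if pres.size == 0 or back.size == 0:
        raise ValueError("both score groups must be non-empty")
    best_t, best_tss = np.inf, -np.inf
    for t in np.unique(np.concatenate([pres, back])):
        sens = np.mean(pres >= t)
        spec = np.mean(back < t)
        tss = sens + spec - 1.0
        if tss > best_tss or (tss == best_tss and t < best_t):
            best_t, best_tss = float(t), float(tss)
    return best_t, best_tss


# ---------------------------------------------------------------------------
# Learners


@runtime_checkable
class LearnerContract(Protocol):
    """Minimal learner interface: probabilistic binary classifier."""

    name: str

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LearnerContract": ...

    def predict_probability(self, X: np.ndarray) -> np.ndarray: ...

    def clone(self) -> "LearnerContract": ...


class LogisticLearner:
    """Binomial GLM with logit link fitted by IRLS; optional quadratic terms.

    Features are standardised on the training data.  If IRLS fails (e.g.
    perfect separation), a ridge-penalised logistic fit takes over.
    """

    def __init__(self, quadratic: bool = False):
        self.quadratic = quadratic
        self.name = "glm_quadratic" if quadratic else "glm"
        self._params = None

    def clone(self) -> "LogisticLearner":
        return LogisticLearner(self.quadratic)

    def _expand(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self._mu) / self._sigma
        if self.quadratic:
            Z = np.column_stack([Z, Z**2])
        return np.column_stack([np.ones(len(Z)), Z])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LogisticLearner":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._mu = X.mean(axis=0)
        self._sigma = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Z = self._expand(X)
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(y, Z, family=sm.families.Binomial()).fit(maxiter=100)
            beta = np.asarray(res.params)
            if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e4:
                raise ValueError("IRLS diverged")
        except Exception:
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(C=10.0, max_iter=1000)
            lr.fit(Z[:, 1:], y)
            beta = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        self._params = beta
        return self

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        if self._params is None:
            raise RuntimeError("learner is not fitted")
        eta = self._expand(np.asarray(X, dtype=float)) @ self._params
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))


class GradientBoostingLearner:
    """Gradient-boosted classification trees (second model class)."""

    def __init__(self, n_estimators: int = 100, max_depth: int = 2, random_state: int = 0):
        self.name = "gbm"
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.random_state = random_state
        self._model = None

    def clone(self) -> "GradientBoostingLearner":
        return GradientBoostingLearner(self.n_estimators, self.max_depth, self.random_state)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GradientBoostingLearner":
        from sklearn.ensemble import GradientBoostingClassifier

        self._model = GradientBoostingClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            random_state=self.random_state,
        )
        self._model.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        return self

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        if self._model is None:
            raise RuntimeError("learner is not fitted")
        return self._model.predict_proba(np.asarray(X, dtype=float))[:, 1]


def default_learners() -> list[LearnerContract]:
    return [LogisticLearner(quadratic=False), LogisticLearner(quadratic=True), GradientBoostingLearner()]


# ---------------------------------------------------------------------------
# Ensemble


@dataclass
class FittedMember:
    learner: LearnerContract
    replicate: int
    auc: float
    included: bool
    weight: float = 0.0


@dataclass
class EnsembleModel:
    """AUC-weighted ensemble of learner fits plus the maxTSS threshold."""

    members: list[FittedMember]
    variables: list[str]
    threshold: float
    tss: float
    auc_cutoff: float = 0.7
    report: dict = field(default_factory=dict)

    @property
    def included(self) -> list[FittedMember]:
        return [m for m in self.members if m.included]

    def predict(self, X: np.ndarray) -> np.ndarray:
        members = self.included
        preds = np.array([m.learner.predict_probability(X) for m in members])
        w = np.array([m.weight for m in members])
        return preds.T @ w


def _env_at_points(env: EnvStack, occ: OccurrenceSet, variables) -> np.ndarray:
    geom = env.geometry
    rows, cols = [], []
    for x, y in occ.xy:
        r, c = geom.cell_of(x, y)
        r = int(np.clip(r, 0, geom.rows - 1))
        c = int(np.clip(c, 0, geom.cols - 1))
        rows.append(r)
        cols.append(c)
    return env.design_matrix(rows, cols, variables)


def _fresh_background(env, variables, exclude_cells, n, rng):
    """Seeded sample of valid cells disjoint from the training background."""
    mask = env.valid_mask(variables)
    cells = np.argwhere(mask)
    keep = [tuple(rc) for rc in cells if tuple(rc) not in exclude_cells]
    if not keep:
        keep = [tuple(rc) for rc in cells]
    idx = rng.choice(len(keep), size=min(n, len(keep)), replace=False)
    chosen = [keep[i] for i in idx]
    rows = [rc[0] for rc in chosen]
    cols = [rc[1] for rc in chosen]
    return env.design_matrix(rows, cols, variables)


def fit_ensemble(
    thinned_sets: list[tuple[OccurrenceSet, OccurrenceSet]],
    background: OccurrenceSet,
    env: EnvStack,
    learners: list[LearnerContract] | None = None,
    auc_cutoff: float = 0.7,
    variables: list[str] | None = None,
    seed: int = 0,
    n_validation_background: int = 200,
) -> EnsembleModel:
    """Fit every learner on every thinned replicate and assemble the
    AUC-weighted ensemble.

    Each fit is validated on the presences *excluded* by its replicate's
    thinning, scored against a fresh seeded background sample disjoint from
    the training background (AUC needs an absence class; the emulated
    workflow validates only with excluded presences).  Fits with AUC > ``auc_cutoff``
    enter the ensemble with weights proportional to AUC; the maxTSS threshold
    is computed on ensemble predictions at all retained presences versus the
    training background.
    """
    if not thinned_sets:
        raise ValueError("at least one thinned dataset required")
    learners = learners if learners is not None else default_learners()
    if not learners:
        raise ValueError("at least one learner required")
    variables = list(variables) if variables is not None else env.names
    rng = np.random.default_rng(seed)

    X_back = _env_at_points(env, background, variables)
    back_cells = set()
    geom = env.geometry
    for x, y in background.xy:
        back_cells.add(geom.cell_of(x, y))

    members: list[FittedMember] = []
    for rep, (retained, excluded) in enumerate(thinned_sets):
        X_pres = _env_at_points(env, retained, variables)
        X_train = np.vstack([X_pres, X_back])
        y_train = np.concatenate([np.ones(len(X_pres)), np.zeros(len(X_back))])
        if len(excluded) == 0:
            warnings.warn(
                f"replicate {rep}: thinning excluded no points; validating on the training presences"
            )
            X_val_pres = X_pres
        else:
            X_val_pres = _env_at_points(env, excluded, variables)
        X_val_back = _fresh_background(
            env, variables, back_cells, max(n_validation_background, len(X_val_pres)), rng
        )
        for proto in learners:
            learner = proto.clone()
            learner.fit(X_train, y_train)
            a = auc(learner.predict_probability(X_val_pres), learner.predict_probability(X_val_back))
            members.append(FittedMember(learner, rep, a, included=a > auc_cutoff))

    included = [m for m in members if m.included]
    if not included:
        raise ValueError(
            "no model passed the AUC cutoff; AUCs: "
            + ", ".join(f"{m.learner.name}/rep{m.replicate}={m.auc:.3f}" for m in members)
        )
    total = sum(m.auc for m in included)
    for m in included:
        m.weight = m.auc / total

    model = EnsembleModel(members, variables, threshold=np.nan, tss=np.nan, auc_cutoff=auc_cutoff)
    all_pres = pd.concat([t[0].points for t in thinned_sets]).drop_duplicates(subset=["x", "y"])
    X_all_pres = _env_at_points(
        env, OccurrenceSet(all_pres, projected=thinned_sets[0][0].projected), variables
    )
    thr, tss = max_tss_threshold(model.predict(X_all_pres), model.predict(X_back))
    model.threshold = thr
    model.tss = tss
    model.report = {
        "n_members": len(members),
        "n_included": len(included),
        "aucs": {f"{m.learner.name}/rep{m.replicate}": m.auc for m in members},
        "weights": {f"{m.learner.name}/rep{m.replicate}": m.weight for m in included},
        "threshold": thr,
        "tss": tss,
        "variables": variables,
        "seed": seed,
    }
    return model


def project(model: EnsembleModel, env_scenario: EnvStack) -> Raster:
    """Per-cell ensemble suitability on a climate scenario; nodata propagated."""
    missing = [v for v in model.variables if v not in env_scenario]
    if missing:
        raise KeyError(f"scenario is missing layers: {missing}")
    geom = env_scenario.geometry
    mask = env_scenario.valid_mask(model.variables)
    out = np.full((geom.rows, geom.cols), -9999.0)
    rows, cols = np.nonzero(mask)
    if len(rows):
        X = env_scenario.design_matrix(rows, cols, model.variables)
        out[rows, cols] = model.predict(X)
    return Raster(geom, out, nodata=-9999.0)


def binarize(suitability: Raster, threshold: float) -> BinaryMap:
    """Threshold a suitability raster: cell = 1 iff suitability >= threshold."""
    vals = np.where(suitability.mask, (suitability.values >= threshold).astype(float), suitability.nodata)
    return BinaryMap(suitability.geometry, vals, nodata=suitability.nodata)
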