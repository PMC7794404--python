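"""SDM machinery: hygiene, thinning, VIF, AUC/TSS, ensemble, consensus."""

import itertools

import numpy as np
import pandas as pd
import pytest

from meltingpot.grid import EnvStack, GridGeometry, Raster
from meltingpot.refugia import AncestralArea, gcm_consensus, stability_areas
from meltingpot.sdm import (
    OccurrenceSet,
    auc,
    binarize,
    clean_occurrences,
    fit_ensemble,
    max_tss_threshold,
    project,
    target_group_background,
    thin_occurrences,
    vif_select,
)

from conftest import make_binary


def occ(points, projected=True, **extra):
    df = pd.DataFrame(points, columns=["x", "y"])
    for k, v in extra.items():
        df[k] = v
    return OccurrenceSet(df, projected=projected)


# ---------------------------------------------------------------------------
# hygiene and thinning


def test_clean_removes_duplicates_and_uncertain_records():
    o = occ([(0, 0), (0, 0), (1, 1), (2, 2)], uncertainty_arcsec=[np.nan, np.nan, 45.0, 10.0])
    cleaned = clean_occurrences(o, max_uncertainty_arcsec=30)
    assert len(cleaned) == 2
    assert (1, 1) not in {tuple(p) for p in cleaned.xy}


def test_clean_identity_on_clean_input():
    o = occ([(0, 0), (5, 5)])
    assert len(clean_occurrences(o)) == 2


def test_thin_identity_when_all_far():
    o = occ([(0, 0), (10, 0), (0, 10)])
    for retained, excluded in thin_occurrences(o, d_min=5, n_datasets=3, seed=0):
        assert len(retained) == 3 and len(excluded) == 0


def test_thin_two_close_points_keeps_one():
    o = occ([(0, 0), (3, 0)])
    for retained, excluded in thin_occurrences(o, d_min=5, n_datasets=4, seed=1):
        assert len(retained) == 1 and len(excluded) == 1


def _max_valid_subset(xy, d_min):
    best = 0
    n = len(xy)
    for r in range(n, 0, -1):
        for sub in itertools.combinations(range(n), r):
            ok = all(
                np.hypot(*(np.array(xy[i]) - np.array(xy[j]))) >= d_min
                for i, j in itertools.combinations(sub, 2)
            )
            if ok:
                return r
    return best


def test_thin_three_collinear_keeps_endpoints():
    pts = [(0, 0), (4, 0), (8, 0)]
    retained, _ = thin_occurrences(occ(pts), d_min=5, n_datasets=1, seed=0)[0]
    assert len(retained) == _max_valid_subset(pts, 5) == 2
    kept = {tuple(p) for p in retained.xy}
    assert kept == {(0.0, 0.0), (8.0, 0.0)}


def test_thin_never_violates_minimum_distance():
    rng = np.random.default_rng(2)
    pts = rng.uniform(0, 30, size=(40, 2))
    for retained, excluded in thin_occurrences(occ(pts.tolist()), d_min=6, n_datasets=5, seed=3):
        xy = retained.xy
        for i, j in itertools.combinations(range(len(xy)), 2):
            assert np.hypot(*(xy[i] - xy[j])) >= 6
        assert len(retained) + len(excluded) == 40


# ---------------------------------------------------------------------------
# VIF


def test_vif_orthogonal_retained():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
    assert vif_select(df, threshold=5) == ["a", "b"]


def test_vif_duplicate_column_removed():
    rng = np.random.default_rng(1)
    a = rng.normal(size=50)
    df = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=50)})
    kept = vif_select(df, threshold=5)
    assert "c" in kept and len([v for v in kept if v in ("a", "b")]) == 1


def test_vif_two_variable_closed_form():
    # correlation 0.9 -> VIF = 1/(1-0.81) = 5.26 >= 5 -> one removed
    rng = np.random.default_rng(3)
    n = 20000
    a = rng.normal(size=n)
    b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=n)
    kept = vif_select(pd.DataFrame({"a": a, "b": b}), threshold=5)
    assert len(kept) == 1
    # at a higher threshold both survive
    kept2 = vif_select(pd.DataFrame({"a": a, "b": b}), threshold=6)
    assert kept2 == ["a", "b"]


# ---------------------------------------------------------------------------
# background, AUC, TSS


def test_target_group_background_mask_and_dedup(geometry):
    mask = make_binary(geometry, [(4, 0), (4, 1)])  # southern two cells
    # two points in cell (4,0), one in (4,1), one outside the mask
    tg = occ([(0.1, 0.1), (-0.2, -0.3), (1.0, 0.0), (3.0, 3.0)])
    back = target_group_background(tg, mask)
    assert len(back) == 2  # one per cell
    assert len(back) <= mask.count()
    with pytest.raises(ValueError):
        target_group_background(occ([(100.0, 100.0)]), mask)


@pytest.mark.parametrize(
    "pres,back,expected",
    [
        ([0.9, 0.8], [0.1, 0.2], 1.0),
        ([0.5, 0.5], [0.5, 0.5], 0.5),
        ([0.9, 0.4], [0.5, 0.1], 0.75),
    ],
)
def test_auc_known_values(pres, back, expected):
    assert auc(pres, back) == pytest.approx(expected)


def _auc_oracle(pres, back):
    wins = sum(1.0 if p > b else 0.5 if p == b else 0.0 for p in pres for b in back)
    return wins / (len(pres) * len(back))


def _tss_oracle(pres, back):
    best = (-np.inf, np.inf)
    for t in np.unique(np.concatenate([pres, back])):
        tss = np.mean(np.asarray(pres) >= t) + np.mean(np.asarray(back) < t) - 1
        if tss > best[0] or (tss == best[0] and t < best[1]):
            best = (tss, t)
    return best[1], best[0]


def test_auc_and_tss_match_brute_force_oracles():
    rng = np.random.default_rng(5)
    for _ in range(50):
        pres = rng.choice(np.round(rng.uniform(0, 1, 10), 2), size=rng.integers(1, 20))
        back = rng.choice(np.round(rng.uniform(0, 1, 10), 2), size=rng.integers(1, 20))
        assert auc(pres, back) == pytest.approx(_auc_oracle(pres, back), rel=1e-12)
        t, tss = max_tss_threshold(pres, back)
        t_o, tss_o = _tss_oracle(pres, back)
        assert (t, tss) == pytest.approx((t_o, tss_o))


def test_tss_worked_examples():
    t, tss = max_tss_threshold([0.9, 0.8], [0.2, 0.1])
    assert (t, tss) == (0.8, 1.0)
    _, tss0 = max_tss_threshold([0.5, 0.5], [0.5])
    assert tss0 == 0.0
    _, tss1 = max_tss_threshold([0.9], [0.1, 0.2])
    assert tss1 == 1.0


# ---------------------------------------------------------------------------
# ensemble fit / project / binarize


class FixedLearner:
    """Scores equal to a fixed linear function of the first feature."""

    def __init__(self, sign=1.0, name="fixed"):
        self.sign = sign
        self.name = name

    def clone(self):
        return FixedLearner(self.sign, self.name)

    def fit(self, X, y):
        return self

    def predict_probability(self, X):
        z = np.asarray(X, dtype=float)[:, 0]
        return 1.0 / (1.0 + np.exp(-3.0 * self.sign * z))


@pytest.fixture(scope="module")
def toy_env():
    geom = GridGeometry(rows=20, cols=20, x_origin=0.0, y_origin=0.0, cell_size=1.0)
    rng = np.random.default_rng(7)
    grad = np.linspace(-2, 2, 20)[None, :] * np.ones((20, 1))
    layers = {
        "bio1": Raster(geom, grad),
        "bio2": Raster(geom, rng.normal(size=(20, 20))),
    }
    return EnvStack(layers)


def _toy_points(env, n, east=True, seed=0):
    rng = np.random.default_rng(seed)
    suit = 1.0 / (1.0 + np.exp(-3.0 * env["bio1"].values))
    if not east:
        suit = 1.0 - suit
    flat = suit.ravel() / suit.sum()
    idx = rng.choice(flat.size, size=n, p=flat)
    rows, cols = np.unravel_index(idx, suit.shape)
    x, y = env.geometry.cell_center(rows, cols)
    return occ(np.column_stack([x, y]).tolist())


def test_fit_ensemble_single_good_learner(toy_env):
    pres = _toy_points(toy_env, 60, seed=1)
    back = _toy_points(toy_env, 80, east=False, seed=2)
    thinned = [(pres, _toy_points(toy_env, 20, seed=3))]
    model = fit_ensemble(thinned, back, toy_env, learners=[FixedLearner(+1)], seed=0)
    assert len(model.included) == 1
    assert model.included[0].weight == pytest.approx(1.0)
    X = np.array([[1.0, 0.0], [-1.0, 0.0]])
    assert np.allclose(model.predict(X), FixedLearner(+1).predict_probability(X))


def test_fit_ensemble_excludes_weak_learner_and_weights_by_auc(toy_env):
    pres = _toy_points(toy_env, 60, seed=1)
    back = _toy_points(toy_env, 80, east=False, seed=2)
    thinned = [(pres, _toy_points(toy_env, 20, seed=3))]
    good = FixedLearner(+1, "good")
    bad = FixedLearner(-1, "bad")  # anti-predicts -> AUC far below 0.7
    model = fit_ensemble(thinned, back, toy_env, learners=[good, bad], seed=0)
    names = {m.learner.name for m in model.included}
    assert names == {"good"}
    aucs = {m.learner.name: m.auc for m in model.members}
    assert aucs["bad"] <= 0.7 < aucs["good"]
    # weights are proportional to AUC and sum to one
    model2 = fit_ensemble([thinned[0], thinned[0]], back, toy_env,
                          learners=[good], seed=0)
    w = np.array([m.weight for m in model2.included])
    a = np.array([m.auc for m in model2.included])
    assert np.allclose(w, a / a.sum()) and w.sum() == pytest.approx(1.0)
    # two included members with exactly equal AUC average arithmetically
    from meltingpot.sdm import EnsembleModel, FittedMember
    members = [FittedMember(FixedLearner(+1), 0, 0.9, True, 0.5),
               FittedMember(FixedLearner(-1), 1, 0.9, True, 0.5)]
    even = EnsembleModel(members, ["bio1", "bio2"], threshold=0.5, tss=1.0)
    X = np.array([[0.3, 0.0], [-0.7, 0.0]])
    expect = 0.5 * (FixedLearner(+1).predict_probability(X)
                    + FixedLearner(-1).predict_probability(X))
    assert np.allclose(even.predict(X), expect)


def test_fit_ensemble_raises_when_nothing_passes(toy_env):
    pres = _toy_points(toy_env, 40, seed=1)
    back = _toy_points(toy_env, 40, east=False, seed=2)
    thinned = [(pres, _toy_points(toy_env, 15, seed=3))]
    with pytest.raises(ValueError, match="AUC"):
        fit_ensemble(thinned, back, toy_env, learners=[FixedLearner(-1)], seed=0)


def test_project_identity_constant_and_bounds(toy_env):
    pres = _toy_points(toy_env, 60, seed=1)
    back = _toy_points(toy_env, 80, east=False, seed=2)
    model = fit_ensemble([(pres, _toy_points(toy_env, 20, seed=3))], back, toy_env,
                         learners=[FixedLearner(+1)], seed=0)
    cal = project(model, toy_env)
    assert cal.mask.all()
    # identity scenario: projecting the calibration stack reproduces the
    # per-cell ensemble predictions
    rows, cols = np.nonzero(cal.mask)
    expect = model.predict(toy_env.design_matrix(rows, cols, model.variables))
    assert np.allclose(cal.values[rows, cols], expect)
    geom = toy_env.geometry
    const = EnvStack({n: Raster(geom, np.full((20, 20), 0.3)) for n in toy_env.names})
    flat = project(model, const)
    assert np.allclose(flat.values, flat.values[0, 0])
    rng = np.random.default_rng(11)
    for _ in range(100):
        rand = EnvStack({n: Raster(geom, rng.normal(scale=5, size=(20, 20))) for n in toy_env.names})
        vals = project(model, rand).values
        assert np.all((vals >= 0) & (vals <= 1))
    with pytest.raises(KeyError):
        project(model, EnvStack({"bio1": toy_env["bio1"]}))


def test_binarize_rules(toy_env):
    suit = project(
        fit_ensemble([(_toy_points(toy_env, 50, seed=1), _toy_points(toy_env, 15, seed=3))],
                     _toy_points(toy_env, 60, east=False, seed=2),
                     toy_env, learners=[FixedLearner(+1)], seed=0),
        toy_env,
    )
    assert binarize(suit, 0.0).count() == suit.values.size
    assert binarize(suit, 1.0 + 1e-9).count() == 0
    b = binarize(suit, 0.4)
    assert np.array_equal(binarize(b, 0.5).values, b.values)


# ---------------------------------------------------------------------------
# consensus and stability


def test_gcm_consensus_two_of_three_rule(geometry):
    m1 = make_binary(geometry, [(0, 0), (1, 1)])
    m2 = make_binary(geometry, [(0, 0)])
    m3 = make_binary(geometry, [(2, 2)])
    cons = gcm_consensus([m1, m2, m3], min_agree=2)
    assert cons.binary.values[0, 0] == 1  # agreement (1,1,0)
    assert cons.binary.values[1, 1] == 0  # agreement (1,0,0)
    assert cons.binary.values[2, 2] == 0
    assert cons.agreement[0, 0] == 2


def test_gcm_consensus_and_or_limits(geometry):
    maps = [make_binary(geometry, [(0, 0), (1, 1)]), make_binary(geometry, [(0, 0), (2, 2)])]
    as_and = gcm_consensus(maps, min_agree=2)
    as_or = gcm_consensus(maps, min_agree=1)
    expected_and = (maps[0].values == 1) & (maps[1].values == 1)
    expected_or = (maps[0].values == 1) | (maps[1].values == 1)
    assert np.array_equal(as_and.binary.values == 1, expected_and)
    assert np.array_equal(as_or.binary.values == 1, expected_or)
    empty = gcm_consensus([make_binary(geometry, []), make_binary(geometry, [])], 1)
    assert empty.count() == 0


def test_stability_overlap_rules(geometry):
    from shapely.geometry import box

    refugia = gcm_consensus([make_binary(geometry, [(4, 0), (4, 1), (0, 5)])], min_agree=1)
    current = make_binary(geometry, [(4, 0), (0, 5)])
    # polygon covering only the south-west corner cells
    area = AncestralArea(box(-0.5, -0.5, 1.5, 0.5), lineage="l1")
    stable = stability_areas(current, refugia, area, include_current=True)
    assert stable.values[4, 0] == 1  # refugium + polygon + current
    assert stable.values[4, 1] == 0  # refugium + polygon, not current
    assert stable.values[0, 5] == 0  # refugium + current, outside polygon
    assert stable.cell_set <= refugia.binary.cell_set
    no_current = stability_areas(current, refugia, area, include_current=False)
    assert no_current.values[4, 1] == 1
    with pytest.warns(UserWarning):
        far = AncestralArea(box(100, 100, 101, 101))
        empty = stability_areas(current, refugia, far)
    assert empty.count() == 0
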