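"""Synthetic study systems with known drivers of genetic diversity.

A synthetic world is a small planar landscape (row 0 = north, cells in km)
carrying everything the downstream pipeline consumes: correlated bioclim-like
raster layers for the present and for ``n_gcm`` perturbed glacial scenarios,
two or more divergent lineages meeting along a logistic cline of admixture,
per-population microsatellite genotypes and mtDNA sequences, a noisy
Q-matrix and DIC-versus-K table (emulating spatial Bayesian clustering
output), occurrence and target-group points, ancestral-area polygons, and a
:class:`TruthRecord` with the realised driver effects.

The driver modes wire diversity to its causes:

* ``admixture`` — lineages carry partly disjoint allele pools (divergence
  fraction ``beta_admixture``), so mixed populations have elevated expected
  heterozygosity: He rises with the Simpson index of the true admixture
  proportions (convexity of ``sum p^2``).
* ``stability`` — allele pools collapse toward a point mass with weight
  ``w(d) = min(1, d / erosion_scale) * beta_stability`` at distance ``d``
  from the nearest true refugium cell, so diversity decays away from
  refugia.
* ``both`` — both mechanisms; ``none`` — shared pools, no erosion: diversity
  varies only by noise.

Identical ``WorldConfig`` + seed yields a bit-identical world.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .admixture import QMatrix, simpson_index
from .grid import BinaryMap, EnvStack, GridGeometry, Raster
from .popgen import GenotypeTable, SequenceSample
from .refugia import AncestralArea, gcm_consensus, stability_areas
from .sdm import OccurrenceSet, binarize

__all__ = [
    "LineageSpec",
    "WorldConfig",
    "TruthRecord",
    "SyntheticWorld",
    "ConfigurationError",
    "admixture_cline",
    "lineage_proportions",
    "mixture_allele_frequencies",
    "sample_occurrences",
    "generate_world",
]

DRIVER_MODES = ("admixture", "stability", "both", "none")
NUCLEOTIDES = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Invalid world configuration; the message names the offending field."""


@dataclass(frozen=True)
class LineageSpec:
    """One divergent lineage: ancestral centre (grid row/col), niche
    coefficients (per environmental layer; None = neutral) and the dispersal
    scale (km) used as the ancestral-area radius."""

    center: tuple[int, int]
    dispersal_scale: float = 60.0
    niche: tuple[float, ...] | None = None


def _default_lineages(rows: int, cols: int, cell_size: float = 5.0) -> tuple[LineageSpec, ...]:
    # ancestral-area radius scales with the landscape: stability areas become
    # substantial (but not exhaustive) subsets of the refugia band, keeping
    # the two distance predictors strongly correlated yet identifiable
    r = int(0.7 * rows)
    radius = 0.24 * rows * cell_size
    return (
        LineageSpec(center=(r, cols // 6), dispersal_scale=radius),
        LineageSpec(center=(r, cols // 2), dispersal_scale=radius),
        LineageSpec(center=(r, (5 * cols) // 6), dispersal_scale=radius),
    )


@dataclass(frozen=True)
class WorldConfig:
    """All knobs of the synthetic study system (distances in km)."""

    grid_rows: int = 50
    grid_cols: int = 70
    cell_size: float = 5.0
    n_layers: int = 5
    collinearity_spec: tuple[tuple[str, str, float], ...] = (("bio2", "bio1", 0.9),)
    lineage_specs: tuple[LineageSpec, ...] | None = None
    cline_axis_deg: float = 0.0  # 0 = west-to-east
    cline_midpoint: float | tuple[float, ...] | None = None
    cline_width: float = 30.0
    n_populations: int = 50
    inds_per_population: int = 10
    n_loci: int = 8
    pool_alleles_per_locus: int = 6
    driver_mode: str = "admixture"
    beta_admixture: float = 0.8
    beta_stability: float = 0.5
    erosion_scale: float = 100.0
    noise_sd: float = 0.02
    n_gcm: int = 3
    gcm_perturbation_sd: float = 0.15
    lgm_shift: float = 1.0
    missing_rate: float = 0.03
    mt_per_population: int = 5
    seq_length: int = 600
    q_concentration: float = 50.0
    dic_replicates: int = 100
    n_occurrences: int = 400
    n_target_group: int = 1500
    seed: int = 0

    def lineages(self) -> tuple[LineageSpec, ...]:
        if self.lineage_specs is not None:
            return tuple(self.lineage_specs)
        return _default_lineages(self.grid_rows, self.grid_cols, self.cell_size)

    def validate(self) -> None:
        counts = {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "n_layers": self.n_layers,
            "n_populations": self.n_populations,
            "inds_per_population": self.inds_per_population,
            "n_loci": self.n_loci,
            "pool_alleles_per_locus": self.pool_alleles_per_locus,
            "n_gcm": self.n_gcm,
            "mt_per_population": self.mt_per_population,
            "seq_length": self.seq_length,
            "dic_replicates": self.dic_replicates,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be a count >= 1 (got {value})")
        if self.cline_width <= 0:
            raise ConfigurationError(f"cline_width must be > 0 (got {self.cline_width})")
        if self.cell_size <= 0:
            raise ConfigurationError(f"cell_size must be > 0 (got {self.cell_size})")
        if self.erosion_scale <= 0:
            raise ConfigurationError(f"erosion_scale must be > 0 (got {self.erosion_scale})")
        if self.driver_mode not in DRIVER_MODES:
            raise ConfigurationError(f"driver_mode must be one of {DRIVER_MODES} (got {self.driver_mode!r})")
        for child, parent, corr in self.collinearity_spec:
            if not (0.0 <= corr <= 1.0):
                raise ConfigurationError(f"collinearity_spec correlation for {child} must be in [0, 1]")
        if len(self.lineages()) < 2:
            raise ConfigurationError("lineage_specs must define at least 2 lineages")
        for name in ("beta_admixture", "beta_stability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1] (got {v})")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError(f"missing_rate must be in [0, 1) (got {self.missing_rate})")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0 (got {self.noise_sd})")


@dataclass
class TruthRecord:
    """Ground truth of a synthetic world, for parameter-recovery testing."""

    driver_mode: str
    beta_admixture: float
    beta_stability: float
    refugia_mask: BinaryMap
    stability_mask: BinaryMap
    table: pd.DataFrame  # per population: true q, simpson, distances


@dataclass
class SyntheticWorld:
    config: WorldConfig
    env_current: EnvStack
    env_gcm: list[EnvStack]
    populations: pd.DataFrame  # population, row, col, x, y, lon, lat
    genotypes: GenotypeTable
    sequences: list[SequenceSample]
    q_matrix: QMatrix
    dic_table: pd.DataFrame
    ancestral_areas: dict[str, AncestralArea]
    occurrences: OccurrenceSet
    target_group: OccurrenceSet
    true_suitability: Raster
    truth: TruthRecord

    def checksum(self) -> str:
        """SHA-256 digest over every generated artifact."""
        h = hashlib.sha256()
        for stack in [self.env_current, *self.env_gcm]:
            for name in stack.names:
                h.update(name.encode())
                h.update(np.ascontiguousarray(stack[name].values).tobytes())
        for df in (self.populations, self.genotypes.df, self.q_matrix.df, self.dic_table,
                   self.occurrences.points, self.target_group.points, self.truth.table):
            h.update(df.to_csv(index=False).encode())
        for sample in self.sequences:
            h.update(sample.population_id.encode())
            h.update("".join(sample.sequences).encode())
        for name, area in self.ancestral_areas.items():
            h.update(name.encode())
            h.update(area.polygon.wkt.encode())
        h.update(np.ascontiguousarray(self.truth.refugia_mask.values).tobytes())
        h.update(np.ascontiguousarray(self.truth.stability_mask.values).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Primitives


def admixture_cline(position_km: float, midpoint: float, width: float):
    """Two-lineage logistic cline across a secondary contact zone:
    ``q1 = 1 / (1 + exp(-(pos - mid)/width))``, ``q2 = 1 - q1``."""
    if width <= 0:
        raise ValueError("cline width must be positive")
    q1 = 1.0 / (1.0 + np.exp(-(np.asarray(position_km, dtype=float) - midpoint) / width))
    return q1, 1.0 - q1


def lineage_proportions(position_km, midpoints, width: float) -> np.ndarray:
    """Admixture proportions of L lineages from L-1 stacked logistic clines.

    ``G_l = sigmoid((pos - m_l)/width)`` is the weight already handed over to
    lineages beyond midpoint l; ``q_1 = 1 - G_1``, ``q_l = G_{l-1} - G_l``,
    ``q_L = G_{L-1}``.  Midpoints must be increasing.
    """
    if width <= 0:
        raise ValueError("cline width must be positive")
    midpoints = np.sort(np.atleast_1d(np.asarray(midpoints, dtype=float)))
    pos = np.atleast_1d(np.asarray(position_km, dtype=float))
    G = 1.0 / (1.0 + np.exp(-(pos[:, None] - midpoints[None, :]) / width))
    q = np.empty((len(pos), len(midpoints) + 1))
    q[:, 0] = 1.0 - G[:, 0]
    for l in range(1, len(midpoints)):
        q[:, l] = G[:, l - 1] - G[:, l]
    q[:, -1] = G[:, -1]
    q = np.clip(q, 0.0, 1.0)
    q /= q.sum(axis=1, keepdims=True)
    return q if np.ndim(position_km) else q[0]


def mixture_allele_frequencies(pools: np.ndarray, q, erosion_weight: float = 0.0) -> np.ndarray:
    """Population allele frequencies from lineage pools and admixture.

    ``p = (1 - w) * sum_l q_l * pool_l + w * delta(argmax of the mixture)``:
    the erosion weight ``w`` collapses the distribution toward its single
    most common allele (diversity loss away from refugia).
    """
    pools = np.asarray(pools, dtype=float)
    q = np.asarray(list(q), dtype=float)
    if pools.ndim != 2 or pools.shape[0] != q.size:
        raise ValueError(f"pools shape {pools.shape} does not match {q.size} lineage proportions")
    if not np.allclose(pools.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each lineage pool must sum to 1")
    if not np.isclose(q.sum(), 1.0, atol=1e-8):
        raise ValueError("admixture proportions must sum to 1")
    if not (0.0 <= erosion_weight <= 1.0):
        raise ValueError("erosion_weight must lie in [0, 1]")
    p = q @ pools
    point = np.zeros_like(p)
    point[np.argmax(p)] = 1.0
    out = (1.0 - erosion_weight) * p + erosion_weight * point
    return out / out.sum()


def sample_occurrences(suitability: Raster, n: int, seed: int = 0) -> OccurrenceSet:
    """Presence points drawn cell-wise with probability proportional to
    suitability, jittered uniformly within the cell."""
    vals = np.where(suitability.mask, suitability.values, 0.0)
    if np.any(vals < 0) or np.any(vals > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    total = vals.sum()
    if n > 0 and total <= 0:
        raise ValueError("cannot sample occurrences from an all-zero suitability surface")
    rng = np.random.default_rng(seed)
    geom = suitability.geometry
    if n == 0:
        return OccurrenceSet(pd.DataFrame(columns=["x", "y"]), projected=geom.projected)
    flat = vals.ravel() / total
    idx = rng.choice(flat.size, size=n, p=flat)
    rows, cols = np.unravel_index(idx, vals.shape)
    cx, cy = geom.cell_center(rows, cols)
    jitter = rng.uniform(-0.5, 0.5, size=(2, n)) * geom.cell_size
    df = pd.DataFrame({"x": cx + jitter[0], "y": cy + jitter[1]})
    return OccurrenceSet(df, projected=geom.projected)


# ---------------------------------------------------------------------------
# World assembly


def _smooth_field(rng, rows, cols, sigma=4.0) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal((rows, cols)), sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _environment(config: WorldConfig, rng) -> tuple[EnvStack, list[EnvStack], Raster]:
    rows, cols = config.grid_rows, config.grid_cols
    geom = GridGeometry(rows, cols, x_origin=0.0, y_origin=0.0,
                        cell_size=config.cell_size, projected=True)
    gradient = np.linspace(-1.0, 1.0, rows)[:, None] * np.ones((1, cols))  # warm south
    raw = {}
    for i in range(config.n_layers):
        name = f"bio{i + 1}"
        if i == 0:
            f = 1.2 * gradient + 0.6 * _smooth_field(rng, rows, cols)
        else:
            f = _smooth_field(rng, rows, cols)
        raw[name] = (f - f.mean()) / f.std()
    for child, parent, corr in config.collinearity_spec:
        if child not in raw or parent not in raw:
            raise ConfigurationError(f"collinearity_spec references unknown layer {child!r} or {parent!r}")
        raw[child] = corr * raw[parent] + np.sqrt(max(0.0, 1.0 - corr**2)) * raw[child]
    env_current = EnvStack({n: Raster(geom, v) for n, v in raw.items()})

    env_gcm = []
    for _ in range(config.n_gcm):
        layers = {}
        for name, v in raw.items():
            perturb = config.gcm_perturbation_sd * _smooth_field(rng, rows, cols)
            shift = config.lgm_shift if name == "bio1" else 0.0
            layers[name] = Raster(geom, v - shift + perturb)
        env_gcm.append(EnvStack(layers))

    suit = 1.0 / (1.0 + np.exp(-2.5 * raw["bio1"]))
    return env_current, env_gcm, Raster(geom, suit)


def _true_refugia(config: WorldConfig, env_gcm: list[EnvStack]) -> BinaryMap:
    maps = []
    for stack in env_gcm:
        s = 1.0 / (1.0 + np.exp(-2.5 * stack["bio1"].values))
        maps.append(binarize(Raster(stack.geometry, s), 0.5))
    return gcm_consensus(maps, min_agree=min(2, config.n_gcm)).binary


def _place_populations(config: WorldConfig, suit: Raster, rng) -> pd.DataFrame:
    vals = suit.values
    good = np.argwhere(vals >= np.median(vals))
    if len(good) < config.n_populations:
        raise ConfigurationError("n_populations exceeds the number of suitable cells")
    pick = rng.choice(len(good), size=config.n_populations, replace=False)
    cells = good[np.sort(pick)]
    geom = suit.geometry
    x, y = geom.cell_center(cells[:, 0], cells[:, 1])
    lat0, lon0 = 38.0, 7.0
    lat = lat0 + np.asarray(y) / 110.574
    lon = lon0 + np.asarray(x) / (111.320 * np.cos(np.radians(lat0)))
    return pd.DataFrame(
        {
            "population": [f"P{i + 1:02d}" for i in range(config.n_populations)],
            "row": cells[:, 0],
            "col": cells[:, 1],
            "x": x,
            "y": y,
            "lon": lon,
            "lat": lat,
        }
    )


def _cline_midpoints(config: WorldConfig, n_lineages: int) -> np.ndarray:
    if config.cline_midpoint is not None:
        mids = np.atleast_1d(np.asarray(config.cline_midpoint, dtype=float))
        if mids.size != n_lineages - 1:
            raise ConfigurationError(
                f"cline_midpoint needs {n_lineages - 1} value(s) for {n_lineages} lineages"
            )
        return mids
    theta = np.radians(config.cline_axis_deg)
    geom_extent_x = config.grid_cols * config.cell_size
    geom_extent_y = config.grid_rows * config.cell_size
    extent = abs(np.cos(theta)) * geom_extent_x + abs(np.sin(theta)) * geom_extent_y
    return np.linspace(0, extent, n_lineages + 1)[1:-1]


def _allele_pools(config: WorldConfig, rng, n_lineages: int):
    """Per-locus lineage pools over a shared block plus lineage-private blocks.

    Divergence fraction beta moves mass from the shared block to each
    lineage's private block; beta=0 makes all lineages identical.
    """
    A = config.pool_alleles_per_locus
    beta = config.beta_admixture if config.driver_mode in ("admixture", "both") else 0.0
    pools = []  # per locus: (n_lineages, (1 + n_lineages) * A)
    allele_ids = []
    for _ in range(config.n_loci):
        shared = rng.dirichlet(np.ones(A))
        # one evenness profile per locus, permuted per lineage: every lineage
        # pool has identical sum(p^2), so mixed-population heterozygosity
        # depends on the admixture proportions only through 1 - sum(q^2)
        profile = rng.dirichlet(np.ones(A))
        width = (1 + n_lineages) * A
        pool = np.zeros((n_lineages, width))
        for l in range(n_lineages):
            pool[l, :A] = (1.0 - beta) * shared
            pool[l, (1 + l) * A : (2 + l) * A] = beta * rng.permutation(profile)
        pools.append(pool)
        allele_ids.append(100 + np.arange(width))
    return pools, allele_ids


def _genotypes(config: WorldConfig, rng, pops: pd.DataFrame, q_true: np.ndarray,
               dist_ref: np.ndarray, pools, allele_ids) -> GenotypeTable:
    if config.driver_mode in ("stability", "both"):
        w = np.minimum(1.0, dist_ref / config.erosion_scale) * config.beta_stability
    else:
        w = np.zeros(len(pops))
    conc = np.inf if config.noise_sd == 0 else 1.0 / config.noise_sd**2
    I = config.inds_per_population
    records = {"population": [], "individual": [], "locus": [],
               "allele_a": [], "allele_b": []}
    for pi, pop in enumerate(pops["population"]):
        inds = [f"{pop}_i{j + 1:02d}" for j in range(I)]
        for li in range(config.n_loci):
            p = mixture_allele_frequencies(pools[li], q_true[pi], float(w[pi]))
            if np.isfinite(conc):
                alpha = p * conc
                keep = alpha > 0
                jit = np.zeros_like(p)
                jit[keep] = rng.dirichlet(alpha[keep])
                p = jit
            copies = rng.choice(allele_ids[li], size=2 * I, p=p)
            a, b = copies[0::2].astype(float), copies[1::2].astype(float)
            miss = rng.random(I) < config.missing_rate
            a[miss] = np.nan
            b[miss] = np.nan
            records["population"].extend([pop] * I)
            records["individual"].extend(inds)
            records["locus"].extend([f"loc{li + 1}"] * I)
            records["allele_a"].extend(a)
            records["allele_b"].extend(b)
    return GenotypeTable(pd.DataFrame(records))


def _sequences(config: WorldConfig, rng, pops: pd.DataFrame, q_true: np.ndarray) -> list[SequenceSample]:
    L = config.seq_length
    n_lineages = q_true.shape[1]
    ancestral = rng.choice(NUCLEOTIDES, size=L)
    lineage_haps = []
    for _ in range(n_lineages):
        base = ancestral.copy()
        div_sites = rng.choice(L, size=max(2, L // 50), replace=False)
        for s in div_sites:
            base[s] = rng.choice(NUCLEOTIDES[NUCLEOTIDES != base[s]])
        haps = []
        for _ in range(6):
            hap = base.copy()
            for s in rng.choice(L, size=3, replace=False):
                hap[s] = rng.choice(NUCLEOTIDES[NUCLEOTIDES != hap[s]])
            haps.append("".join(hap))
        freqs = rng.dirichlet(np.ones(6) * 2.0)
        lineage_haps.append((haps, freqs))
    samples = []
    for pi, pop in enumerate(pops["population"]):
        seqs = []
        lineage_draw = rng.choice(n_lineages, size=config.mt_per_population, p=q_true[pi])
        for l in lineage_draw:
            haps, freqs = lineage_haps[l]
            seqs.append(haps[rng.choice(len(haps), p=freqs)])
        samples.append(SequenceSample(str(pop), seqs))
    return samples


def _q_matrix(config: WorldConfig, rng, pops: pd.DataFrame, q_true: np.ndarray) -> QMatrix:
    rows = []
    for pi, pop in enumerate(pops["population"]):
        alpha = q_true[pi] * config.q_concentration + 0.05
        for j in range(config.inds_per_population):
            q = rng.dirichlet(alpha)
            rows.append([pop, f"{pop}_i{j + 1:02d}", *q])
    cols = ["population", "individual"] + [f"q{k + 1}" for k in range(q_true.shape[1])]
    return QMatrix(pd.DataFrame(rows, columns=cols))


def _dic_table(config: WorldConfig, rng, k_true: int) -> pd.DataFrame:
    ks = np.arange(2, max(9, k_true + 3))
    rows = []
    for K in ks:
        mean = 1000.0 - 150.0 * (min(K, k_true) - 2) - 2.0 * max(0, K - k_true)
        for rep in range(config.dic_replicates):
            rows.append({"K": int(K), "replicate": rep + 1, "dic": mean + rng.normal(0, 5.0)})
    return pd.DataFrame(rows)


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Build a complete synthetic study system from a validated config."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    env_current, env_gcm, true_suit = _environment(config, rng)
    refugia_mask = _true_refugia(config, env_gcm)
    pops = _place_populations(config, true_suit, rng)

    lineages = config.lineages()
    n_lineages = len(lineages)
    theta = np.radians(config.cline_axis_deg)
    positions = pops["x"].to_numpy() * np.cos(theta) + pops["y"].to_numpy() * np.sin(theta)
    midpoints = _cline_midpoints(config, n_lineages)
    q_true = lineage_proportions(positions, midpoints, config.cline_width)

    from .attribution import nearest_distance

    dist_ref = np.array([
        nearest_distance((x, y), refugia_mask) for x, y in zip(pops["x"], pops["y"])
    ])

    pools, allele_ids = _allele_pools(config, rng, n_lineages)
    genotypes = _genotypes(config, rng, pops, q_true, dist_ref, pools, allele_ids)
    sequences = _sequences(config, rng, pops, q_true)
    q_matrix = _q_matrix(config, rng, pops, q_true)
    dic_table = _dic_table(config, rng, n_lineages)

    geom = env_current.geometry
    areas = {}
    from shapely.geometry import Point

    for l, spec in enumerate(lineages):
        cx, cy = geom.cell_center(spec.center[0], spec.center[1])
        areas[f"lineage{l + 1}"] = AncestralArea(
            Point(float(cx), float(cy)).buffer(spec.dispersal_scale), lineage=f"lineage{l + 1}"
        )

    current_binary = binarize(true_suit, 0.5)
    cons = gcm_consensus(
        [BinaryMap(geom, refugia_mask.values, refugia_mask.nodata)], min_agree=1
    )
    union_poly = areas["lineage1"].polygon
    for a in list(areas.values())[1:]:
        union_poly = union_poly.union(a.polygon)
    stability_mask = stability_areas(
        current_binary, cons, AncestralArea(union_poly, lineage="all"), include_current=True
    )
    if stability_mask.count() == 0:
        warnings.warn("synthetic stability mask is empty; distances fall back to the refugia mask")
        stability_mask = refugia_mask
    dist_stab = np.array([
        nearest_distance((x, y), stability_mask) for x, y in zip(pops["x"], pops["y"])
    ])

    occurrences = sample_occurrences(true_suit, config.n_occurrences, seed=int(rng.integers(2**31)))
    occ = occurrences.points.copy()
    occ["source"] = "synthetic_survey"
    occ["uncertainty_arcsec"] = rng.uniform(1, 20, size=len(occ))
    dirty = rng.random(len(occ)) < 0.08
    occ.loc[dirty, "uncertainty_arcsec"] = rng.uniform(30, 90, size=int(dirty.sum()))
    if len(occ) > 5:  # a few literal duplicates, to exercise cleaning
        occ = pd.concat([occ, occ.iloc[:3]], ignore_index=True)
    occurrences = OccurrenceSet(occ, projected=True)

    effort = 1.0 / (1.0 + np.exp(-0.5 * _smooth_field(rng, geom.rows, geom.cols)))
    target_group = sample_occurrences(Raster(geom, effort), config.n_target_group,
                                      seed=int(rng.integers(2**31)))
    tg = target_group.points.copy()
    tg["source"] = "synthetic_target_group"
    target_group = OccurrenceSet(tg, projected=True)

    truth_table = pd.DataFrame(
        {
            "population": pops["population"],
            **{f"q{l + 1}": q_true[:, l] for l in range(n_lineages)},
            "simpson_true": [simpson_index(row) for row in q_true],
            "dist_refugium": dist_ref,
            "dist_stability": dist_stab,
        }
    )
    truth = TruthRecord(
        driver_mode=config.driver_mode,
        beta_admixture=config.beta_admixture if config.driver_mode in ("admixture", "both") else 0.0,
        beta_stability=config.beta_stability if config.driver_mode in ("stability", "both") else 0.0,
        refugia_mask=refugia_mask,
        stability_mask=BinaryMap(geom, stability_mask.values, stability_mask.nodata),
        table=truth_table,
    )
    return SyntheticWorld(
        config=config,
        env_current=env_current,
        env_gcm=env_gcm,
        populations=pops,
        genotypes=genotypes,
        sequences=sequences,
        q_matrix=q_matrix,
        dic_table=dic_table,
        ancestral_areas=areas,
        occurrences=occurrences,
        target_group=target_group,
        true_suitability=true_suit,
        truth=truth,
    )
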