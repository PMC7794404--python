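"""Umbrella pipeline: simulate -> divstats -> admix -> sdm -> refugia -> attribute.

Each stage reads and writes plain-text artifacts in one run directory, so
stages can be run individually (from the CLI) or chained by
:func:`run_pipeline`.  A :class:`RunReport` records parameters, seeds and
row/cell counts per stage; identical config + seed reproduces every artifact
bit-identically.

Stage parameter defaults follow the standard workflow thresholds: population
exclusion below 4 genotypes at any locus, null-allele locus removal at 14
flagged populations, VIF < 5, ensemble inclusion at AUC > 0.7, glacial
consensus at >= 2 GCMs, the 10 lowest-DIC replicates averaged.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .admixture import population_mean_q, population_simpson, select_k_plateau
from .attribution import build_predictor_table, run_model_set, subset_populations
from .grid import EnvStack
from .popgen import (
    bonferroni,
    diversity_table,
    filter_loci,
    filter_populations,
    hwe_test,
)
from .refugia import AncestralArea, gcm_consensus, stability_areas
from .sdm import binarize, clean_occurrences, fit_ensemble, project, thin_occurrences, vif_select
from .synthetic import WorldConfig, generate_world

__all__ = ["RunConfig", "RunReport", "run_pipeline",
           "stage_simulate", "stage_divstats", "stage_admix",
           "stage_sdm", "stage_refugia", "stage_attribute"]


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    world: WorldConfig | None = None  # None: artifacts must already exist in out_dir
    min_n: int = 4
    max_flagged: int = 14
    run_hwe: bool = False
    hwe_permutations: int = 200
    top_m: int = 10
    k_epsilon: float = 0.05
    thin_d_min: float = 6.0
    n_thin: int = 5
    vif_threshold: float = 5.0
    auc_cutoff: float = 0.7
    min_agree: int = 2
    max_uncertainty_arcsec: float = 30.0
    include_current_in_stability: bool = True
    include_interactions: bool = False
    subset_ids: tuple[str, ...] | None = None
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.world is not None:
            d["world"] = asdict(self.world)
        return d


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages[stage] = info

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        return json.dumps({"config": self.config, "stages": self.stages},
                          sort_keys=True, indent=1, default=default)

    def checksum(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _subseed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % 2**31


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(config: RunConfig) -> dict:
    if config.world is None:
        raise ValueError("stage_simulate needs a WorldConfig")
    out = Path(config.out_dir)
    (out / "rasters").mkdir(parents=True, exist_ok=True)
    world = generate_world(config.world)
    mio.write_genepop(world.genotypes, out / "genotypes.gen")
    mio.write_fasta_populations(world.sequences, out / "sequences.fasta")
    mio.write_qmatrix(world.q_matrix, out / "qmatrix.csv")
    world.dic_table.to_csv(out / "dic.csv", index=False)
    world.populations.to_csv(out / "populations.csv", index=False)
    mio.write_occurrences(world.occurrences, out / "occurrences.csv")
    mio.write_occurrences(world.target_group, out / "target_group.csv")
    mio.write_geojson_areas(world.ancestral_areas, out / "ancestral_areas.geojson")
    for name in world.env_current.names:
        mio.write_ascii_grid(world.env_current[name], out / "rasters" / f"current_{name}.asc")
    for g, stack in enumerate(world.env_gcm):
        for name in stack.names:
            mio.write_ascii_grid(stack[name], out / "rasters" / f"gcm{g + 1}_{name}.asc")
    mio.write_ascii_grid(world.truth.refugia_mask, out / "truth_refugia.asc")
    mio.write_ascii_grid(world.truth.stability_mask, out / "truth_stability.asc")
    world.truth.table.to_csv(out / "truth_table.csv", index=False)
    mio.write_yaml(
        {
            "driver_mode": world.truth.driver_mode,
            "beta_admixture": world.truth.beta_admixture,
            "beta_stability": world.truth.beta_stability,
            "seed": config.world.seed,
            "checksum": world.checksum(),
        },
        out / "truth.yaml",
    )
    return {
        "n_populations": len(world.populations),
        "n_layers": len(world.env_current.names),
        "n_gcm": len(world.env_gcm),
        "world_checksum": world.checksum(),
        "driver_mode": world.truth.driver_mode,
    }


def _load_env(out: Path, prefix: str) -> EnvStack:
    layers = {}
    for p in sorted((out / "rasters").glob(f"{prefix}_*.asc")):
        layers[p.stem.removeprefix(f"{prefix}_")] = mio.read_ascii_grid(p)
    if not layers:
        raise FileNotFoundError(f"no rasters with prefix {prefix!r} in {out / 'rasters'}")
    return EnvStack(layers)


def stage_divstats(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    genotypes = mio.read_genepop(out / "genotypes.gen")
    sequences = mio.read_fasta_populations(out / "sequences.fasta")
    flags_path = out / "null_allele_flags.csv"
    info: dict = {"n_populations_in": len(genotypes.populations)}
    if flags_path.exists():
        flags = pd.read_csv(flags_path)
        genotypes, locus_report = filter_loci(genotypes, flags, config.max_flagged)
        info["loci_removed"] = locus_report["locus"].tolist()
    genotypes, pop_report = filter_populations(genotypes, min_n=config.min_n)
    info["populations_removed"] = pop_report["population"].tolist()
    table = diversity_table(genotypes, sequences)
    table.to_csv(out / "diversity.csv", index=False)
    if config.run_hwe:
        seed = _subseed(config.seed, "hwe")
        pvals = []
        for i, pop in enumerate(genotypes.populations):
            recs = genotypes.population(pop)
            for j, locus in enumerate(genotypes.loci):
                sub = recs[recs["locus"] == locus]
                if len(sub.dropna(subset=["allele_a"])) < 3:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = hwe_test(sub, n_perm=config.hwe_permutations,
                                 seed=seed + i * 1000 + j)
                pvals.append({"population": pop, "locus": locus, "p": p})
        hwe_df = pd.DataFrame(pvals)
        hwe_df["p_bonferroni"] = bonferroni(hwe_df["p"])
        hwe_df.to_csv(out / "hwe.csv", index=False)
        info["hwe_significant_after_bonferroni"] = int((hwe_df["p_bonferroni"] < 0.05).sum())
    info["n_populations_out"] = len(genotypes.populations)
    return info


def stage_admix(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    dic = pd.read_csv(out / "dic.csv")
    k = select_k_plateau(dic, epsilon=config.k_epsilon)
    q = mio.read_qmatrix(out / "qmatrix.csv")
    mean_q = population_mean_q(q)
    mean_q.to_csv(out / "pop_admixture.csv")
    simpson = population_simpson(q)
    simpson.rename("simpson").to_csv(out / "simpson.csv")
    return {"selected_K": k, "q_matrix_K": q.k, "n_populations": len(mean_q)}


def stage_sdm(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    env = _load_env(out, "current")
    occurrences = mio.read_occurrences(out / "occurrences.csv", projected=True)
    target_group = mio.read_occurrences(out / "target_group.csv", projected=True)

    occurrences = clean_occurrences(occurrences, config.max_uncertainty_arcsec)
    thinned = thin_occurrences(occurrences, config.thin_d_min, config.n_thin,
                               seed=_subseed(config.seed, "thin"))

    rng = np.random.default_rng(_subseed(config.seed, "vif"))
    mask = env.valid_mask()
    cells = np.argwhere(mask)
    sample = cells[rng.choice(len(cells), size=min(500, len(cells)), replace=False)]
    design = pd.DataFrame(env.design_matrix(sample[:, 0], sample[:, 1]), columns=env.names)
    variables = vif_select(design, threshold=config.vif_threshold)

    from .sdm import target_group_background
    from .grid import BinaryMap

    region = BinaryMap(env.geometry, mask.astype(float))
    background = target_group_background(target_group, region)

    model = fit_ensemble(
        thinned, background, env,
        auc_cutoff=config.auc_cutoff, variables=variables,
        seed=_subseed(config.seed, "ensemble"),
    )
    current = project(model, env)
    mio.write_ascii_grid(current, out / "suitability_current.asc")
    mio.write_ascii_grid(binarize(current, model.threshold), out / "binary_current.asc")
    g = 1
    while (out / "rasters" / f"gcm{g}_{variables[0]}.asc").exists():
        scenario = _load_env(out, f"gcm{g}")
        suit = project(model, scenario)
        mio.write_ascii_grid(suit, out / f"suitability_gcm{g}.asc")
        mio.write_ascii_grid(binarize(suit, model.threshold), out / f"binary_gcm{g}.asc")
        g += 1
    (out / "sdm_report.json").write_text(json.dumps(model.report, indent=1, default=float))
    return {
        "n_occurrences_clean": len(occurrences),
        "n_background": len(background),
        "variables": variables,
        "n_models_included": len(model.included),
        "mean_auc": float(np.mean([m.auc for m in model.members])),
        "threshold": model.threshold,
        "n_gcm_projected": g - 1,
    }


def stage_refugia(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    gcm_maps = []
    g = 1
    while (out / f"binary_gcm{g}.asc").exists():
        gcm_maps.append(mio.read_ascii_grid(out / f"binary_gcm{g}.asc", binary=True))
        g += 1
    if not gcm_maps:
        raise FileNotFoundError("no binary GCM maps; run the sdm stage first")
    consensus = gcm_consensus(gcm_maps, min_agree=config.min_agree)
    mio.write_ascii_grid(consensus.binary, out / "refugia.asc")
    current = mio.read_ascii_grid(out / "binary_current.asc", binary=True)
    areas = mio.read_geojson_areas(out / "ancestral_areas.geojson")
    union = None
    for area in areas.values():
        union = area.polygon if union is None else union.union(area.polygon)
    stability = stability_areas(
        current, consensus, AncestralArea(union, lineage="all"),
        include_current=config.include_current_in_stability,
    )
    mio.write_ascii_grid(stability, out / "stability.asc")
    return {
        "n_gcm": len(gcm_maps),
        "refugia_cells": consensus.count(),
        "stability_cells": stability.count(),
    }


def stage_attribute(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    diversity = pd.read_csv(out / "diversity.csv")
    simpson = pd.read_csv(out / "simpson.csv", index_col=0)["simpson"]
    populations = pd.read_csv(out / "populations.csv")
    refugia_mask = mio.read_ascii_grid(out / "refugia.asc", binary=True)
    stability_mask = mio.read_ascii_grid(out / "stability.asc", binary=True)
    if stability_mask.count() == 0:
        warnings.warn("empty stability map; using the refugia map for stability distances")
        stability_mask = refugia_mask
    predictors = build_predictor_table(populations, simpson, refugia_mask, stability_mask)
    predictors.to_csv(out / "predictors.csv", index=False)
    keep = set(diversity["population"])
    predictors = predictors[predictors["population"].isin(keep)].reset_index(drop=True)
    diversity = diversity[diversity["population"].isin(set(predictors["population"]))]
    if config.subset_ids:
        diversity = subset_populations(diversity, config.subset_ids)
        predictors = subset_populations(predictors, config.subset_ids)
    comparison = run_model_set(diversity, predictors,
                               include_interactions=config.include_interactions)
    (out / "models.json").write_text(json.dumps(comparison.to_dict(), indent=1))
    comparison.summary().to_csv(out / "models.csv", index=False)
    best = {r: comparison.best(r).formula for r in comparison.fits}
    return {
        "n_populations": len(predictors),
        "best_models": best,
        "best_aic": {r: comparison.best(r).aic for r in comparison.fits},
    }


STAGES = {
    "simulate": stage_simulate,
    "divstats": stage_divstats,
    "admix": stage_admix,
    "sdm": stage_sdm,
    "refugia": stage_refugia,
    "attribute": stage_attribute,
}


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage in order, writing artifacts and a JSON run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())
    stage_names = list(STAGES)
    if config.world is None:
        stage_names.remove("simulate")
    for name in stage_names:
        try:
            info = STAGES[name](config)
        except Exception as exc:
            report.record(name, error=str(exc))
            (out / "report.json").write_text(report.to_json())
            raise
        report.record(name, **info)
    (out / "report.json").write_text(report.to_json())
    return report
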