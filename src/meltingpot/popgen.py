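"""Per-population genetic diversity statistics and data-hygiene filters.

Implements the classical microsatellite / mtDNA summary statistics used to
map diversity across a species range:

* haplotype diversity ``h = n/(n-1) * (1 - sum p_i^2)`` (unbiased),
* nucleotide diversity ``pi`` (mean per-site pairwise difference, pairwise
  deletion of N/gap sites),
* observed and expected heterozygosity (``Ho``, ``He`` with Nei's ``2n/(2n-1)``
  small-sample correction),
* rarefaction allelic richness ``Ar`` (hypergeometric expectation of the
  number of alleles in a standardised subsample of ``g`` gene copies),
* a Monte-Carlo exact Hardy-Weinberg test and Bonferroni correction,

plus the two filters applied before any of this: exclusion of populations
with fewer than ``min_n`` scored genotypes at any locus, and removal of loci
flagged for null alleles in at least ``max_flagged`` populations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "SequenceSample",
    "GenotypeTable",
    "UndefinedStatisticError",
    "haplotype_counts",
    "haplotype_diversity",
    "nucleotide_diversity",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "allelic_richness",
    "default_rarefaction_g",
    "hwe_test",
    "bonferroni",
    "filter_populations",
    "filter_loci",
    "diversity_table",
]

GENOTYPE_COLUMNS = ["population", "individual", "locus", "allele_a", "allele_b"]


class UndefinedStatisticError(ValueError):
    """A statistic was requested on a sample too small to define it."""


@dataclass
class SequenceSample:
    """Aligned DNA sequences from one population (alphabet ACGTN-)."""

    population_id: str
    sequences: list[str]

    def __post_init__(self):
        if len(self.sequences) < 1:
            raise ValueError(f"population {self.population_id}: empty sequence sample")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(
                f"population {self.population_id}: unequal sequence lengths {sorted(lengths)}"
            )
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])


class GenotypeTable:
    """Diploid multi-locus genotypes as a tidy records table.

    One row per (population, individual, locus); alleles are positive integers
    and a missing genotype has both alleles absent (NaN).
    """

    def __init__(self, records: pd.DataFrame):
        df = records.copy()
        missing_cols = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"genotype records missing columns {missing_cols}")
        df = df[GENOTYPE_COLUMNS]
        both = df["allele_a"].isna() == df["allele_b"].isna()
        if not both.all():
            bad = df.loc[~both]
            raise ValueError(
                f"alleles must be missing both-or-neither; offending rows: {bad.index.tolist()[:5]}"
            )
        dup = df.duplicated(subset=["population", "individual", "locus"])
        if dup.any():
            raise ValueError("duplicate (individual, locus) records")
        scored = df.dropna(subset=["allele_a"])
        if ((scored[["allele_a", "allele_b"]] <= 0).any().any()):
            raise ValueError("alleles must be positive integers")
        self.df = df.reset_index(drop=True)

    @property
    def populations(self) -> list:
        return list(pd.unique(self.df["population"]))

    @property
    def loci(self) -> list:
        return list(pd.unique(self.df["locus"]))

    def population(self, population_id) -> pd.DataFrame:
        return self.df[self.df["population"] == population_id]

    def scored(self) -> pd.DataFrame:
        """Rows with a non-missing genotype."""
        return self.df.dropna(subset=["allele_a", "allele_b"])

    def allele_counts(self, population_id, locus) -> pd.Series:
        sub = self.scored()
        sub = sub[(sub["population"] == population_id) & (sub["locus"] == locus)]
        alleles = pd.concat([sub["allele_a"], sub["allele_b"]])
        return alleles.value_counts()

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# mtDNA statistics


def _comparable(a: str, b: str):
    """Site indices where neither sequence has N or a gap."""
    arr_a = np.frombuffer(a.encode(), dtype="S1")
    arr_b = np.frombuffer(b.encode(), dtype="S1")
    ok = ~(np.isin(arr_a, [b"N", b"-"]) | np.isin(arr_b, [b"N", b"-"]))
    return arr_a, arr_b, ok

def haplotype_counts(sample: SequenceSample) -> list[int]:
    """Collapse sequences into haplotype counts.

    Sequences that differ only at N/gap positions are treated as the same
    haplotype: each sequence is merged into the first already-seen haplotype
    it is compatible with (greedy, input order).
    """
    reps: list[str] = []
    counts: list[int] = []
    for seq in sample.sequences:
        for i, rep in enumerate(reps):
            arr_a, arr_b, ok = _comparable(seq, rep)
            if np.all(arr_a[ok] == arr_b[ok]):
                counts[i] += 1
                break
        else:
            reps.append(seq)
            counts.append(1)
    return counts


def haplotype_diversity(counts) -> float:
    """Unbiased haplotype (gene) diversity from haplotype counts.

    ``h = n/(n-1) * (1 - sum (c_i/n)^2)`` — the probability that two
    sequences drawn without replacement carry different haplotypes.
    """
    counts = np.asarray(list(counts), dtype=float)
    if np.any(counts <= 0) or np.any(counts != np.round(counts)):
        raise ValueError("haplotype counts must be positive integers")
    n = counts.sum()
    if n < 2:
        raise UndefinedStatisticError("haplotype diversity needs n >= 2 sequences")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(sample: SequenceSample) -> float:
    """Mean per-site pairwise difference with pairwise deletion.

    For each pair, sites where either sequence has N or a gap are excluded;
    the pair's contribution is (differences / comparable sites).  Pairs with
    no comparable site are dropped with a warning.
    """
    n = sample.n
    if n < 2:
        raise UndefinedStatisticError("nucleotide diversity needs n >= 2 sequences")
    if sample.length < 1:
        raise UndefinedStatisticError("nucleotide diversity needs L >= 1 sites")
    ratios = []
    dropped = 0
    for i in range(n):
        for j in range(i + 1, n):
            arr_a, arr_b, ok = _comparable(sample.sequences[i], sample.sequences[j])
            L_eff = int(ok.sum())
            if L_eff == 0:
                dropped += 1
                continue
            d = int(np.sum(arr_a[ok] != arr_b[ok]))
            ratios.append(d / L_eff)
    if dropped:
        warnings.warn(f"{dropped} sequence pair(s) had no comparable sites and were excluded")
    if not ratios:
        raise UndefinedStatisticError("no sequence pair with comparable sites")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Microsatellite statistics


def _per_locus_allele_counts(pop_records: pd.DataFrame):
    """{locus: Series of allele counts} over scored genotypes of one population."""
    scored = pop_records.dropna(subset=["allele_a", "allele_b"])
    out = {}
    for locus, sub in scored.groupby("locus", sort=False):
        alleles = np.concatenate([sub["allele_a"].to_numpy(), sub["allele_b"].to_numpy()])
        vals, counts = np.unique(alleles, return_counts=True)
        out[locus] = pd.Series(counts, index=vals)
    return out


def expected_heterozygosity(pop_records: pd.DataFrame, unbiased: bool = True) -> float:
    """Mean over loci of (unbiased) expected heterozygosity.

    Per locus: ``He = 2n/(2n-1) * (1 - sum p_a^2)`` with ``n`` scored
    genotypes (Nei's small-sample correction); ``unbiased=False`` drops the
    correction factor.
    """
    per_locus = _per_locus_allele_counts(pop_records)
    if not per_locus:
        raise UndefinedStatisticError("no scorable locus for expected heterozygosity")
    vals = []
    for counts in per_locus.values():
        copies = counts.sum()
        p = counts.to_numpy(dtype=float) / copies
        he = 1.0 - np.sum(p**2)
        if unbiased and copies > 1:
            he *= copies / (copies - 1.0)
        vals.append(he)
    return float(np.mean(vals))


def observed_heterozygosity(pop_records: pd.DataFrame) -> float:
    """Fraction of scored genotypes that are heterozygous, averaged over loci."""
    scored = pop_records.dropna(subset=["allele_a", "allele_b"])
    if scored.empty:
        raise UndefinedStatisticError("no scorable locus for observed heterozygosity")
    het = scored["allele_a"] != scored["allele_b"]
    return float(het.groupby(scored["locus"], sort=False).mean().mean())


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a subsample of g gene copies (hypergeometric)."""
    N = int(counts.sum())
    if g < 1 or g > N:
        raise ValueError(f"rarefaction size g={g} outside [1, {N}]")
    # P(allele absent from the subsample) = C(N - N_a, g) / C(N, g)
    Na = counts.astype(float)
    rest = N - Na
    with np.errstate(invalid="ignore"):
        log_absent = gammaln(rest + 1) - gammaln(rest - g + 1) - (gammaln(N + 1) - gammaln(N - g + 1))
    absent = np.where(rest >= g, np.exp(log_absent), 0.0)
    return float(np.sum(1.0 - absent))


def default_rarefaction_g(table: GenotypeTable) -> int:
    """Global rarefaction size: min over populations and loci of 2 x scored genotypes."""
    scored = table.scored()
    if scored.empty:
        raise UndefinedStatisticError("no scored genotypes")
    sizes = scored.groupby(["population", "locus"], sort=False).size()
    return int(2 * sizes.min())


def allelic_richness(pop_records: pd.DataFrame, g: int) -> float:
    """Rarefaction allelic richness: mean over loci of the expected number of
    distinct alleles in a random subsample of ``g`` gene copies."""
    per_locus = _per_locus_allele_counts(pop_records)
    if not per_locus:
        raise UndefinedStatisticError("no scorable locus for allelic richness")
    vals = []
    for counts in per_locus.values():
        N = int(counts.sum())
        if g > N:
            raise ValueError(f"g={g} exceeds {N} gene copies at a locus")
        vals.append(_rarefied_richness(counts.to_numpy(dtype=float), g))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte-Carlo)


def _log_conditional_prob(pairs: np.ndarray) -> float:
    """Log conditional probability of the genotype configuration given the
    allele counts (Guo & Thompson 1992):

    ``P = n! * prod_a N_a! * 2^H / ((2n)! * prod_{i<=j} n_ij!)``
    with ``H`` the number of heterozygotes.
    """
    n = pairs.shape[0]
    geno = np.sort(pairs, axis=1)
    _, geno_counts = np.unique(geno, axis=0, return_counts=True)
    alleles, allele_counts = np.unique(geno.ravel(), return_counts=True)
    H = int(np.sum(geno[:, 0] != geno[:, 1]))
    return (
        gammaln(n + 1)
        + np.sum(gammaln(allele_counts + 1))
        + H * math.log(2.0)
        - gammaln(2 * n + 1)
        - np.sum(gammaln(geno_counts + 1))
    )


def hwe_test(pop_records: pd.DataFrame, n_perm: int = 1000, seed: int = 0) -> float:
    """Monte-Carlo exact Hardy-Weinberg test for one locus in one population.

    The statistic is the conditional probability of the observed genotype
    configuration given the allele counts; the p-value is the proportion of
    random re-pairings of the allele pool with probability <= observed, with
    the add-one correction ``(1 + hits) / (1 + n_perm)``.

    ``pop_records`` must contain exactly one locus.
    """
    scored = pop_records.dropna(subset=["allele_a", "allele_b"])
    loci = pd.unique(scored["locus"]) if "locus" in scored.columns else [None]
    if len(loci) > 1:
        raise ValueError("hwe_test expects records for a single locus")
    pairs = scored[["allele_a", "allele_b"]].to_numpy(dtype=int)
    if pairs.shape[0] < 3:
        raise UndefinedStatisticError("HWE test needs at least 3 genotypes")
    if np.unique(pairs).size < 2:
        warnings.warn("monomorphic locus: HWE p-value is 1 by convention")
        return 1.0
    log_obs = _log_conditional_prob(pairs)
    pool = pairs.ravel().copy()
    rng = np.random.default_rng(seed)
    hits = 0
    tol = 1e-12
    for _ in range(n_perm):
        rng.shuffle(pool)
        perm = pool.reshape(-1, 2)
        if _log_conditional_prob(perm) <= log_obs + tol:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: ``p_i' = min(1, m * p_i)``."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


# ---------------------------------------------------------------------------
# Filters


def filter_populations(table: GenotypeTable, min_n: int = 4):
    """Drop populations with fewer than ``min_n`` scored genotypes at any locus.

    Returns (filtered table, report DataFrame of dropped populations with the
    offending locus and its sample size).
    """
    scored = table.scored()
    sizes = scored.groupby(["population", "locus"], sort=False).size()
    # a locus entirely missing in a population counts as size 0
    full = sizes.unstack(fill_value=0).reindex(
        index=table.populations, columns=table.loci, fill_value=0
    )
    dropped = []
    for pop in full.index:
        row = full.loc[pop]
        if (row < min_n).any():
            worst = row.idxmin()
            dropped.append({"population": pop, "locus": worst, "n": int(row[worst])})
    report = pd.DataFrame(dropped, columns=["population", "locus", "n"])
    keep = [p for p in table.populations if p not in set(report["population"])]
    if not keep:
        raise UndefinedStatisticError("all populations excluded by the sample-size filter")
    out = GenotypeTable(table.df[table.df["population"].isin(keep)])
    return out, report


def filter_loci(table: GenotypeTable, null_allele_flags: pd.DataFrame, max_flagged: int):
    """Drop loci flagged for null alleles in at least ``max_flagged`` populations.

    ``null_allele_flags`` has columns (locus, population, flagged).  Returns
    (filtered table, report of dropped loci with their flag counts).
    """
    if null_allele_flags.empty:
        return table, pd.DataFrame(columns=["locus", "n_flagged"])
    unknown_loci = set(null_allele_flags["locus"]) - set(table.loci)
    unknown_pops = set(null_allele_flags["population"]) - set(table.populations)
    if unknown_loci or unknown_pops:
        raise ValueError(f"flags reference unknown loci {unknown_loci} or populations {unknown_pops}")
    flagged = null_allele_flags[null_allele_flags["flagged"].astype(bool)]
    counts = flagged.groupby("locus").size()
    drop = counts[counts >= max_flagged]
    report = drop.rename("n_flagged").reset_index()
    keep = [l for l in table.loci if l not in set(drop.index)]
    out = GenotypeTable(table.df[table.df["locus"].isin(keep)])
    return out, report


# ---------------------------------------------------------------------------
# Diversity table


def diversity_table(
    genotypes: GenotypeTable | None = None,
    sequences: list[SequenceSample] | None = None,
    g: int | None = None,
) -> pd.DataFrame:
    """Per-population summary: n_mt, h, pi, n_nuc, Ho, He, Ar.

    Populations present in only one of the two marker sets get NaN for the
    other set's statistics.  ``g`` defaults to the global minimum number of
    gene copies across populations and loci.
    """
    rows: dict = {}
    if sequences:
        for sample in sequences:
            entry = rows.setdefault(sample.population_id, {})
            entry["n_mt"] = sample.n
            if sample.n >= 2:
                entry["h"] = haplotype_diversity(haplotype_counts(sample))
                entry["pi"] = nucleotide_diversity(sample)
    if genotypes is not None and len(genotypes):
        if g is None:
            g = default_rarefaction_g(genotypes)
        scored = genotypes.scored()
        # one pass over (population, locus) groups; per-population statistics
        # are the means over loci of the per-locus values
        acc: dict = {}
        a_col = scored["allele_a"].to_numpy(dtype=float)
        b_col = scored["allele_b"].to_numpy(dtype=float)
        for (pop, _locus), idx in scored.groupby(["population", "locus"], sort=False).indices.items():
            a, b = a_col[idx], b_col[idx]
            _, counts = np.unique(np.concatenate([a, b]), return_counts=True)
            copies = counts.sum()
            p = counts / copies
            he = 1.0 - np.sum(p**2)
            if copies > 1:
                he *= copies / (copies - 1.0)
            if g > copies:
                raise ValueError(f"g={g} exceeds {copies} gene copies at a locus")
            entry = acc.setdefault(pop, {"n": [], "Ho": [], "He": [], "Ar": []})
            entry["n"].append(len(a))
            entry["Ho"].append(float(np.mean(a != b)))
            entry["He"].append(he)
            entry["Ar"].append(_rarefied_richness(counts.astype(float), g))
        for pop, entry in acc.items():
            row = rows.setdefault(pop, {})
            row["n_nuc"] = int(max(entry["n"]))
            row["Ho"] = float(np.mean(entry["Ho"]))
            row["He"] = float(np.mean(entry["He"]))
            row["Ar"] = float(np.mean(entry["Ar"]))
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(
        columns=["n_mt", "h", "pi", "n_nuc", "Ho", "He", "Ar"]
    )
    out.index.name = "population"
    return out.reset_index()
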