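"""Diversity statistics against closed forms and enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from meltingpot.popgen import (
    SequenceSample,
    UndefinedStatisticError,
    allelic_richness,
    bonferroni,
    default_rarefaction_g,
    diversity_table,
    expected_heterozygosity,
    filter_loci,
    filter_populations,
    haplotype_counts,
    haplotype_diversity,
    hwe_test,
    nucleotide_diversity,
    observed_heterozygosity,
)

from conftest import genotype_table, table_from_allele_counts


# ---------------------------------------------------------------------------
# haplotype diversity


@pytest.mark.parametrize(
    "counts,expected",
    [
        ([2, 1], 0.667),
        ([4, 1], 0.400),
        ([5], 0.0),
        ([1, 1, 1, 1], 1.0),
    ],
)
def test_haplotype_diversity_known_values(counts, expected):
    assert haplotype_diversity(counts) == pytest.approx(expected, abs=5e-4)


def test_haplotype_diversity_needs_two_sequences():
    with pytest.raises(UndefinedStatisticError):
        haplotype_diversity([1])


@given(st.lists(st.integers(min_value=1, max_value=10), min_size=1, max_size=6))
@settings(max_examples=100, derandomize=True)
def test_haplotype_diversity_matches_direct_recomputation(counts):
    """h equals n/(n-1) * (1 - sum p^2) for every count configuration."""
    n = sum(counts)
    if n < 2:
        return
    expected = n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts))
    assert haplotype_diversity(counts) == pytest.approx(expected, rel=1e-12)


def test_haplotype_counts_merges_ambiguous_sequences():
    sample = SequenceSample("p", ["ACGT", "ACGN", "TTTT"])
    assert sorted(haplotype_counts(sample)) == [1, 2]


# ---------------------------------------------------------------------------
# nucleotide diversity


def test_pi_identical_sequences_zero():
    assert nucleotide_diversity(SequenceSample("p", ["ACGT" * 5] * 4)) == 0.0


def test_pi_single_difference():
    a = "A" * 100
    b = "A" * 99 + "T"
    assert nucleotide_diversity(SequenceSample("p", [a, b])) == pytest.approx(0.01)


def test_pi_three_sequences_average_over_pairs():
    # pairwise differences (1, 2, 1) over 10 sites -> mean 4/3 / 10
    s1 = "AAAAAAAAAA"
    s2 = "TAAAAAAAAA"
    s3 = "TCAAAAAAAA"
    pi = nucleotide_diversity(SequenceSample("p", [s1, s2, s3]))
    assert pi == pytest.approx((4 / 3) / 10)


def _pi_oracle(seqs):
    """Brute-force mean per-pair per-site difference with pairwise deletion."""
    vals = []
    for a, b in itertools.combinations(seqs, 2):
        num = den = 0
        for x, y in zip(a, b):
            if x in "N-" or y in "N-":
                continue
            den += 1
            num += x != y
        if den:
            vals.append(num / den)
    return sum(vals) / len(vals)


@given(
    st.integers(min_value=2, max_value=5),
    st.integers(min_value=1, max_value=20),
    st.randoms(use_true_random=False),
)
@settings(max_examples=60, derandomize=True)
def test_pi_matches_enumeration_oracle(n, L, rnd):
    alphabet = "ACGTN-"
    seqs = ["".join(rnd.choice(alphabet) for _ in range(L)) for _ in range(n)]
    sample = SequenceSample("p", seqs)
    try:
        got = nucleotide_diversity(sample)
    except UndefinedStatisticError:
        return
    assert got == pytest.approx(_pi_oracle(seqs), rel=1e-12)


# ---------------------------------------------------------------------------
# heterozygosity


def test_he_monomorphic_zero():
    t = table_from_allele_counts({1: 10})
    assert expected_heterozygosity(t.df) == 0.0


def test_he_balanced_two_alleles():
    t = table_from_allele_counts({1: 5, 2: 5})
    assert expected_heterozygosity(t.df) == pytest.approx(10 / 9 * 0.5)


def test_he_skewed_two_alleles():
    t = table_from_allele_counts({1: 9, 2: 1})
    assert expected_heterozygosity(t.df) == pytest.approx(10 / 9 * 0.18)


def test_he_invariant_to_allele_relabelling_and_row_order():
    rng = np.random.default_rng(0)
    rows = [("A", f"i{i}", f"L{l}", rng.integers(1, 5), rng.integers(1, 5))
            for i in range(8) for l in range(3)]
    t = genotype_table(rows)
    relabel = {1: 40, 2: 17, 3: 23, 4: 99}
    df2 = t.df.copy()
    df2["allele_a"] = df2["allele_a"].map(lambda a: relabel[int(a)])
    df2["allele_b"] = df2["allele_b"].map(lambda a: relabel[int(a)])
    df2 = df2.sample(frac=1.0, random_state=1)
    assert expected_heterozygosity(df2) == pytest.approx(expected_heterozygosity(t.df))


def test_ho_extremes_and_mean_over_loci():
    hom = genotype_table([("A", f"i{i}", "L1", 1, 1) for i in range(5)])
    assert observed_heterozygosity(hom.df) == 0.0
    het = genotype_table([("A", f"i{i}", "L1", 1, 2) for i in range(5)])
    assert observed_heterozygosity(het.df) == 1.0
    rows = [("A", f"i{i}", "L1", 1, 2 if i < 3 else 1) for i in range(10)]
    rows += [("A", f"i{i}", "L2", 1, 2 if i < 1 else 1) for i in range(10)]
    assert observed_heterozygosity(genotype_table(rows).df) == pytest.approx(0.2)


# ---------------------------------------------------------------------------
# allelic richness


def _ar_oracle(counts: dict, g: int) -> float:
    """Mean number of distinct alleles over all subsets of g gene copies."""
    copies = [a for a, k in counts.items() for _ in range(k)]
    subs = list(itertools.combinations(range(len(copies)), g))
    return sum(len({copies[i] for i in sub}) for sub in subs) / len(subs)


def test_ar_full_sample_is_observed_count():
    t = table_from_allele_counts({1: 4, 2: 2, 3: 2})
    assert allelic_richness(t.df, g=8) == pytest.approx(3.0)


def test_ar_single_copy_is_one():
    t = table_from_allele_counts({1: 4, 2: 2})
    assert allelic_richness(t.df, g=1) == pytest.approx(1.0)


def test_ar_worked_example_n6_g4():
    t = table_from_allele_counts({1: 4, 2: 2})
    assert allelic_richness(t.df, g=4) == pytest.approx(1 + 1 - 1 / 15)
    assert allelic_richness(t.df, g=4) == pytest.approx(_ar_oracle({1: 4, 2: 2}, 4))


@pytest.mark.parametrize(
    "counts",
    [{1: 4, 2: 2}, {1: 6, 2: 2}, {1: 2, 2: 2, 3: 2}, {1: 5, 2: 1, 3: 2}, {1: 8}],
)
def test_ar_equals_subset_enumeration(counts):
    t = table_from_allele_counts(counts)
    N = sum(counts.values())
    for g in range(1, N + 1):
        assert allelic_richness(t.df, g=g) == pytest.approx(_ar_oracle(counts, g), rel=1e-10)


def test_ar_monotone_in_g():
    t = table_from_allele_counts({1: 4, 2: 3, 3: 1})
    values = [allelic_richness(t.df, g=g) for g in range(1, 9)]
    assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))


def test_default_rarefaction_g_is_global_minimum():
    rows = [("A", f"i{i}", "L1", 1, 2) for i in range(5)]
    rows += [("A", f"i{i}", "L2", 1, 1) for i in range(3)]
    rows += [("B", f"j{i}", "L1", 2, 2) for i in range(4)]
    rows += [("B", f"j{i}", "L2", 1, 2) for i in range(4)]
    assert default_rarefaction_g(genotype_table(rows)) == 6


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def _hwe_enumeration_oracle(pairs):
    """Exact p-value by enumerating every ordering of the allele pool."""
    pool = [a for ab in pairs for a in ab]

    def config_of(perm):
        geno = sorted(tuple(sorted(perm[i : i + 2])) for i in range(0, len(perm), 2))
        return tuple(geno)

    freq = {}
    for perm in set(itertools.permutations(pool)):
        freq[config_of(perm)] = freq.get(config_of(perm), 0) + 1
    total = sum(freq.values())
    obs = config_of([a for ab in pairs for a in ab])
    p_obs = freq[obs] / total
    return sum(v / total for v in freq.values() if v / total <= p_obs + 1e-12)


def test_hwe_monomorphic_is_one():
    t = table_from_allele_counts({1: 8})
    with pytest.warns(UserWarning):
        assert hwe_test(t.df, n_perm=100, seed=0) == 1.0


def test_hwe_matches_enumeration_on_tiny_case():
    pairs = [(1, 1), (1, 2), (2, 2)]
    t = genotype_table([("A", f"i{k}", "L1", a, b) for k, (a, b) in enumerate(pairs)])
    exact = _hwe_enumeration_oracle(pairs)
    mc = hwe_test(t.df, n_perm=5000, seed=3)
    assert mc == pytest.approx(exact, abs=0.02)


def test_hwe_at_equilibrium_proportions_large_p():
    pairs = [(1, 1)] * 2 + [(1, 2)] * 4 + [(2, 2)] * 2
    t = genotype_table([("A", f"i{k}", "L1", a, b) for k, (a, b) in enumerate(pairs)])
    assert hwe_test(t.df, n_perm=2000, seed=0) > 0.5


# ---------------------------------------------------------------------------
# corrections and filters


def test_bonferroni():
    assert np.allclose(bonferroni([0.01, 0.04]), [0.02, 0.08])
    assert np.allclose(bonferroni([0.3]), [0.3])
    assert np.allclose(bonferroni([0.9, 0.9, 0.9]), [1, 1, 1])
    with pytest.raises(ValueError):
        bonferroni([1.2])


def test_filter_populations_drops_undersampled():
    rows = [("A", f"i{i}", "L1", 1, 2) for i in range(3)]  # n=3 at L1 -> dropped
    rows += [("A", f"i{i}", "L2", 1, 2) for i in range(10)]
    rows += [("B", f"j{i}", "L1", 1, 2) for i in range(10)]
    rows += [("B", f"j{i}", "L2", 1, 2) for i in range(10)]
    table, report = filter_populations(genotype_table(rows), min_n=4)
    assert table.populations == ["B"]
    assert report.iloc[0]["population"] == "A" and report.iloc[0]["locus"] == "L1"


def test_filter_populations_identity_cases():
    rows = [(p, f"{p}{i}", "L1", 1, 2) for p in "AB" for i in range(5)]
    t = genotype_table(rows)
    kept, report = filter_populations(t, min_n=4)
    assert kept.populations == ["A", "B"] and report.empty
    kept0, _ = filter_populations(t, min_n=0)
    assert len(kept0.df) == len(t.df)


def test_filter_loci_flag_threshold():
    pops = [f"P{i}" for i in range(14)]
    rows = [(p, f"{p}i{j}", loc, 1, 2) for p in pops for j in range(4) for loc in ("L1", "L2")]
    t = genotype_table(rows)
    flags = pd.DataFrame(
        [{"locus": "L1", "population": p, "flagged": True} for p in pops]
    )
    kept, report = filter_loci(t, flags, max_flagged=14)
    assert kept.loci == ["L2"]
    assert report.iloc[0]["locus"] == "L1" and report.iloc[0]["n_flagged"] == 14
    # below the threshold, or with no flags: identity
    kept2, _ = filter_loci(t, flags, max_flagged=15)
    assert kept2.loci == ["L1", "L2"]
    kept3, _ = filter_loci(t, pd.DataFrame(columns=["locus", "population", "flagged"]), 1)
    assert kept3.loci == ["L1", "L2"]


def test_diversity_table_columns(small_world):
    table = diversity_table(small_world.genotypes, small_world.sequences)
    assert {"population", "h", "pi", "Ho", "He", "Ar"} <= set(table.columns)
    assert table["He"].between(0, 1).all()
    assert table["h"].between(0, 1).all()
    assert (table["Ar"] >= 1).all()
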