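"""Per-population diversity statistics: h, pi, Ho, He, rarefied Ar.

Runs the data-hygiene filters and the diversity table on a synthetic
world's genotypes and mtDNA sequences.
"""

import meltingpot as mp

world = mp.generate_world(mp.WorldConfig(seed=11))

genotypes, dropped = mp.filter_populations(world.genotypes, min_n=4)
print(f"populations kept: {len(genotypes.populations)} "
      f"(dropped {len(dropped)} with n < 4 at some locus)")

table = mp.diversity_table(genotypes, world.sequences)
print(table.head(8).round(3).to_string(index=False))
print("h/pi summarise mtDNA variation; He is unbiased expected heterozygosity")
print("and Ar the expected allele count in a standardised subsample (rarefaction),")
print("so populations with different sample sizes are comparable.")

# A single worked value: two haplotypes in counts 2:1 among three sequences
print(f"haplotype diversity of counts (2, 1): {mp.haplotype_diversity([2, 1]):.3f}")
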