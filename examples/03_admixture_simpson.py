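"""From clustering output to the Simpson admixture index.

Selects the number of clusters K from a DIC-versus-K table (plateau rule),
averages population admixture proportions, and computes Simpson's index —
the predictor used for the melting-pot hypothesis.
"""

from meltingpot import generate_world, WorldConfig
from meltingpot.admixture import population_mean_q, population_simpson, select_k_plateau

world = generate_world(WorldConfig(seed=11))

k = select_k_plateau(world.dic_table, epsilon=0.05)
print(f"DIC plateau selects K = {k} genetic clusters "
      f"(the generator used {len(world.config.lineages())} lineages)")

mean_q = population_mean_q(world.q_matrix)
simpson = population_simpson(world.q_matrix)
print(mean_q.head(5).round(3))
print(simpson.head(5).round(3).to_string())
print("each row: a population's mean cluster proportions; Simpson = 1 - sum q^2,")
print("0 for a pure population, larger where lineages mix.")
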