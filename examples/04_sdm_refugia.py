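"""Ensemble SDM, glacial refugia and stability areas.

Cleans and thins occurrences, prunes collinear layers by VIF, fits the
AUC-weighted learner ensemble, projects it onto three glacial scenarios,
and maps the >= 2-GCM consensus refugia and stability areas.
"""

import warnings

import numpy as np
import pandas as pd

import meltingpot as mp
from meltingpot.grid import BinaryMap
from meltingpot.refugia import AncestralArea

warnings.simplefilter("ignore")

world = mp.generate_world(mp.WorldConfig(seed=11))
env = world.env_current

occ = mp.clean_occurrences(world.occurrences)
thinned = mp.thin_occurrences(occ, d_min=6.0, n_datasets=5, seed=1)
print(f"occurrences: {len(world.occurrences)} raw -> {len(occ)} clean -> "
      f"{len(thinned[0][0])} per thinned replicate (d_min = 6 km)")

rng = np.random.default_rng(2)
cells = np.argwhere(env.valid_mask())
sample = cells[rng.choice(len(cells), size=400, replace=False)]
design = pd.DataFrame(env.design_matrix(sample[:, 0], sample[:, 1]), columns=env.names)
variables = mp.vif_select(design, threshold=5.0)
print(f"VIF < 5 keeps layers: {variables} (one of the correlated pair was dropped)")

region = BinaryMap(env.geometry, env.valid_mask().astype(float))
background = mp.target_group_background(world.target_group, region)
model = mp.fit_ensemble(thinned, background, env, variables=variables, seed=3)
print(f"ensemble: {len(model.included)}/{len(model.members)} fits passed AUC > 0.7; "
      f"maxTSS threshold = {model.threshold:.3f}")

gcm_binaries = [mp.binarize(mp.project(model, stack), model.threshold)
                for stack in world.env_gcm]
consensus = mp.gcm_consensus(gcm_binaries, min_agree=2)
current = mp.binarize(mp.project(model, env), model.threshold)
union = None
for area in world.ancestral_areas.values():
    union = area.polygon if union is None else union.union(area.polygon)
stability = mp.stability_areas(current, consensus, AncestralArea(union))
print(f"glacial refugia (>=2 of {len(gcm_binaries)} GCMs): {consensus.count()} cells; "
      f"stability areas (refugia & ancestral & current): {stability.count()} cells")

truth = world.true_suitability
suit = mp.project(model, env)
m = suit.mask & truth.mask
print(f"correlation of ensemble suitability with the generating truth: "
      f"{np.corrcoef(suit.values[m], truth.values[m])[0, 1]:.3f}")
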