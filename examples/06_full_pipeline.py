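"""The whole pipeline in one call, writing every intermediate artifact.

Equivalent to the CLI:  meltingpot all --out run_demo --seed 11
"""

import warnings

import meltingpot as mp

warnings.simplefilter("ignore")

config = mp.RunConfig(out_dir="run_demo", seed=11, world=mp.WorldConfig(seed=11))
report = mp.run_pipeline(config)

print(f"report checksum (rerun with the same seed reproduces it): {report.checksum()[:16]}")
for stage, info in report.stages.items():
    keys = {k: v for k, v in info.items() if not isinstance(v, (list, dict))}
    print(f"{stage}: {keys}")
print("artifacts (GenePop, FASTA, CSV, ESRI ASCII grids, GeoJSON, JSON) are in run_demo/")
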