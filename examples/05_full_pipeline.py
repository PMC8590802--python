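"""Run the whole pipeline end to end with one seeded configuration.

Synthesizes the landscape, builds covariates, fits the population RSF,
predicts suitability, estimates home ranges and the individual RSF,
models connectivity under three resistance shapes, validates the maps
with synthetic dispersers, and writes every artifact plus a hashed
manifest to the output directory.
"""

import json
from pathlib import Path

from habconn.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=11, outdir="pipeline_demo")
manifest = run_pipeline(cfg)

print("stages run:")
for stage, info in manifest["stages"].items():
    print(f"  {stage:10s} seed {info['seed']:>10d}  {info['seconds']:6.2f} s")

print(f"\n{len(manifest['artifacts'])} artifacts in {cfg.outdir}/:")
for name in sorted(manifest["artifacts"]):
    print(f"  {name}")

sel = Path(cfg.outdir) / "map_selection.csv"
print("\nconnectivity map selection table:")
print(sel.read_text())
print("Rerunning with the same seed reproduces every artifact hash in"
      "\nmanifest.json byte for byte.")
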