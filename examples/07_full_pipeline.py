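"""Run the whole analysis end-to-end from one config.

simulate -> enrich -> signatures -> cluster -> survival -> single_cell ->
modules -> annotate, with per-stage derived seeds and a provenance manifest.
All stage outputs are plain TSV/GMT/JSON files in the run directory.
"""

import json
from pathlib import Path

from pathstrat import run_pipeline

outdir = Path("pathstrat_demo_run")
manifest = run_pipeline({"outdir": str(outdir), "seed": 42})

print("stages completed:", ", ".join(manifest.stages_run))
print("per-stage seeds:", manifest.seeds)
labels = (outdir / "labels.tsv").read_text().splitlines()
print(f"cluster labels written for {len(labels) - 1} samples")
robust = json.loads((outdir / "robustness.json").read_text())
print(f"chosen k = {robust['chosen_k']}, random-forest OOB accuracy = "
      f"{robust['oob_accuracy']:.2f}")
print()
print("Re-running with the same seed reproduces byte-identical outputs;")
print("the manifest records config, seeds, and SHA-256 digests of every file.")
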