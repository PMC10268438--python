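"""Full pipeline on a synthetic input bundle.

Writes raw count CSVs, a cohort CSV (covariates, sleep reports, markers) for
30 participants, then runs every stage — accelerometer processing, 24-h
composition assembly, descriptives, robust fit, substitution table — and
prints the run manifest. Outputs land under ./scratch/pipeline_demo/.
"""

import json
from pathlib import Path

from tuscoda import simulate_bundle
from tuscoda.pipeline import RunConfig, run_all

root = Path("scratch/pipeline_demo")
bundle = simulate_bundle(root / "inputs", n=30, seed=7)
config = RunConfig(
    counts_dir=bundle["counts_dir"],
    cohort_csv=bundle["cohort_csv"],
    out_dir=str(root / "outputs"),
    seed=7,
)
manifest = run_all(config)
print(json.dumps(manifest, indent=2, sort_keys=True))
# The manifest records inputs, parameters and the seed; rerunning with the
# same config reproduces every CSV byte-for-byte. Inspect
# outputs/descriptives.csv and outputs/substitution_marker.csv for the
# descriptive table and the reallocation matrix.
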