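"""Generate the four calibrated synthetic cohorts.

Writes per-specimen spectra / mechanical curves plus a ground-truth table
for each preset under results/cohorts/<preset>/.  Every downstream script
reads these directories or regenerates the cohorts from the same seed.
"""

import sys
from pathlib import Path

from osteospec import synth

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"

for name in ["paper-tendon-raman", "paper-bone-ftir", "paper-tensile", "paper-bending"]:
    outdir = OUT / name
    specimens, truth = synth.synth_cohort(name, SEED, outdir=outdir)
    groups = truth.groupby("group").size().to_dict()
    print(f"{name}: {len(specimens)} specimens {groups} -> {outdir}")
print("done")
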