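#!/usr/bin/env python
"""Equilibrium affinity of the sensor from titration histograms.

Simulates pooled efficiency histograms across an eight-point titration
(0.1-100 uM), extracts the bound fraction per concentration as the area of
the high-efficiency Gaussian component, and fits the hyperbolic isotherm
f = A*c/(K_D + c).
"""

import argparse
import json
import warnings
from pathlib import Path

from lumensor.workflows import run_binding_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

warnings.filterwarnings("ignore")
study = run_binding_study(seed=args.seed)
study.points.to_csv(args.out / "binding_isotherm.csv", index=False)
with open(args.out / "binding_summary.json", "w") as fh:
    json.dump(
        {
            "kd_uM": round(study.fit.kd, 4),
            "kd_se": round(study.fit.kd_se, 4),
            "amplitude": round(study.fit.amplitude, 4),
            "n_molecules_total": study.n_molecules_total,
            "seed": args.seed,
        },
        fh, indent=2,
    )

print(study.points.to_string(index=False))
print()
print(
    f"Hyperbolic isotherm fit: K_D = {study.fit.kd:.3f} +- "
    f"{study.fit.kd_se:.3f} uM, saturation amplitude "
    f"{study.fit.amplitude:.3f} ({study.n_molecules_total} molecules)."
)
print(
    "Half of the sensors are peptide-bound at the K_D - the same "
    "concentration scale as one peptide inside a 100-nm liposome (3.2 uM), "
    "which is what makes single-event counting feasible."
)
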