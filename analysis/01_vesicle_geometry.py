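#!/usr/bin/env python
"""Geometry of the single-molecule concentration meter.

Tabulates lumen volumes, the concentration jump caused by one encapsulated
peptide, and Poisson encapsulation statistics for the reconstitution ratios
used in the study (0.2 sensors and 0.1 transporters per liposome), and
solves the design question "how much can the loading be raised before
multi-occupancy becomes non-negligible?".
"""

import argparse
from pathlib import Path

import pandas as pd

from lumensor import (
    design_encapsulation,
    lumen_volume,
    multi_occupancy_given_occupied,
    poisson_occupancy,
    single_molecule_concentration,
)

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

rows = []
for d in (60, 80, 100, 120, 150, 200):
    rows.append(
        {
            "diameter_nm": d,
            "lumen_volume_aL": round(lumen_volume(d), 4),
            "single_peptide_uM": round(single_molecule_concentration(d), 3),
        }
    )
geom = pd.DataFrame(rows)
geom.to_csv(args.out / "vesicle_geometry.csv", index=False)

occ_rows = []
for label, lam in (("sensor", 0.2), ("transporter", 0.1)):
    occ_rows.append(
        {
            "species": label, "mean_per_vesicle": lam,
            "p_empty": round(poisson_occupancy(lam, 0), 4),
            "p_single": round(poisson_occupancy(lam, 1), 4),
            "p_multi_given_occupied": round(
                multi_occupancy_given_occupied(lam), 4
            ),
        }
    )
occ = pd.DataFrame(occ_rows)
occ.to_csv(args.out / "encapsulation_statistics.csv", index=False)

lam_5pct = design_encapsulation(0.05)

print(geom.to_string(index=False))
print()
print(occ.to_string(index=False))
print()
print(
    "A 100-nm liposome encloses "
    f"{lumen_volume(100):.3f} aL, so each translocated peptide raises the "
    f"lumenal concentration by {single_molecule_concentration(100):.2f} uM - "
    "squarely inside the sensor's linear detection range."
)
print(
    "At 0.2 sensors/vesicle, "
    f"{multi_occupancy_given_occupied(0.2) * 100:.1f}% of occupied vesicles "
    "carry more than one sensor; keeping that contamination below 5% would "
    f"allow a mean loading of up to {lam_5pct:.3f} per vesicle."
)
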