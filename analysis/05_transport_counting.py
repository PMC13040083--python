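#!/usr/bin/env python
"""Count single translocation events in individual liposomes.

The headline experiment: Poisson-loaded 100-nm proteoliposomes with exactly
one sensor and one uptake-competent transporter are run through phased
nucleotide protocols; each sensor's closing rate is converted into a lumenal
peptide concentration via the measured calibration response line, and into
an integer peptide count via the 3.17-uM single-molecule increment.

Protocols analyzed:
  * two sequential Mg-ATP single-turnover incubations (counts 0 -> 1 -> 2);
  * two ATP-EDTA incubations followed by Mg-ATP (1 -> 1 -> 2: ATP binding
    without Mg2+ drives exactly one event and locks the transporter
    outward-facing until Mg2+-dependent hydrolysis resets it).
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from lumensor.workflows import run_calibration_study, run_counting_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

warnings.filterwarnings("ignore")
print("Measuring the dwell-pipeline response line on a fresh titration ...")
cal = run_calibration_study(seed=args.seed)

tables = []
for offset, protocol in enumerate(("two_event_mg_atp", "atp_edta")):
    study = run_counting_study(
        seed=args.seed + 100 + offset, curve=cal.curve_dwell,
        protocol_name=protocol, n_eligible=100,
    )
    per = study.per_phase.copy()
    per.insert(0, "protocol", protocol)
    tables.append(per)
    study.report.vesicles.assign(protocol=protocol).to_csv(
        args.out / f"vesicle_counts_{protocol}.csv", index=False
    )
summary = pd.concat(tables, ignore_index=True)
summary.to_csv(args.out / "transport_counting_summary.csv", index=False)

print()
print(summary.to_string(index=False))
print()
two = summary[summary.protocol == "two_event_mg_atp"]
edta = summary[summary.protocol == "atp_edta"]
print(
    "Mg-ATP protocol: modal counts "
    f"{two.modal_count.tolist()} across phases (truth "
    f"{two.true_count.tolist()}); each single-turnover incubation moves the "
    "count up by exactly one peptide."
)
print(
    "ATP-EDTA protocol: modal counts "
    f"{edta.modal_count.tolist()} (truth {edta.true_count.tolist()}); the "
    "second EDTA addition is futile and only Mg-ATP re-arms the transporter, "
    "i.e. ATP binding alone powers one - and only one - translocation event."
)
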