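# lumensor

A single-molecule FRET *concentration meter* for liposome lumens: from
three-channel ALEX fluorescence trajectories of an encapsulated
peptide-binding sensor to lumenal peptide concentrations and integer counts
of translocated substrates — with a matched synthetic-data generator for
every study condition.

## The problem

ABC transporters move substrates across membranes using ATP, but bulk
transport assays average over thousands of proteoliposomes and cannot
resolve *individual* translocation events. The trick this package
implements computationally: encapsulate a two-state peptide sensor (an
OppA-type substrate-binding protein, FRET-labelled) inside ~100-nm
liposomes carrying a single transporter. The sensor's closing rate is
pseudo-first-order in peptide,

    k_close(c) = k_close_base + k_on · c ,      k_on = 0.29 µM⁻¹ s⁻¹

so a hidden-Markov / dwell-time analysis of its FRET trajectory reads out
the lumenal concentration. Because a 100-nm lumen holds only ~0.52 aL, one
translocated peptide raises the concentration by

    c₁ = 1 / (N_A · V) ≈ 3.2 µM ,

a full step on the meter — transport becomes *countable*: concentration ÷
increment, rounded. With this logic a single Mg-ATP incubation moves the
modal count from 0 to 1, a second one to 2; ATP without Mg²⁺ (ATP-EDTA)
drives exactly one event and then stalls until Mg-ATP resets the
transporter — the single-molecule signature that ATP *binding* alone powers
one translocation event while Mg²⁺-dependent hydrolysis resets the cycle.

Intended users: single-molecule biophysicists building or validating
sensor-in-vesicle transport assays, and method developers who need a
ground-truthed testbed for smFRET trace-analysis chains.

## What is inside

| Module | Contents |
| --- | --- |
| `lumensor.simulate` | Two-state state paths, camera-frame rendering (blur, noise, photobleaching), titrations, Poisson vesicle ensembles, phased transport protocols |
| `lumensor.trace` | `Trace`/`FretTrajectory`, apparent E/S, change-point bleach detection, rule-based classification, dwell extraction |
| `lumensor.hmm` | Two-state Gaussian Baum–Welch, Viterbi/MAP decoding, exact forward likelihood |
| `lumensor.mixture` | Gaussian mixture fits of efficiency histograms, bound fractions |
| `lumensor.kinetics` | Censored-exponential and embedded-chain dwell MLEs, decode-free fluctuation (autocovariance) rate estimation, calibration line fit/inversion, binding isotherm, kinetic K_D |
| `lumensor.geometry` | Lumen volumes, single-molecule concentrations, Poisson occupancy, intensity→diameter sizing |
| `lumensor.transport` | Per-vesicle concentration & integer-count inference, population shift, end-to-end `run_pipeline` |
| `lumensor.io` | CSV trace/report round trips, validated YAML run configs |
| `lumensor.workflows` | The five studies used by `analysis/` and the acceptance script |

The `analysis/` directory holds numbered drivers (geometry, sensor
calibration, binding affinity, FRET levels, transport counting) that write
their tables under `results/`.

## Worked example

```python
import numpy as np
from lumensor import (SensorKinetics, PhotophysicsModel, simulate_state_path,
                      render_trace, preprocess_trace, infer_concentration,
                      estimate_peptide_count)
from lumensor.workflows import run_calibration_study

# 1. calibrate the meter once on a simulated titration (1-10 uM)
study = run_calibration_study(seed=1)
print(f"k_on = {study.curve.k_on:.4f} /uM/s, tau = {study.tau:.3f} s")

# 2. a vesicle that just received one peptide (3.17 uM in a 100-nm lumen)
kin, phot = SensorKinetics(), PhotophysicsModel()
rng = np.random.default_rng(7)
path = simulate_state_path(kin, 3.1714, duration=360.0, seed=rng)
trace = render_trace(path, phot, kin, n_frames=3600, seed=rng)

# 3. read the meter
traj = preprocess_trace(trace)
inf = infer_concentration(traj, study.curve_dwell)
count = estimate_peptide_count(inf.concentration, diameter_nm=100.0)
print(f"c = {inf.concentration.concentration:.2f} "
      f"+- {inf.concentration.se:.2f} uM -> count = {count.count}")
```

Output from this exact script:

```
k_on = 0.2842 /uM/s, tau = 0.501 s
c = 3.24 +- 1.33 uM -> count = 1
```

The calibration recovers the sensor's association rate constant
(0.29 µM⁻¹s⁻¹) and closed-state lifetime (0.5 s); the single-vesicle
readout lands on the true concentration within its error and rounds to the
correct count of one peptide. Running
`python analysis/05_transport_counting.py` extends this to 100 vesicles per
protocol: the two-incubation Mg-ATP experiment yields modal counts
0 → 1 → 2, and the ATP-EDTA experiment 1 → 1 → 2 (the second EDTA addition
is futile; Mg-ATP re-arms the transporter).

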