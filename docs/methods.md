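# Methods

## The measurement idea

A promiscuous peptide-binding protein (an OppA-type substrate-binding
protein, dual-labelled with a donor/acceptor FRET pair) is encapsulated
inside ~100-nm liposomes together with a single ABC transporter. The sensor
switches between an open (apo) conformation with apparent FRET efficiency
E ≈ 0.6 and a closed (peptide-bound) conformation with E ≈ 0.9. Opening is
concentration-independent (rate `k_open`, lifetime τ = 1/`k_open`), while
closing is pseudo-first-order in the free peptide concentration `c`:

    k_close(c) = k_close_base + k_on · c

so the sensor's closing rate is a *concentration meter*. A 100-nm lumen
encloses 0.524 aL, hence one encapsulated peptide corresponds to
1/(N_A·V) = 3.17 µM — comfortably inside the meter's linear range. Counting
translocated peptides therefore reduces to: measure the closing rate, invert
the calibration line, divide by the single-molecule increment, round.

Default sensor constants: `k_on` = 0.29 µM⁻¹s⁻¹, `k_open` = 2.0 s⁻¹
(τ = 0.5 s), E_open = 0.6, E_closed = 0.9, per-frame efficiency width
σ_E = 0.06. The baseline closing rate `k_close_base` = 1.28 s⁻¹ is required
for the calibrated rates to span ~1.6 s⁻¹ at 1 µM to ~4.2–4.5 s⁻¹ at 10 µM
with this slope; a zero intercept is inconsistent with those endpoints.
Whether the measured range reflects a true intercept or a mild nonlinearity
cannot be decided from the available calibration; the package models an
intercept and `ENDPOINT_LINE_KINETICS` (slope 29/90, intercept 1.278 —
the exact line through the two endpoints) is provided for simulations that
must reproduce the printed endpoints.

All efficiencies are *apparent* (uncorrected) values: E = I_DA/(I_DA+I_DD),
S = (I_DD+I_DA)/(I_DD+I_DA+I_AA). No γ/crosstalk corrections are applied
(none are published for this sensor); `FretTrajectory.corrected()` is an
affine hook defaulting to the identity.

## Synthetic data generator

`lumensor.simulate` generates everything the analysis consumes, with known
ground truth:

* **State paths** — continuous-time two-state Markov paths; dwells are
  exactly exponential with the rates above; the initial state is drawn from
  the stationary distribution.
* **Camera frames** — each 100-ms frame carries the occupancy-weighted
  average of the two efficiency levels (motion blur), plus Gaussian noise
  σ_E. Channel intensities are synthesized so the uncorrected E/S
  computation recovers the intended efficiency with S ≈ 0.5 (1000
  counts/frame per excitation, Gaussian camera noise of 20 counts/frame by
  default; Poisson shot noise by flag; background 0 by default so apparent
  E/S round-trip exactly).
* **Photobleaching** — single-step, exponential in illumination time,
  0.002 s⁻¹ per dye by default. This reflects the very low excitation
  intensities (≲1 mW/cm²) and oxygen-scavenging/triplet-quenching imaging
  buffer of the experiment being emulated; after donor bleach both
  donor-excited channels fall to background, after acceptor bleach the
  FRET signal is rerouted entirely into the donor channel.
* **Vesicle ensembles** — Poisson copy numbers (defaults 0.2 sensors, 0.1
  transporters per liposome), truncated log-normal diameters (median
  100 nm, geometric SD 1.15, bounds 40–400 nm), 50% uptake-competent
  orientation. Analysis-eligible = exactly one sensor, one competent
  transporter.
* **Phased transport protocols** — peptides are deposited at phase
  boundaries (incubations happen off-microscope): Mg-ATP drives one
  translocation event per competent transporter per incubation and resets
  the transporter; ATP-EDTA drives one event and leaves it locked
  outward-facing until a Mg-ATP phase resets it; Mg-ADP/apo phases do
  nothing. Default acquisition is 3600 frames (6 min) per vesicle per
  phase — a conservative fraction of the hour-long observation window the
  emulated protocol spends per phase, sized so that the per-vesicle
  concentration SE (~1 µM at two peptides; photobleaching caps usable
  illumination at ~250 s) resolves the 3.17-µM single-peptide increment.
  The bleach clock restarts each phase (fields of view are rotated during
  acquisition, so a molecule's movie is its first illumination that phase).

Seeding: one master seed; per-trace substreams via
`numpy.random.SeedSequence.spawn`, so identical seeds give bit-identical
outputs.

What the generator does **not** emulate: photon-level (sub-frame)
timestamps, spectral crosstalk and direct excitation, dye blinking,
multi-exponential dwell mixtures, membrane diffusion, transporter
conformational kinetics within a trace, vesicle lamellarity or osmotic
effects. Passing recovery tests therefore demonstrates correctness of the
inference chain under the stated two-state/blur/noise/bleach model, not
robustness to every artifact of real recordings.

## Trace analysis

* **Quality control** — single-step bleach detection by recursive
  change-point search (two-segment SSE split with a robust,
  successive-difference noise scale) on the two FRET-independent signals:
  I_AA for the acceptor and I_DD+I_DA for the donor; ≥2 acceptor steps flag
  multi-fluorophore vesicles. Frames after the earliest bleach, frames with
  no donor-excitation signal, and frames with apparent E outside
  [−0.2, 1.2] are masked.
* **Classification** — deterministic rules replacing a learned screen:
  median S in [0.3, 0.7], ≥50 usable frames, single-step bleach, robust
  per-frame noise below 0.12; traces with ≥95% occupancy on one side of
  E = 0.75 are static_low/static_high; otherwise a trace is dynamic if the
  Viterbi path of the fitted HMM makes ≥2 transitions.
* **HMM** — two-state Gaussian-emission Baum–Welch, written out for the
  two-state case (scaled forward/backward; EM tolerance 1e-6; max 300
  iterations; variance floor 1e-4; means initialised at the 10th/90th
  percentiles; states reported in ascending mean order). Viterbi decoding
  breaks ties toward the lower-mean state and weights the first frame by
  the stationary distribution. The forward log-likelihood is checked in the
  tests against exhaustive 2^N path enumeration and against an independent
  HMM library under identical parameters.

## Rate estimation: two estimators, used where each is strong

Camera integration is the dominant systematic at these rates
(λ = k_close+k_open ≈ 3.5–6.2 s⁻¹ against a 10-s⁻¹ frame rate). Decoding a
blurred trace frame-by-frame and applying a dwell-time MLE — in any
variant we measured (full Viterbi, neutral-prior MAP, fixed thresholds,
with or without the embedded discrete-chain correction) — misses or merges
short dwells and biases fast closing rates by 5–25%.

1. **Fluctuation analysis** (`rates_from_efficiency`) — the population
   estimator. Two moments of the blurred, noisy signal are exactly
   bias-free: the autocovariance of E decays as γ(m) ∝ exp(−λ·Δt·m) for
   lags m ≥ 1 (integration only rescales the amplitude; frame noise only
   enters lag 0), and the mean of E gives the closed-state occupancy
   π_c = (Ē−E_open)/(E_closed−E_open) against the sensor's calibrated
   levels. λ is fitted to the pooled autocovariance by GLS with an
   empirical (across traces, shrunk toward its diagonal) lag covariance
   and an adaptive lag window; k_close = λπ_c, k_open = λ(1−π_c); SEs by
   leave-one-trace-out jackknife. On ground-truth simulations this
   recovers k_close within ~1% at every calibration concentration. All
   reported physical constants (k_on, intercept, τ) come from this
   estimator.
2. **Dwell chain** (`threshold_states` → `extract_dwells` →
   `rates_from_dwells`) — the per-vesicle estimator. Frames are decoded at
   the calibrated level midpoint (0.75; a per-trace refit would add
   coherent threshold jitter), dwells are run-length encoded with
   first/last dwells censored, and rates invert the embedded discrete-time
   chain: p = 1/mean(complete run length), λΔt = −ln(1−p_oc−p_co),
   k_close = λ·p_oc/(p_oc+p_co). This is the exact MLE under frame-sampled
   observation and has ~40% lower single-trace variance than fluctuation
   analysis, at the price of a stable few-percent blur bias. That bias is
   cancelled by calibrating the *response line* of this same pipeline on
   the titration (`CalibrationStudy.curve_dwell`) and inverting
   concentrations through it — the standard instrument-response approach.
   `estimate_rate` additionally provides the classical exponential MLE
   (1/mean; right-censored dwells via the survival term when included,
   left-censored always excluded) for continuous dwell data.

The kinetic dissociation constant k_open/k_on (≈ 6.9 µM at the default
constants) is reported as a diagnostic next to the equilibrium K_D
(0.9 µM from the isotherm); the two need not agree — a sensor whose
closing is not a single diffusion-limited bimolecular step breaks the
identity — and the package never substitutes one for the other.

## Population and counting analyses

* **Mixture fits** — one- or two-component Gaussian maximum likelihood on
  pooled E (variance floor 1e-4); the bound fraction is the area of the
  high component. When the two fitted means are closer than 0.15 the pool
  is unimodal and a two-component fit would split one Gaussian arbitrarily;
  the population is then assigned wholesale by the side of 0.75 its mode
  lies on.
* **Binding isotherm** — nonlinear least squares of f = A·c/(K_D+c) with
  free saturation amplitude A ∈ (0, 1], because mixture-area fractions need
  not reach 1.
* **Counting** — concentration estimates are clipped at zero (below-
  detection events are expected and flagged, not errors); the integer count
  is round(c / single-molecule increment) with an interval from the ±1.96·SE
  band — rounding rather than Bayesian model comparison, to keep the logic
  auditable. Vesicles whose sensor is statically high-FRET are reported as
  saturated rather than given a count; statically low-FRET sensors report
  an empty lumen. The per-vesicle diameter defaults to 100 nm (the dominant
  population) unless a measured diameter from the intensity→diameter
  conversion is supplied.
* **Population shift** — per-phase high-FRET area fractions with Wilson
  binomial confidence intervals at the molecule level.

## Geometry conventions

Lumen diameter equals nominal diameter (no bilayer-thickness subtraction),
matching the convention 100 nm → 0.52 aL → 3.17 µM. The intensity→diameter
conversion assumes a membrane-partitioning dye (signal ∝ surface area,
d = d_ref·√(I/I_ref)); a cube-root mode exists for lumenal dyes.

## Problem sizes

The bundled studies run on one CPU in minutes: the calibration titration
uses 150 traces × 600 frames at each of 1, 2, 5, 10 µM; the binding
titration 300 molecules × 100 frames at eight concentrations from 0.1 to
100 µM; the efficiency-level studies 200 traces each; the counting studies
100 eligible vesicles × 3 phases × 3600 frames drawn from a 30 000-vesicle
Poisson ensemble.

## Known limitations

* Per-vesicle concentration precision is blur- and bleach-limited to
  ~1 µM; counts beyond ~3 peptides per 100-nm vesicle approach sensor
  saturation and are not meaningfully resolvable.
* The dwell-chain estimator must be inverted through its own response
  line; feeding it the physical calibration line reintroduces the blur
  bias (~+10% on concentrations).
* Only two-state models are supported; no model selection over state
  numbers or dwell-mixture components.
* The rule-based classifier is tuned to this sensor's level separation
  (0.3) and noise scale; markedly different sensors need new thresholds.
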