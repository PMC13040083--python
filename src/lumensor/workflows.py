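"""End-to-end study drivers used by the analysis scripts and acceptance suite.

Each driver simulates a study at its stated conditions, pushes the synthetic
data through the full analysis chain, and returns the recovered quantities
next to the ground truth.  Problem sizes default to desk-scale versions of
the corresponding experiments (hundreds of traces rather than thousands of
molecules) — large enough that parameter-recovery checks are limited by the
method, not by Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kinetics import (
    BindingFit,
    CalibrationCurve,
    RateEstimate,
    fit_binding_isotherm,
    fit_calibration,
    rates_from_dwells,
    rates_from_efficiency,
)
from .mixture import (
    MixtureFit,
    bound_fraction_from_sample,
    fit_fret_histogram,
)
from .params import ENDPOINT_LINE_KINETICS, PhotophysicsModel, SensorKinetics
from .simulate import (
    atp_edta_protocol,
    simulate_binding_titration,
    simulate_titration,
    simulate_transport_experiment,
    simulate_vesicle_ensemble,
    two_event_mg_atp_protocol,
)
from .trace import (
    DYNAMIC,
    DwellSet,
    classify_trace,
    extract_dwells,
    threshold_states,
)
from .transport import analyze_experiment, preprocess_trace


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Calibration study (kinetic titration -> k_on, tau, rate at 10 uM)
# ---------------------------------------------------------------------------

@dataclass
class CalibrationStudy:
    curve: CalibrationCurve          # fluctuation-analysis line (physical constants)
    curve_dwell: CalibrationCurve    # dwell-pipeline response line (for inversion)
    points: pd.DataFrame             # per-concentration recovered rates
    tau: float                       # pooled closed-state lifetime (s)
    tau_se: float
    n_dynamic_traces: int
    n_traces_used: int
    kinetics: SensorKinetics


def titration_dwells(
    titration, thresholds=None, e_mid: float = 0.75,
) -> dict:
    """Pool fixed-threshold dwells of dynamic traces per concentration."""
    pooled: dict = {}
    counts: dict = {}
    for c, traces in titration.traces.items():
        dsets = []
        for tr in traces:
            traj = preprocess_trace(tr)
            if classify_trace(traj, thresholds) != DYNAMIC:
                continue
            path = threshold_states(traj.E_usable, e_mid)
            dsets.append(extract_dwells(path, traj.frame_time))
        if dsets:
            pooled[c] = DwellSet.concatenate(dsets)
            counts[c] = len(dsets)
    return {"dwells": pooled, "n_dynamic": counts}


def run_calibration_study(
    seed: int,
    kinetics: SensorKinetics | None = None,
    phot: PhotophysicsModel | None = None,
    concentrations=(1.0, 2.0, 5.0, 10.0),
    n_traces_per_conc: int = 150,
    n_frames: int = 600,
    frame_time: float = 0.1,
) -> CalibrationStudy:
    """Simulate the calibration titration and recover the line through it.

    Two estimates are produced per concentration and combined into two
    calibration lines:

    * ``curve`` -- closing rates from decode-free fluctuation analysis
      (:func:`lumensor.kinetics.rates_from_efficiency`) over all
      QC-passing traces; unbiased under camera blur, this line carries the
      physical constants (k_on slope, baseline intercept) and the pooled
      closed-state lifetime.
    * ``curve_dwell`` -- closing rates from the HMM/MAP-dwell chain
      (:func:`lumensor.kinetics.rates_from_dwells`) over dynamic traces;
      this is the response line of the per-vesicle dwell pipeline and is
      the correct curve to invert when reading single-vesicle
      concentrations with that same pipeline.
    """
    kin = kinetics or SensorKinetics()
    titr = simulate_titration(
        kin, phot or PhotophysicsModel(), concentrations, n_traces_per_conc,
        frame_time=frame_time, n_frames=n_frames, seed=seed,
    )
    rows = []
    acf_points, dwell_points, ko_rates = [], [], []
    n_used = 0
    pooled = titration_dwells(titr)
    for c in sorted(titr.traces):
        e_traces = []
        for tr in titr.traces[c]:
            traj = preprocess_trace(tr)
            if classify_trace(traj) != "rejected" and traj.n_usable > 2:
                e_traces.append(traj.E_usable)
        n_used += len(e_traces)
        closing, opening = rates_from_efficiency(
            e_traces, frame_time, e_open=kin.E_open, e_closed=kin.E_closed,
        )
        acf_points.append((c, closing))
        ko_rates.append(opening)
        row = {
            "concentration": c,
            "closing_rate": closing.rate, "closing_rate_se": closing.se,
            "opening_rate": opening.rate, "opening_rate_se": opening.se,
            "n_traces": len(e_traces),
            "true_closing_rate": kin.closing_rate(c),
        }
        if c in pooled["dwells"]:
            d_cl, d_op = rates_from_dwells(pooled["dwells"][c])
            dwell_points.append((c, d_cl))
            row.update(
                closing_rate_dwell=d_cl.rate, closing_rate_dwell_se=d_cl.se,
                opening_rate_dwell=d_op.rate,
                n_dynamic_traces=pooled["n_dynamic"][c],
            )
        rows.append(row)
    if len(acf_points) < 2:
        raise ValidationError("titration produced fewer than two usable points")
    curve = fit_calibration(acf_points)
    curve_dwell = fit_calibration(dwell_points) if len(dwell_points) >= 2 else curve
    w = np.array([1.0 / r.se**2 for r in ko_rates])
    ko = float(np.sum(w * [r.rate for r in ko_rates]) / w.sum())
    ko_se = float(1.0 / np.sqrt(w.sum()))
    return CalibrationStudy(
        curve=curve, curve_dwell=curve_dwell,
        points=pd.DataFrame(rows).sort_values("concentration"),
        tau=1.0 / ko, tau_se=ko_se / ko**2,
        n_dynamic_traces=int(sum(pooled["n_dynamic"].values())),
        n_traces_used=n_used, kinetics=kin,
    )


def run_rate_recovery(
    seed: int,
    concentration: float = 10.0,
    kinetics: SensorKinetics = ENDPOINT_LINE_KINETICS,
    n_traces: int = 100,
    n_frames: int = 600,
) -> tuple[RateEstimate, float]:
    """Recover the closing rate at one concentration; returns (estimate, truth)."""
    titr = simulate_titration(
        kinetics, PhotophysicsModel(), [concentration], n_traces,
        n_frames=n_frames, seed=seed,
    )
    e_traces = []
    for tr in titr.traces[concentration]:
        traj = preprocess_trace(tr)
        if classify_trace(traj) != "rejected" and traj.n_usable > 2:
            e_traces.append(traj.E_usable)
    closing, _ = rates_from_efficiency(
        e_traces, titr.frame_time,
        e_open=kinetics.E_open, e_closed=kinetics.E_closed,
    )
    return closing, kinetics.closing_rate(concentration)


# ---------------------------------------------------------------------------
# Equilibrium binding study (isotherm -> K_D)
# ---------------------------------------------------------------------------

@dataclass
class BindingStudy:
    fit: BindingFit
    points: pd.DataFrame
    kd_true: float
    n_molecules_total: int


def run_binding_study(
    seed: int,
    kd_true: float = 0.9,
    concentrations=(0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 60.0, 100.0),
    n_molecules: int = 300,
    n_frames: int = 100,
) -> BindingStudy:
    """Titration histograms -> mixture areas -> hyperbolic isotherm fit."""
    pooled, truth = simulate_binding_titration(
        kd=kd_true, concentrations=concentrations, n_molecules=n_molecules,
        n_frames=n_frames, seed=seed,
    )
    rows = []
    points = []
    for c, e_values in pooled.items():
        f, _fit = bound_fraction_from_sample(e_values)
        points.append((c, f))
        rows.append(
            {"concentration": c, "bound_fraction": f,
             "true_bound_fraction": float(
                 truth.loc[truth.concentration == c, "true_bound_fraction"].iloc[0]
             )}
        )
    bfit = fit_binding_isotherm(points)
    return BindingStudy(
        fit=bfit, points=pd.DataFrame(rows).sort_values("concentration"),
        kd_true=kd_true,
        n_molecules_total=n_molecules * len(list(concentrations)),
    )


# ---------------------------------------------------------------------------
# FRET-state recovery (apo / saturating population peaks)
# ---------------------------------------------------------------------------

@dataclass
class FretStateStudy:
    mode: str
    peak: float                 # recovered efficiency level
    fit: MixtureFit
    n_traces: int
    n_frames_pooled: int


def run_fret_state_study(
    seed: int, mode: str = "apo", n_traces: int = 200, n_frames: int = 600,
) -> FretStateStudy:
    """Pooled efficiency histogram of apo (0 uM) or saturating (100 uM) traces.

    Apo uses a peptide-free sensor (no baseline closing, all-open);
    saturating uses the default kinetics at the top titration concentration
    and reports the high-efficiency component of a two-Gaussian fit.
    """
    if mode not in ("apo", "saturating"):
        raise ValidationError("mode must be 'apo' or 'saturating'")
    if mode == "apo":
        kin = SensorKinetics().replace(k_close_base=0.0)
        conc = 0.0
    else:
        kin = SensorKinetics()
        conc = 100.0
    titr = simulate_titration(
        kin, PhotophysicsModel(), [conc], n_traces, n_frames=n_frames,
        seed=seed,
    )
    pooled = np.concatenate(
        [preprocess_trace(tr).E_usable for tr in titr.traces[conc]]
    )
    if mode == "apo":
        fit = fit_fret_histogram(pooled, n_components=1)
        peak = float(fit.means[0])
    else:
        fit = fit_fret_histogram(pooled, n_components=2)
        peak = fit.mean_high
    return FretStateStudy(
        mode=mode, peak=peak, fit=fit, n_traces=n_traces,
        n_frames_pooled=len(pooled),
    )


# ---------------------------------------------------------------------------
# Counting study (phased transport protocols -> integer peptide counts)
# ---------------------------------------------------------------------------

@dataclass
class CountingStudy:
    report: object                   # TransportReport
    per_phase: pd.DataFrame          # modal count, fraction correct, ...
    n_eligible: int
    protocol_name: str
    truth: pd.DataFrame = field(repr=False, default=None)


def run_counting_study(
    seed: int,
    curve: CalibrationCurve,
    protocol_name: str = "two_event_mg_atp",
    n_eligible: int = 100,
    n_vesicles: int = 30000,
    n_frames_per_phase: int = 3600,
    diameter: float = 100.0,
) -> CountingStudy:
    """Phased transport protocol on single-sensor/single-transporter vesicles.

    Draws a Poisson-loaded ensemble at the reconstitution means, keeps the
    first ``n_eligible`` analysis-eligible vesicles at the reference
    diameter, runs the protocol, and compares inferred integer counts with
    the per-vesicle ground truth.
    """
    protocols = {
        "two_event_mg_atp": two_event_mg_atp_protocol,
        "atp_edta": atp_edta_protocol,
    }
    if protocol_name not in protocols:
        raise ValidationError(f"unknown protocol {protocol_name!r}")
    s_ens, s_exp = _child_seeds(seed, 2)
    ensemble = simulate_vesicle_ensemble(
        n_vesicles, diameter_gsd=1.0, diameter_median=diameter, seed=s_ens,
    )
    eligible = [v for v in ensemble if v.eligible][:n_eligible]
    if len(eligible) < n_eligible:
        raise ValidationError(
            f"only {len(eligible)} eligible vesicles in an ensemble of "
            f"{n_vesicles}; increase n_vesicles"
        )
    experiment = simulate_transport_experiment(
        eligible, protocols[protocol_name](),
        n_frames_per_phase=n_frames_per_phase, seed=s_exp,
    )
    report = analyze_experiment(experiment, curve, seed=seed)
    merged = report.vesicles.merge(
        experiment.truth[["vesicle_id", "phase_index", "n_peptides",
                          "true_concentration"]],
        on=["vesicle_id", "phase_index"], how="left",
    )
    rows = []
    for p_idx, grp in merged.groupby("phase_index"):
        counted = grp.dropna(subset=["count"])
        true_count = int(grp["n_peptides"].iloc[0])
        counts = counted["count"].astype(int)
        modal = int(counts.mode().iloc[0]) if len(counts) else -1
        frac_correct = float((counts == true_count).mean()) if len(counts) else 0.0
        rows.append(
            {
                "phase_index": int(p_idx),
                "phase_label": grp["phase_label"].iloc[0],
                "true_count": true_count, "modal_count": modal,
                "fraction_correct": frac_correct,
                "n_counted": int(len(counts)), "n_total": int(len(grp)),
                "mean_concentration": float(counted["concentration"].mean())
                if len(counted) else np.nan,
            }
        )
    return CountingStudy(
        report=report, per_phase=pd.DataFrame(rows).sort_values("phase_index"),
        n_eligible=len(eligible), protocol_name=protocol_name,
        truth=experiment.truth,
    )
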