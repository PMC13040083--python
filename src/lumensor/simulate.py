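"""Synthetic single-molecule data with known ground truth.

This module generates everything the analysis chain consumes, standing in
for raw microscopy data: continuous-time two-state sensor paths, camera
frames with motion blur, noise and single-step photobleaching, equilibrium
and kinetic titrations, Poisson-loaded vesicle ensembles, and full phased
transport experiments in which discrete translocation events raise the
lumenal peptide concentration in quantized steps.

Randomness discipline: every entry point takes a ``seed`` (or Generator);
per-trace substreams are derived deterministically with
``numpy.random.SeedSequence.spawn``, so identical seeds give bit-identical
output regardless of how many traces are drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import single_molecule_concentration
from .params import (
    DEFAULT_FRAME_TIME,
    DEFAULT_N_FRAMES,
    PhotophysicsModel,
    SensorKinetics,
)
from .trace import CLOSED, OPEN, Trace


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _spawn(seed, n: int) -> list[np.random.Generator]:
    if isinstance(seed, np.random.Generator):
        return [seed for _ in range(n)]  # caller supplied a stream explicitly
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# Continuous-time state paths
# ---------------------------------------------------------------------------

@dataclass
class StatePath:
    """Alternating open/closed dwells covering [0, duration]."""

    states: np.ndarray       # per-dwell codes (OPEN/CLOSED), strictly alternating
    entry_times: np.ndarray  # s
    exit_times: np.ndarray   # s
    duration: float          # s
    concentration: float     # uM

    @property
    def events(self) -> list:
        return list(zip(self.states.tolist(), self.entry_times.tolist(),
                        self.exit_times.tolist()))

    @property
    def dwell_durations(self) -> np.ndarray:
        return self.exit_times - self.entry_times

    def closed_occupancy(self, edges: np.ndarray) -> np.ndarray:
        """Fraction of each [edges[i], edges[i+1]) interval spent closed."""
        knots = np.concatenate(([self.entry_times[0]], self.exit_times))
        closed_cum = np.concatenate(
            ([0.0], np.cumsum(self.dwell_durations * (self.states == CLOSED)))
        )
        c = np.interp(edges, knots, closed_cum)
        return np.diff(c) / np.diff(edges)

    def dominant_states(self, edges: np.ndarray) -> np.ndarray:
        """Majority-occupancy state per interval (ties go to open)."""
        return (self.closed_occupancy(edges) > 0.5).astype(int)


def simulate_state_path(
    kinetics: SensorKinetics, concentration: float, duration: float, seed
) -> StatePath:
    """Draw a two-state Markov path at the given peptide concentration.

    Dwells are exponential with rates k_close_base + k_on*c (open) and
    k_open (closed); the initial state is drawn from the stationary
    distribution.
    """
    if duration <= 0:
        raise ValidationError("duration must be > 0")
    if concentration < 0:
        raise ValidationError("concentration must be >= 0")
    rng = _rng(seed)
    k_close = kinetics.closing_rate(concentration)
    k_open = kinetics.k_open
    total = k_close + k_open
    p_closed = k_close / total if total > 0 else 0.0
    state = CLOSED if rng.random() < p_closed else OPEN

    states, entries, exits = [], [], []
    t = 0.0
    while t < duration:
        rate = k_close if state == OPEN else k_open
        dwell = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        end = min(t + dwell, duration)
        states.append(state)
        entries.append(t)
        exits.append(end)
        t = end
        state = CLOSED if state == OPEN else OPEN
    return StatePath(
        states=np.asarray(states, dtype=int),
        entry_times=np.asarray(entries), exit_times=np.asarray(exits),
        duration=float(duration), concentration=float(concentration),
    )


# ---------------------------------------------------------------------------
# Camera-frame rendering
# ---------------------------------------------------------------------------

def render_trace(
    path: StatePath,
    phot: PhotophysicsModel,
    kinetics: SensorKinetics,
    frame_time: float = DEFAULT_FRAME_TIME,
    n_frames: int = DEFAULT_N_FRAMES,
    seed=None,
    efficiency_noise_sd: float | None = None,
    donor_bleach_time: float | None = None,
    acceptor_bleach_time: float | None = None,
    metadata: dict | None = None,
) -> Trace:
    """Integrate a state path into three-channel camera frames.

    Each frame's apparent efficiency is the occupancy-weighted average of
    E_open/E_closed over the frame window (motion blur) plus Gaussian noise
    of width sigma_E (overridable via ``efficiency_noise_sd``); channel
    intensities are synthesized so the uncorrected E/S computation recovers
    the intended efficiency with S ~ 0.5.  Photobleaching times are drawn
    exponentially unless forced via the ``*_bleach_time`` arguments.
    """
    if n_frames * frame_time > path.duration + 1e-9:
        raise ValidationError("frame window exceeds the state-path duration")
    rng = _rng(seed)
    edges = np.arange(n_frames + 1) * frame_time
    occ = path.closed_occupancy(edges)
    e_true = kinetics.E_open + (kinetics.E_closed - kinetics.E_open) * occ
    sigma = kinetics.sigma_E if efficiency_noise_sd is None else efficiency_noise_sd
    e_app = e_true + (rng.normal(0.0, sigma, n_frames) if sigma > 0 else 0.0)

    def _draw_bleach(rate: float) -> float:
        return rng.exponential(1.0 / rate) if rate > 0 else np.inf

    t_d = donor_bleach_time if donor_bleach_time is not None else _draw_bleach(
        phot.bleach_rate_donor)
    t_a = acceptor_bleach_time if acceptor_bleach_time is not None else _draw_bleach(
        phot.bleach_rate_acceptor)
    frame_mid = (edges[:-1] + edges[1:]) / 2.0
    donor_dead = frame_mid >= t_d
    acceptor_dead = frame_mid >= t_a

    bg = phot.background
    td, ta = phot.total_rate_donor_exc, phot.total_rate_acceptor_exc
    I_DD = bg + td * (1.0 - e_app)
    I_DA = bg + td * e_app
    I_AA = bg + ta * np.ones(n_frames)
    # acceptor gone, donor alive: FRET lost, all donor-excited emission in DD
    acc_only = acceptor_dead & ~donor_dead
    I_DD[acc_only] = bg + td
    I_DA[acc_only] = bg
    I_AA[acceptor_dead] = bg
    I_DD[donor_dead] = bg
    I_DA[donor_dead] = bg

    if phot.noise_model == "gaussian":
        if phot.gaussian_sd > 0:
            I_DD = I_DD + rng.normal(0.0, phot.gaussian_sd, n_frames)
            I_DA = I_DA + rng.normal(0.0, phot.gaussian_sd, n_frames)
            I_AA = I_AA + rng.normal(0.0, phot.gaussian_sd, n_frames)
    else:  # poisson
        I_DD = rng.poisson(np.maximum(I_DD, 0.0)).astype(float)
        I_DA = rng.poisson(np.maximum(I_DA, 0.0)).astype(float)
        I_AA = rng.poisson(np.maximum(I_AA, 0.0)).astype(float)

    meta = dict(metadata or {})
    meta.update(
        true_concentration=path.concentration,
        true_frame_states=path.dominant_states(edges),
        true_donor_bleach_time=float(t_d) if np.isfinite(t_d) else None,
        true_acceptor_bleach_time=float(t_a) if np.isfinite(t_a) else None,
        true_n_transitions=int(len(path.states) - 1),
    )
    return Trace(I_DD=I_DD, I_DA=I_DA, I_AA=I_AA, frame_time=frame_time,
                 metadata=meta)


# ---------------------------------------------------------------------------
# Titrations
# ---------------------------------------------------------------------------

@dataclass
class TitrationSet:
    """Kinetic titration: traces per concentration plus ground truth."""

    traces: dict                       # concentration -> list[Trace]
    kinetics: SensorKinetics
    frame_time: float
    truth: pd.DataFrame

    @property
    def concentrations(self) -> list[float]:
        return sorted(self.traces)


def simulate_titration(
    kinetics: SensorKinetics,
    phot: PhotophysicsModel,
    concentrations,
    n_traces: int,
    frame_time: float = DEFAULT_FRAME_TIME,
    n_frames: int = DEFAULT_N_FRAMES,
    seed=0,
) -> TitrationSet:
    """Independent dynamic traces at each concentration of a titration."""
    concentrations = list(concentrations)
    if not concentrations:
        raise ValidationError("concentration list must not be empty")
    if any(c < 0 for c in concentrations):
        raise ValidationError("concentrations must be >= 0")
    if n_traces < 1:
        raise ValidationError("n_traces must be >= 1")
    duration = n_frames * frame_time
    rngs = _spawn(seed, len(concentrations) * n_traces)
    traces: dict = {}
    rows = []
    i = 0
    for c in concentrations:
        per_c = []
        for j in range(n_traces):
            rng = rngs[i]
            i += 1
            path = simulate_state_path(kinetics, c, duration, rng)
            tr = render_trace(
                path, phot, kinetics, frame_time, n_frames, rng,
                metadata={"concentration": c, "trace_index": j},
            )
            per_c.append(tr)
            rows.append(
                {
                    "concentration": c, "trace_index": j,
                    "true_closing_rate": kinetics.closing_rate(c),
                    "true_opening_rate": kinetics.k_open,
                    "n_transitions": int(len(path.states) - 1),
                }
            )
        traces[c] = per_c
    return TitrationSet(
        traces=traces, kinetics=kinetics, frame_time=frame_time,
        truth=pd.DataFrame(rows),
    )


def simulate_binding_titration(
    kd: float = 0.9,
    concentrations=(0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 60.0, 100.0),
    n_molecules: int = 300,
    n_frames: int = 100,
    kinetics: SensorKinetics | None = None,
    amplitude: float = 1.0,
    seed=0,
):
    """Equilibrium titration for the binding isotherm.

    Each molecule is drawn bound with probability A*c/(K_D + c) and emits
    Gaussian efficiency frames around its state's level; returns
    (concentration -> pooled E values, ground-truth table).
    """
    if kd <= 0:
        raise ValidationError("kd must be > 0")
    if not (0 < amplitude <= 1):
        raise ValidationError("amplitude must lie in (0, 1]")
    kin = kinetics or SensorKinetics()
    rngs = _spawn(seed, len(list(concentrations)))
    pooled: dict = {}
    rows = []
    for rng, c in zip(rngs, concentrations):
        if c < 0:
            raise ValidationError("concentrations must be >= 0")
        f_true = amplitude * c / (kd + c)
        bound = rng.random(n_molecules) < f_true
        levels = np.where(bound, kin.E_closed, kin.E_open)
        e = rng.normal(levels[:, None], kin.sigma_E, (n_molecules, n_frames))
        pooled[float(c)] = e.ravel()
        rows.append(
            {"concentration": float(c), "true_bound_fraction": f_true,
             "n_bound": int(bound.sum()), "n_molecules": n_molecules}
        )
    return pooled, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Vesicle ensembles
# ---------------------------------------------------------------------------

@dataclass
class Vesicle:
    """Geometry and molecular occupancy of one liposome."""

    diameter: float            # nm
    n_sensors: int
    n_transporters: int
    n_peptides_lumen: int = 0
    orientation_ok: bool = False
    vesicle_id: int = -1

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValidationError("diameter must be > 0")
        if min(self.n_sensors, self.n_transporters, self.n_peptides_lumen) < 0:
            raise ValidationError("copy numbers must be >= 0")

    @property
    def lumenal_concentration(self) -> float:
        """uM; n_peptides times the single-molecule increment for this size."""
        return self.n_peptides_lumen * single_molecule_concentration(self.diameter)

    @property
    def eligible(self) -> bool:
        """Exactly one sensor, one uptake-competent transporter."""
        return (
            self.n_sensors == 1 and self.n_transporters == 1
            and self.orientation_ok
        )


def simulate_vesicle_ensemble(
    n_vesicles: int,
    mean_sensors_per_vesicle: float = 0.2,
    mean_transporters_per_vesicle: float = 0.1,
    diameter_median: float = 100.0,
    diameter_gsd: float = 1.15,
    diameter_bounds: tuple = (40.0, 400.0),
    fraction_uptake_competent: float = 0.5,
    seed=0,
) -> list[Vesicle]:
    """Poisson-loaded liposomes with a truncated log-normal size distribution.

    Copy numbers follow Poisson laws with the reconstitution means (defaults
    0.2 sensors and 0.1 transporters per liposome); diameters are log-normal
    with the given median and geometric SD, truncated to ``diameter_bounds``.
    Transporter orientation is uptake-competent with the stated probability.
    """
    if n_vesicles < 0:
        raise ValidationError("n_vesicles must be >= 0")
    if min(mean_sensors_per_vesicle, mean_transporters_per_vesicle) < 0:
        raise ValidationError("Poisson means must be >= 0")
    if diameter_gsd < 1.0:
        raise ValidationError("geometric SD must be >= 1")
    if not (0.0 <= fraction_uptake_competent <= 1.0):
        raise ValidationError("fraction_uptake_competent must lie in [0, 1]")
    lo, hi = diameter_bounds
    if not (0 < lo <= diameter_median <= hi):
        raise ValidationError("size bounds must bracket the median")
    rng = _rng(seed)
    n_s = rng.poisson(mean_sensors_per_vesicle, n_vesicles)
    n_t = rng.poisson(mean_transporters_per_vesicle, n_vesicles)
    if diameter_gsd == 1.0:
        d = np.full(n_vesicles, float(diameter_median))
    else:
        mu, s = np.log(diameter_median), np.log(diameter_gsd)
        d = np.exp(rng.normal(mu, s, n_vesicles))
        bad = (d < lo) | (d > hi)
        while bad.any():  # rejection keeps the in-band shape intact
            d[bad] = np.exp(rng.normal(mu, s, int(bad.sum())))
            bad = (d < lo) | (d > hi)
    orient = rng.random(n_vesicles) < fraction_uptake_competent
    return [
        Vesicle(
            diameter=float(d[i]), n_sensors=int(n_s[i]),
            n_transporters=int(n_t[i]),
            orientation_ok=bool(orient[i]) and n_t[i] > 0, vesicle_id=i,
        )
        for i in range(n_vesicles)
    ]


# ---------------------------------------------------------------------------
# Phased transport experiments
# ---------------------------------------------------------------------------

NUCLEOTIDES = ("none", "Mg-ADP", "Mg-ATP", "ATP-EDTA", "ADP-EDTA")
IF, OF_LOCKED = "IF", "OF_locked"

#: Translocation events per competent transporter and phase.  ATP binding
#: drives a single event; without Mg2+ (ATP-EDTA) the transporter stays
#: locked outward-facing afterwards, and only Mg-ATP (hydrolysis) resets it.
DEFAULT_TRANSPORT_RULE = {
    ("Mg-ATP", IF): 1,
    ("Mg-ATP", OF_LOCKED): 1,   # hydrolysis resets, then a new event
    ("ATP-EDTA", IF): 1,
    ("ATP-EDTA", OF_LOCKED): 0,
}


@dataclass(frozen=True)
class Phase:
    label: str
    nucleotide: str
    peptide_outside: float = 0.0  # uM
    duration: float = 300.0       # s of incubation

    def __post_init__(self) -> None:
        if self.nucleotide not in NUCLEOTIDES:
            raise ValidationError(f"unknown nucleotide {self.nucleotide!r}")
        if self.peptide_outside < 0:
            raise ValidationError("peptide_outside must be >= 0")
        if self.duration <= 0:
            raise ValidationError("phase duration must be > 0")


@dataclass
class ExperimentProtocol:
    """Ordered incubation phases plus the transport/reset rules."""

    phases: tuple
    transport_rule: dict = field(
        default_factory=lambda: dict(DEFAULT_TRANSPORT_RULE))

    def __post_init__(self) -> None:
        self.phases = tuple(self.phases)
        if not self.phases:
            raise ValidationError("protocol needs at least one phase")
        for ph in self.phases:
            if not isinstance(ph, Phase):
                raise ValidationError("phases must be Phase instances")
        for (nuc, _state), n in self.transport_rule.items():
            if nuc not in NUCLEOTIDES or n < 0:
                raise ValidationError("invalid transport rule entry")
            if n > 0 and nuc not in ("Mg-ATP", "ATP-EDTA"):
                raise ValidationError(
                    "transport requires Mg-ATP or ATP-EDTA")

    def events_for(self, phase: Phase, transporter_state: str) -> int:
        if phase.peptide_outside <= 0:
            return 0
        return self.transport_rule.get((phase.nucleotide, transporter_state), 0)

    @staticmethod
    def next_state(phase: Phase, transporter_state: str, transported: bool) -> str:
        if phase.nucleotide == "Mg-ATP":
            return IF  # Mg2+-dependent hydrolysis resets the cycle
        if phase.nucleotide == "ATP-EDTA" and transported:
            return OF_LOCKED
        return transporter_state


def mg_adp_control_protocol(n_imaging_phases: int = 3) -> ExperimentProtocol:
    """Mg-ADP + peptide only: no transport is expected in any phase."""
    phases = [Phase("apo", "none", 0.0)]
    phases += [
        Phase(f"Mg-ADP_{i + 1}", "Mg-ADP", 200.0) for i in range(n_imaging_phases - 1)
    ]
    return ExperimentProtocol(tuple(phases))


def two_event_mg_atp_protocol() -> ExperimentProtocol:
    """Apo baseline, then two sequential Mg-ATP single-turnover incubations."""
    return ExperimentProtocol(
        (
            Phase("apo", "none", 0.0),
            Phase("Mg-ATP_1", "Mg-ATP", 200.0),
            Phase("Mg-ATP_2", "Mg-ATP", 200.0),
        )
    )


def atp_edta_protocol() -> ExperimentProtocol:
    """Two ATP-EDTA additions (second is futile), then a Mg-ATP reset phase."""
    return ExperimentProtocol(
        (
            Phase("ATP-EDTA_1", "ATP-EDTA", 200.0),
            Phase("ATP-EDTA_2", "ATP-EDTA", 200.0),
            Phase("Mg-ATP_reset", "Mg-ATP", 200.0),
        )
    )


@dataclass
class TransportExperiment:
    """Phased traces plus per-vesicle/phase ground truth."""

    protocol: ExperimentProtocol
    kinetics: SensorKinetics
    frame_time: float
    traces: dict                 # phase_index -> list[Trace]
    truth: pd.DataFrame          # vesicle_id, phase_index, counts, ...

    @property
    def phase_labels(self) -> list[str]:
        return [p.label for p in self.protocol.phases]


def simulate_transport_experiment(
    ensemble: list[Vesicle],
    protocol: ExperimentProtocol,
    kinetics: SensorKinetics | None = None,
    phot: PhotophysicsModel | None = None,
    frame_time: float = DEFAULT_FRAME_TIME,
    n_frames_per_phase: int = 6 * DEFAULT_N_FRAMES,
    seed=0,
    eligible_only: bool = True,
) -> TransportExperiment:
    """Run a phased protocol over a vesicle ensemble and image each phase.

    Peptides are deposited at phase boundaries (incubations happen
    off-microscope); sensor traces within a phase are rendered at the
    then-current lumenal concentration.  Each phase's movie illuminates the
    molecule afresh (fields of view are rotated during acquisition), so the
    photobleaching clock restarts with every phase.
    """
    kin = kinetics or SensorKinetics()
    ph = phot or PhotophysicsModel()
    duration = n_frames_per_phase * frame_time
    vesicles = [v for v in ensemble if (v.eligible or not eligible_only)
                and v.n_sensors >= 1]
    rngs = _spawn(seed, max(len(vesicles), 1))
    traces: dict = {i: [] for i in range(len(protocol.phases))}
    rows = []
    for v, rng in zip(vesicles, rngs):
        states = [IF] * v.n_transporters
        n_pept = v.n_peptides_lumen
        for p_idx, phase in enumerate(protocol.phases):
            if v.orientation_ok:
                new_states = []
                for st in states:
                    n_ev = protocol.events_for(phase, st)
                    n_pept += n_ev
                    new_states.append(
                        protocol.next_state(phase, st, n_ev > 0))
                states = new_states
            conc = n_pept * single_molecule_concentration(v.diameter)
            tr = render_trace(
                simulate_state_path(kin, conc, duration, rng),
                ph, kin, frame_time, n_frames_per_phase, rng,
                metadata={
                    "vesicle_id": v.vesicle_id, "phase_index": p_idx,
                    "phase_label": phase.label, "diameter": v.diameter,
                },
            )
            traces[p_idx].append(tr)
            rows.append(
                {
                    "vesicle_id": v.vesicle_id, "phase_index": p_idx,
                    "phase_label": phase.label, "nucleotide": phase.nucleotide,
                    "n_peptides": n_pept, "true_concentration": conc,
                    "diameter": v.diameter, "eligible": v.eligible,
                }
            )
    truth = pd.DataFrame(
        rows, columns=[
            "vesicle_id", "phase_index", "phase_label", "nucleotide",
            "n_peptides", "true_concentration", "diameter", "eligible",
        ],
    )
    return TransportExperiment(
        protocol=protocol, kinetics=kin, frame_time=frame_time,
        traces=traces, truth=truth,
    )
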