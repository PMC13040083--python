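"""Containers and per-trace analysis for three-channel ALEX trajectories.

A :class:`Trace` holds the raw per-frame intensities recorded under
alternating laser excitation: donor-excited donor emission (``I_DD``),
donor-excited acceptor emission (``I_DA``) and acceptor-excited acceptor
emission (``I_AA``).  From these the apparent (uncorrected) FRET efficiency
and stoichiometry are

    E = I_DA / (I_DA + I_DD)
    S = (I_DD + I_DA) / (I_DD + I_DA + I_AA)

No gamma or crosstalk corrections are applied; the open/closed efficiency
levels of the sensor (0.6 / 0.9) are treated as apparent values.  A hook for
an affine efficiency correction exists (:meth:`FretTrajectory.corrected`) and
defaults to the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

OPEN, CLOSED = 0, 1  # hidden-state codes: 0 = open/low-FRET, 1 = closed/high-FRET


@dataclass
class Trace:
    """Raw three-channel intensity time series of one molecule."""

    I_DD: np.ndarray
    I_DA: np.ndarray
    I_AA: np.ndarray
    frame_time: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.I_DD = np.asarray(self.I_DD, dtype=float)
        self.I_DA = np.asarray(self.I_DA, dtype=float)
        self.I_AA = np.asarray(self.I_AA, dtype=float)
        n = len(self.I_DD)
        if len(self.I_DA) != n or len(self.I_AA) != n or n == 0:
            raise ValidationError("channels must be equal-length and non-empty")
        if self.frame_time <= 0:
            raise ValidationError("frame_time must be > 0")
        for ch in (self.I_DD, self.I_DA, self.I_AA):
            if not np.all(np.isfinite(ch)):
                raise ValidationError("intensities must be finite")

    def __len__(self) -> int:
        return len(self.I_DD)

    @property
    def frame(self) -> np.ndarray:
        return np.arange(len(self))

    @property
    def time_s(self) -> np.ndarray:
        return self.frame * self.frame_time

    def to_frame(self):
        """Tabular view with the interchange column layout."""
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frame,
                "time_s": self.time_s,
                "I_DD": self.I_DD,
                "I_DA": self.I_DA,
                "I_AA": self.I_AA,
            }
        )


@dataclass
class FretTrajectory:
    """Derived per-frame efficiency/stoichiometry with a validity mask."""

    E: np.ndarray
    S: np.ndarray
    mask: np.ndarray  # True where the frame is usable
    frame_time: float
    flags: set = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    @property
    def n_usable(self) -> int:
        return int(self.mask.sum())

    @property
    def E_usable(self) -> np.ndarray:
        return self.E[self.mask]

    @property
    def S_usable(self) -> np.ndarray:
        return self.S[self.mask]

    def truncated(self, end_frame: int, extra_flags: set | None = None) -> "FretTrajectory":
        """Restrict the validity mask to frames before ``end_frame``."""
        mask = self.mask.copy()
        mask[end_frame:] = False
        return FretTrajectory(
            E=self.E, S=self.S, mask=mask, frame_time=self.frame_time,
            flags=set(self.flags) | (extra_flags or set()),
            metadata=dict(self.metadata),
        )

    def corrected(self, gamma_slope: float = 1.0, offset: float = 0.0) -> "FretTrajectory":
        """Affine efficiency-correction hook; identity by default."""
        return FretTrajectory(
            E=gamma_slope * self.E + offset, S=self.S, mask=self.mask.copy(),
            frame_time=self.frame_time, flags=set(self.flags),
            metadata=dict(self.metadata),
        )


#: Apparent-efficiency tolerance band; frames outside carry no FRET signal
#: (e.g. noise ratios after an undetected bleach) and are masked out.
E_BAND = (-0.2, 1.2)


def compute_es(trace: Trace) -> FretTrajectory:
    """Apparent FRET efficiency and stoichiometry per frame.

    Frames with zero total donor-excitation signal, or with an apparent
    efficiency outside the tolerance band ``E_BAND``, carry no usable FRET
    information and are masked out; an all-zero trace is returned fully
    masked with the ``"all_zero"`` flag.
    """
    tot_d = trace.I_DD + trace.I_DA
    tot = tot_d + trace.I_AA
    ok = tot_d > 0
    E = np.full(len(trace), np.nan)
    S = np.full(len(trace), np.nan)
    np.divide(trace.I_DA, tot_d, out=E, where=ok)
    np.divide(tot_d, tot, out=S, where=tot > 0)
    ok &= (E >= E_BAND[0]) & (E <= E_BAND[1])
    flags = set()
    if not ok.any():
        flags.add("all_zero")
    return FretTrajectory(
        E=E, S=S, mask=ok, frame_time=trace.frame_time, flags=flags,
        metadata=dict(trace.metadata),
    )


# ---------------------------------------------------------------------------
# Single-step photobleaching detection
# ---------------------------------------------------------------------------

@dataclass
class BleachResult:
    donor_bleach_frame: int | None
    acceptor_bleach_frame: int | None
    usable_end: int            # exclusive end of the pre-bleach range
    multi_fluorophore: bool


def _robust_sd(y: np.ndarray) -> float:
    # successive differences are insensitive to slow drifts and steps
    d = np.diff(y)
    if len(d) == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d))) / np.sqrt(2.0)


def _best_split(y: np.ndarray) -> tuple[int, float, float]:
    """Split index minimising the two-segment SSE, with segment means."""
    n = len(y)
    c1 = np.cumsum(y)
    c2 = np.cumsum(y**2)
    k = np.arange(1, n)
    left_n, right_n = k, n - k
    left_sum = c1[k - 1]
    right_sum = c1[-1] - left_sum
    sse = (c2[k - 1] - left_sum**2 / left_n) + (
        (c2[-1] - c2[k - 1]) - right_sum**2 / right_n
    )
    i = int(np.argmin(sse))
    return int(k[i]), float(left_sum[i] / left_n[i]), float(right_sum[i] / right_n[i])


def _find_down_steps(
    y: np.ndarray, sigma: float, offset: int = 0, min_seg: int = 5,
    threshold: float = 4.0, _depth: int = 0,
) -> list[tuple[int, float]]:
    """Recursively locate significant downward steps (frame, drop)."""
    if len(y) < 2 * min_seg or _depth > 3:
        return []
    k, m_left, m_right = _best_split(y)
    drop = m_left - m_right
    if min(k, len(y) - k) < min_seg:
        return []
    # significance of the step against frame noise on the segment means
    se = sigma * np.sqrt(1.0 / k + 1.0 / (len(y) - k)) if sigma > 0 else 0.0
    if drop <= max(threshold * se, threshold * sigma * 0.25, 1e-12):
        return []
    steps = [(offset + k, drop)]
    steps += _find_down_steps(y[:k], sigma, offset, min_seg, threshold, _depth + 1)
    steps += _find_down_steps(y[k:], sigma, offset + k, min_seg, threshold, _depth + 1)
    return sorted(steps)


def detect_bleach(trace: Trace, min_frames: int = 20) -> BleachResult:
    """Locate single-step photobleaching of donor and acceptor.

    The acceptor is probed on the acceptor-excitation channel ``I_AA``; the
    donor on the FRET-independent donor-excitation sum ``I_DD + I_DA``.  The
    usable range ends at the earliest detected bleach.  Two or more downward
    steps on ``I_AA`` flag the trace as multi-fluorophore.
    """
    if len(trace) < min_frames:
        raise ValidationError(f"trace shorter than {min_frames} frames")
    acc = trace.I_AA
    don = trace.I_DD + trace.I_DA

    acc_steps = _find_down_steps(acc, _robust_sd(acc))
    don_steps = _find_down_steps(don, _robust_sd(don))

    acceptor_frame = acc_steps[0][0] if acc_steps else None
    donor_frame = don_steps[0][0] if don_steps else None
    multi = len(acc_steps) >= 2

    usable_end = len(trace)
    for f in (acceptor_frame, donor_frame):
        if f is not None:
            usable_end = min(usable_end, f)
    return BleachResult(donor_frame, acceptor_frame, usable_end, multi)


# ---------------------------------------------------------------------------
# Rule-based trace classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierThresholds:
    """Deterministic quality/behaviour rules replacing a learned screen."""

    s_band: tuple = (0.3, 0.7)   # acceptable median stoichiometry
    min_frames: int = 50         # minimum usable frames
    e_split: float = 0.75        # midpoint between the two efficiency levels
    static_fraction: float = 0.95  # occupancy beyond which a trace is static
    min_transitions: int = 2     # Viterbi transitions required for "dynamic"
    max_noise_sd: float = 0.12   # 2x the default per-frame efficiency width


def threshold_states(e_values: np.ndarray, e_mid: float = 0.75) -> np.ndarray:
    """Decode open/closed per frame at a fixed efficiency midpoint.

    The sensor's two levels are calibrated instrument constants, so their
    midpoint is a trace-independent decode threshold; this avoids the
    per-trace jitter of refitted emission models.  Ties go to open.
    """
    return (np.asarray(e_values) > e_mid).astype(int)


STATIC_LOW, STATIC_HIGH, DYNAMIC, REJECTED = (
    "static_low", "static_high", "dynamic", "rejected",
)


def classify_trace(
    traj: FretTrajectory, thresholds: ClassifierThresholds | None = None
) -> str:
    """Label a trajectory as static_low / static_high / dynamic / rejected."""
    th = thresholds or ClassifierThresholds()
    if "multi_fluorophore" in traj.flags or "all_zero" in traj.flags:
        return REJECTED
    e = traj.E_usable
    if len(e) < th.min_frames:
        return REJECTED
    s_med = float(np.median(traj.S_usable))
    if not (th.s_band[0] <= s_med <= th.s_band[1]):
        return REJECTED
    if _robust_sd(e) > th.max_noise_sd:
        return REJECTED
    frac_high = float(np.mean(e > th.e_split))
    if frac_high >= th.static_fraction:
        return STATIC_HIGH
    if frac_high <= 1.0 - th.static_fraction:
        return STATIC_LOW
    from .hmm import fit_hmm, viterbi_path

    fit = fit_hmm(e)
    path = viterbi_path(fit, e)
    n_trans = int(np.sum(path[1:] != path[:-1]))
    if n_trans >= th.min_transitions:
        return DYNAMIC
    return STATIC_HIGH if frac_high > 0.5 else STATIC_LOW


# ---------------------------------------------------------------------------
# Dwell extraction
# ---------------------------------------------------------------------------

@dataclass
class DwellSet:
    """State-resolved dwell durations with censoring flags.

    Durations are positive integer multiples of ``frame_time``.  The first
    dwell of a trace is left-censored and the last right-censored (a
    single-dwell trace is both).
    """

    states: np.ndarray          # dwell state codes (OPEN/CLOSED)
    durations: np.ndarray       # seconds
    left_censored: np.ndarray   # bool
    right_censored: np.ndarray  # bool
    frame_time: float

    def __len__(self) -> int:
        return len(self.states)

    @property
    def records(self) -> list:
        return list(
            zip(self.states.tolist(), self.durations.tolist(),
                self.left_censored.tolist(), self.right_censored.tolist())
        )

    def complete(self, state: int) -> np.ndarray:
        """Durations of uncensored dwells in the requested state."""
        sel = (self.states == state) & ~self.left_censored & ~self.right_censored
        return self.durations[sel]

    def right_censored_durations(self, state: int) -> np.ndarray:
        sel = (self.states == state) & ~self.left_censored & self.right_censored
        return self.durations[sel]

    def total_duration(self) -> float:
        return float(self.durations.sum())

    @staticmethod
    def concatenate(dwellsets: list["DwellSet"]) -> "DwellSet":
        if not dwellsets:
            raise ValidationError("cannot concatenate an empty list of DwellSets")
        ft = dwellsets[0].frame_time
        if any(abs(d.frame_time - ft) > 1e-12 for d in dwellsets):
            raise ValidationError("frame_time mismatch across DwellSets")
        return DwellSet(
            states=np.concatenate([d.states for d in dwellsets]),
            durations=np.concatenate([d.durations for d in dwellsets]),
            left_censored=np.concatenate([d.left_censored for d in dwellsets]),
            right_censored=np.concatenate([d.right_censored for d in dwellsets]),
            frame_time=ft,
        )


def extract_dwells(path: np.ndarray, frame_time: float) -> DwellSet:
    """Run-length encode a per-frame state path into censored dwells."""
    path = np.asarray(path)
    if path.ndim != 1 or len(path) == 0:
        raise ValidationError("path must be a non-empty 1-D state sequence")
    if frame_time <= 0:
        raise ValidationError("frame_time must be > 0")
    change = np.flatnonzero(path[1:] != path[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(path)]))
    states = path[starts]
    durations = (ends - starts) * frame_time
    n = len(starts)
    left = np.zeros(n, dtype=bool)
    right = np.zeros(n, dtype=bool)
    left[0] = True
    right[-1] = True
    return DwellSet(
        states=states.astype(int), durations=durations.astype(float),
        left_censored=left, right_censored=right, frame_time=frame_time,
    )
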