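"""Parameter containers for the two-state peptide sensor and the imaging model.

The sensor is a substrate-binding protein with an open (apo, low-FRET) and a
closed (holo, high-FRET) conformation.  Closing is pseudo-first-order in the
peptide concentration ``c``:

    k_close(c) = k_close_base + k_on * c        [1/s]

while opening proceeds at the constant rate ``k_open`` (reciprocal of the
closed-state lifetime tau).  Apparent FRET efficiencies of the two states and
the per-frame Gaussian width of the efficiency complete the spectroscopic
description.

Defaults reproduce the calibrated sensor: k_on = 0.29 / (uM s), tau = 0.5 s
(k_open = 2.0 / s), E_open = 0.6, E_closed = 0.9, sigma_E = 0.06, and a
baseline closing rate of 1.28 / s so that the closing rate runs from ~1.6 / s
at 1 uM to ~4.2-4.5 / s at 10 uM, the sensor's linear detection range.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ValidationError

#: Frame integration time used throughout (s); 100 ms camera exposure.
DEFAULT_FRAME_TIME = 0.1
#: Frames per acquisition movie.
DEFAULT_N_FRAMES = 600


@dataclass(frozen=True)
class SensorKinetics:
    """Kinetic and spectroscopic ground truth of the two-state sensor."""

    k_on: float = 0.29          # association rate constant, 1/(uM s)
    k_close_base: float = 1.28  # peptide-independent closing rate, 1/s
    k_open: float = 2.0         # opening rate, 1/s (tau = 1/k_open)
    E_open: float = 0.6         # apparent FRET efficiency, open state
    E_closed: float = 0.9       # apparent FRET efficiency, closed state
    sigma_E: float = 0.06       # per-frame Gaussian width of apparent E

    def __post_init__(self) -> None:
        if self.k_on <= 0:
            raise ValidationError("k_on must be > 0")
        if self.k_close_base < 0 or self.k_open < 0:
            raise ValidationError("rates must be >= 0")
        if not (0.0 <= self.E_open < self.E_closed <= 1.0):
            raise ValidationError("need 0 <= E_open < E_closed <= 1")
        if self.sigma_E <= 0:
            raise ValidationError("sigma_E must be > 0")

    def closing_rate(self, concentration: float) -> float:
        """Pseudo-first-order closing rate at a peptide concentration (uM)."""
        if concentration < 0:
            raise ValidationError("concentration must be >= 0")
        return self.k_close_base + self.k_on * concentration

    def stationary_closed_fraction(self, concentration: float) -> float:
        """Equilibrium occupancy of the closed state at concentration (uM)."""
        kc = self.closing_rate(concentration)
        if kc == 0 and self.k_open == 0:
            return 0.0
        return kc / (kc + self.k_open)

    @property
    def tau_closed(self) -> float:
        """Closed-state lifetime (s)."""
        return 1.0 / self.k_open

    def replace(self, **kw) -> "SensorKinetics":
        return dataclasses.replace(self, **kw)


#: Ground-truth kinetics used when a simulation should reproduce the printed
#: closing-rate endpoints exactly: the unique line through (1 uM, 1.6 / s)
#: and (10 uM, 4.5 / s).
ENDPOINT_LINE_KINETICS = SensorKinetics(
    k_on=(4.5 - 1.6) / 9.0, k_close_base=1.6 - (4.5 - 1.6) / 9.0
)


@dataclass(frozen=True)
class PhotophysicsModel:
    """Detection and photobleaching model for three-channel ALEX imaging.

    Channel totals are mean detected counts per frame; ``gaussian_sd`` is the
    camera read-noise width per channel when ``noise_model == "gaussian"``
    (``"poisson"`` switches to shot-noise-limited counts).  Bleaching is
    single-step and exponential in illumination time; after donor bleach the
    donor-excited channels fall to background, after acceptor bleach the
    acceptor-excited channel falls to background and donor-excited emission is
    rerouted entirely to the donor channel (FRET is lost).
    """

    total_rate_donor_exc: float = 1000.0    # counts/frame, donor excitation
    total_rate_acceptor_exc: float = 1000.0  # counts/frame, acceptor excitation
    noise_model: str = "gaussian"           # "gaussian" | "poisson"
    gaussian_sd: float = 20.0               # counts/frame per channel
    bleach_rate_donor: float = 0.002        # 1/s of illumination
    bleach_rate_acceptor: float = 0.002     # 1/s of illumination
    background: float = 0.0                 # counts/frame per channel

    def __post_init__(self) -> None:
        if min(self.total_rate_donor_exc, self.total_rate_acceptor_exc) < 0:
            raise ValidationError("channel totals must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValidationError("noise_model must be 'gaussian' or 'poisson'")
        if self.gaussian_sd < 0 or self.background < 0:
            raise ValidationError("noise and background must be >= 0")
        if min(self.bleach_rate_donor, self.bleach_rate_acceptor) < 0:
            raise ValidationError("bleach rates must be >= 0")

    def replace(self, **kw) -> "PhotophysicsModel":
        return dataclasses.replace(self, **kw)


#: Convenience noiseless model for round-trip tests.
NOISELESS_PHOTOPHYSICS = PhotophysicsModel(
    gaussian_sd=0.0, bleach_rate_donor=0.0, bleach_rate_acceptor=0.0
)
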