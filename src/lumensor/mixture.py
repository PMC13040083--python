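"""Gaussian mixture fits of pooled FRET-efficiency histograms.

Population analysis of the sensor works on the pooled per-frame efficiency
values of many molecules: a one- or two-component Gaussian maximum-likelihood
fit, with the area (weight) of the high-efficiency component reporting the
bound fraction of the sensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

from .errors import ValidationError

#: Variance floor applied to mixture components (efficiency units squared).
VAR_FLOOR = 1e-4


@dataclass
class MixtureFit:
    """Components ordered by ascending mean; weights sum to 1."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    n_components: int
    log_likelihood: float
    variance_floored: bool = False

    @property
    def mean_low(self) -> float:
        return float(self.means[0])

    @property
    def mean_high(self) -> float:
        return float(self.means[-1])


def fit_fret_histogram(
    e_values, n_components: int = 2, init_means=None, min_samples: int = 100
) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture fit of pooled efficiency values.

    For two components the means are initialised at the 10th/90th sample
    percentiles unless ``init_means`` is given.  Components whose variance
    collapses are refit against the floor and flagged.
    """
    x = np.asarray(e_values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_samples:
        raise ValidationError(f"need >= {min_samples} efficiency values")
    if n_components not in (1, 2):
        raise ValidationError("n_components must be 1 or 2")

    if n_components == 1:
        mu, sd = norm.fit(x)
        floored = sd**2 < VAR_FLOOR
        sd = max(sd, float(np.sqrt(VAR_FLOOR)))
        ll = float(norm.logpdf(x, mu, sd).sum())
        return MixtureFit(
            means=np.array([mu]), sds=np.array([sd]), weights=np.array([1.0]),
            n_components=1, log_likelihood=ll, variance_floored=bool(floored),
        )

    if init_means is None:
        init_means = np.percentile(x, [10.0, 90.0])
    gm = GaussianMixture(
        n_components=2,
        covariance_type="spherical",
        reg_covar=VAR_FLOOR,
        means_init=np.asarray(init_means, float).reshape(-1, 1),
        max_iter=500,
        tol=1e-6,
        random_state=0,
    ).fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    floored = bool(np.any(gm.covariances_.ravel() <= VAR_FLOOR * 1.001))
    return MixtureFit(
        means=means[order], sds=sds[order], weights=weights[order],
        n_components=2,
        log_likelihood=float(gm.score(x.reshape(-1, 1)) * len(x)),
        variance_floored=floored,
    )


def bound_fraction(fit: MixtureFit) -> float:
    """Area fraction of the high-efficiency (closed/bound) component."""
    if fit.n_components != 2:
        raise ValidationError(
            "bound_fraction needs a two-component fit; refit with n_components=2"
        )
    return float(fit.weights[-1])


def bound_fraction_from_sample(
    e_values, min_separation: float = 0.15, e_mid: float = 0.75,
) -> tuple[float, MixtureFit]:
    """Bound fraction of a pooled efficiency sample, robust to unimodality.

    Fits a two-component mixture; when the fitted components are closer than
    ``min_separation`` the sample is unimodal (a fully apo or fully bound
    population, where a two-component fit would split one Gaussian
    arbitrarily) and the whole population is assigned to the side of
    ``e_mid`` its mode lies on.
    """
    fit = fit_fret_histogram(e_values, n_components=2)
    if fit.means[-1] - fit.means[0] < min_separation:
        pooled_mean = float(np.mean(np.asarray(e_values, dtype=float)))
        return (1.0 if pooled_mean > e_mid else 0.0), fit
    return bound_fraction(fit), fit
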