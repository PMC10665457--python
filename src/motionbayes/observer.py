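"""Bayesian observer combining velocity and spatial-orientation cues.

The observer infers motion direction s (on the full circle) from two noisy
measurements: a velocity measurement x_V in the 360-degree direction space,
and a spatial-orientation measurement x_O ("motion streak") that lives in the
180-degree orientation space and is therefore consistent with two opposite
directions.  With a flat prior, the posterior over direction is the
normalized product of a unimodal von Mises velocity likelihood and a bimodal
orientation likelihood, which collapses analytically to a two-component
von Mises mixture.

A velocity-only observer, which ignores the orientation cue, serves as the
contrast model throughout: its posterior is always unimodal and its
maximum-a-posteriori estimate is simply x_V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .circular import (
    DirectionDistribution,
    DirectionGrid,
    circdist,
    default_grid,
    kappa_to_sigma,
    sigma_to_kappa,
    vm_logpdf,
    wrap_direction,
    wrap_orientation,
)

__all__ = [
    "ObserverParams",
    "Measurement",
    "PosteriorMixture",
    "sample_measurements",
    "velocity_likelihood",
    "orientation_likelihood",
    "combined_posterior",
    "combined_posterior_arrays",
    "map_readout",
    "velocity_only_readout",
    "map_distribution_approx",
    "map_closed_form",
]


@dataclass(frozen=True)
class ObserverParams:
    """Cue precisions of the observer.

    ``kappa_v`` is the concentration of the velocity measurement noise,
    ``kappa_o`` that of the orientation measurement noise.  Either can be
    constructed from circular SDs in degrees via :meth:`from_sigmas`.
    """

    kappa_v: float
    kappa_o: float

    def __post_init__(self):
        if self.kappa_v < 0 or self.kappa_o < 0:
            raise ValueError("cue precisions must be nonnegative")

    @classmethod
    def from_sigmas(cls, sigma_v_deg: float, sigma_o_deg: float) -> "ObserverParams":
        return cls(sigma_to_kappa(sigma_v_deg), sigma_to_kappa(sigma_o_deg))

    @property
    def sigma_v(self) -> float:
        return kappa_to_sigma(self.kappa_v)

    @property
    def sigma_o(self) -> float:
        return kappa_to_sigma(self.kappa_o)


@dataclass(frozen=True)
class Measurement:
    """One trial's noisy measurements: direction x_V, orientation x_O."""

    x_v: float
    x_o: float

    def __post_init__(self):
        if not (0.0 <= self.x_v < 360.0):
            raise ValueError(f"x_v={self.x_v} outside [0, 360)")
        if not (0.0 <= self.x_o < 180.0):
            raise ValueError(f"x_o={self.x_o} outside [0, 180)")


@dataclass
class PosteriorMixture:
    """Analytic two-von-Mises description of the observer posterior.

    Component A is by convention the one whose mean is nearer the velocity
    measurement.  Weights are normalized to one.
    """

    w_a: float
    w_b: float
    theta_a: float
    theta_b: float
    kappa_a: float
    kappa_b: float

    def __post_init__(self):
        if self.w_a < 0 or self.w_b < 0:
            raise ValueError("mixture weights must be nonnegative")
        if abs(self.w_a + self.w_b - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def log_density(self, angles_deg) -> np.ndarray:
        """Log mixture density per radian at the given angles."""
        la = np.log(self.w_a + 1e-300) + vm_logpdf(angles_deg, self.theta_a, self.kappa_a)
        lb = np.log(self.w_b + 1e-300) + vm_logpdf(angles_deg, self.theta_b, self.kappa_b)
        return np.logaddexp(la, lb)

    def on_grid(self, grid: DirectionGrid | None = None) -> DirectionDistribution:
        grid = grid or default_grid()
        logd = self.log_density(grid.angles)
        logd -= logd.max()
        return DirectionDistribution.from_weights(np.exp(logd), grid)

    def entropy_bits(self, grid: DirectionGrid | None = None) -> float:
        return self.on_grid(grid).entropy_bits()


def sample_measurements(
    s_deg: float, params: ObserverParams, rng: np.random.Generator | int
) -> Measurement:
    """Draw one trial's (x_V, x_O) for stimulus direction ``s_deg``.

    x_V ~ VM(s, kappa_v) on the full circle; x_O is s plus VM(0, kappa_o)
    noise on the full circle, wrapped into the 180-degree orientation space.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    x_v = wrap_direction(s_deg + np.rad2deg(rng.vonmises(0.0, _safe_kappa(params.kappa_v))))
    x_o = wrap_orientation(s_deg + np.rad2deg(rng.vonmises(0.0, _safe_kappa(params.kappa_o))))
    return Measurement(float(x_v), float(x_o))


def _safe_kappa(kappa: float) -> float:
    # numpy's von Mises sampler loses accuracy above ~1e7; the distribution
    # is numerically a delta there anyway
    return min(kappa, 1e7)


def velocity_likelihood(
    x_v: float, kappa_v: float, grid: DirectionGrid | None = None
) -> DirectionDistribution:
    """Velocity likelihood over direction: a von Mises centered at x_V."""
    return DirectionDistribution.von_mises(x_v, kappa_v, grid)


def orientation_likelihood(
    x_o: float, kappa_o: float, grid: DirectionGrid | None = None
) -> DirectionDistribution:
    """Orientation likelihood over direction: equal von Mises peaks at
    x_O and x_O + 180, reflecting the streak's sign ambiguity."""
    grid = grid or default_grid()
    l1 = vm_logpdf(grid.angles, x_o, kappa_o)
    l2 = vm_logpdf(grid.angles, x_o + 180.0, kappa_o)
    logw = np.logaddexp(l1, l2)
    logw -= logw.max()
    return DirectionDistribution.from_weights(np.exp(logw), grid)


def _vm_product(mu1, kappa1, mu2, kappa2):
    """Parameters of VM(mu1,k1)*VM(mu2,k2) ∝ c * VM(mu12, k12).

    Resultant-vector addition gives the product's location and concentration;
    the log normalizer log c = log I0(k12) - log(2 pi I0(k1) I0(k2)) is
    returned in a large-kappa-stable form.  All array-broadcastable.
    """
    r1, r2 = np.deg2rad(mu1), np.deg2rad(mu2)
    c = kappa1 * np.cos(r1) + kappa2 * np.cos(r2)
    s = kappa1 * np.sin(r1) + kappa2 * np.sin(r2)
    kappa12 = np.hypot(c, s)
    mu12 = wrap_direction(np.rad2deg(np.arctan2(s, c)))
    # log c up to terms shared by both mixture components:
    # log I0(k12) = log ive(0,k12) + k12
    log_norm = np.log(special.ive(0, kappa12)) + kappa12
    return mu12, kappa12, log_norm


def combined_posterior_arrays(x_v, x_o, kappa_v, kappa_o):
    """Vectorized analytic posterior mixtures for many trials.

    Returns arrays (w_a, w_b, theta_a, theta_b, kappa_a, kappa_b), with
    component A the one nearer x_V.
    """
    x_v = np.asarray(x_v, dtype=float)
    x_o = np.asarray(x_o, dtype=float)
    kappa_v = np.broadcast_to(np.asarray(kappa_v, dtype=float), x_v.shape)
    kappa_o = np.broadcast_to(np.asarray(kappa_o, dtype=float), x_v.shape)

    mu1, k1, logc1 = _vm_product(x_v, kappa_v, x_o, kappa_o)
    mu2, k2, logc2 = _vm_product(x_v, kappa_v, x_o + 180.0, kappa_o)
    m = np.maximum(logc1, logc2)
    c1 = np.exp(logc1 - m)
    c2 = np.exp(logc2 - m)
    w1 = c1 / (c1 + c2)
    w2 = 1.0 - w1

    near1 = np.abs(circdist(mu1, x_v)) <= np.abs(circdist(mu2, x_v))
    w_a = np.where(near1, w1, w2)
    w_b = 1.0 - w_a
    theta_a = np.where(near1, mu1, mu2)
    theta_b = np.where(near1, mu2, mu1)
    kappa_a = np.where(near1, k1, k2)
    kappa_b = np.where(near1, k2, k1)
    return w_a, w_b, theta_a, theta_b, kappa_a, kappa_b


def combined_posterior(m: Measurement, params: ObserverParams) -> PosteriorMixture:
    """Analytic posterior for one trial under a flat direction prior.

    The posterior ∝ L_V * L_O collapses to a two-component von Mises
    mixture; the component means, concentrations and weights follow from
    the product-of-von-Mises identity (resultant-vector addition for the
    location/concentration, Bessel-ratio normalizers for the weights).
    """
    w_a, w_b, th_a, th_b, k_a, k_b = combined_posterior_arrays(
        np.array(m.x_v), np.array(m.x_o), params.kappa_v, params.kappa_o
    )
    return PosteriorMixture(
        float(w_a), float(w_b), float(th_a), float(th_b), float(k_a), float(k_b)
    )


def map_readout(post: PosteriorMixture, grid: DirectionGrid | None = None) -> float:
    """MAP estimate: argmax of the mixture on the direction grid.

    Deterministic tie-break: the smallest canonical angle wins (np.argmax
    returns the first maximizer on the ascending grid).
    """
    grid = grid or default_grid()
    logd = post.log_density(grid.angles)
    return float(grid.angles[int(np.argmax(logd))])


def map_readout_arrays(w_a, w_b, theta_a, theta_b, kappa_a, kappa_b, grid=None):
    """Vectorized grid argmax of many posterior mixtures (trials x grid)."""
    grid = grid or default_grid()
    ang = grid.angles[None, :]
    la = np.log(np.asarray(w_a)[:, None] + 1e-300) + _vm_logpdf_2d(
        ang, np.asarray(theta_a)[:, None], np.asarray(kappa_a)[:, None]
    )
    lb = np.log(np.asarray(w_b)[:, None] + 1e-300) + _vm_logpdf_2d(
        ang, np.asarray(theta_b)[:, None], np.asarray(kappa_b)[:, None]
    )
    logd = np.logaddexp(la, lb)
    return grid.angles[np.argmax(logd, axis=1)]


def _vm_logpdf_2d(x_deg, mu_deg, kappa):
    dx = np.deg2rad(x_deg - mu_deg)
    return kappa * (np.cos(dx) - 1.0) - np.log(2.0 * np.pi * special.ive(0, kappa))


def velocity_only_readout(m: Measurement) -> float:
    """MAP of the velocity-only posterior: the velocity measurement itself."""
    return float(m.x_v)


def map_closed_form(x_v: float, x_o: float, kappa_v: float, kappa_o: float) -> float:
    """Closed-form MAP estimate valid when the secondary weight is negligible.

    s_hat = x_V - atan2(sin(x_V - x_O), kappa_V/kappa_O + cos(x_V - x_O)),
    with the orientation measurement unwrapped to the half-circle nearer x_V.
    """
    # unwrap x_o into direction space on the side closest to x_v
    d = circdist(x_o, x_v, period=360.0)
    x_o_dir = x_v + np.where(np.abs(d) <= 90.0, d, d - np.sign(d) * 180.0)
    delta = np.deg2rad(x_v - x_o_dir)
    shift = np.arctan2(np.sin(delta), kappa_v / kappa_o + np.cos(delta))
    return wrap_direction(x_v - np.rad2deg(shift))


def map_distribution_approx(
    s_deg: float, params: ObserverParams, w_b_threshold: float = 1e-2
) -> tuple[float, float]:
    """von Mises approximation (mu, kappa) to the across-trial MAP
    distribution in the low-velocity-noise regime.

    mu = s and kappa = kappa_o + kappa_v.  Warns when the secondary posterior
    weight is non-negligible for aligned measurements, in which case the
    approximation is unreliable and simulation is required.
    """
    m = Measurement(wrap_direction(s_deg), wrap_orientation(s_deg))
    post = combined_posterior(m, params)
    if post.w_b > w_b_threshold:
        warnings.warn(
            "secondary posterior component is non-negligible "
            f"(w_b={post.w_b:.3g}); the von Mises approximation to the MAP "
            "distribution no longer holds",
            stacklevel=2,
        )
    return float(wrap_direction(s_deg)), params.kappa_o + params.kappa_v
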