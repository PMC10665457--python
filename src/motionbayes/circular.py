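"""Circular-statistics primitives shared by every pipeline stage.

All public interfaces take angles in degrees; radians are used internally.
Motion directions live on [0, 360), spatial orientations on [0, 180).
Probability distributions over direction are represented on a fixed uniform
grid (default 0.5 deg step, 720 bins, bin centers at 0, 0.5, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.spatial.distance import jensenshannon

DEFAULT_STEP = 0.5  #: grid step in degrees

__all__ = [
    "DirectionGrid",
    "DirectionDistribution",
    "wrap_direction",
    "wrap_orientation",
    "circdist",
    "vm_pdf",
    "vm_logpdf",
    "kappa_to_sigma",
    "sigma_to_kappa",
    "entropy_bits",
    "circ_corr",
    "fisher_z",
    "inverse_fisher_z",
    "jsd",
    "circular_mean",
    "circular_sd",
    "resultant_length",
    "ml_kappa",
]


def wrap_direction(angle_deg):
    """Wrap an angle (degrees) into the direction space [0, 360)."""
    r = np.mod(angle_deg, 360.0)
    # np.mod can return the period itself for tiny negative inputs
    return np.where(r >= 360.0, 0.0, r)[()] if np.ndim(r) == 0 else np.where(r >= 360.0, 0.0, r)


def wrap_orientation(angle_deg):
    """Wrap an angle (degrees) into the orientation space [0, 180)."""
    r = np.mod(angle_deg, 180.0)
    return np.where(r >= 180.0, 0.0, r)[()] if np.ndim(r) == 0 else np.where(r >= 180.0, 0.0, r)


def circdist(a_deg, b_deg, period: float = 360.0):
    """Signed circular difference a - b in degrees, in [-period/2, period/2)."""
    d = np.mod(np.asarray(a_deg) - np.asarray(b_deg) + period / 2.0, period)
    return d - period / 2.0


class DirectionGrid:
    """Uniform grid of motion directions covering [0, 360).

    Bin centers sit at ``0, step, 2*step, ...``; ``step`` must divide 360
    exactly.  The grid is shared by value: two grids compare equal iff they
    have the same step.
    """

    def __init__(self, step: float = DEFAULT_STEP):
        n = 360.0 / step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"grid step {step} does not divide 360 exactly")
        self.step = float(step)
        self.n = int(round(n))
        self.angles = np.arange(self.n) * self.step
        self.radians = np.deg2rad(self.angles)

    def __eq__(self, other):
        return isinstance(other, DirectionGrid) and self.n == other.n

    def __hash__(self):
        return hash(("DirectionGrid", self.n))

    def __repr__(self):
        return f"DirectionGrid(step={self.step}, n={self.n})"


_DEFAULT_GRID = DirectionGrid()


def default_grid() -> DirectionGrid:
    return _DEFAULT_GRID


@dataclass
class DirectionDistribution:
    """Probability mass over a :class:`DirectionGrid`.

    ``mass`` holds one nonnegative weight per bin and sums to one.  Densities
    per degree are ``mass / grid.step``; per radian multiply by 180/pi.
    """

    grid: DirectionGrid
    mass: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.shape != (self.grid.n,):
            raise ValueError(
                f"mass has shape {self.mass.shape}, expected ({self.grid.n},)"
            )
        if np.any(self.mass < -1e-12):
            raise ValueError("mass must be nonnegative")
        total = self.mass.sum()
        if not np.isfinite(total) or abs(total - 1.0) > 1e-9:
            raise ValueError(f"mass sums to {total}, expected 1 within 1e-9")

    @classmethod
    def from_weights(cls, weights, grid: DirectionGrid | None = None):
        """Normalize arbitrary nonnegative weights into a distribution."""
        grid = grid or _DEFAULT_GRID
        w = np.asarray(weights, dtype=float)
        w = np.clip(w, 0.0, None)
        total = w.sum()
        if total <= 0:
            raise ValueError("weights sum to zero; cannot normalize")
        return cls(grid, w / total)

    @classmethod
    def uniform(cls, grid: DirectionGrid | None = None):
        grid = grid or _DEFAULT_GRID
        return cls(grid, np.full(grid.n, 1.0 / grid.n))

    @classmethod
    def delta(cls, angle_deg: float, grid: DirectionGrid | None = None):
        grid = grid or _DEFAULT_GRID
        mass = np.zeros(grid.n)
        mass[int(round(wrap_direction(angle_deg) / grid.step)) % grid.n] = 1.0
        return cls(grid, mass)

    @classmethod
    def von_mises(cls, mu_deg: float, kappa: float, grid: DirectionGrid | None = None):
        grid = grid or _DEFAULT_GRID
        logw = vm_logpdf(grid.angles, mu_deg, kappa)
        logw -= logw.max()
        return cls.from_weights(np.exp(logw), grid)

    def mode(self) -> float:
        """Grid argmax in degrees; ties broken by the smallest canonical angle."""
        return float(self.grid.angles[int(np.argmax(self.mass))])

    def mean_direction(self) -> float:
        """Circular mean of the distribution, degrees in [0, 360)."""
        z = np.sum(self.mass * np.exp(1j * self.grid.radians))
        return float(wrap_direction(np.rad2deg(np.angle(z))))

    def entropy_bits(self) -> float:
        return entropy_bits(self)

    def to_csv(self, path):
        import pandas as pd

        pd.DataFrame({"angle_deg": self.grid.angles, "mass": self.mass}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path):
        import pandas as pd

        df = pd.read_csv(path)
        step = float(df["angle_deg"].iloc[1] - df["angle_deg"].iloc[0])
        return cls(DirectionGrid(step), df["mass"].to_numpy())

    def to_npy(self, path):
        np.save(path, self.mass)

    @classmethod
    def from_npy(cls, path):
        mass = np.load(path)
        return cls(DirectionGrid(360.0 / len(mass)), mass)


# ---------------------------------------------------------------------------
# von Mises density and precision/width conversion


def _log_i0(kappa):
    """log I0(kappa), stable for large kappa via the scaled Bessel function."""
    kappa = np.asarray(kappa, dtype=float)
    return np.log(special.ive(0, kappa)) + kappa


def vm_logpdf(x_deg, mu_deg, kappa):
    """Log of the von Mises density (per radian) at ``x_deg``.

    Stable for arbitrarily large kappa: the density is evaluated as
    ``kappa*(cos(x-mu)-1) - log(2*pi*ive(0,kappa))``.
    """
    kappa = float(kappa)
    if not np.isfinite(kappa) or kappa < 0:
        raise ValueError(f"kappa must be finite and nonnegative, got {kappa}")
    dx = np.deg2rad(np.asarray(x_deg, dtype=float) - mu_deg)
    # kappa*cos(dx) - log I0(kappa) = kappa*(cos(dx)-1) - log ive(0,kappa)
    return kappa * (np.cos(dx) - 1.0) - np.log(2.0 * np.pi * special.ive(0, kappa))


def vm_pdf(x_deg, mu_deg, kappa):
    """von Mises density (per radian) at ``x_deg`` (degrees)."""
    return np.exp(vm_logpdf(x_deg, mu_deg, kappa))


def _bessel_ratio(kappa):
    """A(kappa) = I1(kappa)/I0(kappa), the mean resultant length."""
    kappa = np.asarray(kappa, dtype=float)
    return special.ive(1, kappa) / special.ive(0, kappa)


def kappa_to_sigma(kappa) -> float:
    """Circular standard deviation (degrees) implied by concentration kappa.

    sigma = sqrt(-2 log(I1(kappa)/I0(kappa))); decreasing in kappa, infinite
    at kappa = 0.
    """
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa < 0):
        raise ValueError("kappa must be nonnegative")
    r = _bessel_ratio(kappa)
    with np.errstate(divide="ignore"):
        sigma_rad = np.sqrt(-2.0 * np.log(r))
    return float(np.rad2deg(sigma_rad)) if np.ndim(kappa) == 0 else np.rad2deg(sigma_rad)


def sigma_to_kappa(sigma_deg) -> float:
    """Inverse of :func:`kappa_to_sigma` by bracketed root-finding."""
    scalar = np.ndim(sigma_deg) == 0
    out = []
    for s in np.atleast_1d(np.asarray(sigma_deg, dtype=float)):
        if s <= 0:
            raise ValueError("sigma must be positive")
        target = np.exp(-0.5 * np.deg2rad(s) ** 2)  # resultant length

        def f(log_k):
            return _bessel_ratio(np.exp(log_k)) - target

        out.append(np.exp(optimize.brentq(f, np.log(1e-8), np.log(1e8), xtol=1e-12)))
    return float(out[0]) if scalar else np.array(out)


_KAPPA_TABLE = np.concatenate([[0.0], np.logspace(-6, 8, 4000)])
_A_TABLE = special.ive(1, _KAPPA_TABLE) / special.ive(0, _KAPPA_TABLE)


def convolved_kappa(kappa1, kappa2):
    """Effective concentration of the sum of two independent von Mises
    variables, via the resultant-length product identity
    A(k_eff) = A(k1) * A(k2).

    The convolution of two von Mises distributions is not von Mises, but the
    matched-resultant approximation is standard and accurate; k_eff is
    dominated by the smaller of the two concentrations.  Vectorized through
    a dense monotone lookup table (relative accuracy ~1e-3).
    """
    a = np.interp(np.asarray(kappa1, dtype=float), _KAPPA_TABLE, _A_TABLE) * np.interp(
        np.asarray(kappa2, dtype=float), _KAPPA_TABLE, _A_TABLE
    )
    return np.interp(a, _A_TABLE, _KAPPA_TABLE)


def resultant_length(angles_deg, period: float = 360.0) -> float:
    """Mean resultant length of a sample of angles."""
    rad = np.deg2rad(np.asarray(angles_deg)) * (360.0 / period)
    return float(np.abs(np.mean(np.exp(1j * rad))))


def circular_mean(angles_deg, period: float = 360.0) -> float:
    """Circular mean of a sample, in degrees on [0, period)."""
    rad = np.deg2rad(np.asarray(angles_deg)) * (360.0 / period)
    mean = np.angle(np.mean(np.exp(1j * rad)))
    return float(np.mod(np.rad2deg(mean) * (period / 360.0), period))


def circular_sd(angles_deg, period: float = 360.0) -> float:
    """Circular standard deviation of a sample, degrees."""
    r = min(resultant_length(angles_deg, period), 1.0)
    if r <= 0:
        return np.inf
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(r))) * (period / 360.0))


def ml_kappa(angles_deg, mu_deg=None, period: float = 360.0) -> float:
    """Maximum-likelihood von Mises concentration for a sample.

    If ``mu_deg`` is given the resultant is projected onto that mean;
    otherwise the ML mean (the sample circular mean) is used.
    """
    rad = np.deg2rad(np.asarray(angles_deg)) * (360.0 / period)
    if mu_deg is None:
        r = np.abs(np.mean(np.exp(1j * rad)))
    else:
        mu = np.deg2rad(mu_deg) * (360.0 / period)
        r = float(np.mean(np.cos(rad - mu)))
    r = min(max(r, 1e-12), 1.0 - 1e-12)

    def f(log_k):
        return _bessel_ratio(np.exp(log_k)) - r

    return float(np.exp(optimize.brentq(f, np.log(1e-8), np.log(1e8), xtol=1e-12)))


# ---------------------------------------------------------------------------
# information measures


def entropy_bits(dist: DirectionDistribution) -> float:
    """Shannon entropy of the grid masses, in bits.

    Zero-mass bins contribute zero by the usual 0*log(0)=0 convention.
    The maximum, attained by the uniform distribution, is log2(n bins).
    """
    p = dist.mass[dist.mass > 0]
    return float(-np.sum(p * np.log2(p)))


def jsd(p: DirectionDistribution, q: DirectionDistribution) -> float:
    """Jensen-Shannon divergence between two distributions on the same grid.

    Base-2 convention: symmetric, zero iff p == q, bounded above by 1 bit.
    """
    if p.grid != q.grid:
        raise ValueError("distributions live on different grids")
    return float(jensenshannon(p.mass, q.mass, base=2) ** 2)


# ---------------------------------------------------------------------------
# circular correlation


def circ_corr(a_deg, b_deg) -> float:
    """Fisher-Lee circular correlation between two samples of directions.

    Computed with the O(n) expansion of the pairwise definition
    ``sum_{i<j} sin(a_i-a_j) sin(b_i-b_j) / sqrt(...)``.  Invariant to
    rotating either sample; +1 when b = a + const.
    """
    a = np.deg2rad(np.asarray(a_deg, dtype=float))
    b = np.deg2rad(np.asarray(b_deg, dtype=float))
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D samples")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 paired angles")

    num = _pairwise_sine_sum(a, b)
    den_a = _pairwise_sine_sum(a, a)
    den_b = _pairwise_sine_sum(b, b)
    if den_a <= 1e-12 or den_b <= 1e-12:
        raise ValueError("circular correlation undefined for (near-)constant input")
    return float(num / np.sqrt(den_a * den_b))


def _pairwise_sine_sum(a, b):
    """sum over all ordered pairs (i, j) of sin(a_i - a_j) * sin(b_i - b_j).

    Expands to O(n) sums:  sin(ai-aj)sin(bi-bj)
      = (sin ai cos aj - cos ai sin aj)(sin bi cos bj - cos bi sin bj).
    """
    sa, ca = np.sin(a), np.cos(a)
    sb, cb = np.sin(b), np.cos(b)
    # sum_ij sin(ai-aj)sin(bi-bj)
    #  = sum_ij [sa_i ca_j sb_i cb_j - sa_i ca_j cb_i sb_j
    #            - ca_i sa_j sb_i cb_j + ca_i sa_j cb_i sb_j]
    t1 = np.sum(sa * sb) * np.sum(ca * cb)
    t2 = np.sum(sa * cb) * np.sum(ca * sb)
    t3 = np.sum(ca * sb) * np.sum(sa * cb)
    t4 = np.sum(ca * cb) * np.sum(sa * sb)
    return t1 - t2 - t3 + t4


def fisher_z(r) -> float:
    """Fisher z-transform (arctanh) for aggregating correlation coefficients."""
    return float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))


def inverse_fisher_z(z) -> float:
    return float(np.tanh(z))
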