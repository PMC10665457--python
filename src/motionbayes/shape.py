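"""Trial-by-trial quantification of posterior shape.

A descriptive mixture of two von Mises components plus a circular uniform
("lapse") component is fitted to each posterior by minimizing the
Jensen-Shannon divergence between the posterior and the mixture, with
bounded parameters and many random restarts.  Fitted component locations
are disambiguated either by height or by proximity to the true direction,
clustered on the torus with bivariate von Mises mixtures compared by WAIC,
and regressed against behavioral errors after a sine transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .circular import (
    DirectionDistribution,
    circdist,
    circular_sd,
    default_grid,
    vm_logpdf,
    wrap_direction,
)

logger = logging.getLogger(__name__)

KAPPA_BOUNDS = (0.001, 100.0)
ALPHA_BOUNDS = (1e-5, 1.0 - 1e-5)
LAPSE_BOUNDS = (0.0, 0.9)

__all__ = [
    "DescriptiveMixture",
    "PeakPair",
    "fit_descriptive_mixture",
    "fit_mixture_batch",
    "disambiguate",
    "cluster_peak_pairs",
    "fit_cluster_model_em",
    "peak_error_regression",
    "compute_waic",
]


@dataclass
class DescriptiveMixture:
    """Fitted two-von-Mises + uniform mixture (Eq.-style descriptive model).

    ``lapse_weight`` is the uniform component's weight; ``alpha`` the
    relative weight of component 1 among the von Mises part.
    """

    lapse_weight: float
    alpha: float
    mu1: float
    kappa1: float
    mu2: float
    kappa2: float
    jsd: float = np.nan
    restart_sd_mu1: float = np.nan
    restart_sd_mu2: float = np.nan
    converged: bool = True

    def density(self, angles_deg) -> np.ndarray:
        """Mixture density per radian."""
        f1 = np.exp(vm_logpdf(angles_deg, self.mu1, self.kappa1))
        f2 = np.exp(vm_logpdf(angles_deg, self.mu2, self.kappa2))
        vm_part = self.alpha * f1 + (1.0 - self.alpha) * f2
        return (1.0 - self.lapse_weight) * vm_part + self.lapse_weight / (2.0 * np.pi)

    def on_grid(self, grid=None) -> DirectionDistribution:
        grid = grid or default_grid()
        return DirectionDistribution.from_weights(self.density(grid.angles), grid)

    def component_heights(self) -> tuple[float, float]:
        """Full mixture density evaluated at each component's mean."""
        return float(self.density(self.mu1)), float(self.density(self.mu2))


@dataclass
class PeakPair:
    """Per-trial component locations under both disambiguation conventions."""

    trial: int
    mu_large: float
    mu_small: float
    mu_near_true: float
    mu_near_opposite: float
    jsd: float
    conventions_agree: bool


def _mixture_mass(params, grid):
    lapse, alpha, mu1, k1, mu2, k2 = params
    f1 = np.exp(k1 * (np.cos(np.deg2rad(grid.angles - mu1)) - 1.0)) / special.ive(0, k1)
    f2 = np.exp(k2 * (np.cos(np.deg2rad(grid.angles - mu2)) - 1.0)) / special.ive(0, k2)
    vm_part = alpha * f1 + (1.0 - alpha) * f2
    m = (1.0 - lapse) * vm_part / (2.0 * np.pi) + lapse / (2.0 * np.pi)
    return m / m.sum()


def _jsd_mass(p, q):
    # base-2 JSD of two mass vectors; inline for speed in the optimizer loop
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(p > 0, p * (np.log2(np.where(p > 0, p, 1.0)) - np.log2(m)), 0.0)
        t2 = np.where(q > 0, q * (np.log2(np.where(q > 0, q, 1.0)) - np.log2(m)), 0.0)
    return 0.5 * (t1.sum() + t2.sum())


def _jsd_objective_and_grad(params, target, grid):
    """JSD(target, mixture) in bits and its analytic gradient in the six
    mixture parameters (lapse, alpha, mu1, kappa1, mu2, kappa2).

    The chain runs gradient-of-JSD-in-mass -> normalization -> von Mises
    density partials; angles differentiate in degrees.
    """
    lapse, alpha, mu1, k1, mu2, k2 = params
    r1 = np.deg2rad(grid.angles - mu1)
    r2 = np.deg2rad(grid.angles - mu2)
    c1, c2 = np.cos(r1), np.cos(r2)
    f1 = np.exp(k1 * (c1 - 1.0)) / special.ive(0, k1)
    f2 = np.exp(k2 * (c2 - 1.0)) / special.ive(0, k2)
    vm_part = alpha * f1 + (1.0 - alpha) * f2
    u = (1.0 - lapse) * vm_part + lapse
    U = u.sum()
    m = u / U

    p = target
    mid = 0.5 * (p + m)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0) / mid), 0.0)
        lm = np.where(m > 0, np.log2(np.where(m > 0, m, 1.0) / mid), 0.0)
    jsd_val = 0.5 * (np.sum(p * lp) + np.sum(m * lm))

    g_m = 0.5 * lm  # dJSD/dm_i
    # through normalization m = u/U
    g_u = (g_m - np.dot(g_m, m)) / U

    a1 = special.ive(1, k1) / special.ive(0, k1)
    a2 = special.ive(1, k2) / special.ive(0, k2)
    deg = np.pi / 180.0
    du = np.empty((6, grid.n))
    du[0] = 1.0 - vm_part
    du[1] = (1.0 - lapse) * (f1 - f2)
    du[2] = (1.0 - lapse) * alpha * f1 * k1 * np.sin(r1) * deg
    du[3] = (1.0 - lapse) * alpha * f1 * (c1 - a1)
    du[4] = (1.0 - lapse) * (1.0 - alpha) * f2 * k2 * np.sin(r2) * deg
    du[5] = (1.0 - lapse) * (1.0 - alpha) * f2 * (c2 - a2)
    grad = du @ g_u
    return float(jsd_val), grad


def _data_driven_starts(posterior: DirectionDistribution):
    """Starting points built from the posterior's own peak structure."""
    from scipy.signal import find_peaks

    p = posterior.mass
    grid = posterior.grid
    tiled = np.concatenate([p, p, p])
    idx, _ = find_peaks(tiled, height=0.005 * p.max())
    idx = idx[(idx >= grid.n) & (idx < 2 * grid.n)] - grid.n
    if len(idx) == 0:
        idx = np.array([int(np.argmax(p))])
    order = np.argsort(p[idx])[::-1]
    mu_a = grid.angles[idx[order[0]]]
    starts = []
    if len(order) > 1:
        mu_b = grid.angles[idx[order[1]]]
        starts.append([0.05, 0.7, mu_a, 20.0, mu_b, 10.0])
    # co-located pair (peak + shoulder of a single bump) is always a candidate
    starts.append([0.05, 0.7, mu_a, 20.0, mu_a, 3.0])
    starts.append([0.05, 0.5, mu_a, 5.0, mu_a, 5.0])
    return starts


def fit_descriptive_mixture(
    posterior: DirectionDistribution,
    n_restarts: int = 100,
    seed: int = 0,
    extra_starts=None,
    near_optimal_frac: float = 0.05,
    early_stop_jsd: float = 1e-10,
    max_lapse: float = LAPSE_BOUNDS[1],
) -> DescriptiveMixture:
    """Best-of-restarts JSD fit of the two-component descriptive mixture.

    Parameters are bounded (kappa in [0.001, 100], alpha in
    [1e-5, 1-1e-5], lapse in [0, 0.9]); each restart draws random starting
    values within bounds.  Data-driven starts from the posterior's own peaks
    and any caller-supplied ``extra_starts`` are always included.  The
    restart dispersion (circular SD of component locations across solutions
    whose JSD is within ``near_optimal_frac`` of the best) flags trials
    whose description is not unique.
    """
    rng = np.random.default_rng(seed)
    grid = posterior.grid
    target = posterior.mass

    def objective(x):
        return _jsd_objective_and_grad(x, target, grid)

    bounds = [
        (LAPSE_BOUNDS[0], max_lapse),
        ALPHA_BOUNDS,
        (None, None),
        KAPPA_BOUNDS,
        (None, None),
        KAPPA_BOUNDS,
    ]

    starts = list(extra_starts or []) + _data_driven_starts(posterior)
    for _ in range(n_restarts):
        starts.append(
            [
                rng.uniform(0.0, min(0.3, max_lapse)),
                rng.uniform(*ALPHA_BOUNDS),
                rng.uniform(0.0, 360.0),
                np.exp(rng.uniform(np.log(0.5), np.log(50.0))),
                rng.uniform(0.0, 360.0),
                np.exp(rng.uniform(np.log(0.5), np.log(50.0))),
            ]
        )

    solutions = []
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds, jac=True,
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if np.isfinite(res.fun):
            solutions.append((float(res.fun), res.x))
            # JSD >= 0, so a solution this close to zero is a global optimum
            # and further restarts cannot improve on it
            if res.fun <= early_stop_jsd:
                break
    if not solutions:
        logger.warning("all descriptive-mixture restarts failed; flagging trial")
        return DescriptiveMixture(0.9, 0.5, 0.0, 0.001, 180.0, 0.001, np.inf, converged=False)

    solutions.sort(key=lambda t: t[0])
    best_jsd, best_x = solutions[0]
    near = [x for f, x in solutions if f <= best_jsd * (1.0 + near_optimal_frac) + 1e-15]
    # align component labels to the best solution before measuring dispersion
    mus1, mus2 = [], []
    for x in near:
        d_direct = abs(circdist(x[2], best_x[2])) + abs(circdist(x[4], best_x[4]))
        d_swap = abs(circdist(x[4], best_x[2])) + abs(circdist(x[2], best_x[4]))
        if d_swap < d_direct:
            mus1.append(x[4])
            mus2.append(x[2])
        else:
            mus1.append(x[2])
            mus2.append(x[4])
    sd1 = circular_sd(np.array(mus1)) if len(mus1) > 1 else 0.0
    sd2 = circular_sd(np.array(mus2)) if len(mus2) > 1 else 0.0

    lapse, alpha, mu1, k1, mu2, k2 = best_x
    return DescriptiveMixture(
        lapse_weight=float(lapse),
        alpha=float(alpha),
        mu1=float(wrap_direction(mu1)),
        kappa1=float(k1),
        mu2=float(wrap_direction(mu2)),
        kappa2=float(k2),
        jsd=float(best_jsd),
        restart_sd_mu1=float(sd1),
        restart_sd_mu2=float(sd2),
    )


def fit_mixture_batch(
    posteriors: np.ndarray,
    grid=None,
    n_restarts: int = 5,
    seed: int = 0,
    analytic_starts: pd.DataFrame | None = None,
) -> list[DescriptiveMixture]:
    """Fit the descriptive mixture to many posteriors (rows of masses).

    ``analytic_starts`` may supply per-trial starting parameters (columns
    dec_w_a, dec_theta_a, dec_kappa_a, ...) — e.g. the analytic mixture of a
    simulated posterior — which are added to the restart pool for that trial.
    """
    grid = grid or default_grid()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(posteriors.shape[0]):
        extra = None
        if analytic_starts is not None:
            row = analytic_starts.iloc[i]
            extra = [
                [
                    0.0,
                    np.clip(row["dec_w_a"], *ALPHA_BOUNDS),
                    row["dec_theta_a"],
                    np.clip(row["dec_kappa_a"], *KAPPA_BOUNDS),
                    row["dec_theta_b"],
                    np.clip(row["dec_kappa_b"], *KAPPA_BOUNDS),
                ]
            ]
        post = DirectionDistribution(grid, posteriors[i])
        out.append(
            fit_descriptive_mixture(
                post,
                n_restarts=n_restarts,
                seed=int(rng.integers(2**31)),
                extra_starts=extra,
            )
        )
    return out


def disambiguate(m: DescriptiveMixture, true_direction: float, trial: int = 0) -> PeakPair:
    """Label the fitted components by height and by proximity to the truth.

    Height compares the full mixture density at each component's mean; an
    exact height tie falls back to the proximity convention.
    """
    h1, h2 = m.component_heights()
    d1 = abs(circdist(m.mu1, true_direction))
    d2 = abs(circdist(m.mu2, true_direction))
    if h1 > h2:
        mu_large, mu_small = m.mu1, m.mu2
    elif h2 > h1:
        mu_large, mu_small = m.mu2, m.mu1
    else:  # tie: the component nearer the truth is called "large"
        mu_large, mu_small = (m.mu1, m.mu2) if d1 <= d2 else (m.mu2, m.mu1)
    mu_near_true, mu_near_opposite = (m.mu1, m.mu2) if d1 <= d2 else (m.mu2, m.mu1)
    return PeakPair(
        trial=trial,
        mu_large=float(mu_large),
        mu_small=float(mu_small),
        mu_near_true=float(mu_near_true),
        mu_near_opposite=float(mu_near_opposite),
        jsd=m.jsd,
        conventions_agree=bool(
            abs(circdist(mu_large, mu_near_true)) < 1e-9
        ),
    )


# ---------------------------------------------------------------------------
# bivariate von Mises clustering with WAIC


def _n_cluster_params(n_clusters, background):
    # 4 location/width params per cluster plus mixing weights: with a
    # background there are n_clusters free weight params (uniform fixed as
    # reference), without it n_clusters - 1
    return 4 * n_clusters + (n_clusters if background else n_clusters - 1)


def _cluster_loglik_pointwise(params, x, y, n_clusters, background=True):
    """Pointwise log-likelihood of (x, y) peak pairs under the cluster model.

    Each cluster is a product of independent von Mises densities in the two
    coordinates; an optional circular-uniform background component (density
    1/(4 pi^2)) absorbs stray pairs, mirroring the lapse term of the
    trial-level descriptive mixture.  Mixing weights close the model.
    """
    logw = []
    for c in range(n_clusters):
        mux, muy, logkx, logky = params[4 * c : 4 * c + 4]
        kx, ky = np.exp(logkx), np.exp(logky)
        lc = vm_logpdf(np.rad2deg(x), np.rad2deg(mux), kx) + vm_logpdf(
            np.rad2deg(y), np.rad2deg(muy), ky
        )
        logw.append(lc)
    if background:
        logw.append(np.full_like(x, -np.log(4.0 * np.pi**2)))
    logw = np.stack(logw, axis=0)
    n_comp = logw.shape[0]
    if n_comp > 1:
        raw = params[4 * n_clusters :]
        pis = _softmax_weights(raw, n_comp)
        logw = logw + np.log(np.maximum(pis, 1e-300))[:, None]
    return special.logsumexp(logw, axis=0)


def _softmax_weights(raw, n_components):
    z = np.concatenate([np.asarray(raw, dtype=float), [0.0]])
    assert len(z) == n_components
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _log_prior(params, n_clusters, background=True):
    lp = 0.0
    for c in range(n_clusters):
        mux, muy, logkx, logky = params[4 * c : 4 * c + 4]
        if not (-np.pi <= mux < 3 * np.pi and -np.pi <= muy < 3 * np.pi):
            return -np.inf
        # log kappa ~ N(log 5, 1.5^2), weakly informative
        lp += -0.5 * ((logkx - np.log(5.0)) / 1.5) ** 2
        lp += -0.5 * ((logky - np.log(5.0)) / 1.5) ** 2
        if not (-15 < logkx < np.log(500.0) and -15 < logky < np.log(500.0)):
            return -np.inf
    raw = params[4 * n_clusters :]
    if len(raw):
        if np.any(np.abs(np.asarray(raw)) > 10):
            return -np.inf
        lp += -0.5 * np.sum((np.asarray(raw) / 3.0) ** 2)
    return lp


def fit_cluster_model_em(
    x_rad, y_rad, n_clusters, seed=0, n_init=5, max_iter=200, background=True
):
    """Deterministic EM fit of the product-von-Mises cluster mixture
    (optionally with a circular-uniform background component); returns
    (params vector, loglik, bic)."""
    rng = np.random.default_rng(seed)
    n = len(x_rad)
    n_comp = n_clusters + (1 if background else 0)
    log_uniform = -np.log(4.0 * np.pi**2)
    best = None
    for init in range(n_init):
        # responsibilities from random cluster seeds
        centers = rng.integers(0, n, size=n_clusters)
        d = np.array(
            [np.cos(x_rad - x_rad[c]) + np.cos(y_rad - y_rad[c]) for c in centers]
        )
        resp = (d == d.max(axis=0)).astype(float) + 1e-3
        if background:
            resp = np.vstack([resp, np.full(n, 0.02)])
        resp /= resp.sum(axis=0)
        ll_prev = -np.inf
        params = None
        for _ in range(max_iter):
            params = []
            pis = resp.sum(axis=1) / n
            for c in range(n_clusters):
                w = resp[c]
                zx = np.sum(w * np.exp(1j * x_rad))
                zy = np.sum(w * np.exp(1j * y_rad))
                mux, muy = np.angle(zx), np.angle(zy)
                rx = np.abs(zx) / max(w.sum(), 1e-12)
                ry = np.abs(zy) / max(w.sum(), 1e-12)
                params.extend(
                    [mux, muy, np.log(_kappa_from_r(rx)), np.log(_kappa_from_r(ry))]
                )
            if n_comp > 1:
                raw = np.log(np.maximum(pis[:-1], 1e-12) / max(pis[-1], 1e-12))
                params = np.concatenate([params, raw])
            else:
                params = np.asarray(params)
            # E-step
            logcomp = []
            for c in range(n_clusters):
                mux, muy, logkx, logky = params[4 * c : 4 * c + 4]
                lc = (
                    vm_logpdf(np.rad2deg(x_rad), np.rad2deg(mux), np.exp(logkx))
                    + vm_logpdf(np.rad2deg(y_rad), np.rad2deg(muy), np.exp(logky))
                    + np.log(max(pis[c], 1e-300))
                )
                logcomp.append(lc)
            if background:
                logcomp.append(
                    np.full(n, log_uniform) + np.log(max(pis[-1], 1e-300))
                )
            logcomp = np.stack(logcomp)
            lse = special.logsumexp(logcomp, axis=0)
            resp = np.exp(logcomp - lse)
            ll = float(lse.sum())
            if abs(ll - ll_prev) < 1e-8:
                break
            ll_prev = ll
        k_free = _n_cluster_params(n_clusters, background)
        bic = k_free * np.log(n) - 2.0 * ll
        if best is None or ll > best[1]:
            best = (params, ll, bic)
    return best


def _kappa_from_r(r):
    from .circular import ml_kappa

    r = min(max(r, 1e-6), 1 - 1e-9)
    # Banerjee approximation, adequate inside EM
    k = r * (2 - r**2) / (1 - r**2)
    return min(max(k, 1e-3), 450.0)


def compute_waic(pointwise_loglik: np.ndarray) -> tuple[float, float]:
    """WAIC (deviance scale) and effective parameter count from an
    (n_draws, n_obs) pointwise log-likelihood matrix.

    lppd_i = log mean_s exp(ll_si); p_waic_i = var_s(ll_si);
    WAIC = -2 * sum_i (lppd_i - p_waic_i).
    """
    ll = np.asarray(pointwise_loglik)
    lppd = special.logsumexp(ll, axis=0) - np.log(ll.shape[0])
    p_waic = np.var(ll, axis=0, ddof=1)
    return float(-2.0 * np.sum(lppd - p_waic)), float(np.sum(p_waic))


def cluster_peak_pairs(
    pairs: pd.DataFrame,
    cluster_counts=(1, 2, 3),
    seed: int = 0,
    n_walkers: int = 32,
    n_steps: int = 1500,
    n_burn: int = 500,
    thin: int = 5,
    method: str = "waic",
    background: bool = True,
):
    """Fit bivariate von Mises cluster models to peak-location pairs and
    compare them.

    ``pairs`` needs columns ``mu_large`` and ``mu_small`` (degrees).  With
    ``method='waic'`` each cluster count is sampled with an affine-invariant
    ensemble sampler initialized at the EM solution, and models are compared
    by WAIC from the pointwise log-likelihood over posterior draws; with
    ``method='bic'`` the deterministic EM fits are compared by BIC.
    ``background`` adds a circular-uniform component to every model, which
    absorbs trials whose smaller component is unidentifiable (e.g., fits of
    effectively unimodal posteriors) so that the cluster count reflects
    genuine structure.

    Returns a dict with the comparison table, the preferred cluster count,
    per-trial assignment probabilities under the preferred model, and
    sampler diagnostics.
    """
    if len(pairs) < 50:
        raise ValueError("need at least 50 peak pairs for cluster comparison")
    x = np.deg2rad(pairs["mu_large"].to_numpy())
    y = np.deg2rad(pairs["mu_small"].to_numpy())

    rows = []
    fits = {}
    rng = np.random.default_rng(seed)
    for n_clusters in cluster_counts:
        em_params, em_ll, em_bic = fit_cluster_model_em(
            x, y, n_clusters, seed=int(rng.integers(2**31)), background=background
        )
        entry = {"n_clusters": n_clusters, "loglik_em": em_ll, "bic": em_bic}
        if method == "waic":
            waic, p_eff, diag = _sample_waic(
                x, y, n_clusters, em_params, rng, n_walkers, n_steps, n_burn, thin,
                background,
            )
            entry.update({"waic": waic, "p_waic": p_eff, **diag})
        rows.append(entry)
        fits[n_clusters] = em_params

    table = pd.DataFrame(rows)
    crit = "waic" if method == "waic" else "bic"
    best_n = int(table.loc[table[crit].idxmin(), "n_clusters"])

    assign = _assignment_probs(fits[best_n], x, y, best_n, background)
    merged = _distinct_clusters(fits[best_n], best_n, background)
    result = {
        "table": table,
        "criterion": crit,
        "preferred_model": best_n,
        # mixture components are exchangeable density pieces; the scientific
        # cluster count is the number of DISTINCT peak-location clusters of
        # the preferred model (components within 90 deg in both coordinates
        # describe one cluster's shape, not separate clusters)
        "preferred_clusters": len(merged),
        "cluster_locations": merged,
        "assignments": assign,
        "params": fits,
    }
    if best_n > 1:
        # fraction of trials in the cluster whose coordinates straddle
        # the true/opposite directions (bimodal-like cluster)
        hard = assign.argmax(axis=0)
        result["cluster_fractions"] = np.bincount(hard, minlength=best_n) / len(hard)
    return result


def _distinct_clusters(params, n_clusters, background=True, min_weight=0.05):
    """Merge mixture components into distinct peak-location clusters.

    Greedy, in decreasing weight order: a component joins an existing
    cluster when both its coordinates are within 90 degrees of the cluster
    center.  Merged clusters below ``min_weight`` total weight are dropped.
    Returns a list of (x_deg, y_deg, weight) tuples.
    """
    n_comp = n_clusters + (1 if background else 0)
    pis = (
        _softmax_weights(params[4 * n_clusters :], n_comp)
        if n_comp > 1
        else np.array([1.0])
    )
    comps = [
        (np.rad2deg(params[4 * c]) % 360.0, np.rad2deg(params[4 * c + 1]) % 360.0, pis[c])
        for c in range(n_clusters)
    ]
    comps.sort(key=lambda t: -t[2])
    clusters = []
    for cx, cy, w in comps:
        for k, (mx, my, mw) in enumerate(clusters):
            if abs(circdist(cx, mx)) <= 90.0 and abs(circdist(cy, my)) <= 90.0:
                # weight-averaged circular center
                nx = circular_mean_pair(mx, cx, mw, w)
                ny = circular_mean_pair(my, cy, mw, w)
                clusters[k] = (nx, ny, mw + w)
                break
        else:
            clusters.append((cx, cy, w))
    return [
        (round(float(cx), 2), round(float(cy), 2), round(float(w), 4))
        for cx, cy, w in clusters
        if w >= min_weight
    ]


def circular_mean_pair(a_deg, b_deg, wa, wb):
    z = wa * np.exp(1j * np.deg2rad(a_deg)) + wb * np.exp(1j * np.deg2rad(b_deg))
    return np.rad2deg(np.angle(z)) % 360.0


def _sample_waic(
    x, y, n_clusters, em_params, rng, n_walkers, n_steps, n_burn, thin, background=True
):
    import emcee

    ndim = len(em_params)

    def log_prob(p):
        lp = _log_prior(p, n_clusters, background)
        if not np.isfinite(lp):
            return -np.inf
        return lp + float(
            np.sum(_cluster_loglik_pointwise(p, x, y, n_clusters, background))
        )

    # project the EM optimum into the prior's support (the background weight
    # can collapse to ~0 in EM, pushing its logit past the prior bound)
    start = np.array(em_params, dtype=float)
    for c in range(n_clusters):
        start[4 * c] = (start[4 * c] + np.pi) % (2 * np.pi) - np.pi
        start[4 * c + 1] = (start[4 * c + 1] + np.pi) % (2 * np.pi) - np.pi
        start[4 * c + 2] = np.clip(start[4 * c + 2], -14.0, np.log(499.0))
        start[4 * c + 3] = np.clip(start[4 * c + 3], -14.0, np.log(499.0))
    start[4 * n_clusters :] = np.clip(start[4 * n_clusters :], -8.0, 8.0)
    p0 = start + 1e-3 * rng.standard_normal((max(n_walkers, 2 * ndim + 2), ndim))
    sampler = emcee.EnsembleSampler(p0.shape[0], ndim, log_prob)
    state = sampler.run_mcmc(
        p0, n_steps, progress=False, skip_initial_state_check=True
    )
    chain = sampler.get_chain(discard=n_burn, thin=thin, flat=True)
    ll = np.stack(
        [_cluster_loglik_pointwise(p, x, y, n_clusters, background) for p in chain]
    )
    waic, p_eff = compute_waic(ll)
    try:
        tau = sampler.get_autocorr_time(quiet=True)
        max_tau = float(np.nanmax(tau))
    except Exception:  # pragma: no cover - emcee raises on short chains
        max_tau = np.nan
    diag = {
        "acceptance_fraction": float(np.mean(sampler.acceptance_fraction)),
        "max_autocorr_time": max_tau,
        "n_draws": int(chain.shape[0]),
    }
    if diag["acceptance_fraction"] < 0.1:
        logger.warning(
            "low sampler acceptance (%.2f) for %d clusters; WAIC may be unreliable",
            diag["acceptance_fraction"],
            n_clusters,
        )
    return waic, p_eff, diag


def _assignment_probs(params, x, y, n_clusters, background=True):
    n_comp = n_clusters + (1 if background else 0)
    if n_comp == 1:
        return np.ones((1, len(x)))
    logcomp = []
    raw = params[4 * n_clusters :]
    pis = _softmax_weights(raw, n_comp)
    for c in range(n_clusters):
        mux, muy, logkx, logky = params[4 * c : 4 * c + 4]
        lc = (
            vm_logpdf(np.rad2deg(x), np.rad2deg(mux), np.exp(logkx))
            + vm_logpdf(np.rad2deg(y), np.rad2deg(muy), np.exp(logky))
            + np.log(max(pis[c], 1e-300))
        )
        logcomp.append(lc)
    if background:
        logcomp.append(
            np.full(len(x), -np.log(4.0 * np.pi**2)) + np.log(max(pis[-1], 1e-300))
        )
    logcomp = np.stack(logcomp)
    return np.exp(logcomp - special.logsumexp(logcomp, axis=0))


# ---------------------------------------------------------------------------
# peak-location vs behavioral-error regression


def peak_error_regression(
    peak_near_true,
    peak_near_opposite,
    true_direction,
    behavioral_errors,
    subject=None,
    n_permutations: int = 1000,
    seed: int = 0,
):
    """Regress behavioral error on sine-transformed peak locations.

    Trials are selected as bimodal when one peak lies within 90 degrees of
    the true direction and the other within 90 degrees of the opposite.
    The first peak is re-centered on the true direction and the second on
    the opposite direction before the transform mu' = sin(pi * mu / 90)
    (mu in degrees), which linearizes the circular relationship.  Slopes
    come from OLS with per-subject intercepts; permutation p-values shuffle
    the errors within subject.
    """
    import statsmodels.api as sm

    peak1 = circdist(np.asarray(peak_near_true), np.asarray(true_direction))
    peak2 = circdist(
        np.asarray(peak_near_opposite), wrap_direction(np.asarray(true_direction) + 180.0)
    )
    err = np.asarray(behavioral_errors, dtype=float)
    sel = (np.abs(peak1) < 90.0) & (np.abs(peak2) < 90.0)
    if sel.sum() < 20:
        raise ValueError(
            f"only {sel.sum()} bimodal-selected trials; need at least 20 for regression"
        )
    p1 = np.sin(np.pi * peak1[sel] / 90.0)
    p2 = np.sin(np.pi * peak2[sel] / 90.0)
    y = err[sel]

    if subject is None:
        subj = np.zeros(sel.sum(), dtype=int)
    else:
        _, subj = np.unique(np.asarray(subject)[sel], return_inverse=True)
    dummies = np.eye(subj.max() + 1)[subj]
    X = np.column_stack([p1, p2, dummies])
    fit = sm.OLS(y, X).fit()
    slope1, slope2 = fit.params[0], fit.params[1]

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, 2))
    for i in range(n_permutations):
        yp = y.copy()
        for s in range(dummies.shape[1]):
            mask = subj == s
            yp[mask] = rng.permutation(yp[mask])
        null[i] = sm.OLS(yp, X).fit().params[:2]
    p1_val = float((np.sum(np.abs(null[:, 0]) >= abs(slope1)) + 1) / (n_permutations + 1))
    p2_val = float((np.sum(np.abs(null[:, 1]) >= abs(slope2)) + 1) / (n_permutations + 1))

    return {
        "slope_first_peak": float(slope1),
        "slope_second_peak": float(slope2),
        "p_first_peak": p1_val,
        "p_second_peak": p2_val,
        "n_selected": int(sel.sum()),
        "null_sd_first": float(null[:, 0].std()),
        "null_sd_second": float(null[:, 1].std()),
    }
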