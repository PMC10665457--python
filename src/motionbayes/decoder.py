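"""Generative-model probabilistic decoder for voxel activity patterns.

The decoder assumes each voxel's response is a weighted sum of K = 8
direction-tuned basis channels plus multivariate normal noise with a
structured covariance.  Training estimates the tuning weights by ordinary
least squares and the noise covariance by shrinkage: a convex blend of the
sample covariance with the structured form
``sigma^2 W W' + (1-rho) diag(tau^2) + rho tau tau'``, with per-voxel
variances themselves shrunk toward their median.  Decoding inverts the
model with Bayes' rule under a flat stimulus prior, yielding a posterior
distribution over direction for every test trial; uncertainty is its
entropy.  Cross-validated decoding leaves one run out at a time and
averages posteriors over bootstrap-resampled refits ("bagging").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .circular import DirectionDistribution, DirectionGrid, default_grid

logger = logging.getLogger(__name__)

N_CHANNELS = 8
TUNING_EXPONENT = 5

__all__ = [
    "TuningModel",
    "NoiseModel",
    "DecodeResult",
    "basis_response",
    "fit_tuning",
    "fit_noise",
    "decode_trial",
    "decode_trials",
    "crossval_decode",
    "select_shrinkage",
]


def basis_response(s_deg, n_channels: int = N_CHANNELS) -> np.ndarray:
    """Channel responses g_k(s) = max(0, cos(s - phi_k))^5.

    Preferred directions phi_k are spread evenly over the circle starting at
    0.  Each channel has one-sided support of width 180 degrees and unit
    peak response.  Returns shape (..., K).
    """
    s = np.deg2rad(np.atleast_1d(np.asarray(s_deg, dtype=float)))
    phi = 2.0 * np.pi * np.arange(n_channels) / n_channels
    g = np.maximum(0.0, np.cos(s[..., None] - phi[None, :])) ** TUNING_EXPONENT
    return g


@dataclass
class TuningModel:
    """Fitted voxel tuning: W maps channel responses to voxel means."""

    W: np.ndarray  # voxels x K
    n_channels: int = N_CHANNELS

    def predict(self, s_deg) -> np.ndarray:
        """Mean voxel pattern(s) f(s) for the given direction(s)."""
        return basis_response(s_deg, self.n_channels) @ self.W.T


@dataclass
class NoiseModel:
    """Fitted structured-shrinkage noise covariance."""

    tau: np.ndarray
    rho: float
    sigma2: float
    lambda_shrink: float
    lambda_var: float
    omega: np.ndarray = field(repr=False)

    def cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.omega)


@dataclass
class DecodeResult:
    """Per-trial decoded posterior and its summaries."""

    trial: int
    posterior: DirectionDistribution
    decoded_direction: float  # circular mean by default
    map_direction: float
    uncertainty_bits: float


def fit_tuning(B_train: np.ndarray, s_train, n_channels: int = N_CHANNELS):
    """Ordinary-least-squares voxel tuning weights.

    Returns (TuningModel, residuals) where residuals are B - G W' with shape
    trials x voxels.  Raises on a rank-deficient design (e.g., all trials
    sharing one direction).
    """
    B = np.asarray(B_train, dtype=float)
    G = basis_response(s_train, n_channels)  # trials x K
    rank = np.linalg.matrix_rank(G)
    if rank < n_channels:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {n_channels}); "
            "training directions do not span the basis"
        )
    coef, *_ = np.linalg.lstsq(G, B, rcond=None)  # K x voxels
    W = coef.T
    residuals = B - G @ coef
    return TuningModel(W=W, n_channels=n_channels), residuals


def _omega_structured(tau, rho, sigma2, W):
    return (
        sigma2 * W @ W.T
        + (1.0 - rho) * np.diag(tau**2)
        + rho * np.outer(tau, tau)
    )


def _gaussian_loglik(residuals, omega):
    """Mean log-likelihood of residual rows under N(0, omega)."""
    n, v = residuals.shape
    try:
        c, low = cho_factor(omega, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = np.sum(residuals * cho_solve((c, low), residuals.T).T) / n
    return -0.5 * (v * np.log(2.0 * np.pi) + logdet + quad)


def fit_noise(
    residuals: np.ndarray,
    W: np.ndarray,
    lambda_shrink: float = 0.2,
    lambda_var: float = 0.5,
    method: str = "ml",
) -> NoiseModel:
    """Fit the structured-shrinkage noise covariance from OLS residuals.

    ``tau'`` is fixed at the residual SDs (shrunk toward their median by
    ``lambda_var``); (rho, sigma2) maximize the Gaussian likelihood of the
    residuals under the structured form (``method='ml'``) or come from
    moment matching of the off-diagonal sample covariance (``method='moment'``).
    The final covariance blends sample and structured forms by
    ``lambda_shrink`` and is jittered to positive definiteness if needed.
    """
    R = np.asarray(residuals, dtype=float)
    n, v = R.shape
    if v < 2:
        raise ValueError("need at least 2 voxels to fit a noise covariance")
    if not (0.0 <= lambda_shrink <= 1.0 and 0.0 <= lambda_var <= 1.0):
        raise ValueError("shrinkage weights must lie in [0, 1]")

    omega_sample = R.T @ R / n
    tau_raw2 = np.diag(omega_sample).copy()
    tau2 = lambda_var * np.median(tau_raw2) + (1.0 - lambda_var) * tau_raw2
    tau = np.sqrt(np.maximum(tau2, 1e-12))

    rho, sigma2 = _fit_rho_sigma2(R, omega_sample, tau, W, method)
    omega0 = _omega_structured(tau, rho, sigma2, W)
    omega = lambda_shrink * omega_sample + (1.0 - lambda_shrink) * omega0

    # guarantee positive definiteness
    jitter = 0.0
    for _ in range(8):
        try:
            np.linalg.cholesky(omega + jitter * np.eye(v))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * np.trace(omega) / v)
    if jitter > 0:
        logger.info("noise covariance jittered by %.3g for positive definiteness", jitter)
        omega = omega + jitter * np.eye(v)

    return NoiseModel(
        tau=tau,
        rho=float(rho),
        sigma2=float(sigma2),
        lambda_shrink=lambda_shrink,
        lambda_var=lambda_var,
        omega=omega,
    )


def _fit_rho_sigma2(R, omega_sample, tau, W, method):
    if method == "moment":
        return _moment_rho_sigma2(omega_sample, tau, W)

    def nll(params):
        rho, log_sigma2 = params
        omega0 = _omega_structured(tau, rho, np.exp(log_sigma2), W)
        return -_gaussian_loglik(R, omega0)

    x0 = np.array([0.05, np.log(0.05 * np.mean(tau**2) / max(np.mean(W**2), 1e-12))])
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, 0.999), (np.log(1e-10), np.log(1e4))],
    )
    if not res.success or not np.isfinite(res.fun):
        logger.info("ML (rho, sigma2) fit failed (%s); falling back to moments", res.message)
        return _moment_rho_sigma2(omega_sample, tau, W)
    return float(res.x[0]), float(np.exp(res.x[1]))


def _moment_rho_sigma2(omega_sample, tau, W):
    """Least-squares fit of the off-diagonal covariance to
    sigma2*(WW')_ij + rho*tau_i*tau_j."""
    v = len(tau)
    iu = np.triu_indices(v, k=1)
    y = omega_sample[iu]
    x1 = (W @ W.T)[iu]
    x2 = np.outer(tau, tau)[iu]
    X = np.column_stack([x1, x2])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    sigma2 = float(np.clip(coef[0], 0.0, None))
    rho = float(np.clip(coef[1], 0.0, 0.999))
    return rho, sigma2


def select_shrinkage(
    B_train,
    s_train,
    run_id,
    grid_points=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
    var_points=(0.0, 0.5, 1.0),
    noise_method: str = "ml",
):
    """Pick (lambda_shrink, lambda_var) by held-out likelihood.

    The training runs are split once: the last run serves as an inner
    validation fold.  For each grid combination the model is fit on the
    remaining runs and scored by the Gaussian log-likelihood of the
    validation residuals; the best pair is returned.
    """
    runs = np.unique(run_id)
    if len(runs) < 2:
        return 0.2, 0.5
    val_run = runs[-1]
    tr = run_id != val_run
    va = ~tr
    tuning, resid_tr = fit_tuning(B_train[tr], np.asarray(s_train)[tr])
    resid_va = B_train[va] - tuning.predict(np.asarray(s_train)[va])

    best, best_pair = -np.inf, (0.2, 0.5)
    for lv in var_points:
        for ls in grid_points:
            noise = fit_noise(resid_tr, tuning.W, ls, lv, method=noise_method)
            score = _gaussian_loglik(resid_va, noise.omega)
            if score > best:
                best, best_pair = score, (ls, lv)
    return best_pair


def decode_trials(
    B_test: np.ndarray,
    tuning: TuningModel,
    noise: NoiseModel,
    grid: DirectionGrid | None = None,
) -> np.ndarray:
    """Posterior masses (trials x grid) for test patterns under the model."""
    grid = grid or default_grid()
    F = tuning.predict(grid.angles)  # grid x voxels
    chol = noise.cholesky()
    phi = solve_triangular(chol, F.T, lower=True)  # voxels x grid
    phinorm = np.sum(phi**2, axis=0)  # grid

    B = np.atleast_2d(B_test)
    beta = solve_triangular(chol, B.T, lower=True)  # voxels x trials
    cross = phi.T @ beta  # grid x trials
    logp = -0.5 * (phinorm[:, None] - 2.0 * cross + np.sum(beta**2, axis=0)[None, :])
    logp -= logp.max(axis=0, keepdims=True)
    # numerical floor avoids exact zeros after exponentiation in log space
    p = np.exp(np.maximum(logp, -745.0))
    p /= p.sum(axis=0, keepdims=True)
    return p.T


def decode_trial(
    b: np.ndarray,
    tuning: TuningModel,
    noise: NoiseModel,
    grid: DirectionGrid | None = None,
    trial: int = 0,
) -> DecodeResult:
    """Decode a single voxel pattern into a posterior over direction."""
    grid = grid or default_grid()
    b = np.asarray(b, dtype=float)
    if b.shape != (tuning.W.shape[0],):
        raise ValueError(
            f"pattern has {b.shape} entries, model expects {tuning.W.shape[0]} voxels"
        )
    mass = decode_trials(b[None, :], tuning, noise, grid)[0]
    post = DirectionDistribution(grid, mass)
    return DecodeResult(
        trial=trial,
        posterior=post,
        decoded_direction=post.mean_direction(),
        map_direction=post.mode(),
        uncertainty_bits=post.entropy_bits(),
    )


def crossval_decode(
    dataset,
    n_boot: int = 50,
    seed: int = 0,
    grid: DirectionGrid | None = None,
    noise_method: str = "ml",
    select_lambdas: bool = True,
    return_posteriors: bool = False,
):
    """Leave-one-run-out bagged decoding of a voxel dataset.

    For each held-out run, the training trials are resampled with
    replacement ``n_boot`` times; tuning and noise are refit per resample
    and the per-trial posteriors are averaged across resamples.  Shrinkage
    weights are selected once per fold on an inner run split and reused
    across that fold's bootstraps.  A bootstrap draw whose design does not
    span the channel basis is redrawn.

    Returns a DataFrame (trial, run, s_true, s_decoded, s_map, entropy_bits)
    and, if requested, the full posterior array (trials x grid).
    """
    grid = grid or default_grid()
    B, s, run_id = dataset.B, dataset.s, dataset.run_id
    runs = np.unique(run_id)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for leave-one-run-out decoding")
    rng = np.random.default_rng(seed)

    n_trials = len(s)
    posteriors = np.zeros((n_trials, grid.n))
    for run in runs:
        test = run_id == run
        train = ~test
        B_tr, s_tr = B[train], s[train]
        if select_lambdas:
            lam, lam_var = select_shrinkage(
                B_tr, s_tr, run_id[train], noise_method=noise_method
            )
        else:
            lam, lam_var = 0.2, 0.5
        n_tr = len(s_tr)
        acc = np.zeros((test.sum(), grid.n))
        for _ in range(n_boot):
            for attempt in range(20):
                idx = rng.integers(0, n_tr, size=n_tr) if n_boot > 1 else np.arange(n_tr)
                try:
                    tuning, resid = fit_tuning(B_tr[idx], s_tr[idx])
                    break
                except ValueError:
                    logger.info("degenerate bootstrap design; redrawing")
            else:
                raise RuntimeError("could not draw a non-degenerate bootstrap sample")
            noise = fit_noise(resid, tuning.W, lam, lam_var, method=noise_method)
            acc += decode_trials(B[test], tuning, noise, grid)
        posteriors[test] = acc / n_boot

    z = posteriors @ np.exp(1j * grid.radians)
    decoded = np.mod(np.rad2deg(np.angle(z)), 360.0)
    map_dir = grid.angles[np.argmax(posteriors, axis=1)]
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(posteriors > 0, np.log2(np.where(posteriors > 0, posteriors, 1.0)), 0.0)
    entropy = -np.sum(posteriors * logs, axis=1)

    table = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "run": run_id,
            "s_true": s,
            "s_decoded": decoded,
            "s_map": map_dir,
            "entropy_bits": entropy,
        }
    )
    if return_posteriors:
        return table, posteriors
    return table
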