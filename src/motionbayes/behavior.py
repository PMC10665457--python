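"""Behavioral preprocessing and response-distribution model comparison.

Covers cardinal-bias removal (per-bin 4th-degree polynomial fits of error
against direction, with attraction and repulsion variants selected by
likelihood), heteroscedastic outlier flagging at +/- 3 predicted SDs,
oblique-effect summaries, the uncertainty-variability regression, and the
unimodal-vs-bimodal maximum-likelihood comparison of error distributions
with peaks fixed at the true and opposite directions.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import optimize, special

from .circular import circdist, vm_logpdf, wrap_direction

KAPPA_BOUNDS = (0.001, 100.0)

__all__ = [
    "BiasModel",
    "ResponseModelFit",
    "remove_cardinal_bias",
    "flag_outliers",
    "oblique_distance",
    "uncertainty_variability_regression",
    "fit_response_models",
]

CARDINALS = np.array([0.0, 90.0, 180.0, 270.0])
OBLIQUES = np.array([45.0, 135.0, 225.0, 315.0])


@dataclass
class BiasModel:
    """Fitted cardinal-bias model: 4 x 90-degree bins, polynomial mean and
    log-linear SD per bin."""

    kind: str  # "attraction" (bins centered at cardinals) or "repulsion"
    coef_mean: dict  # bin center -> Legendre coefficients (degree 4)
    coef_sd: dict  # bin center -> (intercept, slope) for log SD vs |distance|
    loglik: float

    @property
    def bin_centers(self):
        return CARDINALS if self.kind == "attraction" else OBLIQUES

    def predict(self, s_deg):
        """Predicted mean error and SD at the given directions."""
        s = np.asarray(s_deg, dtype=float)
        mean = np.empty_like(s)
        sd = np.empty_like(s)
        centers = self.bin_centers
        for c in centers:
            d = circdist(s, c)
            mask = np.abs(d) <= 45.0
            if c == centers[0]:
                # make bin edges unambiguous: first bin takes its lower edge
                pass
            x = d[mask] / 45.0
            mean[mask] = legendre.legval(x, self.coef_mean[c])
            b0, b1 = self.coef_sd[c]
            sd[mask] = np.exp(b0 + b1 * np.abs(x))
        return mean, sd


def _fit_bias_variant(s, err, centers):
    """Fit the per-bin polynomial mean + log-linear SD model; Gaussian
    log-likelihood of the whole dataset is the selection score."""
    coef_mean, coef_sd = {}, {}
    loglik = 0.0
    for c in centers:
        d = circdist(s, c)
        mask = np.abs(d) <= 45.0
        if mask.sum() < 10:
            raise ValueError(
                f"bin centered at {c} deg has only {int(mask.sum())} trials (need >= 10)"
            )
        x = d[mask] / 45.0
        y = err[mask]
        cm = legendre.legfit(x, y, 4)
        resid = y - legendre.legval(x, cm)
        # two-stage heteroscedastic fit: log SD linear in |distance|
        b = _fit_log_sd(np.abs(x), resid)
        sd = np.exp(b[0] + b[1] * np.abs(x))
        loglik += float(
            np.sum(-0.5 * np.log(2 * np.pi * sd**2) - 0.5 * (resid / sd) ** 2)
        )
        coef_mean[c], coef_sd[c] = cm, b
    return coef_mean, coef_sd, loglik


def _fit_log_sd(absx, resid):
    """ML fit of log SD = b0 + b1*|x| for centered Gaussian residuals."""

    def nll(b):
        logsd = b[0] + b[1] * absx
        return float(np.sum(logsd + 0.5 * resid**2 * np.exp(-2.0 * logsd)))

    s0 = np.log(max(np.std(resid), 1e-6))
    res = optimize.minimize(nll, [s0, 0.0], method="Nelder-Mead")
    return res.x


def remove_cardinal_bias(trials: pd.DataFrame):
    """Remove cardinal biases from behavioral errors.

    ``trials`` needs columns ``s_true_deg`` and ``response_deg``.  Both an
    attraction variant (bins centered on the cardinals, where attractive
    biases vanish) and a repulsion variant (bins centered on the obliques)
    are fitted; the better-likelihood model is selected.  Returns
    (residual_errors, predicted_sd, BiasModel).
    """
    s = trials["s_true_deg"].to_numpy(dtype=float)
    err = circdist(trials["response_deg"].to_numpy(dtype=float), s)

    fits = {}
    for kind, centers in (("attraction", CARDINALS), ("repulsion", OBLIQUES)):
        cm, csd, ll = _fit_bias_variant(s, err, centers)
        fits[kind] = BiasModel(kind=kind, coef_mean=cm, coef_sd=csd, loglik=ll)
    best = max(fits.values(), key=lambda m: m.loglik)
    mean, sd = best.predict(s)
    return err - mean, sd, best


def flag_outliers(residuals, predicted_sd) -> np.ndarray:
    """Boolean mask of residuals beyond +/- 3 predicted SDs."""
    residuals = np.asarray(residuals, dtype=float)
    predicted_sd = np.asarray(predicted_sd, dtype=float)
    return np.abs(residuals) > 3.0 * predicted_sd


def oblique_distance(s_deg):
    """Distance (degrees, in [0, 45]) to the nearest cardinal direction."""
    s = np.mod(np.asarray(s_deg, dtype=float), 90.0)
    return np.minimum(s, 90.0 - s)


def uncertainty_variability_regression(
    trials: pd.DataFrame,
    entropy_col: str = "entropy_bits",
    n_permutations: int = 1000,
    seed: int = 0,
    log_transform: bool = False,
):
    """Slope of squared behavioral error on within-subject-demeaned decoded
    uncertainty, controlling for the oblique effect.

    ``trials`` needs ``s_true_deg``, ``response_deg``, ``entropy_bits`` and
    optionally ``subject``.  Permutation inference shuffles the entropy
    within subject.
    """
    import statsmodels.api as sm

    s = trials["s_true_deg"].to_numpy(dtype=float)
    err = circdist(trials["response_deg"].to_numpy(dtype=float), s)
    y = err**2
    if log_transform:
        y = np.log(y + 1e-6)
    subj = (
        trials["subject"].to_numpy()
        if "subject" in trials
        else np.zeros(len(trials), dtype=int)
    )
    _, subj_idx = np.unique(subj, return_inverse=True)
    ent = trials[entropy_col].to_numpy(dtype=float).copy()
    for k in range(subj_idx.max() + 1):
        m = subj_idx == k
        ent[m] -= ent[m].mean()
    obl = oblique_distance(s)
    dummies = np.eye(subj_idx.max() + 1)[subj_idx]
    X = np.column_stack([ent, obl, dummies])
    slope = float(sm.OLS(y, X).fit().params[0])

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        ep = ent.copy()
        for k in range(subj_idx.max() + 1):
            m = subj_idx == k
            ep[m] = rng.permutation(ep[m])
        null[i] = sm.OLS(y, np.column_stack([ep, obl, dummies])).fit().params[0]
    p = float((np.sum(np.abs(null) >= abs(slope)) + 1) / (n_permutations + 1))
    return {"slope": slope, "p": p, "null_sd": float(null.std())}


# ---------------------------------------------------------------------------
# unimodal vs bimodal response-distribution comparison


@dataclass
class ResponseModelFit:
    """MLE fit of a response-error distribution model."""

    kind: str  # "unimodal" | "bimodal"
    lapse: float
    alpha: float  # weight of the true-direction peak (1 for unimodal)
    kappa1: float
    kappa2: float  # ignored for unimodal
    loglik: float
    bic: float
    n: int


def _model_loglik(errors_rad_deg, lapse, alpha, kappa1, kappa2, bimodal):
    f1 = np.exp(vm_logpdf(errors_rad_deg, 0.0, kappa1))
    if bimodal:
        f2 = np.exp(vm_logpdf(errors_rad_deg, 180.0, kappa2))
        vm_part = alpha * f1 + (1.0 - alpha) * f2
    else:
        vm_part = f1
    dens = (1.0 - lapse) * vm_part + lapse / (2.0 * np.pi)
    # density per radian; errors are angles, likelihood in radian measure
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def _fit_one_model(errors, bimodal, seed):
    rng = np.random.default_rng(seed)
    n = len(errors)

    if bimodal:
        bounds = [(0.0, 0.9), (1e-5, 1 - 1e-5), KAPPA_BOUNDS, KAPPA_BOUNDS]

        def nll(p):
            return -_model_loglik(errors, p[0], p[1], p[2], p[3], True)

        starts = [[0.1, 0.7, 8.0, 8.0], [0.3, 0.5, 3.0, 3.0]]
        starts += [
            [rng.uniform(0, 0.6), rng.uniform(0.2, 0.8),
             np.exp(rng.uniform(np.log(0.5), np.log(50))),
             np.exp(rng.uniform(np.log(0.5), np.log(50)))]
            for _ in range(6)
        ]
        k_free = 4
    else:
        bounds = [(0.0, 0.9), KAPPA_BOUNDS]

        def nll(p):
            return -_model_loglik(errors, p[0], 1.0, p[1], p[1], False)

        starts = [[0.1, 8.0], [0.3, 3.0]]
        starts += [
            [rng.uniform(0, 0.6), np.exp(rng.uniform(np.log(0.5), np.log(50)))]
            for _ in range(6)
        ]
        k_free = 2

    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    ll = -float(best.fun)
    bic = k_free * np.log(n) - 2.0 * ll
    if bimodal:
        lapse, alpha, k1, k2 = best.x
    else:
        lapse, k1 = best.x
        alpha, k2 = 1.0, np.nan
    return ResponseModelFit(
        kind="bimodal" if bimodal else "unimodal",
        lapse=float(lapse),
        alpha=float(alpha),
        kappa1=float(k1),
        kappa2=float(k2),
        loglik=ll,
        bic=float(bic),
        n=n,
    )


def fit_response_models(errors_deg, seed: int = 0):
    """Fit unimodal and bimodal error-distribution models by MLE.

    ``errors_deg`` are response errors relative to the true direction.  The
    unimodal model is a von Mises at 0 plus a uniform lapse; the bimodal
    model adds a second von Mises fixed at 180 degrees.  Returns
    (unimodal fit, bimodal fit, delta_bic = BIC_unimodal - BIC_bimodal);
    positive delta favors the bimodal model.
    """
    errors = circdist(np.asarray(errors_deg, dtype=float), 0.0)
    if len(errors) < 30:
        warnings.warn(
            f"only {len(errors)} errors; model comparison may be unstable", stacklevel=2
        )
    uni = _fit_one_model(errors, bimodal=False, seed=seed)
    bim = _fit_one_model(errors, bimodal=True, seed=seed + 1)
    return uni, bim, uni.bic - bim.bic
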