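"""Synthetic-data generators for voxel patterns and behavioral trials.

Voxel datasets are drawn from the decoder's own generative model: each
voxel's mean response is a weighted sum of K = 8 direction-tuned basis
channels, trial-to-trial noise is multivariate normal with the structured
covariance sigma^2 W W' + (1-rho) diag(tau^2) + rho tau tau'.  An optional
180-degree-periodic "orientation code" component mixes in voxel means that
respond equally to opposite directions, emulating a population that also
carries motion-streak signals.

Behavioral datasets draw responses from the Bayesian observer with three
real-data features layered on top: an oblique effect (precision falls with
distance from the cardinal axes), additive cardinal biases, and a uniform
lapse component for random guesses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import circular_mean, wrap_direction, wrap_orientation
from .observer import (
    Measurement,
    ObserverParams,
    combined_posterior_arrays,
    map_readout_arrays,
)

__all__ = [
    "VoxelTruth",
    "SyntheticVoxelDataset",
    "BehavioralDataset",
    "make_design",
    "make_truth",
    "sample_voxel_patterns",
    "make_behavioral_dataset",
]


@dataclass
class VoxelTruth:
    """Ground-truth generating parameters of a synthetic voxel dataset."""

    W: np.ndarray  # voxels x K tuning weights
    tau: np.ndarray  # per-voxel noise scale
    rho: float  # globally shared noise correlation
    sigma2: float  # tuning-shared variance scale
    orientation_mix: float  # weight of the 180-deg-periodic mean component

    def covariance(self) -> np.ndarray:
        """The generating noise covariance (positive definite by construction)."""
        omega = (
            self.sigma2 * self.W @ self.W.T
            + (1.0 - self.rho) * np.diag(self.tau**2)
            + self.rho * np.outer(self.tau, self.tau)
        )
        return omega

    def to_json(self, path):
        payload = {
            "W": self.W.tolist(),
            "tau": self.tau.tolist(),
            "rho": self.rho,
            "sigma2": self.sigma2,
            "orientation_mix": self.orientation_mix,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            np.asarray(d["W"]),
            np.asarray(d["tau"]),
            d["rho"],
            d["sigma2"],
            d["orientation_mix"],
        )


@dataclass
class SyntheticVoxelDataset:
    """Trial x voxel responses with run and stimulus labels plus ground truth."""

    B: np.ndarray = field(repr=False)  # trials x voxels, z-scored within run
    s: np.ndarray = field(repr=False)  # per-trial stimulus direction (deg)
    run_id: np.ndarray = field(repr=False)
    truth: VoxelTruth | None = None

    @property
    def n_trials(self) -> int:
        return self.B.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.B.shape[1]

    def save(self, directory):
        import os

        os.makedirs(directory, exist_ok=True)
        pd.DataFrame({"s_deg": self.s, "run": self.run_id}).to_csv(
            os.path.join(directory, "trials.csv"), index=False
        )
        np.save(os.path.join(directory, "B.npy"), self.B)
        if self.truth is not None:
            self.truth.to_json(os.path.join(directory, "truth.json"))

    @classmethod
    def load(cls, directory):
        import os

        df = pd.read_csv(os.path.join(directory, "trials.csv"))
        B = np.load(os.path.join(directory, "B.npy"))
        truth_path = os.path.join(directory, "truth.json")
        truth = VoxelTruth.from_json(truth_path) if os.path.exists(truth_path) else None
        return cls(B, df["s_deg"].to_numpy(), df["run"].to_numpy(), truth)


@dataclass
class BehavioralDataset:
    """Per-trial stimulus/response table plus generator metadata."""

    trials: pd.DataFrame  # columns: subject, run, s_true_deg, response_deg
    observer: ObserverParams
    oblique_amp: float
    bias_amp: float
    lapse: float


def make_design(n_runs: int, trials_per_run: int = 18, seed: int = 0) -> pd.DataFrame:
    """Stimulus/run table: per run, evenly spaced directions with a random
    offset, presented in random order."""
    rng = np.random.default_rng(seed)
    spacing = 360.0 / trials_per_run
    rows = []
    for run in range(n_runs):
        offset = rng.uniform(0.0, spacing)
        dirs = wrap_direction(offset + spacing * np.arange(trials_per_run))
        rng.shuffle(dirs)
        for s in dirs:
            rows.append({"run": run, "s_deg": float(s)})
    return pd.DataFrame(rows)


def make_truth(
    n_voxels: int = 200,
    n_channels: int = 8,
    orientation_mix: float = 0.0,
    signal_amp: float = 1.0,
    noise_scale: float = 0.3,
    rho: float = 0.05,
    sigma2: float = 0.02,
    seed: int = 0,
) -> VoxelTruth:
    """Random ground-truth tuning and noise parameters.

    Each voxel is a nonnegative random mixture over the K basis channels
    (gamma-distributed weights, so tuning heterogeneity across voxels).
    ``orientation_mix`` in [0, 1] blends in a 180-degree-periodic component
    built from equal-weight pairs of opposite-preferring channels.
    """
    if not 0.0 <= orientation_mix <= 1.0:
        raise ValueError("orientation_mix must lie in [0, 1]")
    if n_channels % 2:
        raise ValueError("n_channels must be even to form opposite-preferring pairs")
    rng = np.random.default_rng(seed)
    W_dir = rng.gamma(shape=1.5, scale=1.0, size=(n_voxels, n_channels))
    W_dir *= signal_amp / W_dir.sum(axis=1, keepdims=True)
    half = n_channels // 2
    # equal-weight pairs of channels 180 degrees apart -> 180-deg-periodic mean
    W_sym = 0.5 * (W_dir + np.roll(W_dir, half, axis=1))
    W = (1.0 - orientation_mix) * W_dir + orientation_mix * W_sym
    tau = noise_scale * rng.uniform(0.6, 1.4, size=n_voxels)
    return VoxelTruth(W=W, tau=tau, rho=rho, sigma2=sigma2, orientation_mix=orientation_mix)


def sample_voxel_patterns(
    design: pd.DataFrame,
    truth: VoxelTruth,
    seed: int = 0,
    zscore: bool = True,
) -> SyntheticVoxelDataset:
    """Draw trial x voxel responses B = W g(s) + eps, eps ~ N(0, Omega).

    Responses are z-scored per voxel within each run (mirroring run-wise
    normalization of real data, applied at the trial-pattern level since no
    time dimension is simulated).
    """
    from .decoder import basis_response

    rng = np.random.default_rng(seed)
    omega = truth.covariance()
    try:
        chol = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "ground-truth covariance is not positive definite "
            f"(min eigenvalue {np.linalg.eigvalsh(omega).min():.3g})"
        ) from exc

    s = design["s_deg"].to_numpy()
    run_id = design["run"].to_numpy()
    G = basis_response(s, n_channels=truth.W.shape[1])  # trials x K
    mean = G @ truth.W.T
    noise = rng.standard_normal((len(s), truth.W.shape[0])) @ chol.T
    B = mean + noise
    if zscore:
        for run in np.unique(run_id):
            mask = run_id == run
            mu = B[mask].mean(axis=0)
            sd = B[mask].std(axis=0, ddof=0)
            B[mask] = (B[mask] - mu) / np.where(sd > 0, sd, 1.0)
    return SyntheticVoxelDataset(B=B, s=s, run_id=run_id, truth=truth)


def make_behavioral_dataset(
    design: pd.DataFrame,
    observer: ObserverParams,
    oblique_amp: float = 0.0,
    bias_amp: float = 0.0,
    lapse: float = 0.0,
    subject: str = "sim",
    seed: int = 0,
) -> BehavioralDataset:
    """Observer-model responses with oblique-effect noise modulation,
    cardinal biases, and a uniform lapse component.

    ``oblique_amp`` scales the cue noise SDs by (1 + amp*sin(2*s)^2), so
    variability peaks at the oblique directions.  ``bias_amp`` (degrees)
    adds an attractive cardinal bias amp*sin(4*s)/ ... to the mean response.
    ``lapse`` is the probability of a uniform random response.
    """
    from .circular import sigma_to_kappa, kappa_to_sigma

    if not 0.0 <= lapse <= 1.0:
        raise ValueError("lapse must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    s = design["s_deg"].to_numpy()
    n = len(s)

    # oblique modulation of both cue noise SDs
    modulation = 1.0 + oblique_amp * np.sin(np.deg2rad(2.0 * s)) ** 2
    sigma_v = kappa_to_sigma(observer.kappa_v) * modulation
    sigma_o = kappa_to_sigma(observer.kappa_o) * modulation
    kappa_v = np.array([sigma_to_kappa(sv) for sv in sigma_v])
    kappa_o = np.array([sigma_to_kappa(so) for so in sigma_o])

    x_v = wrap_direction(s + np.rad2deg(rng.vonmises(0.0, np.minimum(kappa_v, 1e7))))
    x_o = wrap_orientation(s + np.rad2deg(rng.vonmises(0.0, np.minimum(kappa_o, 1e7))))
    mix = combined_posterior_arrays(x_v, x_o, kappa_v, kappa_o)
    resp = map_readout_arrays(*mix)

    # attractive cardinal bias: responses pulled toward the nearest cardinal
    resp = wrap_direction(resp - bias_amp * np.sin(np.deg2rad(4.0 * resp)))

    lapse_mask = rng.uniform(size=n) < lapse
    resp[lapse_mask] = rng.uniform(0.0, 360.0, size=lapse_mask.sum())

    trials = pd.DataFrame(
        {
            "subject": subject,
            "run": design["run"].to_numpy(),
            "s_true_deg": s,
            "response_deg": resp,
        }
    )
    return BehavioralDataset(
        trials=trials,
        observer=observer,
        oblique_amp=oblique_amp,
        bias_amp=bias_amp,
        lapse=lapse,
    )
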