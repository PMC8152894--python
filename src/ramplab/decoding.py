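"""Naive-Bayes temporal decoding of ensemble firing rates.

Each trial is summarized as a units x bins matrix of Gaussian kernel-density
firing-rate estimates (bandwidth 1.2 s, 0.1 s bins) over a padded window
from 6 s before the cue to 6 s after interval end; padding prevents edge
effects from biasing the classifier.  Training estimates a per-unit,
per-bin expected rate (Poisson likelihood by default, a rate-space Gaussian
KDE alternatively); decoding a held-out trial assigns each observed bin the
maximum-a-posteriori time bin under a uniform prior, naively multiplying
likelihoods across units.  Performance is the squared Pearson correlation
(R^2) of observed versus predicted time pooled over in-interval bins only,
under leave-one-out cross-validation.  The chance control circularly shifts
each unit's single-trial rate vector by an independent random offset, which
preserves rate marginals while destroying time locking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import InsufficientDataError
from .model import INTERVAL_DURATIONS, TrialRecord, UnitRecord, trial_relative_spikes
from .ramping import kde_rate


@dataclass
class DecoderConfig:
    bin_width: float = 0.1
    kde_bandwidth: float = 1.2  # seconds of temporal smoothing
    pad: float = 6.0  # seconds before the cue and after interval end
    likelihood: str = "poisson"  # or "gaussian_kde"
    r2_method: str = "pearson"  # or "ss" (1 - SS_res/SS_tot)
    rate_floor: float = 1e-3  # expected spikes/bin floor for the Poisson model

    def validate(self) -> None:
        if self.pad < 0:
            raise ValueError("pad must be nonnegative")
        if self.bin_width <= 0 or self.kde_bandwidth <= 0:
            raise ValueError("bin_width and kde_bandwidth must be positive")
        if self.likelihood not in ("poisson", "gaussian_kde"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.r2_method not in ("pearson", "ss"):
            raise ValueError(f"unknown r2_method {self.r2_method!r}")


def padded_bin_centers(T: float, config: DecoderConfig) -> np.ndarray:
    """Bin centers over [-pad, T + pad]."""
    n = int(round((T + 2 * config.pad) / config.bin_width))
    return -config.pad + (np.arange(n) + 0.5) * config.bin_width


def rate_features(unit: UnitRecord, trial: TrialRecord, config: DecoderConfig) -> np.ndarray:
    """Single-trial KDE firing-rate vector (Hz) over the padded window."""
    T = trial.interval_duration
    centers = padded_bin_centers(T, config)
    margin = 4.0 * config.kde_bandwidth
    spikes = trial_relative_spikes(unit, trial, (-config.pad - margin, T + config.pad + margin))
    return kde_rate(spikes, centers, config.kde_bandwidth)


def ensemble_features(
    units: list[UnitRecord], trials: list[TrialRecord], config: DecoderConfig
) -> np.ndarray:
    """Feature tensor (n_trials, n_units, n_bins) for one interval type."""
    types = {t.interval_type for t in trials}
    if len(types) != 1:
        raise ValueError(f"trials mix interval types {sorted(types)}")
    T = INTERVAL_DURATIONS[types.pop()]
    n_bins = padded_bin_centers(T, config).size
    F = np.empty((len(trials), len(units), n_bins))
    for i, t in enumerate(trials):
        for j, u in enumerate(units):
            F[i, j] = rate_features(u, t, config)
    return F


@dataclass
class DecoderModel:
    """Per-bin likelihood model trained on ensemble features."""

    config: DecoderConfig
    bin_centers: np.ndarray
    mean_rates: np.ndarray | None = None  # (units, bins); poisson mode
    train_rates: np.ndarray | None = None  # (trials, units, bins); kde mode
    kde_bandwidths: np.ndarray | None = None  # (units,); kde mode


def train_decoder(
    features: np.ndarray, bin_centers: np.ndarray, config: DecoderConfig | None = None
) -> DecoderModel:
    """Fit the per-(unit, bin) likelihood from training-trial features."""
    config = config or DecoderConfig()
    config.validate()
    F = np.asarray(features, dtype=float)
    if F.ndim != 3 or F.shape[0] < 2:
        raise InsufficientDataError("training needs a (>=2 trials, units, bins) feature tensor")
    if config.likelihood == "poisson":
        return DecoderModel(config=config, bin_centers=bin_centers, mean_rates=F.mean(axis=0))
    sd = F.reshape(F.shape[0], F.shape[1], -1).std(axis=(0, 2), ddof=1)
    h = np.maximum(1.06 * sd * F.shape[0] ** (-0.2), 1e-3)
    return DecoderModel(config=config, bin_centers=bin_centers, train_rates=F, kde_bandwidths=h)


def _log_likelihood_matrix(model: DecoderModel, X: np.ndarray) -> np.ndarray:
    """Log p(observed | candidate bin), shape (n_candidate_bins, n_observed_bins).

    X is the held-out trial's (units, bins) rate matrix.
    """
    cfg = model.config
    if cfg.likelihood == "poisson":
        counts = X * cfg.bin_width  # pseudo-counts from smoothed rates
        mu = np.maximum(model.mean_rates * cfg.bin_width, cfg.rate_floor)
        return np.log(mu).T @ counts - mu.sum(axis=0)[:, None]
    R = model.train_rates  # (trials, units, bins)
    h = model.kde_bandwidths[None, :, None, None]
    # diff: (trials, units, cand, obs)
    diff = R[:, :, :, None] - X[None, :, None, :]
    log_k = -0.5 * (diff / h) ** 2 - np.log(h * np.sqrt(2.0 * np.pi))
    log_dens = logsumexp(log_k, axis=0) - np.log(R.shape[0])  # (units, cand, obs)
    return log_dens.sum(axis=0)


def decode_trial(model: DecoderModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MAP time per observed bin under a uniform prior; ties take the earliest bin.

    Returns (predicted times, posterior matrix with candidate bins on axis 0
    summing to 1 per observed bin).
    """
    log_lik = _log_likelihood_matrix(model, np.asarray(X, dtype=float))
    log_post = log_lik - logsumexp(log_lik, axis=0, keepdims=True)
    posterior = np.exp(log_post)
    best = log_post.max(axis=0)
    # earliest-bin tie break with a tiny relative tolerance
    tol = 1e-12 * np.maximum(1.0, np.abs(best))
    pred_idx = np.array(
        [int(np.flatnonzero(log_post[:, j] >= best[j] - tol[j])[0]) for j in range(log_post.shape[1])]
    )
    return model.bin_centers[pred_idx], posterior


@dataclass
class DecodeResult:
    """Observed/predicted time pairs over in-interval bins, pooled across trials."""

    pairs: pd.DataFrame  # columns: trial_id, observed, predicted
    r_squared: float
    shuffled: bool
    interval_type: str = ""
    extra: dict = field(default_factory=dict)


def r_squared_of_pairs(observed: np.ndarray, predicted: np.ndarray, method: str = "pearson") -> float:
    """Decoder score; degenerate (constant) predictions score 0."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    tol_p = 1e-12 * max(1.0, float(np.max(np.abs(predicted))) if predicted.size else 1.0)
    tol_o = 1e-12 * max(1.0, float(np.max(np.abs(observed))) if observed.size else 1.0)
    if observed.size < 2 or np.std(predicted) <= tol_p or np.std(observed) <= tol_o:
        return 0.0
    if method == "pearson":
        return float(np.corrcoef(observed, predicted)[0, 1] ** 2)
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    return max(0.0, 1.0 - ss_res / ss_tot)


def circular_shuffle(features: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independently circular-shift each (trial, unit) rate vector in time."""
    F = np.array(features, copy=True)
    n_trials, n_units, n_bins = F.shape
    shifts = rng.integers(0, n_bins, size=(n_trials, n_units))
    for i in range(n_trials):
        for j in range(n_units):
            F[i, j] = np.roll(F[i, j], shifts[i, j])
    return F


def loocv_r2(
    ensemble: list[UnitRecord] | np.ndarray,
    trials: list[TrialRecord] | None = None,
    config: DecoderConfig | None = None,
    shuffle: bool = False,
    seed: int | None = None,
    interval_type: str | None = None,
    trial_ids: list | None = None,
) -> DecodeResult:
    """Leave-one-out decoding R^2 for one ensemble on one interval type.

    ``ensemble`` may be a list of units (features are computed from spikes
    and ``trials``) or a precomputed (trials, units, bins) feature tensor,
    in which case ``interval_type`` names the interval.
    """
    config = config or DecoderConfig()
    config.validate()
    if isinstance(ensemble, np.ndarray):
        F = np.asarray(ensemble, dtype=float)
        if interval_type is None:
            raise ValueError("interval_type is required with precomputed features")
        itype = interval_type
    else:
        if trials is None:
            raise ValueError("trials are required when passing unit records")
        itype = trials[0].interval_type
        F = ensemble_features(ensemble, trials, config)
    if F.shape[0] < 3:
        raise InsufficientDataError("leave-one-out decoding needs at least 3 trials")
    T = INTERVAL_DURATIONS[itype]
    centers = padded_bin_centers(T, config)
    if trial_ids is None:
        trial_ids = (
            [t.trial_id for t in trials] if trials is not None else list(range(F.shape[0]))
        )

    if shuffle:
        rng = np.random.default_rng(seed)
        F = circular_shuffle(F, rng)

    in_interval = (centers >= 0.0) & (centers <= T)
    obs_times = centers[in_interval]
    rows = []
    n_trials = F.shape[0]
    total = F.sum(axis=0)
    for i in range(n_trials):
        if config.likelihood == "poisson":
            model = DecoderModel(
                config=config,
                bin_centers=centers,
                mean_rates=(total - F[i]) / (n_trials - 1),
            )
        else:
            model = train_decoder(np.delete(F, i, axis=0), centers, config)
        predicted, _ = decode_trial(model, F[i][:, in_interval])
        rows.append(
            pd.DataFrame(
                {"trial_id": trial_ids[i], "observed": obs_times, "predicted": predicted}
            )
        )
    pairs = pd.concat(rows, ignore_index=True)
    r2 = r_squared_of_pairs(pairs["observed"], pairs["predicted"], config.r2_method)
    return DecodeResult(pairs=pairs, r_squared=r2, shuffled=shuffle, interval_type=itype)
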