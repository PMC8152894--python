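"""Time-related ramping: PETHs, ensemble PCA, slope fits, modulation screens.

A unit's peri-event time histogram (PETH) is a trial-averaged Gaussian
kernel-density rate estimate over the interval (FI3 bandwidth 0.2 s, FI12
bandwidth 0.5 s), z-scored per unit.  Ensemble PCA treats units as
observations and time bins as variables; the first principal component
carries the monotonic ramp, and a unit's ramping strength is the absolute
value of its PC1 score (units can ramp up or down, so the sign is ignored).
Per-unit ramp slopes come from an identity-link regression of the
trial-averaged binned firing rate on time, and interval modulation from a
Poisson regression of per-trial spike counts on interval type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA

from .exceptions import DegenerateDataError, InsufficientDataError
from .model import INTERVAL_DURATIONS, PethMatrix, TrialRecord, UnitRecord, trial_relative_spikes

#: Default PETH kernel bandwidths (seconds) per interval type.
DEFAULT_BANDWIDTHS = {"FI3": 0.2, "FI12": 0.5}

#: Kernel support truncation, in bandwidths.
KERNEL_TRUNCATION = 4.0

BIN_WIDTH = 0.1


def bin_centers_for(T: float, bin_width: float = BIN_WIDTH) -> np.ndarray:
    """Bin centers 0.05, 0.15, ... covering [0, T]."""
    n = int(round(T / bin_width))
    return (np.arange(n) + 0.5) * bin_width


def kde_rate(
    spikes: np.ndarray, eval_times: np.ndarray, bandwidth: float, truncate: float = KERNEL_TRUNCATION
) -> np.ndarray:
    """Gaussian kernel rate estimate (Hz): sum of unit-mass kernels at spikes.

    Kernels are truncated at ``truncate`` bandwidths and the tails are not
    renormalized at the window edges.
    """
    spikes = np.asarray(spikes, dtype=float)
    out = np.zeros(eval_times.size)
    if spikes.size == 0:
        return out
    norm = 1.0 / (bandwidth * np.sqrt(2.0 * np.pi))
    for s in spikes:
        d = eval_times - s
        near = np.abs(d) <= truncate * bandwidth
        if np.any(near):
            out[near] += norm * np.exp(-0.5 * (d[near] / bandwidth) ** 2)
    return out


def compute_peth(
    unit: UnitRecord,
    trials: list[TrialRecord],
    bandwidth: float | None = None,
    bin_width: float = BIN_WIDTH,
) -> PethMatrix:
    """Trial-averaged KDE firing rate for one unit over [0, T] (one-row matrix).

    All trials must share one interval type; the bandwidth defaults to the
    type-specific value (0.2 s for FI3, 0.5 s for FI12).
    """
    if not trials:
        raise ValueError("compute_peth requires at least one trial")
    types = {t.interval_type for t in trials}
    if len(types) != 1:
        raise ValueError(f"trials mix interval types {sorted(types)}")
    itype = types.pop()
    T = INTERVAL_DURATIONS[itype]
    if bandwidth is None:
        bandwidth = DEFAULT_BANDWIDTHS[itype]
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    centers = bin_centers_for(T, bin_width)
    margin = KERNEL_TRUNCATION * bandwidth
    acc = np.zeros(centers.size)
    for t in trials:
        spikes = trial_relative_spikes(unit, t, (-margin, T + margin))
        acc += kde_rate(spikes, centers, bandwidth)
    return PethMatrix(
        unit_ids=[unit.unit_id],
        bin_centers=centers,
        values=acc[None, :] / len(trials),
        normalization="rate_hz",
        bandwidth=bandwidth,
    )


def stack_peths(rows: list[PethMatrix]) -> PethMatrix:
    """Stack single-unit PETH rows computed on identical bins."""
    if not rows:
        raise ValueError("no PETH rows to stack")
    centers = rows[0].bin_centers
    for r in rows[1:]:
        if not np.array_equal(r.bin_centers, centers):
            raise ValueError("PETH rows have mismatched bins")
    return PethMatrix(
        unit_ids=[uid for r in rows for uid in r.unit_ids],
        bin_centers=centers,
        values=np.vstack([r.values for r in rows]),
        normalization=rows[0].normalization,
        bandwidth=rows[0].bandwidth,
    )


def zscore_rows(peth: PethMatrix) -> PethMatrix:
    """Z-score each unit's PETH row; zero-variance rows are dropped with a warning."""
    sd = peth.values.std(axis=1, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = [uid for uid, k in zip(peth.unit_ids, keep) if not k]
        warnings.warn(f"dropping zero-variance (silent) units before z-scoring: {dropped}")
    vals = peth.values[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=0, keepdims=True)
    return PethMatrix(
        unit_ids=[uid for uid, k in zip(peth.unit_ids, keep) if k],
        bin_centers=peth.bin_centers,
        values=z,
        normalization="zscore",
        bandwidth=peth.bandwidth,
    )


@dataclass
class PcaResult:
    """Ensemble PCA of z-scored PETHs (units are observations, bins variables)."""

    unit_ids: list[str]
    bin_centers: np.ndarray
    components: np.ndarray  # (n_components, n_bins), rows unit-norm
    explained_variance_fraction: np.ndarray
    scores: np.ndarray  # (n_units, n_components)

    def score_of(self, unit_id: str, component: int = 0) -> float:
        return float(self.scores[self.unit_ids.index(unit_id), component])


def ensemble_pca(peth: PethMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of the units x bins matrix (column-mean centered).

    Pools whatever units the caller stacked (typically all areas and days of
    one interval type).  Scores are projections of the centered rows onto
    the components.
    """
    X = peth.values
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise InsufficientDataError("ensemble PCA needs at least 2 units and 2 bins")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaResult(
        unit_ids=list(peth.unit_ids),
        bin_centers=peth.bin_centers,
        components=pca.components_,
        explained_variance_fraction=pca.explained_variance_ratio_,
        scores=scores,
    )


def ramp_strength(pca: PcaResult, unit_id: str) -> float:
    """|PC1 score|: ramping strength regardless of ramp direction."""
    return abs(pca.score_of(unit_id, 0))


@dataclass
class SlopeFit:
    """Linear fit of firing rate (Hz) versus time (s) over the interval."""

    slope: float
    intercept: float
    p_value: float

    @property
    def abs_slope(self) -> float:
        return abs(self.slope)


def binned_rates(
    unit: UnitRecord, trials: list[TrialRecord], bin_width: float = BIN_WIDTH
) -> tuple[np.ndarray, np.ndarray]:
    """(bin centers, trial-averaged rate in Hz) from raw spike counts."""
    types = {t.interval_type for t in trials}
    if len(types) != 1:
        raise ValueError(f"trials mix interval types {sorted(types)}")
    T = INTERVAL_DURATIONS[types.pop()]
    edges = np.arange(0.0, T + bin_width / 2, bin_width)
    counts = np.zeros(edges.size - 1)
    for t in trials:
        spikes = trial_relative_spikes(unit, t, (0.0, T))
        counts += np.histogram(spikes, bins=edges)[0]
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts / (len(trials) * bin_width)


def fit_ramp_slope(
    unit: UnitRecord,
    trials: list[TrialRecord],
    bin_width: float = BIN_WIDTH,
    min_trials: int = 10,
    method: str = "ols",
) -> SlopeFit:
    """Ramp slope in Hz/s with a p-value for slope != 0.

    Default is identity-link least squares on the trial-averaged binned
    rates (slope directly in Hz/s); ``method="poisson"`` refits the summed
    counts with an identity-link Poisson GLM.
    """
    if len(trials) < min_trials:
        raise InsufficientDataError(f"slope fit needs >= {min_trials} trials, got {len(trials)}")
    centers, rates = binned_rates(unit, trials, bin_width)
    if not np.any(rates > 0):
        raise DegenerateDataError("all-zero counts: slope undefined")
    if method == "ols":
        res = sps.linregress(centers, rates)
        return SlopeFit(slope=float(res.slope), intercept=float(res.intercept), p_value=float(res.pvalue))
    if method == "poisson":
        import statsmodels.api as sm

        exposure = len(trials) * bin_width
        counts = rates * exposure
        # identity link with exposure folded into the design: E[count] = (a + b t) * e
        X = np.column_stack([np.full(centers.size, exposure), centers * exposure])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(counts, X,
                           family=sm.families.Poisson(link=sm.families.links.Identity()))
            fit = model.fit()
        return SlopeFit(
            slope=float(fit.params[1]), intercept=float(fit.params[0]), p_value=float(fit.pvalues[1])
        )
    raise ValueError(f"unknown method {method!r}")


def classify_ramping(fit: SlopeFit, alpha: float = 0.05) -> bool:
    """A unit ramps if its slope differs from zero at level alpha."""
    return fit.p_value < alpha


@dataclass
class ModulationResult:
    unit_id: str
    interval_effect_p: float
    modulated: bool
    also_ramping: bool
    rate_fi3: float
    rate_fi12: float


def interval_counts_table(
    unit: UnitRecord, fi3_trials: list[TrialRecord], fi12_trials: list[TrialRecord]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(counts, is_fi3 indicator, exposure seconds) over both trial sets."""
    counts, is_fi3, exposure = [], [], []
    for trials, flag in ((fi12_trials, 0.0), (fi3_trials, 1.0)):
        for t in trials:
            T = t.interval_duration
            counts.append(trial_relative_spikes(unit, t, (0.0, T)).size)
            is_fi3.append(flag)
            exposure.append(T)
    return np.asarray(counts, float), np.asarray(is_fi3), np.asarray(exposure)


def screen_interval_modulation(
    unit: UnitRecord,
    fi3_trials: list[TrialRecord],
    fi12_trials: list[TrialRecord],
    alpha: float = 0.05,
    min_trials: int = 10,
) -> ModulationResult | None:
    """Poisson regression of per-trial spike counts on interval type.

    The count outcome uses log(interval duration) as exposure so the
    interval effect tests a rate difference between FI3 and FI12.  Returns
    ``None`` when either trial set is too small (undefined marker).
    """
    import statsmodels.api as sm

    if len(fi3_trials) < min_trials or len(fi12_trials) < min_trials:
        return None
    counts, is_fi3, exposure = interval_counts_table(unit, fi3_trials, fi12_trials)
    X = sm.add_constant(is_fi3)
    fit = sm.GLM(counts, X, family=sm.families.Poisson(), exposure=exposure).fit()
    p = float(fit.pvalues[1])
    also = False
    for trials in (fi3_trials, fi12_trials):
        try:
            if classify_ramping(fit_ramp_slope(unit, trials, min_trials=min_trials), alpha):
                also = True
                break
        except (InsufficientDataError, DegenerateDataError):
            continue
    fi3_mask = is_fi3 == 1.0
    return ModulationResult(
        unit_id=unit.unit_id,
        interval_effect_p=p,
        modulated=p < alpha,
        also_ramping=also,
        rate_fi3=float(counts[fi3_mask].sum() / exposure[fi3_mask].sum()),
        rate_fi12=float(counts[~fi3_mask].sum() / exposure[~fi3_mask].sum()),
    )
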