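# Methods

## Task structure and behavioral model

A session is a sequence of fixed-interval trials: a cue starts the
interval, the first lever press after the interval duration T (3 s or 12 s)
is rewarded, and trials are separated by intertrial intervals drawn
uniformly from {6, 8, 10, 12} s. Day 0 contains only FI12 trials; Days 1–3
randomly interleave equal numbers of FI12 and FI3 trials. All analyses use
cue-relative time; session-clock times exist only in storage.

The synthetic generator models responding as a two-state renewal process:
presses occur at a low rate (default 0.05 Hz) before a latent start time s
and a high rate (default 1.0 Hz) after it, continuing until the first press
after T (the rewarded press, which ends the trial). The start time is drawn
from Normal(f·T, (cv·f·T)²) truncated to (0, T) with f = 0.8 and cv = 0.15
by default, so start-time variability is proportional to the interval — the
scalar property — by construction, and the mean FI12 start sits near 9.6 s.
This is the minimal structure the single-trial change-point analysis
assumes; it deliberately omits within-session learning, post-reward
behavior, and any coupling between behavior and spiking beyond the
response-locked unit class.

## Spiking model

Units are inhomogeneous Poisson processes λ(t) = max(0, b + m(t)) with
baseline b (default 5 Hz) and a class-specific modulation m:

- **ramp_up / ramp_down** — ±β·t over the interval, with β = 0.5 Hz/s on
  FI12 and β scaled by `slope_scale_fi3` = 4 on FI3 (drift inversely
  proportional to the timed interval, i.e. 12 s / 3 s).
- **interval_modulated** — a rate offset (default 3 Hz) on one interval
  type only.
- **response_locked** — a Gaussian bump (amplitude 8 Hz, σ = 0.3 s) around
  every press.
- **untuned** — homogeneous.

Spikes are drawn by exact thinning (candidate homogeneous process at an
upper bound of λ, acceptance with probability λ/λ_max), which avoids the
bin-size artifacts of discretized Bernoulli simulation. A 2 ms absolute
dead time is then enforced so that generated units pass the refractory
screen, as real sorted units must. The dead time removes roughly λ·2 ms of
spikes (1–2% at default rates) and correspondingly shrinks fitted ramp
slopes by a few percent at the steepest rates; the parameter-recovery tests
run inside this envelope. For response-locked units the thinning bound caps
the summed bump amplitude at three overlapping presses and clips λ there; a
tighter cluster of presses is astronomically rare at the default press
rates.

Waveforms come from a biphasic difference-of-Gaussians template. The
positive peak's FWHM is the class's half-peak width (putative MSN: 0.30 ±
0.02 ms; putative interneuron: 0.12 ± 0.012 ms), the trough trails far
enough that the template's analytic half-peak width equals the generating
FWHM to under one 25 µs sample, and amplitudes set the peak-to-trough ratio
(MSN 2.0 ± 0.15; interneuron 0.9 ± 0.08). Additive noise is 2% of the peak.
The two classes are fully separable at the default classification
boundaries — passing the 100%-accuracy test therefore validates the metric
computation and decision rule, not performance on real, overlapping
waveform clusters.

## Unit screening and classification

Units are analyzed if they fire above `min_rate` = 0.1 Hz over the session
and at most 1% of interspike intervals violate the `min_refractory` = 2 ms
criterion (a "consistent" refractory period tolerates rare violations;
exactly zero would reject genuine units on a single artifact). DMS units
with half-peak width ≥ 0.20 ms *and* peak-to-trough ratio ≥ 1.2 are labeled
putative MSNs, otherwise putative interneurons; both boundaries are
configurable because the feature pair is standard but published cutoffs
vary with the recording system. MFC units are labeled putative pyramidal
neurons — cortical interneurons are assumed removed at spike sorting, so
this module never assigns them.

## PETHs, ensemble PCA, slopes, modulation

Per-trial firing rates are Gaussian kernel-density estimates (sum of
unit-mass kernels at the spikes, in Hz) evaluated at 0.1 s bin centers over
[0, T], averaged across trials; bandwidths are 0.2 s (FI3) and 0.5 s
(FI12). Kernels are truncated at ±4 bandwidths and edge tails are not
renormalized. Rows are z-scored per unit; zero-variance (silent) rows are
dropped with a warning rather than propagating NaNs.

Ensemble PCA treats units as observations and bins as variables
(column-mean centered, covariance convention — on z-scored rows the
correlation alternative is nearly identical). By default all areas and days
of one interval type are pooled into a single decomposition so that every
unit's score is measured against the same components; per-area PCA is a
caller choice. Component signs follow the deterministic SVD convention, and
all downstream ramping statistics use |PC1 score|, which is invariant to
that convention.

Ramp slopes are ordinary least squares of the trial-averaged binned rate
(raw counts, not KDE) on bin time: identity link keeps the slope directly
in Hz/s, and with ≥10 trials the averaged Poisson counts are close enough
to homoscedastic normal for the regression t-test to be calibrated (the
type-I tests check this at 1000 null units). An identity-link Poisson GLM
alternative is available behind `method="poisson"`. A unit "ramps" when its
slope differs from zero at α = 0.05 — the same α as the modulation screen,
since no separate criterion is published for the ramping percentages.
Interval modulation is a Poisson regression of per-trial in-interval spike
counts on interval type with the interval duration as exposure, so the test
compares rates, not raw counts, across FI3 and FI12.

## Temporal decoding

Each trial × unit is summarized as a KDE rate vector (bandwidth 1.2 s,
interpreted as seconds of temporal smoothing) over [−6 s, T + 6 s] in 0.1 s
bins; the padding exists so interval-edge bins have symmetric candidate
neighborhoods rather than an edge bias. Training estimates the per-unit,
per-bin mean rate; the default likelihood treats the observed smoothed rate
× bin width as a Poisson pseudo-count with that mean (Poisson matching the
firing-rate model family used throughout), with a floor of 10⁻³ expected
spikes/bin to keep log-likelihoods finite in silent bins. A rate-space
Gaussian-KDE likelihood is available as an alternative. Decoding is MAP
under a uniform prior over all padded bins, naïvely multiplying unit
likelihoods; exact ties resolve to the earliest bin, so a completely
uninformative ensemble predicts the first padding bin and scores R² = 0.

Leave-one-out cross-validation trains on all other trials (computed by a
leave-one-out mean, so the full tensor is built once) and scores the
squared Pearson correlation of observed versus predicted time pooled over
in-interval bins only; `r2_method="ss"` switches to 1 − SS_res/SS_tot. The
chance control circularly shifts each unit's single-trial rate vector by an
independent uniform offset before training and testing — preserving each
unit's rate marginal while destroying time locking; an independent-bin
permutation would additionally break within-trial autocorrelation. A
pure-ramp ensemble decodes mid-interval bins to within a few hundred
milliseconds but confuses near-cue bins with the flat-rate padding, which
caps pooled Pearson R² well below 1 even for strong ensembles; the
shuffled control collapses toward 0 regardless.

## Single-trial start times and CV

For presses p₁ < … < pₙ in [0, T], the start time is the press maximizing

    index(s) = s·(r − r_pre(s)) + (T − s)·(r_post(s) − r),

where r is the whole-trial press rate and r_pre/r_post the rates before and
after the candidate (a press at s counts as post — the transition begins
with it). Ties resolve to the earliest press within a 10⁻⁹ relative
tolerance; perfectly periodic presses make the index exactly constant, so
the earliest press is returned. Only the start transition is estimated:
fixed-interval trials end at reward, so the stop transition of the
peak-interval version of this analysis does not exist here. Trials with
fewer than two in-interval presses are undefined and excluded from CV
summaries (CV = sample SD with n−1 denominator / mean).

The index maximizer is algebraically the press maximizing (2n/W)·pᵢ − 2i,
which in a two-state press process is (usually) the first high-state press.
The estimate therefore lags the latent start by roughly the first
high-state waiting time — median ln 2 / rate_high, about 0.7 s at the
default 1 Hz — and Poisson clumping within the high state adds a heavy
right tail. At the default press rates, single-trial precision is limited:
estimates correlate strongly with planted starts but absolute errors below
~0.5 s per trial are not achievable with this index, a property the test
suite measures directly. Scale invariance holds exactly: scaling presses
and T by c scales the estimate by c.

## Statistical models

`fit_model` consumes a declarative spec (outcome, formula terms, random
effects, family, optional exposure). Gaussian outcomes with random effects
fit a linear mixed model (REML) with the first random-effect column as the
grouping factor; statsmodels has no crossed-random-effects GLMM, so
specifications listing several random factors use the first and report the
rest unconsumed. Poisson outcomes fit a GLM, with cluster-robust covariance
over the first random-effect factor when one is declared — a pragmatic
stand-in for a Poisson GLMM that keeps the Wald tests honest about
within-cluster correlation. Per-term tests are large-sample Wald statistics
reported as F = W/df with a χ² reference; no small-sample denominator-df
convention is asserted. A singular mixed fit falls back to fixed effects
only and flags the result.

Post hoc contrasts are estimated marginal means: predictions with the
factor column set to each level, averaged over the observed covariate
distribution, compared pairwise with Tukey's studentized-range adjustment
(for two levels this reduces exactly to the unadjusted test). The 2×2
contingency test is Pearson's χ² without continuity correction — the
convention that reproduces the published statistic from the published
counts — and requires positive margins. The signed-rank test drops zero
differences, mid-ranks ties, and switches to the normal approximation
beyond 25 informative pairs; Cohen's d = mean/SD of the paired differences,
reported as signed infinity with a `d_capped` flag when the differences are
constant. The Bayes-factor companion to the CV null comparison is out of
scope (no prior specification to reproduce).

## Pipeline, seeds, and problem sizes

The pipeline derives every stochastic stage's generator from a named
substream of the master seed (keyed by stage, animal, day), so disabling a
stage never shifts another's randomness, and identical config + seed yields
a byte-identical summary. Test and acceptance problem sizes are chosen as
the smallest that leave the checked properties comfortably outside sampling
noise: 20 replicate 20-unit/60-trial ensembles for the decoder comparison,
1000 null units for screen calibration, 200 trials per condition for
parameter recovery, 500 trials per interval for the scalar-CV property.

## Known limitations

- No learning dynamics: generator parameters are constant within and across
  days, so day effects exist in the pipeline's outputs only as noise.
- The Poisson decoder likelihood treats smoothed rates as pseudo-counts;
  this is a scoring rule, not a generative claim about the KDE features.
- Waveform classes are synthetic and fully separable; real MSN/interneuron
  boundaries overlap and the default cutoffs are conventions to revisit on
  real data.
- Mixed models use a single grouping factor (see above); crossed
  unit-by-response random effects are not fitted.
- Spike-sorting, LFPs, and proprietary acquisition formats are out of
  scope; the pipeline starts from sorted spike times in plain-text tables.
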