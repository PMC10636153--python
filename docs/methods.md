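# Methods

This note documents the models, estimators and parameter choices in
`v4attn`, what the synthetic-data generator does and does not emulate, and
the numerical conventions that matter for reproducing its outputs.

## Synthetic laminar recordings (`v4attn.synth`)

The generator produces the statistical structure the analysis assumes, not a
biophysical simulation of V4.

**Population.** Each unit carries a spiking class (narrow / medium / broad),
a laminar label (superficial / input / deep), a ground-truth peak-to-trough
duration (PTD), an attend-away contrast response function, an attention
effect, and an onset latency. Class proportions default to 43:54:78
(narrow:medium:broad), the composition of the laminar population the package
emulates; layers are uniform. PTD modes are 0.20 / 0.35 / 0.55 ms with SD
0.03 ms — magnitudes plausible for primate extracellular waveforms, chosen
so the pooled width distribution is clearly trimodal (dip test p < 0.01 at
n = 300).

**CRFs and attention.** Attend-away parameters are drawn from log-normal
priors (median r_max 30 spikes/s, c50 20% contrast, exponent 2, baseline
5 spikes/s, clipped to physiological ranges). The attend-in CRF is derived
from the attend-away CRF by an `AttentionEffect`: a response gain g_r on
r_max, a contrast gain g_c ≥ 1 applied as a leftward c50 shift
(c50 → c50/g_c), and a baseline gain on m. The identity effect reproduces
the attend-away CRF exactly. The *laminar-gain* scenario assigns: narrow —
pure response gain (g_r = 1.10) in all layers; medium — pure response gain
(1.12) in all layers; broad — contrast gain (g_c = 1.6, with a small 1.05
response gain) in superficial and input layers and pure response gain (1.15)
in the deep layer. This injects the qualitative target pattern: positive CDI
only for broad units in superficial/input layers. Gains were chosen to give
mean AMIs in the 0.04–0.13 range, comparable to attentional effects in
mid-tier visual cortex.

**Trials.** Spiking is inhomogeneous Poisson on a piecewise-constant rate:
baseline m from −200 ms until stimulus onset plus the unit's latency, then
the condition-specific CRF value until +400 ms. There is no refractoriness,
bursting, trial-to-trial gain variability, or noise correlation between
units — so passing tests demonstrate correctness of the estimators under
the assumed model, not robustness to those real-data features. Default
contrasts are six log-spaced values in [2.5, 80]%; class latency means are
45 (medium) / 55 (narrow) / 65 (broad) ms with SD 5 ms, giving the
medium < narrow < broad ordering the latency stage is asked to recover.
Because the spike-count window opens at 60 ms, units with latency > 60 ms
have a small (few-percent) downward bias in measured rates; this is within
the tolerance of all recovery checks.

**Waveforms.** Templates are two Gaussian lobes (trough then peak, widths
scaled to the PTD); the lobe separation is numerically corrected so the
continuous template's extrema are exactly the nominal PTD apart, making the
measured PTD agree with ground truth to well under half a sampling step at
30 kHz.

## Waveform classification (`v4attn.waveforms`)

*PTD* is measured on a cubic-spline ×10 upsampled trace as the time from
the global minimum to the subsequent global maximum; constant, monotone and
polarity-inverted traces are rejected as non-biphasic.

*Meta-clustering*: k-means with random initialization is restarted many
times (default 500); restarts are aggregated into a co-assignment
(consensus) matrix; the final partition is an average-linkage hierarchical
cut of 1 − consensus at k clusters. With a single restart this reduces to
plain k-means. Cluster names are assigned by ascending mean PTD.

*Model selection*: AIC/BIC from a hard-assignment Gaussian-mixture
log-likelihood (per-cluster mean and variance, mixing weights; p = 3k − 1
parameters in 1-D), with the variance floored at the squared waveform
sampling step to survive singleton clusters. The elbow is the kneedle
construction: min-max normalize both axes, difference curve
d_i = (1 − x̂_i) − ŷ_i, elbow at the global maximum (smallest k on ties);
an exactly linear curve returns "no elbow".

*Dip test*: Hartigan's dip — the sup-norm distance from the ECDF to the
nearest unimodal CDF — computed by splitting the sorted sample at every
candidate mode position and measuring, for each side, half the maximum
deviation of the band centers from their greatest convex minorant (left,
convex side) or least concave majorant (right, mirrored). The statistic is
provably within [0, 0.25]; atoms are handled by splits inside tie blocks
(so two equal point masses give 0.25 and a constant sample gives 0). A
brute-force feasibility construction (binary search over the band
half-width with an explicit convex-envelope check) validates the
implementation exactly at small n in the test suite. p-values come from
2000 bootstrap samples of the uniform(0,1) null at the same n (the standard
calibration); null tables are cached per sample size.

## CRF fitting and attention indices (`v4attn.crf`)

Rates are spike counts in the half-open window [60, 260) ms divided by
0.2 s, averaged over trials. Visual responsiveness is a one-sided
Mann–Whitney test (α = 0.05) of evoked (highest contrast) versus baseline
(−200–0 ms) per-trial rates.

The fit is bounded nonlinear least squares (trust-region reflective) on
trial-mean rates — unweighted ordinary least squares in the parameters —
multi-started over c50 ∈ {5, 10, 20, 40, 80} and n ∈ {1, 2, 4}, keeping the
lowest-SSE solution. Bounds: r_max ∈ [0, 5·max rate], c50 ∈ [0.5, 100],
n ∈ [0.3, 6], m ∈ [0, max rate]. The fitted curve is nondecreasing by
construction (nonnegative r_max). `fit_crf_grid` provides a dense
50×50×20×20 brute-force grid evaluation over the same box (vectorized via
the quadratic expansion of the SSE in r_max and m) as an independent
optimization oracle.

Blank (0%-contrast) trials are included by default and participate in the
CRF fit — they anchor the baseline parameter m, which otherwise dominates
the variance of the fitted low-contrast responses and, through it, of the
low-contrast AMIs; the attention indices themselves are evaluated at the
stimulus (positive) contrasts.

AMI uses the standard contrast index (in − away)/(in + away), applied per
contrast and to each parameter pair; it is antisymmetric under swapping
conditions and equals (g − 1)/(g + 1) exactly under pure response gain.
CDI splits contrasts at the attend-away c50 (c = c50 counts as low; this is
the inflection point of the attend-away curve for n-near-2 fits). A unit's
CDI is flagged invalid when either side of the split is empty, when
|mean AMI| < 0.01, or when the unit's overall attend-in vs attend-away rate
difference is unresolved (Stouffer-combined per-contrast z of the rate
difference, |Z| < 1.96) — the ratio is meaningless without detectable
modulation, and this gate is dominated by the high-contrast comparisons so
it barely selects on the low-minus-high AMI numerator. Group summaries
additionally exclude |CDI| > 10 and report percentile bootstrap CIs of the
mean. Note a statistical fact about the class×layer CDI table: with seven
no-effect groups each carrying a 95% CI, roughly a third of simulated
datasets show one spurious CI excluding zero purely by multiplicity; the
pipeline reports all nine CIs so such cases are visible.

## Response latency (`v4attn.latency`)

The adaptive rate estimate pools spikes across trials into 1-ms bins and,
for every bin, selects a Gaussian kernel bandwidth from a log grid in
[1, 50] ms by minimizing a localized MISE cost
C(w;t) = Σ_{ij} k_{w√2}(t_i−t_j) φ(mid_ij − t) − 2 Σ_{i≠j} k_w(t_i−t_j)
φ(mid_ij − t). Selection is a fixed-point iteration started at the global
optimum, with the localizing window φ tied to the *current* bandwidth
estimate (SD = 3 w); localizing each candidate with its own width biases
the argmin toward small, high-variance bandwidths. The bandwidth profile is
median-smoothed over 5 bins. On homogeneous Poisson data the time-averaged
estimate is accurate to a few percent, and bandwidths contract near rate
steps.

Detection runs on a *causal* (past-only, renormalized half-Gaussian) rate
computed with the adaptive bandwidths: a symmetric kernel leaks a response
backward in time, which makes any threshold crossing precede the true onset
— a causal kernel cannot. The threshold is the larger of (a) the 97.5th
percentile of the bootstrap distribution (1000 trial resamples) of the
pre-stimulus (−200–0 ms) mean rate and (b) the maximum of the
pre-stimulus rate curve re-estimated at the smallest bandwidth the detector
uses in the first 100 ms after onset (so baseline fluctuations are compared
at the smoothing scale of the crossing search); the response time is the
first post-onset bin from which the rate stays above threshold for ≥ 100
consecutive 1-ms bins ("consistently greater"). The duration and the floor
were calibrated on step and null fixtures so that a 10× step at 50 ms is
detected within [50, 70] ms in ≥ 90% of runs while flat-rate nulls yield no
detection in ≥ 95%; the calibration fixtures used seeds disjoint from the
test suite's. The trade-off is insensitivity to transient responses
shorter than ~100 ms.

The fixed-bandwidth control estimates causal rates with kernels of 1–10 ms,
thresholds at the maximum pre-stimulus rate, requires five consecutive
supra-threshold bins, and reports the median over bandwidths. Class
summaries bootstrap the mean latency per class and compare classes by
two-sided rank-sum tests at the Bonferroni threshold 0.05/3.

## Estimation statistics (`v4attn.bootstats`)

Percentile (not BCa) intervals with n_boot = 10,000 by default — the
estimation-statistics convention; coverage of the 95% CI is 95 ± 2% in the
acceptance check. Rank tests are two-sided scipy implementations; the
Bonferroni threshold for the three pairwise class comparisons is
0.05/3 ≈ 0.0167.

## Normalization model of attention (`v4attn.normmodel`)

One-dimensional space (two mirror-symmetric stimuli at ±4°, grid of 160
points over ±10°) crossed with orientation (64 wrapped points over 180°).
The stimulus drive is contrast × Gaussian(space; σ = 1°) ×
Gaussian(orientation; 20°), passed through a pointwise power (io exponent,
default 2), blurred by the stimulation field (Gaussian, default σ = 1° in
space × 30° in orientation), and multiplied by the attention field
(1 + (gain−1)·Gaussian of σ = 4° at the attended stimulus; gain 2). The
suppressive drive pools the excitatory drive over all orientations and a
spatial Gaussian (default σ = 3°); the probed neuron sits on the attended
stimulus at its orientation and responds as R = E/(S + σ_norm) with
σ_norm = 10⁻². Defaults put the model in a contrast-gain-like regime
(CDI ≈ 0.7) from which CDI decreases monotonically as either the
stimulation field or the suppressive field widens. The ±4° separation keeps
the attention field selective for one hemifield across the robustness grid
(attention σ up to 6°); with stimuli closer together a very wide attention
field covers both stimuli and the inverse relation degrades, which is a
property of the model geometry rather than a numerical artifact. Responses
use unit-normalized convolution kernels, making the CDI invariant under
joint rescaling of all spatial σs, and the model is homogeneous of degree
zero under joint scaling of drive and σ_norm when the io exponent is 1.
The CDI split point is the contrast where the attend-away curve crosses
half its maximum (log-interpolated).

## Columnar E–I network (`v4attn.einet`)

Nine columns in a line, 80 E + 20 I conductance-based LIF neurons per
column (4:1 fixed). Membrane: τ_m 20 ms (E) / 10 ms (I), V_rest −70 mV,
threshold −50 mV, reset −60 mV, refractory 2 ms, exponential conductances
(τ_exc 5 ms onto both; τ_inh 10 ms), reversal 0 / −80 mV, Euler step
0.1 ms. Only E cells project across columns; the cross-column weight decays
as a Gaussian of column distance with σ_E (onto E) or σ_I (onto I), each
kernel normalized over source columns so total excitatory input is
independent of the pooling width (what varies is *where* it comes from).
Inhibition is within-column. Every neuron receives independent external
Poisson drive (base 1.5 kHz of weight 0.02, stepping to 4 kHz during the
200–1000 ms stimulus interval of each 1-s trial); I cells receive it scaled
by 0.1, so inhibitory spiking is driven almost entirely by the pooled
recurrent excitation whose spatial footprint is the object under test.
Weights (w_EE 0.3, w_EI 4.0, w_IE 0.1, w_II 0.05 total leak-conductance
units) were set so that steady-state rates are ≈ 20 spikes/s (E) and
≈ 50 spikes/s (I), the corrected E–I correlogram has a small positive peak,
and the near-feedforward inhibitory readout avoids loop-induced gamma
oscillations that would otherwise cancel the ±25-ms window mean. The
narrow default σ_E = 0.5 keeps neighbouring columns' excitatory pools
weakly correlated, which is what lets a wide σ_I dilute the local E–I
correlation. Runs abort with diagnostics if the mean rate exceeds
200 spikes/s. Analysis pools the centre column's E and I spikes per trial,
drops the first 100 ms after step onset, and computes shuffle-corrected
CCGs.

## Cross-correlograms (`v4attn.ccg`)

Trains are binned at 1 ms within trials; the raw correlogram counts
coincidences at bin-difference lags in ±100 ms and is normalized by the
geometric mean of the two pooled spike counts. This makes swap-antisymmetry
(lag reversal) and total-pair-count conservation exact integer identities.
The default correction is the all-trial-pairs *shuffle* predictor (the
PSTH cross-product with same-trial pairs removed — equal to the average of
every possible trial rotation), which has far lower variance than a single
rotation; one-rotation shift and 25-ms interval-jitter predictors are
available options. The "50-ms window" summary is the mean corrected value
over lags in [−25, +25] ms, preserving the antisymmetry property. Grouped
analyses pool spikes per class per layer within a session and average
corrected CCGs across sessions.

## Pipeline (`v4attn.pipeline`)

`run_all` chains the stages from one seed, writes deterministic CSV/JSON
outputs, and reports only qualitative claims (selected k, agreement with
ground truth, latency ordering and tests, class×layer CDI table with
bootstrap CIs, model monotonicity flags). Reruns with the same
configuration are byte-identical. Default problem sizes (240 units, 60
trials per contrast per condition, 200 clustering restarts, 5000 bootstrap
draws; smaller model sweeps) were chosen as the smallest sizes at which the
injected class×layer pattern is recovered with comfortable CI margins on a
desktop CPU. The trial count matters beyond precision: the per-unit CDI is a
ratio of noisy AMI averages whose low/high split sits at the *fitted*
attend-away c50, which couples split placement to fit noise and biases CDI
upward at low trial counts (≈ +0.4 at 30 trials per condition for a pure
response-gain unit, ≈ 0 by 60); the default sits where that bias is
negligible.

## Known limitations

* The generator's Poisson spiking has no refractoriness, Fano-factor
  structure, or inter-unit noise correlations; estimator robustness to
  those is untested.
* The latency detector is calibrated for sustained responses; transients
  shorter than the 75-ms persistence requirement are not detected.
* The E–I network is a minimal mechanism probe (near-feedforward inhibitory
  readout, no plasticity, no attention input, open boundary); its weights
  are calibrated for rate ranges and correlation sign, not fitted to data,
  and inhibitory rates (~50 spikes/s) sit at the high end of the
  physiological range.
* The normalization model uses 1-D space; receptive-field structure beyond
  the two-stimulus geometry is out of scope.
* AIC/BIC use a hard-assignment mixture likelihood, which slightly favours
  well-separated solutions relative to a full EM mixture.
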