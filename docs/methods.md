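# Methods

`rgcpipe` analyses trial-structured extracellular recordings of retinal
ganglion cells (RGCs) that were retrogradely labelled from one of two
retinorecipient targets — the superior colliculus (SC) or the dorsal
lateral geniculate nucleus (dLGN) — and asks whether the two targets
receive functionally similar retinal input. It also analyses maps of
labelled cell positions on the flattened retina. This note documents the
models, estimators, defaults and their rationale, and what the synthetic
data generator does and does not emulate.

## Spike density function (SDF)

Firing rate is estimated by an edge-corrected Gaussian kernel density:

    r(t) = (1 / n_trials) · Σ_spikes φ_σ(t − s_j) / c(s_j)

where φ_σ is a Gaussian of SD σ (the bandwidth) and
c(s) = ∫_span φ_σ(u − s) du renormalises each spike's kernel to unit mass
*within the analysis span*. Spikes outside the span are excluded. Two
consequences are load-bearing: the integral of the SDF equals the mean
in-span spike count per trial (mass conservation, tested against a
brute-force kernel-sum oracle), and rates near the span edges are not
biased downward.

Defaults: bandwidth 25 ms, grid step 2 ms. The kernel width is a genuine
free choice (no canonical value exists for this preparation); 25 ms is
narrow enough to resolve transient responses with ~60 ms decay constants
and wide enough that five-trial averages are stable. Both are `RunConfig`
fields and every output table embeds the configuration hash.

## Per-cell metrics

- **Spontaneous rate** — spikes in the pre-onset baseline window divided by
  (trials × window length), in AP/s.
- **Latency** — earliest time after the driving luminance transition at
  which the SDF exceeds threshold continuously for ≥ 50 ms, with
  threshold = baseline + 0.1 × (peak − baseline). Two deliberate choices:
  (1) the threshold is referenced to the spontaneous baseline, because for
  tonically active cells (~10 AP/s) a plain 10%-of-peak threshold sits
  inside the resting discharge and fires on noise; (2) for Off-polarity
  cells the search starts at stimulus *offset* — their response follows the
  decrease in light intensity, and searching the silent stimulus-on period
  invites spurious crossings. With baseline 0 and onset search the rule
  reduces exactly to the plain fraction-of-peak criterion.
- **Response duration** — ∫ SDF over a 500-ms window from the latency,
  divided by (window peak × window length). Ranges over [0, 1]: 1 for a
  rate held at peak (sustained), →0 for a brief transient. Computed on the
  raw (baseline-unsubtracted) SDF because the definition divides by the
  peak response.
- **Polarity** — on/off peaks are baseline-subtracted SDF maxima in the
  stimulus-on window and the 500 ms after offset; the on window stops
  3 kernel bandwidths before offset so the smoothed offset response cannot
  leak into it. on_off_index = (on − off)/(on + off); label ON when the
  index ≥ +0.5, OFF when ≤ −0.5, otherwise ON_OFF (thresholds
  configurable, boundary inclusive).
- **Direction selectivity** — normalised vector sum length
  NVSL = |Σ r_j e^{iθ_j}| / Σ r_j over the 8 tested directions, preferred
  direction = argument of the vector sum. The per-direction response r_j
  defaults to the trial-mean firing rate during the bar transit
  (`direction_mode="count"`); the SDF-peak variant is available as
  `direction_mode="peak"`. The mean rate is both what direction panels of
  this kind plot and a lower-variance statistic than the peak (a maximum),
  which matters at 5 trials/direction: with the default the preferred
  direction of a κ=2 cell at 60 AP/s is recovered within ±10° in ≈98% of
  cells, versus ≈93% for the peak variant.
- **Tuning curves and widths** — trial-mean peak response per tested size
  (50–800 μm) or speed (50–3,200 μm/s); width = trapezoidal integral over
  the tested range divided by the peak, so a flat curve has width equal to
  the x-range (750 μm for sizes) and narrow selectivity gives small widths.
  Best size/speed is the measured argmax (ties to the smaller stimulus).
- **Gamma fit / interpolated best size** — least squares of
  R(x) = baseline + amplitude · (x/x*)^{k−1} e^{−(k−1)(x − x*)/x*}, a
  gamma-shaped bump whose amplitude is the fitted peak above baseline and
  whose optimum x* is a free parameter bounded to [min x / 2, 2·max x].
  Multi-start (geometric grid of x*, two shape seeds) with an analytic
  Jacobian; a fit whose optimum lands at or beyond the largest tested
  stimulus is flagged `unbounded_within_range`, and non-convergence is
  returned flagged rather than silently. The interpolated best size falls
  back to the measured argmax when the fit is flagged.
- **Cutoff frequency** — the frequency above the argmax at which the peak
  response to sinusoidal luminance modulation falls to half its maximum,
  interpolated linearly in log₂(frequency) between tested frequencies
  (1, 2, 4 Hz); undefined when the response never falls to half max —
  a three-point protocol frequently cannot bracket the corner, and the
  pipeline reports `None` rather than extrapolating.

## Classification

Six functional groups, assigned by fixed rules in order: (1) ON_OFF
polarity with NVSL > 0.2 → On-Off direction-selective; (2) OFF polarity →
sustained/transient Off by response duration ≥ / < 0.4; (3) ON polarity →
small-transient On when duration < 0.4 *and* size tuning width < 500 μm,
else sustained/transient On by duration. Anything else (no polarity,
missing duration, non-DS ON_OFF) is UNCLASSIFIED.

The 0.2 NVSL and 500 μm width criteria are the source analysis's own
thresholds. The 0.4 duration cutoff is a package choice: the
sustained/transient split is bimodal but no printed cutoff exists; 0.4
sits in the gap and is a config field (sweeping it over [0.3, 0.5]
requires no code change). The "best size ≤ 200 μm" property of
small-transient On cells holds only *generally* in the source data, so it
is reported but never enforced. Off cells with narrow widths remain
transient Off — no seventh class is invented.

## Population statistics

Class proportions between projection groups are compared with Pearson's
χ² (1 df) on 2×2 tables, **without** continuity correction by default:
the published p < 0.03 for the On-fraction table [[45,44],[36,67]] is
reproduced without correction (p ≈ 0.029) but not with Yates
(p ≈ 0.042). The correction is a flag. Metric distributions are compared
with the two-sided Wilcoxon-Mann-Whitney test — exact null when
min(n, m) ≤ 8 and the data are tie-free, normal approximation with tie
correction otherwise. Labelling proportions get Wilson 95% intervals, and
replicate retinas are summarised as mean ± SE. No multiple-testing
correction is applied, matching the source analysis.

Co-label fractions are computed inside a density mask: the retina is
binned on a 100-μm grid and bins with ≥ 25% of the peak labelled-cell
density are kept. "Densely labelled" is qualitative in the source; both
knobs are config fields reported with every output.

## Retinotopy

Labelled-cell point clouds are summarised by moment-based 2D Gaussian
fits: centre = sample mean, axis SDs = square roots of the sample
covariance eigenvalues (an axis-aligned reading of "the SD of the fit";
the eigen-decomposition is the default since no convention is stated).
Derived quantities: centroid vector (angle/length from the optic nerve
head at the origin), angular separation of two vectors (min(|Δ|, 360−|Δ|)),
centroid distance, and the number of one population's cells within
Mahalanobis distance 2 of the other's centre (boundary inclusive; zero
replicates full spatial separation). Fitting uses cell coordinates, not
fluorescence intensity grids; an intensity-based variant would be a
straightforward extension.

## Synthetic data generator

No recordings or retinas are deposited for this analysis, so the
generator is a first-class module with known ground truth. The response
model is separable:

    rate(t) = spontaneous + peak_gain · contrast · K(t) · G_dir · G_size · G_speed

- K(t): exponential decay (time constant `kinetics_tau`) triggered at
  onset and/or offset according to polarity for stationary spots; a
  raised-cosine burst spanning the transit for moving bars; a rectified
  raised cosine scaled by a first-order low-pass gain (corner
  `tf_cutoff`) for sinusoidal modulation.
- G_dir: von Mises, exp(κ(cos Δ − 1)), peak 1 at the preferred direction,
  flat at κ = 0.
- G_size, G_speed: gamma-shaped gains normalised to peak 1 over the tested
  stimulus range.

Sustained vs transient ground truth is set by `kinetics_tau` (0.6 s vs
0.06 s defaults; ≥ 0.4 s counts as sustained, ≤ 0.08 s as transient).
The moving-bar burst lasts the stimulus epoch (0.5 s at 800 μm/s) — the
time a bar takes to cross a receptive field — rather than the step-response
time constant; a bar is not a flash, and a millisecond-scale burst would
leave too few evoked spikes per trial for any estimator to recover
direction at the protocol's 5 trials/direction. Peak gains default to
150 AP/s (the scale of the published response traces); the transient-Off
archetype has projection-specific spontaneous rates (dLGN 10.7, SC
1.8 AP/s), mirroring the published means.

Spikes are drawn by thinning a homogeneous Poisson candidate stream at the
grid maximum, holding the rate piecewise-constant at 1-ms resolution, with
at most one spike kept per grid bin (a 1-ms refractory period; the
collision loss is < 1% at the rates used). Each cell has its own RNG
stream keyed by (master seed, cell index), so datasets are reproducible
and order-independent.

The default population composition is the *classified* subset of each
recorded group, anchored to every printed count: dLGN 74 cells
(10 On-Off DS, 11/8 sustained/transient Off, 30/14/1
sustained/transient/small-transient On) and SC 79 cells
(20, 8, 15, 12, 16, 8). The ~20% of recorded cells that defied
classification have no stated generative criteria and are not simulated;
the printed denominators (89/103) are available separately via
`classify.paper_composition()` for the proportion tests.

The retina-map generator draws isotropic Gaussian clusters per fluorophore
channel, rejection-sampled to the retina radius, with Bernoulli co-labels
at a specified probability.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: receptive-field spatial structure (size tuning
is a scalar gain), contrast-response functions (contrast is a scalar
gain; the pipeline computes no contrast metrics), serial correlations or
adaptation across trials, bursting/refractory statistics beyond the 1-ms
bin rule, recording artefacts, and the unclassified ~20% of real cells.
Recovery percentages on synthetic data are statements about estimator
noise under the protocol's sample sizes, not about biological
separability.

## Numerical choices and degenerate inputs

Peak searches break ties toward the earliest time / smallest stimulus.
All-zero direction responses leave NVSL undefined (`None`), all-zero
tuning curves leave widths undefined, and an unresponsive step leaves
polarity (and hence the class) undefined — undefined values propagate as
`None`/NaN and classify as UNCLASSIFIED rather than erroring. χ² on a
table with a zero margin and Mann-Whitney on an empty sample raise
errors. The SDF grid is inclusive of both span endpoints; integrals use
the trapezoid rule on the grid.

## Problem sizes

The recovery analyses use 200 cells (direction), 200 cells per class
across both groups (classification; 1,200 cells × 120 trials), 6 synthetic
eyes (retinotopy) and 3/7 synthetic retinas (label fractions) — the same
order as the study's own sample sizes where those are printed, and enough
for the binomial error on a 95%-recovery claim to be ~1.5 percentage
points.

## Known limitations

The cutoff-frequency estimator cannot report corners above 4 Hz or below
1 Hz with the three-point protocol. The gamma-fit parameterisation is one
concrete choice (the cited fitting reference is not reproduced here); its
optimum, not its shape parameters, is the quantity consumed downstream.
Anatomical (nasal/temporal) axes are not assigned to retinal coordinates,
matching the acquisition's unknown eye orientation. The classifier is
deliberately rule-based; unsupervised taxonomies with 12+ clusters are out
of scope.
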