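# Methods

This note documents the models, the parameters that matter, the numerical
choices, what the synthetic-data generators do and do not emulate, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Locomotion state model

A crawling worm imaged at low resolution yields, per frame, a centroid
position, a body-axis unit vector (from the inertia-matrix ellipse fit;
elongation is defined as 2·√λ_max of the per-point second central moment
matrix — the constant is immaterial because only *relative* elongation
r = elongation / track mean enters the model), and from these two derived
observables: r and the body-axis-projected displacement Δx. The axis sign
is arbitrary per frame; preprocessing flips any axis opposing its
predecessor so the projected coordinate stays consistent along a track.

The hidden state space has six members: forward±, backward±, forward turn,
omega turn. The ± doubling tracks whether increasing projected coordinate
corresponds to forward movement — head and tail are indistinguishable in
the images, so this is a latent orientation, inferred rather than observed.
Emissions:

- r | crawling ~ Gaussian(1, σ) with σ = 0.075 (close to the observed
  spread of moving worms);
- r | turning = 1 for r ≤ 1 and a Gaussian tail above 1. This factor is
  deliberately unnormalized; per-frame posterior normalization makes
  constant factors irrelevant;
- direction factors P(state | Δx) with the sigmoid (1 + erf(2x))/2 of
  x = Δx/(cΔt), c = 0.1 mm/s — a fraction of the typical 0.25 mm/s crawl
  speed, so a worm must travel a finite distance before direction is
  scored with confidence and stationary jitter is discounted. Turning
  states get the constant ½ (it cancels; the model is silent on turn
  directionality).

Permitted transitions: self-loops everywhere; forward± ↔ backward± with
matching sign (reversing does not flip the projection orientation);
forward± ↔ forward turn; backward± → omega turn → forward± (either sign —
an omega turn reorients the body, which can flip the orientation). All
other entries are structurally zero and stay exactly zero through EM,
because expected transition counts inherit the zeros.

Baum–Welch re-estimates only the transition matrix and initial
distribution; σ and c stay fixed. The initializer puts 0.95 stay
probability on crawl states, 0.01 on forward→backward and 0.05 on
backward→forward: this asymmetry breaks the forward/backward relabeling
symmetry, and EM converges to the labeling that assigns the longer bouts
to forward movement (backward bouts are genuinely brief). Convergence:
relative log-likelihood change < 1e-6 or 200 iterations (the synthetic
cohorts typically converge in < 10). Recursions are scaled, so tracks of
10⁵+ frames are safe. Tracks of equal length are batched through a single
vectorized forward–backward pass; a movie-sized cohort (20 worms × 3600
frames) fits in a few seconds on one core. Frames with non-finite
observations receive uniform emissions instead of breaking the track, and
all emissions are floored at 1e-15 to keep the scaled recursions defined
when the direction sigmoid saturates.

Decoding thresholds P(backward⁺) + P(backward⁻) at ½; turn frames count as
part of the surrounding forward period. Intervals touching a track
boundary are flagged censored.

## Survival estimation and the repetitive behavior index

Forward-bout durations cannot be read off directly because tracks are lost
(field-of-view exits, collisions). The discrete product-limit estimator
uses the per-step hazard p_{f→b}(i) = events_i / at-risk_i. Conventions: a
bout of L steps is an event at hazard index L−1, so p_f(n) = P(L > n);
end-censored bouts leave the risk set without contributing events;
*start*-censored bouts (the track begins mid-bout) are excluded entirely,
since their elapsed forward time is unknown — the standard left-truncation
treatment when entry times are unavailable.

The reversal hazard model r(t) = r₀ + δr·e^(−t/τ) integrates to
log p_f(t) = −r₀t − δl(1 − e^(−t/τ)), δl = τδr. τ is fixed (default 20 s,
one value for all lines, keeping "early" vs "late" comparable across
genotypes), which makes the fit linear: regressors −t and −(1 − e^(−t/τ))
with coefficients (r₀, δl). RI = δl/ln 2, so RI = 1 means exactly a 50%
asymptotic deficit of forward-moving worms relative to the baseline
exponential: p_f(t)/e^(−r₀t) → e^(−δl) = ½. The "log 2" in the index
definition is the natural logarithm — anything else breaks that anchored
50% statement. δl is unconstrained in sign; negative values (more regular
than Poisson) are reported with an `anti_repetitive` flag.

Fitting choices: native time steps up to the last bin with ≥ 5 bouts at
risk; p_f = 0 bins dropped (log undefined) rather than pseudo-counted.
Weights are 1/variance. When across-movie variances are supplied they are
used directly; otherwise the default derives per-bin variances of log p_f
from the curve's own hazards and at-risk counts (the Greenwood cumulative
sum, floored at its smallest positive value so pre-first-event bins cannot
acquire infinite weight). This keeps the long, noisy survival tail from
dominating the fit; on direct hazard-sampled cohorts the estimator is
unbiased with roughly a third the variance of the unweighted fit. A
non-identifiability guard rejects fits whose largest usable time is below
τ/10, where the two regressors are numerically collinear. Standard errors
come from (XᵀWX)⁻¹, scaled by the residual mean square when weights are
internal (the survival points are serially correlated, so these SEs are
indicative, not exact).

Goodness of fit: S = Σ Δr_i²/σ_i² compared to χ² with dof equal to the
number of binned time points — parameters are *not* subtracted by default,
following the definition used for this statistic, but a `subtract_params`
argument exposes the textbook alternative. Zero-σ bins are excluded with a
warning.

The optogenetic summary (R_multiple⁺ − R_multiple⁻)/(R_total⁺ − R_total⁻)
subtracts the retinal(−) response rates to isolate the light-specific
component; a non-positive denominator (no light-specific responders) is an
error, not a number.

## Fluorescence conditioning and wavelet spectra

Traces (1 frame/s, 540 s spontaneous window before two food-cue-removal
verification cycles) are smoothed with a Gaussian kernel (sd 1 s,
truncated at ±4 sd, reflect boundary), min/max-normalized to [0, 1], and
differentiated as (F(tₙ) − F(tₙ₋₁))/(2Δt). Note the factor: a one-frame
difference over *twice* the frame interval halves true slopes. It is kept
exactly as defined because every detection threshold (cue response > 0.05
within ±5 s; onset > 0.15 once or > 0.05 twice consecutively, with onset
assigned to the second frame of the pair) is calibrated on that same
scale; "fixing" the derivative would silently double the effective
thresholds.

The wavelet family is φ(t, f) = √(π/σ)·e^(−t²/2σ²)·e^(i2πft) with
σ = ξ/(2πf) and ξ = 4 — about two oscillation periods under the envelope,
a compromise between temporal localization and frequency resolution. The
1/√σ normalization makes ∫|φ|²dt = π^{3/2} at every frequency, so
amplitudes are comparable across the 0.01–0.2 Hz band. The grid is 100
log-spaced frequencies (log spacing matches the constant-Q family).
Implementation: direct FFT convolution with the kernel truncated at ±4σ,
after removing the signal mean and reflect-padding one full signal length
per side. One analytic consequence of this normalization worth knowing:
for a pure oscillation at f₀ the continuous-frequency amplitude argmax
sits at f₀·(1 − 1/(2ξ²)) ≈ 3% below f₀ — about one step of the default
grid. Peak-frequency readouts are therefore accurate to one grid step by
construction, not better.

Per-animal spectra are |W| time-averaged from spontaneous-activity onset
to the end of the 540 s window; animals without onset get weight zero.
Genotype spectra weight each animal by its active fraction. The two-group
comparison draws, for each of n_boot = 10⁴ iterations, a with-replacement
resample of the pooled animals, randomly re-splits it into the two group
sizes, and recomputes the weighted-mean difference per frequency; the
two-sided p is (1 + #{|null| ≥ |observed|})/(n_boot + 1). Per-frequency
tests are unadjusted (pointwise shading at α = 0.05 is the convention this
follows); a `family_wise` flag switches to a max-statistic null. Measured
on independent-amplitude null ensembles, the false-positive rate is
slightly conservative (≈ 0.044 at α = 0.05), as expected from the +1
correction and the bootstrap's mild variance inflation.

Cross-correlation scans integer lags within ±30 s; positive lag means
channel A leads. The motion/calcium association smooths position at 3 s
and calcium at 1.5 s, normalizes calcium to unit variance, segments
high/low episodes at derivative crossings of ±0.1 (an episode starts at an
upward crossing and ends at the next downward one; partial first/last
episodes are kept if ≥ 3 frames), assigns each episode
forward/backward by the sign of its net position change, and reports
Pearson's φ of the 2×2 table.

## Expression enrichment

Fold-enrichment tables are rank-transformed per cell type (highest FE =
rank 1, ties averaged). At each mouse cutoff, a gene belongs to a cell
type's set only if it clears the cutoff there and nowhere else
(specificity rule). The enrichment score for a worm gene set is
(fraction of set genes with ≥ 1 ortholog on the mouse list) /
(same fraction over the whole worm universe); both fractions condition on
having a mouse ortholog at all, so unmapped genes cancel from numerator
and denominator alike. "Any ortholog counts" uses the union of
least-diverged and other ortholog classes. Cells with no mapped genes are
flagged undefined rather than zero. The association score normalizes each
cutoff pair's scores by their across-cell-type mean (the expected value
under no cell-type specificity, in the observed/expected sense of a
contingency analysis) and averages over the grid; a `reciprocal` flag
reports expected/observed for users who prefer the inverse orientation.

## Synthetic data: what it emulates, what it does not

All generators are deterministic given config + seed.

**Tracks.** The binary forward/backward alternation is sampled *directly*
from the planted hazards — per-step reversal probability
1 − e^(−r(iΔt)Δt) during forward periods, constant backward→forward
hazard — so the forward-period duration law is the discrete closed form
exactly, and the survival estimator can be validated against it
(Dvoretzky–Kiefer–Wolfowitz bounds). Turn states are then overlaid inside
forward periods without changing their durations: an omega-turn prefix
after half of the reversals (geometric length, always leaving at least one
crawl frame before the next reversal) and occasional forward-turn runs
strictly between crawl frames — the overlay never produces a state
sequence that is illegal under the model's transition topology.
Kinematics: crawl speed 0.25 mm/s along a diffusing heading
(sd 0.15 rad/√s), reversed during backward bouts; omega turns end in a
near-180° heading flip; relative elongation 𝒩(1, 0.075) while crawling
and 𝒩(0.6, 0.075) while turning (the turn elongation level is a free
parameter — only "less than one" is constrained); centroid jitter
0.005 mm; raw axis signs flip randomly (p = 0.02/frame) to exercise the
continuity repair. Default conditions are a 30 min movie at 2 fps,
20 worms, r₀ = 0.02 s⁻¹, δl = ln 2 (RI = 1, the repetitive phenotype the
index exists to detect), τ = 20 s, mean backward duration 2 s. Track-loss
censoring (`lost_rate`) is available but off by default. Not emulated:
body-shape imagery, pauses as a distinct behavioral state, inter-worm
collisions, pharmacology or optogenetic light delivery.

**Traces.** Glutamate transients are difference-of-exponential kernels at
event times (periodic with jitter, or Poisson); calcium follows with a lag
(`glu_lead`, default 2 s) and slower kernel; baselines are flat before
onset; each cue removal adds one response transient; Gaussian sensor
noise on top. The kernel shape is a modeling convenience — any smooth
transient would serve — chosen for its two interpretable time constants.
The 540 s `record_duration` is the spontaneous window; the trace extends
past it through the cue-removal cycles (defaults at 560 s and 600 s),
matching the recording protocol in which the cue cycles follow the
spontaneous period. Not emulated: bleaching, motion artifacts, sensor
nonlinearity.

**Motion/calcium.** Alternating high/low calcium episodes (smoothed square
wave plus noise) with per-episode net head displacement whose sign agrees
with the state with probability (1 + φ_target)/2, planting an expected phi
of φ_target.

**Expression.** Poisson ortholog counts per worm gene; a planted worm-
enriched set; in the target cell type, orthologs of worm-enriched genes
are enriched with probability `association_strength` while everything else
(all genes in other cell types, non-ortholog genes in the target) is
enriched at the background rate — so strength equal to background means no
signal at all, and the two parameters are directly comparable.

Because the generators share the analysis model's own structure (matched
emissions, exact hazard law), passing tests demonstrate correctness of the
inference machinery and estimator arithmetic — not robustness to the model
mismatch of real movies (shape-estimation noise, pauses, collisions,
non-stationary speeds). That caveat applies to every recovery number the
suite reports.

## Problem sizes used in the validation suite

The standing test suite runs the full chain at movie scale: RI recovery
uses nine cohorts of 20 worms × 30 min at 2 fps (three per planted RI in
{0, 0.5, 1}); forward–backward is checked against exhaustive enumeration
on ≤ 6-frame tracks; transition-matrix recovery uses 10⁵ frames; χ²
calibration uses 10⁴ replicates at 20 bins; permutation-test calibration
uses 100 replicate null comparisons at 25 frequencies with 2000 bootstrap
iterations each (the library default remains 10⁴); enrichment checks span
20 generator seeds. These sizes give each stochastic check comfortable
margins relative to its tolerance while keeping the whole suite around a
minute on one core.

## Known limitations

- The HMM decoder still merges a small fraction of one-frame bouts, which
  biases recovered RI slightly downward (≈ 0.05–0.1 at RI = 1 under the
  default conditions); the effect is visible in the recovery tests'
  planted-vs-estimated margins.
- Survival-fit standard errors ignore the serial correlation of
  product-limit points; use across-cohort spread for honest uncertainty.
- The bootstrap-permutation comparison assumes exchangeable animals under
  the null; strong weight heterogeneity between groups would distort it.
- Association scores at the highest cutoff pairs rest on small gene
  counts and are noisy; the per-cell-type mean over the grid damps but
  does not remove this.
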