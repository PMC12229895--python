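# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices made where the design was genuinely
open, and what the synthetic cohorts can and cannot show about real data.

## Trial amplitudes and responsiveness

Raw traces are converted to ΔF/F with `F_corr = F_soma − r·F_neuropil`
(contamination ratio `r ∈ [0,1]`, default 0.7) and a rolling rank-order
baseline: `F0(t)` is the 30th percentile of `F_corr` over the 201-frame
window centred on `t` (100 frames before and after). At the trace edges the
window is truncated to the available frames rather than padded. Frames with
`F0 ≤ 0` are flagged invalid and masked (NaN), never propagated.

At the 5-Hz frame rate one frame spans 200 ms, so "two frames" cover
400 ms. The evoked amplitude of a trial with onset frame `i` is
`mean(dff[i+1], dff[i+2]) − mean(dff[i−2], dff[i−1])` (post window
200–400 ms minus the prestimulus window). The paired null observation — the
"prestimulus spontaneous amplitude" — is computed with the identical
statistic on the window ending at the onset, so evoked and null values have
the same sampling distribution when no stimulus is present. Prestimulus
nulls are paired with trials in acquisition order.

Responsiveness per neuron and session: a two-sided Wilcoxon signed-rank
test of the 10 evoked amplitudes against the 10 paired baselines, per
stimulus; Benjamini–Hochberg adjustment across the neuron's 34-stimulus
family; responsive ⇔ any adjusted value < 0.05. Conventions that matter:

- Exact null distribution of the positive-rank sum (dynamic-programming
  table over the 2ⁿ sign patterns) for n ≤ 15 usable differences; normal
  approximation with continuity and tie corrections above, or when |d| ties
  make the exact table invalid. Zero differences are discarded before
  ranking; this sets the attainable minimal p (2/2¹⁰ ≈ 0.00195 for n = 10),
  which in turn means a *single* minimally significant stimulus never
  survives the BH(34) family (q = 0.0664) while three do (q = 0.0221). The
  exact path is verified against full enumeration and `scipy.stats.wilcoxon`
  in the tests.
- Two-sided testing is an assumption (the direction convention of the
  original analysis is not stated); the discreteness argument above is
  unchanged for one-sided tests up to a factor 2.
- Stimuli with fewer than 5 valid paired trials are excluded from the BH
  family; a neuron whose usable differences are all zero gets p = 1.
- The best stimulus is the arg-max of the trial-mean amplitude **over the
  significant stimuli only**; its amplitude is binned into the four
  categories [0,15), [15,25), [25,55), [55,1000) %ΔF/F (left-closed,
  right-open; values ≥1000 clamp into the top bin with a warning, negative
  significant amplitudes fall in bin 1).

## Tuning statistics

*Split-half reliability.* Trials are split 5+5 per stimulus (stratified, so
both half-mean curves cover all 34 stimuli — the natural reading of "half
of the trials" that avoids empty cells), the Pearson correlation of the two
half-mean curves is computed, and the value is averaged over 10 seeded
pseudorandom splits. Across-day variants draw one independent half from
each session. Splits with a zero-variance half are skipped; a neuron with
no valid split gets NaN. For half-means of 5 trials the expectation is the
attenuation `σ_s²/(σ_s² + σ_n²/5)`, which the calibration tests reproduce
to < 0.01 (the residual is the finite-sample Pearson bias at 34 points).

*Tuning width.* Curves are sorted descending and divided by the peak; the
width statistic is the normalised amplitude at sorted rank 15 (0 = one-hot,
1 = flat; invariant to amplitude scaling). Neurons with non-positive peaks
are excluded.

*Signal correlations.* Pearson correlations of trial-averaged curves for
all unordered pairs of responsive neurons within one FOV (never across
FOVs). A pair's amplitude bin is the bin of the mean of the two best
amplitudes; constant curves are excluded from pairing and counted.

*Reference profiles.* Correlations of each spared neuron's tuning to every
frozen day-5 reference (high-category) curve are pooled pair-wise, split by
day-5 responsiveness group (R5 = responsive on day 5; G = unresponsive on
day 5 but responsive on some other day — a partition), binned from −0.6 to
1.0 in steps of 0.2, normalised within group × day, and baseline-subtracted
(mean of days 1 and 3). The default includes all spared neurons regardless
of current-day responsiveness, with a `responsive_only` switch for the
stricter variant.

*Drift retention estimator.* For adjacent 2-day session pairs, the cross-day
correlation of trial-mean curves (neurons responsive on both days) is
divided by the geometric mean of the two sessions' Spearman–Brown-corrected
split-half reliabilities; the pooled mean of the corrected ratios estimates
the per-2-day retention ρ. The estimator carries a small negative bias
(≈0.015 at ρ = 0.85) from the exponential tuning nonlinearity, well inside
the ±0.05 recovery tolerance.

## Representational maps

Single-trial similarity: element (s₁,s₂) is the mean Pearson correlation
over all pairs of single-trial population vectors, excluding identical-trial
pairings on the diagonal (45 pairs per diagonal element and 100 per
off-diagonal element at T = 10); the diagonal is therefore the
trial-to-trial reliability of the population response. Trial-averaged
similarity correlates trial-mean vectors (unit diagonal). Zero-variance
vectors are excluded from the elements they would enter. Grand averages are
elementwise means across FOVs; the off-diagonal mean counts each unordered
stimulus pair once; normalised summaries divide by the mean over the
baseline days {1,3,5} (configurable — pre-ablation figures use {1,3,5},
the reference-profile baseline is {1,3}).

Classical (Torgerson) MDS double-centres the squared dissimilarity
(1 − r)² and takes the top positive eigencomponents; coordinates are
defined up to rotation/reflection and negative eigenvalues are reported as
a non-Euclideanity diagnostic. The implementation is ~15 lines and is
cross-checked against `skbio`'s PCoA in the tests.

Pairwise decoding: a linear-kernel SVM (C = 1, not stated in the original
description and therefore fixed and recorded here) per stimulus pair on the
2×10 population vectors, stratified fivefold cross-validation so each trial
is tested exactly once. Cross-day decoding trains on the training day's
fold-train trials and tests the matching fold-test trials of the test day
(fold-respecting protocol), restricted to neurons present on both days so
dimensionality matches.

## Ablation design

Targets are selected from the two pre-ablation baselines (days 3 and 5):

- *responsive*: per day, each responsive neuron's amplitude is its mean
  over significant stimuli; the two days' descending distributions are
  merged, sorted by amplitude, and deduplicated keeping the higher-ranked
  entry — equivalently each neuron enters at the larger of its two day
  amplitudes (the merge key is ambiguous in the original description; this
  reading is implemented and the dedup is oracle-tested). Ties break by
  neuron id so selection is deterministic and order-independent.
- *nonresponsive*: neurons responsive on neither day, ranked per day by
  absolute mean amplitude ascending; the two ranks are averaged and the
  smallest average ranks are targeted.
- *inhibitory*: responsive interneurons by the responsive-mode criterion,
  topped up with non-significant interneurons of largest mean evoked
  amplitude (averaged over both days).

Ineligible neurons (occluded nuclei etc., a simulator flag) are skipped
with a recorded reason; 4–8 targets per FOV are requested and shortfalls
warn. High-category neurons are the 5 top-ranked responsive neurons per FOV
(excluding ablated interneurons in the inhibitory cohort); low-category the
5 minimal-|amplitude| nonresponsive ones. Digital exclusions per cohort:
responsive ablation filters low-category, nonresponsive and inhibitory
ablation filter high-category, control filters both.

The spared mask excludes every targeted neuron (successful ablation or
not — unclear ablations show abnormal signals, so exclusion spheres are
centred on all targets), every neuron within 15 µm (boundary inclusive:
exactly 15 µm is excluded, "within a sphere of radius 15 µm"), the
applicable category sets, and neurons with missing positions
(conservatively). Each neuron records one primary reason in that priority
order.

## Perturbation inference

*Cohort permutation test.* Mouse-level statistics, difference of cohort
means, 200 label permutations, two-sided by absolute value, add-one
smoothing `p = (1 + #extreme)/(n+1)`. The add-one smoothing makes the test
slightly conservative; calibration on null simulations stays within 2.5
percentage points of the nominal 5% level.

*FOV-shuffle null.* Trial-averaged tuning curves of responsive neurons are
pooled and randomly reassigned to pseudo-FOVs of the original sizes
(single-neuron properties preserved exactly; only the grouping changes);
per draw the across-FOV mean of the off-diagonal similarity mean is
recorded, 500 draws, 95% envelope from the 2.5/97.5 percentiles. With no
FOV-shared tuning the observed value falls inside the envelope at the
nominal rate; with shared structure the observed value exceeds the shuffled
mean because reassignment mixes FOVs with different stimulus preferences.

*Width-scaling simulation.* Each neuron's descending-sorted curve is
replaced by its own peak times a target sorted-normalised profile (its
bin's profile), written back in the neuron's own stimulus order — best
stimulus and best amplitude are preserved exactly. When the target equals a
neuron's own profile the curve is unchanged to machine precision, so
identity scaling is inert; imposing a pointwise-narrower profile lowers the
trial-averaged off-diagonal mean and a flat profile raises it toward 1.

*Stability overlap.* Fraction of neurons responsive on both of two adjacent
sessions, with the union of the two responsive sets as the default
denominator (Jaccard); `first` and `total` denominators are available
because the original definition does not fix one.

*Spatial profile.* Distance is 3-D Euclidean to the nearest targeted
neuron; effects are averaged per distance bin; empty bins are missing, not
zero.

*E/I balance.* Per class, total response = responsive fraction × mean best
amplitude; balance = `E/(E+I)`; missing when a class is absent or both
totals vanish.

## The synthetic cohort generator

Per FOV, `k = 5` latent stimulus factors `M` (k × 34) are drawn; neuron `n`
has static loadings `v_n = (2·1 + u_n)/√5` (a common mean — the FOV's own
stimulus preference — plus idiosyncratic diversity) and a latent tuning
field `g = √c · v_n M_d /√k + √(1−c) · e_nd` with `c = 0.3`. Both `M` and
the private fields `e` evolve as stationary AR(1) processes on an internal
2-day grid with per-step retention ρ (default 0.85); the 4-day gap between
days 11 and 15 counts as two steps. Cross-day field correlation is
therefore ρ^lag, symmetric in the lag. The common-loading structure is what
gives within-FOV co-tuning that FOV-shuffling destroys (reassignment mixes
FOVs with different preferences, diluting the off-diagonal mean); purely
neuron-independent stimulus covariance would leave the shuffle null
centred on the observed value.

The noiseless tuning curve is `amp_n · exp(β(g − max g))` when the neuron's
responsiveness state is on, zero otherwise; β = 0.5 puts the mean
15th-stimulus width near 0.4, and interneurons divide β by 1.8 (broader
tuning). Responsiveness follows a two-state Markov chain with stationary
probability 0.12 and drop rate 0.3 per 2-day step (gain rate derived from
stationarity), giving a consecutive-day overlap near 0.45 and a measured
responsive fraction of 10–12% after classification attenuation. Amplitudes
are log-normal with (μ, σ) = (3.357, 0.963) on ln %ΔF/F, fixed analytically
so the distribution's quartiles match the printed bin edges (15 and 55
%ΔF/F) and the four bins hold roughly a quarter of responsive neurons
each. Trial amplitudes add i.i.d. Gaussian noise (σ = 5 %ΔF/F); prestimulus
baselines are zero-mean draws of the same noise. Positions are uniform in a
367 × 367 × 200 µm slab; a 2% per-day quality-gate dropout and a 5% target
ineligibility rate exercise the masking paths. All randomness derives from
one seed through named streams (per FOV and purpose), so subsetting a
cohort reproduces the remaining draws bit-exactly.

### Ablation effects

Effects apply only after day 6, relax as `exp(−(d−7)/τ)` with
`recovery_tau_days` (default 2), and can decay spatially as
`exp(−distance/spatial_scale_um)` from the nearest target:

- `reliability_dip` δ: trial noise is multiplied by `1/(1−δ·w(d))` — a
  fractional drop in trial SNR of δ on day 7.
- `narrowing_factor` ν: day-5-responsive spared neurons' peak-normalised
  curves are raised to the power `1 + ν·w(d)` (tails compressed, peak and
  best amplitude preserved).
- `gain_boost`: the Markov gain rate of spared neurons is multiplied by
  `1 + boost·amp_weight` for all post-ablation steps (a persistent
  recruitment pressure, not a transient), with `amp_weight` the neuron's
  amplitude relative to the FOV median, capped at 4 — recruitment favours
  strong responders, so the responsive pool's mean amplitude rises with a
  delay as gained neurons accumulate.
- `gain_alignment` a: gained neurons' post-ablation fields become
  `a·ĝ_ref + √(1−a²)·g_own`, with `ĝ_ref` the normalised mean day-5 field
  of the ablated targets.
- `ei_shift` e: spared excitatory amplitudes ×(1+e·w), inhibitory ×(1−e·w).

Injection recomposes amplitudes from the stored simulation state plus the
dataset's own noise residuals, so the null intervention (all parameters 0)
returns bit-identical data, and the chain rerun is coupled through the
stored uniforms (monotone in the gain rate).

The *demonstration condition* used by the analysis drivers and the
phenocopy checks is δ = 0.5, ν = 0.8, boost = 0.15, a = 0.6, e = 0.2,
τ = 1.5 d. The in vivo effect sizes are figure-normalised and not printed,
so these magnitudes are illustrative: δ and τ are set so the day-7 drop is
unambiguous and recovery completes by day 9–11 ("within 3 days"); the
boost and alignment are set from the analytic expectations above so that
recruitment produces a delayed amplitude rise and correlated gained
neurons without overwhelming the day-7 disturbance. Effects are applied to
the responsive-ablation cohort only; nonresponsive and inhibitory cohorts
are simulated as null interventions, matching the observation that removing
weak or inhibitory units leaves the spared network's map intact.

### What the generator does and does not emulate

It reproduces the *statistical* structure the estimators assume: trial
counts and session layout, responsive fractions, amplitude-bin occupancy,
symmetric tuning drift, within-FOV co-tuning, detection attenuation, and
parameterised perturbation phenomenology with ground truth. It does not
model calcium-indicator kinetics, spikes, tonotopic spatial gradients
(positions are independent of tuning), noise correlations, or behavioural
state; passing tests therefore validate the estimators and inference
machinery, not any biological claim about the real recordings. One known
departure: with persistent recruitment and alignment the simulated map
overshoots baseline at late days, whereas the recorded maps plateau — the
phenocopy checks target the disturbance-and-recovery window (days 7–9).

## Problem sizes and determinism

The analysis drivers and reference computations run on scaled-down cohorts
chosen as the package's default study size: 4 mice × 3 FOVs × ~150 neurons
per cohort for the drivers, 6 mice per cohort for the phenocopy statistics
(the permutation test needs ≥5 mice per group for useful resolution), 600
null simulations for permutation calibration and 300 for shuffle coverage,
and 10,000 split repetitions for the reliability calibration. Every
stochastic step takes an explicit seed; the acceptance script threads its
`--seed` through all of them.

## Known limitations

- The exact signed-rank path assumes continuous data; heavy ties fall back
  to the normal approximation (correct, but with a different minimal p).
- Baseline-normalised map summaries are sensitive to the category-exclusion
  step at small FOV counts (removing the top-5 baseline responders
  suppresses baseline-day correlations relative to other days); cohort
  comparisons difference this artifact out, absolute normalised levels
  should be read with care.
- The drift-retention estimator assumes reliability-based attenuation
  correction is exact; its small model bias is documented above.
- `pairwise_decode` fits one SVM per fold and pair; all 561 pairs × many
  FOVs is deliberately not the default (drivers use random pair subsets).
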