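# Methods

## The problem this package addresses

A cohort of larval zebrafish is shown a repeated sequence of drifting
sinusoidal gratings while calcium activity is recorded across the optic
tectum. Development that is strongly *canalized* produces individuals
whose evoked population dynamics are nearly interchangeable; mutations
that *decanalize* development produce individuals that each respond
reliably but differ stochastically from one another. canaldyn turns
per-neuron ΔF/F traces into a small set of latent time courses per
individual, places those time courses in a common order and sign across
individuals, and summarizes canalization as distributions of Pearson
correlations — within individuals (across trials), between individuals and
a group average, and between all pairs within a group. A synthetic-cohort
generator supplies data with the same statistical structure so that every
stage is testable without raw recordings.

## Stimulation protocol

The default protocol presents 12 grating directions at 30° steps, each 5 s
on followed by 10 s of gray, giving a 180 s trial; the sequence is
repeated three times with 50 s of gray between trials after a 45 s gray
lead-in, for a 735 s timeline sampled at 1 Hz. The published trial
structure (3 × 180 s, 50 s between presentations) leaves 95 s of the 735 s
timeline unaccounted for; we allocate 45 s to an initial lead-in and a
50 s gray period after the final trial, which reproduces the total exactly
while keeping the printed trial structure. All five timing parameters are
configurable, and the reconstruction matters to nothing downstream: trial
averaging only indexes the three trial windows. Sample indices are 0-based
with half-open windows so stimulus and gap windows tile each trial without
overlap; a `stim_first` flag supports gap-first dialects.

## Synthetic cohorts

The generator's defaults are the study conditions used throughout the
tests: 9 fish × 250 neurons per cohort, class fractions 0.30 direction- /
0.30 orientation-selective / 0.40 unresponsive, von Mises concentrations
κ ∈ [2, 8], peak response amplitudes ∈ [0.5, 1.5] ΔF/F, baselines
∈ [0.05, 0.15], trial noise at 10% of each neuron's signal SD. Tuned
fractions in the tectum are not established quantities; the 0.3/0.3/0.4
split is a generator choice giving a realistic mix of cell classes, made
once and not revisited.

Evoked drive follows a von Mises tuning curve with period 360°
(direction cells) or 180° (orientation cells), held constant during each
stimulus-on window and zero otherwise; angle differences are reduced
modulo the period in degrees before the cosine so that probes exactly one
period apart produce bit-identical drives. "Untuned" cells carry no evoked
drive — their trace is a flat baseline — which makes them exactly the
population the responsiveness filter removes. The drive is low-pass
filtered by a causal exponential calcium kernel (τ = 1.5 s, unit peak,
slow nuclear-indicator regime at 1 Hz sampling) **truncated at the
gray-gap length** (support = gap + 1 samples). At τ = 1.5 s against a 10 s
gap the truncation discards under 0.2% of the kernel mass; in exchange,
every direction slot's measured response depends only on its own and the
immediately preceding slot's drive, so tuning curves with exact angular
symmetries stay exactly symmetric after filtering (a noiseless
orientation cell's DSI is exactly 0, not 1e-15). Noise is iid Gaussian per
sample with SD equal to `trial_noise_sd` × the neuron's noiseless signal
SD; no autocorrelation structure is modelled (an AR(1) hook would slot
into `simulate_individual` if needed).

Decanalization is a single knob, σ_d (degrees): each individual perturbs
the shared blueprint by preferred-angle jitter ~ Normal(0, σ_d) and an
amplitude multiplier ~ LogNormal(0, σ_d/100). σ_d = 0 reproduces identical
individuals up to imaging noise. Cohort seed `s` draws the blueprint;
individual *i* uses generator seed `s + 1 + i` (the offset keeps fish 0's
stream distinct from the blueprint stream), so cohorts are bit-reproducible
and extendable fish by fish.

What the generator does *not* emulate: spatial structure and segmentation
artifacts, spike-to-fluorescence nonlinearity, slow drift, correlated
(shared) noise across neurons, adaptation across trials, and
between-individual differences in neuron count. Passing tests therefore
demonstrate that the statistics behave correctly on data with the assumed
structure, not that real recordings satisfy those assumptions.

## Responsiveness filter and trial averaging

The inclusion rule — keep cells responsive in each of the three trials —
is not operationalized in the source description (segmentation software
applies its own internal criteria upstream). Our stand-in: a neuron passes
a trial if at least one direction's stimulus-window mean strictly exceeds
the trial's gray-gap mean plus `z_thresh` (default 3) gap SDs, with the
baseline taken from that trial's own within-trial gaps so the rule is
trial-local; a neuron is retained only if it passes every trial. The rule
is idempotent and order-preserving. Trial averaging is the per-sample mean
across the protocol's trial windows.

## Latent dynamics

PCA is fit per individual on the trial average with time samples as
observations and neurons as variables, after per-neuron mean centering
only — ΔF/F is already a normalized unit and no z-scoring is prescribed,
so none is applied. The analysis keeps k = 5 modes by default
(configurable); the full variance spectrum is retained for diagnostics.
Per-trial latent dynamics are obtained by projecting each trial block onto
the trial-averaged model's loadings (centering with the model's means).
The alternative — separate PCA per trial followed by alignment — is
equally consistent with the source description; projection keeps trials in
a common basis without extra alignment steps and is what we implement.

### Cross-individual alignment

Modes fitted per individual differ in order (variance ranking varies
between fish) and sign (PCA sign is arbitrary). Alignment to a reference
solves the optimal assignment maximizing Σ_m |r(target_perm(m), ref_m)| on
the 5 × 5 absolute-correlation matrix (Hungarian algorithm; deterministic,
and verified exact against brute-force enumeration of all 120 × 32
order/sign combinations), then flips each matched mode to the sign of its
correlation (zero-variance modes get r = 0 with a warning, sign +1).
Cohorts are put in canonical order by a two-pass procedure: align all
individuals to a seed individual (lowest sorted fish id by default, since
no natural first reference exists), average the aligned dynamics, then
re-align everyone to that average. Comparison groups are aligned to the
control group's canonical reference, and their within-group pairwise
correlations use those same aligned modes.

## Stereotypy statistics

All statistics are Pearson correlations of full trial-length mode time
courses (180 samples; no detrending or smoothing). Zero-variance time
courses yield r = 0 with a warning rather than an exception so cohort
summaries stay total.

* **Trial-to-trial**: per mode, the mean of the three pairwise inter-trial
  correlations of single-trial dynamics (general n supported).
* **Reference correlations**: each control individual vs the leave-one-out
  average of the other controls; each comparison-group individual vs the
  full control average.
* **Within-group pairwise**: all C(n, 2) correlations per mode.
* **Group averages**: modes averaged within each group, correlated per
  mode across groups.
* **Pooled distribution**: all pairwise correlations pooled across the
  five modes, with a right-continuous ECDF.

## Tuning statistics

Per-direction amplitudes F(θ) are the stimulus-window mean minus a
baseline, rectified at zero. The baseline is the *later half* of the gray
gap preceding that direction's grating (early gap samples still carry
indicator decay from the previous response, which otherwise biases the
peak direction near bin boundaries); for the trial-opening direction the
baseline wraps to the trial's final gap. Differences below numerical
precision are snapped to zero before rectification so a constant trace
yields F ≡ 0 exactly.

OSI = (F_pref − F_orth)/(F_pref + F_orth) with F_pref the maximum over the
12 directions (ties to the lowest index) and F_orth the mean of the
responses at +90° and −90° from preferred — the symmetric choice; a
singular +90°-only variant is available via `orthogonal_mode="plus"`.
DSI = (F_pref − F_opp)/(F_pref + F_opp) with F_opp the response at 180°.
Rectification keeps both indices in [0, 1]. All-zero response vectors give
missing values rather than errors. The preferred direction is the circular
vector average arg Σ F(θ)e^{iθ} with mean resultant length |Σ F e^{iθ}|/ΣF;
antipodal cancellation (resultant ≈ 0) is reported missing. A neuron is
direction selective when DSI strictly exceeds 1/3 — the threshold is
stored as exactly 1/3 (the F_pref = 2·F_opp boundary), so a boundary cell
is excluded under the strict inequality. Polar histograms assign each
selective cell's preferred direction to the nearest stimulus direction
(30° bins centered on the stimulus angles).

## Hypothesis tests

* **Dunnett's many-to-one test** (two-sided, family-wise error controlled)
  compares treatment-group means against the control; backed by scipy.
* **Dunn's post-hoc test** is written in-house (no installed
  implementation): joint ranking, tie-corrected pairwise z statistics,
  Bonferroni adjustment by default (the most common convention); with two
  tie-free groups it reduces exactly to the Wilcoxon rank-sum normal
  statistic, which the tests verify in closed form.
* **Watson's two-sample U²** for circular distributions is computed from
  the combined sorted sample's ECDF differences, centered so the statistic
  is invariant to the circular origin. The primary p-value is a
  label-permutation p (vectorized, seeded, (1 + #{≥ observed})/(R + 1));
  the asymptotic series tail probability 2Σ(−1)^{k−1}exp(−2k²π²U²) is
  reported alongside.

All permutation p-values are reproducible under a fixed seed, and both
tests' empirical type-I error is checked against the binomial 95% interval
around α = 0.05 on simulated nulls.

## Problem sizes and numerical choices

The test and acceptance workloads use the generator defaults — cohorts of
9 fish × 250 neurons under the 735 s protocol, decanalization grids
σ_d ∈ {0, 15, 30}°, 10-individual replicates for variance summaries,
200-replicate null calibrations with 199 permutations each — sizes at
which every statistic is stable yet the whole suite runs in well under a
minute. Orthonormality of loadings is enforced to 1e-8, the
variance-accounting (Pythagoras) identity to 1e-6, assignment ties break
to the lowest permutation index, and degenerate inputs (zero-variance
modes, all-zero tuning vectors, empty histograms) are flagged rather than
fatal.

## Known limitations

* The responsiveness rule stands in for unpublished segmentation-internal
  criteria; the retained-cell set on real data would differ.
* Alignment assumes the same *kinds* of dynamics exist in all individuals;
  with fewer than k genuine covariation patterns the trailing modes match
  noise to noise and their correlations are uninformative (they are
  flagged only when variance is exactly zero).
* Pearson correlation on 180-sample time courses treats all timepoints
  equally; stimulus-locked and gap portions are not weighted separately.
* The Dunn and Watson implementations target the sizes used here (tens to
  hundreds of values per group); no continuity corrections or exact
  small-sample tables are included.
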