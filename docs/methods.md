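# Methods

This note documents the models, parameter choices and numerical decisions
behind `densnav`, in the spirit of a simulation appendix: what each stage
assumes, what the synthetic data do and do not emulate, and where the
design was genuinely open.

## Stimulus model

Spectral density is the number of simultaneous random-frequency pure tones
in a 190-ms stack (2-ms raised-cosine on/off ramps, 10 ms of silence after
each stack, so a series advances at 5 stacks/s).  Densities live on a
26-level grid spanning 2–196 tones.  The grid is geometric —
`2*(98)**(i/25)` — rounded to integers; at the sparse end rounding
collides (the second point rounds back to 2), and collisions are resolved
by bumping to the next unused integer, which keeps the endpoints exact and
strict monotonicity at the cost of slightly compressed spacing over the
first ~10 levels.  Tone frequencies are i.i.d. log-uniform on
250–4000 Hz, redrawn for every stack so the fine spectrum carries no
density information.  Component phases are uniform random to avoid onset
artifacts.  All stacks are scaled to a common RMS (computed over the full
stack including ramps; the ramps are 2% of the duration so this choice is
immaterial at the 1% equality tolerance).  The default RMS target of 0.04
keeps even the densest stacks, whose crest factor approaches
`sqrt(2N) ~ 20`, below full scale; a uniform peak rescale to 0.9 is
applied at WAV-write time only if needed, preserving relative RMS.
Spoken digits are represented by event metadata (value 1–10, voice tag,
onset, duration ≤ 0.4 s); audio re-synthesis of speech is out of scope.

## Experimental schedule

Four conditions cross memory (M/N) with adjustment (A/P).  A trial is:
2 s instructions (silence), 2 s of ten stacks (constant at the target for
M trials; alternating between the scale extremes as an ignored dummy for
N trials), 1–3 s silence (uniform; the maintenance interval), 8 s of 40
stacks plus 1–6 spoken digits, a 3-s rating window, and a 0–2 s ITI.
Digits occupy integer-second slots 2–7 of the 8-s phase, leaving its first
and last second free.

Each run holds 28 trials in seven sets of four (one per condition), with
MA before NA and MP before NP within a set and no condition repeated
back-to-back; orderings are rejection-sampled per set.  Starts and targets
are dealt from a shuffled set of 28 (start, target) pairs.  The pair set
is not published, so we construct one consistent instantiation: targets
stratified into quartiles nested in the two halves of the scale (7 per
quartile, hence exactly half low/half high), 14 upward and 14 downward
trajectories, each at least 5 scale steps long; lowest-quartile targets
are approached from above and highest from below (shorter approaches do
not exist there), the middle quartiles sharing the remaining directions at
random.

Yoking matches acoustics and motor demands across the task factor: each
MP/NP trial's 40-stack series copies the most recent MA/NA series, and
each MA/NA trial's (ignored) digits copy the most recent MP/NP digits.  A
seeded dummy trial bootstraps each stream at the start of a block — for
digits as specified, and, by extension, for the series when an MP/NP
happens to precede any same-stream A trial (the ordering constraints do
not preclude this).  After yoking, a P trial's start level is the copied
series' first level.

The digit count of a parity trial is the previous adjustment trial's count
plus the mean number of unanswered digits over all previous parity trials
of the block (0.5 when none exist), stochastically rounded, clamped to
1–6.  Note this rule is a ratchet: counts only grow through missed digits,
and a low dummy bootstrap can lock a block at one digit per trial.  That
is a faithful consequence of the rule, not a bug; sessions simulated with
the default ~8% miss rate typically settle between 2 and 6.

Runs serialize to BIDS-style tab-separated event tables (one row per
stack, digit, phase, press, response) and reload losslessly; the `NA`
condition code requires disabling pandas' default NA parsing.

## Observers

All observer quantities live in log2-density units, because density
discrimination is Weber-like: JNDs grow roughly proportionally with
density (this is also why the stimulus grid is logarithmic).

**Discrimination.**  A two-interval comparison is modelled as
signal detection with independent Gaussian noise per interval:
`P(correct) = (1-lapse)*Phi(|delta|/(sqrt(2)*sigma_log)) + lapse/2`.  The
default `sigma_log = 1.3` encodes a JND near one octave, consistent with
navigation accuracy on the 26-level scale (mean final distances of
several levels ~ one octave).

**Staircase.**  Two-down/one-up with steps of 1/3 (to the second
reversal) then 1/6 log2 units; threshold = mean of the last two of six
reversals, converted to components/octave via
`jnd = ref*(2**threshold - 1)`.  Long tracks sit at the theoretical
`sqrt(0.5) ~ 70.7%` point.  Two validity conditions matter and are part
of the default calibration: the fine step must be small relative to
`sigma_log` (the convergence analysis assumes small steps), and the
initial difference (default one octave) must lie within about a coarse
step of the threshold, else the six-reversal estimate retains a transient
bias of 1–4 percentage points.  Tracks failing to reach six reversals in
200 trials raise an error.

**Navigation agent.**  The agent stores the target as
`log2-density + N(0, memory_sigma)`, perceives the current stack with
noise `perceive_sigma`, and while the perceived distance exceeds
`stop_criterion` holds the button toward the target; each 200-ms stack
moves the density one scale level (clipped at the scale ends; the
adjustment rate is not specified in the paradigm, and one level per stack
is the simplest rule consistent with the 26-level/40-stack geometry).
Defaults (`memory_sigma 0.9`, `perceive_sigma 0.05`, `stop_criterion
0.9`) were calibrated against the reported human figures — most trials
ending closer to the target, a mean final distance near 15% of the scale,
and ~70% undershoot.  Undershoot emerges mechanistically: a conservative
stop band halts the approach on the starting side whenever the memory
error is smaller than the band.  The no-target agent presses in random
bouts matched to the running mean of the targeted agent's press-step
count.  Parity responses miss a digit with probability `miss` (default
0.08) and otherwise lapse to a uniform guess with probability `lapse`
(default 0.05).  Ratings report the truth bin (distance-to-target bins
for M trials, density quartile for N trials) through Gaussian response
noise, with occasional omissions.

None of the observer parameters are fitted to individual human data; they
are generator calibration knobs set once against the published group-level
figures.

## Synthetic BOLD

The generator produces per-subject 4D arrays on a small grid (defaults:
20x20x16 or smaller, 3-mm voxels, TR 1.056 s) with an ellipsoidal brain
mask and four disjoint blob ROIs of exactly 80 voxels each (nearest
voxels to fixed fractional centres; deterministic).  Signals are built
from the session's own event table with the same HRF and sampling code the
analysis uses:

* condition effects: whole-trial boxcars x ROI amplitude, with Gaussian
  between-subject amplitude deviations (`subject_sigma`, default 20%);
* a univariate density slope: the density modulator's component
  orthogonal to the low/high label regressors, nuisance, drift and
  constant;
* multivoxel patterns: a voxelwise pattern drawn once per cohort (shared
  across subjects — across-participant decoding needs a common voxel
  code) entering as ±pattern/2 on the high/low label contrast, scaled per
  subject by `1 + N(0, pattern_subject_sigma)` (default 0.3) so pattern
  voxels have finite between-subject variance;
* noise: stationary AR(1) (coefficient 0.3), cosine drift spanning the
  high-pass band, and a leak of the nuisance series (six motion random
  walks, a 0.25-Hz respiration sinusoid aliased to the TR grid) through
  random spatial maps.

The orthogonal construction of the two density plants deserves emphasis:
the linear density modulator and the binary label split are ~0.9
correlated, so without it each plant contaminates the other's analysis.
With it, a GLM carrying the label regressors plus a label-orthogonalized
modulator recovers the planted slope essentially exactly, and the label
contrast recovers the pattern, with cross-talk at numerical-precision
level (under OLS; AR(1) prewhitening rotates the design and would
reintroduce a small leak, so the pattern-analysis GLMs use OLS).  Real
data offer no such orthogonality — there, univariate and multivariate
density signals genuinely overlap — so passing recovery tests demonstrate
pipeline correctness, not that the two effect types are separable in
practice.

Effect amplitudes in the recovery experiments (slope −0.8 noise-SD units,
pattern SD 1.0) yield group peak t-statistics of roughly 9–27 with ten
subjects, the order of the strongest effects such paradigms report.

## Univariate GLM

The canonical HRF is the SPM-convention double gamma (peak 6 s,
undershoot 16 s, ratio 6, 32 s support), peak-normalized, cross-checked
in tests against nilearn's implementation.  Regressors are built at 16x
oversampling and sampled at volume onsets; convolved columns are not
dt-normalized, so beta units are per unit of the convolved regressor —
consistent between generator and analysis, which is what the recovery
contracts require.  Parametric modulators are centered over their events
and serially orthogonalized (Gram–Schmidt) in declared order against
their parent and earlier siblings, or against an explicitly named basis;
constant modulators are dropped with a warning.  The high-pass basis is
the DCT set with `floor(2*T*f_c)` columns (cutoff 1/230 Hz, twice the
longest same-condition trial interval).  Fitting is voxelwise OLS with
optional AR(1) prewhitening, the coefficient pooled over the mask from
first-pass residual lag-1 autocorrelation.  Rank deficiency raises with
the offending columns named.

Group inference is a voxelwise one-sample t (zero-variance voxels
masked).  Family-wise error control uses sign-flip max-|t| permutation:
the observed labelling counts as one permutation, the threshold is the
ceil((1-alpha)(B+1))-th order statistic of the max distribution, and the
observed statistic is computed through the same arithmetic as the
permuted ones so that sign patterns reproducing the data tie exactly
(this matters at small n, where the null has atoms).  Small-volume
correction reruns the identical procedure restricted to an a priori
mask; Bonferroni is available as a fast alternative.  Clusters use
6-connectivity with a configurable minimum extent (default 5 voxels).

## Searchlight crossnobis

Spheres contain all in-mask voxels within 4 mm of a centre (7 voxels in
the interior at 3-mm resolution).  Noise covariance per sphere and
subject is the sample covariance of GLM residuals with off-diagonals
shrunk toward zero — the variance-retaining Ledoit–Wolf flavour, with the
analytic Schafer–Strimmer weight (estimated sampling variance of the
off-diagonal entries over their squared sum, clipped to [0,1]).  For a
truly diagonal population the weight correctly stays near 1 at any sample
size.  Patterns are whitened by the inverse matrix square root; a
per-voxel (`diag`) variant and no whitening are available, and the
leave-one-subject-out fold distance is the normalized dot product of the
training-mean and test pattern differences.  Under label-free nulls the
fold mean is zero to Monte-Carlo precision while the naive squared
distance stays positive — the bias cross-validation removes.

Fold maps are smoothed (Gaussian, FWHM/2.3548 SD, support-renormalized at
mask edges) and passed to the same permutation machinery.  One caveat
documented from experience: with ~10 folds, smoothed t-maps peak at
variance flukes on the skirt of a true signal, so peak *localization* is
read from the fold-mean distance map (the effect-size map), while the
smoothed-t path is used for detection/thresholding.  SnPM-style variance
smoothing would be the fuller remedy.

## Problem sizes

Defaults are chosen for desk-scale runtimes: recovery experiments use a
16x16x12 grid (≈1500 brain voxels), 10 subjects, one 28-trial run each
(≈480 volumes), completing the full two-GLM + searchlight pipeline in a
few seconds per subject; null-calibration suites use 12³ grids with
directly simulated beta/residual cohorts (200 cohorts in a couple of
minutes).  All stages scale to larger grids linearly in voxel count.

## What the synthetic layer does not emulate

No scanner physics (EPI distortion, field inhomogeneity, motion beyond
nuisance series), no anatomical geometry or MNI space, no SPM "FAST"
autocorrelation model (AR(1) instead), no random-field-theory FWE
(permutation/Bonferroni instead), and no real speech audio.  Passing
tests therefore certify the statistical machinery — estimator
unbiasedness, error-rate calibration, parameter recovery under the
generator's assumptions — not robustness to the artifacts of real
acquisitions.
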