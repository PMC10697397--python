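# Methods

This note documents the models, conventions, and design choices behind the
package, in the spirit of a methods appendix: what each procedure assumes,
which knobs matter, what the synthetic generator does and does not emulate,
and where the numerically delicate spots are.

## Conventions

All times are seconds relative to stimulus onset; intervals are half-open
`[start, stop)`; frames are 0-based and sampled at the acquisition rate
(default 15 Hz).  Trial windows are fixed frame *offsets* from each trial's
start frame (stimulus `[0, 3)` s → frames 0–44 at 15 Hz), so a session whose
trial starts fall on half-frames never shifts a window's length.  Undefined
quantities (a d′ bin missing one trial type, a modulation index with an empty
group or non-positive denominator) propagate as flagged missing values with a
reason code; nothing is imputed.

## Behavioral metrics

d′ = Φ⁻¹(hit fraction) − Φ⁻¹(false-alarm fraction) with within-trial-type
fractions, Hits/(Hits+Misses) and FAs/(FAs+CRs).  An all-trial normalization
is exposed behind the `fractions` argument for comparison, but the
within-type convention is standard signal detection and is the default.
Degenerate fractions use the log-linear clip (0 → 1/(2N), 1 → 1 − 1/(2N));
without it the quantile diverges at perfect sessions, which are common in
10-trial bins.  The trial classifier counts licks in the reward window
`[2, 3)` s — the reward contingency defines the operant response — with a
`decision_window` switch for whole-stimulus licking.  The human forced-choice
d′ normalizes Right and Wrong counts by all trials including no-responses;
with the clip this stays finite even for all-NR blocks.  An optional
punish-time rule (from session 6, time-out 6.5 s → 4.5 s when misses dominate
or 9.5 s when false alarms dominate, triggered below d′ = 1) adjusts the
simulator's task clock only; no metric reads it.

## Lick decoding

Features are integer lick counts in 0.1 s bins over `[0, 1.9)` s — 19 bins,
deliberately stopping before the reward window so the decoder reads
anticipatory licking, not reward consumption.  The window is half-open: a
lick at exactly 1.9 s is excluded.  The classifier is an RBF-kernel SVC with
`gamma='scale'` (1 / (n_features × feature variance)) and C = 1; accuracy is
bootstrapped over stratified 80/20 splits, re-splitting rather than
resampling on each iteration (a with-replacement variant exists behind
`resample=True`).  Stratification matters: small sessions produce single-class
test sets under unstratified splits.  Shuffled controls permute labels
independently on every iteration; with imbalanced classes they converge to
the majority-rate accuracy, not 50%, which is why calibration checks use
balanced data.  Counts (not binary indicators) are the default features; a
`binary` switch is provided.

## Trace processing

Neuropil correction subtracts 0.7 times the surrounding neuropil signal; the
coefficient is exposed, 0.7 being the conventional choice for GCaMP imaging.
The modified Z-score standardizes the corrected fluorescence by the mean and
SD of the quietest 10 s window — the contiguous stretch minimizing the SD of
ΔF/F.  Since ΔF/F with a whole-trace-median F₀ is an affine rescaling of F,
the search runs on the corrected fluorescence directly; ties resolve to the
earliest window.  The windowed SD uses a sliding-window reduction that is
bit-identical to a per-window loop, which the test suite verifies against an
exhaustive argmin.

Event detection takes local maxima of z at or above threshold 3 separated by
at least `min_separation` frames (default 3).  For rate-recovery work a
separation of one kernel decay constant (~10 frames at 15 Hz) is more
appropriate, because a transient stays above threshold for about half a
second and noise ripples on the decay flank otherwise double-count.  Cells
with zero detected events are flagged inactive and excluded from group
summaries.

Per-window activity is the AUC rate: the frame-sum of z over the window,
divided by the frame count, multiplied by the frame rate — i.e.
mean(z) × frame rate, "Z-score of fluorescence per second" (a unit trace over
45 frames at 15 Hz gives exactly 15/s).  Note the quantity scales with the
acquisition rate by construction; the rate-free per-frame mean is what is
invariant under consistent resampling, and both facts are asserted in tests.

## Stimulus responsiveness (epoch-scrambling bootstrap)

Epochs are maximal runs of consecutive frames with z ≥ 3, treated as whole
calcium events.  The null is built by scrambling: the alternating sequence of
epoch and gap segments is reassembled with epoch segments permuted among
epoch slots and gap segments among gap slots (`mode='joint'`, the default; an
`epochs_only` mode leaves gaps fixed).  Every scramble preserves the multiset
of samples and the trace length, so the null correlations reduce to affine
functions of segment-permuted dot products with the stimulus indicator — the
implementation exploits this for speed but still rebuilds each surrogate
trace.  The observed Pearson correlation is ranked against 1000 scrambles;
the percentile is the upper-tail rank (fraction of scrambles ≥ observed), and
a cell is responsive below the 1% percentile.  Cells with zero epochs show no
transients at all and are declared non-responsive rather than untestable.

Calibration on simulated null cells (stimulus-independent events through the
full pipeline) lands the false-positive rate inside the binomial CI around
1%, and power exceeds 90% once the evoked z-excess reaches 2 — both
recomputed by `scripts/acceptance.py` on every run.  One structural caveat:
for a cell whose epochs already tile every stimulus window (an untuned cell
tested against a single stimulus class), the scramble largely preserves the
alignment and per-class power is intrinsically modest; the tuning-breadth
sweep therefore runs at a 5% percentile threshold.

## Trial modulation

Per-trial AUC-rate activity is computed in the stimulus `[0, 3)`,
poststimulus `[3, 6)` and time-out `[6, 12.5)` s windows (the time-out only
on Miss/FA trials, which are the only trials that have one).  Activity is
computed per trial and then averaged — not on concatenated trials — so trial
counts weight groups explicitly.  The error modulation index divides the mean
over error trials by the mean over correct trials within a window; it is
scale-invariant and recovers injected gains within a few percent at ~100
trials per group (the acceptance script reruns this recovery at gains 1, 1.5
and 2).  The visual modulation index is the normalized difference
(E − S)/(E + S), chosen over the raw ratio because it is signed, bounded in
[−1, 1] for non-negative inputs, and matches the small signed magnitudes
such an index takes in practice; the raw evoked and spontaneous values are
also written for transparency.  Early/late comparisons take the first and
last 20 trials after restricting to the distractor condition of interest,
flagging overlap when fewer than 40 eligible trials exist.  "Incorrect"
always pools FAs and Misses.

## Single-neuron ROC

Only Hit and CR trials enter: each trial's stimulus-window PSTH is scored by
its dot product with the leave-one-out mean Hit PSTH minus the mean CR PSTH
(the trial's own class template excludes the trial).  DVs are raw dot
products, unnormalized; classes with one trial have no leave-one-out template
and are skipped with a warning.  The ROC sweeps the criterion over all unique
DV values plus sentinels with strict `>` classification (ties fall to CR), so
the curve's endpoints are exactly (0,0) and (1,1), and the trapezoidal AUC
equals the Mann–Whitney U statistic divided by n₁n₂ with ties counted half —
an identity the tests assert to 1e-12.  Swapping class labels maps AUC to
1 − AUC exactly, which makes the orientation convention auditable; with this
package's convention a selective cell scores above 0.5.

## The synthetic cohort generator

The generator emulates the statistical structure of a two-genotype distractor
experiment; it is a stand-in, since the task defines no behavioral model.

*Behavior.*  Trials are 3 s stimulus + 3 s ITI, with a 6.5 s time-out
appended after errors; stimulus classes are equiprobable and distractors are
Bernoulli(0.5).  The licking policy is: go with probability `p_hit` on
preferred trials and `p_fa_base` plus a distractor boost decaying as
exp(−trial/τ) on nonpreferred ones, with a lapse probability flipping the
decision.  A go decision places one lick uniformly in the reward window plus
anticipatory licks from a linearly ramping Poisson process, so stored
outcomes always reclassify exactly.  The distractor effect enters only
through the false-alarm probability, matching FA-dominated errors.

*Calcium.*  Events are an inhomogeneous Poisson process: baseline rate ×
stimulus gain during stimulus frames × a von Mises tuning factor (pyramidal
cells; the two orthogonal gratings give the nonpreferred class a factor
exp(−2κ)) × an error gain over the stimulus+poststimulus window of error
trials (the VIP error signal).  Events are convolved with a
difference-of-exponentials kernel (rise 50 ms, decay 700 ms — GCaMP7f-like
widths at 15 Hz), mixed with a shared low-frequency neuropil signal
(smoothed Gaussian noise, 2 s timescale) scaled by the neuropil coupling,
plus white noise.

*Cohorts.*  The WT-like profile uses an accurate policy (p_hit 0.9, base FA
0.12, boost 0.25 decaying with τ = 25 trials) and VIP error gain 2; the
KO-like profile uses base FA 0.3, boost 0.5 with τ = 80, and error gain 1 —
the orderings the group-level analyses should recover.  Each profile carries
4 VIP and 2 pyramidal cells per animal (scaled far below real fields of view
to keep desk-scale runs fast; population sizes are not the target of any
analysis here).  Per-animal heterogeneity draws the VIP error gain from a
lognormal (CV 0.2) and lowers that animal's distractor boost in proportion
(coupling 0.1) — stronger error signals drive fewer mistakes, which is what
makes the across-animal modulation-vs-%-incorrect correlation negative.
Seeding is hierarchical: every animal, neuron and neuropil stream is keyed by
its position (genotype, animal, cell class, index) through SeedSequence spawn
keys, so a fixed seed gives byte-identical datasets and adding a neuron never
perturbs any other stream.

*What it does not emulate.*  No pixel-level movies (ROI extraction is out of
scope), no slow drift or bleaching, no motion artifacts, no correlated noise
across cells beyond the shared neuropil, no within-session learning of the
basic task, no eye or locomotion state.  Passing tests therefore demonstrate
that the analysis chain recovers known generative structure under clean,
stationary conditions — not that it is robust to every artifact of real
recordings.

## Problem sizes

The default validation studies use: 500 null cells × 1000 scrambles for the
responsiveness calibration and 50 driven cells for power; 1000 bootstrap
iterations for SVM chance calibration; 20 replicates × 3 gains for error-gain
recovery; and 20 seeded cohort replicates (5 animals per genotype, 200-trial
sessions) for the group-level sign structure.  These sizes put Monte-Carlo
error comfortably inside each check's tolerance while keeping the full suite
around one to two minutes on a single core.

## Known limitations

- The epoch-scramble null assumes segment arrangement is exchangeable under
  the null; strong slow autocorrelation in gaps (drift) would inflate the
  false-positive rate.  The calibration study covers stationary noise only.
- The error modulation index is a ratio of noisy means: it is undefined when
  the correct-trial mean is non-positive, and per-cell estimates are noisy at
  realistic event rates (SD ≈ 0.2 at 100 trials/group); group inferences
  should average cells or animals, as the pipeline does.
- The AUC rate is tied to the acquisition frame rate by definition; compare
  across rigs via the per-frame mean z.
- Group statistics in `pipeline.group_report` (Mann–Whitney, Cohen's d) are
  reporting plumbing for synthetic cohorts, not a reimplementation of any
  particular study's inference.
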