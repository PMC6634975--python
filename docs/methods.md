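# Methods

`wmpop` implements the quantitative analysis stack for head-fixed rodent
olfactory working-memory experiments: delayed non-match-to-sample (DNMS),
delayed paired association (DPA, including a six-sample variant), Go/No-go
(GNG) and a dual task that inserts a GNG distractor into the DPA delay.
This note documents the models, conventions, and the design choices made
where more than one reasonable convention exists.

## Data model and conventions

Time is trial-relative with t = 0 at sample-odor onset; all windows are
half-open `[start, stop)`. The canonical trial timeline is 1 s of sample
odor, a delay of `delay_s` seconds, 1 s of test odor, a 1 s pre-response
delay and a 0.5 s response window. In the dual task the distractor cue
occupies 3.0–3.5 s into the delay. Sessions are stored as plain TSVs
(UTF-8, header row, lists as comma-joined decimals, missing values empty);
the writer emits a canonical form, and `write(load(f))` is byte-identical
to a canonically written `f`.

Spike binning produces `floor((t1 − t0 − width)/step) + 1` bins; bin *b* of
a unit/trial is the spike count in `[t0 + b·step, t0 + b·step + width)`
divided by the width. Overlapping bins (step < width) are allowed; spike
conservation holds for the non-overlapping configuration.

**Baseline Z-scoring.** Each unit is standardised against the 1 s
pre-sample baseline. The baseline statistics are the mean and SD of the
unit's baseline-window *bin values pooled over trials*, so that after
normalisation the baseline bins themselves have exactly mean 0 / SD 1 per
unit — a checkable contract. (Averaging the baseline bins within each trial
first, then taking cross-trial moments, gives slightly different statistics;
we chose the pooled convention because it makes the normalisation
self-verifying.) A unit with zero baseline variance gets SD 1 substituted
and is flagged with a warning.

**Unit quality control.** A single unit passes when at most 0.15% of its
inter-spike intervals are shorter than 2 ms and its mean rate exceeds 2 Hz.
The mean-rate denominator is the summed duration of the per-trial recording
windows (1 s pre-sample through response-window end), not wall-clock time.
Units with fewer than two spikes have the violation fraction defined as 0
and still face the rate criterion.

## Behavioural metrics

A lick inside the response window on a rewarded-type trial (nonmatch /
paired / go) is a *hit*, on an unrewarded-type trial a *false alarm*;
withholding gives a *miss* or *correct rejection*. Correct rate is
(hits + correct rejections)/trials; d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-choice
rate), with rates of 0 or 1 clamped to 1/(2n) and 1 − 1/(2n) to keep the
inverse normal finite; lick efficiency is rewarded / (rewarded + unrewarded)
response-window licks.

**Well-trained windows** are evaluated over unperturbed (laser-off) trials
only: a run of 40 (or 20) consecutive unperturbed trials at ≥ 80% correct,
or ≥ 6 correct unperturbed trials in a 32-trial block. The thresholds are
inclusive (32/40 qualifies). A qualifying window flags every trial in the
index span it covers, so interleaved laser-on trials inside a well-trained
stretch are retained for the perturbation analyses.

**Memory decay.** Correct rate versus delay is fit by
C(d) = asymptote + A·exp(−d/τ) with least squares; the asymptote is a free
parameter bounded to [0.45, 0.6] (the chance neighbourhood for a
two-alternative task) and initialised at 0.5. Fits with A ≈ 0 are flagged
unidentifiable. τ is weakly identified at small trial counts: at 100 trials
per delay over delays {5, 8, 12, 20, 40} s, the Cramér–Rao bound already
implies a median relative error near 20% for *any* unbiased estimator with
the amplitude free, and the free-asymptote convention roughly ~30%;
consumers should treat single-cohort τ estimates as order-of-magnitude.

## Resampling statistics

Two-sample permutation tests pool the groups and regroup at the original
sizes; the statistic is the absolute difference of means (two-sided). The
paired variant flips the signs of paired differences. When the number of
distinct regroupings (or sign patterns) is at most the requested repeat
count, the null is enumerated exhaustively and the p-value is exact;
Monte-Carlo p-values carry the +1/(n+1) correction and can never be 0.
Bootstrap CIs are percentile intervals of resampled means (1000 repeats,
95% by default). Cohen's d is provided in both pooled-SD (unpaired) and
SD-of-differences (paired) forms. The optogenetic causal criterion is the
genotype × laser interaction of a mixed between-within ANOVA (backed by
`pingouin.mixed_anova`). Outlier screens: the 1.5·IQR fence and iterative
two-sided Grubbs at α = 0.05. Fractions are compared with a 2×2 chi-square
(1 df, no continuity correction); multiplicity uses Bonferroni.

## GLM model comparison

Trials are grouped by combinations of task covariates — sample odor, test
odor, match/non-match relation, genotype, laser, perturbation epoch, a
delay covariate exp(−delay/τ) with τ from the memory-decay fit, and an
*effective delay-suppression* indicator (ChR2 AND laser on AND delay-epoch
perturbation). The group-mean correct rate μ is modelled as μ = Xᵀb via
weighted least squares (Gaussian family, identity link, weights = group
sizes); AIC = 2k − 2 log L with k = coefficients + 1 for the variance.

Seven editable default candidates run from the intercept-only null through
sensory cues, the decay covariate, the manipulation main effects and their
interactions, to a compact model of {suppression, relation, decay} with all
their interactions, and a saturated pairwise-interaction model. For
comparison all candidates are fit to the *same* response vector (trials
grouped by the union of every candidate's covariates); otherwise the null
model would collapse to a single perfectly-interpolated point and AICs
would not be comparable. Bootstrap comparison (default 500 replicates)
resamples trials with replacement within those groups — which keeps the
design fixed and lets the solvers be cached — and the winner is the lowest
mean bootstrap AIC; pairwise differences are tested by sign-flip
permutation across replicates. τ is held fixed across replicates (from the
point fit), and plain AIC (not AICc) is used.

## Single-unit selectivity

The selectivity index is (FR_S1 − FR_S2)/(FR_S1 + FR_S2) from per-sample
mean rates (0 when both means are 0). auROC uses the rank (Mann-Whitney)
convention with ties counted half, the alphabetically-first sample as the
positive class; label swap maps it to 1 − auROC. Per-bin significance is a
label-permutation test on the absolute mean-rate difference at α = 0.05 (a
rank-sum mode is available and labelled). Persistence classes count *total*
significant time across bins — not the longest run — with > 0.5 s transient
and > 5 s persistent. The heat-map ordering utility sorts units by
delay-period FR_S1 − FR_S2; plotting itself is out of scope.

## Mutual information

Within each 500 ms window (100 ms step) the rates of the trials sharing a
sample are fit by a Gaussian (empirical mean; SD floored at
max(10⁻³ Hz, 10⁻⁶·|μ|)); with empirical priors the MI integral
MI = Σ_s P[s] ∫ dr P[r|s] log₂(P[r|s]/P[r]) is evaluated over the union of
±8σ intervals. The headline scalar uses adaptive quadrature; the
permutation loop evaluates the same integrand on a fixed Simpson grid,
vectorised over permutations (agreement is tested to 10⁻⁵ bits). Gaussians
are supported on all reals — no truncation at zero rate — which matches the
fitting convention but slightly mis-models near-zero-rate units; a known
limitation. MI is clamped to [0, log₂ K] after a tolerance check and the
same formula serves K = 6 samples.

Significance masks mark bins at p < 0.001 against a trial-relabelling null.
The default two-tailed p is 2·min(P(null ≥ obs), P(null ≤ obs)) clamped to
1; with the +1/(n+1) correction its floor is 2/(n_perm+1), so masking at
0.001 needs at least 2000 permutations (the code enforces a tail-aware
resolution check; a one-tailed mode is provided and labelled).

## Population decoding

Included units need strictly more than 30 correct well-trained trials per
class. Rates are min-max scaled to [0, 1] per neuron (constant neurons map
to 0). Pseudopopulations hold, per class and neuron, a pool of same-class
single-trial rates; a pseudotrial draws one value per neuron independently
from its pool — the central modelling assumption, required because units
come from different sessions.

Each repeat holds out one trial per class per neuron, trains an RBF-kernel
SVM on 30 bootstrap pseudotrials per class drawn from the remainder (no
train/test overlap by construction, asserted in the loop), and tests on the
held-out pseudotrial vectors; accuracy averages over 500 repeats (resampled
leave-one-trial-out). (c, γ) are grid-searched once per bin on
2^[−5..5] × 2^[−10..0] by inner 5-fold cross-validation on training
pseudotrials, ties broken toward the smallest c then γ. The shuffle null
relabels trials (per neuron, preserving class sizes) and re-runs the
procedure with the observed-data hyperparameters and a reduced repeat count
(200 per permutation); p-values carry the 1/(n_shuffles+1) floor.

Random streams are derived from one master seed per training bin
(`SeedSequence([seed, bin])` split into grid / repeat / null streams), so
cross-temporal decoding — which trains at bin i with bin-i hyperparameters
and tests at every bin j using the same held-out trials — reproduces the
time-resolved accuracy exactly on its diagonal. The decoding-versus-
behaviour correlation bootstraps (accuracy, correct-rate) pairs across
conditions and reports the Pearson statistic with its bootstrap
distribution.

## Synthetic data

The behavioural generator schedules balanced four-trial blocks of
sample/relation combinations, interleaves laser conditions
trial-by-trial or in alternating 24-trial blocks (starting off), and draws
outcomes Bernoulli from P(correct | delay) = chance + A·exp(−delay/τ) minus
a suppression drop applied only on ChR2 delay-perturbed laser trials. The
drop grows linearly with laser duration and onset phase; a lapse process
responds at chance; an optional relation bias offsets rewarded versus
unrewarded trial difficulty. Defaults: chance 0.5, A 0.45, τ 20 s, 10
subjects, no lapse or bias. Licks are emitted in the response window
exactly on hit and false-alarm trials.

Spiking units are inhomogeneous Poisson processes, generated by thinning at
1 ms resolution, with multiplicative odor gain during the sample epoch, an
additive ± selectivity/2 delay component decaying with time constant
τ_sel, attenuated selectivity on error trials (outcome drawn first, spikes
conditioned on it), a distractor-cue response (optionally cue-specific),
and a 2.5 ms refractory dead time so that generated units pass the
single-unit ISI screen a real sorted unit would. Everything is
deterministic given (spec, seed).

What the generator does *not* emulate: rate nonstationarities across a
session, correlated noise between simultaneously recorded neurons, lick
artefacts, bursting, or electrode drift. Passing tests therefore show that
the analysis code is correct under the generative assumptions the analyses
themselves make, not that those assumptions hold in any particular
recording.

## Problem sizes used in tests and the acceptance script

Calibration rates use 1000–2000 null simulations; model recovery uses
50–100 cohorts of 10 subjects × 400 trials with 100 bootstrap replicates;
decoding checks use 8–10 units, 40–55 correct trials per class, a reduced
3 × 3 hyperparameter grid and 30–500 repeats. These sizes were chosen so
the whole suite runs on a single CPU in minutes while keeping every check's
sampling error well inside its tolerance band.
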