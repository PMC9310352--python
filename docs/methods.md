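# Methods

This note documents the models, the synthetic-data generator, the analysis
pipeline and the statistical procedures implemented in `predlearn`, together
with the design choices made where the underlying account leaves matters
open, and what the package's tests do and do not establish.

## Task structure

All designs present letter triplets at the apexes of a notional triangle: a
**target** letter (Q/P or Y/Z) defining the correct key response, a
**correlated** letter shown with its target on 100% of training trials, and
an **uncorrelated** letter shown with each target equally often.  Temporal
formats: *Simultaneous* (all letters onset together), *Serial-Target* (cue
pair 2000 ms, then target 2000 ms), *Serial-Stimuli* (as Serial-Target, but
the participant may respond before the target appears).  Counterbalancing is
a deterministic index into the 24 permutations of the four cue letters over
the four cue roles.  Trial order is a uniform random permutation of the full
trial list (no run-length constraints), and screen positions are assigned by
cycling through balanced slot permutations before shuffling, which makes the
equal-frequency property exact by construction rather than approximate.

Target-absent probe trials (test trials) are interleaved: 24 in the
single-group design (5000 ms displays), 8 in the three-group design and 24
at the end of the two-stage design (2000 ms displays).

## Models

### Trial-level Mackintosh

Associative learning uses the individual error term ΔV_A = α_A·θ·(λ−V_A),
with λ = 1 for the trial's outcome and 0 for rival outcomes (so associations
to the wrong target extinguish and contingencies are discriminated).
Attention changes by Δα_A = k·(|λ−V_r| − |λ−V_A|), clipped into
[0.05, 1.0]; at exact equality of the error magnitudes the change is zero,
the boundary of the "decrease" branch.  The on-screen target letter is
treated purely as the outcome at this level: it does not compete as a cue
for its own identity.  Predicted dwell share is α normalised over the
displayed stimuli; only the sign and ordering of share differences is ever
interpreted, never their magnitude.

### Response-gated variant

Identical associative learning; the attention update is applied only on
trials where the response epoch strictly precedes the target-onset epoch
(t_CR < t_λ, ties excluded).  For designs without an on-screen target (the
cue-pair reference design) the outcome is taken to arrive as feedback at cue
offset, so ordinary post-cue responding still opens the gate — which is what
makes the variant reproduce classic learned predictiveness while predicting
no bias in simultaneous formats.

### Epoch-based stimulus–response model

Trials are discretised into fixed windows of associability (default
1000 ms, giving the canonical six windows over a serial trial including
fixation and inter-trial interval; only event-bearing windows matter to the
updates).  Within each window:

1. **Stimulus→outcome learning** (rate β_target = 0.8): co-active non-target
   stimuli update toward λ = 1 for an on-screen target and toward 0 for a
   rival target, with a summed error term over the co-active cue set.  When
   no target is on screen the links are left alone — the trial's outcome has
   not been revealed yet, and extinguishing an association in the very
   window where it is being anticipated would make anticipatory learning
   impossible in serial formats.
2. **Stimulus→response learning** (rate β_response = 0.6): every co-active
   stimulus — including the target letter, with salience 2.0 — updates
   toward λ = 1 for the emitted key response, summed error again; absent
   responses extinguish (a configurable flag, on by default).  The target's
   higher salience is what makes it overshadow the cue→response association
   whenever response and target share a window.
3. **Attention**: the Mackintosh rule applied with the *response* as the
   outcome, only in response-active windows.

Events persist one additional window after their offset (full salience by
default, configurable).  This one-window persistence is what gives serially
presented cues any co-activity with the target, matching the overlap the
account's own timeline depicts; with persistence disabled and a single
window per trial the model collapses exactly onto a per-trial summed-error
learner, which the tests verify against an independent oracle.

The response policy is deterministic unless seeded: responses follow target
onset at a fixed latency, and when anticipation is allowed an early response
with the predicted identity is emitted once the summed cue→outcome strength
exceeds a threshold (0.6).  In the two-stage transfer design this policy
produces, without further assumptions, the empirical signatures of the
congruency manipulation: incongruent groups begin Stage 2 anticipating the
wrong target (lower early accuracy), recover as the stale associations
extinguish, and end with a positive attentional bias toward the newly
correlated stimulus.

**Parameter defaults.**  θ = 0.3, α₀ = 0.5, k = 0.1, α ∈ [0.05, 1] follow
common Mackintosh simulation practice.  The epoch-model rates, target
salience, persistence and anticipation threshold are free parameters of this
package's formalisation; they were chosen so that the qualitative
bias pattern implied by the account (no bias without anticipatory
responding; positive bias with it, including all four Stage-2 groups) is
robust across trial orderings, verified over a dozen design seeds.  The
models license ordinal claims only; no magnitude is ever asserted.

**Known limitation.**  Human data show the Stage-2 bias numerically largest
in the incongruent groups.  The epoch model predicts the opposite ordering
(congruent ≥ incongruent): the early wrong-target anticipation phase in
incongruent groups first credits the to-be-uncorrelated stimulus, and the
incremental attention rule needs time to unwind that head start.  The sign
pattern (positive bias in all four groups) is reproduced; the congruency
ordering is not, and is therefore not asserted anywhere.

## Synthetic data

The generator emulates the *statistical structure* the analyses assume, not
oculomotor dynamics.  Per trial, dwell shares for the target, correlated and
uncorrelated ROIs are drawn from clipped normals with means
(base_target, base + b/2, base − b/2), where b is the participant's dwell
bias: a population mean (the injected effect) plus a between-participant
normal deviate (sd 0.02).  The remaining gaze window is split between a
tracked off-ROI fixation and untracked time, so the configured missing
fraction is exactly the gap between expected and recorded gaze time and the
>20% exclusion rule triggers precisely when configured to.  Defaults:
base cue share 0.10 (0.20 on target-absent probes), trial noise sd 0.03,
missing rate 0.05, accuracy 0.96.  RTs are drawn per response mode
(to-target ≈ onset + 600 ± 150 ms; anticipatory 1000 ± 200 ms), with the
anticipatory probability ramping linearly over blocks where early responding
is allowed — reproducing the characteristic RT decline from ≈2600 ms to
≈1000 ms.  Questionnaire ratings are 1–10 Likert draws whose paired/unpaired
gap equals the configured knowledge effect (default 4) for correlated
stimuli and zero for uncorrelated ones.

What passing tests show: the pipeline recovers injected dwell biases without
systematic error and its paired t test is calibrated under the null.  What
they do not show: robustness to structured tracker loss, oculomotor
sequence effects, fixation-detector artefacts, or any feature of real gaze
data beyond the generative assumptions above.

Monte-Carlo design: bias recovery uses 200 replicate cohorts of 18
participants with 8 training blocks (the acceptance tolerance is two
Monte-Carlo standard errors); the null-calibration check uses 800 replicate
2-block cohorts so that the binomial standard error (≈0.8 points) sits well
inside the ±1.5-point band.  All randomness flows from named master seeds
via `numpy.random.SeedSequence` spawning.

## Gaze pipeline

Fixations (trial-relative, pixel coordinates, origin top-left) accrue to the
ROI square containing their coordinates, boundary-inclusive; ROIs are
2.7 × 2.7 cm squares converted at 37.8 px/cm on a 1920 × 1080 screen.  Dwell
proportion divides by the trial RT on responded trials and by the fixed
display duration on target-absent probes — the latter is an interpretive
choice (no response exists there) and is recorded as such.  Missing data is
(expected − recorded gaze time)/expected over training trials.  Exclusions:
>20% missing or <60% correct.  Blocked means use 18-trial blocks over
training trials in presented order; a partial final block is averaged as-is
and flagged.  Questionnaire difference scores subtract the unpaired-target
rating from the paired-target rating for correlated stimuli and use a fixed
alternating orientation for uncorrelated ones, whose expected score is zero
under no knowledge.  Dwell on incorrect trials is included (RTs are defined
on correct and incorrect trials alike).

## Statistics

t tests are two-sided throughout (α = .05); zero-variance input raises
rather than returning an undefined statistic.  The JZS Bayes factor
integrates the Cauchy-prior scale mixture

    BF10 = ∫₀^∞ (1+Ngr²)^(−1/2) (1 + t²/((1+Ngr²)ν))^(−(ν+1)/2)
            (2π)^(−1/2) g^(−3/2) e^(−1/(2g)) dg  /  (1+t²/ν)^(−(ν+1)/2)

by adaptive quadrature on the transformed half-line g = z/(1−z) (relative
tolerance 1e−8; non-convergence raises).  One-sample/paired designs use
N = n, ν = n−1; independent designs N = n₁n₂/(n₁+n₂), ν = n₁+n₂−2.  The
integrand is stated exactly so the R `BayesFactor` package can serve as an
external cross-check; in-repo, an independent dense-grid trapezoid
integrator and `pingouin` play that role.

The repeated-measures ANOVA is computed from the classical balanced
subject-within decomposition: per-subject effect scores are formed by
centring the cell-mean array along the factors in the effect and averaging
over the rest; each within effect is tested against its interaction with
subjects (nested in groups for split-plot designs), the between factor
against subjects-within-groups.  Unequal group sizes use weighted
(per-subject) means; unbalanced within-cells raise.  Greenhouse–Geisser ε is
computed from the pooled covariance of the effect's orthonormal (Helmert)
contrast scores and applied when Mauchly's test rejects at .05 (single-df
effects are exempt — sphericity holds trivially, ε = 1).  Simple main
effects re-run the analysis on each slice so every test uses its own
level-specific error term; a two-level slice reproduces the squared paired
t exactly.  Bonferroni adjustment multiplies p by the number of pairwise
comparisons, capped at 1.

Degrees of freedom are always computed from the data actually analysed;
reported values elsewhere that are inconsistent with the stated sample sizes
are not reproduced.
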