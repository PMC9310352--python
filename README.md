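# predlearn

Associative-attention modelling and eye-tracking analysis for
learned-predictiveness experiments.

## The problem

Stimuli that predict task-relevant outcomes come to attract more overt
visual attention — the *learned predictiveness* effect.  Classic associative
accounts explain it with the Mackintosh attention rule: cue→outcome strength
V changes by an individual error term,

    ΔV_A = α_A · θ · (λ − V_A),

and per-stimulus attention α rises when a cue's prediction error is smaller
than its rivals' and falls otherwise,

    Δα_A = k · ( |λ − V_r| − |λ − V_A| ),   V_r = Σ_{B≠A} V_B,

so better predictors gain attention.  But this rule makes no reference to
time: it cannot distinguish a cue that *precedes* an outcome from one merely
*co-present* with it.  Experiments separating the two find that a dwell-time
bias toward a perfectly correlated stimulus only develops when participants
make a predictive response *before* the target appears — mere association,
and even mere serial order, are not enough.

`predlearn` implements the machinery to study this dissociation end to end:

* **designs** — the exact trial structures (counterbalanced letter triplets,
  three temporal formats, two-stage congruent/incongruent transfer, plus the
  classic cue-pair reference design), with balanced screen positions;
* **models** — trial-level Mackintosh, a *response-gated* variant (attention
  updates only when the response epoch precedes target onset, t_CR < t_λ),
  and an *epoch-based stimulus–response* model in which trials are
  discretised into windows of associability, learning follows a summed-error
  (Rescorla–Wagner) rule, and attention tracks each stimulus's association
  with the key **response**, so the co-present target letter overshadows the
  cue→response link except under anticipatory responding;
* **synthetic_data** — participant-level fixation/response/questionnaire
  generator with injectable dwell bias, anticipatory-RT shift, tracker loss
  and Likert ratings;
* **gaze_pipeline** — ROI dwell proportions (dwell / RT on training trials,
  dwell / display duration on target-absent test trials), missing-data and
  accuracy exclusions, blocked means and questionnaire difference scores;
* **stats** — t tests, default (JZS) Bayes factors by numerical quadrature
  (Cauchy prior on effect size, scale r = .707), balanced repeated-measures /
  split-plot ANOVA with Greenhouse–Geisser correction and Mauchly's test,
  simple main effects and Bonferroni post hocs.

## Worked example

```python
from predlearn import RunConfig, run_experiment

bundle = run_experiment(RunConfig(experiment=2, seed=5,
                                  outdir="out", n_per_group=18))
for group, res in bundle["stats"]["groups"].items():
    td = res["test_dwell"]
    print(group, f"t({td['df']}) = {td['t']:+.2f}", td["bf_report"])
```

prints

```
Serial-Stimuli  t(17) = +13.69, mean diff = +0.065, BF = 68449554.86 in favor of the alternative
Serial-Target   t(17) = +1.20, mean diff = +0.008, BF = 2.21 in favor of the null
Simultaneous    t(17) = +1.02, mean diff = +0.007, BF = 2.61 in favor of the null
```

i.e. the synthesized cohort, pushed through the fixation→ROI→dwell pipeline
and the Bayes-factor machinery, recovers the injected structure: evidence
for a correlated-vs-uncorrelated dwell difference only in the group allowed
to respond before target onset, and evidence *for the null* in the other
two.  The epoch-based stimulus–response model predicts the same pattern from
first principles (`examples/02_model_comparison.py` and
`examples/05_full_run.py`), while the classic trial-level model wrongly
predicts a bias whenever a stimulus is merely correlated with the target.

The `examples/` directory has one short script per capability; a thin CLI
(`predlearn design|synth|simulate|pipeline|analyze|run-all`) wraps the same
functions for shell use.

## Layout

    src/predlearn/        designs, models, synthetic_data, gaze_pipeline,
                          stats, reporting, cli
    examples/             narrative scripts, one per capability
    tests/                pytest suite (unit, property and acceptance tests)
    docs/methods.md       modelling and statistical methods note
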