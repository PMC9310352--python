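"""Build the trial designs and verify their defining contingencies.

Each training triplet contains a target letter (defining the correct key),
a correlated letter (always presented with its target) and an uncorrelated
letter (presented with each target equally often).
"""

import collections

from predlearn import build_exp1_design, build_exp2_design, build_exp3_design

exp1 = build_exp1_design(seed=1)
print(f"Experiment 1: {len(exp1.training_trials)} training + "
      f"{len(exp1.test_trials)} test = {len(exp1)} trials")

pairings = collections.defaultdict(collections.Counter)
for t in exp1.training_trials:
    for e in t.events:
        if e.stimulus.role != "target":
            pairings[(e.stimulus.label, e.stimulus.role)][t.correct_response] += 1
for (label, role), counts in sorted(pairings.items()):
    print(f"  {label} ({role:12s}) seen with targets: {dict(counts)}")

for group in ("Simultaneous", "Serial-Target", "Serial-Stimuli"):
    d = build_exp2_design(group, seed=1)
    onset = d.training_trials[0].target_onset_ms
    early = d.training_trials[0].allow_early_response
    print(f"Experiment 2 {group:14s}: {len(d.training_trials)} training "
          f"trials, target onset {onset} ms, anticipation allowed: {early}")

d3 = build_exp3_design("Serial-Incongruent", seed=1)
s1 = {e.stimulus.label for t in d3.trials if t.trial_kind == "training"
      for e in t.events if e.stimulus.role == "correlated"}
s2 = {e.stimulus.label for t in d3.trials if t.trial_kind == "stage2_training"
      for e in t.events if e.stimulus.role == "correlated"}
print(f"Experiment 3 Serial-Incongruent: correlated letters {sorted(s1)} in "
      f"Stage 1 become {sorted(s2)} in Stage 2 (roles swapped)")
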