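"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: the Bayes-factor
oracle is a plain trapezoid rule on a dense grid, and the trial-level
learning oracle is a direct loop over the update equations.
"""

import numpy as np


def brute_force_bf10(t, N, nu, r=0.707, grid=400_000, upper=1e8):
    """High-resolution trapezoid evaluation of the JZS scale-mixture
    integral over g (log-spaced grid, far tail included)."""
    g = np.geomspace(1e-8, upper, grid)
    a = 1 + N * r * r * g
    integ = (a ** -0.5 * (1 + t * t / (a * nu)) ** (-(nu + 1) / 2)
             * (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1 / (2 * g)))
    num = np.trapezoid(integ, g)
    return num / (1 + t * t / nu) ** (-(nu + 1) / 2)


def single_epoch_trial_oracle(design, p):
    """Per-trial summed-error learner with response-driven attention: what
    the epoch model must reduce to when every trial is one epoch.

    Returns (V, V_SR, alpha) keyed like the package state (response outcomes
    prefixed with 'R:').
    """
    stimuli = sorted({e.stimulus.label for t in design.trials
                      for e in t.events})
    outcomes = sorted({t.correct_response for t in design.training_trials})
    V = {(s, o): 0.0 for s in stimuli for o in outcomes}
    VSR = {(s, o): 0.0 for s in stimuli for o in outcomes}
    alpha = {s: p.alpha0 for s in stimuli}
    lo, hi = p.alpha_bounds
    for t in design.trials:
        if t.correct_response is None:
            continue
        labels = [e.stimulus.label for e in t.events]
        target = t.correct_response
        cues = [e.stimulus.label for e in t.events
                if e.stimulus.role != "target"]
        for o in outcomes:
            lam = 1.0 if o == target else 0.0
            err = lam - sum(V[(c, o)] for c in cues)
            for c in cues:
                V[(c, o)] += alpha[c] * p.beta_target * err
        for o in outcomes:  # deterministic policy responds with the target
            lam = 1.0 if o == target else 0.0
            err = lam - sum(VSR[(c, o)] for c in labels)
            for c in labels:
                w = p.target_cue_salience if c == target else 1.0
                VSR[(c, o)] += w * alpha[c] * p.beta_response * err
        for a in labels:
            vr = sum(VSR[(b, target)] for b in labels if b != a)
            alpha[a] += p.alpha_gain * (abs(1 - vr)
                                        - abs(1 - VSR[(a, target)]))
            alpha[a] = min(hi, max(lo, alpha[a]))
    vsr = {(s, "R:" + o): v for (s, o), v in VSR.items()}
    return V, vsr, alpha
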