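"""Associative-attention models for learned predictiveness.

Three model variants are implemented:

``mackintosh``
    The classic trial-level attention model.  Cue->outcome associative
    strength V changes with an *individual* error term,

        dV_A = alpha_A * theta * (lambda - V_A),

    and the attention (associability) parameter alpha of each presented cue
    rises when its error is smaller than that of the other cues on the trial
    and falls otherwise, in proportion to the difference of the two error
    magnitudes:

        d(alpha_A) = k * (|lambda - V_r| - |lambda - V_A|),

    where V_r is the summed strength of the other cues present.

``response_gated``
    Identical associative learning, but attention changes are applied only on
    trials where the task-relevant response was emitted *before* target onset
    (t_CR < t_lambda).  Associative knowledge therefore accrues in every
    group, while attentional biases can develop only under anticipatory
    responding.

``epoch_sr``
    A real-time variant.  Each trial is discretised into fixed windows of
    associability (epochs).  Events co-active within an epoch associate by a
    summed-error (Rescorla-Wagner) rule, for two outcome families: the target
    identity (stimulus->outcome links V) and the key response
    (stimulus->response links V_SR, for which the on-screen target letter
    also acts as a competing cue).  Attention follows the Mackintosh rule but
    with the *response* as the outcome, applied only in response-active
    epochs.  When cues, response and target share an epoch the target
    overshadows the cue->response association, so an attentional bias emerges
    only when responding precedes the target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .designs import Design, TrialTemplate

__all__ = [
    "ModelParams",
    "AssociativeState",
    "Epoch",
    "EpochTimeline",
    "Trajectory",
    "MODEL_VARIANTS",
    "mackintosh_trial_update",
    "response_gated_update",
    "epoch_expand",
    "epoch_rw_update",
    "sr_attention_update",
    "response_policy",
    "simulate",
    "compare_models",
]

MODEL_VARIANTS = ("mackintosh", "response_gated", "epoch_sr")

#: prefix marking response outcomes in the V_SR maps
RESP = "R:"


@dataclass(frozen=True)
class ModelParams:
    """Model parameters.

    theta : stimulus->outcome learning rate, (0, 1].
    lam : outcome magnitude on outcome-present trials/epochs (0 when absent).
    alpha0 : initial attention for every stimulus.
    alpha_gain : proportionality constant k for attention changes.
    alpha_bounds : attention is clipped into [lo, hi] after every update.
    beta_target / beta_response : epoch-model learning rates for the target
        identity and key-response outcome families.
    target_cue_salience : salience of the on-screen target letter when it acts
        as a cue for the response outcome (>1 strengthens overshadowing).
    trace_epochs / trace_salience : a stimulus remains a weak cue for this
        many epochs after its offset, with its rate scaled by trace_salience;
        this is what lets serially-presented cues associate with the target.
    response_threshold : summed cue->outcome strength above which an
        anticipatory response is emitted (when the design allows it).
    epoch_ms : duration of one window of associability.
    rt_to_target_ms : response latency after target onset.
    rt_anticipatory_ms : latency of anticipatory responses after cue onset.
    extinction_sr : whether stimulus->response links extinguish in
        response-absent epochs.
    softmax_temperature : temperature for sampling response identity from the
        outcome strengths (stochastic mode only).
    gating_enabled : when False the response_gated variant applies attention
        updates unconditionally (degenerates to the standard model).
    """

    theta: float = 0.3
    lam: float = 1.0
    alpha0: float = 0.5
    alpha_gain: float = 0.1
    alpha_bounds: tuple[float, float] = (0.05, 1.0)
    beta_target: float = 0.8
    beta_response: float = 0.6
    target_cue_salience: float = 2.0
    trace_epochs: int = 1
    trace_salience: float = 1.0
    response_threshold: float = 0.6
    epoch_ms: int = 1000
    rt_to_target_ms: int = 600
    rt_anticipatory_ms: int = 1600
    extinction_sr: bool = True
    softmax_temperature: float = 0.25
    p_correct_target: float = 0.98
    gating_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.theta <= 1:
            raise ValueError("theta must be in (0, 1]")
        lo, hi = self.alpha_bounds
        if not 0 <= lo < hi <= 1:
            raise ValueError("alpha_bounds must satisfy 0 <= lo < hi <= 1")
        if self.epoch_ms <= 0:
            raise ValueError("epoch_ms must be positive")


class AssociativeState:
    """Associative strengths and attention weights of a simulated learner.

    V maps (stimulus, outcome) to cue->outcome strength; V_SR maps
    (stimulus, response) to cue->response strength; alpha maps each stimulus
    to its attention weight, kept within the configured bounds.
    """

    def __init__(self, stimuli, outcomes, params: ModelParams):
        self.params = params
        self.stimuli = list(stimuli)
        self.outcomes = list(outcomes)
        self.responses = [RESP + o for o in outcomes]
        self.V: dict[tuple[str, str], float] = {
            (s, o): 0.0 for s in self.stimuli for o in self.outcomes
        }
        self.V_SR: dict[tuple[str, str], float] = {
            (s, r): 0.0 for s in self.stimuli for r in self.responses
        }
        self.alpha: dict[str, float] = {s: params.alpha0 for s in self.stimuli}

    def check_registered(self, labels) -> None:
        unknown = [s for s in labels if s not in self.alpha]
        if unknown:
            raise KeyError(f"stimuli not registered in state: {unknown}")

    def clip_alpha(self, label: str) -> None:
        lo, hi = self.params.alpha_bounds
        self.alpha[label] = float(min(hi, max(lo, self.alpha[label])))

    def prediction(self, cues, outcome: str) -> float:
        """Summed cue->outcome strength for the given cue set."""
        return float(sum(self.V[(c, outcome)] for c in cues))

    def copy(self) -> "AssociativeState":
        new = AssociativeState(self.stimuli, self.outcomes, self.params)
        new.V = dict(self.V)
        new.V_SR = dict(self.V_SR)
        new.alpha = dict(self.alpha)
        return new


# ---------------------------------------------------------------------------
# trial-level updates


def _mackintosh_alpha_deltas(values: dict[str, float], lam: float, k: float):
    """Attention changes for co-present cues given their strengths toward the
    trial outcome.  At exact equality of the two error magnitudes the change
    is non-positive (the >= branch of the rule), which the proportional form
    realises as zero."""
    deltas = {}
    for a, va in values.items():
        vr = sum(v for b, v in values.items() if b != a)
        deltas[a] = k * (abs(lam - vr) - abs(lam - va))
    return deltas


def mackintosh_trial_update(state: AssociativeState, present_stimuli,
                            outcome: str) -> AssociativeState:
    """One trial of the standard model: individual-error learning toward every
    registered outcome (lambda = 1 for the trial outcome, 0 otherwise), then
    attention changes computed from the trial-start strengths."""
    p = state.params
    present = list(present_stimuli)
    state.check_registered(present)
    if outcome not in state.outcomes:
        raise KeyError(f"unknown outcome {outcome!r}")
    snapshot = {a: state.V[(a, outcome)] for a in present}

    for a in present:
        for o in state.outcomes:
            lam_o = p.lam if o == outcome else 0.0
            v = state.V[(a, o)]
            state.V[(a, o)] = v + state.alpha[a] * p.theta * (lam_o - v)

    for a, d in _mackintosh_alpha_deltas(snapshot, p.lam, p.alpha_gain).items():
        state.alpha[a] += d
        state.clip_alpha(a)
    return state


def response_gated_update(state: AssociativeState, timeline: "EpochTimeline",
                          present_stimuli, outcome: str) -> AssociativeState:
    """Standard associative learning; attention changes only when the response
    preceded target onset (t_CR < t_lambda).  A missing response leaves
    attention unchanged."""
    p = state.params
    present = list(present_stimuli)
    state.check_registered(present)
    snapshot = {a: state.V[(a, outcome)] for a in present}

    for a in present:
        for o in state.outcomes:
            lam_o = p.lam if o == outcome else 0.0
            v = state.V[(a, o)]
            state.V[(a, o)] = v + state.alpha[a] * p.theta * (lam_o - v)

    gate_open = (not p.gating_enabled) or (
        timeline.t_cr is not None
        and timeline.t_lambda is not None
        and timeline.t_cr < timeline.t_lambda
    )
    if gate_open:
        for a, d in _mackintosh_alpha_deltas(snapshot, p.lam, p.alpha_gain).items():
            state.alpha[a] += d
            state.clip_alpha(a)
    return state


# ---------------------------------------------------------------------------
# epoch machinery


@dataclass(frozen=True)
class Epoch:
    """One window of associability.

    ``active`` maps stimulus label -> salience weight (1 while the stimulus is
    on screen, ``trace_salience`` during its post-offset trace).  ``target``
    is the identity of an on-screen target, ``response`` the identity of a key
    response emitted in this window (or None).
    """

    index: int
    active: dict[str, float]
    target: str | None
    response: str | None


@dataclass(frozen=True)
class EpochTimeline:
    epochs: tuple[Epoch, ...]
    t_cr: int | None
    t_lambda: int | None
    epoch_ms: int

    def with_response(self, epoch_index: int | None, identity: str | None):
        if epoch_index is None:
            return self
        epochs = tuple(
            replace(e, response=identity) if e.index == epoch_index else e
            for e in self.epochs
        )
        return EpochTimeline(epochs, epoch_index, self.t_lambda, self.epoch_ms)


def epoch_expand(trial: TrialTemplate, response_latency_ms: int | None,
                 epoch_ms: int, fallback_duration_ms: int = 1000) -> EpochTimeline:
    """Discretise a trial into epochs of fixed duration.

    Each event is active in every epoch overlapping its half-open interval
    [onset, onset + duration).  Response-terminated displays (duration None)
    are taken to last until the response (or ``fallback_duration_ms`` when no
    response occurred).  The response occupies the single epoch containing its
    latency.
    """
    if epoch_ms <= 0:
        raise ValueError("epoch_ms must be positive")
    end_fallback = (response_latency_ms if response_latency_ms is not None
                    else fallback_duration_ms)
    spans = []
    for e in trial.events:
        dur = e.dur_ms
        if dur is None:
            dur = max(end_fallback, 1)
        spans.append((e.stimulus, e.onset_ms, e.onset_ms + dur))
    trial_end = max(s[2] for s in spans)
    if trial.display_duration_ms:
        trial_end = max(trial_end, trial.display_duration_ms)
    if response_latency_ms is not None:
        if not 0 <= response_latency_ms <= trial_end:
            raise ValueError("response latency outside the trial")
        trial_end = max(trial_end, response_latency_ms + 1)
    n_epochs = int(np.ceil(trial_end / epoch_ms))

    t_cr = (int(response_latency_ms // epoch_ms)
            if response_latency_ms is not None else None)
    if trial.target_onset_ms is not None:
        t_lambda = int(trial.target_onset_ms // epoch_ms)
    elif trial.correct_response is not None:
        # no on-screen target: the outcome is delivered as feedback when the
        # cue display ends
        t_lambda = int(max(s[2] for s in spans) // epoch_ms)
    else:
        t_lambda = None

    epochs = []
    for i in range(n_epochs):
        lo, hi = i * epoch_ms, (i + 1) * epoch_ms
        active: dict[str, float] = {}
        target = None
        for stim, on, off in spans:
            if on < hi and off > lo:
                active[stim.label] = 1.0
                if stim.role == "target":
                    target = stim.label
        response = None
        if t_cr is not None and i == t_cr:
            # identity filled in by the caller via with_response
            response = "?"
        epochs.append(Epoch(i, active, target, response))
    return EpochTimeline(tuple(epochs), t_cr, t_lambda, epoch_ms)


def _with_traces(timeline: EpochTimeline, params: ModelParams) -> EpochTimeline:
    """Extend each stimulus's activity by ``trace_epochs`` windows after its
    offset at reduced salience.  The trace never overrides real presence."""
    if params.trace_epochs <= 0 or params.trace_salience <= 0:
        return timeline
    n = len(timeline.epochs)
    new = []
    for ep in timeline.epochs:
        active = dict(ep.active)
        for back in range(1, params.trace_epochs + 1):
            j = ep.index - back
            if j < 0:
                continue
            prev = timeline.epochs[j]
            for label in prev.active:
                if label not in active:
                    active[label] = params.trace_salience
        new.append(replace(ep, active=active))
    return EpochTimeline(tuple(new), timeline.t_cr, timeline.t_lambda,
                         timeline.epoch_ms)


def epoch_rw_update(state: AssociativeState, epoch: Epoch) -> AssociativeState:
    """Summed-error learning within one epoch, for both outcome families.

    Target-identity outcomes: the co-active non-target stimuli update toward
    lambda = 1 for the on-screen target and toward 0 for rival targets; when
    no target is on screen the outcome is still unresolved and the links are
    left alone (a trial's absent outcome is only experienced when a rival
    target appears).

    Response outcomes: every co-active stimulus -- including the target
    letter, weighted by its salience -- updates toward lambda = 1 for the
    emitted response; absent responses extinguish toward 0 when
    ``extinction_sr`` is enabled.
    """
    p = state.params
    if not epoch.active:
        return state
    state.check_registered(epoch.active)

    # --- stimulus -> target-identity learning (targets are not cues here)
    cues = {s: w for s, w in epoch.active.items() if s != epoch.target}
    if epoch.target is not None and cues:
        for o in state.outcomes:
            lam_o = p.lam if o == epoch.target else 0.0
            total = sum(state.V[(c, o)] for c in cues)
            err = lam_o - total
            for c, w in cues.items():
                state.V[(c, o)] += w * state.alpha[c] * p.beta_target * err

    # --- stimulus -> response learning (target letter competes as a cue)
    sr_cues = {
        s: (w * p.target_cue_salience if s == epoch.target else w)
        for s, w in epoch.active.items()
    }
    for r in state.responses:
        active_resp = epoch.response is not None and RESP + epoch.response == r
        if not active_resp and not p.extinction_sr:
            continue
        lam_r = p.lam if active_resp else 0.0
        total = sum(state.V_SR[(c, r)] for c in sr_cues)
        err = lam_r - total
        for c, w in sr_cues.items():
            state.V_SR[(c, r)] += w * state.alpha[c] * p.beta_response * err
    return state


def sr_attention_update(state: AssociativeState, epoch: Epoch) -> AssociativeState:
    """Mackintosh attention rule with the emitted response as the outcome:
    attention rises for co-active stimuli whose response-prediction error is
    smaller than their rivals'.  No response in the epoch, no change."""
    p = state.params
    if epoch.response is None or not epoch.active:
        return state
    r = RESP + epoch.response
    values = {s: state.V_SR[(s, r)] for s in epoch.active}
    for a, d in _mackintosh_alpha_deltas(values, p.lam, p.alpha_gain).items():
        state.alpha[a] += d
        state.clip_alpha(a)
    return state


# ---------------------------------------------------------------------------
# response generation


def response_policy(state: AssociativeState, trial: TrialTemplate,
                    params: ModelParams, rng: np.random.Generator | None = None):
    """Decide when and how the simulated participant responds on a trial.

    Returns ``(latency_ms, identity, correct)`` or ``None`` (test trials).
    With anticipation allowed, an early response with the predicted identity
    is emitted once the summed cue->outcome strength of the displayed cues
    exceeds ``response_threshold`` before target onset.  Otherwise the
    response follows target onset and names the visible target.  With an rng,
    identities are sampled (softmax over outcome strengths, fixed lapse rate
    on target-present responses); without one the policy is deterministic.
    """
    if trial.correct_response is None:
        return None
    p = params
    cues = [e.stimulus.label for e in trial.events if e.stimulus.role != "target"]
    t_on = trial.target_onset_ms or 0

    if trial.allow_early_response and t_on > 0:
        preds = {o: state.prediction(cues, o) for o in state.outcomes}
        best = max(preds, key=lambda o: preds[o])
        if preds[best] > p.response_threshold:
            latency = min(p.rt_anticipatory_ms, t_on - 1)
            if rng is None:
                identity = best
            else:
                z = np.array([preds[o] for o in state.outcomes], dtype=float)
                w = np.exp((z - z.max()) / max(p.softmax_temperature, 1e-9))
                identity = state.outcomes[
                    rng.choice(len(state.outcomes), p=w / w.sum())]
            return latency, identity, identity == trial.correct_response

    latency = t_on + p.rt_to_target_ms
    if rng is None or rng.random() < p.p_correct_target:
        identity = trial.correct_response
    else:
        others = [o for o in state.outcomes if o != trial.correct_response]
        identity = others[rng.integers(len(others))] if others else trial.correct_response
    return latency, identity, identity == trial.correct_response


# ---------------------------------------------------------------------------
# simulation driver


@dataclass
class Trajectory:
    """Per-trial record of a simulation run.

    ``records`` is a long table with one row per (training trial, displayed
    stimulus): associative strengths, attention and the predicted dwell share
    (attention normalised over the display).  ``responses`` has one row per
    training trial.
    """

    design: Design
    variant: str
    records: pd.DataFrame
    responses: pd.DataFrame
    state: AssociativeState
    block_size: int = 18

    def per_block(self) -> pd.DataFrame:
        df = self.records.copy()
        df["block"] = df["trial"].map(
            dict(zip(self.responses["trial"],
                     self.responses.index // self.block_size)))
        return (df.groupby(["block", "role"], as_index=False)
                  [["alpha", "dwell_share", "V", "V_SR"]].mean())

    def bias(self, stage: str | None = None, last_blocks: int = 1) -> float:
        """Correlated-minus-uncorrelated predicted dwell share at the end of
        training (mean over the last ``last_blocks`` blocks)."""
        df = self.records
        if stage is not None:
            df = df[df["kind"] == stage]
        trials = sorted(df["trial"].unique())
        n_keep = self.block_size * last_blocks
        tail = set(trials[-min(len(trials), n_keep):])
        df = df[df["trial"].isin(tail)]
        mean = df.groupby("role")["dwell_share"].mean()
        return float(mean.get("correlated", np.nan)
                     - mean.get("uncorrelated", np.nan))

    def alpha_by_role(self) -> dict[str, float]:
        """Final attention averaged over stimuli, keyed by their design role."""
        roles: dict[str, list[float]] = {}
        for label, role in self._final_roles().items():
            roles.setdefault(role, []).append(self.state.alpha[label])
        return {r: float(np.mean(v)) for r, v in roles.items()}

    def _final_roles(self) -> dict[str, str]:
        roles = {}
        for t in self.design.training_trials:
            for e in t.events:
                roles[e.stimulus.label] = e.stimulus.role
        return roles


def _design_vocabulary(design: Design):
    stimuli, outcomes = [], []
    for t in design.trials:
        for e in t.events:
            if e.stimulus.label not in stimuli:
                stimuli.append(e.stimulus.label)
        if t.correct_response and t.correct_response not in outcomes:
            outcomes.append(t.correct_response)
    return stimuli, outcomes


def simulate(design: Design, model_variant: str, params: ModelParams | None = None,
             seed: int | None = None, block_size: int = 18) -> Trajectory:
    """Run one model over a design and record attention/association
    trajectories and predicted dwell shares.

    ``seed=None`` gives the deterministic policy (always-correct responses,
    argmax anticipation); an integer seed samples identities and lapses.
    """
    if model_variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown variant {model_variant!r}; expected {MODEL_VARIANTS}")
    params = params or ModelParams()
    rng = np.random.default_rng(seed) if seed is not None else None
    stimuli, outcomes = _design_vocabulary(design)
    state = AssociativeState(stimuli, outcomes, params)

    rec_rows, resp_rows = [], []
    for idx, trial in enumerate(design.trials):
        if trial.correct_response is None:
            continue  # probe trials: no feedback, no learning
        resp = response_policy(state, trial, params, rng)
        latency, identity, correct = resp
        cues = [e.stimulus.label for e in trial.events if e.stimulus.role != "target"]

        if model_variant == "mackintosh":
            mackintosh_trial_update(state, cues, trial.correct_response)
        elif model_variant == "response_gated":
            timeline = epoch_expand(trial, latency, params.epoch_ms)
            response_gated_update(state, timeline, cues, trial.correct_response)
        else:  # epoch_sr
            timeline = epoch_expand(trial, latency, params.epoch_ms)
            timeline = timeline.with_response(timeline.t_cr, identity)
            timeline = _with_traces(timeline, params)
            for epoch in timeline.epochs:
                epoch_rw_update(state, epoch)
                sr_attention_update(state, epoch)

        shown = [e.stimulus for e in trial.events]
        alpha_sum = sum(state.alpha[s.label] for s in shown)
        for s in shown:
            rec_rows.append({
                "trial": idx,
                "kind": trial.trial_kind,
                "stimulus": s.label,
                "role": s.role,
                "V": state.V[(s.label, trial.correct_response)],
                "V_SR": state.V_SR[(s.label, RESP + trial.correct_response)],
                "alpha": state.alpha[s.label],
                "dwell_share": state.alpha[s.label] / alpha_sum,
            })
        resp_rows.append({
            "trial": idx, "kind": trial.trial_kind, "rt_ms": latency,
            "identity": identity, "correct": correct,
            "anticipatory": trial.target_onset_ms is not None
                            and latency < trial.target_onset_ms,
        })

    records = pd.DataFrame(rec_rows)
    responses = pd.DataFrame(resp_rows).reset_index(drop=True)
    return Trajectory(design, model_variant, records, responses, state,
                      block_size=block_size)


#: The qualitative pattern the experiments observed: sign of the
#: correlated-minus-uncorrelated attentional bias by condition.
OBSERVED_PATTERN = {
    ("1", "Simultaneous", "training"): 0,
    ("2", "Simultaneous", "training"): 0,
    ("2", "Serial-Target", "training"): 0,
    ("2", "Serial-Stimuli", "training"): +1,
    ("3", "Simultaneous-Congruent", "training"): 0,
    ("3", "Simultaneous-Incongruent", "training"): 0,
    ("3", "Serial-Congruent", "training"): 0,
    ("3", "Serial-Incongruent", "training"): 0,
    ("3", "Simultaneous-Congruent", "stage2_training"): +1,
    ("3", "Simultaneous-Incongruent", "stage2_training"): +1,
    ("3", "Serial-Congruent", "stage2_training"): +1,
    ("3", "Serial-Incongruent", "stage2_training"): +1,
}


def compare_models(designs, variants=MODEL_VARIANTS,
                   params: ModelParams | None = None,
                   zero_tol: float = 0.02) -> pd.DataFrame:
    """End-of-training bias sign per design x variant, with a column saying
    whether it matches the observed behavioural pattern.

    A bias is counted positive above ``zero_tol`` predicted-dwell-share
    difference, negative below ``-zero_tol`` and null in between; only signs
    are compared (the models make ordinal predictions, not magnitudes).
    """
    rows = []
    for design in designs:
        stages = sorted({t.trial_kind for t in design.training_trials})
        for variant in variants:
            traj = simulate(design, variant, params)
            for stage in stages:
                bias = traj.bias(stage=stage)
                sign = 0 if abs(bias) < zero_tol else int(np.sign(bias))
                key = (design.experiment_id, design.group, stage)
                expected = OBSERVED_PATTERN.get(key)
                rows.append({
                    "experiment": design.experiment_id,
                    "group": design.group,
                    "stage": stage,
                    "variant": variant,
                    "bias": bias,
                    "sign": sign,
                    "expected_sign": expected,
                    "matches_observed": (None if expected is None
                                         else sign == expected),
                })
    return pd.DataFrame(rows)
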