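"""Trial-structure generators for learned-predictiveness experiments.

The experiments train participants with triplets of letter stimuli containing a
*target* (which defines the correct key response), a *correlated* stimulus
(present with its target on 100% of trials) and an *uncorrelated* stimulus
(present with each target on 50% of trials).  Three temporal formats are used:

* ``Simultaneous`` -- all three letters onset together;
* ``Serial-Target`` -- the cue pair precedes the target;
* ``Serial-Stimuli`` -- as Serial-Target, but anticipatory responding before
  target onset is permitted.

A classic learned-predictiveness reference design (pairs of cues, one
predictive and one irrelevant, followed by one of two outcomes) is also
provided for model validation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Stimulus",
    "StimulusEvent",
    "TrialTemplate",
    "Design",
    "EXP2_GROUPS",
    "EXP3_GROUPS",
    "build_exp1_design",
    "build_exp2_design",
    "build_exp3_design",
    "build_lepelley_design",
    "assign_positions",
    "design_to_json",
    "design_from_json",
]

#: Valid stimulus roles within a stage.
ROLES = ("target", "correlated", "uncorrelated", "predictive", "irrelevant")

EXP2_GROUPS = ("Simultaneous", "Serial-Target", "Serial-Stimuli")
EXP3_GROUPS = (
    "Simultaneous-Congruent",
    "Simultaneous-Incongruent",
    "Serial-Congruent",
    "Serial-Incongruent",
)

#: Display duration of target-absent test trials (ms).
TEST_DISPLAY_MS = {1: 5000, 2: 2000, 3: 2000}

CUE_DUR_MS = 2000
TARGET_DUR_MS = 2000
FIXATION_MS = 1000
ITI_MS = 1000

#: Apex position slots of the notional triangle.
SLOTS = (0, 1, 2)


@dataclass(frozen=True)
class Stimulus:
    """A single-letter stimulus with its within-stage role."""

    label: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation within a trial.

    ``dur_ms=None`` means the stimulus remains until the trial terminates
    (response-terminated displays).  ``slot=None`` means the screen position
    has not been assigned yet (see :func:`assign_positions`).
    """

    stimulus: Stimulus
    onset_ms: int
    dur_ms: int | None
    slot: int | None = None


@dataclass(frozen=True)
class TrialTemplate:
    trial_kind: str  # training | test | stage2_training | final_test
    events: tuple[StimulusEvent, ...]
    correct_response: str | None
    display_duration_ms: int | None = None  # fixed display time for test trials
    allow_early_response: bool = False
    fixation_duration_ms: int = FIXATION_MS
    iti_ms: int = ITI_MS

    def __post_init__(self) -> None:
        n_targets = sum(e.stimulus.role == "target" for e in self.events)
        if self.trial_kind in ("training", "stage2_training"):
            # triplet designs show the target; reference cue-pair designs
            # deliver the outcome off screen but still require a response
            if n_targets > 1 or self.correct_response is None:
                raise ValueError(
                    "training trials have at most one target and a correct response")
        elif n_targets != 0:
            raise ValueError("test trials contain no target")
        labels = [e.stimulus.label for e in self.events]
        if len(set(labels)) != len(labels):
            raise ValueError("stimulus labels must be unique within a display")

    @property
    def stimuli(self) -> tuple[Stimulus, ...]:
        return tuple(e.stimulus for e in self.events)

    def role_of(self, label: str) -> str:
        for e in self.events:
            if e.stimulus.label == label:
                return e.stimulus.role
        raise KeyError(label)

    @property
    def target_onset_ms(self) -> int | None:
        for e in self.events:
            if e.stimulus.role == "target":
                return e.onset_ms
        return None

    @property
    def end_ms(self) -> int:
        """Offset of the last stimulus (ms, relative to first onset)."""
        out = 0
        for e in self.events:
            dur = e.dur_ms
            if dur is None:
                dur = self.display_duration_ms or 0
            out = max(out, e.onset_ms + dur)
        if self.display_duration_ms is not None:
            out = max(out, self.display_duration_ms)
        return out


@dataclass
class Design:
    experiment_id: str
    group: str
    stage: str
    trials: list[TrialTemplate]
    counterbalance: dict[str, str]  # letter -> role description
    seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def training_trials(self) -> list[TrialTemplate]:
        return [t for t in self.trials if t.trial_kind in ("training", "stage2_training")]

    @property
    def test_trials(self) -> list[TrialTemplate]:
        return [t for t in self.trials if t.trial_kind in ("test", "final_test")]

    def __len__(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# counterbalancing


def _cue_assignment(letters: tuple[str, str, str, str], index: int) -> tuple[str, ...]:
    """Deterministic letter->role permutation for a counterbalance index.

    The four cue letters are permuted over the ordered roles
    (correlated-with-target-1, correlated-with-target-2, uncorrelated-1,
    uncorrelated-2); there are 24 assignments.
    """
    perms = list(itertools.permutations(letters))
    if not 0 <= index < len(perms):
        raise ValueError(f"counterbalance_index must be in [0, {len(perms)}), got {index}")
    return perms[index]


def _compounds(c1: str, c2: str, u1: str, u2: str, t1: str, t2: str):
    """The four training compounds: each correlated cue with each uncorrelated."""
    return [
        ((c1, u1), t1),
        ((c1, u2), t1),
        ((c2, u1), t2),
        ((c2, u2), t2),
    ]


def _triplet_trial(cues, target, serial: bool, kind: str = "training",
                   allow_early: bool = False, response_terminated: bool = False):
    c1, u1 = cues
    cue_dur = None if response_terminated else CUE_DUR_MS
    events = [
        StimulusEvent(Stimulus(c1, "correlated"), 0, cue_dur),
        StimulusEvent(Stimulus(u1, "uncorrelated"), 0, cue_dur),
    ]
    t_onset = CUE_DUR_MS if serial else 0
    t_dur = None if response_terminated else TARGET_DUR_MS
    events.append(StimulusEvent(Stimulus(target, "target"), t_onset, t_dur))
    return TrialTemplate(
        trial_kind=kind,
        events=tuple(events),
        correct_response=target,
        allow_early_response=allow_early,
    )


def _test_trial(cues, display_ms: int, kind: str = "test"):
    c1, u1 = cues
    events = (
        StimulusEvent(Stimulus(c1, "correlated"), 0, display_ms),
        StimulusEvent(Stimulus(u1, "uncorrelated"), 0, display_ms),
    )
    return TrialTemplate(
        trial_kind=kind,
        events=events,
        correct_response=None,
        display_duration_ms=display_ms,
    )


def _shuffled(trials, rng: np.random.Generator) -> list[TrialTemplate]:
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


# ---------------------------------------------------------------------------
# experiment builders


def build_exp1_design(seed: int, counterbalance_index: int = 0,
                      repetitions: int = 72) -> Design:
    """Experiment 1: simultaneous triplets, response-terminated displays.

    Four compounds x ``repetitions`` training trials (288 at the default) plus
    target-absent test trials (24 at the default), shuffled into a single
    sequence with balanced screen positions.
    """
    c1, c2, u1, u2 = _cue_assignment(("U", "V", "W", "X"), counterbalance_index)
    t1, t2 = "Y", "Z"
    test_repetitions = round(repetitions / 12)  # paper ratio 72 : 6

    trials: list[TrialTemplate] = []
    for cues, target in _compounds(c1, c2, u1, u2, t1, t2):
        trials += [
            _triplet_trial(cues, target, serial=False, response_terminated=True)
            for _ in range(repetitions)
        ]
    test_pairs = [(c1, u1), (c1, u2), (c2, u1), (c2, u2)]
    for cues in test_pairs:
        trials += [_test_trial(cues, TEST_DISPLAY_MS[1]) for _ in range(test_repetitions)]

    rng = np.random.default_rng(seed)
    design = Design(
        experiment_id="1",
        group="Simultaneous",
        stage="training",
        trials=_shuffled(trials, rng),
        counterbalance={c1: f"correlated:{t1}", c2: f"correlated:{t2}",
                        u1: "uncorrelated", u2: "uncorrelated",
                        t1: "target", t2: "target"},
        seed=seed,
    )
    return assign_positions(design, seed)


def build_exp2_design(group: str, seed: int, counterbalance_index: int = 0,
                      repetitions: int = 36) -> Design:
    """Experiment 2: fixed 2000-ms displays, three temporal-format groups."""
    if group not in EXP2_GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {EXP2_GROUPS}")
    serial = group != "Simultaneous"
    allow_early = group == "Serial-Stimuli"
    c1, c2, u1, u2 = _cue_assignment(("J", "V", "W", "Z"), counterbalance_index)
    t1, t2 = "Q", "P"
    test_repetitions = round(repetitions / 18)  # paper ratio 36 : 2

    trials: list[TrialTemplate] = []
    for cues, target in _compounds(c1, c2, u1, u2, t1, t2):
        trials += [
            _triplet_trial(cues, target, serial=serial, allow_early=allow_early)
            for _ in range(repetitions)
        ]
    for cues in [(c1, u1), (c1, u2), (c2, u1), (c2, u2)]:
        trials += [_test_trial(cues, TEST_DISPLAY_MS[2]) for _ in range(test_repetitions)]

    rng = np.random.default_rng(seed)
    design = Design(
        experiment_id="2",
        group=group,
        stage="training",
        trials=_shuffled(trials, rng),
        counterbalance={c1: f"correlated:{t1}", c2: f"correlated:{t2}",
                        u1: "uncorrelated", u2: "uncorrelated",
                        t1: "target", t2: "target"},
        seed=seed,
    )
    return assign_positions(design, seed)


def build_exp3_design(group: str, seed: int, counterbalance_index: int = 0,
                      repetitions: int = 18, final_test_repetitions: int = 6) -> Design:
    """Experiment 3: Stage 1 in the group's format, Stage 2 serial-with-
    anticipation for everyone, then target-absent final test trials.

    Incongruent groups swap the correlated/uncorrelated roles between stages:
    the Stage-2 role map reassigns each compound's outcome so the previously
    uncorrelated letters become perfectly correlated with a target.
    """
    if group not in EXP3_GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {EXP3_GROUPS}")
    fmt, congruency = group.split("-")
    serial_stage1 = fmt == "Serial"
    c1, c2, u1, u2 = _cue_assignment(("J", "V", "W", "Z"), counterbalance_index)
    t1, t2 = "Q", "P"

    stage1: list[TrialTemplate] = []
    for cues, target in _compounds(c1, c2, u1, u2, t1, t2):
        stage1 += [
            _triplet_trial(cues, target, serial=serial_stage1)
            for _ in range(repetitions)
        ]

    # Stage-2 compounds: same letter pairs; incongruent groups reassign the
    # outcome so the formerly uncorrelated letter of each pair is correlated.
    stage2: list[TrialTemplate] = []
    if congruency == "Congruent":
        stage2_map = _compounds(c1, c2, u1, u2, t1, t2)
        stage2_cb = {c1: f"correlated:{t1}", c2: f"correlated:{t2}",
                     u1: "uncorrelated", u2: "uncorrelated"}
    else:
        # pairs (c1,u1)->t1, (c2,u1)->t1, (c1,u2)->t2, (c2,u2)->t2: u1 is now
        # correlated with t1, u2 with t2, and c1/c2 are uncorrelated.
        stage2_map = [
            ((u1, c1), t1),
            ((u1, c2), t1),
            ((u2, c1), t2),
            ((u2, c2), t2),
        ]
        stage2_cb = {u1: f"correlated:{t1}", u2: f"correlated:{t2}",
                     c1: "uncorrelated", c2: "uncorrelated"}
    for cues, target in stage2_map:
        stage2 += [
            _triplet_trial(cues, target, serial=True, kind="stage2_training",
                           allow_early=True)
            for _ in range(repetitions)
        ]
    final = []
    for cues, _target in stage2_map:
        final += [
            _test_trial(cues, TEST_DISPLAY_MS[3], kind="final_test")
            for _ in range(final_test_repetitions)
        ]

    rng = np.random.default_rng(seed)
    trials = _shuffled(stage1, rng) + _shuffled(stage2, rng) + _shuffled(final, rng)
    design = Design(
        experiment_id="3",
        group=group,
        stage="two-stage",
        trials=trials,
        counterbalance={**{c1: f"stage1-correlated:{t1}", c2: f"stage1-correlated:{t2}",
                           u1: "stage1-uncorrelated", u2: "stage1-uncorrelated",
                           t1: "target", t2: "target"},
                        **{f"stage2:{k}": v for k, v in stage2_cb.items()}},
        seed=seed,
        metadata={"congruency": congruency, "stage1_format": fmt},
    )
    return assign_positions(design, seed)


def build_lepelley_design(n_blocks: int, seed: int = 0) -> Design:
    """Reference learned-predictiveness design: cue pairs AV/AW/BV/BW -> O1/O2
    (and the mirrored DX/DY/CX/CY set), one presentation of each of the eight
    trial types per block.  Used for model validation only.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    table = [
        (("A", "V"), "O1"), (("A", "W"), "O1"),
        (("B", "V"), "O2"), (("B", "W"), "O2"),
        (("D", "X"), "O1"), (("D", "Y"), "O1"),
        (("C", "X"), "O2"), (("C", "Y"), "O2"),
    ]
    rng = np.random.default_rng(seed)
    trials: list[TrialTemplate] = []
    for _ in range(n_blocks):
        block = []
        for (pred, irrel), outcome in table:
            events = (
                StimulusEvent(Stimulus(pred, "predictive"), 0, CUE_DUR_MS),
                StimulusEvent(Stimulus(irrel, "irrelevant"), 0, CUE_DUR_MS),
            )
            block.append(TrialTemplate(
                trial_kind="training", events=events, correct_response=outcome))
        trials += _shuffled(block, rng)
    return Design(
        experiment_id="lepelley",
        group="reference",
        stage="training",
        trials=trials,
        counterbalance={s: r for s, r in
                        [("A", "predictive"), ("B", "predictive"),
                         ("C", "predictive"), ("D", "predictive"),
                         ("V", "irrelevant"), ("W", "irrelevant"),
                         ("X", "irrelevant"), ("Y", "irrelevant")]},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# position assignment


def _balanced_sequences(n: int, arrangements: list, rng: np.random.Generator):
    """A length-``n`` shuffled sequence cycling over ``arrangements`` so that
    per-arrangement counts differ by at most one."""
    reps = -(-n // len(arrangements))
    seq = (arrangements * reps)[:n]
    order = rng.permutation(n)
    return [seq[i] for i in order]


def assign_positions(design: Design, seed: int) -> Design:
    """Assign each stimulus to one of the three apex slots so that, over the
    design, every role occupies every slot equally often (counts differ by at
    most 1).  Balanced slot sequences are constructed per trial arity and then
    shuffled, which guarantees the marginal balance by construction.
    """
    rng = np.random.default_rng(seed)
    three = [t for t in design.trials if len(t.events) == 3]
    two = [t for t in design.trials if len(t.events) == 2]

    # three stimuli: the 6 permutations of slots over the role-sorted events
    perms3 = list(itertools.permutations(SLOTS))
    seq3 = _balanced_sequences(len(three), perms3, rng)
    # two stimuli: ordered pairs of distinct slots (6 arrangements)
    perms2 = list(itertools.permutations(SLOTS, 2))
    seq2 = _balanced_sequences(len(two), perms2, rng)

    assigned: dict[int, TrialTemplate] = {}
    it3, it2 = iter(seq3), iter(seq2)
    for idx, trial in enumerate(design.trials):
        slots = next(it3) if len(trial.events) == 3 else next(it2)
        # deterministic event order: sort by role name so that the same role
        # always consumes the same position of the arrangement
        order = sorted(range(len(trial.events)),
                       key=lambda i: trial.events[i].stimulus.role)
        new_events = list(trial.events)
        for k, i in enumerate(order):
            new_events[i] = replace(trial.events[i], slot=slots[k])
        assigned[idx] = replace(trial, events=tuple(new_events))

    new_trials = [assigned[i] for i in range(len(design.trials))]
    return replace_design_trials(design, new_trials)


def replace_design_trials(design: Design, trials: list[TrialTemplate]) -> Design:
    return Design(
        experiment_id=design.experiment_id,
        group=design.group,
        stage=design.stage,
        trials=trials,
        counterbalance=design.counterbalance,
        seed=design.seed,
        metadata=design.metadata,
    )


# ---------------------------------------------------------------------------
# serialization


def design_to_json(design: Design) -> str:
    obj = {
        "experiment_id": design.experiment_id,
        "group": design.group,
        "stage": design.stage,
        "seed": design.seed,
        "counterbalance": design.counterbalance,
        "metadata": design.metadata,
        "trials": [
            {
                "kind": t.trial_kind,
                "stimuli": [
                    {"label": e.stimulus.label, "role": e.stimulus.role,
                     "slot": e.slot, "onset_ms": e.onset_ms, "dur_ms": e.dur_ms}
                    for e in t.events
                ],
                "correct_response": t.correct_response,
                "allow_early_response": t.allow_early_response,
                "display_duration_ms": t.display_duration_ms,
            }
            for t in design.trials
        ],
    }
    return json.dumps(obj, indent=1)


def design_from_json(text: str) -> Design:
    obj = json.loads(text)
    trials = []
    for t in obj["trials"]:
        events = tuple(
            StimulusEvent(Stimulus(s["label"], s["role"]), s["onset_ms"],
                          s["dur_ms"], s["slot"])
            for s in t["stimuli"]
        )
        trials.append(TrialTemplate(
            trial_kind=t["kind"],
            events=events,
            correct_response=t["correct_response"],
            display_duration_ms=t.get("display_duration_ms"),
            allow_early_response=t.get("allow_early_response", False),
        ))
    return Design(
        experiment_id=obj["experiment_id"],
        group=obj["group"],
        stage=obj["stage"],
        trials=trials,
        counterbalance=obj["counterbalance"],
        seed=obj["seed"],
        metadata=obj.get("metadata", {}),
    )
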