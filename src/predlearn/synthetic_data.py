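"""Synthetic participant data with the statistical structure the analyses
assume.

The generator emulates, per participant: fixation sequences over the three
ROIs with a configurable correlated-vs-uncorrelated dwell bias, key responses
with configurable accuracy and per-mode RT distributions (including the
anticipatory-RT shift of the group allowed to respond early), tracker data
loss, and 10-point questionnaire ratings.

Dwell structure: on each trial the proportions of gaze time on the target,
correlated and uncorrelated ROIs are drawn from truncated normals whose means
are (baseline + bias/2) for the correlated and (baseline - bias/2) for the
uncorrelated stimulus; the remaining time is split between tracked off-ROI
gaze and untracked (missing) time, so the configured missing fraction is
exactly the gap between expected and recorded gaze time.  Participants carry
a normally distributed random effect on the bias, so cohort-level tests see
realistic between-subject variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import Design
from .gaze_pipeline import RoiLayout

__all__ = [
    "ParticipantProfile",
    "ParticipantDataset",
    "default_profile",
    "generate_participant",
    "generate_cohort",
    "write_dataset",
    "read_fixation_report",
]


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters for one participant's data.

    Dwell parameters are proportions of the trial's gaze window; RT
    parameters are milliseconds.  ``anticipation_onset_block`` only matters
    for designs that allow early responding: the probability of an
    anticipatory response ramps linearly from 0 at that block to 1 at the
    final block.
    """

    group: str
    accuracy: float = 0.96
    rt_to_target_ms: tuple[float, float] = (600.0, 150.0)  # after target onset
    rt_anticipatory_ms: tuple[float, float] = (1000.0, 200.0)  # after cue onset
    anticipation_onset_block: int = 1
    dwell_bias_effect: float = 0.0
    dwell_bias_between_sd: float = 0.02
    dwell_base_cue: float = 0.10
    dwell_base_target: float = 0.45
    dwell_base_cue_test: float = 0.20
    dwell_noise_sd: float = 0.03
    missing_rate: float = 0.05
    questionnaire_effect: float = 4.0
    rating_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("accuracy", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dwell_noise_sd < 0 or self.rating_noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")


def default_profile(group: str, dwell_bias_effect: float | None = None
                    ) -> ParticipantProfile:
    """Profiles mirroring each group's qualitative behaviour: anticipatory
    responding (and a dwell bias) only where early responses are allowed."""
    if dwell_bias_effect is None:
        dwell_bias_effect = 0.06 if group == "Serial-Stimuli" else 0.0
    return ParticipantProfile(group=group, dwell_bias_effect=dwell_bias_effect,
                              anticipation_onset_block=2)


@dataclass
class ParticipantDataset:
    participant: str
    group: str
    design: Design
    fixations: pd.DataFrame  # trial, start_ms, end_ms, x_px, y_px
    responses: pd.DataFrame  # trial, kind, key, correct, rt_ms
    ratings: pd.DataFrame    # stimulus, target, rating


def generate_participant(design: Design, profile: ParticipantProfile,
                         seed, layout: RoiLayout | None = None
                         ) -> ParticipantDataset:
    """Simulate one participant's fixations, responses and questionnaire.

    ``seed`` may be an int or a numpy SeedSequence.  The participant's dwell
    bias is the profile mean plus a between-subject normal deviate.
    """
    if profile.group != design.group:
        raise ValueError(
            f"profile group {profile.group!r} does not match design group "
            f"{design.group!r}")
    layout = layout or RoiLayout.default()
    rng = np.random.default_rng(seed)
    trials = design.trials
    n = len(trials)

    bias = profile.dwell_bias_effect + rng.normal(0, profile.dwell_bias_between_sd)

    # ---- responses (training trials)
    train_idx = [i for i, t in enumerate(trials) if t.correct_response is not None]
    n_train = len(train_idx)
    allow_early = np.array([trials[i].allow_early_response for i in train_idx])
    t_onset = np.array([trials[i].target_onset_ms or 0 for i in train_idx], float)
    n_blocks = max(n_train // 18, 1)
    block = np.minimum(np.arange(n_train) // 18, n_blocks - 1)

    ramp = np.zeros(n_train)
    if n_blocks > 1:
        start = profile.anticipation_onset_block
        ramp = np.clip((block - start) / max(n_blocks - 1 - start, 1), 0, 1)
    anticipatory = allow_early & (rng.random(n_train) < ramp) & (t_onset > 0)

    mu_t, sd_t = profile.rt_to_target_ms
    mu_a, sd_a = profile.rt_anticipatory_ms
    rt = np.where(
        anticipatory,
        rng.normal(mu_a, sd_a, n_train),
        t_onset + rng.normal(mu_t, sd_t, n_train),
    )
    # keep RTs inside the physically possible window
    upper = np.array([trials[i].end_ms or 6000 for i in train_idx], float)
    rt = np.clip(rt, 150.0, np.maximum(upper, 500.0))
    rt = np.where(anticipatory, np.minimum(rt, t_onset - 1), rt)

    correct = rng.random(n_train) < profile.accuracy
    keys = []
    targets = sorted({t.correct_response for t in design.training_trials})
    for i, ok in zip(train_idx, correct):
        truth = trials[i].correct_response
        keys.append(truth if ok else [o for o in targets if o != truth][0])
    responses = pd.DataFrame({
        "trial": train_idx,
        "kind": [trials[i].trial_kind for i in train_idx],
        "key": keys,
        "correct": correct,
        "rt_ms": rt,
    })

    # ---- fixations
    rt_by_trial = dict(zip(train_idx, rt))
    denom = np.array([
        t.display_duration_ms if t.correct_response is None else rt_by_trial[i]
        for i, t in enumerate(trials)
    ], float)

    roles = ["target", "correlated", "uncorrelated"]
    # slot centres per trial and role; NaN when the role is absent
    centers = np.asarray(layout.centers)
    pos = np.full((n, 3, 2), np.nan)
    for i, t in enumerate(trials):
        for e in t.events:
            r = roles.index(e.stimulus.role) if e.stimulus.role in roles else None
            if r is not None and e.slot is not None:
                pos[i, r] = centers[e.slot]

    means = np.zeros((n, 3))
    for i, t in enumerate(trials):
        has_target = any(e.stimulus.role == "target" for e in t.events)
        base = (profile.dwell_base_cue if has_target
                else profile.dwell_base_cue_test)
        means[i] = [profile.dwell_base_target if has_target else 0.0,
                    base + bias / 2, base - bias / 2]
    shares = np.clip(rng.normal(means, profile.dwell_noise_sd), 0.0, None)
    shares[np.isnan(pos[:, :, 0])] = 0.0  # no ROI on screen, no dwell there
    # leave room for the configured missing fraction
    cap = 1.0 - profile.missing_rate
    total = shares.sum(axis=1)
    over = total > cap
    shares[over] *= (cap / total[over])[:, None]
    off = cap - shares.sum(axis=1)

    jitter_scale = layout.half_px * 0.6
    fix_rows = []
    segs_dur = np.concatenate([shares * denom[:, None],
                               (off * denom)[:, None]], axis=1)  # n x 4
    order = np.argsort(rng.random((n, 4)), axis=1)
    for i in range(n):
        t0 = 0.0
        for k in order[i]:
            d = segs_dur[i, k]
            if d < 1.0:
                continue
            if k < 3:
                if np.isnan(pos[i, k, 0]):
                    t0 += d
                    continue
                x = pos[i, k, 0] + rng.uniform(-jitter_scale, jitter_scale)
                y = pos[i, k, 1] + rng.uniform(-jitter_scale, jitter_scale)
            else:  # tracked off-ROI gaze: screen centre, outside every ROI
                x, y = 960.0 + rng.uniform(-20, 20), 540.0 + rng.uniform(-20, 20)
            fix_rows.append((i, t0, t0 + d, x, y))
            t0 += d
    fixations = pd.DataFrame(fix_rows,
                             columns=["trial", "start_ms", "end_ms",
                                      "x_px", "y_px"])

    # ---- questionnaire
    role_of: dict[str, str] = {}
    paired: dict[str, str] = {}
    for t in design.training_trials:
        for e in t.events:
            if e.stimulus.role == "correlated":
                role_of[e.stimulus.label] = "correlated"
                paired[e.stimulus.label] = t.correct_response
            elif e.stimulus.role == "uncorrelated":
                role_of.setdefault(e.stimulus.label, "uncorrelated")
    rating_rows = []
    for label in sorted(role_of):
        for target in targets:
            mu = 5.5
            if role_of[label] == "correlated":
                mu += (profile.questionnaire_effect / 2
                       if target == paired[label]
                       else -profile.questionnaire_effect / 2)
            raw = rng.normal(mu, profile.rating_noise_sd)
            rating_rows.append((label, target,
                                int(np.clip(np.rint(raw), 1, 10))))
    ratings = pd.DataFrame(rating_rows,
                           columns=["stimulus", "target", "rating"])

    return ParticipantDataset(
        participant=f"p{seed if isinstance(seed, int) else 'x'}",
        group=design.group,
        design=design,
        fixations=fixations,
        responses=responses,
        ratings=ratings,
    )


def generate_cohort(design_builder, group_sizes: dict, profiles: dict,
                    seed: int) -> list[ParticipantDataset]:
    """Independent participants with per-participant seed derivation.

    ``design_builder(group, seed)`` returns the design a participant of that
    group experiences; ``profiles[group]`` their generative profile.  The
    whole cohort is a deterministic function of the master seed.
    """
    root = np.random.SeedSequence(seed)
    datasets = []
    pid = 0
    for group in sorted(group_sizes):
        size = group_sizes[group]
        if size < 1:
            raise ValueError("group sizes must be >= 1")
        for _ in range(size):
            child = root.spawn(1)[0]
            design_seed = int(child.generate_state(1)[0] % (2**31))
            design = design_builder(group, design_seed)
            ds = generate_participant(design, profiles[group], child)
            ds.participant = f"p{pid:03d}"
            datasets.append(ds)
            pid += 1
    return datasets


# ---------------------------------------------------------------------------
# on-disk dialects


def write_dataset(ds: ParticipantDataset, outdir) -> None:
    """Fixation report TSV + responses/ratings CSV, one trio per participant."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fx = ds.fixations.copy()
    fx.insert(0, "participant", ds.participant)
    fx.to_csv(out / f"{ds.participant}_fixations.tsv", sep="\t", index=False)
    ds.responses.assign(participant=ds.participant).to_csv(
        out / f"{ds.participant}_responses.csv", index=False)
    ds.ratings.assign(participant=ds.participant).to_csv(
        out / f"{ds.participant}_ratings.csv", index=False)


def read_fixation_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"trial", "start_ms", "end_ms", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fixation report lacks columns: {sorted(missing)}")
    return df
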