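"""From raw fixation tables to the analysis quantities.

The experiments measure overt attention as *dwell proportion*: the total
fixation time inside a stimulus's region of interest (ROI) on a trial,
divided by the response time on that trial (training trials) or by the fixed
display duration (target-absent test trials, where no response is required).
ROIs are squares centred on the three apex positions of a notional triangle.

Coordinates are screen pixels, origin top-left, y increasing downwards; ROI
containment is boundary-inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import Design

__all__ = [
    "RoiLayout",
    "assign_fixations",
    "dwell_proportions",
    "participant_quality",
    "apply_exclusions",
    "block_means",
    "questionnaire_role_map",
    "difference_scores",
]

SCREEN_PX = (1920, 1080)
PX_PER_CM = 37.8  # 96 dpi
ROI_CM = 2.7

#: missing-gaze and accuracy exclusion thresholds
MISSING_THRESHOLD = 0.20
ACCURACY_THRESHOLD = 0.60


@dataclass(frozen=True)
class RoiLayout:
    """Square ROIs (center, half-width, px) for the three apex slots."""

    centers: tuple[tuple[float, float], ...]
    half_px: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.centers, float)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if (np.abs(pts[i] - pts[j]) <= 2 * self.half_px).all():
                    raise ValueError("ROIs overlap")

    @classmethod
    def default(cls) -> "RoiLayout":
        w, h = SCREEN_PX
        return cls(
            centers=((w / 2, h / 2 - 300), (w / 2 - 400, h / 2 + 250),
                     (w / 2 + 400, h / 2 + 250)),
            half_px=ROI_CM * PX_PER_CM / 2,
        )

    def slot_of(self, x, y):
        """Vectorised point->slot lookup; -1 where outside every ROI."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        out = np.full(x.shape, -1, dtype=int)
        for s, (cx, cy) in enumerate(self.centers):
            inside = ((np.abs(x - cx) <= self.half_px)
                      & (np.abs(y - cy) <= self.half_px))
            out[inside & (out == -1)] = s
        return out


def assign_fixations(fixations: pd.DataFrame, layout: RoiLayout,
                     design: Design) -> pd.DataFrame:
    """Accrue fixation time to stimulus roles, per trial.

    ``fixations`` needs columns trial, start_ms, end_ms, x_px, y_px.  Returns
    one row per trial with dwell milliseconds per role plus ``off`` (tracked
    gaze outside every ROI) and ``recorded`` (total fixation time).
    """
    n_trials = len(design.trials)
    bad = set(fixations["trial"]) - set(range(n_trials))
    if bad:
        raise KeyError(f"fixations reference unknown trials: {sorted(bad)[:5]}")

    roles = sorted({e.stimulus.role for t in design.trials for e in t.events})
    # (trial, slot) -> role index lookup table
    role_idx = {r: i for i, r in enumerate(roles)}
    lut = np.full((n_trials, len(layout.centers)), -1, dtype=int)
    for ti, t in enumerate(design.trials):
        for e in t.events:
            if e.slot is not None:
                lut[ti, e.slot] = role_idx[e.stimulus.role]

    dur = (fixations["end_ms"] - fixations["start_ms"]).to_numpy(float)
    if (dur <= 0).any():
        raise ValueError("fixation end must be after start")
    trial = fixations["trial"].to_numpy(int)
    slot = layout.slot_of(fixations["x_px"].to_numpy(),
                          fixations["y_px"].to_numpy())
    role = np.where(slot >= 0, lut[trial, np.clip(slot, 0, None)], -1)

    out = np.zeros((n_trials, len(roles) + 2))
    for ri in range(len(roles)):
        np.add.at(out[:, ri], trial[role == ri], dur[role == ri])
    np.add.at(out[:, len(roles)], trial[role == -1], dur[role == -1])
    np.add.at(out[:, len(roles) + 1], trial, dur)
    df = pd.DataFrame(out, columns=roles + ["off", "recorded"])
    df.insert(0, "trial", np.arange(n_trials))
    df.insert(1, "kind", [t.trial_kind for t in design.trials])
    return df


def trial_denominators(design: Design, responses: pd.DataFrame) -> np.ndarray:
    """Per-trial normalising duration: the response time on responded
    (training) trials, the fixed display duration on test trials."""
    rt = dict(zip(responses["trial"], responses["rt_ms"]))
    denom = np.empty(len(design.trials))
    for i, t in enumerate(design.trials):
        if t.correct_response is None:
            if not t.display_duration_ms:
                raise ValueError(f"test trial {i} lacks a display duration")
            denom[i] = t.display_duration_ms
        else:
            if i not in rt:
                raise KeyError(f"no response recorded for training trial {i}")
            if rt[i] <= 0:
                raise ValueError(f"non-positive RT on trial {i}")
            denom[i] = rt[i]
    return denom


def dwell_proportions(trial_dwell: pd.DataFrame, responses: pd.DataFrame,
                      design: Design) -> pd.DataFrame:
    """Dwell milliseconds -> proportions of the trial's denominator.

    Raises when recorded dwell exceeds the denominator (an impossible trial,
    indicating clock mismatch between fixations and responses).
    """
    denom = trial_denominators(design, responses)
    denom = denom[trial_dwell["trial"].to_numpy(int)]
    value_cols = [c for c in trial_dwell.columns if c not in ("trial", "kind")]
    out = trial_dwell.copy()
    if (out["recorded"].to_numpy() > denom + 1e-6).any():
        raise ValueError("recorded dwell exceeds the trial duration")
    for c in value_cols:
        out[c] = out[c] / denom
    out["denominator_ms"] = denom
    return out


def participant_quality(trial_dwell: pd.DataFrame, responses: pd.DataFrame,
                        design: Design) -> dict:
    """Missing-gaze fraction and response accuracy over training trials.

    Missing data = (expected gaze time - recorded fixation time) / expected,
    where expected gaze time is the trial denominator.
    """
    denom = trial_denominators(design, responses)
    training = np.array([t.correct_response is not None for t in design.trials])
    rec = trial_dwell.sort_values("trial")["recorded"].to_numpy()
    expected = denom[training].sum()
    missing = float((expected - rec[training].sum()) / expected)
    accuracy = float(responses["correct"].mean())
    return {"missing_frac": missing, "accuracy": accuracy}


def apply_exclusions(quality: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the preregistered-style exclusion rules to a cohort.

    ``quality`` has one row per participant with columns participant,
    missing_frac, accuracy.  Participants with more than 20% missing gaze
    data, or below 60% correct responses, are removed.  Returns (retained
    rows, exclusion report).
    """
    reasons = []
    for _, row in quality.iterrows():
        why = []
        if row["missing_frac"] > MISSING_THRESHOLD:
            why.append("missing_data")
        if row["accuracy"] < ACCURACY_THRESHOLD:
            why.append("accuracy")
        reasons.append(why)
    excluded = [bool(w) for w in reasons]
    report = quality.assign(
        excluded=excluded,
        reason=[",".join(w) if w else "" for w in reasons],
    )
    retained = quality.loc[[not e for e in excluded]]
    return retained, report


def block_means(proportions: pd.DataFrame, responses: pd.DataFrame,
                block_size: int = 18,
                roles=("target", "correlated", "uncorrelated")) -> pd.DataFrame:
    """Blocked means of dwell proportion (per role), accuracy and RT over
    training trials.  Blocks are counted over training trials in their
    presented order; a partial final block is averaged as-is and flagged.
    """
    train = proportions[proportions["kind"].isin(
        ["training", "stage2_training"])].sort_values("trial")
    resp = responses.sort_values("trial").reset_index(drop=True)
    order = {t: i for i, t in enumerate(train["trial"])}
    block = train["trial"].map(order).to_numpy() // block_size

    rows = []
    present = [r for r in roles if r in train.columns]
    rt = dict(zip(resp["trial"], resp["rt_ms"]))
    acc = dict(zip(resp["trial"], resp["correct"]))
    tmp = train.assign(
        block=block,
        rt_ms=train["trial"].map(rt),
        accuracy=train["trial"].map(acc).astype(float),
    )
    agg = tmp.groupby("block", as_index=False)[present + ["rt_ms", "accuracy"]].mean()
    agg["n_trials"] = tmp.groupby("block").size().to_numpy()
    agg["partial"] = agg["n_trials"] < block_size
    return agg


def questionnaire_role_map(design: Design) -> dict:
    """Which target each stimulus's difference score is oriented toward.

    Correlated stimuli: paired target minus the other target.  Uncorrelated
    stimuli: a fixed arbitrary orientation, alternating over the uncorrelated
    set so that the expected score is zero under no knowledge.
    """
    targets = sorted({t.correct_response for t in design.training_trials
                      if t.correct_response})
    paired: dict[str, str] = {}
    roles: dict[str, str] = {}
    for t in design.training_trials:
        for e in t.events:
            if e.stimulus.role == "correlated":
                paired[e.stimulus.label] = t.correct_response
                roles[e.stimulus.label] = "correlated"
            elif e.stimulus.role == "uncorrelated":
                roles.setdefault(e.stimulus.label, "uncorrelated")
    orient = {}
    flip = False
    for label in sorted(roles):
        if roles[label] == "correlated":
            first = paired[label]
        else:
            first = targets[1] if flip else targets[0]
            flip = not flip
        second = [t for t in targets if t != first][0]
        orient[label] = {"role": roles[label], "first": first, "second": second}
    return orient


def difference_scores(ratings: pd.DataFrame, role_map: dict
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Questionnaire difference scores: rating(stimulus, first target) minus
    rating(stimulus, other target), averaged per role.

    ``ratings`` has columns stimulus, target, rating (1-10); a missing
    stimulus x target cell raises.
    """
    pivot = ratings.pivot_table(index="stimulus", columns="target",
                                values="rating")
    rows = []
    for label, ori in role_map.items():
        try:
            a = pivot.loc[label, ori["first"]]
            b = pivot.loc[label, ori["second"]]
        except KeyError as exc:
            raise KeyError(f"missing rating for stimulus {label}: {exc}") from exc
        if np.isnan(a) or np.isnan(b):
            raise ValueError(f"missing rating for stimulus {label}")
        rows.append({"stimulus": label, "role": ori["role"],
                     "score": float(a - b)})
    df = pd.DataFrame(rows)
    means = df.groupby("role", as_index=False)["score"].mean()
    return df, means
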