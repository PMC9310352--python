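"""ROI assignment, dwell proportions, exclusions, blocks, difference scores."""

import numpy as np
import pandas as pd
import pytest

from predlearn.designs import build_exp2_design
from predlearn.gaze_pipeline import (RoiLayout, apply_exclusions,
                                     assign_fixations, block_means,
                                     difference_scores, dwell_proportions,
                                     participant_quality,
                                     questionnaire_role_map)
from predlearn.synthetic_data import (ParticipantProfile, default_profile,
                                      generate_participant)


def fix_df(rows):
    return pd.DataFrame(rows, columns=["trial", "start_ms", "end_ms",
                                       "x_px", "y_px"])


class TestAssignFixations:
    def test_containment_accrues_to_role(self, exp1_design, layout):
        trial = exp1_design.trials[0]
        target_slot = next(e.slot for e in trial.events
                           if e.stimulus.role == "target")
        cx, cy = layout.centers[target_slot]
        out = assign_fixations(fix_df([(0, 100, 400, cx, cy)]), layout,
                               exp1_design)
        assert out.loc[0, "target"] == 300
        assert out.loc[0, "off"] == 0

    def test_boundary_is_inclusive(self, exp1_design, layout):
        trial = exp1_design.trials[0]
        slot = trial.events[0].slot
        cx, cy = layout.centers[slot]
        edge = cx + layout.half_px  # exactly on the ROI border
        out = assign_fixations(fix_df([(0, 0, 200, edge, cy)]), layout,
                               exp1_design)
        role = trial.events[0].stimulus.role
        assert out.loc[0, role] == 200

    def test_outside_all_rois_counts_as_off(self, exp1_design, layout):
        out = assign_fixations(fix_df([(0, 0, 500, 5.0, 5.0)]), layout,
                               exp1_design)
        assert out.loc[0, "off"] == 500
        assert out.loc[0, ["correlated", "uncorrelated", "target"]].sum() == 0

    def test_unknown_trial_raises(self, exp1_design, layout):
        with pytest.raises(KeyError):
            assign_fixations(fix_df([(9999, 0, 100, 0, 0)]), layout,
                             exp1_design)

    def test_row_order_invariance(self, serial_stimuli_participant, layout):
        ds = serial_stimuli_participant
        a = assign_fixations(ds.fixations, layout, ds.design)
        shuffled = ds.fixations.sample(frac=1.0, random_state=0)
        b = assign_fixations(shuffled, layout, ds.design)
        pd.testing.assert_frame_equal(a, b)


class TestDwellProportions:
    def test_training_trial_uses_rt(self, exp1_design, layout):
        trial = exp1_design.trials[0]
        slot = next(e.slot for e in trial.events
                    if e.stimulus.role == "correlated")
        cx, cy = layout.centers[slot]
        dwell = assign_fixations(fix_df([(0, 0, 400, cx, cy)]), layout,
                                 exp1_design)
        responses = pd.DataFrame({
            "trial": [i for i, t in enumerate(exp1_design.trials)
                      if t.correct_response],
        })
        responses["rt_ms"] = 1000.0
        props = dwell_proportions(dwell, responses, exp1_design)
        idx = props.index[props["trial"] == 0][0]
        if exp1_design.trials[0].correct_response:
            assert props.loc[idx, "correlated"] == pytest.approx(0.4)

    def test_test_trial_uses_display_duration(self, exp1_design, layout):
        test_idx = next(i for i, t in enumerate(exp1_design.trials)
                        if t.correct_response is None)
        trial = exp1_design.trials[test_idx]
        cx, cy = layout.centers[trial.events[0].slot]
        dwell = assign_fixations(fix_df([(test_idx, 0, 1000, cx, cy)]),
                                 layout, exp1_design)
        responses = pd.DataFrame({
            "trial": [i for i, t in enumerate(exp1_design.trials)
                      if t.correct_response],
        })
        responses["rt_ms"] = 900.0
        props = dwell_proportions(dwell, responses, exp1_design)
        role = trial.events[0].stimulus.role
        row = props[props["trial"] == test_idx].iloc[0]
        assert row["denominator_ms"] == 5000  # fixed display, not an RT
        assert row[role] == pytest.approx(0.2)

    def test_dwell_exceeding_denominator_raises(self, exp1_design, layout):
        dwell = assign_fixations(
            fix_df([(0, 0, 3000, *RoiLayout.default().centers[0])]), layout,
            exp1_design)
        responses = pd.DataFrame({
            "trial": [i for i, t in enumerate(exp1_design.trials)
                      if t.correct_response]})
        responses["rt_ms"] = 500.0
        with pytest.raises(ValueError, match="exceeds"):
            dwell_proportions(dwell, responses, exp1_design)

    def test_nonpositive_rt_raises(self, exp1_design, layout):
        dwell = assign_fixations(fix_df([]), layout, exp1_design)
        responses = pd.DataFrame({
            "trial": [i for i, t in enumerate(exp1_design.trials)
                      if t.correct_response]})
        responses["rt_ms"] = 0.0
        with pytest.raises(ValueError, match="non-positive RT"):
            dwell_proportions(dwell, responses, exp1_design)

    def test_role_plus_off_shares_account_for_all_recorded_time(
            self, serial_stimuli_participant, layout):
        ds = serial_stimuli_participant
        dwell = assign_fixations(ds.fixations, layout, ds.design)
        props = dwell_proportions(dwell, ds.responses, ds.design)
        parts = props[["target", "correlated", "uncorrelated", "off"]].sum(1)
        assert np.allclose(parts, props["recorded"], atol=1e-9)


class TestRoundTrip:
    def test_noise_free_shares_recovered_exactly(self, layout):
        """Generator -> pipeline round trip is exact without noise/missing."""
        design = build_exp2_design("Simultaneous", seed=4)
        profile = ParticipantProfile(
            group="Simultaneous", dwell_bias_effect=0.08,
            dwell_bias_between_sd=0.0, dwell_noise_sd=0.0, missing_rate=0.0,
            rt_to_target_ms=(800.0, 0.0))
        ds = generate_participant(design, profile, seed=0, layout=layout)
        dwell = assign_fixations(ds.fixations, layout, design)
        props = dwell_proportions(dwell, ds.responses, design)
        train = props[props["kind"] == "training"]
        assert train["correlated"].mean() == pytest.approx(0.14, abs=1e-9)
        assert train["uncorrelated"].mean() == pytest.approx(0.06, abs=1e-9)
        assert train["target"].mean() == pytest.approx(0.45, abs=1e-9)


class TestExclusions:
    def quality(self, missing, accuracy):
        return pd.DataFrame({
            "participant": [f"p{i}" for i in range(len(missing))],
            "missing_frac": missing, "accuracy": accuracy})

    def test_missing_data_rule(self):
        retained, report = apply_exclusions(self.quality([0.25, 0.05],
                                                         [0.9, 0.9]))
        assert list(retained["participant"]) == ["p1"]
        assert report.loc[0, "reason"] == "missing_data"

    def test_accuracy_rule(self):
        retained, report = apply_exclusions(self.quality([0.0], [0.59]))
        assert retained.empty
        assert report.loc[0, "reason"] == "accuracy"

    def test_clean_cohort_untouched(self):
        q = self.quality([0.1, 0.0], [0.95, 0.61])
        retained, report = apply_exclusions(q)
        assert len(retained) == 2
        assert not report["excluded"].any()

    def test_generator_missing_rate_triggers_rule_downstream(self, layout):
        design = build_exp2_design("Simultaneous", seed=4)
        profile = ParticipantProfile(group="Simultaneous", missing_rate=0.25)
        ds = generate_participant(design, profile, seed=1, layout=layout)
        dwell = assign_fixations(ds.fixations, layout, design)
        q = participant_quality(dwell, ds.responses, design)
        _, report = apply_exclusions(pd.DataFrame([{"participant": "p0", **q}]))
        assert report.loc[0, "excluded"]
        assert "missing_data" in report.loc[0, "reason"]


class TestBlockMeans:
    def make(self, n_trials, value=0.3):
        props = pd.DataFrame({
            "trial": range(n_trials), "kind": "training",
            "correlated": value, "uncorrelated": value, "target": value,
        })
        resp = pd.DataFrame({"trial": range(n_trials), "rt_ms": 1000.0,
                             "correct": True})
        return props, resp

    @pytest.mark.parametrize("n,expected", [(288, 16), (144, 8)])
    def test_block_counts(self, n, expected):
        bm = block_means(*self.make(n), block_size=18)
        assert len(bm) == expected
        assert not bm["partial"].any()

    def test_constant_input_gives_constant_means(self):
        bm = block_means(*self.make(144, value=0.3))
        assert np.allclose(bm["correlated"], 0.3)
        assert np.allclose(bm["accuracy"], 1.0)

    def test_partial_final_block_flagged(self):
        bm = block_means(*self.make(40), block_size=18)
        assert len(bm) == 3
        assert list(bm["partial"]) == [False, False, True]
        assert bm["n_trials"].iloc[-1] == 4


class TestDifferenceScores:
    def test_arithmetic(self, exp1_design):
        role_map = questionnaire_role_map(exp1_design)
        corr = next(k for k, v in role_map.items() if v["role"] == "correlated")
        rows = []
        for label, ori in role_map.items():
            rows.append({"stimulus": label, "target": ori["first"],
                         "rating": 9 if label == corr else 5})
            rows.append({"stimulus": label, "target": ori["second"],
                         "rating": 2 if label == corr else 5})
        scores, means = difference_scores(pd.DataFrame(rows), role_map)
        assert scores.set_index("stimulus").loc[corr, "score"] == 7

    def test_equal_ratings_give_zero(self, exp1_design):
        role_map = questionnaire_role_map(exp1_design)
        rows = [{"stimulus": k, "target": t, "rating": 6}
                for k, v in role_map.items()
                for t in (v["first"], v["second"])]
        scores, means = difference_scores(pd.DataFrame(rows), role_map)
        assert (scores["score"] == 0).all()

    def test_missing_rating_raises(self, exp1_design):
        role_map = questionnaire_role_map(exp1_design)
        rows = [{"stimulus": k, "target": v["first"], "rating": 5}
                for k, v in role_map.items()]
        with pytest.raises((KeyError, ValueError)):
            difference_scores(pd.DataFrame(rows), role_map)

    def test_generator_effect_recovered(self, layout):
        """questionnaire_effect=4 -> correlated scores near 4, uncorrelated
        near 0, averaging over participants."""
        design = build_exp2_design("Serial-Stimuli", seed=2)
        profile = default_profile("Serial-Stimuli")
        role_map = questionnaire_role_map(design)
        per = []
        for seed in range(40):
            ds = generate_participant(design, profile, seed=seed,
                                      layout=layout)
            scores, means = difference_scores(ds.ratings, role_map)
            per.append(means.set_index("role")["score"])
        mean = pd.concat(per, axis=1).mean(axis=1)
        assert mean["correlated"] == pytest.approx(4.0, abs=0.5)
        assert mean["uncorrelated"] == pytest.approx(0.0, abs=0.5)
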