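"""End-to-end orchestration: design -> synthesize -> pipeline -> stats ->
model comparison, with seed control and a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import designs as D
from . import models as M
from .gaze_pipeline import (RoiLayout, apply_exclusions, assign_fixations,
                            block_means, difference_scores, dwell_proportions,
                            participant_quality, questionnaire_role_map)
from .stats import bonferroni_pairwise, jzs_bf, rm_anova, t_test
from .synthetic_data import (ParticipantDataset, default_profile,
                             generate_cohort, write_dataset)

__all__ = ["RunConfig", "run_experiment", "render_tables",
           "cohort_summaries", "analyze_summaries"]

log = logging.getLogger("predlearn")

GROUPS_BY_EXPERIMENT = {
    1: ("Simultaneous",),
    2: D.EXP2_GROUPS,
    3: D.EXP3_GROUPS,
}
BLOCK_SIZE = 18


@dataclass
class RunConfig:
    experiment: int
    seed: int
    outdir: str
    groups: tuple[str, ...] | None = None
    n_per_group: int = 18
    dwell_bias: dict = field(default_factory=dict)  # group -> injected bias
    model_variants: tuple[str, ...] = M.MODEL_VARIANTS
    write_raw: bool = False

    def __post_init__(self) -> None:
        if self.experiment not in GROUPS_BY_EXPERIMENT:
            raise ValueError(f"unknown experiment {self.experiment}")
        valid = GROUPS_BY_EXPERIMENT[self.experiment]
        if self.groups is None:
            self.groups = tuple(valid)
        unknown = set(self.groups) - set(valid)
        if unknown:
            raise ValueError(
                f"config error (stage=validate): unknown groups {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            obj = yaml.safe_load(fh)
        obj["groups"] = tuple(obj["groups"]) if obj.get("groups") else None
        return cls(**obj)


def _design_builder(experiment: int):
    if experiment == 1:
        return lambda group, seed: D.build_exp1_design(seed)
    if experiment == 2:
        return lambda group, seed: D.build_exp2_design(group, seed)
    return lambda group, seed: D.build_exp3_design(group, seed)


def cohort_summaries(datasets: list[ParticipantDataset],
                     layout: RoiLayout | None = None) -> dict:
    """Run the gaze pipeline over a cohort.

    Returns tidy tables: per-participant quality (for exclusions), blocked
    training means, per-trial test-trial proportions and questionnaire
    difference scores.
    """
    layout = layout or RoiLayout.default()
    quality_rows, block_rows, test_rows, score_rows = [], [], [], []
    for ds in datasets:
        dwell = assign_fixations(ds.fixations, layout, ds.design)
        props = dwell_proportions(dwell, ds.responses, ds.design)
        q = participant_quality(dwell, ds.responses, ds.design)
        quality_rows.append({"participant": ds.participant, "group": ds.group,
                             **q})
        stages = sorted({t for t in props["kind"].unique()
                         if t in ("training", "stage2_training")})
        for stage in stages:
            bm = block_means(props[props["kind"] == stage],
                             ds.responses[ds.responses["kind"] == stage],
                             block_size=BLOCK_SIZE)
            bm.insert(0, "participant", ds.participant)
            bm.insert(1, "group", ds.group)
            bm.insert(2, "stage", stage)
            block_rows.append(bm)
        tests = props[props["kind"].isin(["test", "final_test"])]
        for _, row in tests.iterrows():
            test_rows.append({
                "participant": ds.participant, "group": ds.group,
                "trial": row["trial"],
                "correlated": row.get("correlated", np.nan),
                "uncorrelated": row.get("uncorrelated", np.nan),
            })
        scores, _ = difference_scores(ds.ratings,
                                      questionnaire_role_map(ds.design))
        scores.insert(0, "participant", ds.participant)
        scores.insert(1, "group", ds.group)
        score_rows.append(scores)
    return {
        "quality": pd.DataFrame(quality_rows),
        "blocks": pd.concat(block_rows, ignore_index=True),
        "test_trials": pd.DataFrame(test_rows),
        "scores": pd.concat(score_rows, ignore_index=True),
    }


def analyze_summaries(summaries: dict) -> dict:
    """The study's inferential battery over pipeline summaries.

    Per group: paired t and JZS Bayes factor on test-trial dwell
    (correlated vs uncorrelated), a stimulus-type x block repeated-measures
    ANOVA on training dwell, accuracy against chance, and the questionnaire
    difference-score contrast; across groups (when more than one), a mixed
    ANOVA with the between factor of group and Bonferroni pairwise RT
    comparisons.
    """
    retained, report = apply_exclusions(summaries["quality"])
    keep = set(retained["participant"])
    blocks = summaries["blocks"]
    blocks = blocks[blocks["participant"].isin(keep)]
    tests = summaries["test_trials"]
    tests = tests[tests["participant"].isin(keep)]
    scores = summaries["scores"]
    scores = scores[scores["participant"].isin(keep)]

    results: dict = {"exclusions": report.to_dict("records"), "groups": {}}
    stages = sorted(blocks["stage"].unique())
    for group, gblocks in blocks.groupby("group"):
        gres: dict = {}
        # accuracy against chance, final block of the last stage
        last_stage = stages[-1]
        gb = gblocks[gblocks["stage"] == last_stage]
        final = gb[gb["block"] == gb["block"].max()]
        try:
            acc = t_test(final["accuracy"].to_numpy(), mu=0.5)
            gres["accuracy_vs_chance"] = {
                "t": acc.t, "df": acc.df, "p": acc.p, "mean": acc.mean + 0.5}
        except ValueError:
            gres["accuracy_vs_chance"] = {
                "note": "degenerate (zero variance)",
                "mean": float(final["accuracy"].mean())}

        # training dwell: stimulus type x block, per stage
        for stage in stages:
            sb = gblocks[gblocks["stage"] == stage]
            long = sb.melt(id_vars=["participant", "block"],
                           value_vars=["correlated", "uncorrelated"],
                           var_name="stimulus_type", value_name="dwell")
            res = rm_anova(long, dv="dwell",
                           within=["stimulus_type", "block"],
                           subject="participant")
            gres[f"dwell_anova_{stage}"] = res.table.to_dict("records")

        # test trials: paired t + JZS BF
        gt = tests[tests["group"] == group]
        per = gt.groupby("participant")[["correlated", "uncorrelated"]].mean()
        tt = t_test(per["correlated"].to_numpy(),
                    per["uncorrelated"].to_numpy(), design="paired")
        bf = jzs_bf(tt.t, tt.n)
        gres["test_dwell"] = {
            "t": tt.t, "df": tt.df, "p": tt.p, "mean_diff": tt.mean,
            "bf10": bf.bf10, "bf01": bf.bf01, "bf_report": bf.report()}

        # questionnaire
        gs = scores[scores["group"] == group]
        per_s = gs.pivot_table(index="participant", columns="role",
                               values="score")
        qt = t_test(per_s["correlated"].to_numpy(),
                    per_s["uncorrelated"].to_numpy(), design="paired")
        gres["questionnaire"] = {"t": qt.t, "df": qt.df, "p": qt.p,
                                 "mean_diff": qt.mean}
        results["groups"][group] = gres

    if blocks["group"].nunique() > 1:
        long = blocks[blocks["stage"] == stages[0]].melt(
            id_vars=["participant", "group", "block"],
            value_vars=["correlated", "uncorrelated"],
            var_name="stimulus_type", value_name="dwell")
        res = rm_anova(long, dv="dwell", within=["stimulus_type", "block"],
                       subject="participant", between="group")
        results["dwell_mixed_anova"] = res.table.to_dict("records")
        rt_groups = {
            g: gb.groupby("participant")["rt_ms"].mean().to_numpy()
            for g, gb in blocks[blocks["stage"] == stages[0]].groupby("group")}
        results["rt_pairwise_bonferroni"] = bonferroni_pairwise(
            rt_groups).to_dict("records")
    return results


def run_experiment(config: RunConfig) -> dict:
    """Full pipeline for one experiment; deterministic under a fixed config.

    Writes designs, tidy summaries, a stats JSON, the model-prediction table
    and a manifest (seeds, config hash, package version) under
    ``config.outdir`` and returns the bundle in memory.
    """
    from . import __version__

    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    builder = _design_builder(config.experiment)

    log.info("stage=design experiment=%s groups=%s", config.experiment,
             config.groups)
    example_designs = {g: builder(g, config.seed) for g in config.groups}
    for g, d in example_designs.items():
        (out / f"design_{g}.json").write_text(D.design_to_json(d))

    log.info("stage=synthesize n_per_group=%d", config.n_per_group)
    profiles = {
        g: default_profile(g, config.dwell_bias.get(g)) for g in config.groups
    }
    datasets = generate_cohort(builder,
                               {g: config.n_per_group for g in config.groups},
                               profiles, config.seed)
    if config.write_raw:
        for ds in datasets:
            write_dataset(ds, out / "raw")

    log.info("stage=pipeline participants=%d", len(datasets))
    summaries = cohort_summaries(datasets)
    for name, df in summaries.items():
        df.to_csv(out / f"summary_{name}.csv", index=False)

    log.info("stage=stats")
    stats_results = analyze_summaries(summaries)
    (out / "stats.json").write_text(json.dumps(stats_results, indent=1,
                                               default=float))

    log.info("stage=models variants=%s", config.model_variants)
    model_table = M.compare_models(example_designs.values(),
                                   config.model_variants)
    model_table.to_csv(out / "model_predictions.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return {"designs": example_designs, "datasets": datasets,
            "summaries": summaries, "stats": stats_results,
            "model_table": model_table, "manifest": manifest}


def render_tables(bundle: dict) -> dict[str, pd.DataFrame]:
    """Tidy per-figure-panel tables from a report bundle: accuracy by block,
    RT by block, dwell by block x stimulus, test-trial dwell and
    questionnaire difference scores (stage-resolved where applicable)."""
    if not bundle or "summaries" not in bundle or bundle["summaries"] is None:
        raise ValueError("empty report bundle")
    blocks = bundle["summaries"]["blocks"]
    tables = {
        "accuracy_by_block": blocks.groupby(
            ["group", "stage", "block"], as_index=False)["accuracy"].mean(),
        "rt_by_block": blocks.groupby(
            ["group", "stage", "block"], as_index=False)["rt_ms"].mean(),
        "dwell_by_block": blocks.groupby(
            ["group", "stage", "block"], as_index=False)[
                ["target", "correlated", "uncorrelated"]].mean(),
        "test_dwell": bundle["summaries"]["test_trials"].groupby(
            "group", as_index=False)[["correlated", "uncorrelated"]].mean(),
        "difference_scores": bundle["summaries"]["scores"].groupby(
            ["group", "role"], as_index=False)["score"].mean(),
    }
    return tables
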