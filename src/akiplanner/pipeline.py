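"""End-to-end pipeline: generate/ingest -> label -> split -> impute ->
train both planners -> evaluate -> cluster -> export.

All randomness flows from the pipeline's root seed, split deterministically
per stage, so re-running the same config reproduces identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io
from .config import GROUP_NEG, GROUP_POS, PLAN_PARAMS, PREOP_FEATURES, PipelineConfig
from .labeling import label_cohort, stratified_split
from .planners import Imputer, PlannerModel, train_planner
from .risk import EvalReport, PlanScaler, evaluate, kmeans_treatments

log = logging.getLogger("akiplanner")

__all__ = ["PipelineResult", "run_pipeline", "stage_seeds"]

_STAGES = ("cohort", "split", "train_neg", "train_pos", "kmeans", "recommend")


def stage_seeds(root_seed: int) -> Dict[str, int]:
    """Derive one independent sub-seed per stage from the root seed."""
    children = np.random.SeedSequence(root_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    partition: pd.Series
    imputer: Imputer
    model_minus: PlannerModel
    model_plus: PlannerModel
    plan_scaler: PlanScaler
    report_train: EvalReport
    report_test: EvalReport
    clusters: list
    config: PipelineConfig


def run_pipeline(
    config: Optional[PipelineConfig] = None, outdir: Optional[str] = None
) -> PipelineResult:
    """Run every stage and optionally export all artifacts to ``outdir``."""
    config = config or PipelineConfig()
    seeds = stage_seeds(config.seed)

    stage = "ingest"
    try:
        if config.input_csv is not None:
            cohort = io.read_cohort_csv(config.input_csv)
            log.info("ingested %d records from %s", len(cohort), config.input_csv)
        else:
            stage = "generate"
            from .cohort import generate_cohort

            cfg = config.cohort.model_copy(deep=True)
            cfg.seed = seeds["cohort"]
            cohort = generate_cohort(cfg)
            log.info("generated %d records (seed %d)", len(cohort), cfg.seed)
        if len(cohort) == 0:
            raise ValueError("cohort is empty")

        stage = "label"
        cohort = label_cohort(cohort)
        n_pos = int((cohort["Group"] == GROUP_POS).sum())
        log.info("labeled cohort: %d AKI+, %d AKI-", n_pos, len(cohort) - n_pos)

        stage = "split"
        partition = stratified_split(
            cohort, train_fraction=config.train_fraction, seed=seeds["split"]
        )
        train = cohort[partition == "train"]
        test = cohort[partition == "test"]
        log.info("split: %d train / %d test (seed %d)", len(train), len(test), seeds["split"])

        stage = "impute"
        imputer = Imputer.fit(train, columns=PREOP_FEATURES)
        train = imputer.apply(train)
        test = imputer.apply(test)

        stage = "train_planners"
        model_minus = train_planner(
            train[train["Group"] == GROUP_NEG],
            stratum=GROUP_NEG,
            arch=config.arch,
            seed=seeds["train_neg"],
        )
        model_plus = train_planner(
            train[train["Group"] == GROUP_POS],
            stratum=GROUP_POS,
            arch=config.arch,
            seed=seeds["train_pos"],
        )
        log.info(
            "planners trained: AKI- on %d, AKI+ on %d records",
            model_minus.training_meta["n_train"],
            model_plus.training_meta["n_train"],
        )

        stage = "evaluate"
        plan_scaler = PlanScaler.fit_plans(train)
        mode = config.risk.rounding_mode
        report_train = evaluate(model_minus, model_plus, train, plan_scaler, mode=mode)
        report_test = evaluate(model_minus, model_plus, test, plan_scaler, mode=mode)
        log.info(
            "accuracy: train %.3f / test %.3f",
            report_train.metrics["accuracy"],
            report_test.metrics["accuracy"],
        )

        stage = "cluster"
        clusters = kmeans_treatments(
            train[PLAN_PARAMS],
            strata=train["Group"].to_numpy(),
            k=config.risk.n_clusters,
            seed=seeds["kmeans"],
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(
        cohort=cohort,
        partition=partition,
        imputer=imputer,
        model_minus=model_minus,
        model_plus=model_plus,
        plan_scaler=plan_scaler,
        report_train=report_train,
        report_test=report_test,
        clusters=clusters,
        config=config,
    )
    if outdir is not None:
        export_artifacts(result, outdir)
    return result


def export_artifacts(result: PipelineResult, outdir) -> None:
    """Write every artifact (models, report, scatter, clusters) to disk."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    io.write_cohort_csv(result.cohort, out / "labeled.csv")
    pd.DataFrame(
        {"PatientID": result.cohort["PatientID"], "partition": result.partition}
    ).to_csv(out / "partition.csv", index=False)
    result.model_minus.to_json(out / "planner_neg.json")
    result.model_plus.to_json(out / "planner_pos.json")
    for name, rep in (("train", result.report_train), ("test", result.report_test)):
        rep.scatter.to_csv(out / f"scatter_{name}.csv", index=False, float_format="%.10g")
    io.write_report(
        {
            "config": result.config.model_dump(mode="json"),
            "train": result.report_train.to_dict(),
            "test": result.report_test.to_dict(),
            "clusters": [
                {
                    "label": c.label,
                    "member_count": c.member_count,
                    "center": c.center,
                    "ranges": {k: list(v) for k, v in c.ranges.items()},
                }
                for c in result.clusters
            ],
        },
        out / "report.json",
    )
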