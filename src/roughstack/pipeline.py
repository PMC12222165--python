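"""End-to-end orchestration: reduct -> scale/split -> classifiers -> stacks
-> MEREC/TOPSIS ranking -> grid-search refinement of the winning stack.

Every stage is a pure function of (config, seed, input) apart from wall
clock timing fields, and every intermediate table is written under the run
directory together with a final JSON report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mcdm import McdmMatrix, merec_weights, topsis_rank
from .prep import split, standard_scale
from .roughset import (DecisionTable, build_discernibility, discretize,
                       johnson_reduct, select_features)
from .stacking import build_stacks, evaluate_stacks, fit_base_models, fit_stack, pearson_correlation
from .synth import SynthConfig, generate_hd_like
from .tuning import select_best_classifier

log = logging.getLogger("roughstack")

__all__ = ["PipelineConfig", "run_pipeline", "rank_matrix"]

#: default criterion directions for the 8 canonical metrics
DEFAULT_DIRECTIONS = {"Ac": "benefit", "Pr": "benefit", "Sp": "benefit",
                      "Sn": "benefit", "F1": "benefit", "MCC": "benefit",
                      "MAE": "cost", "Tt": "cost"}


@dataclass
class PipelineConfig:
    """Full-pipeline configuration; exactly one of ``input_csv`` /
    ``synth`` must be set."""

    seed: int
    input_csv: str | None = None
    synth: SynthConfig | None = None
    decision: str = "target"
    nominal: tuple = ()
    discretize_method: str = "equal_frequency"
    discretize_bins: int = 3
    test_fraction: float = 0.2
    stratify: bool = False
    cross_fit: bool = True
    stack_overrides: dict = field(default_factory=dict)
    registry_config: dict = field(default_factory=dict)
    grids: dict = field(default_factory=dict)
    folds: int = 5
    directions: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    fixed_tt: float | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synth is None):
            raise ValueError("exactly one of input_csv / synth must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SynthConfig(**raw["synth"])
        return cls(**raw)


def _load_table(cfg: PipelineConfig):
    if cfg.input_csv is not None:
        table = DecisionTable.from_csv(cfg.input_csv, cfg.decision,
                                       cfg.nominal)
        return table, None
    return generate_hd_like(cfg.synth)


def rank_matrix(dm: McdmMatrix):
    """MEREC weights + TOPSIS ranking of an arbitrary performance matrix."""
    w = merec_weights(dm)
    res = topsis_rank(dm, w)
    return w, res


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run report dict.

    Stages: reduct selection on the discretized table, restriction of the
    raw table to the reduct, standard scaling fitted on the train split,
    nine base classifiers, the five stacks, MEREC-weighted TOPSIS ranking
    of the stacks, and grid-search refinement of the members of the
    top-ranked stack.  A stage failure raises with the stage name after
    writing the partial report.
    """
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}
    stage = "load"
    try:
        table, ground_truth = _load_table(cfg)
        if ground_truth:
            report["ground_truth"] = ground_truth

        stage = "reduct"
        t0 = time.perf_counter()
        disc = discretize(table, cfg.discretize_method, cfg.discretize_bins)
        dfct = build_discernibility(disc)
        reduct = johnson_reduct(dfct)
        log.info("stage=reduct seed=%d elapsed=%.2fs reduct=%s",
                 cfg.seed, time.perf_counter() - t0, list(reduct))
        report["reduct"] = list(reduct.attributes)
        report["reduct_trace"] = [[a, w] for a, w in reduct.selection_trace]
        report["inconsistent_pairs"] = dfct.inconsistent_pairs
        report["clause_count"] = len(dfct)
        selected = select_features(table, reduct)

        stage = "prep"
        X = selected.conditions().to_numpy(dtype=float)
        y = selected.decision_values.to_numpy(dtype=int)
        idx = split(len(X), cfg.test_fraction, cfg.seed,
                    labels=y if cfg.stratify else None)
        sc_train, sc_test = standard_scale(
            pd.DataFrame(X[idx.train_idx], columns=selected.attributes),
            X[idx.test_idx])
        Xtr, Xte = sc_train.values, sc_test.values
        ytr, yte = y[idx.train_idx], y[idx.test_idx]

        stage = "base_models"
        t0 = time.perf_counter()
        _, base_perf = fit_base_models(Xtr, ytr, Xte, yte, cfg.seed,
                                       cfg.registry_config)
        log.info("stage=base_models seed=%d elapsed=%.2fs",
                 cfg.seed, time.perf_counter() - t0)
        report["base_table"] = base_perf.reset_index().to_dict("records")
        corr = pearson_correlation(base_perf, axis="metrics")

        stage = "stacks"
        t0 = time.perf_counter()
        defs, advisory = build_stacks(cfg.stack_overrides,
                                      pearson_correlation(base_perf, "models"))
        fitted = []
        for d in defs:
            d.cross_fit = cfg.cross_fit
            fitted.append(fit_stack(d, Xtr, ytr, cfg.seed,
                                    cfg.registry_config, cfg.folds))
        stack_perf = evaluate_stacks(fitted, Xte, yte)
        if cfg.fixed_tt is not None:
            # wall-clock timings break run-to-run determinism; a fixed Tt
            # makes the whole report a pure function of (config, seed)
            stack_perf["Tt"] = cfg.fixed_tt
        log.info("stage=stacks seed=%d elapsed=%.2fs",
                 cfg.seed, time.perf_counter() - t0)
        report["stack_table"] = stack_perf.reset_index().to_dict("records")
        report["stack_advisory"] = advisory

        stage = "mcdm"
        dm = McdmMatrix(stack_perf, cfg.directions)
        weights, ranking = rank_matrix(dm)
        report["weights"] = weights.as_series().round(6).to_dict()
        report["closeness"] = ranking.closeness.round(6).to_dict()
        report["ranks"] = ranking.ranks.to_dict()
        best_stack_id = ranking.best
        report["best_stack"] = best_stack_id
        log.info("stage=mcdm seed=%d best=%s", cfg.seed, best_stack_id)

        stage = "tuning"
        t0 = time.perf_counter()
        best_def = next(d for d in defs
                        if f"Stack-{d.stack_id}" == best_stack_id)
        winner, comparison = select_best_classifier(
            best_def, cfg.grids, Xtr, ytr, Xte, yte, cfg.folds, cfg.seed)
        log.info("stage=tuning seed=%d elapsed=%.2fs best=%s",
                 cfg.seed, time.perf_counter() - t0, winner.model_id)
        report["best_classifier"] = winner.model_id
        report["best_params"] = winner.best_params
        report["cv_score"] = winner.cv_score
        report["test_metrics"] = winner.test_record.to_row()
        report["tuning_table"] = comparison.reset_index().to_dict("records")

        if outdir:
            base_perf.to_csv(outdir / "base_models.csv")
            stack_perf.to_csv(outdir / "stacks.csv")
            comparison.to_csv(outdir / "tuning.csv")
            (outdir / "report.json").write_text(
                json.dumps(report, indent=1, default=str))
        return report
    except Exception as exc:
        if outdir:
            partial = outdir / "partial_report.json"
            partial.write_text(json.dumps(report, indent=1, default=str))
            log.error("stage=%s failed; partial report at %s", stage, partial)
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc}") from exc
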