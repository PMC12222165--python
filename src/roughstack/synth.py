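"""Synthetic cardiology-style decision tables and embedded fixtures.

The generator emulates a 13-attribute clinical schema (age, resting blood
pressure, serum cholesterol, chest-pain type, ...) with a *planted* subset
of truly informative attributes.  Numeric attributes are drawn uniformly
within their schema ranges; nominal attributes uniformly over their coded
levels.  The binary outcome follows a logistic model over the informative
attributes' empirical tercile categories -- i.e. risk rises in steps across
low/middle/high clinical bands, the regime in which the planted set is a
genuine reduct of the tercile-discretized table and feature-recovery
experiments are well-posed.  Categories are computed with the same
equal-frequency coder the reduct pipeline uses.

With per-attribute effect ``b`` (log-odds per tercile step, scores
s in {-1, 0, 1}) the linear predictor is ``eta = b * sum(s) - b/2``; the
half-step intercept keeps every tercile cell away from p = 0.5 so that at
strong effects labels are near-deterministic.  ``effect_size = 0`` is the
pure-noise mode (p = 0.5 everywhere).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .mcdm import McdmMatrix
from .roughset import (DecisionTable, build_discernibility,
                       enumerate_minimal_reducts)

__all__ = ["SynthConfig", "load_schema", "generate_hd_like",
           "generate_toy_reduct_cases", "load_fixture", "FIXTURE_NAMES"]

#: effect size (log-odds per tercile step) used as the "strong" preset in
#: feature-recovery studies: labels are then near-deterministic per cell.
STRONG_EFFECT = 20.0


def _fixture_path(name: str):
    return resources.files("roughstack") / "fixtures" / name


def load_schema() -> dict:
    """The default clinical schema: attribute -> {type, range|levels}."""
    with _fixture_path("hd_schema.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class SynthConfig:
    """Configuration of the synthetic cohort generator.

    ``informative`` names the planted attributes; ``effect_size`` is the
    log-odds increment per tercile step for each of them (scalar or
    per-attribute mapping).  ``noise_attrs`` limits how many of the
    remaining schema attributes are kept (None = all).
    """

    n: int = 1000
    informative: tuple = ("age", "trestbps", "chol")
    effect_size: float | dict = STRONG_EFFECT
    noise_attrs: int | None = None
    seed: int = 0
    schema: dict = field(default_factory=load_schema)

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValueError("n must be >= 20")
        cond = [a for a in self.schema if a != "target"]
        unknown = set(self.informative) - set(cond)
        if unknown:
            raise ValueError(f"informative attributes not in schema: "
                             f"{sorted(unknown)}")
        for a in self.informative:
            if self.schema[a]["type"] != "numeric":
                raise ValueError(f"informative attribute {a!r} must be numeric")

    def effects(self) -> dict:
        if isinstance(self.effect_size, dict):
            return {a: float(self.effect_size.get(a, 0.0))
                    for a in self.informative}
        return {a: float(self.effect_size) for a in self.informative}


def _tercile_scores(x: np.ndarray) -> np.ndarray:
    """Equal-frequency tercile codes shifted to scores in {-1, 0, 1}.

    Uses the same quantile binning as the pipeline discretizer so generated
    categories and analysis bins coincide exactly.
    """
    return pd.qcut(x, 3, labels=False, duplicates="drop") - 1


def generate_hd_like(cfg: SynthConfig):
    """Draw a synthetic cohort; returns ``(DecisionTable, ground_truth)``.

    ``ground_truth`` records the planted attribute set, the per-attribute
    log-odds effects, the intercept and the realized label marginal.
    """
    rng = np.random.default_rng(cfg.seed)
    cond = [a for a in cfg.schema if a != "target"]
    if cfg.noise_attrs is not None:
        noise_pool = [a for a in cond if a not in cfg.informative]
        keep_noise = noise_pool[:cfg.noise_attrs]
        cond = [a for a in cond if a in cfg.informative or a in keep_noise]

    data = {}
    nominal = set()
    for a in cond:
        spec = cfg.schema[a]
        if spec["type"] == "numeric":
            lo, hi = spec["range"]
            data[a] = rng.uniform(lo, hi, cfg.n)
        else:
            data[a] = rng.choice(np.asarray(spec["levels"]), cfg.n)
            nominal.add(a)
    df = pd.DataFrame(data)[cond]

    effects = cfg.effects()
    pure_noise = not effects or all(v == 0 for v in effects.values())
    intercept = 0.0 if pure_noise else -0.5 * np.mean(list(effects.values()))
    eta = np.full(cfg.n, intercept)
    for a, b in effects.items():
        eta += b * _tercile_scores(df[a].to_numpy())
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.uniform(size=cfg.n) < p).astype(int)
    df["target"] = y

    table = DecisionTable(df, "target", frozenset(nominal),
                          provenance={"generator": "generate_hd_like",
                                      "seed": cfg.seed})
    ground_truth = {
        "informative": list(cfg.informative),
        "effects": effects,
        "intercept": float(intercept),
        "label_marginal": float(y.mean()),
        "pure_noise": pure_noise,
    }
    return table, ground_truth


def generate_toy_reduct_cases(count: int = 20, max_attrs: int = 6,
                              seed: int = 0):
    """Small random discrete decision tables with their exhaustively
    enumerated minimal reducts -- an oracle feed for reducer tests."""
    if max_attrs > 10:
        raise ValueError("max_attrs must be <= 10 (exhaustive oracle)")
    rng = np.random.default_rng(seed)
    cases = []
    while len(cases) < count:
        d = int(rng.integers(2, max_attrs + 1))
        n = int(rng.integers(4, 13))
        attrs = [f"a{j}" for j in range(d)]
        df = pd.DataFrame(rng.integers(0, 3, size=(n, d)), columns=attrs)
        df["target"] = rng.integers(0, 2, size=n)
        if df["target"].nunique() < 2:
            continue
        table = DecisionTable(df, "target", frozenset(attrs))
        expected = enumerate_minimal_reducts(build_discernibility(table),
                                             max_attrs=10)
        cases.append((table, expected))
    return cases


FIXTURE_NAMES = ("stack_performance_table3", "table4_weights", "hd_schema")


def _verify_checksum(name: str) -> None:
    with _fixture_path("checksums.json").open() as fh:
        sums = json.load(fh)
    digest = hashlib.sha256(_fixture_path(name).read_bytes()).hexdigest()
    if sums.get(name) != digest:
        raise RuntimeError(f"fixture {name} fails its checksum")


def load_fixture(name: str):
    """Load an embedded fixture by name.

    - ``stack_performance_table3``: the five-stack performance matrix as an
      :class:`~roughstack.mcdm.McdmMatrix` (MAE and Tt cost, others benefit);
    - ``table4_weights``: the published criteria-weight vector as a Series;
    - ``hd_schema``: the clinical schema mapping.

    Every fixture is verified against its committed checksum.
    """
    if name == "stack_performance_table3":
        for f in ("stack_performance_table3.csv",
                  "stack_performance_table3.directions.yaml"):
            _verify_checksum(f)
        with resources.as_file(
                _fixture_path("stack_performance_table3.csv")) as mp, \
             resources.as_file(_fixture_path(
                 "stack_performance_table3.directions.yaml")) as dp:
            return McdmMatrix.from_csv(mp, dp)
    if name == "table4_weights":
        _verify_checksum("table4_weights.csv")
        with _fixture_path("table4_weights.csv").open() as fh:
            df = pd.read_csv(fh, index_col=0)
        return df["weight"]
    if name == "hd_schema":
        _verify_checksum("hd_schema.yaml")
        return load_schema()
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
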