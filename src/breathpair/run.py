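"""Orchestration: simulate/load a cohort, evaluate model x visit-pair grid,
write reports.

Outputs (all CSV/JSON, deterministic for a fixed config):

* ``models_report.csv`` — one row per (model, visit pair): accuracy (%) with
  its Monte-Carlo CI, AUC, Youden's J, diagnostic odds ratio, sensitivity,
  specificity, permutation p, significance flag, subjects used/excluded.
* ``univariate_report.csv`` — the per-feature testing cascade across visits.
* ``correlations.csv`` — long-format pooled Pearson correlation table.
* ``manifest.json`` — seeds, package version, model definitions, exclusions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .classify import CVConfig, CVResult, mccv_classify
from .cohort import Cohort, read_cohort, write_cohort
from .config import SyntheticConfig, config_from_dict, default_config
from .errors import ConfigError
from .multilevel import PipelineConfig, assemble_paired
from .stats import cascade_report, correlations
from .synthetic import simulate

__all__ = ["ModelDef", "RunConfig", "run", "round_sig", "result_row", "all_visit_pairs"]


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reports print OR/AUC this way)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class ModelDef:
    name: str
    blocks: tuple[str, ...]


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run."""

    synthetic: SyntheticConfig | None = None
    cohort_path: str | None = None
    models: tuple[ModelDef, ...] = ()
    pairs: tuple[tuple[str, str], ...] = ()   # empty = all consecutive-order pairs
    cv: CVConfig = field(default_factory=CVConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0

    def validate(self, cohort: Cohort) -> None:
        if not self.models:
            raise ConfigError("models: at least one model definition is required")
        names = [m.name for m in self.models]
        if len(set(names)) != len(names):
            raise ConfigError(f"models: names must be unique, got {names}")
        for m in self.models:
            if not m.blocks:
                raise ConfigError(f"model {m.name!r}: blocks must be non-empty")
            for b in m.blocks:
                if b not in cohort.blocks:
                    raise ConfigError(
                        f"model {m.name!r}: unknown block {b!r} "
                        f"(cohort has {cohort.block_names})"
                    )
        for pair in self.pairs:
            for v in pair:
                if v not in cohort.visits:
                    raise ConfigError(f"pairs: unknown visit {v!r} (cohort has {cohort.visits})")
        self.cv.validate()


def all_visit_pairs(visits: Sequence[str]) -> tuple[tuple[str, str], ...]:
    return tuple(
        (visits[i], visits[j])
        for i in range(len(visits))
        for j in range(i + 1, len(visits))
    )


def default_models(cohort: Cohort) -> tuple[ModelDef, ...]:
    """The two-model contrast: everything vs spirometry alone."""
    models = [ModelDef("multidimensional", tuple(cohort.block_names))]
    if "spirometry" in cohort.blocks:
        models.append(ModelDef("spirometry", ("spirometry",)))
    return tuple(models)


def result_row(model: ModelDef, result: CVResult) -> dict:
    lo, hi = result.accuracy_ci
    return {
        "model": model.name,
        "comparison": f"{result.visit_pair[0]} vs {result.visit_pair[1]}",
        "n_subjects": result.n_subjects,
        "accuracy_pct": round(result.accuracy, 1),
        "ci95_low_pct": round(lo, 1),
        "ci95_high_pct": round(hi, 1),
        "auc": round_sig(result.auc, 3),
        "youden_j": round_sig(result.youden_j, 3),
        "odds_ratio": round_sig(result.odds_ratio, 3),
        "sensitivity": round(result.sensitivity, 3),
        "specificity": round(result.specificity, 3),
        "permutation_p": result.permutation_p,
        "significant": result.significant,
        "excluded_subjects": ";".join(result.excluded_subjects),
    }


def run(config: RunConfig, out_dir) -> pd.DataFrame:
    """Execute all model x visit-pair combinations and write the report bundle.

    Returns the models report as a DataFrame. Identical configs produce
    byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
    else:
        synth = config.synthetic or default_config(seed=config.seed)
        cohort = simulate(synth)
        write_cohort(cohort, out / "cohort")

    models = config.models or default_models(cohort)
    config = RunConfig(
        synthetic=config.synthetic,
        cohort_path=config.cohort_path,
        models=models,
        pairs=config.pairs or all_visit_pairs(cohort.visits),
        cv=config.cv,
        pipeline=config.pipeline,
        seed=config.seed,
    )
    config.validate(cohort)

    rows = []
    exclusions: dict[str, list[str]] = {}
    for model in config.models:
        for visit_a, visit_b in config.pairs:
            paired = assemble_paired(cohort, list(model.blocks), visit_a, visit_b)
            result = mccv_classify(paired, config.pipeline, config.cv)
            rows.append(result_row(model, result))
            exclusions[f"{model.name}:{visit_a}-{visit_b}"] = result.excluded_subjects
    report = pd.DataFrame(rows)
    report.to_csv(out / "models_report.csv", index=False)

    cascade_report(cohort).to_csv(out / "univariate_report.csv", index=False)
    correlations(cohort).to_long().to_csv(out / "correlations.csv", index=False)

    manifest = {
        "package": "breathpair",
        "version": __version__,
        "seed": config.seed,
        "cv": {
            "k": config.cv.k,
            "n_iterations": config.cv.n_iterations,
            "test_fraction": config.cv.test_fraction,
            "n_permutations": config.cv.n_permutations,
            "permutation_iterations": config.cv.permutation_iterations,
            "accuracy_threshold": config.cv.accuracy_threshold,
            "alpha": config.cv.alpha,
            "seed": config.cv.seed,
        },
        "pipeline": {
            "n_components": config.pipeline.n_components,
            "autoscale": config.pipeline.autoscale,
            "block_weight": config.pipeline.block_weight,
        },
        "models": [{"name": m.name, "blocks": list(m.blocks)} for m in config.models],
        "pairs": [list(p) for p in config.pairs],
        "cohort": {
            "source": config.cohort_path or "synthetic",
            "n_subjects": len(cohort.subjects),
            "visits": cohort.visits,
            "blocks": cohort.block_names,
        },
        "excluded_subjects": exclusions,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# YAML run config
# ---------------------------------------------------------------------------


def run_config_from_yaml(path, seed: int | None = None) -> RunConfig:
    """Load a RunConfig from YAML; ``seed`` (e.g. from the CLI) overrides the
    file's seed everywhere it applies."""
    from dataclasses import replace as _replace

    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    eff_seed = int(seed if seed is not None else d.get("seed", 0))

    cohort_cfg = d.get("cohort", {}) or {}
    cohort_path = cohort_cfg.get("path")
    synthetic = None
    if cohort_path is None:
        synth_d = cohort_cfg.get("synthetic")
        if isinstance(synth_d, dict) and "blocks" in synth_d:
            synthetic = config_from_dict(synth_d)
            if seed is not None:
                synthetic = _replace(synthetic, seed=eff_seed)
        else:
            synthetic = default_config(
                seed=int((synth_d or {}).get("seed", eff_seed)) if seed is None else eff_seed
            )

    if "models" in d and not d["models"]:
        raise ConfigError("models: at least one model definition is required")
    models = tuple(
        ModelDef(name=m["name"], blocks=tuple(m["blocks"])) for m in d.get("models", [])
    )
    pairs = tuple((a, b) for a, b in d.get("pairs", []))
    cv_d = dict(d.get("cv") or {})
    cv_d.setdefault("seed", eff_seed)
    if seed is not None:
        cv_d["seed"] = eff_seed
    cv = CVConfig(**cv_d)
    pipeline = PipelineConfig(**(d.get("pipeline") or {}))
    return RunConfig(
        synthetic=synthetic,
        cohort_path=cohort_path,
        models=models,
        pairs=pairs,
        cv=cv,
        pipeline=pipeline,
        seed=eff_seed,
    )
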