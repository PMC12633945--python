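"""End-to-end experiment orchestration.

``run_full_experiment`` ties the stages together — generate (or load) a
cohort, split it, build matched cohorts, run the alpha sweep, compute
feature attributions, and write a reproducible set of artifacts (CSV/JSON/
YAML) plus a run report.  Per-stage seeds are derived deterministically from
one master seed and never shared between stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .attribution import attribution_shift, attribution_table_from_models, rank_features
from .io import FLOAT_FORMAT, config_to_yaml, write_cohort_csv
from .ridge import AlphaGrid
from .sweep import RegionReport, SweepResult, identify_regions, prepare_study, run_alpha_sweep
from .synthetic import GeneratorConfig, SyntheticCohort, generate_cohort

__all__ = ["RunConfig", "RunReport", "run_full_experiment"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full experiment run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    alpha_min_exp: float = -5.0
    alpha_max_exp: float = 5.0
    alpha_ticks: int = 100
    n_train: int = 5000
    n_resamples: int = 10
    n_folds: int | None = None
    n_boot: int = 1000
    caliper_sd: float = 0.25
    test_fraction: float = 0.25
    master_seed: int = 0
    output_dir: str = "runs/default"
    make_plots: bool = False

    @property
    def grid(self) -> AlphaGrid:
        return AlphaGrid(np.logspace(self.alpha_min_exp, self.alpha_max_exp, self.alpha_ticks))

    def validate(self) -> None:
        self.generator.validate()
        if self.n_train < 2 or self.n_resamples < 1:
            raise ValueError("n_train must be >= 2 and n_resamples >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.caliper_sd <= 0:
            raise ValueError("caliper_sd must be > 0")
        self.grid  # constructor enforces grid invariants


@dataclass
class RunReport:
    """Summary of a completed run; serialized as report.json."""

    config_hash: str
    version: str
    n_subjects: int
    n_train_pool: int
    n_test_pool: int
    matched_pairs: dict[str, int]
    alpha_mae_opt: float
    mae_at_opt: float
    alpha_d_opt: dict[str, float]
    alpha_majority_opt: float
    sensitivity_gain: dict[str, float]
    inverse_flag: dict[str, bool]
    global_mass_at_mae_opt: float | None
    global_mass_at_majority_opt: float | None
    stage_seconds: dict[str, float]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _hash_config(config: RunConfig) -> str:
    text = config_to_yaml(config.generator) + json.dumps(
        {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("generator", "output_dir", "make_plots")
        },
        sort_keys=True,
    )
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_full_experiment(config: RunConfig, cohort: SyntheticCohort | None = None) -> RunReport:
    """Execute generate -> split -> match -> sweep -> attribute -> report.

    Idempotent given the master seed: identical configs produce byte-identical
    artifacts.  Any stage failure aborts with the stage name while earlier
    artifacts stay on disk.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "generate"
    try:
        t0 = time.perf_counter()
        if cohort is None:
            gen = dataclasses.replace(config.generator, seed=config.generator.seed)
            cohort = generate_cohort(gen)
        write_cohort_csv(cohort, out / "cohort.csv", out / "cohort_truth.csv")
        if cohort.config is not None:
            config_to_yaml(cohort.config, out / "generator.yaml")
        timings[stage] = time.perf_counter() - t0

        stage = "match"
        t0 = time.perf_counter()
        study = prepare_study(
            cohort, config.test_fraction, config.caliper_sd, seed=config.master_seed
        )
        for cond, mc in study.matched.items():
            mc.pairs.to_csv(out / f"matched_{cond}.csv", index=False, float_format=FLOAT_FORMAT)
            mc.balance.to_csv(out / f"balance_{cond}.csv", float_format=FLOAT_FORMAT)
        timings[stage] = time.perf_counter() - t0

        stage = "sweep"
        t0 = time.perf_counter()
        sweep = run_alpha_sweep(
            cohort,
            grid=config.grid,
            n_train=config.n_train,
            n_resamples=config.n_resamples,
            seed=config.master_seed,
            study=study,
        )
        sweep.mae.to_csv(out / "sweep_mae.csv", index=False, float_format=FLOAT_FORMAT)
        sweep.d.to_csv(out / "sweep_d.csv", index=False, float_format=FLOAT_FORMAT)
        sweep.mae_agg.to_csv(out / "sweep_mae_agg.csv", index=False, float_format=FLOAT_FORMAT)
        sweep.d_agg.to_csv(out / "sweep_d_agg.csv", index=False, float_format=FLOAT_FORMAT)
        regions = identify_regions(sweep)
        timings[stage] = time.perf_counter() - t0

        stage = "attribute"
        t0 = time.perf_counter()
        healthy_te = ~study.test_pool.is_diagnosed.to_numpy()
        table = attribution_table_from_models(
            sweep.grid,
            sweep.models,
            study.test_pool.features.to_numpy()[healthy_te],
            cohort.feature_names,
        )
        table.to_csv(out / "attribution.csv", float_format=FLOAT_FORMAT)
        rank_features(table, k=min(10, table.shape[1])).to_csv(
            out / "attribution_top.csv", index=False, float_format=FLOAT_FORMAT
        )
        designated = cohort.feature_groups.get("disease") or None
        mass = attribution_shift(table, designated) if designated else None
        if mass is not None:
            mass.to_csv(out / "global_mass.csv", float_format=FLOAT_FORMAT)
        timings[stage] = time.perf_counter() - t0

        stage = "report"
        t0 = time.perf_counter()
        report = _build_report(config, cohort, sweep, regions, mass)
        _write_regions(out / "regions.json", regions)
        report_path = out / "report.json"
        timings[stage] = time.perf_counter() - t0
        report.stage_seconds = {k: round(v, 3) for k, v in timings.items()}
        report.to_json(report_path)
        if config.make_plots:
            from .plots import plot_attribution_heatmap, plot_sweep

            plot_sweep(sweep, regions, out / "sweep.png")
            plot_attribution_heatmap(table, out / "attribution.png")
        return report
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _interp_mass(mass: pd.Series | None, alpha: float) -> float | None:
    if mass is None:
        return None
    return float(mass.loc[alpha])


def _build_report(
    config: RunConfig,
    cohort: SyntheticCohort,
    sweep: SweepResult,
    regions: RegionReport,
    mass: pd.Series | None,
) -> RunReport:
    return RunReport(
        config_hash=_hash_config(config),
        version=__version__,
        n_subjects=cohort.n_subjects,
        n_train_pool=len(sweep.study.train_pool.subjects),
        n_test_pool=len(sweep.study.test_pool.subjects),
        matched_pairs={c: mc.n_pairs for c, mc in sweep.study.matched.items()},
        alpha_mae_opt=regions.alpha_mae_opt,
        mae_at_opt=regions.mae_at_opt,
        alpha_d_opt={c: r.alpha_d_opt for c, r in regions.per_condition.items()},
        alpha_majority_opt=regions.alpha_majority_opt,
        sensitivity_gain={c: r.sensitivity_gain for c, r in regions.per_condition.items()},
        inverse_flag={c: r.inverse_flag for c, r in regions.per_condition.items()},
        global_mass_at_mae_opt=_interp_mass(mass, regions.alpha_mae_opt),
        global_mass_at_majority_opt=_interp_mass(mass, regions.alpha_majority_opt),
        stage_seconds={},
    )


def _write_regions(path: Path, regions: RegionReport) -> None:
    payload = {
        "alpha_mae_opt": regions.alpha_mae_opt,
        "mae_at_opt": regions.mae_at_opt,
        "alpha_majority_opt": regions.alpha_majority_opt,
        "per_condition": {c: dataclasses.asdict(r) for c, r in regions.per_condition.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
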