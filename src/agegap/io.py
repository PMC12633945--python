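"""Reading and writing the cohort CSV dialect and run artifacts.

Cohort tables are wide CSVs: ``subject_id`` first, then ``age``, covariate
columns, one 0/1 column per condition, and feature columns named
``f0001``... .  Hidden ground-truth latents live in a separate sidecar CSV
(absent for user-supplied real data).  Generator configs round-trip through
YAML.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import (
    COVARIATE_NAMES,
    ConditionSpec,
    CovariateSpec,
    GeneratorConfig,
    SyntheticCohort,
)

__all__ = [
    "config_from_yaml",
    "config_to_yaml",
    "read_cohort_csv",
    "stage_frame",
    "write_cohort_csv",
]

log = logging.getLogger(__name__)

FEATURE_RE = re.compile(r"^f\d{4,}$")
FLOAT_FORMAT = "%.10g"  # fixed text format so identical runs write identical bytes


def write_cohort_csv(cohort: SyntheticCohort, path: str | Path, truth_path: str | Path | None = None) -> None:
    """Write the cohort table (and the truth sidecar when present)."""
    table = pd.concat([cohort.subjects, cohort.features], axis=1)
    table.to_csv(path, float_format=FLOAT_FORMAT)
    if truth_path is not None and cohort.truth is not None:
        cohort.truth.to_csv(truth_path, float_format=FLOAT_FORMAT)


def read_cohort_csv(
    path: str | Path,
    truth_path: str | Path | None = None,
    condition_cols: list[str] | None = None,
    covariate_cols: list[str] | None = None,
) -> SyntheticCohort:
    """Read a cohort table written by :func:`write_cohort_csv` or user data.

    Columns matching ``f\\d{4,}`` are features.  Unless given explicitly,
    covariates are the known default names present in the file and every
    remaining 0/1 column is a condition label.  Raises on missing required
    columns; missing values are kept and dropped per analysis stage (see
    :func:`stage_frame`).
    """
    table = pd.read_csv(path)
    if table.empty:
        raise ValueError(f"empty cohort file: {path}")
    if "subject_id" not in table.columns:
        raise ValueError("missing required column: subject_id")
    if "age" not in table.columns:
        raise ValueError("missing required column: age")
    table = table.set_index("subject_id")

    feature_cols = [c for c in table.columns if FEATURE_RE.match(c)]
    if not feature_cols:
        raise ValueError("no feature columns (f0001...) found")
    rest = [c for c in table.columns if c not in feature_cols and c != "age"]
    if covariate_cols is None:
        covariate_cols = [c for c in COVARIATE_NAMES if c in rest]
    if condition_cols is None:
        condition_cols = [
            c
            for c in rest
            if c not in covariate_cols
            and set(table[c].dropna().unique()) <= {0, 1, 0.0, 1.0}
        ]
    if not condition_cols:
        raise ValueError("no condition label column found")
    log.info(
        "loaded cohort %s: %d subjects, %d features, conditions=%s, missing cells=%d",
        path,
        len(table),
        len(feature_cols),
        condition_cols,
        int(table.isna().sum().sum()),
    )

    truth = None
    if truth_path is not None and Path(truth_path).exists():
        truth = pd.read_csv(truth_path).set_index("subject_id")
    return SyntheticCohort(
        subjects=table[["age"] + covariate_cols + condition_cols],
        features=table[feature_cols],
        truth=truth,
        covariate_names=covariate_cols,
        condition_names=condition_cols,
        feature_groups={"age": [], "disease": [], "noise": []},
        config=None,
    )


def stage_frame(cohort: SyntheticCohort, columns: list[str], stage: str) -> pd.DataFrame:
    """Rows usable by one analysis stage: drop rows missing any used column.

    Missing data are excluded on an analysis-by-analysis basis — a row with
    a missing feature value is dropped from model fitting but still usable
    by stages that only need age and labels.  Dropped counts are logged.
    """
    table = pd.concat([cohort.subjects, cohort.features], axis=1)[columns]
    kept = table.dropna()
    if len(kept) < len(table):
        log.info("stage %s: dropped %d/%d rows with missing values", stage, len(table) - len(kept), len(table))
    return kept


def config_to_yaml(config: GeneratorConfig, path: str | Path | None = None) -> str:
    payload = dataclasses.asdict(config)
    payload["age_loadings"] = [float(v) for v in config.age_loadings]
    payload["conditions"] = [
        {**dataclasses.asdict(c), "focal_shifts": dict(c.focal_shifts)} for c in config.conditions
    ]
    payload["covariates"] = {
        "diagnosis_log_odds": dict(config.covariates.diagnosis_log_odds),
        "age_log_odds_per_year": config.covariates.age_log_odds_per_year,
        "global_factor_effects": dict(config.covariates.global_factor_effects),
    }
    text = yaml.safe_dump(payload, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(source: str | Path) -> GeneratorConfig:
    text = str(source)
    if isinstance(source, Path) or ("\n" not in text and Path(text).exists()):
        text = Path(text).read_text()
    payload = yaml.safe_load(text)
    payload["conditions"] = [ConditionSpec(**c) for c in payload.get("conditions", [])] or None
    if "covariates" in payload:
        payload["covariates"] = CovariateSpec(**payload["covariates"])
    if payload.get("age_loadings") is not None:
        payload["age_loadings"] = np.asarray(payload["age_loadings"], dtype=float)
    return GeneratorConfig(**payload)
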