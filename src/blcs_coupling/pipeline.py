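"""End-to-end orchestration: cohort -> harmonisation -> BLCS -> report.

One :class:`RunConfig` drives a fully reproducible run: generate (or load)
a two-wave cohort, keep one subject per family, harmonise each MRI feature
across sites, fit the four multigroup BLCS models, run the sixteen
sex-difference chi-square tests, FDR-adjust, and write the report bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import combat as combat_mod
from .cohort import (CohortConfig, GroundTruth, default_config,
                     default_truths, generate_cohort, inject_site_effects,
                     apply_attrition, select_unrelated, read_cohort,
                     write_cohort)
from .combat import harmonize_feature, site_variance_diagnostic, to_long
from .inference import (DiffTestResult, assemble_results,
                        chisq_difference_test, enumerate_test_family)
from .model import BLCSSpec, EstimatorOptions, FitResult, fit

__all__ = ["RunConfig", "ValidationReport", "validate_input", "run_pipeline",
           "fit_all_models", "run_difference_tests"]

logger = logging.getLogger("blcs_coupling")

#: covariates entering both the harmonisation and the BLCS models
DEFAULT_MODEL_COVARIATES = ("age_t1", "bmi", "ses", "ancestry")
DEFAULT_COMBAT_COVARIATES = ("age", "pds", "bmi", "ses", "ancestry")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    input_csv: str | None = None          # None -> synthetic mode
    features: tuple[str, ...] = ("fa", "md", "ct", "sa")
    covariates: tuple[str, ...] = DEFAULT_MODEL_COVARIATES
    harmonize: bool = True
    inject_site_effects: bool = True      # synthetic mode only
    select_one_per_family: bool = True
    harmonize_after_selection: bool = True
    attrition: bool = True
    cohort: CohortConfig = field(default_factory=default_config)
    estimator: EstimatorOptions = field(default_factory=EstimatorOptions)
    out_dir: str = "results"
    seed: int = 2023
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.input_csv is None:
            self.cohort.validate()
        unknown = set(self.features) - set(cohort_mod.FEATURES)
        if self.input_csv is None and unknown:
            raise ValueError(f"synthetic mode cannot generate {sorted(unknown)}")

    def config_hash(self) -> str:
        d = _jsonable(self)
        d.pop("out_dir", None)    # output location is not part of the design
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_kw = raw.pop("cohort", {})
        est_kw = raw.pop("estimator", {})
        for key in ("features", "covariates"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if cohort_kw:
            cfg.cohort = CohortConfig(**{**dataclasses.asdict(cfg.cohort),
                                         **cohort_kw})
        if est_kw:
            cfg.estimator = EstimatorOptions(**est_kw)
        return cfg


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    n_rows: int
    hard_failures: list[str]
    missingness: dict[str, int]
    wave2_missing: int

    @property
    def ok(self) -> bool:
        return not self.hard_failures


#: plausibility ranges for hard checks (units: years, PDS total, mm, cm^2)
_RANGES = {
    "age_t1": (5.0, 18.0), "age_t2": (5.0, 20.0),
    "pds_t1": (5.0, 20.0), "pds_t2": (5.0, 20.0),
    "ct_t1": (1.0, 5.0), "ct_t2": (1.0, 5.0),
}


def validate_input(table: pd.DataFrame, config: RunConfig) -> ValidationReport:
    """Schema, range and missingness checks; hard failures enumerated."""
    failures: list[str] = []
    required = ["subject_id", "family_id", "sex", "site_id",
                "age_t1", "age_t2", "pds_t1", "pds_t2"]
    required += [f"{f}_{w}" for f in config.features for w in ("t1", "t2")]
    required += [c for c in config.covariates if c not in required]
    for col in required:
        if col not in table.columns:
            failures.append(f"missing column: {col}")
    if failures:
        return ValidationReport(len(table), failures, {}, 0)

    if table["subject_id"].duplicated().any():
        dups = table.loc[table["subject_id"].duplicated(), "subject_id"]
        failures.append(f"duplicate subject_id values: {dups.head().tolist()}")
    both = table["age_t1"].notna() & table["age_t2"].notna()
    bad_age = both & (table["age_t2"] <= table["age_t1"])
    if bad_age.any():
        failures.append(f"{int(bad_age.sum())} rows with age_t2 <= age_t1")
    for col, (lo, hi) in _RANGES.items():
        if col in table.columns:
            v = table[col]
            bad = v.notna() & ((v < lo) | (v > hi))
            if bad.any():
                failures.append(
                    f"{int(bad.sum())} rows with {col} outside [{lo}, {hi}]")
    # monotone missingness: wave-2 values require a wave-1 record
    for f in config.features:
        orphan = table[f"{f}_t2"].notna() & table[f"{f}_t1"].isna()
        if orphan.any():
            failures.append(
                f"{int(orphan.sum())} rows with {f}_t2 but no {f}_t1")
    missing = {c: int(table[c].isna().sum()) for c in required
               if c in table.columns}
    wave2 = int(table["pds_t2"].isna().sum())
    return ValidationReport(len(table), failures, missing, wave2)


# ---------------------------------------------------------------------------
# model fitting stages
# ---------------------------------------------------------------------------

def _spec_for(feature: str, config: RunConfig,
              constraints: tuple[str, ...] = ()) -> BLCSSpec:
    return BLCSSpec(pds=("pds_t1", "pds_t2"),
                    mri=(f"{feature}_t1", f"{feature}_t2"),
                    group="sex", covariates=tuple(config.covariates),
                    constraints=constraints)


def fit_all_models(table: pd.DataFrame, config: RunConfig
                   ) -> dict[str, FitResult]:
    """Fit the free multigroup BLCS model for every feature."""
    fits = {}
    for f in config.features:
        t0 = time.perf_counter()
        fits[f] = fit(_spec_for(f, config), table, config.estimator)
        logger.info("fitted %s: chisq=%.2f df=%d conv=%s (%.1fs)", f,
                    fits[f].chisq, fits[f].df, fits[f].converged,
                    time.perf_counter() - t0)
    return fits


def run_difference_tests(table: pd.DataFrame, config: RunConfig,
                         free_fits: Mapping[str, FitResult]
                         ) -> list[DiffTestResult]:
    """The sixteen constrained refits and chi-square difference tests."""
    family = enumerate_test_family(config.features, fitted=free_fits)
    opts = dataclasses.replace(config.estimator, compute_se=False)
    tests = []
    for feature, param in family:
        t0 = time.perf_counter()
        constrained = fit(_spec_for(feature, config, constraints=(param,)),
                          table, opts)
        res = chisq_difference_test(free_fits[feature], constrained,
                                    model=feature, parameter=param)
        logger.info("constraint %s/%s: dchisq=%.3f (%.1fs)", feature, param,
                    res.chisq_diff, time.perf_counter() - t0)
        tests.append(res)
    return tests


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the report bundle to ``config.out_dir``.

    Returns a dict with the in-memory artefacts (tables, fits, tests).
    Deterministic given the config (one root seed, documented stream split).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    cfg_hash = config.config_hash()
    stream = np.random.SeedSequence(config.seed).spawn(3)
    seed_attrition = int(stream[1].generate_state(1)[0] % (2 ** 31))
    seed_select = int(stream[2].generate_state(1)[0] % (2 ** 31))

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        logger.info("stage: %s", name)

    try:
        stage("input")
        truths: Mapping[str, GroundTruth] | None = None
        if config.input_csv is None:
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            truths = default_truths(cohort_cfg)
            table = generate_cohort(
                cohort_cfg, {f: truths[f] for f in config.features})
            if config.inject_site_effects:
                table = inject_site_effects(
                    table, {f: truths[f] for f in config.features})
            if config.attrition and cohort_cfg.retention_rate < 1:
                table = apply_attrition(
                    table, cohort_cfg.retention_rate,
                    cohort_cfg.attrition_mechanism,
                    slope=cohort_cfg.mar_slope, seed=seed_attrition)
        else:
            table = read_cohort(config.input_csv)

        stage("validate")
        report = validate_input(table, config)
        if not report.ok:
            raise ValueError("input validation failed: "
                             + "; ".join(report.hard_failures))

        stage("select_unrelated")
        if config.select_one_per_family:
            table = select_unrelated(table, seed=seed_select)

        stage("harmonize")
        diagnostics = {}
        batch_models = {}
        if config.harmonize:
            for f in config.features:
                before = site_variance_diagnostic(to_long(table, f))
                table, bm = harmonize_feature(table, f)
                after = site_variance_diagnostic(to_long(table, f))
                diagnostics[f] = {"site_r2_before": before,
                                  "site_r2_after": after,
                                  "n_excluded": bm.n_excluded_rows}
                batch_models[f] = bm
                logger.info("harmonised %s: site R2 %.4f -> %.6f", f,
                            before, after)

        stage("fit")
        free_fits = fit_all_models(table, config)

        stage("difference_tests")
        tests = run_difference_tests(table, config, free_fits)

        stage("report")
        estimates, differences = assemble_results(free_fits, tests)
        estimates.insert(0, "config_hash", cfg_hash)
        differences.insert(0, "config_hash", cfg_hash)
        estimates.to_csv(out / "results_estimates.csv", index=False)
        differences.to_csv(out / "results_differences.csv", index=False)
        (out / "fit_summaries.json").write_text(json.dumps(
            {f: {"chisq": r.chisq, "df": r.df, "cfi": r.cfi,
                 "rmsea": r.rmsea, "loglik": r.loglik,
                 "converged": r.converged, "n": r.n_per_group,
                 "patterns": r.pattern_census}
             for f, r in free_fits.items()}, indent=2))
        (out / "harmonization_diagnostics.json").write_text(
            json.dumps(diagnostics, indent=2))
        (out / "config_echo.json").write_text(json.dumps(
            {"config": _jsonable(config), "hash": cfg_hash,
             "seed": config.seed}, indent=2))
        write_cohort(table, out / "analysis_table.csv")
        return {"table": table, "fits": free_fits, "tests": tests,
                "estimates": estimates, "differences": differences,
                "diagnostics": diagnostics, "validation": report,
                "truths": truths, "config_hash": cfg_hash,
                "batch_models": batch_models}
    except Exception as exc:
        logger.error("pipeline aborted at stage %r: %s",
                     current["stage"], exc)
        raise RuntimeError(
            f"pipeline failed at stage {current['stage']!r}: {exc}") from exc
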