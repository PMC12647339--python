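"""End-to-end orchestration: simulate/ingest, test missingness, impute,
derive flags, tabulate, and run the mediation decomposition."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptive, mediation, missing, preprocessing, synthetic

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "validate_input", "load_config"]

log = logging.getLogger("famstress")

_RAW_COLUMNS = [
    "child_id",
    "income",
    "n_adults",
    "n_other_14_plus",
    "n_children_under_14",
    *[f"dass_{i}" for i in range(1, 7)],
    "closeness",
    "conflict",
    "sdq_total",
    "maternal_education",
    "maternal_age_band",
    "maternal_employed",
    "one_parent",
    "ethnic_minority",
    "weight",
]


@dataclass
class RunConfig:
    """Pipeline configuration; exactly one of ``input_path`` /
    ``simulation`` must be set."""

    output_dir: str
    input_path: str | None = None
    simulation: dict | None = None
    m_imputations: int = 20
    imputation_iterations: int = 50
    imputation_seed: int = 0
    n_boot: int = 1000
    bootstrap_seed: int = 0
    exposure_mediator_interactions: bool = False
    ci_level: float = 0.95
    run_bootstrap: bool = True
    use_simulator_cutoffs: bool = True
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("set exactly one of input_path / simulation")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


_AGE_BANDS = {"<20", "20-29", "30-39", "40+"}
_EDU_BANDS = {"no_qualifications", "standard_grade", "higher", "degree_or_vocational"}


def validate_input(table: pd.DataFrame) -> list[str]:
    """Schema/range checks for an ingested raw cohort; returns issue list."""
    issues: list[str] = []
    for col in _RAW_COLUMNS:
        if col not in table.columns:
            issues.append(f"missing column: {col}")
    if issues:
        return issues
    if table["child_id"].duplicated().any():
        raise ValueError("duplicate child ids")
    sdq = table["sdq_total"].dropna()
    if ((sdq < 0) | (sdq > 40)).any():
        issues.append("sdq_total outside [0, 40]")
    for i in range(1, 7):
        d = table[f"dass_{i}"].dropna()
        if ((d < 0) | (d > 3)).any():
            issues.append(f"dass_{i} outside [0, 3]")
    if (table["income"].dropna() < 0).any():
        issues.append("negative income")
    if (table["weight"].dropna() <= 0).any():
        issues.append("non-positive weight")
    bad_age = set(table["maternal_age_band"].dropna()) - _AGE_BANDS
    if bad_age:
        issues.append(f"unknown maternal_age_band values: {sorted(bad_age)}")
    bad_edu = set(table["maternal_education"].dropna()) - _EDU_BANDS
    if bad_edu:
        issues.append(f"unknown maternal_education values: {sorted(bad_edu)}")
    n_miss = int(table[_RAW_COLUMNS].isna().sum().sum())
    log.info("validated %d rows; %d missing cells", len(table), n_miss)
    return issues


@dataclass
class PipelineResult:
    analysis_set: pd.DataFrame
    mcar: missing.McarTestResult | None
    fit: mediation.NaturalEffectsFit
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    output_dir: Path = field(default_factory=lambda: Path("."))


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # attach the stage name for diagnosis
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle to ``output_dir``.

    Stages: load/simulate -> validate -> derive flags -> MCAR test ->
    multiple imputation -> descriptive tables -> natural-effects
    decomposition (Rubin-pooled over imputations, bootstrap CIs) -> outputs
    (CSV tables, JSON fit record, log of all seeds).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run(config: RunConfig, out: Path) -> PipelineResult:
    cutoffs = None
    if config.simulation is not None:
        params = synthetic.StructuralParams.from_dict(config.simulation)
        log.info("simulating cohort: n=%d seed=%d", params.n_children, params.seed)
        cohort = _stage("simulate")(synthetic.generate_cohort)(params)
        if config.use_simulator_cutoffs:
            cutoffs = cohort.cutoffs
        cohort.to_csv(out / "cohort.csv")
        params.to_json(out / "simulation_params.json")
    else:
        log.info("ingesting cohort from %s", config.input_path)
        cohort = synthetic.Cohort.from_csv(config.input_path)

    issues = _stage("validate")(validate_input)(cohort.data)
    if issues:
        raise RuntimeError(f"pipeline stage 'validate' failed: {issues}")

    analysis = _stage("derive")(preprocessing.derive_analysis_set)(cohort, cutoffs=cutoffs)
    analysis.to_csv(out / "analysis_set.csv", index=False)

    model_cols = ["X", "M1", "M2", "Y", *preprocessing.CONFOUNDERS]
    incomplete = analysis[model_cols].isna().any().any()
    mcar = None
    if incomplete:
        mcar = _stage("mcar-test")(missing.littles_mcar_test)(analysis[model_cols])
        log.info("Little's MCAR test: chi2=%.2f df=%d p=%.4g", mcar.chi2, mcar.df, mcar.p)
        (out / "mcar_test.json").write_text(
            json.dumps(dataclasses.asdict(mcar), indent=2)
        )
        imp = _stage("impute")(missing.chained_impute)(
            analysis[model_cols],
            m=config.m_imputations,
            n_iterations=config.imputation_iterations,
            seed=config.imputation_seed,
        )
        log.info("imputation: m=%d iterations=%d seed=%d", imp.m, imp.n_iterations,
                 config.imputation_seed)
        diag = missing.compare_imputed(analysis[model_cols], imp)
        diag.to_csv(out / "imputation_diagnostics.csv")
        completed = [
            d.assign(weight=analysis["weight"].to_numpy()) for d in imp.datasets
        ]
    else:
        imp = None
        completed = [analysis]

    table1 = _stage("describe")(descriptive.sample_characteristics)(
        analysis[model_cols], imp
    )
    table1.to_csv(out / "table1_characteristics.csv", index=False)
    table2 = _stage("describe")(descriptive.exposure_stratified_table)(
        completed[0]
    )
    table2.to_csv(out / "table2_stratified.csv")

    spec = mediation.NaturalModelSpec(
        exposure_mediator_interactions=config.exposure_mediator_interactions,
        n_boot=config.n_boot,
        seed=config.bootstrap_seed,
        ci_level=config.ci_level,
    )
    fits = [
        _stage("mediate")(mediation.natural_effects)(d, spec) for d in completed
    ]
    fit = mediation.pool_over_imputations(fits) if len(fits) > 1 else fits[0]

    if config.run_bootstrap:
        if imp is None:
            cis = _stage("bootstrap")(mediation.bootstrap_cis)(analysis, spec)
        else:
            # boot-then-impute: each replicate resamples children, runs a
            # single stochastic imputation, then estimates
            def boot_estimator(sample: pd.DataFrame, rng: np.random.Generator):
                one = missing.chained_impute(
                    sample[model_cols],
                    m=1,
                    n_iterations=max(5, config.imputation_iterations // 5),
                    seed=int(rng.integers(2**31)),
                )
                d = one.datasets[0].assign(weight=sample["weight"].to_numpy())
                return mediation.natural_effects(d, spec).effects()

            cis = _stage("bootstrap")(mediation.bootstrap_cis)(
                analysis, spec, estimator=boot_estimator
            )
        fit.cis = cis
        fit.n_boot = spec.n_boot
        fit.seed = spec.seed
    log.info("effects: %s", fit.effects())

    fit.to_json(out / "fit.json")
    table3 = fit.to_table()
    table3.to_csv(out / "table3_effects.csv", index=False)
    return PipelineResult(
        analysis_set=analysis,
        mcar=mcar,
        fit=fit,
        table1=table1,
        table2=table2,
        table3=table3,
        output_dir=out,
    )
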