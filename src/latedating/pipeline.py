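"""End-to-end orchestration: simulate/ingest -> validate -> date -> exclude ->
agreement -> derive -> report.

Every exclusion is logged with a reason code (``implausible_date``,
``out_of_range_measurement``, ``outlier_gt_60d``, ``no_birthweight``,
``ga_ge_42wk``, ``out_of_window``); no silent drops. Re-running with the same
config reproduces byte-identical delimited outputs: all reported day
quantities are formatted at 0.1-day precision and writing is locale-independent
(ASCII minus, decimal point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import agreement as ag
from . import model_derivation as md
from .dating_equations import (
    PLAUSIBLE_RANGES,
    DatingEquation,
    default_equations,
    ga_from_biometry,
    load_equations,
)
from .synthetic_cohort import (
    BIRTH_COLUMNS,
    SCAN_COLUMNS,
    SyntheticCohortConfig,
    generate_cohort,
)
from .study_design import assign_window

logger = logging.getLogger(__name__)

DEFAULT_ESTIMATORS = (
    "chavez_tcd",
    "hadlock_bpd",
    "intergrowth_hc",
    "hadlock_fl",
    "hadlock_ac",
    "hadlock_combo",
    "intergrowth_combo",
)

MEASUREMENT_COLUMNS = {
    "bpd_cm": "BPD",
    "hc_cm": "HC",
    "fl_cm": "FL",
    "ac_cm": "AC",
    "tcd_cm": "TCD",
}


class PipelineError(RuntimeError):
    """Fatal pipeline failure (schema violation, empty cohort, ...)."""


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one input source plus stage settings."""

    synthetic: SyntheticCohortConfig | None = None
    scan_table: str | None = None
    birth_table: str | None = None
    equations_path: str | None = None
    reference_estimator: str = "hadlock_combo"
    estimators: tuple[str, ...] = DEFAULT_ESTIMATORS
    include_strata: bool = True
    derive: bool = True
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        from_files = self.scan_table is not None
        if from_files == (self.synthetic is not None):
            raise ValueError(
                "exactly one input source required: synthetic config or cohort files"
            )
        if from_files and self.birth_table is None:
            raise ValueError("a birth table must accompany the scan table")


def load_run_config(path: str, **overrides) -> RunConfig:
    """Read a RunConfig from YAML. Top-level keys: ``synthetic`` (generator
    knobs) or ``inputs`` (scan/birth table paths), plus any RunConfig field."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "synthetic" in doc:
        kwargs["synthetic"] = SyntheticCohortConfig(**doc["synthetic"])
    if "inputs" in doc:
        kwargs["scan_table"] = doc["inputs"].get("scans")
        kwargs["birth_table"] = doc["inputs"].get("births")
    for key in (
        "equations_path",
        "reference_estimator",
        "estimators",
        "include_strata",
        "derive",
        "out_dir",
        "seed",
    ):
        if key in doc:
            kwargs[key] = tuple(doc[key]) if key == "estimators" else doc[key]
    kwargs.update(overrides)
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# Stage: acquire + validate
# ---------------------------------------------------------------------------


def read_cohort(scan_path: str, birth_path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    scans = pd.read_csv(scan_path, sep="\t")
    births = pd.read_csv(birth_path, sep="\t")
    return scans, births


def _require_columns(df: pd.DataFrame, columns: Sequence[str], table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PipelineError(f"{table} table is missing columns {missing}")


def validate_cohort(
    scans: pd.DataFrame, births: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Schema and consistency validation with row-level diagnostics.

    - out-of-range measurements are set missing and logged (rows retained);
    - scans whose gold GA falls outside both windows are excluded;
    - participants with irreconcilable dates (birth at or before a scan GA)
      are excluded entirely.

    Returns (clean scans, clean births, exclusion log).
    """
    if scans.empty:
        raise PipelineError("empty cohort: no scan rows")
    _require_columns(scans, SCAN_COLUMNS, "scan")
    _require_columns(births, BIRTH_COLUMNS, "birth")

    bad_ga = scans[~np.isfinite(pd.to_numeric(scans["ga_gold_days"], errors="coerce"))]
    if not bad_ga.empty:
        raise PipelineError(
            "non-numeric ga_gold_days in scan rows: "
            + ", ".join(map(str, bad_ga["visit_id"].head(10)))
        )

    scans = scans.copy()
    exclusions: list[dict] = []

    for col, parameter in MEASUREMENT_COLUMNS.items():
        values = pd.to_numeric(scans[col], errors="coerce")
        lo, hi = PLAUSIBLE_RANGES[parameter]
        bad = values.notna() & ~values.between(lo, hi)
        for _, row in scans.loc[bad].iterrows():
            exclusions.append(
                {
                    "stage": "validate",
                    "visit_id": row["visit_id"],
                    "participant_id": row["participant_id"],
                    "window": row["window"],
                    "reason": "out_of_range_measurement",
                    "detail": f"{parameter}={row[col]}",
                }
            )
        values[bad] = np.nan
        scans[col] = values

    windows = scans["ga_gold_days"].map(assign_window)
    out_of_window = windows.isna()
    for _, row in scans.loc[out_of_window].iterrows():
        exclusions.append(
            {
                "stage": "validate",
                "visit_id": row["visit_id"],
                "participant_id": row["participant_id"],
                "window": row["window"],
                "reason": "out_of_window",
                "detail": f"ga_gold_days={row['ga_gold_days']}",
            }
        )
    scans = scans.loc[~out_of_window].copy()
    scans["window"] = scans["ga_gold_days"].map(assign_window)

    # irreconcilable dates: birth GA at or before a scan's gold GA
    merged = scans.merge(
        births[["participant_id", "birth_ga_days"]], on="participant_id", how="left"
    )
    implausible = merged["birth_ga_days"].notna() & (
        merged["birth_ga_days"] <= merged["ga_gold_days"]
    )
    bad_participants = set(merged.loc[implausible, "participant_id"])
    for pid in sorted(bad_participants):
        exclusions.append(
            {
                "stage": "validate",
                "visit_id": "",
                "participant_id": pid,
                "window": "",
                "reason": "implausible_date",
                "detail": "birth GA at or before scan GA",
            }
        )
    scans = scans[~scans["participant_id"].isin(bad_participants)].reset_index(drop=True)
    births = births[~births["participant_id"].isin(bad_participants)].reset_index(
        drop=True
    )
    if scans.empty:
        raise PipelineError("empty cohort after validation")
    log = pd.DataFrame(
        exclusions,
        columns=["stage", "visit_id", "participant_id", "window", "reason", "detail"],
    )
    return scans, births, log


# ---------------------------------------------------------------------------
# Stage: estimation + flow summary
# ---------------------------------------------------------------------------


def estimate_table(
    scans: pd.DataFrame, equations: Mapping[str, DatingEquation], estimators: Sequence[str]
) -> pd.DataFrame:
    """Long-format GA estimates: one row per scan x estimator."""
    frames = []
    for name in estimators:
        eq = equations[name]
        est = scans.apply(lambda r: ga_from_biometry(r, eq), axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "visit_id": scans["visit_id"],
                    "participant_id": scans["participant_id"],
                    "window": scans["window"],
                    "estimator": name,
                    "ga_gold_days": scans["ga_gold_days"],
                    "ga_est_days": est,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """round(100 * numerator / denominator, decimals); NaN for a zero denominator."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, decimals)


def compute_flow_summary(
    scans_clean: pd.DataFrame,
    retained: pd.DataFrame,
    births: pd.DataFrame,
    exclusions: pd.DataFrame,
    standard: ag.BirthweightStandard,
) -> pd.DataFrame:
    """Attrition counts per stage, window and site, with percentages."""
    rows = []

    def add(step, group, count, denominator=None):
        rows.append(
            {
                "step": step,
                "group": group,
                "count": int(count),
                "percent": percentage(count, denominator) if denominator else np.nan,
            }
        )

    enrolled = scans_clean["participant_id"].nunique()
    add("enrolled_with_scan", "all", enrolled)
    for window in ("W1", "W2"):
        add(f"scanned_{window}", "all", (scans_clean["window"] == window).sum())
    n_impl = (exclusions["reason"] == "implausible_date").sum()
    add("excluded_implausible_dates", "all", n_impl)
    for window in ("W1", "W2"):
        n_out = (
            (exclusions["reason"] == "outlier_gt_60d")
            & (exclusions["window"] == window)
        ).sum()
        add(f"excluded_outliers_{window}", window, n_out)
        add(f"retained_{window}", window, (retained["window"] == window).sum())

    flags = births.apply(
        lambda r: ag.classify_sga(r["birthweight_g"], r["sex"], r["birth_ga_days"], standard),
        axis=1,
    )
    classified = flags.notna()
    add("with_birthweight", "all", len(births), enrolled)
    add("classifiable_lt_42wk", "all", classified.sum(), len(births))
    n_sga = int((flags[classified]).sum())
    n_aga = int(classified.sum() - n_sga)
    add("sga", "all", n_sga, classified.sum())
    add("aga", "all", n_aga, classified.sum())
    for site in sorted(births["site"].unique()):
        mask = (births["site"] == site) & classified
        add(f"sga_site", site, int(flags[mask].sum()), mask.sum())
    return pd.DataFrame(rows, columns=["step", "group", "count", "percent"])


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


@dataclass
class ResultBundle:
    scans_clean: pd.DataFrame
    births: pd.DataFrame
    retained: pd.DataFrame
    exclusions: pd.DataFrame
    agreement: pd.DataFrame
    model_report: pd.DataFrame
    cv_report: pd.DataFrame
    flow_summary: pd.DataFrame
    derived_equations: dict[str, DatingEquation] = field(default_factory=dict)
    selection: md.ModelSelection | None = None


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute all stages in order and (optionally) persist the reports."""
    equations = (
        load_equations(config.equations_path)
        if config.equations_path
        else default_equations()
    )
    if config.synthetic is not None:
        scans_raw, births_raw = generate_cohort(config.synthetic, equations)
    else:
        scans_raw, births_raw = read_cohort(config.scan_table, config.birth_table)
    logger.info("cohort: %d scan rows, %d birth rows", len(scans_raw), len(births_raw))

    scans, births, exclusions = validate_cohort(scans_raw, births_raw)

    reference = equations[config.reference_estimator]
    retained, outlier_log = ag.exclude_outliers(scans, reference)
    if not outlier_log.empty:
        outlier_log = outlier_log.assign(
            stage="exclude",
            participant_id="",
            detail=outlier_log["difference_days"].map(lambda d: f"diff={d:.1f}d"),
        )[["stage", "visit_id", "participant_id", "window", "reason", "detail"]]
        exclusions = pd.concat([exclusions, outlier_log], ignore_index=True)

    standard = (
        config.synthetic.standard
        if config.synthetic is not None
        else ag.ParametricBirthweightStandard()
    )

    estimators = list(config.estimators)
    derived: dict[str, DatingEquation] = {}
    selection = None
    model_report = pd.DataFrame()
    cv_report = pd.DataFrame()
    if config.derive:
        fits, kfold, loso = md.derive_models(retained, seed=config.seed)
        selection = md.select_model(retained, fits, kfold)
        for name, fit in fits.items():
            eq = md.fit_to_equation(fit)
            derived[eq.name] = eq
            equations[eq.name] = eq
        estimators += sorted(derived)
        model_report = _model_report(fits, kfold, loso, selection)
        cv_report = _cv_report(kfold, loso)

    with_strata = ag.attach_sga_strata(retained, births, standard)
    strata = ag.STRATA if config.include_strata else ("ALL",)
    agreement = ag.agreement_table(with_strata, equations, estimators, strata)

    flow = compute_flow_summary(scans, retained, births, exclusions, standard)

    bundle = ResultBundle(
        scans_clean=scans,
        births=births,
        retained=retained,
        exclusions=exclusions,
        agreement=agreement,
        model_report=model_report,
        cv_report=cv_report,
        flow_summary=flow,
        derived_equations=derived,
        selection=selection,
    )
    if config.out_dir:
        write_reports(bundle, config.out_dir)
    return bundle


def _model_report(fits, kfold, loso, selection) -> pd.DataFrame:
    rows = []
    for name, fit in fits.items():
        terms = ("intercept",) + fit.model.term_names
        rows.append(
            {
                "model": name,
                "covariates": "+".join(fit.model.term_names),
                "coefficients": ";".join(f"{t}={b:.6g}" for t, b in zip(terms, fit.coefficients)),
                "cluster_robust_se": ";".join(f"{s:.6g}" for s in fit.cluster_robust_se),
                "adjusted_r2": round(fit.adjusted_r2, 4),
                "aic": round(fit.aic, 1),
                "n_obs": fit.n_obs,
                "n_clusters": fit.n_clusters,
                "cv_error_5fold": round(kfold[name].summary_error, 4) if name in kfold else np.nan,
                "cv_error_site": round(loso[name].summary_error, 4) if name in loso else np.nan,
                "selected": selection is not None and selection.chosen.name == name,
            }
        )
    return pd.DataFrame(rows)


def _cv_report(kfold, loso) -> pd.DataFrame:
    rows = []
    for source in (kfold, loso):
        for name, cv in source.items():
            for label, err in zip(cv.fold_labels, cv.fold_errors):
                rows.append(
                    {
                        "model": name,
                        "scheme": cv.scheme,
                        "fold": label,
                        "mean_standardized_error": round(err, 4),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report writing (deterministic formatting)
# ---------------------------------------------------------------------------

_DAY_COLUMNS = ("bias", "ci_low", "ci_high", "loa_low", "loa_high", "approximation")


def _format_agreement(agreement: pd.DataFrame) -> pd.DataFrame:
    out = agreement.copy()
    for col in _DAY_COLUMNS:
        out[col] = out[col].map(lambda v: f"{v:.1f}")
    return out


def write_reports(bundle: ResultBundle, out_dir: str) -> dict[str, Path]:
    """Persist all reports as TSV with fixed float formatting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name: str, df: pd.DataFrame, float_format="%.4f") -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format=float_format)
        paths[name] = path

    _write("cohort_scans.tsv", bundle.scans_clean)
    _write("cohort_births.tsv", bundle.births)
    _write("retained_scans.tsv", bundle.retained)
    _write("exclusions.tsv", bundle.exclusions)
    _write("agreement.tsv", _format_agreement(bundle.agreement))
    if not bundle.model_report.empty:
        _write("model_report.tsv", bundle.model_report)
        _write("cv_errors.tsv", bundle.cv_report)
    _write("flow_summary.tsv", bundle.flow_summary, float_format="%.1f")
    return paths
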