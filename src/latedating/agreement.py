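"""Bland-Altman agreement of late-pregnancy GA estimators against the gold standard.

Sign convention: d = late-pregnancy estimate - gold-standard GA, so a negative
bias means the estimator underestimates gestational age.

Limits of agreement use the sample SD (n-1 denominator) with a 1.96
multiplier; the bias CI is normal-theory d_bar +/- 1.96*SD/sqrt(n) without
cluster adjustment (per-window rows come from distinct visits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dating_equations import DatingEquation, ga_from_biometry

Z95 = 1.96
#: Births at or beyond 42+0 weeks are excluded from size stratification.
STRATIFICATION_GA_CAP_DAYS = 294.0
#: Absolute estimate-vs-gold difference beyond which a visit is implausible.
OUTLIER_THRESHOLD_DAYS = 60.0

STRATA = ("ALL", "AGA", "SGA")


class InsufficientDataError(ValueError):
    """Raised when fewer than two paired differences are available."""


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman summary for one estimator/window/stratum."""

    estimator_name: str
    window: str
    stratum: str
    n: int
    mean_diff_days: float
    ci95_low: float
    ci95_high: float
    loa_low: float
    loa_high: float
    approximation_days: float

    def as_dict(self) -> dict:
        return {
            "estimator": self.estimator_name,
            "window": self.window,
            "stratum": self.stratum,
            "n": self.n,
            "bias": self.mean_diff_days,
            "ci_low": self.ci95_low,
            "ci_high": self.ci95_high,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "approximation": self.approximation_days,
        }


def approximation_midpoint(loa_low: float, loa_high: float) -> float:
    """Midpoint between the unsigned limits of agreement: (|lo| + |hi|) / 2."""
    if loa_low > loa_high:
        raise ValueError(f"loa_low {loa_low} exceeds loa_high {loa_high}")
    return (abs(loa_low) + abs(loa_high)) / 2.0


def bland_altman(
    differences: Sequence[float],
    estimator_name: str = "",
    window: str = "",
    stratum: str = "ALL",
) -> AgreementResult:
    """Bland-Altman bias, 95% CI of the bias, and 95% limits of agreement.

    *differences* are estimate-minus-gold values in days; at least two are
    required. No rounding is applied here (reporting rounds to 0.1 day).
    """
    d = np.asarray(list(differences), dtype=float)
    if d.size < 2:
        raise InsufficientDataError(f"need >= 2 paired differences, got {d.size}")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    n = int(d.size)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = Z95 * sd
    loa_low, loa_high = bias - half, bias + half
    ci_half = Z95 * sd / math.sqrt(n)
    return AgreementResult(
        estimator_name=estimator_name,
        window=window,
        stratum=stratum,
        n=n,
        mean_diff_days=bias,
        ci95_low=bias - ci_half,
        ci95_high=bias + ci_half,
        loa_low=loa_low,
        loa_high=loa_high,
        approximation_days=approximation_midpoint(loa_low, loa_high),
    )


# ---------------------------------------------------------------------------
# Birthweight standard and SGA classification
# ---------------------------------------------------------------------------


class BirthweightStandard(Protocol):
    """Sex- and GA-specific newborn weight standard (10th-centile provider)."""

    def median_g(self, ga_days: float, sex: str) -> float: ...

    def centile_g(self, ga_days: float, sex: str, centile: float) -> float: ...


@dataclass(frozen=True)
class ParametricBirthweightStandard:
    """Smooth two-parameter (median, log-scale SD) stand-in standard.

    Median weight is log-quadratic in GA around 280 days with a sex offset;
    weight is lognormal around the median. Pluggable: any object with the
    same ``centile_g`` surface (e.g. transcribed reference tables) can be
    substituted wherever a standard is accepted.
    """

    median_280_male_g: float = 3350.0
    median_280_female_g: float = 3230.0
    log_slope_per_day: float = 0.0062
    log_curvature_per_day2: float = 2.4e-05
    sigma_log: float = 0.13
    standard_id: str = "parametric-standin-v1"

    def median_g(self, ga_days: float, sex: str) -> float:
        base = self.median_280_male_g if sex == "M" else self.median_280_female_g
        dt = ga_days - 280.0
        return base * math.exp(self.log_slope_per_day * dt - self.log_curvature_per_day2 * dt * dt)

    def centile_g(self, ga_days: float, sex: str, centile: float) -> float:
        z = norm.ppf(centile / 100.0)
        return self.median_g(ga_days, sex) * math.exp(self.sigma_log * z)


def classify_sga(
    birthweight_g: float,
    sex: str,
    birth_ga_days: float,
    standard: BirthweightStandard,
) -> bool | None:
    """SGA flag: birthweight strictly below the standard's 10th centile.

    Returns None (excluded from stratification, not classified) for births at
    >= 42+0 weeks or with missing birthweight. Weight exactly at the centile
    is not SGA (strict inequality).
    """
    if birthweight_g is None or not math.isfinite(birthweight_g):
        return None
    if birth_ga_days >= STRATIFICATION_GA_CAP_DAYS:
        return None
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    return birthweight_g < standard.centile_g(birth_ga_days, sex, 10.0)


# ---------------------------------------------------------------------------
# Exclusions and table assembly
# ---------------------------------------------------------------------------


def exclude_outliers(
    scans: pd.DataFrame,
    reference_equation: DatingEquation,
    threshold_days: float = OUTLIER_THRESHOLD_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop visits whose reference-estimator GA differs from gold by > threshold.

    The rule is strict ("greater than"): |d| == threshold is retained. A visit
    where the reference estimator cannot be computed (missing inputs) is
    retained — the rule targets implausible measurements, not missing ones.
    Returns (retained scans, exclusion log with visit_id/window/difference).
    """
    diffs = scans.apply(
        lambda row: ga_from_biometry(row, reference_equation) - row["ga_gold_days"],
        axis=1,
    )
    is_outlier = diffs.abs() > threshold_days
    is_outlier &= diffs.notna()
    log = pd.DataFrame(
        {
            "visit_id": scans.loc[is_outlier, "visit_id"],
            "window": scans.loc[is_outlier, "window"],
            "difference_days": diffs[is_outlier],
            "reason": "outlier_gt_60d",
        }
    ).reset_index(drop=True)
    return scans.loc[~is_outlier].reset_index(drop=True), log


def required_enrolment(
    min_sga_per_site: int, sga_prevalence: float, loss_rate: float
) -> int:
    """Enrolment per site needed to observe *min_sga_per_site* SGA infants.

    round(min_sga / (prevalence * (1 - loss_rate))), nearest integer.
    """
    if not 0.0 < sga_prevalence <= 1.0:
        raise ValueError(f"sga_prevalence must be in (0, 1], got {sga_prevalence}")
    if not 0.0 <= loss_rate < 1.0:
        raise ValueError(f"loss_rate must be in [0, 1), got {loss_rate}")
    return round(min_sga_per_site / (sga_prevalence * (1.0 - loss_rate)))


def attach_sga_strata(
    scans: pd.DataFrame, births: pd.DataFrame, standard: BirthweightStandard
) -> pd.DataFrame:
    """Merge birth outcomes onto scans and add a ``stratum`` column.

    Stratum is "AGA"/"SGA" for classified infants and NA for scans whose
    infant lacks a birthweight or was born at >= 42 weeks.
    """
    merged = scans.merge(
        births[["participant_id", "birthweight_g", "sex", "birth_ga_days"]],
        on="participant_id",
        how="left",
    )

    def _stratum(row):
        if pd.isna(row.get("birthweight_g")) or pd.isna(row.get("birth_ga_days")):
            return pd.NA
        flag = classify_sga(
            row["birthweight_g"], row["sex"], row["birth_ga_days"], standard
        )
        if flag is None:
            return pd.NA
        return "SGA" if flag else "AGA"

    merged["stratum"] = merged.apply(_stratum, axis=1)
    return merged


def agreement_table(
    scans_with_strata: pd.DataFrame,
    equations: dict[str, DatingEquation],
    estimators: Sequence[str],
    strata: Sequence[str] = STRATA,
) -> pd.DataFrame:
    """Tidy agreement report: one row per estimator x window x stratum.

    ``scans_with_strata`` must carry ``ga_gold_days``, ``window``, the
    measurement columns, and a ``stratum`` column (see
    :func:`attach_sga_strata`). The ALL stratum uses every scan in the window;
    AGA/SGA restrict to classified infants.
    """
    rows = []
    for name in estimators:
        eq = equations[name]
        est = scans_with_strata.apply(lambda r: ga_from_biometry(r, eq), axis=1)
        d = est - scans_with_strata["ga_gold_days"]
        for window in sorted(scans_with_strata["window"].unique()):
            in_window = scans_with_strata["window"] == window
            for stratum in strata:
                if stratum == "ALL":
                    mask = in_window
                else:
                    mask = in_window & (scans_with_strata["stratum"] == stratum)
                diffs = d[mask].dropna()
                if len(diffs) < 2:
                    continue
                rows.append(
                    bland_altman(diffs, name, window, stratum).as_dict()
                )
    return pd.DataFrame(rows)


def bland_altman_plot(
    gold: Sequence[float],
    estimate: Sequence[float],
    result: AgreementResult,
    ax=None,
):
    """Difference-vs-gold plot with identity line at 0, solid bias line and
    dashed LOA lines. Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    gold = np.asarray(gold, dtype=float)
    diff = np.asarray(estimate, dtype=float) - gold
    ax.scatter(gold, diff, s=8, alpha=0.5)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axhline(result.mean_diff_days, color="C0", lw=1.5)
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="C0", lw=1.0, ls="--")
    ax.set_xlabel("Gold-standard GA (days)")
    ax.set_ylabel("Estimate - gold (days)")
    ax.set_title(f"{result.estimator_name} {result.window} {result.stratum}")
    return ax
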