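"""Seeded synthetic-cohort generator for the late-pregnancy dating analysis.

The generating model is internally consistent with the configured dating
equations: the "growth curve" for each parameter is the numerical inverse of
its dating nomogram, so a noiseless, unrestricted fetus measured at GA g and
re-dated through :func:`~latedating.dating_equations.ga_from_biometry`
recovers g exactly. On top of that curve the generator layers:

- multiplicative log-normal between-fetus size variation (a factor shared
  across body parameters plus a parameter-specific component; the cerebellum
  gets a damped share of the common factor),
- growth restriction for a site-calibrated fraction of fetuses, with the
  transcerebellar diameter protected by ``sparing_factor``,
- additive measurement noise per replicate, sporadic missingness, and loss
  to follow-up before birth.

Site-level SGA prevalence is hit by calibrating the restricted fraction
against the analytic probability that a restricted fetus falls below the
birthweight standard's 10th centile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from .agreement import ParametricBirthweightStandard, classify_sga
from .dating_equations import (
    DatingEquation,
    MeasurementRangeError,
    default_equations,
)
from .study_design import SITES, WINDOWS, assign_window

_CURVE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def growth_curve_value(eq: DatingEquation, ga_days: float) -> float:
    """Measurement on the nomogram-inverse growth curve at *ga_days*.

    Tabulates the (monotone) equation once on a dense grid and interpolates
    the inverse; equivalent to root-finding to well below 1e-4 days but fast
    enough for large cohorts.
    """
    key = (eq.name, eq.coefficients)
    if key not in _CURVE_CACHE:
        (p,) = eq.required_parameters
        lo, hi = eq.valid_range[p]
        xs = np.linspace(lo, hi, 4001)
        gas = np.array([eq.evaluate(**{p: float(x)}) for x in xs])
        _CURVE_CACHE[key] = (gas, xs)
    gas, xs = _CURVE_CACHE[key]
    if not gas[0] <= ga_days <= gas[-1]:
        raise MeasurementRangeError(
            f"{eq.name}: GA {ga_days:.1f} d outside achievable span "
            f"[{gas[0]:.1f}, {gas[-1]:.1f}]"
        )
    return float(np.interp(ga_days, gas, xs))

#: Dating equation used as growth curve per parameter.
GROWTH_EQUATIONS = {
    "BPD": "hadlock_bpd",
    "HC": "intergrowth_hc",
    "FL": "hadlock_fl",
    "AC": "hadlock_ac",
    "TCD": "chavez_tcd",
}

BODY_PARAMETERS = ("BPD", "HC", "FL", "AC")

SCAN_COLUMNS = [
    "visit_id",
    "participant_id",
    "site",
    "window",
    "ga_gold_days",
    "bpd_cm",
    "hc_cm",
    "fl_cm",
    "ac_cm",
    "tcd_cm",
]
BIRTH_COLUMNS = ["participant_id", "site", "birth_ga_days", "birthweight_g", "sex"]


def _default_size_sd() -> dict[str, float]:
    # parameter-specific log-SD on top of the shared size factor
    return {"BPD": 0.02, "HC": 0.02, "FL": 0.02, "AC": 0.03, "TCD": 0.02}


def _default_noise_sd() -> dict[str, float]:
    # cm per replicate; calibrated so W1 individual-parameter limits of
    # agreement land around +/-12-17 days (illustrative, not a fitted value)
    return {"BPD": 0.15, "HC": 0.40, "FL": 0.18, "AC": 0.50, "TCD": 0.16}


def _default_missingness() -> dict[str, float]:
    return {p: 0.003 for p in GROWTH_EQUATIONS}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """All generator knobs. Defaults emulate a three-site cohort with high,
    medium and low SGA prevalence and W1 agreement spans near the teens of
    days for individual parameters."""

    n_per_site: int = 400
    site_sga_prevalence: tuple[float, float, float] = (0.44, 0.28, 0.10)
    fetal_size_sd_shared: float = 0.03
    fetal_size_sd: Mapping[str, float] = field(default_factory=_default_size_sd)
    tcd_shared_weight: float = 0.5
    measurement_noise_sd: Mapping[str, float] = field(default_factory=_default_noise_sd)
    tcd_noise_inflation_per_week: float = 0.0
    sparing_factor: float = 0.85
    restriction_severity: float = 0.15
    restriction_shape: float = 4.0
    max_restriction_deficit: float = 0.45
    biometry_deficit_scale: float = 0.25
    missingness_rate: Mapping[str, float] = field(default_factory=_default_missingness)
    loss_to_followup: float = 0.14
    visit_attendance: float = 0.95
    birth_ga_mean: float = 278.0
    birth_ga_sd: float = 9.0
    male_fraction: float = 0.515
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_site < 1:
            raise ValueError("n_per_site must be >= 1")
        props = [
            *self.site_sga_prevalence,
            self.sparing_factor,
            self.loss_to_followup,
            self.visit_attendance,
            self.male_fraction,
            *self.missingness_rate.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in props):
            raise ValueError("all proportions must lie in [0, 1]")
        sds = [
            self.fetal_size_sd_shared,
            *self.fetal_size_sd.values(),
            *self.measurement_noise_sd.values(),
            self.birth_ga_sd,
        ]
        if any(s < 0 for s in sds):
            raise ValueError("standard deviations must be nonnegative")
        if self.restriction_severity < 0:
            raise ValueError("restriction_severity must be nonnegative")

    @property
    def standard(self) -> ParametricBirthweightStandard:
        return ParametricBirthweightStandard()


@dataclass(frozen=True)
class SyntheticPregnancy:
    participant_id: str
    site: str
    true_ga_at_enrolment: float
    restricted: bool
    restriction_draw: float
    fetal_size_factor: Mapping[str, float]
    scheduled_visit_gas: tuple[float | None, float | None]
    birth_ga_days: float
    birthweight_g: float | None
    sex: str


# ---------------------------------------------------------------------------
# Restricted-fraction calibration
# ---------------------------------------------------------------------------


def _restriction_quantiles(config: SyntheticCohortConfig, n: int = 401) -> np.ndarray:
    """Deterministic quantile grid of the fetal deficit distribution."""
    if config.restriction_severity == 0:
        return np.zeros(n)
    shape = config.restriction_shape
    scale = config.restriction_severity / shape
    q = (np.arange(n) + 0.5) / n
    draws = gamma_dist.ppf(q, a=shape, scale=scale)
    return np.minimum(draws, config.max_restriction_deficit)


def sga_probability_given_restricted(config: SyntheticCohortConfig) -> float:
    """P(birthweight < 10th centile | restricted), by quadrature over the
    deficit distribution under the lognormal birthweight model."""
    sigma = config.standard.sigma_log
    z10 = norm.ppf(0.10)
    r = _restriction_quantiles(config)
    return float(np.mean(norm.cdf(z10 - np.log1p(-r) / sigma)))


def restricted_fraction_for_prevalence(
    target: float, config: SyntheticCohortConfig
) -> float:
    """Fraction of fetuses to restrict so SGA prevalence converges to *target*.

    Solves target = f*q + (1-f)*0.10 where q = P(SGA | restricted). The
    unrestricted population sits at 10% by construction of the centile.
    """
    base = 0.10
    if target <= base:
        if target < base:
            warnings.warn(
                f"target SGA prevalence {target} below the baseline 10%; "
                "using no restricted fetuses",
                stacklevel=2,
            )
        return 0.0
    q = sga_probability_given_restricted(config)
    if q <= target:
        raise ValueError(
            f"restriction_severity {config.restriction_severity} too mild: "
            f"P(SGA|restricted)={q:.3f} cannot reach prevalence {target}"
        )
    return (target - base) / (q - base)


# ---------------------------------------------------------------------------
# Per-pregnancy generation
# ---------------------------------------------------------------------------


def _pregnancy_rng(seed: int, site_index: int, index: int) -> np.random.Generator:
    # one global seed feeds a per-pregnancy stream: reproducible under subsetting
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(site_index, index))
    )


def _draw_pregnancy(
    config: SyntheticCohortConfig,
    site: str,
    site_index: int,
    index: int,
    p_restricted: float,
) -> SyntheticPregnancy:
    rng = _pregnancy_rng(config.seed, site_index, index)
    participant_id = f"{site}{index:05d}"
    enrol_ga = rng.uniform(56.0, 98.0)

    restricted = bool(rng.random() < p_restricted)
    if restricted and config.restriction_severity > 0:
        shape = config.restriction_shape
        draw = rng.gamma(shape, config.restriction_severity / shape)
        restriction_draw = float(min(draw, config.max_restriction_deficit))
    else:
        restricted = False
        restriction_draw = 0.0

    shared_z = rng.normal(0.0, config.fetal_size_sd_shared)
    size = {}
    for p in GROWTH_EQUATIONS:
        weight = config.tcd_shared_weight if p == "TCD" else 1.0
        own = rng.normal(0.0, config.fetal_size_sd.get(p, 0.0))
        size[p] = float(math.exp(weight * shared_z + own))

    visit_gas: list[float | None] = []
    for lo, hi in WINDOWS.values():
        if rng.random() < config.visit_attendance:
            visit_gas.append(float(rng.uniform(lo, hi + 0.99)))
        else:
            visit_gas.append(None)

    sex = "M" if rng.random() < config.male_fraction else "F"
    birth_ga = float(
        np.clip(rng.normal(config.birth_ga_mean, config.birth_ga_sd), 238.0, 300.0)
    )
    lost = rng.random() < config.loss_to_followup
    if lost:
        birthweight = None
    else:
        std = config.standard
        noise = math.exp(rng.normal(0.0, std.sigma_log))
        birthweight = float(std.median_g(birth_ga, sex) * (1.0 - restriction_draw) * noise)

    return SyntheticPregnancy(
        participant_id=participant_id,
        site=site,
        true_ga_at_enrolment=enrol_ga,
        restricted=restricted,
        restriction_draw=restriction_draw,
        fetal_size_factor=size,
        scheduled_visit_gas=tuple(visit_gas),
        birth_ga_days=birth_ga,
        birthweight_g=birthweight,
        sex=sex,
    )


def measure_fetus(
    pregnancy: SyntheticPregnancy,
    ga_days: float,
    config: SyntheticCohortConfig,
    rng: np.random.Generator | None = None,
    equations: Mapping[str, DatingEquation] | None = None,
    return_replicates: bool = False,
):
    """Emit one scan row for *pregnancy* at gold-standard GA *ga_days*.

    True value = nomogram-inverse growth curve x fetal size factor x
    (1 - effective deficit), where the deficit equals the restriction draw for
    body parameters and ``restriction_draw * (1 - sparing_factor)`` for TCD.
    Two noisy replicates per parameter are averaged into the stored value.
    """
    if assign_window(ga_days) is None:
        raise ValueError(f"GA {ga_days} d outside the supported scan windows")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eqs = equations if equations is not None else default_equations()

    window = assign_window(ga_days)
    row: dict = {
        "visit_id": f"{pregnancy.participant_id}-{window}",
        "participant_id": pregnancy.participant_id,
        "site": pregnancy.site,
        "window": window,
        "ga_gold_days": float(ga_days),
    }
    replicate_rows = []
    for p, eq_name in GROWTH_EQUATIONS.items():
        # biometry expresses only part of the birthweight deficit: growth
        # restriction hits soft tissue harder than skeletal/head dimensions
        deficit = pregnancy.restriction_draw * config.biometry_deficit_scale
        if p == "TCD":
            deficit *= 1.0 - config.sparing_factor
        true_value = (
            growth_curve_value(eqs[eq_name], ga_days)
            * pregnancy.fetal_size_factor[p]
            * (1.0 - deficit)
        )
        noise_sd = config.measurement_noise_sd.get(p, 0.0)
        if p == "TCD" and config.tcd_noise_inflation_per_week > 0:
            # optional: TCD gets harder to measure near term (skull shadowing)
            weeks_past_24 = max(0.0, (ga_days - 168.0) / 7.0)
            noise_sd *= 1.0 + config.tcd_noise_inflation_per_week * weeks_past_24
        reps = [max(true_value + rng.normal(0.0, noise_sd), 1e-3) for _ in range(2)]
        value: float | None = float(np.mean(reps))
        if rng.random() < config.missingness_rate.get(p, 0.0):
            value = None
        row[f"{p.lower()}_cm"] = value
        if return_replicates and value is not None:
            for k, rep in enumerate(reps, start=1):
                replicate_rows.append(
                    {
                        "visit_id": row["visit_id"],
                        "parameter": p,
                        "replicate_index": k,
                        "value": float(rep),
                        "unit": "cm",
                    }
                )
    if return_replicates:
        return row, replicate_rows
    return row


def assign_birth_outcome(
    pregnancy: SyntheticPregnancy, config: SyntheticCohortConfig
) -> tuple[float | None, str, bool | None]:
    """Birthweight, sex, and the SGA flag under the configured standard."""
    flag = (
        classify_sga(
            pregnancy.birthweight_g,
            pregnancy.sex,
            pregnancy.birth_ga_days,
            config.standard,
        )
        if pregnancy.birthweight_g is not None
        else None
    )
    return pregnancy.birthweight_g, pregnancy.sex, flag


def generate_pregnancies(config: SyntheticCohortConfig) -> list[SyntheticPregnancy]:
    fractions = [
        restricted_fraction_for_prevalence(t, config)
        for t in config.site_sga_prevalence
    ]
    out = []
    for s_idx, (site, frac) in enumerate(zip(SITES, fractions)):
        for i in range(config.n_per_site):
            out.append(_draw_pregnancy(config, site, s_idx, i, frac))
    return out


def generate_cohort(
    config: SyntheticCohortConfig,
    equations: Mapping[str, DatingEquation] | None = None,
    return_replicates: bool = False,
):
    """Generate (scan table, birth table) as DataFrames; deterministic in seed.

    Each pregnancy contributes 0-2 scan rows (independent window attendance)
    and 0-1 birth rows (loss to follow-up). With ``return_replicates`` a third
    replicate-level table (visit_id, parameter, replicate_index, value, unit)
    is returned as well.
    """
    eqs = equations if equations is not None else default_equations()
    scan_rows, birth_rows, replicate_rows = [], [], []
    for s_idx, site in enumerate(SITES):
        frac = restricted_fraction_for_prevalence(
            config.site_sga_prevalence[s_idx], config
        )
        for i in range(config.n_per_site):
            preg = _draw_pregnancy(config, site, s_idx, i, frac)
            # dedicated measurement stream so pregnancy-level draws stay stable
            m_rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(s_idx, i, 1))
            )
            for ga in preg.scheduled_visit_gas:
                if ga is None:
                    continue
                result = measure_fetus(
                    preg, ga, config, m_rng, eqs, return_replicates=return_replicates
                )
                if return_replicates:
                    row, reps = result
                    replicate_rows.extend(reps)
                else:
                    row = result
                scan_rows.append(row)
            if preg.birthweight_g is not None:
                birth_rows.append(
                    {
                        "participant_id": preg.participant_id,
                        "site": preg.site,
                        "birth_ga_days": preg.birth_ga_days,
                        "birthweight_g": preg.birthweight_g,
                        "sex": preg.sex,
                    }
                )
    scans = pd.DataFrame(scan_rows, columns=SCAN_COLUMNS)
    births = pd.DataFrame(birth_rows, columns=BIRTH_COLUMNS)
    for col in ("bpd_cm", "hc_cm", "fl_cm", "ac_cm", "tcd_cm"):
        scans[col] = pd.to_numeric(scans[col])
    if return_replicates:
        replicates = pd.DataFrame(
            replicate_rows,
            columns=["visit_id", "parameter", "replicate_index", "value", "unit"],
        )
        return scans, births, replicates
    return scans, births


def noiseless_config(base: SyntheticCohortConfig | None = None) -> SyntheticCohortConfig:
    """Copy of *base* with every noise and variation source zeroed.

    Scans from this config round-trip exactly through the dating equations.
    """
    cfg = base if base is not None else SyntheticCohortConfig()
    return replace(
        cfg,
        site_sga_prevalence=(0.10, 0.10, 0.10),
        fetal_size_sd_shared=0.0,
        fetal_size_sd={p: 0.0 for p in GROWTH_EQUATIONS},
        measurement_noise_sd={p: 0.0 for p in GROWTH_EQUATIONS},
        restriction_severity=0.0,
        missingness_rate={p: 0.0 for p in GROWTH_EQUATIONS},
    )
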