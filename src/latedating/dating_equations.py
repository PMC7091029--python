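"""Validation of fetal biometry and conversion of measurements to gestational age.

A :class:`DatingEquation` maps one or more biometric measurements to an
estimated gestational age (GA) in days. Equations ship as configuration data
(``data/equations.yaml``) rather than hard-coded constants: one record per
equation holding the functional form, coefficients, valid input ranges and a
source citation. The evaluation engine implements a small set of named
functional forms; the coefficients are data.

Measurement storage conventions: CRL in mm, all other parameters in cm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import yaml
from scipy.optimize import brentq

from .units import DAYS_PER_WEEK, convert_length

#: Biometric parameters handled by the pipeline.
PARAMETERS = ("CRL", "BPD", "HC", "FL", "AC", "TCD")

#: Closed plausible measurement ranges (data-cleaning bounds), CRL in mm,
#: everything else in cm. Values outside are set missing downstream.
PLAUSIBLE_RANGES: dict[str, tuple[float, float]] = {
    "CRL": (2.0, 95.0),
    "BPD": (3.0, 11.0),
    "HC": (10.0, 40.0),
    "FL": (2.0, 9.0),
    "AC": (12.0, 42.0),
    "TCD": (1.5, 6.0),
}

#: Unit each parameter is stored in throughout the pipeline.
STORED_UNIT = {p: ("mm" if p == "CRL" else "cm") for p in PARAMETERS}

#: Replicate counts per protocol: three CRL measurements, two of everything else.
EXPECTED_REPLICATES = {p: (3 if p == "CRL" else 2) for p in PARAMETERS}

#: Missing-value sentinel used throughout (never a magic number).
MISSING = float("nan")


class UnknownParameterError(KeyError):
    """Raised for a parameter name outside the six supported ones."""


class MeasurementRangeError(ValueError):
    """Raised when an equation is evaluated strictly outside its valid range."""


def _check_parameter(parameter: str) -> str:
    if parameter not in PARAMETERS:
        raise UnknownParameterError(
            f"unknown parameter {parameter!r}; expected one of {PARAMETERS}"
        )
    return parameter


def validate_measurement(parameter: str, value: float) -> bool:
    """Return True iff *value* lies within the closed plausible range.

    Boundary values pass (closed-interval convention). Non-finite values fail.
    Unknown parameter names are a hard error.
    """
    _check_parameter(parameter)
    if value is None or not math.isfinite(value):
        return False
    lo, hi = PLAUSIBLE_RANGES[parameter]
    return lo <= value <= hi


@dataclass(frozen=True)
class RawMeasurementSet:
    """Replicate measurements of one parameter at one visit.

    CRL carries three replicates, every other parameter two. Lost replicates
    are recorded as None and flagged, not silently dropped.
    """

    parameter: str
    replicates: tuple[float | None, ...]
    visit_id: str = ""

    def __post_init__(self) -> None:
        _check_parameter(self.parameter)
        expected = EXPECTED_REPLICATES[self.parameter]
        if len(self.replicates) != expected:
            raise ValueError(
                f"{self.parameter} requires {expected} replicate slots, "
                f"got {len(self.replicates)}"
            )
        for v in self.replicates:
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ValueError(
                    f"replicate values must be strictly positive, got {v!r}"
                )

    @property
    def present(self) -> tuple[float, ...]:
        return tuple(v for v in self.replicates if v is not None)


def summarize_replicates(raw: RawMeasurementSet) -> float:
    """Collapse replicates to a single summary length.

    CRL: median of replicates. All other parameters: arithmetic mean.
    A single surviving replicate is used as-is (with a warning); zero valid
    replicates yield the missing sentinel, not an error.
    """
    values = raw.present
    if not values:
        return MISSING
    if len(values) < EXPECTED_REPLICATES[raw.parameter]:
        warnings.warn(
            f"{raw.parameter} visit {raw.visit_id!r}: only {len(values)} of "
            f"{EXPECTED_REPLICATES[raw.parameter]} replicates present",
            stacklevel=2,
        )
    if raw.parameter == "CRL":
        return float(np.median(values))
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Functional forms
# ---------------------------------------------------------------------------

FUNCTIONAL_FORMS = ("polynomial", "log_linear", "crl_sqrt", "hc_log")


def _eval_polynomial(coeffs: tuple[float, ...], x: float) -> float:
    return float(sum(c * x**k for k, c in enumerate(coeffs)))


@dataclass(frozen=True)
class DatingEquation:
    """A named, parameterized mapping from measurement(s) to GA in days.

    ``functional_form`` selects the evaluator:

    - ``polynomial``: single parameter; GA = sum_k c_k * x**k in
      ``output_unit`` (weeks or days), converted to days.
    - ``log_linear``: GA_days = c0 + sum_i c_i * ln(x_i), parameters in the
      order of ``required_parameters``.
    - ``crl_sqrt``: GA_days = c0 + c1*sqrt(x) + c2*x (first-trimester CRL
      dating form; x in mm).
    - ``hc_log``: GA_days = exp(c0 + c1*ln(x)**2 + c2*x**3) (head-circumference
      dating form; x in mm).
    """

    name: str
    required_parameters: tuple[str, ...]
    functional_form: str
    coefficients: tuple[float, ...]
    valid_range: dict[str, tuple[float, float]]
    input_unit: str = "cm"
    output_unit: str = "days"
    source: str = ""

    def __post_init__(self) -> None:
        if self.functional_form not in FUNCTIONAL_FORMS:
            raise ValueError(f"unknown functional form {self.functional_form!r}")
        for p in self.required_parameters:
            _check_parameter(p)
            if p not in self.valid_range:
                raise ValueError(f"{self.name}: no valid range for {p}")

    def _to_input_unit(self, parameter: str, value: float) -> float:
        return convert_length(value, STORED_UNIT[parameter], self.input_unit)

    def in_range(self, **values: float) -> bool:
        """True iff every required parameter is present and within its valid range."""
        for p in self.required_parameters:
            v = values.get(p)
            if v is None or not math.isfinite(v):
                return False
            lo, hi = self.valid_range[p]
            if not (lo <= v <= hi):
                return False
        return True

    def evaluate(self, **values: float) -> float:
        """Evaluate GA in days. Missing input -> missing sentinel; an input
        outside the equation's valid range -> :class:`MeasurementRangeError`."""
        xs = []
        for p in self.required_parameters:
            v = values.get(p)
            if v is None or not math.isfinite(v):
                return MISSING
            lo, hi = self.valid_range[p]
            if not (lo <= v <= hi):
                raise MeasurementRangeError(
                    f"{self.name}: {p}={v} outside valid range [{lo}, {hi}]"
                )
            xs.append(self._to_input_unit(p, v))

        form = self.functional_form
        c = self.coefficients
        if form == "polynomial":
            (x,) = xs
            ga = _eval_polynomial(c, x)
            if self.output_unit == "weeks":
                ga *= DAYS_PER_WEEK
        elif form == "log_linear":
            ga = c[0] + sum(ci * math.log(x) for ci, x in zip(c[1:], xs))
        elif form == "crl_sqrt":
            (x,) = xs
            ga = c[0] + c[1] * math.sqrt(x) + c[2] * x
        elif form == "hc_log":
            (x,) = xs
            ga = math.exp(c[0] + c[1] * math.log(x) ** 2 + c[2] * x**3)
        else:  # pragma: no cover - guarded in __post_init__
            raise AssertionError(form)
        return float(ga)

    def ga_bounds(self) -> tuple[float, float]:
        """GA in days at the lower/upper corners of the valid range.

        Valid because every shipped equation is monotone increasing in each
        required parameter (asserted by the grid-sweep check).
        """
        lo = {p: self.valid_range[p][0] for p in self.required_parameters}
        hi = {p: self.valid_range[p][1] for p in self.required_parameters}
        return self.evaluate(**lo), self.evaluate(**hi)


def equation_is_monotone(eq: DatingEquation, n_grid: int = 200) -> bool:
    """Grid-sweep check that GA increases strictly in each required parameter.

    Each parameter is swept across its valid range while the others are held
    at their range midpoints.
    """
    mid = {
        p: 0.5 * (eq.valid_range[p][0] + eq.valid_range[p][1])
        for p in eq.required_parameters
    }
    for p in eq.required_parameters:
        lo, hi = eq.valid_range[p]
        grid = np.linspace(lo, hi, n_grid)
        gas = [eq.evaluate(**{**mid, p: float(x)}) for x in grid]
        if not all(b > a for a, b in zip(gas, gas[1:])):
            return False
    return True


def invert_equation(eq: DatingEquation, ga_days: float) -> float:
    """Measurement value producing *ga_days* under a single-parameter equation.

    Used by the synthetic generator as the growth curve (nomogram inverse),
    guaranteeing round-trip consistency with :func:`ga_from_biometry`.
    """
    if len(eq.required_parameters) != 1:
        raise ValueError(f"{eq.name}: inversion requires a single-parameter equation")
    (p,) = eq.required_parameters
    lo, hi = eq.valid_range[p]
    ga_lo, ga_hi = eq.ga_bounds()
    if not (ga_lo <= ga_days <= ga_hi):
        raise MeasurementRangeError(
            f"{eq.name}: GA {ga_days:.1f} d outside achievable span "
            f"[{ga_lo:.1f}, {ga_hi:.1f}]"
        )
    return float(brentq(lambda x: eq.evaluate(**{p: x}) - ga_days, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# Equation registry (configuration file I/O)
# ---------------------------------------------------------------------------


def _equation_from_record(rec: Mapping) -> DatingEquation:
    return DatingEquation(
        name=rec["name"],
        required_parameters=tuple(rec["required_parameters"]),
        functional_form=rec["functional_form"],
        coefficients=tuple(float(c) for c in rec["coefficients"]),
        valid_range={p: (float(lo), float(hi)) for p, (lo, hi) in rec["valid_range"].items()},
        input_unit=rec.get("input_unit", "cm"),
        output_unit=rec.get("output_unit", "days"),
        source=rec.get("source", ""),
    )


def _equation_to_record(eq: DatingEquation) -> dict:
    return {
        "name": eq.name,
        "required_parameters": list(eq.required_parameters),
        "functional_form": eq.functional_form,
        "coefficients": list(eq.coefficients),
        "valid_range": {p: [lo, hi] for p, (lo, hi) in eq.valid_range.items()},
        "input_unit": eq.input_unit,
        "output_unit": eq.output_unit,
        "source": eq.source,
    }


def load_equations(path: str | None = None) -> dict[str, DatingEquation]:
    """Load the equation registry from a YAML config (default: packaged file)."""
    if path is None:
        text = resources.files("latedating").joinpath("data/equations.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    eqs = [_equation_from_record(rec) for rec in doc["equations"]]
    names = [e.name for e in eqs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate equation names in config")
    return {e.name: e for e in eqs}


def save_equations(equations: Iterable[DatingEquation], path: str) -> None:
    """Write an equation registry to YAML; reloads bit-exact."""
    doc = {"equations": [_equation_to_record(e) for e in equations]}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


_DEFAULT_REGISTRY: dict[str, DatingEquation] | None = None


def default_equations() -> dict[str, DatingEquation]:
    """Cached copy of the packaged equation registry."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = load_equations()
    return dict(_DEFAULT_REGISTRY)


# ---------------------------------------------------------------------------
# High-level dating operations
# ---------------------------------------------------------------------------


def ga_from_crl(crl_mm: float, equation: DatingEquation | None = None) -> float:
    """First-trimester GA in days from the median CRL (mm).

    Raises :class:`MeasurementRangeError` outside the equation's valid range.
    """
    eq = equation if equation is not None else default_equations()["intergrowth_crl"]
    if crl_mm is None or not math.isfinite(crl_mm):
        raise MeasurementRangeError(f"CRL must be a finite number, got {crl_mm!r}")
    return eq.evaluate(CRL=crl_mm)


def ga_from_biometry(scan: Mapping, equation: DatingEquation) -> float:
    """GA in days from one scan row (mapping with ``<param>_cm`` keys).

    Missing or out-of-range inputs propagate to the missing sentinel (the
    cleaning stage has already logged out-of-range values as missing).
    """
    values = {}
    for p in equation.required_parameters:
        v = scan.get(f"{p.lower()}_cm", scan.get(p))
        values[p] = v
    if not equation.in_range(**values):
        return MISSING
    return equation.evaluate(**values)
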