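"""Derivation of new GA prediction formulas by ln-transformed regression.

Gold-standard GA in days is regressed on natural-log-transformed biometry
(Gaussian family, identity link, least squares) with variance estimates
cluster-robust by participant, since most participants contribute two visits.
Candidate formulas are ranked by a standardized cross-validated prediction
error under two schemes: 5-fold (folds partition participants, so clustered
visits never straddle train/test) and leave-one-site-out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dating_equations import PLAUSIBLE_RANGES, DatingEquation

logger = logging.getLogger(__name__)

#: Covariates allowed in candidate models (ln-transformed at fit time).
MODEL_PARAMETERS = ("TCD", "BPD", "HC", "FL", "AC")


@dataclass(frozen=True)
class CandidateModel:
    """A regression specification: GA (days) on ln-transformed parameters."""

    name: str
    covariates: tuple[str, ...]

    def __post_init__(self) -> None:
        for p in self.covariates:
            if p not in MODEL_PARAMETERS:
                raise ValueError(f"unsupported covariate {p!r}")

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(f"ln{p}" for p in self.covariates)


#: The four shipped candidates: a full model and three two-parameter ones.
CANDIDATE_MODELS: tuple[CandidateModel, ...] = (
    CandidateModel("model1", ("TCD", "BPD", "FL", "AC")),
    CandidateModel("model2", ("TCD", "FL")),
    CandidateModel("model3", ("TCD", "BPD")),
    CandidateModel("model4", ("TCD", "AC")),
)

PARSIMONIOUS_MODELS = ("model2", "model3", "model4")


@dataclass(frozen=True)
class ModelFit:
    model: CandidateModel
    coefficients: tuple[float, ...]  # intercept first, then per covariate
    cluster_robust_se: tuple[float, ...]
    p_values: tuple[float, ...]
    adjusted_r2: float
    aic: float
    n_obs: int
    n_clusters: int

    def predict(self, scan: Mapping) -> float:
        """Linear predictor on ln-covariates; missing covariate -> NaN."""
        ga = self.coefficients[0]
        for c, p in zip(self.coefficients[1:], self.model.covariates):
            v = scan.get(f"{p.lower()}_cm", scan.get(p))
            if v is None or not np.isfinite(v) or v <= 0:
                return float("nan")
            ga += c * math.log(v)
        return float(ga)


@dataclass(frozen=True)
class CVResult:
    model_name: str
    scheme: str  # "FIVE_FOLD" or "LEAVE_ONE_SITE_OUT"
    fold_errors: tuple[float, ...]
    fold_labels: tuple[str, ...]
    summary_error: float
    n_obs: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.summary_error < 0 or any(e < 0 for e in self.fold_errors):
            raise ValueError("standardized errors are nonnegative by construction")


class SingularDesignError(np.linalg.LinAlgError):
    """Raised for a collinear or degenerate design matrix."""


def _design(scans: pd.DataFrame, model: CandidateModel) -> pd.DataFrame:
    """Complete-case ln-design with response and cluster columns."""
    cols = [f"{p.lower()}_cm" for p in model.covariates]
    needed = cols + ["ga_gold_days", "participant_id"]
    df = scans[needed].dropna(subset=cols + ["ga_gold_days"]).copy()
    df = df[(df[cols] > 0).all(axis=1)]
    for p, col in zip(model.covariates, cols):
        df[f"ln{p}"] = np.log(df[col])
    return df


def fit_model(scans: pd.DataFrame, model: CandidateModel) -> ModelFit:
    """Least-squares fit of GA on ln-covariates with cluster-robust SEs.

    Complete-case rows for this model's covariates; both scan windows pooled;
    outlier exclusion is assumed done upstream.
    """
    df = _design(scans, model)
    p = len(model.covariates)
    if len(df) < p + 2:
        raise ValueError(
            f"{model.name}: need >= {p + 2} complete-case rows, got {len(df)}"
        )
    X = sm.add_constant(df[list(model.term_names)], has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise SingularDesignError(
            f"{model.name}: design is rank-deficient over covariates "
            f"{model.term_names}"
        )
    ols = sm.OLS(df["ga_gold_days"], X)
    res = ols.fit()
    robust = res.get_robustcov_results(
        cov_type="cluster", groups=df["participant_id"]
    )
    return ModelFit(
        model=model,
        coefficients=tuple(float(b) for b in res.params),
        cluster_robust_se=tuple(float(s) for s in robust.bse),
        p_values=tuple(float(v) for v in robust.pvalues),
        adjusted_r2=float(res.rsquared_adj),
        aic=float(res.aic),
        n_obs=int(res.nobs),
        n_clusters=int(df["participant_id"].nunique()),
    )


def predict_ga(fit: ModelFit, scans: pd.DataFrame | Mapping) -> pd.Series | float:
    """Predicted GA in days for scan rows (or a single mapping)."""
    if isinstance(scans, pd.DataFrame):
        return scans.apply(lambda r: fit.predict(r), axis=1)
    return fit.predict(scans)


def fit_to_equation(fit: ModelFit, name: str | None = None) -> DatingEquation:
    """Register a fitted formula as a log-linear DatingEquation.

    Valid ranges reuse the plausible measurement ranges, so the agreement
    module can evaluate the derived formula exactly like a published one.
    """
    return DatingEquation(
        name=name or f"amanhi_{fit.model.name}",
        required_parameters=fit.model.covariates,
        functional_form="log_linear",
        coefficients=fit.coefficients,
        valid_range={p: PLAUSIBLE_RANGES[p] for p in fit.model.covariates},
        input_unit="cm",
        output_unit="days",
        source=f"derived in-cohort ({fit.model.name}: "
        + " + ".join(fit.model.term_names)
        + ")",
    )


def standardized_error(observed_ga: float, predicted_ga: float) -> float:
    """(observed - predicted)^2 / predicted, GA in days."""
    if not predicted_ga > 0:
        raise ValueError(f"predicted GA must be positive, got {predicted_ga}")
    return (observed_ga - predicted_ga) ** 2 / predicted_ga


def _fold_errors(
    train: pd.DataFrame, test: pd.DataFrame, model: CandidateModel
) -> np.ndarray:
    """Standardized errors on *test* from a fit on *train* (complete cases).

    Observations with a nonpositive prediction are flagged and skipped.
    """
    fit = fit_model(train, model)
    test_cc = _design(test, model)
    pred = (
        fit.coefficients[0]
        + test_cc[list(model.term_names)].to_numpy()
        @ np.asarray(fit.coefficients[1:])
    )
    obs = test_cc["ga_gold_days"].to_numpy()
    bad = pred <= 0
    if bad.any():
        logger.warning(
            "%s: skipping %d observations with nonpositive predicted GA",
            model.name,
            int(bad.sum()),
        )
    return (obs[~bad] - pred[~bad]) ** 2 / pred[~bad]


def _summarize(errors: Sequence[np.ndarray], statistic: str) -> float:
    allerr = np.concatenate([np.asarray(e) for e in errors])
    if statistic == "mean":
        return float(np.mean(allerr))
    if statistic == "median":
        return float(np.median(allerr))
    if statistic == "sum":
        return float(np.sum(allerr))
    raise ValueError(f"unknown summary statistic {statistic!r}")


def cross_validate_kfold(
    scans: pd.DataFrame,
    model: CandidateModel,
    k: int = 5,
    seed: int = 0,
    summary: str = "mean",
) -> CVResult:
    """K-fold CV with folds partitioning participants, not rows.

    Per withheld fold, the model is refit on the remainder and standardized
    errors are computed on the fold; ``summary_error`` pools errors over all
    observations. Deterministic given *seed*.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    participants = np.sort(scans["participant_id"].unique())
    if k > len(participants):
        raise ValueError(f"k={k} exceeds {len(participants)} participants")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(participants))
    assignments = np.empty(len(participants), dtype=int)
    assignments[order] = np.arange(len(participants)) % k
    fold_of = dict(zip(participants, assignments))
    fold_ids = scans["participant_id"].map(fold_of)

    per_fold_errors, labels, means = [], [], []
    for fold in range(k):
        test = scans[fold_ids == fold]
        train = scans[fold_ids != fold]
        errs = _fold_errors(train, test, model)
        if errs.size == 0:
            raise ValueError(f"fold {fold}: no complete-case test observations")
        per_fold_errors.append(errs)
        labels.append(f"fold{fold}")
        means.append(float(np.mean(errs)))
    return CVResult(
        model_name=model.name,
        scheme="FIVE_FOLD" if k == 5 else f"{k}_FOLD",
        fold_errors=tuple(means),
        fold_labels=tuple(labels),
        summary_error=_summarize(per_fold_errors, summary),
        n_obs=int(sum(e.size for e in per_fold_errors)),
        seed=seed,
    )


def cross_validate_leave_site_out(
    scans: pd.DataFrame, model: CandidateModel, summary: str = "mean"
) -> CVResult:
    """Leave-one-site-out CV, cycling every site as the withheld fold."""
    sites = sorted(scans["site"].unique())
    if len(sites) < 2:
        raise ValueError("leave-one-site-out requires >= 2 sites")
    per_fold_errors, labels, means = [], [], []
    for site in sites:
        test = scans[scans["site"] == site]
        train = scans[scans["site"] != site]
        errs = _fold_errors(train, test, model)
        if errs.size == 0:
            raise ValueError(f"site {site}: no complete-case test observations")
        per_fold_errors.append(errs)
        labels.append(str(site))
        means.append(float(np.mean(errs)))
    return CVResult(
        model_name=model.name,
        scheme="LEAVE_ONE_SITE_OUT",
        fold_errors=tuple(means),
        fold_labels=tuple(labels),
        summary_error=_summarize(per_fold_errors, summary),
        n_obs=int(sum(e.size for e in per_fold_errors)),
    )


@dataclass(frozen=True)
class ModelSelection:
    chosen: CandidateModel
    final_fit: ModelFit
    ranking: pd.DataFrame = field(repr=False)
    near_tie: bool = False


def select_model(
    scans: pd.DataFrame,
    fits: Mapping[str, ModelFit],
    cv_results: Mapping[str, CVResult],
    candidates: Sequence[str] = PARSIMONIOUS_MODELS,
    near_tie_tolerance: float = 0.02,
) -> ModelSelection:
    """Choose the parsimonious candidate with the lowest CV summary error.

    Ties (within *near_tie_tolerance*, relative) are flagged and broken by
    fewer covariates, then lower AIC. The winner is refit on the full dataset
    for its final coefficients. The full ranking of every fitted candidate is
    reported alongside.
    """
    rows = []
    for name, fit in fits.items():
        cv = cv_results.get(name)
        rows.append(
            {
                "model": name,
                "covariates": "+".join(fit.model.term_names),
                "n_obs": fit.n_obs,
                "adjusted_r2": fit.adjusted_r2,
                "aic": fit.aic,
                "cv_summary_error": cv.summary_error if cv else float("nan"),
            }
        )
    ranking = pd.DataFrame(rows).sort_values("cv_summary_error").reset_index(drop=True)

    pool = [n for n in candidates if n in fits and n in cv_results]
    if not pool:
        raise ValueError("no candidate has both a fit and a CV result")
    keyed = sorted(
        pool,
        key=lambda n: (
            cv_results[n].summary_error,
            len(fits[n].model.covariates),
            fits[n].aic,
        ),
    )
    best = keyed[0]
    best_err = cv_results[best].summary_error
    near = [
        n
        for n in pool
        if n != best
        and cv_results[n].summary_error <= best_err * (1.0 + near_tie_tolerance)
    ]
    if near:
        logger.info("near-tied candidates with %s: %s", best, near)
    final = fit_model(scans, fits[best].model)
    return ModelSelection(
        chosen=fits[best].model, final_fit=final, ranking=ranking, near_tie=bool(near)
    )


def derive_models(
    scans: pd.DataFrame,
    candidates: Sequence[CandidateModel] = CANDIDATE_MODELS,
    k: int = 5,
    seed: int = 0,
) -> tuple[dict[str, ModelFit], dict[str, CVResult], dict[str, CVResult]]:
    """Fit and cross-validate every candidate; returns (fits, kfold, site CV)."""
    fits = {m.name: fit_model(scans, m) for m in candidates}
    kfold = {m.name: cross_validate_kfold(scans, m, k=k, seed=seed) for m in candidates}
    n_sites = scans["site"].nunique()
    loso = (
        {m.name: cross_validate_leave_site_out(scans, m) for m in candidates}
        if n_sites >= 2
        else {}
    )
    return fits, kfold, loso
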