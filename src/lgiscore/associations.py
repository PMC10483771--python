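"""Association analyses: quartile logistic models, trend tests, stratification.

The exposure is the cohort quartile of the LGI score (reference: quartile
1, the least inflamed).  For each endpoint a logistic model is fitted at
three adjustment tiers:

    crude   — quartile indicators only
    model1  — + gender, age
    model2  — + smoking, drinking, prior stroke, AF, CHD, hypertension,
              diabetes, dyslipidemia; for the 90-day outcome additionally
              the baseline NIHSS score

Odds ratios are exp(beta) with Wald 95% confidence intervals
exp(beta ± 1.96·SE).  The p-for-trend refits the model with the quartile
entered as a single ordinal covariate (1..4) and reports the Wald p-value
of that term.  Stratified analyses fit crude within-stratum models and
test effect modification with a 1-df likelihood-ratio test on the
stratifier × ordinal-quartile product term.  All models are complete-case;
each report records the rows used and dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

try:  # statsmodels moved/deprecated this exception across versions
    from statsmodels.tools.sm_exceptions import (
        PerfectSeparationError,
        PerfectSeparationWarning,
    )
except ImportError:  # pragma: no cover
    PerfectSeparationError = RuntimeError
    PerfectSeparationWarning = UserWarning

__all__ = [
    "OUTCOMES",
    "TIERS",
    "ModelSpec",
    "QuartileOR",
    "ModelReport",
    "QuartileLogisticModel",
    "fit_quartile_logistic",
    "p_for_trend",
    "spearman_lgi_nihss",
    "stratified_analysis",
    "default_strata",
]

OUTCOMES = ("severe_baseline", "severe_day7", "end_flag", "poor_90d")
TIERS = ("crude", "model1", "model2")

_MODEL1_COVARIATES = ["male", "age"]
_MODEL2_EXTRA = [
    "smoking", "drinking", "prior_stroke", "af", "chd",
    "hypertension", "diabetes", "dyslipidemia",
]


@dataclass
class ModelSpec:
    """Outcome, exposure coding tier, and the resolved covariate list."""

    outcome: str
    tier: str = "crude"
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(
                f"outcome must be one of {OUTCOMES}, got {self.outcome!r}"
            )
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}, got {self.tier!r}")
        if not self.covariates:
            self.covariates = self.resolve_covariates(self.outcome, self.tier)

    @staticmethod
    def resolve_covariates(outcome: str, tier: str) -> list[str]:
        if tier == "crude":
            return []
        cov = list(_MODEL1_COVARIATES)
        if tier == "model2":
            cov += _MODEL2_EXTRA
            if outcome == "poor_90d":
                cov.append("nihss_baseline")
        return cov


@dataclass
class QuartileOR:
    quartile: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class ModelReport:
    """Fitted quartile logistic model: per-quartile ORs plus trend test."""

    outcome: str
    tier: str
    covariates: list[str]
    quartile_ors: list[QuartileOR]
    p_for_trend: float | None
    n_used: int
    n_dropped: int
    converged: bool
    separation: bool
    log_likelihood: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


class ConvergenceError(RuntimeError):
    pass


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """MLE logistic fit; returns (result_or_None, converged, separation)."""
    separation = False
    result = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            model = sm.Logit(y, X)
            result = model.fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return None, False, True
        for w in caught:
            if issubclass(w.category, PerfectSeparationWarning):
                separation = True
    converged = bool(result.mle_retvals.get("converged", False))
    if result is not None and np.any(np.abs(result.params) > 15):
        # fitted log-odds walking off to infinity: quasi-separation
        separation = True
        converged = False
    return result, converged and not separation, separation


def _complete_cases(
    data: pd.DataFrame, columns: Sequence[str]
) -> tuple[pd.DataFrame, int]:
    sub = data[list(columns)].apply(pd.to_numeric, errors="coerce")
    kept = sub.dropna()
    return kept, len(data) - len(kept)


def fit_quartile_logistic(data: pd.DataFrame, spec: ModelSpec) -> ModelReport:
    """Fit the quartile-indicator logistic model for one endpoint and tier.

    ``data`` must carry the endpoint column, ``lgi_quartile`` and any tier
    covariates.  Non-convergence or separation is flagged on the report
    rather than silently worked around; a single-class outcome raises.
    """
    cols = [spec.outcome, "lgi_quartile", *spec.covariates]
    sub, n_dropped = _complete_cases(data, cols)
    y = sub[spec.outcome].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"outcome {spec.outcome!r} has a single class in the analysis rows"
        )
    q = sub["lgi_quartile"].astype(int)
    present = sorted(q.unique())
    if 1 not in present:
        raise ValueError("reference quartile (1) is empty in the analysis rows")
    fit_levels = [lv for lv in (2, 3, 4) if lv in present]
    X = pd.DataFrame(index=sub.index)
    X["const"] = 1.0
    for level in fit_levels:
        X[f"q{level}"] = (q == level).astype(float)
    for c in spec.covariates:
        X[c] = sub[c].astype(float)

    result, converged, separation = _fit_logit(y, X)
    quartile_ors = [QuartileOR(1, 1.0, 1.0, 1.0, float("nan"))]
    llf = None
    if result is not None:
        llf = float(result.llf)
        with np.errstate(over="ignore"):
            for level in fit_levels:
                name = f"q{level}"
                beta = float(result.params[name])
                se = float(result.bse[name])
                quartile_ors.append(
                    QuartileOR(
                        quartile=level,
                        odds_ratio=float(np.exp(beta)),
                        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                        p_value=float(result.pvalues[name]),
                    )
                )
    trend = None
    if converged:
        trend = p_for_trend(data, spec)
    return ModelReport(
        outcome=spec.outcome,
        tier=spec.tier,
        covariates=list(spec.covariates),
        quartile_ors=quartile_ors,
        p_for_trend=trend,
        n_used=len(sub),
        n_dropped=n_dropped,
        converged=converged,
        separation=separation,
        log_likelihood=llf,
    )


def p_for_trend(data: pd.DataFrame, spec: ModelSpec) -> float:
    """Wald p-value of the quartile index (1..4) entered as one ordinal term."""
    cols = [spec.outcome, "lgi_quartile", *spec.covariates]
    sub, _ = _complete_cases(data, cols)
    y = sub[spec.outcome].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"outcome {spec.outcome!r} has a single class in the analysis rows"
        )
    X = pd.DataFrame(index=sub.index)
    X["const"] = 1.0
    X["quartile"] = sub["lgi_quartile"].astype(float)
    for c in spec.covariates:
        X[c] = sub[c].astype(float)
    result, converged, separation = _fit_logit(y, X)
    if result is None:
        raise ConvergenceError("trend model separated; p-for-trend undefined")
    return float(result.pvalues["quartile"])


def spearman_lgi_nihss(
    lgi_scores: Sequence[float], nihss_values: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks under ties) with two-sided p."""
    x = np.asarray(lgi_scores, dtype=float)
    z = np.asarray(nihss_values, dtype=float)
    if x.shape != z.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(z == z[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, z)
    return float(rho), float(p)


def default_strata(data: pd.DataFrame) -> dict[str, pd.Series]:
    """The standard stratifiers as label series aligned with ``data``."""
    strata: dict[str, pd.Series] = {}
    strata["nihss"] = np.where(data["nihss_baseline"] > 5, ">5", "<=5")
    strata["gender"] = np.where(data["male"].astype(int) == 1, "male", "female")
    strata["age"] = np.where(data["age"] >= 65, ">=65", "<65")
    for flag in (
        "smoking", "drinking", "prior_stroke", "chd", "af",
        "hypertension", "diabetes", "dyslipidemia",
    ):
        strata[flag] = np.where(data[flag].astype(int) == 1, "yes", "no")
    return {k: pd.Series(v, index=data.index) for k, v in strata.items()}


def _interaction_p(
    data: pd.DataFrame, outcome: str, stratum_indicator: pd.Series
) -> float:
    """1-df LRT on stratifier × ordinal-quartile in the pooled crude model."""
    sub = pd.DataFrame(
        {
            "y": pd.to_numeric(data[outcome], errors="coerce"),
            "quartile": pd.to_numeric(data["lgi_quartile"], errors="coerce"),
            "s": pd.to_numeric(stratum_indicator, errors="coerce"),
        }
    ).dropna()
    y = sub["y"].to_numpy()
    X0 = pd.DataFrame(
        {
            "const": 1.0,
            "quartile": sub["quartile"].astype(float),
            "s": sub["s"].astype(float),
        },
        index=sub.index,
    )
    X1 = X0.copy()
    X1["qxs"] = X1["quartile"] * X1["s"]
    r0, c0, _ = _fit_logit(y, X0)
    r1, c1, _ = _fit_logit(y, X1)
    if r0 is None or r1 is None:
        return float("nan")
    lr = 2.0 * (r1.llf - r0.llf)
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def stratified_analysis(
    data: pd.DataFrame,
    outcome: str = "poor_90d",
    strata_defs: Mapping[str, pd.Series] | None = None,
    tier: str = "crude",
) -> dict[str, dict]:
    """Within-stratum quartile models plus one interaction p per stratifier.

    Quartile labels are those of the full cohort (grouping is not redone
    within strata).  Strata where the model cannot be fitted (empty
    quartile cell, single-class outcome) are skipped with a warning and
    flagged in the output.
    """
    strata = dict(strata_defs) if strata_defs is not None else default_strata(data)
    out: dict[str, dict] = {}
    for name, labels in strata.items():
        labels = pd.Series(labels, index=data.index)
        levels = [lv for lv in pd.unique(labels.dropna())]
        per_level: dict[str, ModelReport | None] = {}
        for lv in levels:
            rows = data.loc[labels == lv]
            try:
                spec = ModelSpec(outcome=outcome, tier=tier)
                per_level[str(lv)] = fit_quartile_logistic(rows, spec)
            except (ValueError, ConvergenceError) as exc:
                warnings.warn(
                    f"stratum {name}={lv!r} skipped: {exc}", UserWarning,
                    stacklevel=2,
                )
                per_level[str(lv)] = None
        if len(levels) == 2:
            indicator = (labels == levels[1]).astype(float)
            p_int = _interaction_p(data, outcome, indicator)
        else:
            p_int = float("nan")
        out[name] = {"levels": per_level, "p_interaction": p_int}
    return out


class QuartileLogisticModel(BaseEstimator):
    """Scikit-learn style wrapper around the quartile logistic fit.

    Parameters
    ----------
    outcome : str
        One of ``severe_baseline``, ``severe_day7``, ``end_flag``,
        ``poor_90d``.
    tier : str
        Adjustment tier: ``crude``, ``model1`` or ``model2``.

    After ``fit(data)`` the report is available as ``report_`` and the
    per-quartile odds ratios as ``odds_ratios_``.
    """

    def __init__(self, outcome: str = "poor_90d", tier: str = "crude"):
        self.outcome = outcome
        self.tier = tier

    def fit(self, X: pd.DataFrame, y=None) -> "QuartileLogisticModel":
        spec = ModelSpec(outcome=self.outcome, tier=self.tier)
        self.spec_ = spec
        self.report_ = fit_quartile_logistic(X, spec)
        self.odds_ratios_ = {
            qr.quartile: qr.odds_ratio for qr in self.report_.quartile_ors
        }
        self.p_for_trend_ = self.report_.p_for_trend
        return self
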