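"""Predictive performance and added value: ROC/AUC, continuous NRI, IDI.

The AUC is the Mann–Whitney concordance probability (ties count 1/2),
with a DeLong variance for the 95% confidence interval.  The continuous
net reclassification improvement (NRI) and integrated discrimination
improvement (IDI) follow their standard definitions:

    NRI = [P(up | event) − P(down | event)]
        + [P(down | nonevent) − P(up | nonevent)]            ∈ [−2, 2]

    IDI = [mean(p_new | event) − mean(p_new | nonevent)]
        − [mean(p_old | event) − mean(p_old | nonevent)]     ∈ [−1, 1]

where "up"/"down" mean the new model's predicted risk strictly rose or
fell; exact ties contribute no movement.  Inference is asymptotic: for
the NRI the variance of each group's net proportion, for the IDI a
paired-difference z-test on the risk contrasts; a seeded bootstrap
percentile interval is available as an option.

``compare_models`` reproduces the add-on analysis for the 90-day
outcome: a conventional logistic model (age + baseline NIHSS) versus the
same model with the continuous LGI score added, compared through their
in-sample predicted risks.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "AucResult",
    "ReclassResult",
    "DiscriminationReport",
    "roc_auc",
    "delong_ci",
    "continuous_nri",
    "idi",
    "compare_models",
    "roc_curve_points",
    "AddedValueComparison",
]


@dataclass
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    variance: float
    n_events: int
    n_nonevents: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReclassResult:
    value: float
    se: float
    z: float
    p_value: float
    ci_low: float | None = None
    ci_high: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class DiscriminationReport:
    auc_lgi: AucResult
    auc_conventional: AucResult
    auc_addon: AucResult
    c_statistic_delta: float
    continuous_nri: ReclassResult
    idi: ReclassResult
    converged: bool

    def to_dict(self) -> dict:
        return {
            "auc_lgi": self.auc_lgi.to_dict(),
            "auc_conventional": self.auc_conventional.to_dict(),
            "auc_addon": self.auc_addon.to_dict(),
            "c_statistic_delta": self.c_statistic_delta,
            "continuous_nri": self.continuous_nri.to_dict(),
            "idi": self.idi.to_dict(),
            "converged": self.converged,
        }


def _split(scores, outcomes):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and outcomes must be the same length")
    if not np.isin(np.unique(y), [0.0, 1.0]).all():
        raise ValueError("outcomes must be binary 0/1")
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both events and nonevents")
    return pos, neg


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components V10 (events) and V01 (nonevents)."""
    m, n = pos.size, neg.size
    allv = np.concatenate([pos, neg])
    tz = rankdata(allv, method="average")
    tx = rankdata(pos, method="average")
    ty = rankdata(neg, method="average")
    v10 = (tz[:m] - tx) / n  # per-event placement values
    v01 = 1.0 - (tz[m:] - ty) / m  # per-nonevent placement values
    return v10, v01


def roc_auc(scores, outcomes, alpha: float = 0.05) -> AucResult:
    """AUC (ties 1/2) with a DeLong-variance confidence interval."""
    pos, neg = _split(scores, outcomes)
    v10, v01 = _delong_components(pos, neg)
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if pos.size > 1 else 0.0
    s01 = v01.var(ddof=1) if neg.size > 1 else 0.0
    var = s10 / pos.size + s01 / neg.size
    zcrit = stats.norm.ppf(1 - alpha / 2)
    half = zcrit * np.sqrt(var)
    return AucResult(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        variance=float(var),
        n_events=int(pos.size),
        n_nonevents=int(neg.size),
    )


def delong_ci(scores, outcomes, alpha: float = 0.05) -> tuple[float, float, float]:
    """(auc, ci_low, ci_high) convenience wrapper around :func:`roc_auc`."""
    r = roc_auc(scores, outcomes, alpha=alpha)
    return r.auc, r.ci_low, r.ci_high


def roc_curve_points(scores, outcomes) -> pd.DataFrame:
    """Empirical ROC coordinates (threshold, fpr, tpr) for export/plotting."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = tps / max(y.sum(), 1)
    fpr = fps / max((1 - y).sum(), 1)
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, s[distinct]],
            "fpr": np.r_[0.0, fpr],
            "tpr": np.r_[0.0, tpr],
        }
    )


def _check_risk_pairs(p_old, p_new, outcomes):
    po = np.asarray(p_old, dtype=float)
    pn = np.asarray(p_new, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if not (po.shape == pn.shape == y.shape):
        raise ValueError("p_old, p_new, outcomes must be the same length")
    if np.any((po <= 0) | (po >= 1)) or np.any((pn <= 0) | (pn >= 1)):
        raise ValueError("predicted risks must lie strictly in (0, 1)")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("need both events and nonevents")
    return po, pn, y


def continuous_nri(p_old, p_new, outcomes) -> ReclassResult:
    """Continuous net reclassification improvement with asymptotic p.

    Ties (p_new exactly equal to p_old) count as no movement.
    """
    po, pn, y = _check_risk_pairs(p_old, p_new, outcomes)
    ev, ne = y == 1, y == 0
    n_e, n_ne = int(ev.sum()), int(ne.sum())
    up_e = float(np.mean(pn[ev] > po[ev]))
    down_e = float(np.mean(pn[ev] < po[ev]))
    up_ne = float(np.mean(pn[ne] > po[ne]))
    down_ne = float(np.mean(pn[ne] < po[ne]))
    nri_e = up_e - down_e
    nri_ne = down_ne - up_ne
    nri = nri_e + nri_ne
    var_e = (up_e + down_e - nri_e**2) / n_e
    var_ne = (up_ne + down_ne - nri_ne**2) / n_ne
    se = float(np.sqrt(var_e + var_ne))
    z = nri / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return ReclassResult(value=float(nri), se=se, z=float(z), p_value=p)


def idi(p_old, p_new, outcomes) -> ReclassResult:
    """Integrated discrimination improvement with asymptotic p.

    IDI is the change in the discrimination slope (mean risk in events
    minus mean risk in nonevents) between the two models; the p-value is
    a paired-difference z-test on the per-subject risk contrasts.
    """
    po, pn, y = _check_risk_pairs(p_old, p_new, outcomes)
    ev, ne = y == 1, y == 0
    diff = pn - po
    value = float(diff[ev].mean() - diff[ne].mean())
    se_e = diff[ev].std(ddof=1) / np.sqrt(ev.sum()) if ev.sum() > 1 else 0.0
    se_ne = diff[ne].std(ddof=1) / np.sqrt(ne.sum()) if ne.sum() > 1 else 0.0
    se = float(np.sqrt(se_e**2 + se_ne**2))
    z = value / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return ReclassResult(value=value, se=se, z=float(z), p_value=p)


def bootstrap_ci(
    statistic, p_old, p_new, outcomes, n_boot: int = 2000, seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Seeded bootstrap percentile CI for an NRI/IDI-style statistic."""
    po, pn, y = _check_risk_pairs(p_old, p_new, outcomes)
    rng = np.random.default_rng(seed)
    n = y.size
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        if y[idx].sum() in (0, n):
            continue
        vals.append(statistic(po[idx], pn[idx], y[idx]).value)
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


class AddedValueComparison(BaseEstimator):
    """Added predictive value of the LGI score over a conventional model.

    Fits two nested logistic models for a binary outcome — conventional
    (age + baseline NIHSS) and add-on (+ LGI score) — and compares their
    predicted risks via AUC (DeLong CIs), ΔC, continuous NRI and IDI.

    Parameters
    ----------
    outcome : str, default "poor_90d"
    lgi_coding : {"continuous", "quartile"}
        How the LGI score enters the add-on model.  ``quartile`` uses the
        cohort quartile indicators instead of the raw score.
    cv : int or None
        If an integer k, risks are out-of-fold predictions from seeded
        stratified k-fold fitting instead of in-sample (apparent) risks.
    random_state : int
        Seed for the k-fold shuffle (unused when ``cv`` is None).
    """

    _CONVENTIONAL = ["age", "nihss_baseline"]

    def __init__(
        self,
        outcome: str = "poor_90d",
        lgi_coding: str = "continuous",
        cv: int | None = None,
        random_state: int = 0,
    ):
        self.outcome = outcome
        self.lgi_coding = lgi_coding
        self.cv = cv
        self.random_state = random_state

    def _design(self, df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        X_old = pd.DataFrame(index=df.index)
        X_old["const"] = 1.0
        for c in self._CONVENTIONAL:
            X_old[c] = df[c].astype(float)
        X_new = X_old.copy()
        if self.lgi_coding == "continuous":
            X_new["lgi_score"] = df["lgi_score"].astype(float)
        elif self.lgi_coding == "quartile":
            q = df["lgi_quartile"].astype(int)
            for level in (2, 3, 4):
                X_new[f"lgi_q{level}"] = (q == level).astype(float)
        else:
            raise ValueError(
                f"lgi_coding must be 'continuous' or 'quartile', "
                f"got {self.lgi_coding!r}"
            )
        return X_old, X_new

    def fit(self, X: pd.DataFrame, y=None) -> "AddedValueComparison":
        need = [self.outcome, "lgi_score", *self._CONVENTIONAL]
        if self.lgi_coding == "quartile":
            need.append("lgi_quartile")
        missing = [c for c in need if c not in X.columns]
        if missing:
            raise ValueError(f"input is missing column(s): {missing}")
        df = X[need].apply(pd.to_numeric, errors="coerce").dropna()
        yv = df[self.outcome].to_numpy()
        if len(np.unique(yv)) < 2:
            raise ValueError("outcome has a single class")
        X_old, X_new = self._design(df)
        converged = True
        if self.cv is None:
            p_old, c1 = self._fit_predict(yv, X_old, X_old)
            p_new, c2 = self._fit_predict(yv, X_new, X_new)
            converged = c1 and c2
        else:
            p_old = np.empty(len(df))
            p_new = np.empty(len(df))
            skf = StratifiedKFold(
                n_splits=self.cv, shuffle=True, random_state=self.random_state
            )
            for train, test in skf.split(X_old, yv):
                po, c1 = self._fit_predict(
                    yv[train], X_old.iloc[train], X_old.iloc[test]
                )
                pn, c2 = self._fit_predict(
                    yv[train], X_new.iloc[train], X_new.iloc[test]
                )
                p_old[test], p_new[test] = po, pn
                converged = converged and c1 and c2
        eps = 1e-12
        p_old = np.clip(p_old, eps, 1 - eps)
        p_new = np.clip(p_new, eps, 1 - eps)

        self.n_used_ = len(df)
        self.risk_old_ = p_old
        self.risk_new_ = p_new
        self.outcome_values_ = yv
        auc_lgi = roc_auc(df["lgi_score"].to_numpy(), yv)
        auc_old = roc_auc(p_old, yv)
        auc_new = roc_auc(p_new, yv)
        self.report_ = DiscriminationReport(
            auc_lgi=auc_lgi,
            auc_conventional=auc_old,
            auc_addon=auc_new,
            c_statistic_delta=float(auc_new.auc - auc_old.auc),
            continuous_nri=continuous_nri(p_old, p_new, yv),
            idi=idi(p_old, p_new, yv),
            converged=converged,
        )
        return self

    @staticmethod
    def _fit_predict(y, X_train, X_pred) -> tuple[np.ndarray, bool]:
        res = sm.Logit(y, X_train).fit(disp=0, maxiter=200)
        ok = bool(res.mle_retvals.get("converged", False))
        return np.asarray(res.predict(X_pred)), ok


def compare_models(
    data: pd.DataFrame,
    outcome: str = "poor_90d",
    lgi_coding: str = "continuous",
    cv: int | None = None,
    random_state: int = 0,
) -> DiscriminationReport:
    """Conventional (age + NIHSS) vs LGI add-on model comparison."""
    est = AddedValueComparison(
        outcome=outcome, lgi_coding=lgi_coding, cv=cv, random_state=random_state
    )
    est.fit(data)
    return est.report_
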