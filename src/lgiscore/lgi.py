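"""Low-grade inflammation (LGI) composite score.

Four inflammatory markers from the routine admission blood panel — CRP,
the leukocyte count (WBC), the platelet count (PLT), and the
neutrophil/lymphocyte ratio (NLR) — are each ranked within the analyzed
cohort and assigned to deciles.  Each decile maps to a fixed per-marker
score: deciles 1–4 score −4..−1, deciles 5–6 score 0, deciles 7–10 score
1..4.  The LGI score is the sum of the four marker scores and therefore
ranges from −16 to 16; higher values mean more intense low-grade
inflammation.  For reporting, cohort quartiles of the LGI score are also
formed.

Deciles are defined through mid-ranks so that ties are deterministic and
order-independent: observation i with mid-rank r_i (average rank among
equal values) in a cohort of n falls in decile ceil(10 * r_i / n).  The
same rule with 4 in place of 10 yields the quartile grouping.

The scoring is cohort-relative, so it is exposed as a scikit-learn style
transformer (:class:`LGIScorer`): ``fit`` stores the per-marker reference
distributions, ``transform`` ranks values against them.  Fitting and
transforming the same cohort reproduces the cohort-internal deciles
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .synth import PatientRecord, records_to_frame

__all__ = [
    "LGI_MARKERS",
    "LgiResult",
    "LGIScorer",
    "compute_nlr",
    "assign_deciles",
    "decile_to_score",
    "compute_lgi_scores",
    "quartile_groups",
    "NLRDomainError",
]

#: The four scored markers, in reporting order.
LGI_MARKERS = ("crp", "wbc", "plt", "nlr")

#: Fixed decile -> marker-score map (decile 1 -> -4 ... decile 10 -> 4).
DECILE_SCORE_MAP = {
    1: -4, 2: -3, 3: -2, 4: -1, 5: 0, 6: 0, 7: 1, 8: 2, 9: 3, 10: 4,
}


class NLRDomainError(ValueError):
    """Neutrophil/lymphocyte ratio undefined (non-positive lymphocyte count)."""


@dataclass
class LgiResult:
    """Per-patient scoring breakdown."""

    id: str
    nlr: float
    deciles: dict[str, int]
    marker_scores: dict[str, int]
    lgi_score: int
    quartile: int | None = None


def compute_nlr(neut: float, lymph: float) -> float:
    """Neutrophil count divided by lymphocyte count.

    Raises :class:`NLRDomainError` when ``lymph <= 0``; callers scoring a
    cohort exclude (and report) such records rather than failing.
    """
    if lymph <= 0:
        raise NLRDomainError(
            f"lymphocyte count must be > 0 to form NLR, got {lymph!r}"
        )
    if neut < 0:
        raise NLRDomainError(f"neutrophil count must be >= 0, got {neut!r}")
    return neut / lymph


def _midranks_against(reference: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Mid-rank of each value within the reference sample.

    For values drawn from the reference sample itself this reproduces the
    ordinary mid-rank (average rank under ties).
    """
    less = np.searchsorted(reference, values, side="left")
    leq = np.searchsorted(reference, values, side="right")
    return less + (leq - less + 1) / 2.0


def assign_deciles(values: Sequence[float]) -> np.ndarray:
    """Cohort-internal decile (1–10) of each observation via mid-ranks.

    decile_i = ceil(10 * r_i / n) with r_i the mid-rank.  Ties share a
    decile and the assignment is non-decreasing in the value.  Requires
    n >= 10 and finite values.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if arr.size < 10:
        raise ValueError(f"deciles undefined for n={arr.size} < 10")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise ValueError(f"non-finite value(s) at row(s) {bad.tolist()}")
    r = rankdata(arr, method="average")
    return np.ceil(10.0 * r / arr.size).astype(int)


def decile_to_score(decile: int) -> int:
    """Fixed decile-to-score map: 1→−4 … 4→−1, 5–6→0, 7→1 … 10→4."""
    if isinstance(decile, float) and not decile.is_integer():
        raise ValueError(f"decile must be an integer in 1..10, got {decile!r}")
    try:
        return DECILE_SCORE_MAP[int(decile)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"decile must be an integer in 1..10, got {decile!r}")


def quartile_groups(
    scores: Sequence[float],
) -> tuple[np.ndarray, list[float]]:
    """Cohort quartile group (1–4) of each score, plus realized cut points.

    Groups follow the mid-rank rule quartile_i = ceil(4 * r_i / n), which
    partitions at the empirical 25/50/75 percentiles while keeping tied
    scores together.  The returned cut points are the largest score in
    groups 1–3 (the realized upper bounds used in table headers such as
    "Q1 (<= -5)").  A degenerate input (all scores equal) collapses to a
    single group and emits a warning.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 4:
        raise ValueError(f"quartiles undefined for n={arr.size} < 4")
    if np.all(arr == arr[0]):
        warnings.warn(
            "degenerate score distribution (all equal): single quartile group",
            UserWarning,
            stacklevel=2,
        )
        return np.ones(arr.size, dtype=int), []
    r = rankdata(arr, method="average")
    groups = np.ceil(4.0 * r / arr.size).astype(int)
    cuts = [float(arr[groups == g].max()) for g in (1, 2, 3) if np.any(groups == g)]
    return groups, cuts


class LGIScorer(TransformerMixin, BaseEstimator):
    """Cohort-relative LGI score transformer.

    Parameters
    ----------
    add_quartiles : bool, default True
        Also assign cohort quartile groups of the LGI score during
        ``transform``.

    Attributes
    ----------
    reference_ : dict of str -> ndarray
        Sorted per-marker reference distributions (CRP, WBC, PLT, NLR)
        from the fitted cohort.
    n_reference_ : int
        Number of scoreable records in the fitted cohort.
    excluded_ids_ : list of str
        Ids of fitted records excluded because the NLR was undefined
        (lymphocyte count <= 0).
    quartile_cuts_ : list of float
        Realized upper bounds of LGI-score quartiles 1–3 in the fitted
        cohort (set by ``transform`` when ``add_quartiles``).
    """

    def __init__(self, add_quartiles: bool = True):
        self.add_quartiles = add_quartiles

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _marker_frame(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
        required = {"crp", "wbc", "plt", "neut", "lymph"}
        missing = sorted(required - set(X.columns))
        if missing:
            raise ValueError(f"input is missing marker column(s): {missing}")
        ok = X["lymph"] > 0
        out = pd.DataFrame(index=X.index)
        out["crp"] = X["crp"].astype(float)
        out["wbc"] = X["wbc"].astype(float)
        out["plt"] = X["plt"].astype(float)
        out.loc[ok, "nlr"] = X.loc[ok, "neut"].astype(float) / X.loc[
            ok, "lymph"
        ].astype(float)
        return out, X.index[~ok]

    def fit(self, X: pd.DataFrame, y=None) -> "LGIScorer":
        markers, excluded = self._marker_frame(X)
        usable = markers.drop(index=excluded)
        if len(usable) < 10:
            raise ValueError(
                f"need >= 10 scoreable records to define deciles, got {len(usable)}"
            )
        self.reference_ = {
            m: np.sort(usable[m].to_numpy()) for m in LGI_MARKERS
        }
        self.n_reference_ = len(usable)
        self.excluded_ids_ = (
            X.loc[excluded, "id"].astype(str).tolist()
            if "id" in X.columns
            else [str(i) for i in excluded]
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Append nlr, per-marker deciles, lgi_score (and quartile) columns.

        Rows whose NLR is undefined get NaN scores and are excluded from
        quartile grouping.
        """
        check_is_fitted(self, "reference_")
        markers, excluded = self._marker_frame(X)
        out = X.copy()
        out["nlr"] = markers["nlr"]
        total = np.zeros(len(out))
        for m in LGI_MARKERS:
            ref = self.reference_[m]
            vals = markers[m].to_numpy()
            finite = np.isfinite(vals)
            r = _midranks_against(ref, np.where(finite, vals, ref[0]))
            dec = np.clip(np.ceil(10.0 * r / self.n_reference_), 1, 10)
            dec = np.where(finite, dec, np.nan)
            score = np.array(
                [DECILE_SCORE_MAP[int(d)] if np.isfinite(d) else np.nan for d in dec]
            )
            out[f"decile_{m}"] = dec
            total = total + score
        out["lgi_score"] = total
        if self.add_quartiles:
            ok = out["lgi_score"].notna()
            labels = np.full(len(out), np.nan)
            groups, cuts = quartile_groups(out.loc[ok, "lgi_score"].to_numpy())
            labels[np.flatnonzero(ok.to_numpy())] = groups
            out["lgi_quartile"] = labels
            self.quartile_cuts_ = cuts
        return out


def compute_lgi_scores(cohort: Sequence[PatientRecord]) -> list[LgiResult]:
    """Score a cohort of records, preserving order.

    Deciles are computed cohort-internally per marker.  Records whose NLR
    is undefined are excluded from the reference distributions and carry no
    result; their ids are reported in the raised warning.
    """
    df = records_to_frame(cohort)
    scorer = LGIScorer(add_quartiles=True)
    scored = scorer.fit(df).transform(df)
    if scorer.excluded_ids_:
        warnings.warn(
            f"records excluded from LGI scoring (NLR undefined): "
            f"{scorer.excluded_ids_}",
            UserWarning,
            stacklevel=2,
        )
    results: list[LgiResult] = []
    for _, row in scored.iterrows():
        if not np.isfinite(row["lgi_score"]):
            continue
        deciles = {m: int(row[f"decile_{m}"]) for m in LGI_MARKERS}
        marker_scores = {m: DECILE_SCORE_MAP[d] for m, d in deciles.items()}
        results.append(
            LgiResult(
                id=str(row["id"]),
                nlr=float(row["nlr"]),
                deciles=deciles,
                marker_scores=marker_scores,
                lgi_score=int(row["lgi_score"]),
                quartile=int(row["lgi_quartile"])
                if np.isfinite(row.get("lgi_quartile", np.nan))
                else None,
            )
        )
    return results
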