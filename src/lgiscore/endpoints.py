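"""Clinical endpoints and threshold-defined risk factors.

Severity: NIHSS > 5 denotes moderate/severe stroke (assessed at baseline
and at day 7).  Early neurological deterioration (END): a rise of >= 2
NIHSS points within 7 days of admission.  90-day functional outcome:
excellent (mRS 0-1) versus poor (mRS 2-6).

Risk-factor thresholds: hypertension = SBP >= 140 mmHg or DBP >= 90 mmHg
or antihypertensive use; diabetes = fasting glucose > 7.0 mmol/L or
antidiabetic use (a single measurement stands in for the repeat-measure
clinical definition, since the schema carries one value per record);
dyslipidemia = total cholesterol > 5.18 mmol/L or triglycerides
> 1.7 mmol/L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "EndpointSet",
    "classify_severity",
    "detect_end",
    "classify_outcome",
    "derive_risk_factors",
    "add_endpoint_columns",
]


@dataclass
class EndpointSet:
    severe_baseline: bool
    severe_day7: bool
    end_flag: bool | None
    poor_90d: bool
    excellent_90d: bool


def classify_severity(nihss: int) -> bool:
    """True iff the NIHSS total exceeds 5 (moderate/severe stroke)."""
    if nihss is None or nihss < 0:
        raise ValueError(f"NIHSS must be a non-negative integer, got {nihss!r}")
    return nihss > 5


def detect_end(nihss_baseline: float | None, nihss_day7: float | None) -> bool | None:
    """Early neurological deterioration: day-7 NIHSS rose by >= 2 points.

    Returns None (flagged missing) when either value is absent; such rows
    are excluded from END analyses.
    """
    if nihss_baseline is None or nihss_day7 is None:
        return None
    if isinstance(nihss_baseline, float) and math.isnan(nihss_baseline):
        return None
    if isinstance(nihss_day7, float) and math.isnan(nihss_day7):
        return None
    if nihss_baseline < 0 or nihss_day7 < 0:
        raise ValueError(
            f"NIHSS values must be >= 0, got ({nihss_baseline!r}, {nihss_day7!r})"
        )
    return nihss_day7 - nihss_baseline >= 2


def classify_outcome(mrs_90d: int) -> str:
    """'excellent' for mRS 0-1, 'poor' for mRS 2-6."""
    if not 0 <= mrs_90d <= 6:
        raise ValueError(f"mRS must be in 0..6, got {mrs_90d!r}")
    return "excellent" if mrs_90d <= 1 else "poor"


def derive_risk_factors(record) -> dict[str, bool | None]:
    """Threshold-derived hypertension/diabetes/dyslipidemia flags.

    Thresholds apply when the underlying measurements are present; when a
    raw field is absent the recorded flag (if any) takes precedence, and
    with neither the derived flag is None.  Accepts a PatientRecord or any
    object/mapping with the raw fields.
    """

    def get(name):
        if isinstance(record, dict):
            v = record.get(name)
        else:
            v = getattr(record, name, None)
        if v is None:
            return None
        if isinstance(v, float) and math.isnan(v):
            return None
        return v

    sbp, dbp = get("sbp"), get("dbp")
    if sbp is None and dbp is None:
        hyp = get("hypertension")
    else:
        hyp = (
            (sbp is not None and sbp >= 140)
            or (dbp is not None and dbp >= 90)
            or bool(get("antihypertensives"))
        )
    fbg = get("fbg")
    if fbg is None:
        dm = get("diabetes")
    else:
        dm = fbg > 7.0 or bool(get("antidiabetics"))
    tc, tg = get("tc"), get("tg")
    if tc is None and tg is None:
        dys = get("dyslipidemia")
    else:
        dys = (tc is not None and tc > 5.18) or (tg is not None and tg > 1.7)
    return {
        "hypertension": None if hyp is None else bool(hyp),
        "diabetes": None if dm is None else bool(dm),
        "dyslipidemia": None if dys is None else bool(dys),
    }


def add_endpoint_columns(df: pd.DataFrame, derived_factors: bool = False) -> pd.DataFrame:
    """Append severe_baseline, severe_day7, end_flag, poor_90d to a scored frame.

    With ``derived_factors=True`` also appends threshold-derived
    hypertension/diabetes/dyslipidemia as ``derived_*`` columns.
    """
    out = df.copy()
    if (out["nihss_baseline"] < 0).any() or (out["nihss_day7"] < 0).any():
        raise ValueError("NIHSS columns must be non-negative")
    if not out["mrs_90d"].between(0, 6).all():
        bad = out.index[~out["mrs_90d"].between(0, 6)].tolist()
        raise ValueError(f"mrs_90d outside 0..6 at row(s) {bad}")
    out["severe_baseline"] = (out["nihss_baseline"] > 5).astype(int)
    out["severe_day7"] = (out["nihss_day7"] > 5).astype(int)
    delta = out["nihss_day7"] - out["nihss_baseline"]
    out["end_flag"] = (delta >= 2).astype("float")
    out.loc[delta.isna(), "end_flag"] = float("nan")
    out["poor_90d"] = (out["mrs_90d"] >= 2).astype(int)
    if derived_factors:
        derived = [derive_risk_factors(row) for row in out.to_dict("records")]
        for key in ("hypertension", "diabetes", "dyslipidemia"):
            out[f"derived_{key}"] = [
                None if d[key] is None else int(d[key]) for d in derived
            ]
    return out
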