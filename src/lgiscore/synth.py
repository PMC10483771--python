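"""Synthetic acute-ischemic-stroke cohort generator.

The registry data behind the LGI-score analysis are not publicly deposited,
so every downstream stage of this package is exercised on synthetic cohorts
that reproduce the *statistical structure* the analysis assumes: routine
blood-panel biomarkers tied together by a single latent inflammation factor,
an NIHSS severity count whose mean rises with that factor, and logistic
links from the factor (plus age and baseline NIHSS) to early neurological
deterioration (END) and the 90-day functional outcome.  Because the latent
factor and the link coefficients are configured, true effect sizes are known
and parameter recovery is testable.

The generative model, per patient:

    f ~ N(0, 1)                                   latent inflammation
    log(marker) = log(median) + loading * f + sigma * eps
    NIHSS_0 ~ NegBin(mean = mu * exp(b_f * f), dispersion k)
    deteriorate ~ Bernoulli(expit(a_END + b_END * f))
    NIHSS_7 = NIHSS_0 + 2 + Pois(1)   if deteriorate else max(0, NIHSS_0 - Pois(1))
    poor_90d ~ Bernoulli(expit(a + b_f * f + b_age * (age - 70) + b_NIHSS * NIHSS_0))

so END (NIHSS rise >= 2 within 7 days) is exactly the deterioration draw and
its prevalence is tunable through the END link.  Lymphocytes load negatively
on the factor, which makes the neutrophil/lymphocyte ratio (NLR) rise with
inflammation, as it does physiologically.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BiomarkerPanel",
    "PatientRecord",
    "CohortConfig",
    "CohortSchemaError",
    "CohortValidationError",
    "SCHEMA_COLUMNS",
    "TOAST_SUBTYPES",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "records_to_frame",
    "frame_to_records",
    "load_config",
]

TOAST_SUBTYPES = ("LAA", "CE", "SAA", "Other")

#: Fixed CSV schema (column order is part of the on-disk contract).
SCHEMA_COLUMNS = [
    "id", "age", "male",
    "hypertension", "diabetes", "dyslipidemia", "chd", "af",
    "smoking", "drinking", "prior_stroke",
    "antihypertensives", "antidiabetics", "statins",
    "sbp", "dbp", "tc", "tg", "fbg",
    "crp", "wbc", "neut", "lymph", "plt",
    "nihss_baseline", "nihss_day7", "mrs_baseline", "mrs_90d",
    "toast_subtype",
]

_FLAG_COLUMNS = [
    "male", "hypertension", "diabetes", "dyslipidemia", "chd", "af",
    "smoking", "drinking", "prior_stroke",
    "antihypertensives", "antidiabetics", "statins",
]
_BIOMARKER_COLUMNS = ["crp", "wbc", "neut", "lymph", "plt"]
_RISK_FACTORS = [
    "hypertension", "diabetes", "dyslipidemia", "chd", "af",
    "smoking", "drinking", "prior_stroke",
]


class CohortSchemaError(ValueError):
    """A cohort CSV does not match the fixed schema."""


class CohortValidationError(ValueError):
    """A field value violates a cohort invariant."""


@dataclass
class BiomarkerPanel:
    """Admission blood panel.

    crp in mg/L; wbc, neut, lymph, plt in 10^9/L.  All values must be
    strictly positive.  ``neut <= wbc`` is *not* enforced: real panels
    occasionally violate it and such rows are flagged downstream, not
    rejected here.
    """

    crp: float
    wbc: float
    neut: float
    lymph: float
    plt: float

    def __post_init__(self) -> None:
        for name in _BIOMARKER_COLUMNS:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise CohortValidationError(
                    f"biomarker '{name}' must be finite and > 0, got {v!r}"
                )


@dataclass
class PatientRecord:
    """One subject: demographics, risk factors, blood panel, NIHSS/mRS trajectory."""

    id: str
    age: float
    male: bool
    hypertension: bool
    diabetes: bool
    dyslipidemia: bool
    chd: bool
    af: bool
    smoking: bool
    drinking: bool
    prior_stroke: bool
    antihypertensives: bool
    antidiabetics: bool
    statins: bool
    sbp: float
    dbp: float
    tc: float
    tg: float
    fbg: float
    biomarkers: BiomarkerPanel
    nihss_baseline: int
    nihss_day7: int
    mrs_baseline: int
    mrs_90d: int
    toast_subtype: str

    def __post_init__(self) -> None:
        if self.nihss_baseline < 0 or self.nihss_day7 < 0:
            raise CohortValidationError(
                f"record {self.id}: NIHSS must be >= 0, got "
                f"({self.nihss_baseline}, {self.nihss_day7})"
            )
        for name in ("mrs_baseline", "mrs_90d"):
            v = getattr(self, name)
            if not 0 <= v <= 6:
                raise CohortValidationError(
                    f"record {self.id}: {name} must be in 0..6, got {v}"
                )
        if self.toast_subtype not in TOAST_SUBTYPES:
            raise CohortValidationError(
                f"record {self.id}: toast_subtype must be one of "
                f"{TOAST_SUBTYPES}, got {self.toast_subtype!r}"
            )


def _default_risk_prevalences() -> dict[str, float]:
    # Marginal prevalences of the emulated registry cohort (n=876).
    return {
        "hypertension": 0.692,
        "diabetes": 0.242,
        "dyslipidemia": 0.439,
        "chd": 0.130,
        "af": 0.106,
        "smoking": 0.292,
        "drinking": 0.268,
        "prior_stroke": 0.110,
    }


def _default_biomarker_params() -> dict[str, dict[str, float]]:
    # Log-normal location (median, natural units) and log-scale sigma.
    # The source study prints no biomarker summaries, so these are
    # population-plausible admission values for ischemic stroke.
    return {
        "crp": {"median": 2.2, "sigma": 0.90},
        "wbc": {"median": 6.6, "sigma": 0.25},
        "neut": {"median": 4.2, "sigma": 0.32},
        "lymph": {"median": 1.7, "sigma": 0.30},
        "plt": {"median": 215.0, "sigma": 0.24},
    }


def _default_inflammation_loading() -> dict[str, float]:
    # Coefficient of the latent standard-normal inflammation factor on each
    # log-biomarker.  Lymphocytes load negatively so NLR rises with f.
    return {
        "crp": 0.55,
        "wbc": 0.16,
        "neut": 0.22,
        "lymph": -0.14,
        "plt": 0.05,
    }


def _default_outcome_model() -> dict[str, dict[str, float]]:
    # Logistic links; intercepts calibrated so the default cohort matches
    # the emulated study's outcome prevalences (poor 90-day outcome ~26%,
    # END ~10%).  Age enters centred at 70 years.
    return {
        "end": {"intercept": -2.20, "inflammation": 0.60},
        "poor_90d": {
            "intercept": -2.05,
            "inflammation": 0.55,
            "age": 0.035,
            "nihss": 0.28,
        },
    }


def _default_nihss_dist() -> dict[str, float]:
    # Right-skewed count: negative binomial with latent-factor log-link.
    return {"mean": 2.6, "dispersion": 1.3, "inflammation": 0.45}


def _default_toast_probs() -> dict[str, float]:
    return {"LAA": 0.354, "CE": 0.137, "SAA": 0.409, "Other": 0.100}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the marginals of the study cohort (n=876, 58% male,
    median age 70 [60.5, 78], hypertension 69.2%, ...); biomarker medians
    are population-plausible because the source tables print none.
    """

    n_patients: int = 876
    seed: int = 0
    prop_male: float = 0.58
    age_median: float = 70.0
    age_iqr_low: float = 60.5
    age_iqr_high: float = 78.0
    risk_factor_prevalences: dict[str, float] = field(
        default_factory=_default_risk_prevalences
    )
    biomarker_params: dict[str, dict[str, float]] = field(
        default_factory=_default_biomarker_params
    )
    inflammation_loading: dict[str, float] = field(
        default_factory=_default_inflammation_loading
    )
    outcome_model: dict[str, dict[str, float]] = field(
        default_factory=_default_outcome_model
    )
    nihss_baseline_dist: dict[str, float] = field(default_factory=_default_nihss_dist)
    toast_probs: dict[str, float] = field(default_factory=_default_toast_probs)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 1:
            raise CohortValidationError(
                f"n_patients must be a positive integer, got {self.n_patients!r}"
            )
        if not 0.0 <= self.prop_male <= 1.0:
            raise CohortValidationError(
                f"prop_male must be in [0, 1], got {self.prop_male!r}"
            )
        if not self.age_iqr_low <= self.age_median <= self.age_iqr_high:
            raise CohortValidationError(
                "age_median must lie within [age_iqr_low, age_iqr_high], got "
                f"median={self.age_median}, IQR=({self.age_iqr_low}, {self.age_iqr_high})"
            )
        for name, p in self.risk_factor_prevalences.items():
            if name not in _RISK_FACTORS:
                raise CohortValidationError(
                    f"risk_factor_prevalences: unknown factor {name!r}"
                )
            if not 0.0 <= p <= 1.0:
                raise CohortValidationError(
                    f"risk_factor_prevalences[{name!r}] must be in [0, 1], got {p!r}"
                )
        for marker in _BIOMARKER_COLUMNS:
            if marker not in self.biomarker_params:
                raise CohortValidationError(
                    f"biomarker_params missing marker {marker!r}"
                )
            params = self.biomarker_params[marker]
            if params.get("median", 0) <= 0 or params.get("sigma", -1) < 0:
                raise CohortValidationError(
                    f"biomarker_params[{marker!r}] needs median > 0 and sigma >= 0, "
                    f"got {params!r}"
                )
            if marker not in self.inflammation_loading:
                raise CohortValidationError(
                    f"inflammation_loading missing marker {marker!r}"
                )
        for key in ("end", "poor_90d"):
            if key not in self.outcome_model:
                raise CohortValidationError(f"outcome_model missing block {key!r}")
        nd = self.nihss_baseline_dist
        if nd.get("mean", 0) <= 0 or nd.get("dispersion", 0) <= 0:
            raise CohortValidationError(
                f"nihss_baseline_dist needs mean > 0 and dispersion > 0, got {nd!r}"
            )
        total = sum(self.toast_probs.get(s, 0.0) for s in TOAST_SUBTYPES)
        if abs(total - 1.0) > 1e-6:
            raise CohortValidationError(
                f"toast_probs must sum to 1 over {TOAST_SUBTYPES}, got {total}"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise CohortValidationError(
                f"unknown config field(s): {sorted(unknown)}"
            )
        base = cls()
        kwargs: dict = {}
        for key, value in d.items():
            default = getattr(base, key)
            if isinstance(default, dict) and isinstance(value, Mapping):
                merged = {
                    k: ({**default[k], **v} if isinstance(v, Mapping)
                        and isinstance(default.get(k), dict) else v)
                    for k, v in {**default, **dict(value)}.items()
                }
                kwargs[key] = merged
            else:
                kwargs[key] = value
        return cls(**kwargs)


def load_config(path: str | Path) -> CohortConfig:
    """Read a YAML/JSON key-value config file mirroring :class:`CohortConfig`."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise CohortSchemaError(f"config file {path} must contain a mapping")
    return CohortConfig.from_dict(data)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(config: CohortConfig | None = None) -> list[PatientRecord]:
    """Draw a synthetic cohort.

    All randomness flows from ``np.random.default_rng(config.seed)``; the
    same config therefore reproduces the identical cohort.
    """
    cfg = config if config is not None else CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    f = rng.standard_normal(n)  # latent inflammation factor

    # demographics: normal age matched to median/IQR, truncated to adults
    age_sd = (cfg.age_iqr_high - cfg.age_iqr_low) / 1.349
    age = np.clip(np.round(rng.normal(cfg.age_median, age_sd, n), 1), 18.0, 100.0)
    male = rng.random(n) < cfg.prop_male

    flags = {
        name: rng.random(n) < cfg.risk_factor_prevalences.get(name, 0.0)
        for name in _RISK_FACTORS
    }
    meds = {
        "antihypertensives": rng.random(n)
        < np.where(flags["hypertension"], 0.70, 0.05),
        "antidiabetics": rng.random(n) < np.where(flags["diabetes"], 0.70, 0.02),
        "statins": rng.random(n) < np.where(flags["dyslipidemia"], 0.40, 0.10),
    }

    # blood pressure: shifted upward for hypertensives and with inflammation
    sbp = np.round(rng.normal(148, 14, n) + 4.0 * f + 8.0 * flags["hypertension"], 0)
    dbp = np.round(rng.normal(84, 9, n) + 2.0 * f + 4.0 * flags["hypertension"], 0)
    sbp = np.clip(sbp, 80, 260)
    dbp = np.clip(dbp, 40, 160)

    tc = np.round(np.clip(rng.normal(4.7, 1.0, n), 1.5, None), 2)
    tg = np.round(np.exp(rng.normal(np.log(1.4), 0.5, n)), 2)
    fbg = np.round(
        np.exp(rng.normal(np.log(5.3), 0.22, n)) + 2.0 * flags["diabetes"], 2
    )

    markers = {}
    for name in _BIOMARKER_COLUMNS:
        params = cfg.biomarker_params[name]
        loading = cfg.inflammation_loading[name]
        log_v = (
            np.log(params["median"])
            + loading * f
            + params["sigma"] * rng.standard_normal(n)
        )
        markers[name] = np.round(np.exp(log_v), 2)

    # NIHSS baseline: negative binomial with latent-factor log-link
    nd = cfg.nihss_baseline_dist
    mu = nd["mean"] * np.exp(nd.get("inflammation", 0.0) * f)
    k = nd["dispersion"]
    nihss0 = rng.negative_binomial(k, k / (k + mu))

    # day-7 NIHSS: deterioration (>= +2) with probability rising in f
    om_end = cfg.outcome_model["end"]
    p_up = _sigmoid(om_end["intercept"] + om_end["inflammation"] * f)
    deteriorate = rng.random(n) < p_up
    worsen = 2 + rng.poisson(1.0, n)
    improve = rng.poisson(1.0, n)
    nihss7 = np.where(deteriorate, nihss0 + worsen, np.maximum(0, nihss0 - improve))

    mrs0 = np.clip(rng.poisson(1.2 + 0.18 * np.minimum(nihss0, 15)), 0, 5)

    om_poor = cfg.outcome_model["poor_90d"]
    lin = (
        om_poor["intercept"]
        + om_poor["inflammation"] * f
        + om_poor.get("age", 0.0) * (age - 70.0)
        + om_poor.get("nihss", 0.0) * nihss0
    )
    poor = rng.random(n) < _sigmoid(lin)
    mrs90 = np.where(
        poor,
        np.minimum(6, 2 + rng.poisson(1.0, n)),
        rng.integers(0, 2, n),
    )

    subtype_idx = rng.choice(
        len(TOAST_SUBTYPES),
        size=n,
        p=[cfg.toast_probs[s] for s in TOAST_SUBTYPES],
    )

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                id=f"P{i + 1:0{width}d}",
                age=float(age[i]),
                male=bool(male[i]),
                hypertension=bool(flags["hypertension"][i]),
                diabetes=bool(flags["diabetes"][i]),
                dyslipidemia=bool(flags["dyslipidemia"][i]),
                chd=bool(flags["chd"][i]),
                af=bool(flags["af"][i]),
                smoking=bool(flags["smoking"][i]),
                drinking=bool(flags["drinking"][i]),
                prior_stroke=bool(flags["prior_stroke"][i]),
                antihypertensives=bool(meds["antihypertensives"][i]),
                antidiabetics=bool(meds["antidiabetics"][i]),
                statins=bool(meds["statins"][i]),
                sbp=float(sbp[i]),
                dbp=float(dbp[i]),
                tc=float(tc[i]),
                tg=float(tg[i]),
                fbg=float(fbg[i]),
                biomarkers=BiomarkerPanel(
                    crp=float(markers["crp"][i]),
                    wbc=float(markers["wbc"][i]),
                    neut=float(markers["neut"][i]),
                    lymph=float(markers["lymph"][i]),
                    plt=float(markers["plt"][i]),
                ),
                nihss_baseline=int(nihss0[i]),
                nihss_day7=int(nihss7[i]),
                mrs_baseline=int(mrs0[i]),
                mrs_90d=int(mrs90[i]),
                toast_subtype=TOAST_SUBTYPES[subtype_idx[i]],
            )
        )
    return records


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in SCHEMA_COLUMNS if c not in _BIOMARKER_COLUMNS}
        row.update({c: getattr(r.biomarkers, c) for c in _BIOMARKER_COLUMNS})
        rows.append(row)
    df = pd.DataFrame(rows, columns=SCHEMA_COLUMNS)
    for c in _FLAG_COLUMNS:
        df[c] = df[c].astype(int)
    return df


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for idx, row in df.iterrows():
        try:
            panel = BiomarkerPanel(
                **{c: float(row[c]) for c in _BIOMARKER_COLUMNS}
            )
            records.append(
                PatientRecord(
                    id=str(row["id"]),
                    age=float(row["age"]),
                    male=bool(int(row["male"])),
                    hypertension=bool(int(row["hypertension"])),
                    diabetes=bool(int(row["diabetes"])),
                    dyslipidemia=bool(int(row["dyslipidemia"])),
                    chd=bool(int(row["chd"])),
                    af=bool(int(row["af"])),
                    smoking=bool(int(row["smoking"])),
                    drinking=bool(int(row["drinking"])),
                    prior_stroke=bool(int(row["prior_stroke"])),
                    antihypertensives=bool(int(row["antihypertensives"])),
                    antidiabetics=bool(int(row["antidiabetics"])),
                    statins=bool(int(row["statins"])),
                    sbp=float(row["sbp"]),
                    dbp=float(row["dbp"]),
                    tc=float(row["tc"]),
                    tg=float(row["tg"]),
                    fbg=float(row["fbg"]),
                    biomarkers=panel,
                    nihss_baseline=int(row["nihss_baseline"]),
                    nihss_day7=int(row["nihss_day7"]),
                    mrs_baseline=int(row["mrs_baseline"]),
                    mrs_90d=int(row["mrs_90d"]),
                    toast_subtype=str(row["toast_subtype"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CohortValidationError(f"row {idx}: {exc}") from exc
    return records


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort to the fixed-schema UTF-8 CSV."""
    records_to_frame(records).to_csv(path, index=False, encoding="utf-8")


def read_cohort(path: str | Path | io.TextIOBase) -> list[PatientRecord]:
    """Read a fixed-schema cohort CSV, validating columns and field invariants.

    Raises
    ------
    CohortSchemaError
        When columns are missing or unknown (all offenders listed).
    CohortValidationError
        When a row value cannot be parsed or violates an invariant; the
        message carries the 0-based row index.
    """
    df = pd.read_csv(path, dtype={"id": str, "toast_subtype": str})
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    unknown = [c for c in df.columns if c not in SCHEMA_COLUMNS]
    if missing or unknown:
        parts = []
        if missing:
            parts.append(f"missing column(s): {missing}")
        if unknown:
            parts.append(f"unknown column(s): {unknown}")
        raise CohortSchemaError("; ".join(parts))
    for c in _BIOMARKER_COLUMNS:
        numeric = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            raise CohortValidationError(
                f"non-numeric value in biomarker column '{c}' at row(s) {list(bad)}"
            )
        df[c] = numeric
    return frame_to_records(df)
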