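"""Descriptive statistics, the EPV sample-size utility, and the pipeline.

The descriptive table mirrors the conventional baseline-characteristics
layout: categorical variables are summarized as count (%) per LGI-score
quartile and compared by chi-square (Fisher's exact for 2x2 tables with
any expected cell < 5); continuous variables pass through a normality
(Lilliefors-corrected Kolmogorov–Smirnov) and Levene equal-variance gate
that selects ANOVA/t-test with mean ± SD, or Kruskal–Wallis/Mann–Whitney
with median [IQR].

``run_pipeline`` chains the full analysis — scoring, endpoint derivation,
descriptive table, quartile association models at all tiers, stratified
analysis, and the discrimination/added-value report — writing a
deterministic bundle of CSV/JSON outputs plus a log with seed and
row-exclusion accounting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from . import __version__ as _pkg_version
from .associations import (
    ModelSpec,
    fit_quartile_logistic,
    spearman_lgi_nihss,
    stratified_analysis,
)
from .discrimination import compare_models, roc_curve_points
from .endpoints import add_endpoint_columns
from .lgi import LGIScorer
from .synth import CohortConfig, generate_cohort, read_cohort, records_to_frame

__all__ = [
    "EpvResult",
    "DescriptiveRow",
    "DescriptiveTable",
    "epv_sample_size",
    "chi_square_or_fisher",
    "build_descriptive_table",
    "run_pipeline",
]


@dataclass
class EpvResult:
    """Events-per-variable sample-size requirement for logistic regression."""

    n_factors: int
    epv: int
    event_proportion: float
    required_n: float


def epv_sample_size(n_factors: int, epv: int, event_proportion: float) -> EpvResult:
    """required_n = n_factors * epv / event_proportion (not rounded).

    The EPV rule of thumb asks for ``epv`` (commonly 10–20) outcome events
    per candidate predictor; dividing by the anticipated event proportion
    converts the required event count into a total sample size.
    """
    if n_factors < 1 or epv < 1:
        raise ValueError("n_factors and epv must be >= 1")
    if not 0 < event_proportion <= 1:
        raise ValueError(
            f"event_proportion must be in (0, 1], got {event_proportion!r}"
        )
    return EpvResult(
        n_factors=n_factors,
        epv=epv,
        event_proportion=event_proportion,
        required_n=n_factors * epv / event_proportion,
    )


def chi_square_or_fisher(table: np.ndarray) -> dict:
    """Chi-square test of independence, gated to Fisher's exact for sparse 2x2.

    The gate follows the standard convention: if the contingency table is
    2x2 and any expected cell count is below 5, Fisher's exact test is
    used.  Larger sparse tables keep the chi-square with a recorded note.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    chi2, p, dof, expected = stats.chi2_contingency(tab, correction=False)
    note = ""
    test = "chi-square"
    if (expected < 5).any():
        if tab.shape == (2, 2):
            _, p = stats.fisher_exact(tab)
            test = "fisher"
            chi2 = float("nan")
        else:
            note = "expected cell < 5 but table larger than 2x2; chi-square kept"
    return {
        "test": test,
        "statistic": float(chi2),
        "p_value": float(p),
        "dof": int(dof),
        "note": note,
    }


@dataclass
class DescriptiveRow:
    variable: str
    kind: str  # "categorical" | "continuous"
    summaries: dict[str, str]
    test: str
    p_value: float
    note: str = ""


@dataclass
class DescriptiveTable:
    group_col: str
    group_sizes: dict[str, int]
    rows: list[DescriptiveRow] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {"variable": r.variable, "test": r.test, "p_value": r.p_value}
            rec.update(r.summaries)
            recs.append(rec)
        return pd.DataFrame(recs)


_DEFAULT_CATEGORICAL = [
    "male", "smoking", "drinking", "prior_stroke", "hypertension",
    "diabetes", "dyslipidemia", "chd", "af", "toast_subtype",
]
_DEFAULT_CONTINUOUS = [
    "age", "sbp", "dbp", "nihss_baseline", "mrs_baseline", "mrs_90d",
]


def _fmt_count_pct(k: int, n: int) -> str:
    pct = 100.0 * k / n if n else 0.0
    return f"{k} ({pct:.1f})"


def _continuous_gate(values_by_group: list[np.ndarray], alpha: float = 0.05):
    """Normality (Lilliefors KS) + Levene gate, per variable across groups."""
    pooled = np.concatenate(values_by_group)
    try:
        _, p_norm = lilliefors(pooled, dist="norm")
    except (ValueError, ZeroDivisionError):
        p_norm = 0.0
    try:
        _, p_lev = stats.levene(*values_by_group)
    except ValueError:
        p_lev = 0.0
    return p_norm > alpha and p_lev > alpha, p_norm, p_lev


def build_descriptive_table(
    data: pd.DataFrame,
    group_col: str = "lgi_quartile",
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
    alpha: float = 0.05,
) -> DescriptiveTable:
    """Baseline-characteristics table by group with gated tests.

    Categorical variables: per-group count (%) and chi-square (or Fisher
    for sparse 2x2).  Continuous variables: the normality/equal-variance
    gate chooses ANOVA (t-test for two groups) with mean ± SD, otherwise
    Kruskal–Wallis (Mann–Whitney for two groups) with median [IQR].
    All-missing variables are skipped with a warning.
    """
    if group_col not in data.columns:
        raise ValueError(f"grouping column {group_col!r} not in data")
    groups = data[group_col].dropna()
    levels = sorted(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("grouping column must have >= 2 levels")
    df = data.loc[groups.index]
    table = DescriptiveTable(
        group_col=group_col,
        group_sizes={str(lv): int((df[group_col] == lv).sum()) for lv in levels},
    )
    categorical = _present(categorical, _DEFAULT_CATEGORICAL, df)
    continuous = _present(continuous, _DEFAULT_CONTINUOUS, df)

    for var in categorical:
        col = df[var]
        if col.isna().all():
            warnings.warn(f"variable {var!r} all-missing; skipped", UserWarning,
                          stacklevel=2)
            continue
        ct = pd.crosstab(col, df[group_col])
        ct = ct.reindex(columns=levels, fill_value=0)
        res = chi_square_or_fisher(ct.to_numpy())
        if ct.shape[0] == 2 and set(ct.index) <= {0, 1, "0", "1"}:
            pos = ct.loc[[i for i in ct.index if str(i) == "1"][0]]
            summaries = {
                str(lv): _fmt_count_pct(int(pos[lv]), int(ct[lv].sum()))
                for lv in levels
            }
        else:
            summaries = {
                str(lv): "; ".join(
                    f"{idx}: {_fmt_count_pct(int(ct.loc[idx, lv]), int(ct[lv].sum()))}"
                    for idx in ct.index
                )
                for lv in levels
            }
        table.rows.append(
            DescriptiveRow(var, "categorical", summaries, res["test"],
                           res["p_value"], res["note"])
        )

    for var in continuous:
        col = pd.to_numeric(df[var], errors="coerce")
        if col.isna().all():
            warnings.warn(f"variable {var!r} all-missing; skipped", UserWarning,
                          stacklevel=2)
            continue
        by_group = [
            col[df[group_col] == lv].dropna().to_numpy() for lv in levels
        ]
        parametric, p_norm, p_lev = _continuous_gate(by_group, alpha)
        if parametric:
            if len(levels) == 2:
                _, p = stats.ttest_ind(*by_group)
                test = "t-test"
            else:
                _, p = stats.f_oneway(*by_group)
                test = "anova"
            summaries = {
                str(lv): f"{g.mean():.1f} ± {g.std(ddof=1):.1f}"
                for lv, g in zip(levels, by_group)
            }
        else:
            if len(levels) == 2:
                _, p = stats.mannwhitneyu(*by_group, alternative="two-sided")
                test = "mann-whitney"
            else:
                _, p = stats.kruskal(*by_group)
                test = "kruskal-wallis"
            summaries = {
                str(lv): (
                    f"{np.median(g):.1f} "
                    f"[{np.percentile(g, 25):.1f}, {np.percentile(g, 75):.1f}]"
                )
                for lv, g in zip(levels, by_group)
            }
        table.rows.append(
            DescriptiveRow(
                var, "continuous", summaries, test, float(p),
                note=f"normality p={p_norm:.3g}, levene p={p_lev:.3g}",
            )
        )
    return table


def _present(requested, default, df) -> list[str]:
    cols = default if requested is None else requested
    return [c for c in cols if c in df.columns]


class _StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True), encoding="utf-8")


def run_pipeline(
    input_path: str | Path | None = None,
    config: CohortConfig | None = None,
    out_dir: str | Path = "lgi_report",
    seed: int | None = None,
    simulate: bool = False,
) -> dict:
    """Run score → endpoints → descriptive → association → discrimination.

    Reads a fixed-schema cohort CSV, or simulates one when ``simulate`` is
    set (or no input path is given).  Writes the report bundle to
    ``out_dir``: scored.csv, table1.json, associations.jsonl,
    stratified.jsonl, discrimination.json, plus roc_curve.csv and
    run_log.json.  Deterministic given the seed.  Any stage failure is
    re-raised with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"package_version": _pkg_version, "stages": {}}

    # --- input ------------------------------------------------------------
    try:
        if simulate or input_path is None:
            cfg = config if config is not None else CohortConfig()
            if seed is not None:
                cfg = CohortConfig(**{**asdict_config(cfg), "seed": seed})
            records = generate_cohort(cfg)
            log["seed"] = cfg.seed
            log["input"] = "simulated"
        else:
            records = read_cohort(input_path)
            log["seed"] = seed
            log["input"] = str(input_path)
    except Exception as exc:
        raise _StageError("input", exc) from exc
    df = records_to_frame(records)
    n_in = len(df)

    # --- scoring ----------------------------------------------------------
    try:
        scorer = LGIScorer(add_quartiles=True)
        scored = scorer.fit(df).transform(df)
    except Exception as exc:
        raise _StageError("score", exc) from exc
    n_scored = int(scored["lgi_score"].notna().sum())
    log["stages"]["score"] = {
        "rows_in": n_in,
        "rows_analyzed": n_scored,
        "rows_excluded": n_in - n_scored,
        "excluded_ids": scorer.excluded_ids_,
        "quartile_cuts": scorer.quartile_cuts_,
    }

    # --- endpoints ----------------------------------------------------------
    try:
        scored = add_endpoint_columns(scored)
    except Exception as exc:
        raise _StageError("endpoints", exc) from exc
    scored.to_csv(out / "scored.csv", index=False)

    analyzed = scored[scored["lgi_score"].notna()]

    # --- descriptive table --------------------------------------------------
    try:
        table1 = build_descriptive_table(analyzed, "lgi_quartile")
    except Exception as exc:
        raise _StageError("descriptive", exc) from exc
    _json_dump(table1.to_dict(), out / "table1.json")

    # --- correlation + association models -----------------------------------
    try:
        rho_b, p_b = spearman_lgi_nihss(
            analyzed["lgi_score"], analyzed["nihss_baseline"]
        )
        rho_7, p_7 = spearman_lgi_nihss(
            analyzed["lgi_score"], analyzed["nihss_day7"]
        )
        reports = []
        for outcome in ("end_flag", "severe_baseline", "severe_day7", "poor_90d"):
            for tier in ("crude", "model1", "model2"):
                rep = fit_quartile_logistic(
                    analyzed, ModelSpec(outcome=outcome, tier=tier)
                )
                reports.append(rep.to_dict())
    except Exception as exc:
        raise _StageError("associations", exc) from exc
    with open(out / "associations.jsonl", "w", encoding="utf-8") as fh:
        for rep in reports:
            fh.write(json.dumps(rep, sort_keys=True) + "\n")
    log["stages"]["associations"] = {
        "rows_in": n_scored,
        "rows_analyzed": int(min(r["n_used"] for r in reports)),
        "rows_excluded": n_scored - int(min(r["n_used"] for r in reports)),
        "spearman_lgi_nihss_baseline": {"rho": rho_b, "p": p_b},
        "spearman_lgi_nihss_day7": {"rho": rho_7, "p": p_7},
    }

    # --- stratified analysis -------------------------------------------------
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            strat = stratified_analysis(analyzed, outcome="poor_90d")
    except Exception as exc:
        raise _StageError("stratified", exc) from exc
    with open(out / "stratified.jsonl", "w", encoding="utf-8") as fh:
        for name, block in strat.items():
            rec = {
                "stratifier": name,
                "p_interaction": block["p_interaction"],
                "levels": {
                    lv: (rep.to_dict() if rep is not None else None)
                    for lv, rep in block["levels"].items()
                },
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")

    # --- discrimination ------------------------------------------------------
    try:
        disc = compare_models(analyzed, outcome="poor_90d")
        roc = roc_curve_points(
            analyzed.dropna(subset=["lgi_score", "poor_90d"])["lgi_score"],
            analyzed.dropna(subset=["lgi_score", "poor_90d"])["poor_90d"],
        )
    except Exception as exc:
        raise _StageError("discrimination", exc) from exc
    _json_dump(disc.to_dict(), out / "discrimination.json")
    roc.to_csv(out / "roc_curve.csv", index=False)

    _json_dump(log, out / "run_log.json")
    return {
        "out_dir": str(out),
        "files": sorted(p.name for p in out.iterdir()),
        "log": log,
        "discrimination": disc.to_dict(),
    }


def asdict_config(cfg: CohortConfig) -> dict:
    import dataclasses

    return dataclasses.asdict(cfg)
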