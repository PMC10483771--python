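"""AUC/DeLong, continuous NRI, IDI and the add-on model comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lgiscore.discrimination import (
    AddedValueComparison,
    compare_models,
    continuous_nri,
    idi,
    roc_auc,
    roc_curve_points,
)


def brute_force_auc(scores, outcomes):
    """Exhaustive pairwise concordance with ties counted 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(outcomes, int)
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation_gives_one(self):
        r = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0

    def test_all_tied_scores_give_half(self):
        r = roc_auc([5.0] * 20, [0, 1] * 10)
        assert r.auc == 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.normal(size=100), 1)  # rounding forces ties
        y = rng.integers(0, 2, 100)
        r = roc_auc(scores, y)
        assert r.auc == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_ci_brackets_auc_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=200) + np.repeat([0, 1], 100)
        y = np.repeat([0, 1], 100)
        r = roc_auc(scores, y)
        assert 0.0 <= r.ci_low <= r.auc <= r.ci_high <= 1.0
        assert r.variance > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_roc_curve_starts_at_origin_and_ends_at_one(self):
        pts = roc_curve_points([3, 1, 2, 5], [1, 0, 0, 1])
        assert (pts.iloc[0][["fpr", "tpr"]] == 0).all()
        assert (pts.iloc[-1][["fpr", "tpr"]] == 1).all()


class TestContinuousNri:
    def test_no_risk_movement_gives_zero(self):
        p = np.linspace(0.1, 0.9, 10)
        y = np.array([0, 1] * 5)
        assert continuous_nri(p, p.copy(), y).value == 0.0

    def test_perfect_reclassification_gives_two(self):
        y = np.array([1] * 5 + [0] * 5)
        p_old = np.full(10, 0.5)
        p_new = np.where(y == 1, 0.9, 0.1)
        r = continuous_nri(p_old, p_new, y)
        assert r.value == 2.0

    def test_hand_counted_eight_subject_example(self):
        # events move up,up,down,tie,up; nonevents move down,up,down
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0])
        p_old = np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        p_new = np.array([0.6, 0.7, 0.4, 0.5, 0.8, 0.3, 0.6, 0.2])
        r = continuous_nri(p_old, p_new, y)
        assert r.value == pytest.approx((3 / 5 - 1 / 5) + (2 / 3 - 1 / 3))

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            continuous_nri([0.2, 0.3], [0.3, 0.4], [0, 0])


class TestIdi:
    def test_no_risk_movement_gives_zero(self):
        p = np.linspace(0.1, 0.9, 10)
        y = np.array([0, 1] * 5)
        assert idi(p, p.copy(), y).value == 0.0

    def test_discrimination_slope_change_is_definitional(self):
        # slope improves from 0.10 to 0.18 by construction
        y = np.array([1] * 4 + [0] * 4)
        p_old = np.where(y == 1, 0.30, 0.20)
        p_new = np.where(y == 1, 0.40, 0.22)
        assert idi(p_old, p_new, y).value == pytest.approx(0.08)

    def test_hand_computed_ten_pair_example(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 1, 0, 0])
        rng = np.random.default_rng(4)
        p_old = rng.uniform(0.1, 0.9, 10)
        p_new = rng.uniform(0.1, 0.9, 10)
        ev, ne = y == 1, y == 0
        oracle = (p_new[ev].mean() - p_new[ne].mean()) - (
            p_old[ev].mean() - p_old[ne].mean()
        )
        assert idi(p_old, p_new, y).value == pytest.approx(oracle, abs=1e-12)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_nri_and_idi_negate_under_model_swap(seed):
    rng = np.random.default_rng(seed)
    n = 40
    y = np.r_[np.ones(10, int), rng.integers(0, 2, n - 20), np.zeros(10, int)]
    p_old = rng.uniform(0.05, 0.95, n)
    p_new = rng.uniform(0.05, 0.95, n)
    assert continuous_nri(p_new, p_old, y).value == pytest.approx(
        -continuous_nri(p_old, p_new, y).value, abs=1e-12
    )
    assert idi(p_new, p_old, y).value == pytest.approx(
        -idi(p_old, p_new, y).value, abs=1e-12
    )


def test_label_permutation_null_centres_nri_and_idi():
    """Permuting outcomes should centre both statistics at zero."""
    rng = np.random.default_rng(12)
    n = 300
    y = rng.integers(0, 2, n)
    p_old = rng.uniform(0.05, 0.95, n)
    p_new = np.clip(p_old + rng.normal(0, 0.1, n), 0.01, 0.99)
    nris, idis = [], []
    for _ in range(500):
        yp = rng.permutation(y)
        nris.append(continuous_nri(p_old, p_new, yp).value)
        idis.append(idi(p_old, p_new, yp).value)
    for vals in (np.array(nris), np.array(idis)):
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 2 * se + 1e-12


class TestCompareModels:
    def test_addon_auc_not_below_conventional_in_sample(self, analysis_frame):
        rep = compare_models(analysis_frame, outcome="poor_90d")
        assert rep.auc_addon.auc >= rep.auc_conventional.auc - 1e-12
        assert rep.c_statistic_delta == pytest.approx(
            rep.auc_addon.auc - rep.auc_conventional.auc
        )
        assert -2 <= rep.continuous_nri.value <= 2
        assert -1 <= rep.idi.value <= 1
        assert rep.converged

    def test_strong_lgi_effect_detected_across_seeds(self):
        from lgiscore.endpoints import add_endpoint_columns
        from lgiscore.lgi import LGIScorer
        from lgiscore.synth import CohortConfig, generate_cohort, records_to_frame

        wins = 0
        for seed in range(5):
            cfg = CohortConfig(n_patients=600, seed=100 + seed)
            cfg.outcome_model["poor_90d"]["inflammation"] = 1.2
            df = records_to_frame(generate_cohort(cfg))
            scored = add_endpoint_columns(LGIScorer().fit(df).transform(df))
            rep = compare_models(scored, outcome="poor_90d")
            wins += rep.auc_addon.auc > rep.auc_conventional.auc
        assert wins >= 4

    def test_quartile_coding_variant_runs(self, analysis_frame):
        rep = compare_models(analysis_frame, lgi_coding="quartile")
        assert rep.auc_addon.auc >= rep.auc_conventional.auc - 1e-12

    def test_out_of_fold_risks_option(self, analysis_frame):
        est = AddedValueComparison(cv=5, random_state=0).fit(analysis_frame)
        rep = est.report_
        assert 0.5 < rep.auc_conventional.auc < 1.0
        # honest estimates may order either way; only structural checks here
        assert rep.continuous_nri.se > 0

    def test_estimator_round_trips_params(self):
        from sklearn.base import clone

        est = AddedValueComparison(outcome="poor_90d", lgi_coding="quartile", cv=3)
        assert clone(est).get_params() == est.get_params()
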