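"""Stratified splitting, downsampling, and IRLS logistic regression."""

import numpy as np
import pandas as pd
import pytest

from homeclass.model import (
    HomelessnessClassifier,
    downsample_majority,
    fit_logistic,
    predict_probability,
    round_half_up,
    stratified_split,
)


def two_by_two(n11, n10, n01, n00):
    """Dataset with one binary predictor: exposed n11 pos / n10 neg,
    unexposed n01 pos / n00 neg."""
    x = np.concatenate([np.ones(n11 + n10), np.zeros(n01 + n00)])
    y = np.concatenate([np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)])
    return x[:, None], y


class TestStratifiedSplit:
    def test_exact_quarters(self):
        ids = np.arange(20)
        labels = ids < 8  # 8 positives, 12 negatives
        out = stratified_split(ids, labels, 0.75, seed=3)
        dev = out[out.partition == "development"]
        assert (dev.stratum == "known_homeless").sum() == 6
        assert (dev.stratum == "not_known_homeless").sum() == 9

    def test_round_half_up_allocation(self):
        # 0.75 * 41,457 = 31,092.75 -> 31,093; 0.75 * 5,009,182 = 3,756,886.5 -> 3,756,887
        assert round_half_up(0.75 * 41_457) == 31_093
        assert round_half_up(0.75 * 5_009_182) == 3_756_887
        assert round_half_up(0.75 * 41_457) + round_half_up(0.75 * 5_009_182) == 3_787_980

    def test_deterministic_and_exhaustive(self):
        ids = np.arange(101)
        labels = np.arange(101) % 7 == 0
        a = stratified_split(ids, labels, 0.75, seed=11)
        b = stratified_split(ids, labels, 0.75, seed=11)
        pd.testing.assert_frame_equal(a, b)
        assert set(a.partition) == {"development", "validation"}
        assert sorted(a.person_id) == list(ids)

    def test_single_member_stratum_goes_to_development(self):
        out = stratified_split(np.arange(5), np.array([True, False, False, False, False]), 0.75, seed=0)
        row = out[out.stratum == "known_homeless"].iloc[0]
        assert row.partition == "development"  # round_half_up(0.75) = 1

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            stratified_split(np.arange(4), np.zeros(4, bool), 1.0, seed=0)


class TestDownsample:
    def test_one_to_one_contract(self):
        ids = np.arange(13)
        labels = ids < 3
        kept = downsample_majority(ids, labels, seed=0)
        assert len(kept) == 6
        assert set(ids[:3]) <= set(kept)

    def test_balanced_input_unchanged(self):
        ids = np.arange(10)
        labels = ids < 5
        assert sorted(downsample_majority(ids, labels, seed=1)) == list(ids)

    def test_deterministic(self):
        ids = np.arange(50)
        labels = ids < 9
        assert (downsample_majority(ids, labels, seed=4) == downsample_majority(ids, labels, seed=4)).all()

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            downsample_majority(np.arange(5), np.zeros(5, bool), seed=0)


class TestLogisticFit:
    def test_matches_closed_form_2x2(self):
        # saturated 2x2: slope = ln((20*40)/(10*5)), intercept = ln(10/40)
        x, y = two_by_two(20, 5, 10, 40)
        res = fit_logistic(x, y)
        assert res.converged
        assert res.params["x1"] == pytest.approx(np.log(20 * 40 / (10 * 5)), abs=1e-6)
        assert res.params["const"] == pytest.approx(np.log(10 / 40), abs=1e-6)

    def test_null_predictor_coefficient_is_zero(self):
        # second predictor split 50/50 inside every (x1, y) cell -> exact zero effect
        x1, y = two_by_two(20, 6, 10, 40)
        x2 = np.zeros(len(y))
        for val in (0, 1):
            for lab in (0, 1):
                idx = np.flatnonzero((x1[:, 0] == val) & (y == lab))
                x2[idx[: len(idx) // 2]] = 1.0
        res = fit_logistic(np.column_stack([x1[:, 0], x2]), y)
        assert abs(res.params["x2"]) < 1e-6

    def test_duplication_invariance(self):
        x, y = two_by_two(12, 7, 9, 22)
        res1 = fit_logistic(x, y)
        res2 = fit_logistic(np.vstack([x, x]), np.concatenate([y, y]))
        assert np.allclose(res1.params.to_numpy(), res2.params.to_numpy(), atol=1e-8)

    def test_loglikelihood_monotone_over_iterations(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(400, 3))
        y = (rng.random(400) < 1 / (1 + np.exp(-(x @ [0.5, -1.0, 2.0])))).astype(float)
        res = fit_logistic(x, y)
        hist = np.array(res.llf_history)
        assert np.all(np.diff(hist) >= -1e-9)

    def test_separation_gets_ridge_and_warning(self):
        x = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])  # perfectly separated
        with pytest.warns(UserWarning, match="separation"):
            res = fit_logistic(x, y)
        assert res.ridge > 0
        assert np.all(np.isfinite(res.params))

    def test_constant_predictor_dropped_with_warning(self):
        rng = np.random.default_rng(0)
        x = np.column_stack([rng.integers(0, 2, 80), np.ones(80)])
        y = rng.integers(0, 2, 80).astype(float)
        with pytest.warns(UserWarning, match="constant"):
            res = fit_logistic(x, y, feature_names=["a", "b"])
        assert res.dropped == ["b"]
        assert "b" not in res.params.index

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(21)
        x = rng.integers(0, 2, size=(500, 4)).astype(float)
        y = (rng.random(500) < 1 / (1 + np.exp(-(x @ [1.0, -0.5, 0.3, 0.0] - 0.7)))).astype(float)
        ours = fit_logistic(x, y)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert np.allclose(ours.params.to_numpy(), ref.params, atol=1e-6)
        assert np.allclose(ours.bse.to_numpy(), ref.bse, atol=1e-5)


class TestPrediction:
    def test_probability_matches_empirical_2x2(self):
        x, y = two_by_two(20, 5, 10, 40)
        res = fit_logistic(x, y)
        p_exposed = predict_probability(res, np.array([[1.0]]))[0]
        assert p_exposed == pytest.approx(20 / 25, abs=1e-6)
        p_unexposed = predict_probability(res, np.array([[0.0]]))[0]
        assert p_unexposed == pytest.approx(10 / 50, abs=1e-6)

    def test_extreme_linear_predictor_stays_in_unit_interval(self):
        x, y = two_by_two(20, 5, 10, 40)
        res = fit_logistic(x, y)
        res.params["x1"] = 50.0
        hi = res.predict(np.array([[1.0]]))[0]
        res.params["x1"] = -50.0
        lo = res.predict(np.array([[1.0]]))[0]
        assert 0.0 <= lo <= hi <= 1.0
        assert np.isfinite([lo, hi]).all()

    def test_unknown_feature_name_rejected(self):
        df = pd.DataFrame({"a": [0, 1, 0, 1] * 10, "label": [0, 0, 1, 1] * 10})
        res = HomelessnessClassifier.from_dataframe(df, "label", ["a"]).fit()
        with pytest.raises(KeyError):
            res.predict(pd.DataFrame({"zzz": [1]}))
        with pytest.raises(KeyError):
            res.predict(pd.DataFrame({}))

    def test_summary_mentions_terms(self):
        df = pd.DataFrame({"a": [0, 1, 0, 1] * 10, "label": [0, 0, 1, 1] * 10})
        res = HomelessnessClassifier.from_dataframe(df, "label", ["a"]).fit()
        text = res.summary()
        assert "const" in text and "a" in text and "log-likelihood" in text
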