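"""Metric oracles and estimator behaviour: R², RMSE, labelling rule,
AUROC/AUPRC, OR per SD, likelihood-ratio tests and the bootstrap."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from heightprs.errors import ConfigurationError
from heightprs.metrics import (
    ShortStatureRule,
    adjusted_r2,
    auprc,
    auroc,
    bootstrap_ci,
    build_report,
    label_short_stature,
    lrt_nested,
    or_per_sd,
    read_report,
    rmse,
    write_report,
)


class TestAdjustedR2:
    def test_perfect_fit(self):
        y = np.array([1.0, 2, 3, 4, 5])
        assert adjusted_r2(y, y, 1) == pytest.approx(1.0)

    def test_hand_formula(self):
        # R^2 = 0.5, n = 100, p = 2 -> 1 - 0.5*99/97
        rng = np.random.default_rng(0)
        y = rng.normal(size=100)
        ss_tot = np.sum((y - y.mean()) ** 2)
        resid = y - y.mean()
        yhat = y - resid * np.sqrt(0.5 * ss_tot / np.sum(resid**2))
        assert adjusted_r2(y, yhat, 2) == pytest.approx(0.4897, abs=1e-4)

    def test_noise_predictor_penalized_on_null_data(self):
        rng = np.random.default_rng(1)
        deltas = []
        for _ in range(200):
            y = rng.normal(size=60)
            X1 = np.column_stack([np.ones(60)])
            X2 = np.column_stack([np.ones(60), rng.normal(size=60)])
            fit = lambda X: X @ np.linalg.lstsq(X, y, rcond=None)[0]
            deltas.append(
                adjusted_r2(y, fit(X2), 1) - adjusted_r2(y, fit(X1), 0)
            )
        assert np.mean(deltas) < 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigurationError):
            adjusted_r2([1.0, 2.0], [1.0, 2.0], 1)


class TestRmse:
    def test_zero_for_perfect_prediction(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert rmse([3.0, -4.0], [0.0, 0.0]) == pytest.approx(3.5355, abs=1e-4)

    def test_constant_bias_lower_bound(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=500)
        assert rmse(y, y + 2.5) >= 2.5 - 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            rmse([], [])


class TestShortStatureRule:
    def test_hand_threshold_labels_nothing(self):
        h = np.array([150.0, 160, 170, 180, 190])
        labels = label_short_stature(h, np.array(["F"] * 5))
        assert labels.sum() == 0  # threshold 170 - 2*15.81 = 138.4

    def test_location_invariance(self):
        rng = np.random.default_rng(3)
        h = rng.normal(170, 7, size=2000)
        sex = np.array(["F", "M"] * 1000)
        assert np.array_equal(
            label_short_stature(h, sex), label_short_stature(h + 10, sex)
        )

    def test_sd_and_quantile_modes_agree_on_gaussian(self):
        rng = np.random.default_rng(4)
        h = rng.normal(170, 7, size=200_000)
        sex = np.where(rng.random(200_000) < 0.5, "F", "M")
        sd_labels = label_short_stature(h, sex, ShortStatureRule(mode="sd"))
        q_labels = label_short_stature(h, sex, ShortStatureRule(mode="quantile"))
        assert (sd_labels == q_labels).mean() > 0.99

    def test_degenerate_heights_rejected(self):
        with pytest.raises(ConfigurationError):
            label_short_stature([170.0, 170.0], ["F", "F"])


def _pairwise_auroc(scores, labels):
    """Exhaustive Mann-Whitney probability over all case/non-case pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p, n in itertools.product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_hand_example(self):
        assert auroc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ConfigurationError):
            auroc([0.1, 0.2], [1, 1])

    @settings(max_examples=300, deadline=None)
    @given(
        st.lists(
            st.tuples(st.integers(0, 4), st.booleans()), min_size=2, max_size=12
        ).filter(lambda xs: 0 < sum(l for _, l in xs) < len(xs))
    )
    def test_matches_exhaustive_pairwise_oracle(self, pairs):
        scores = [s for s, _ in pairs]
        labels = [l for _, l in pairs]
        assert auroc(scores, labels) == pytest.approx(_pairwise_auroc(scores, labels))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.2
        labels[0], labels[1] = True, False
        base = auroc(scores, labels)
        assert auroc(np.exp(scores), labels) == pytest.approx(base)
        assert auroc(3 * scores - 7, labels) == pytest.approx(base)


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_hand_example(self):
        assert auprc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(
            0.8333, abs=1e-4
        )

    def test_random_scores_baseline_is_prevalence(self):
        rng = np.random.default_rng(6)
        prevalence = 0.15
        vals = []
        for _ in range(300):
            labels = rng.random(200) < prevalence
            if not labels.any():
                continue
            vals.append(auprc(rng.normal(size=200), labels))
        assert abs(np.mean(vals) - prevalence) < 0.02

    def test_matches_sklearn_without_ties(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        scores = rng.normal(size=300)  # continuous: ties a.s. absent
        labels = rng.random(300) < 0.1
        labels[:2] = [True, False]
        assert auprc(scores, labels) == pytest.approx(
            sk.average_precision_score(labels, scores)
        )

    def test_no_positives_rejected(self):
        with pytest.raises(ConfigurationError):
            auprc([0.1, 0.2], [0, 0])


class TestOrPerSd:
    def test_null_predictor_or_near_one(self):
        rng = np.random.default_rng(8)
        z = rng.normal(size=5000)
        labels = rng.random(5000) < 0.1
        labels[:2] = [True, False]
        orr, lo, hi = or_per_sd(z, labels)
        assert lo < 1.0 < hi
        assert abs(np.log(orr)) < 0.2

    def test_negation_inverts_exactly(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=2000)
        labels = rng.random(2000) < 1 / (1 + np.exp(1.5 + 0.5 * z))
        labels[:2] = [True, False]
        orr, lo, hi = or_per_sd(z, labels)
        inv, ilo, ihi = or_per_sd(-z, labels)
        assert inv == pytest.approx(1.0 / orr)
        assert ilo == pytest.approx(1.0 / hi) and ihi == pytest.approx(1.0 / lo)

    def test_complete_separation_advises_penalty(self):
        z = np.linspace(-2, 2, 100)
        labels = z < -1.0
        with pytest.raises(ConfigurationError, match="firth"):
            or_per_sd(z, labels)
        orr, lo, hi = or_per_sd(z, labels, firth=True)
        assert orr > 1.0


class TestLrtNested:
    def _data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 2.0 + 0.5 * x + rng.normal(size=n)
        return x, y, rng

    def test_duplicate_column_adds_nothing(self):
        x, y, _ = self._data()
        Xs = np.column_stack([np.ones(len(x)), x])
        Xl = np.column_stack([Xs, x])  # same column twice
        statistic, df, p = lrt_nested(Xs, Xl, y)
        assert statistic == pytest.approx(0.0, abs=1e-8)
        assert df == 0 and p == 1.0

    def test_planted_signal_detected(self):
        rng = np.random.default_rng(10)
        n = 5000
        x = rng.normal(size=n)
        signal = rng.normal(size=n)
        y = x + 2.0 * signal + rng.normal(size=n)
        Xs = np.column_stack([np.ones(n), x])
        Xl = np.column_stack([Xs, signal])
        _, df, p = lrt_nested(Xs, Xl, y)
        assert df == 1 and p < 1e-10

    def test_non_nested_rejected(self):
        x, y, rng = self._data()
        Xs = np.column_stack([np.ones(len(x)), x])
        Xl = np.column_stack([np.ones(len(x)), rng.normal(size=len(x))])
        with pytest.raises(ConfigurationError):
            lrt_nested(Xs, Xl, y)


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        point, lo, hi = bootstrap_ci(lambda x: 1.23, (np.arange(50),), B=50, seed=0)
        assert point == lo == hi == 1.23

    def test_same_seed_identical_endpoints(self):
        rng = np.random.default_rng(11)
        data = (rng.normal(size=100),)
        a = bootstrap_ci(np.mean, data, B=200, seed=7)
        b = bootstrap_ci(np.mean, data, B=200, seed=7)
        assert a == b

    def test_interval_brackets_point_for_smooth_metric(self):
        rng = np.random.default_rng(12)
        data = (rng.normal(size=300),)
        point, lo, hi = bootstrap_ci(np.mean, data, B=500, seed=1)
        assert lo <= point <= hi


class TestBuildReport:
    @pytest.fixture()
    def cohort_and_predictions(self, small_cohort):
        cohort, _ = small_cohort
        fam = cohort.families
        rng = np.random.default_rng(13)
        oracle = fam["true_genetic_value_cm"] + fam.groupby("sex")[
            "adult_height_cm"
        ].transform("mean")
        noise = fam["adult_height_cm"].mean() + rng.normal(0, 5, len(fam))
        predictions = pd.concat(
            [
                pd.DataFrame(
                    {"child_id": fam["child_id"], "predictor": "oracle",
                     "predicted_height_cm": oracle}
                ),
                pd.DataFrame(
                    {"child_id": fam["child_id"], "predictor": "oracle_copy",
                     "predicted_height_cm": oracle}
                ),
                pd.DataFrame(
                    {"child_id": fam["child_id"], "predictor": "noise",
                     "predicted_height_cm": noise}
                ),
            ],
            ignore_index=True,
        )
        return cohort, predictions

    def test_identical_predictors_identical_rows(self, cohort_and_predictions):
        cohort, predictions = cohort_and_predictions
        report = build_report(predictions, cohort, B=60, seed=3)
        tab = report["metrics"].set_index(["predictor", "stratum"])
        a = tab.loc["oracle"].reset_index(drop=True)
        b = tab.loc["oracle_copy"].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_oracle_dominates_noise(self, cohort_and_predictions):
        cohort, predictions = cohort_and_predictions
        report = build_report(predictions, cohort, B=60, seed=3)
        tab = report["metrics"].set_index(["predictor", "stratum"])
        o = tab.loc[("oracle", "all")]
        z = tab.loc[("noise", "all")]
        assert o["adj_r2"] > z["adj_r2"]
        assert o["rmse"] < z["rmse"]
        assert o["auroc"] > z["auroc"]
        assert o["auprc"] > z["auprc"]

    def test_report_round_trips(self, cohort_and_predictions, tmp_path):
        cohort, predictions = cohort_and_predictions
        report = build_report(predictions, cohort, B=30, seed=4)
        _, js = write_report(report, str(tmp_path / "eval"))
        back = read_report(js)
        pd.testing.assert_frame_equal(
            back["metrics"], report["metrics"], check_dtype=False
        )

    def test_deterministic_given_seed(self, cohort_and_predictions):
        cohort, predictions = cohort_and_predictions
        r1 = build_report(predictions, cohort, B=40, seed=9)
        r2 = build_report(predictions, cohort, B=40, seed=9)
        pd.testing.assert_frame_equal(r1["metrics"], r2["metrics"])
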