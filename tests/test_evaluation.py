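"""Counting metrics, calibration, binned diagnostics, beta-coverage fits."""

import math

import numpy as np
import pytest

from sndm.evaluation import (CountRecord, bin_by_feature, beta_coverage_fit,
                             evaluate, mae, records_to_frame, smape,
                             within_sigma_fraction, _stratum_metrics)


def _rec(n, n_hat, sigma=0.0, beta=1.0, coverage=0.0, size=5.0, i=0):
    return CountRecord(image_id=f"r{i}", n=n, n_hat=n_hat, sigma=sigma,
                       beta=beta, coverage=coverage, mean_colony_size=size)


class TestMae:
    def test_perfect_prediction(self):
        assert mae([_rec(5, 5.0), _rec(0, 0.0)]) == 0.0

    def test_two_dish_example(self):
        assert mae([_rec(16, 17.0), _rec(72, 63.0)]) == pytest.approx(5.0)

    def test_single_outlier_dish(self):
        assert mae([_rec(77, 29.0)]) == pytest.approx(48.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mae([])


class TestSmape:
    def test_zero_for_exact_predictions(self):
        assert smape([_rec(4, 4.0), _rec(30, 30.0)]) == 0.0

    def test_two_dish_example(self):
        expected = 100 * (1 / 33 + 9 / 135) / 2
        assert smape([_rec(16, 17.0), _rec(72, 63.0)]) == \
            pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(4.848, abs=1e-3)

    def test_single_outlier_dish(self):
        assert smape([_rec(77, 29.0)]) == pytest.approx(100 * 48 / 106, abs=1e-9)

    def test_empty_dish_zero_over_zero_convention(self):
        assert smape([_rec(0, 0.0)]) == 0.0

    def test_bounded_between_zero_and_hundred(self, rng):
        recs = [_rec(int(n), float(p), i=i) for i, (n, p) in
                enumerate(zip(rng.integers(0, 100, 50), rng.uniform(0, 100, 50)))]
        assert 0.0 <= smape(recs) <= 100.0


class TestWithinSigma:
    def test_all_none_half(self):
        covered = [_rec(10, 10.5, sigma=1.0), _rec(5, 5.2, sigma=0.5)]
        missed = [_rec(10, 15.0, sigma=1.0), _rec(5, 9.0, sigma=0.5)]
        assert within_sigma_fraction(covered, 1.0) == 1.0
        assert within_sigma_fraction(missed, 1.0) == 0.0
        assert within_sigma_fraction(covered + missed, 1.0) == 0.5

    def test_zero_sigma_requires_exact_match(self):
        assert within_sigma_fraction([_rec(3, 3.0, sigma=0.0)]) == 1.0
        assert within_sigma_fraction([_rec(3, 3.1, sigma=0.0)]) == 0.0


class TestBinByFeature:
    def test_single_bin_recovers_global_mean(self):
        recs = [_rec(5, 5, sigma=s, size=3.0, i=i) for i, s in enumerate((1, 2, 3))]
        table = bin_by_feature(recs, "mean_colony_size", [0, 10])
        assert table.loc[0, "mean_sigma"] == pytest.approx(2.0)

    def test_hand_placed_records_per_bin(self):
        recs = [_rec(5, 5, sigma=1.0, size=2.0), _rec(5, 5, sigma=3.0, size=8.0)]
        table = bin_by_feature(recs, "mean_colony_size", [0, 5, 10])
        assert table["mean_sigma"].tolist() == [1.0, 3.0]

    def test_empty_bins_flagged_not_dropped(self):
        recs = [_rec(5, 5, sigma=1.0, size=2.0)]
        table = bin_by_feature(recs, "mean_colony_size", [0, 5, 10])
        assert len(table) == 2
        assert bool(table.loc[1, "empty"])
        assert math.isnan(table.loc[1, "mean_sigma"])

    def test_sigma_per_colony_only_for_positive_counts(self):
        recs = [_rec(0, 0, sigma=1.0, coverage=0.1),
                _rec(10, 9, sigma=2.0, coverage=0.1)]
        table = bin_by_feature(recs, "coverage", [0, 1])
        assert table.loc[0, "mean_sigma_per_colony"] == pytest.approx(0.2)

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_by_feature([_rec(1, 1)], "n", [0, 5, 5])


class TestBetaCoverageFit:
    def test_exact_linear_relation_recovered(self):
        recs = [_rec(5, 5, beta=1 + 2 * c, coverage=c, size=4.0, i=i)
                for i, c in enumerate(np.linspace(0.05, 0.4, 8))]
        table = beta_coverage_fit(recs, [0, 10])
        assert table.loc[0, "fit"]
        assert table.loc[0, "slope"] == pytest.approx(2.0)
        assert table.loc[0, "intercept"] == pytest.approx(1.0)

    def test_constant_beta_zero_slope(self):
        recs = [_rec(5, 5, beta=1.1, coverage=c, size=4.0, i=i)
                for i, c in enumerate((0.1, 0.2, 0.3))]
        table = beta_coverage_fit(recs, [0, 10])
        assert table.loc[0, "slope"] == pytest.approx(0.0, abs=1e-12)

    def test_single_record_group_flagged_unfit(self):
        table = beta_coverage_fit([_rec(5, 5, coverage=0.2, size=4.0)], [0, 10])
        assert not table.loc[0, "fit"]

    def test_zero_coverage_variance_flagged_not_crash(self):
        recs = [_rec(5, 5, beta=b, coverage=0.2, size=4.0, i=i)
                for i, b in enumerate((0.9, 1.1))]
        table = beta_coverage_fit(recs, [0, 10])
        assert not table.loc[0, "fit"]

    def test_noisy_linear_recovery_within_three_se(self, rng):
        cov = rng.uniform(0.05, 0.5, 60)
        beta = 1.0 + 1.5 * cov + rng.normal(0, 0.02, 60)
        recs = [_rec(5, 5, beta=b, coverage=c, size=4.0, i=i)
                for i, (b, c) in enumerate(zip(beta, cov))]
        table = beta_coverage_fit(recs, [0, 10])
        from scipy import stats
        se = stats.linregress(cov, beta).stderr
        assert abs(table.loc[0, "slope"] - 1.5) < 3 * se


class TestStratification:
    def test_overall_mae_is_weighted_stratum_mean(self, rng):
        recs = [_rec(int(n), float(n + e), i=i) for i, (n, e) in enumerate(
            zip(rng.integers(0, 100, 40), rng.normal(0, 5, 40)))]
        table = _stratum_metrics(recs, 50).set_index("stratum")
        lo, hi = table.loc["<=50"], table.loc[">50"]
        weighted = (lo["mae"] * lo["N"] + hi["mae"] * hi["N"]) / (lo["N"] + hi["N"])
        assert table.loc["overall", "mae"] == pytest.approx(weighted)

    def test_empty_stratum_flagged(self):
        recs = [_rec(5, 5.0), _rec(10, 11.0, i=1)]
        table = _stratum_metrics(recs, 50).set_index("stratum")
        assert bool(table.loc[">50", "empty"])


class TestEvaluate:
    def test_perfect_oracle_predictor(self, tiny_splits, monkeypatch):
        test_set = tiny_splits["test"]
        truth = test_set.counts.astype(float)
        monkeypatch.setattr(
            "sndm.evaluation.predict_counts",
            lambda model, ds, batch=8, return_beta=False:
                (truth.copy(), np.ones_like(truth)) if return_beta else truth.copy())
        report, frame = evaluate(object(), test_set, method="single")
        assert report.mae == 0.0
        assert report.smape == 0.0
        assert len(frame) == len(test_set)

    def test_single_model_run_is_reproducible(self, tiny_trained, tiny_splits):
        model, _ = tiny_trained
        r1, f1 = evaluate(model, tiny_splits["test"], method="single")
        r2, f2 = evaluate(model, tiny_splits["test"], method="single")
        assert f1.equals(f2)
        assert r1.mae == r2.mae

    def test_mc_dropout_produces_sigmas(self, tiny_trained, tiny_splits):
        from sndm.uncertainty import DropoutInferenceConfig
        model, _ = tiny_trained
        report, frame = evaluate(model, tiny_splits["test"],
                                 method="mc_dropout",
                                 dropout_config=DropoutInferenceConfig(r=4, seed=2))
        assert (frame["sigma"] > 0).any()
        assert 0.0 <= report.within_1sigma <= 1.0

    def test_report_agrees_with_bruteforce_recomputation_from_csv(
            self, tiny_trained, tiny_splits, tmp_path):
        model, _ = tiny_trained
        report, frame = evaluate(model, tiny_splits["test"], method="single")
        path = tmp_path / "records.csv"
        frame.to_csv(path, index=False)
        import pandas as pd
        back = pd.read_csv(path)
        mae_bf = (back["n"] - back["n_hat"]).abs().mean()
        terms = ((back["n"] - back["n_hat"]).abs()
                 / (back["n"] + back["n_hat"]).abs()).fillna(0.0)
        assert report.mae == pytest.approx(mae_bf, rel=1e-9)
        assert report.smape == pytest.approx(100 * terms.mean(), rel=1e-9)

    def test_rounded_counts_reported_alongside(self):
        frame = records_to_frame([_rec(5, 5.4), _rec(7, 6.6, i=1)])
        assert frame["n_hat_rounded"].tolist() == [5, 7]

    def test_unknown_method_rejected(self, tiny_splits):
        with pytest.raises(ValueError):
            evaluate(object(), tiny_splits["test"], method="jackknife")
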