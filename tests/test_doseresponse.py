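"""Robust 4PL fitting, EC50/AUC quantification and subtype statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pdoniche.doseresponse import (
    DoseResponseDataset,
    DrugSensitivity,
    FourPLFit,
    FourPLRegressor,
    auc_log_dose,
    compare_subtypes,
    fit_4pl_robust,
    four_pl,
    normalize_to_reference,
    soft_l1_loss,
    spearman_niche_vs_auc,
)


def make_ds(dose, response, **kw):
    return DoseResponseDataset(drug="drugX", sample_id="s1", dose=dose,
                               response=response, **kw)


class TestNormalization:
    def test_all_equal_responses_become_100(self):
        df = pd.DataFrame({"dose": [0.001, 0.01, 0.1], "response": [5.0] * 3})
        out = normalize_to_reference(df, 0.001, by=())
        np.testing.assert_allclose(out["response"], 100.0)

    def test_hand_scaling(self):
        df = pd.DataFrame({"dose": [0.001, 1.0], "response": [2000.0, 500.0]})
        out = normalize_to_reference(df, 0.001, by=())
        np.testing.assert_allclose(out["response"], [100.0, 25.0])

    def test_reference_dose_absent_errors(self):
        df = pd.DataFrame({"dose": [0.01, 1.0], "response": [1.0, 2.0]})
        with pytest.raises(ValueError, match="reference dose"):
            normalize_to_reference(df, 0.001, by=())

    def test_per_group_scaling(self):
        df = pd.DataFrame({
            "drug": ["a"] * 2 + ["b"] * 2, "sample_id": ["s"] * 4,
            "dose": [1.0, 10.0, 1.0, 10.0],
            "response": [50.0, 25.0, 200.0, 100.0]})
        out = normalize_to_reference(df, 1.0)
        np.testing.assert_allclose(out["response"], [100.0, 50.0, 100.0, 50.0])


class TestFourPLModel:
    def test_midpoint_at_ec50(self):
        assert four_pl(100.0, 10.0, 90.0, 2.0, 1.7) == pytest.approx(50.0)

    def test_ec50_conversion(self):
        fit = FourPLFit(bottom=0, top=100, log10_ec50=2.0, hill_slope=1.0,
                        loss_value=0.0, converged=True, n_points=8)
        assert fit.ec50 == pytest.approx(100.0)


class TestRobustFit:
    def test_requires_four_distinct_doses_and_positive_doses(self):
        with pytest.raises(ValueError, match="4 distinct doses"):
            FourPLRegressor().fit([1, 1, 2, 3], [1, 1, 2, 3])
        with pytest.raises(ValueError, match="positive"):
            FourPLRegressor().fit([0, 1, 2, 3], [1, 1, 2, 3])

    @pytest.mark.parametrize("draw", range(50))
    def test_noise_free_recovery(self, draw):
        """Noise-free curves are recovered to optimizer tolerance."""
        rng = np.random.default_rng(1000 + draw)
        bottom = rng.uniform(0, 30)
        top = rng.uniform(70, 120)
        log_e = rng.uniform(-1, 2)
        hill = rng.choice([-1, 1]) * rng.uniform(0.5, 3.0)
        dose = np.power(10.0, np.linspace(log_e - 2, log_e + 2,
                                          int(rng.integers(6, 10))))
        y = four_pl(dose, bottom, top, log_e, hill)
        reg = FourPLRegressor().fit(dose, y)
        assert reg.ec50_ == pytest.approx(10.0**log_e, rel=1e-6)
        assert reg.hill_ == pytest.approx(hill, rel=1e-4)
        assert reg.bottom_ == pytest.approx(bottom, abs=1e-4)
        assert reg.top_ == pytest.approx(top, abs=1e-4)
        assert reg.converged_

    def test_loss_beats_dense_grid_oracle(self):
        rng = np.random.default_rng(7)
        dose = np.power(10.0, np.linspace(-2, 2, 7))
        y = four_pl(dose, 5, 95, 0.3, -1.2) * rng.lognormal(0, 0.08, dose.size)
        reg = FourPLRegressor().fit(dose, y)
        grid_best = np.inf
        for b in np.linspace(0, 30, 8):
            for t in np.linspace(70, 120, 8):
                for le in np.linspace(-2, 2, 17):
                    for h in np.linspace(-3, 3, 13):
                        r = four_pl(dose, b, t, le, h) - y
                        grid_best = min(grid_best, soft_l1_loss(r, 5.0))
        assert reg.loss_value_ <= grid_best + 1e-8

    def test_invariant_to_point_order_and_duplication(self):
        dose = np.power(10.0, np.linspace(-2, 2, 8))
        rng = np.random.default_rng(3)
        y = four_pl(dose, 10, 100, 0.0, -1.0) * rng.lognormal(0, 0.05, dose.size)
        ref = FourPLRegressor().fit(dose, y)
        perm = np.argsort(rng.random(dose.size))
        shuffled = FourPLRegressor().fit(dose[perm], y[perm])
        assert shuffled.ec50_ == pytest.approx(ref.ec50_, rel=1e-6)
        doubled = FourPLRegressor().fit(np.tile(dose, 2), np.tile(y, 2))
        assert doubled.ec50_ == pytest.approx(ref.ec50_, rel=1e-6)

    def test_flat_data_flagged_unidentifiable(self):
        reg = FourPLRegressor().fit([1, 10, 100, 1000], [50.0] * 4)
        assert reg.hill_unidentifiable_
        assert reg.top_ >= reg.bottom_

    def test_median_ec50_error_under_noise(self):
        """5% CV multiplicative noise: median |EC50 error| below 15%."""
        rng = np.random.default_rng(99)
        errors = []
        for _ in range(200):
            log_e = rng.uniform(-0.5, 1.5)
            dose = np.power(10.0, np.linspace(-3, 4, 8))
            truth = four_pl(dose, rng.uniform(0, 20), 100.0, log_e,
                            -rng.uniform(0.8, 1.5))
            y = truth * rng.lognormal(0, 0.05, dose.size)
            reg = FourPLRegressor().fit(dose, y)
            errors.append(abs(reg.ec50_ - 10.0**log_e) / 10.0**log_e)
        assert np.median(errors) < 0.15


class TestAUC:
    def test_flat_curve(self):
        fit = FourPLFit(bottom=100, top=100, log10_ec50=0, hill_slope=1,
                        loss_value=0, converged=True, n_points=4)
        assert auc_log_dose(fit, (1.0, 1000.0)) == pytest.approx(300.0)

    def test_linear_response_trapezoid_by_hand(self):
        class LinearCurve:
            def predict(self, dose):
                # 100% at dose 1 falling linearly in log10 dose to 0% at dose 100
                return 100.0 * (1.0 - np.log10(np.asarray(dose)) / 2.0)

        assert auc_log_dose(LinearCurve(), (1.0, 100.0)) == pytest.approx(100.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(shift=st.floats(min_value=0.1, max_value=50.0))
    def test_pointwise_higher_curve_has_larger_auc(self, shift):
        low = FourPLFit(bottom=10, top=90, log10_ec50=0.5, hill_slope=-1,
                        loss_value=0, converged=True, n_points=8)
        high = FourPLFit(bottom=10 + shift, top=90 + shift, log10_ec50=0.5,
                         hill_slope=-1, loss_value=0, converged=True, n_points=8)
        rng = (0.001, 1000.0)
        assert auc_log_dose(high, rng) > auc_log_dose(low, rng)

    def test_fit_auc_matches_function_route(self):
        dose = np.power(10.0, np.linspace(-2, 2, 8))
        y = four_pl(dose, 10, 100, 0.0, -1.0)
        reg = FourPLRegressor().fit(dose, y)
        assert reg.auc() == pytest.approx(
            auc_log_dose(reg.to_fit(), (dose.min(), dose.max())))


def sens(sample, auc, drug="gem"):
    return DrugSensitivity(sample_id=sample, drug=drug, ec50=1.0, auc=auc,
                           dose_range=(0.001, 1000))


class TestGroupStatistics:
    labels = {"a": "Low", "b": "Low", "c": "High", "d": "High"}

    def test_identical_groups_give_t0_p1(self):
        s = [sens("a", 100), sens("b", 200), sens("c", 100), sens("d", 200)]
        res = compare_subtypes(s, self.labels)
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_separated_constants_give_p_zero(self):
        s = [sens("a", 1), sens("b", 1), sens("c", 9), sens("d", 9)]
        res = compare_subtypes(s, self.labels)
        assert res.p_value == 0.0

    def test_hand_checked_three_vs_three(self):
        labels = {"a": "Low", "b": "Low", "c": "Low",
                  "x": "High", "y": "High", "z": "High"}
        s = [sens(k, v) for k, v in
             zip("abcxyz", [1.0, 2.0, 3.0, 4.0, 5.0, 6.0])]
        res = compare_subtypes(s, labels)
        # textbook pooled t: diff -3, s2p = 1, se = sqrt(2/3)
        assert res.t_statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
        assert res.p_value == pytest.approx(0.0213116, abs=1e-6)
        assert res.group_means == {"Low": 2.0, "High": 5.0}

    def test_mixed_drugs_rejected(self):
        s = [sens("a", 1), sens("b", 2), sens("c", 3, drug="other"), sens("d", 4)]
        with pytest.raises(ValueError, match="multiple drugs"):
            compare_subtypes(s, self.labels)

    def test_spearman_directions(self):
        scores = {"a": 1.0, "b": 2.0, "c": 3.0}
        up = [sens("a", 10), sens("b", 20), sens("c", 30)]
        rho, _ = spearman_niche_vs_auc(scores, up)
        assert rho == pytest.approx(1.0)
        down = [sens("a", 30), sens("b", 20), sens("c", 10)]
        rho, _ = spearman_niche_vs_auc(scores, down)
        assert rho == pytest.approx(-1.0)


class TestDatasetValidation:
    def test_dose_zero_disallowed(self):
        with pytest.raises(ValueError, match="positive"):
            make_ds([0.0, 1.0, 10.0, 100.0], [1, 2, 3, 4])

    def test_functional_wrapper_matches_estimator(self):
        dose = np.power(10.0, np.linspace(0, 3, 8))
        y = four_pl(dose, 1.0, 8.0, np.log10(63.89), 1.0)
        fit = fit_4pl_robust(make_ds(dose, y))
        assert fit.ec50 == pytest.approx(63.89, rel=1e-6)
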