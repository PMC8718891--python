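import json

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from aadrisk.risk import (
    KdeRiskModel,
    extreme_separation_check,
    fit_kde_model,
    minmax_normalize,
    predict_p_aad,
    region_risk_ratio,
    silverman_bandwidth,
)


def brute_force_density(centers, h, x):
    """Independent re-implementation: explicit sum of Gaussian terms."""
    total = 0.0
    for c in centers:
        total += np.exp(-0.5 * ((x - c) / h) ** 2) / (h * np.sqrt(2 * np.pi))
    return total / len(centers)


class TestMinMax:
    def test_maps_onto_unit_interval(self):
        v, lo, hi = minmax_normalize([2.0, 4.0, 6.0])
        assert v.tolist() == [0.0, 0.5, 1.0]
        assert (lo, hi) == (2.0, 6.0)

    def test_order_preserved(self):
        raw = np.array([3.0, 1.0, 10.0, 7.0])
        v, _, _ = minmax_normalize(raw)
        assert (np.argsort(v) == np.argsort(raw)).all()

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            minmax_normalize([5.0, 5.0])


class TestFitAndPredict:
    def test_single_sample_group_is_one_gaussian(self):
        model = fit_kde_model([0.0], [1.0], bandwidth=0.2)
        xs = np.linspace(-0.5, 1.5, 41)
        xn = model.normalize(xs)
        expected = norm.pdf(xn, loc=0.0, scale=0.2)
        assert np.allclose(model.density_aad(xn), expected)

    def test_refit_is_deterministic(self):
        rng = np.random.default_rng(0)
        a, b = rng.lognormal(17, 1, 13), rng.lognormal(18, 1, 17)
        m1 = fit_kde_model(a, b)
        m2 = fit_kde_model(a, b)
        assert m1.bandwidth == m2.bandwidth
        xs = np.linspace(0, 1, 11)
        assert np.array_equal(m1.density_aad(xs), m2.density_aad(xs))

    def test_group_pdfs_integrate_to_one(self):
        rng = np.random.default_rng(1)
        model = fit_kde_model(rng.uniform(1e6, 1e8, 13),
                              rng.uniform(1e6, 1e8, 17))
        for density in (model.density_aad, model.density_non_aad):
            total, err = quad(lambda t: float(density(t)), -20, 21, limit=200)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_densities_match_brute_force_summation(self):
        rng = np.random.default_rng(2)
        model = fit_kde_model(rng.uniform(0, 1e8, 13), rng.uniform(0, 1e8, 17),
                              bandwidth=0.13)
        for x in np.linspace(-0.3, 1.3, 23):
            assert float(model.density_aad(x)) == pytest.approx(
                brute_force_density(model.x_aad, 0.13, x), abs=1e-12
            )

    def test_symmetric_groups_give_half_at_midpoint(self):
        model = fit_kde_model([0.0, 0.4], [0.6, 1.0], bandwidth=0.15)
        assert predict_p_aad(model, 0.5).p_aad == pytest.approx(0.5)

    def test_extreme_query_near_certainty(self):
        model = fit_kde_model([0.0], [1.0], bandwidth=0.2)
        assert predict_p_aad(model, 0.0).p_aad > 0.999

    def test_equal_group_multisets_flat_posterior(self):
        model = fit_kde_model([1e6, 5e7, 1e8], [1e6, 5e7, 1e8], bandwidth=0.1)
        for x in (2e6, 3e7, 9e7):
            assert predict_p_aad(model, x).p_aad == pytest.approx(0.5)

    def test_posterior_probabilities_are_complementary(self):
        rng = np.random.default_rng(3)
        model = fit_kde_model(rng.uniform(0, 5e7, 13),
                              rng.uniform(3e7, 1e8, 17))
        for x in rng.uniform(0, 1e8, 20):
            pred = predict_p_aad(model, x)
            p_non = pred.f_non_aad / (pred.f_aad + pred.f_non_aad)
            assert pred.p_aad + p_non == pytest.approx(1.0, abs=1e-15)

    def test_vanishing_densities_raise_with_guidance(self):
        model = fit_kde_model([0.0], [0.01], bandwidth=1e-3)
        with pytest.raises(ValueError, match="bandwidth"):
            predict_p_aad(model, 1e9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            fit_kde_model([], [1.0, 2.0])


class TestRegionRiskRatio:
    def test_identical_groups_ratio_one(self):
        model = fit_kde_model([1e6, 5e7, 1e8], [1e6, 5e7, 1e8], bandwidth=0.1)
        assert region_risk_ratio(model, 2.4e7, 8.0e7) == pytest.approx(1.0)

    def test_stochastically_lower_aad_group_ratio_above_one(self):
        model = KdeRiskModel(np.array([0.2]), np.array([0.8]), 0.15, 0.0, 1e8)
        assert region_risk_ratio(model, 0.4e8, 0.6e8) > 1.0

    def test_single_gaussian_groups_match_closed_form(self):
        h, mu_a, mu_n = 0.12, 0.25, 0.75
        model = KdeRiskModel(np.array([mu_a]), np.array([mu_n]), h, 0.0, 1.0)
        lo, hi = 0.4, 0.6
        ratio = region_risk_ratio(model, lo, hi)
        mass = lambda mu, a, b: norm.cdf(b, mu, h) - norm.cdf(a, mu, h)
        p_low = mass(mu_a, -np.inf, lo) / (mass(mu_a, -np.inf, lo) + mass(mu_n, -np.inf, lo))
        p_high = mass(mu_a, hi, np.inf) / (mass(mu_a, hi, np.inf) + mass(mu_n, hi, np.inf))
        assert ratio == pytest.approx(p_low / p_high, abs=1e-8)

    def test_pointwise_mode_uses_threshold_densities(self):
        model = KdeRiskModel(np.array([0.2]), np.array([0.8]), 0.15, 0.0, 1.0)
        expected = (predict_p_aad(model, 0.4).p_aad
                    / predict_p_aad(model, 0.6).p_aad)
        assert region_risk_ratio(model, 0.4, 0.6, mode="pointwise") == \
            pytest.approx(expected)

    def test_threshold_order_enforced(self):
        model = fit_kde_model([1e6], [1e8], bandwidth=0.2)
        with pytest.raises(ValueError, match="below"):
            region_risk_ratio(model, 8e7, 2.4e7)

    def test_empty_region_mass_rejected(self):
        model = KdeRiskModel(np.array([0.5]), np.array([0.5]), 1e-3, 0.0, 1.0)
        with pytest.raises(ValueError, match="mass"):
            region_risk_ratio(model, -10.0, 10.0)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        model = fit_kde_model([1e6, 2e7], [5e7, 9e7])
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = KdeRiskModel.from_json(path)
        assert loaded.bandwidth == model.bandwidth
        assert np.array_equal(loaded.x_aad, model.x_aad)
        assert json.loads(path.read_text())["format_version"] == 1


class TestExtremeSeparation:
    def test_perfect_separation_has_no_violations(self):
        ranked = [("a", 0.02, True), ("b", 0.03, True), ("c", 0.2, False)]
        out = extreme_separation_check(ranked, low=0.05, high=0.16)
        assert out["aad_below_low"] == 2
        assert out["non_aad_above_high"] == 1
        assert out["violations"] == []

    def test_empty_extremes_report_zeros(self):
        ranked = [("a", 0.1, True), ("b", 0.12, False)]
        out = extreme_separation_check(ranked, low=0.05, high=0.16)
        assert out["aad_below_low"] == 0 and out["non_aad_above_high"] == 0

    def test_misplaced_subjects_reported(self):
        ranked = [("a", 0.2, True), ("b", 0.01, False)]
        out = extreme_separation_check(ranked, low=0.05, high=0.16)
        kinds = {v[2] for v in out["violations"]}
        assert kinds == {"AAD above high", "non-AAD below low"}


def test_silverman_bandwidth_shrinks_with_n():
    rng = np.random.default_rng(5)
    small = silverman_bandwidth(rng.uniform(0, 1, 10))
    large = silverman_bandwidth(rng.uniform(0, 1, 10_000))
    assert large < small
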