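"""Power-law fitting, the Rule of Exponents, and scaling strategies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcscale import (
    AllometricModel,
    ValidationError,
    fit_corrected,
    fit_power_law,
    roe_select,
    scale_one_species,
    scale_one_species_average,
    scale_three_species,
    scale_two_species,
)
from adcscale.allometry import FittingError
from adcscale.datasets import SpeciesObservation


def grid_search_fit(points, n_grid=601):
    """Independent brute-force oracle: dense grid over (log a, b) minimising
    the sum of squared log residuals, centred +/-50% around the OLS estimate."""
    logw = np.log([w for w, _ in points])
    logv = np.log([v for _, v in points])
    ols = fit_power_law(points)
    la0, b0 = math.log(ols.coefficient_a), ols.exponent_b
    las = np.linspace(la0 - 0.5 * abs(la0) - 0.1, la0 + 0.5 * abs(la0) + 0.1, n_grid)
    bs = np.linspace(b0 - 0.5 * abs(b0) - 0.1, b0 + 0.5 * abs(b0) + 0.1, n_grid)
    resid = logv[None, None, :] - (las[:, None, None] + bs[None, :, None] * logw[None, None, :])
    sse = (resid**2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return math.exp(las[i]), bs[j]


class TestFitPowerLaw:
    def test_three_species_fit_matches_printed_parameters(self, dataset):
        # DSTP3086S total antibody panel
        points = [(0.02, 0.20), (0.25, 2.37), (3.5, 46.9)]
        fit = fit_power_law(points)
        assert round(fit.coefficient_a, 1) == 11.7
        assert round(fit.exponent_b, 2) == 1.06

    def test_noiseless_power_law_recovered_exactly(self):
        points = [(w, 5.0 * w) for w in (0.02, 0.25, 3.5)]
        fit = fit_power_law(points)
        assert fit.coefficient_a == pytest.approx(5.0, rel=1e-12)
        assert fit.exponent_b == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "key",
        [("DSTP3086S", "total"), ("Thiomab", "conjugate"), ("Anti-5T4", "total")],
    )
    def test_ols_matches_grid_search_oracle(self, dataset, registry, key):
        series = dataset[key]
        points = [
            (registry.body_weight(o.species), o.clearance_ml_day)
            for o in series.animals
        ]
        fit = fit_power_law(points)
        a_grid, b_grid = grid_search_fit(points)
        # agreement to grid resolution
        assert fit.exponent_b == pytest.approx(b_grid, abs=5e-3)
        assert fit.coefficient_a == pytest.approx(a_grid, rel=5e-3)

    @pytest.mark.parametrize(
        "points,match",
        [
            ([(0.02, 1.0)], "at least two"),
            ([(0.02, 1.0), (0.02, 2.0)], "distinct"),
            ([(0.02, 1.0), (0.25, -2.0)], "positive"),
        ],
    )
    def test_invalid_inputs_rejected(self, points, match):
        with pytest.raises(FittingError, match=match):
            fit_power_law(points)

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.floats(0.1, 100),
        b=st.floats(0.2, 2.0),
        k=st.floats(0.1, 10),
    )
    def test_unit_rescaling_covariance(self, a, b, k):
        """Rescaling all weights by k leaves b unchanged and maps a -> a*k^-b."""
        weights = np.array([0.02, 0.25, 3.5])
        values = a * weights**b * np.array([1.1, 0.9, 1.05])  # fixed noise pattern
        fit = AllometricModel(weights, values).fit()
        fit_scaled = AllometricModel(weights * k, values).fit()
        assert fit_scaled.exponent_b == pytest.approx(fit.exponent_b, rel=1e-9)
        assert fit_scaled.coefficient_a == pytest.approx(
            fit.coefficient_a * k**-fit.exponent_b, rel=1e-9
        )

    @settings(max_examples=50, derandomize=True)
    @given(
        w1=st.floats(0.01, 1.0),
        w2=st.floats(2.0, 100.0),
        v1=st.floats(0.01, 100),
        v2=st.floats(0.01, 100),
    )
    def test_two_point_fit_is_exact_interpolant(self, w1, w2, v1, v2):
        fit = fit_power_law([(w1, v1), (w2, v2)])
        assert fit.predict(w1) == pytest.approx(v1, rel=1e-9)
        assert fit.predict(w2) == pytest.approx(v2, rel=1e-9)
        assert np.allclose(fit.log_residuals(), 0.0, atol=1e-10)


class TestCorrectedFits:
    def test_brain_weight_product_matches_printed(self, dataset, registry):
        fit = fit_corrected(dataset[("DSTP3086S", "total")], registry, "brain_weight")
        assert round(fit.coefficient_a, 1) == 155.7
        assert round(fit.exponent_b, 2) == 2.06
        fit2 = fit_corrected(dataset[("DNIB0600A", "total")], registry, "brain_weight")
        assert round(fit2.coefficient_a, 1) == 182.5
        assert round(fit2.exponent_b, 2) == 2.08

    def test_unit_correction_degenerates_to_simple(self, dataset, tmp_path, registry):
        # a registry whose correction constants are all 1 must reproduce
        # the simple fit exactly
        path = tmp_path / "unit.csv"
        path.write_text(
            "species,body_weight_kg,brain_weight_g,mlp_years\n"
            "mouse,0.02,1,1\nrat,0.25,1,1\nmonkey,3.5,1,1\nhuman,70,1,1\n"
        )
        from adcscale import load_constants

        unit = load_constants(path)
        series = dataset[("T-DM1", "total")]
        simple = AllometricModel.from_series(series, unit).fit()
        mlp = fit_corrected(series, unit, "mlp")
        assert mlp.coefficient_a == pytest.approx(simple.coefficient_a, rel=1e-12)
        assert mlp.exponent_b == pytest.approx(simple.exponent_b, abs=1e-12)

    def test_predict_human_mlp_matches_printed(self, dataset, registry):
        tdm1 = fit_corrected(dataset[("T-DM1", "total")], registry, "mlp")
        assert tdm1.predict_human(registry) == pytest.approx(111, rel=0.01)
        brentux = fit_corrected(
            dataset[("Brentuximab vedotin", "total")], registry, "mlp"
        )
        assert brentux.predict_human(registry) == pytest.approx(274, rel=0.01)

    def test_constant_model_predicts_coefficient(self):
        fit = fit_power_law([(0.02, 1.0), (3.5, 1.0)])
        assert fit.predict_human() == pytest.approx(1.0, rel=1e-9)


class TestRuleOfExponents:
    @pytest.mark.parametrize(
        "b,mclass,expected_method,expected_band",
        [
            (1.06, "biologic", "brain_weight_product", "brain_band"),
            (0.89, "biologic", "simple", "mlp_band"),
            (1.0, "biologic", "simple", "brain_band"),  # strict > 1.0 for biologics
            (0.85, "small_molecule", "mlp_product", "mlp_band"),
            (0.60, "small_molecule", "simple", "sa_band"),
            (1.2, "small_molecule", "brain_weight_product", "brain_band"),
            (0.3, "biologic", "simple", "low"),
            (1.5, "biologic", "brain_weight_product", "high"),
            (1.5, "small_molecule", "simple", "high"),
        ],
    )
    def test_method_selection(self, b, mclass, expected_method, expected_band):
        decision = roe_select(b, mclass)
        assert decision.chosen_method == expected_method
        assert decision.band == expected_band

    def test_mlp_never_chosen_for_biologics(self):
        for b in np.linspace(0.3, 1.5, 61):
            assert roe_select(float(b), "biologic").chosen_method != "mlp_product"


class TestScalingStrategies:
    def test_three_species_simple_matches_printed(self, dataset, registry):
        p = scale_three_species(dataset[("Anti-5T4", "total")], registry, "sa_only")
        assert p.predicted_cl == pytest.approx(323, rel=0.01)
        assert p.ratio == pytest.approx(0.90, abs=0.01)
        p2 = scale_three_species(dataset[("T-DM1", "conjugate")], registry, "sa_only")
        assert p2.predicted_cl == pytest.approx(683, rel=0.01)

    def test_three_species_roe_switches_to_brain_weight(self, dataset, registry):
        p = scale_three_species(dataset[("DNIB0600A", "total")], registry, "roe")
        assert p.detail["method"] == "brain_weight_product"
        assert p.predicted_cl == pytest.approx(886, rel=0.01)

    def test_roe_keeps_simple_when_exponent_below_one(self, dataset, registry):
        p = scale_three_species(dataset[("T-DM1", "total")], registry, "roe")
        assert p.detail["method"] == "simple"
        assert p.predicted_cl == pytest.approx(236, rel=0.01)

    def test_two_species_requires_present_species(self, dataset, registry):
        with pytest.raises(ValidationError, match="rat"):
            scale_two_species(dataset[("DMOT4039A", "total")], ("mouse", "rat"), registry)

    def test_three_species_rejects_two_species_series(self, dataset, registry):
        with pytest.raises(ValidationError, match="two"):
            scale_three_species(dataset[("DMOT4039A", "total")], registry)

    def test_two_species_exponents_match_printed(self, dataset, registry):
        p = scale_two_species(dataset[("DNIB0600A", "total")], ("mouse", "monkey"), registry)
        assert round(p.exponent, 2) == 1.08
        p2 = scale_two_species(
            dataset[("Brentuximab vedotin", "total")], ("mouse", "rat"), registry
        )
        assert p2.exponent == pytest.approx(0.59, abs=0.006)

    def test_one_species_weight_ratio_form(self, dataset, registry):
        dnib = dataset[("DNIB0600A", "total")]
        monkey = scale_one_species(dnib.observation("monkey"), registry, 1.0)
        assert monkey.predicted_cl == pytest.approx(931, rel=1e-12)  # 46.55 * 20
        rat = scale_one_species(dnib.observation("rat"), registry, 1.0)
        assert round(rat.predicted_cl) == 1114  # 3.98 * 280

    def test_exponent_one_equals_per_kg_extrapolation(self, dataset, registry):
        for series in dataset:
            for obs in series.animals:
                p = scale_one_species(obs, registry, 1.0)
                linear = obs.clearance_ml_day * 70 / registry.body_weight(obs.species)
                assert p.predicted_cl == pytest.approx(linear, rel=1e-12)

    def test_human_weight_species_is_identity(self, registry, tmp_path):
        from adcscale import load_constants

        path = tmp_path / "constants.csv"
        path.write_text(
            "species,body_weight_kg,brain_weight_g,mlp_years\n"
            "bigape,70,400,40\nhuman,70,1400,93.4\n"
        )
        reg = load_constants(path)
        obs = SpeciesObservation("bigape", 123.0)
        for e in (0.75, 1.0, 1.3):
            assert scale_one_species(obs, reg, e).predicted_cl == pytest.approx(123.0)

    def test_average_of_singleton_equals_fixed(self, dataset, registry):
        obs = dataset[("DNIB0600A", "total")].observation("mouse")
        avg = scale_one_species_average(obs, registry, [1.0])
        fixed = scale_one_species(obs, registry, 1.0)
        assert avg.predicted_cl == pytest.approx(fixed.predicted_cl, rel=1e-12)

    def test_average_strategy_direct_evaluation(self, dataset, registry):
        obs = dataset[("DNIB0600A", "total")].observation("mouse")
        avg = scale_one_species_average(obs, registry, [0.85, 1.0, 1.1])
        expected = np.mean([0.18 * 3500**e for e in (0.85, 1.0, 1.1)])
        assert avg.predicted_cl == pytest.approx(expected, rel=1e-12)
        assert avg.predicted_cl == pytest.approx(747, abs=1)

    def test_single_exponent_085_matches_printed(self, dataset, registry):
        obs = dataset[("DMOT4039A", "total")].observation("mouse")
        p = scale_one_species(obs, registry, 0.85)
        assert p.predicted_cl == pytest.approx(196, abs=1)

    def test_mlp_underpredicts_simple_for_default_registry(self, dataset, registry):
        """MLP/93.4 ratios are all < 1 and increase with body weight, so the
        corrected prediction falls below simple allometry for every series."""
        for series in dataset.three_species():
            sa = scale_three_species(series, registry, "sa_only")
            mlp = scale_three_species(series, registry, "mlp_forced")
            assert mlp.predicted_cl < sa.predicted_cl
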