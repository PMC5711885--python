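"""Poisson vesicle-occupancy model: transformations, closed form, fitting."""

import numpy as np
import pytest

from scramblefit import (
    AssayPoint,
    VesiclePopulation,
    alpha_to_mass,
    fit_alpha,
    mass_to_alpha,
    mean_occupancy,
    normalize_reduction,
    oligomer_order,
    ppr_star,
    predict_p_at_least_one,
)
from scramblefit.occupancy import ConfigurationError, DegenerateDataError

from conftest import monte_carlo_p_at_least_one


class TestNormalizeReduction:
    @pytest.mark.parametrize(
        "f_end, expected",
        [(45.0, 0.0), (82.5, 1.0), (63.75, 0.5)],
    )
    def test_linear_transform(self, population, f_end, expected):
        assert normalize_reduction(f_end, population) == pytest.approx(expected)

    def test_below_baseline_clamps_with_warning(self, population):
        with pytest.warns(UserWarning, match="below baseline"):
            assert normalize_reduction(40.0, population) == 0.0

    def test_degenerate_population_rejected(self):
        with pytest.raises(ConfigurationError):
            VesiclePopulation(f_o=82.5, f_max=82.5)


class TestPprStar:
    @pytest.mark.parametrize("ppr, expected", [(0.0, 0.0), (0.65, 1.0), (1.3, 2.0)])
    def test_refractory_correction(self, population, ppr, expected):
        assert ppr_star(ppr, population) == pytest.approx(expected)

    def test_negative_ppr_rejected(self, population):
        with pytest.raises(ValueError):
            ppr_star(-0.1, population)


class TestMeanOccupancy:
    def test_zero_protein_zero_occupancy(self):
        assert mean_occupancy(88.0, 1e-3, 0.0) == 0.0

    def test_reciprocal_cancellation(self):
        alpha = 16 / (41700 * 0.472**2)
        x = 41700 * 0.472**2 / 16
        assert mean_occupancy(1.0, alpha, x) == pytest.approx(0.5)

    def test_matches_lipid_count_route(self):
        # independent route: lipids per vesicle times protein/lipid ratio
        alpha, x, r, eps = 8.17e-4, 1.0, 88.0, 0.472
        mass = 16.0 / (alpha * eps**2)
        expected = (8 * r**2 / eps**2) * (x / mass)
        assert mean_occupancy(r, alpha, x) == pytest.approx(expected, rel=1e-12)

    def test_quadratic_radius_scaling(self):
        assert mean_occupancy(176.0, 1e-3, 1.0) == pytest.approx(
            4 * mean_occupancy(88.0, 1e-3, 1.0)
        )


class TestClosedForm:
    def test_default_coefficients_exact(self, population):
        assert population.sigma_sq == 784.0
        assert population.half_mean_radius_sq == 3872.0

    def test_no_protein_gives_zero(self, population):
        assert predict_p_at_least_one(0.0, 8.17e-4, population) == 0.0

    def test_saturates_to_one(self, population):
        # the 1/sqrt factor makes convergence slow, O((alpha*x)^-1/2)
        assert predict_p_at_least_one(1e4, 8.17e-4, population) > 0.9999
        assert predict_p_at_least_one(1e6, 8.17e-4, population) > 0.99999

    def test_frozen_monte_carlo_value(self, population):
        # 0.8864 computed with the truncated-Gaussian Poisson oracle at 1e6
        assert predict_p_at_least_one(1.0, 8.17e-4, population) == pytest.approx(
            0.8864, abs=1.5e-3
        )

    @pytest.mark.parametrize("alpha", [2e-4, 8.17e-4, 2e-3])
    @pytest.mark.parametrize("x", [0.1, 1.0, 5.0])
    def test_matches_monte_carlo_oracle(self, population, alpha, x):
        rng = np.random.default_rng(2024)
        n = 200_000
        p_mc, se = monte_carlo_p_at_least_one(alpha, x, n, population, rng)
        # 3 binomial SE plus the <1e-3 truncation discrepancy budget
        assert predict_p_at_least_one(x, alpha, population) == pytest.approx(
            p_mc, abs=3 * se + 1e-3
        )

    def test_monotone_in_x_and_alpha(self, population):
        xs = np.linspace(0.0, 5.0, 50)
        for alpha in (2e-4, 8.17e-4, 2e-3):
            p = predict_p_at_least_one(xs, alpha, population)
            assert np.all(np.diff(p) >= 0)
        alphas = np.linspace(2e-4, 2e-3, 50)
        p_by_alpha = [predict_p_at_least_one(1.0, a, population) for a in alphas]
        assert np.all(np.diff(p_by_alpha) >= 0)

    def test_no_inflection_over_assay_range(self, population):
        # concave in x for x > 0: the single-occupancy curve has no
        # inflection point over the assay range
        x = np.linspace(0.01, 5.0, 500)
        p = predict_p_at_least_one(x, 18.9e-4, population)
        assert np.all(np.diff(p, 2) < 1e-12)


class TestMassConversion:
    @pytest.mark.parametrize(
        "alpha, expected, rel",
        [(8.17e-4, 87_905, 1e-4), (18.90e-4, 38_000, 5e-4)],
    )
    def test_table_masses(self, alpha, expected, rel):
        assert alpha_to_mass(alpha, 0.472) == pytest.approx(expected, rel=rel)

    def test_round_trip_identity(self):
        for mass in (41_700.0, 83_400.0, 38_000.0):
            assert alpha_to_mass(mass_to_alpha(mass)) == pytest.approx(mass, rel=1e-14)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            alpha_to_mass(0.0)
        with pytest.raises(ValueError):
            mass_to_alpha(41700, -1.0)


class TestOligomerOrder:
    @pytest.mark.parametrize(
        "mass, expected",
        [(38_000, "1"), (87_905, ">=2"), (41_700, "1")],
    )
    def test_assignment(self, mass, expected):
        assert str(oligomer_order(mass, 41_700)) == expected

    def test_margin_controls_at_least_flag(self):
        assert not oligomer_order(41_700 * 2.04, 41_700).at_least
        assert oligomer_order(41_700 * 2.06, 41_700).at_least


def _points_from_model(alpha, x_values, population, noise_sd=0.0, rng=None):
    p = predict_p_at_least_one(np.asarray(x_values, float), alpha, population)
    if noise_sd:
        p = np.clip(p + rng.normal(0.0, noise_sd, len(p)), 0.0, 1.0)
    return [
        AssayPoint(ppr=x * 0.65, ppr_star=x, f_end=None, p_active=pv)
        for x, pv in zip(x_values, p)
    ]


class TestFitAlpha:
    def test_noiseless_self_consistency(self, population):
        x = np.linspace(0.05, 4.6, 12)
        fit = fit_alpha(_points_from_model(1e-3, x, population), population)
        assert fit.alpha == pytest.approx(1e-3, rel=1e-6)

    def test_noisy_recovery_within_two_se(self, population):
        rng = np.random.default_rng(0)
        x = np.array([0, 0.03, 0.06, 0.09, 0.12, 0.16, 0.2, 0.3, 0.5, 1, 2, 3]) / 0.65
        fit = fit_alpha(
            _points_from_model(18.9e-4, x, population, 0.03, rng), population
        )
        assert abs(fit.alpha - 18.9e-4) <= 2 * fit.alpha_se

    def test_mass_se_propagation(self, population):
        rng = np.random.default_rng(1)
        x = np.linspace(0.05, 4.6, 12)
        fit = fit_alpha(
            _points_from_model(8.17e-4, x, population, 0.02, rng), population
        )
        assert fit.molar_mass_se / fit.molar_mass == pytest.approx(
            fit.alpha_se / fit.alpha
        )

    def test_ci_band_brackets_fit(self, population):
        rng = np.random.default_rng(2)
        x = np.linspace(0.05, 4.6, 12)
        fit = fit_alpha(
            _points_from_model(1e-3, x, population, 0.02, rng), population
        )
        grid = np.linspace(0.1, 4.0, 20)
        lo, hi = fit.ci_band(grid)
        assert np.all(lo <= fit.predict(grid)) and np.all(fit.predict(grid) <= hi)

    def test_all_zero_p_is_degenerate(self, population):
        pts = [
            AssayPoint(ppr=x * 0.65, ppr_star=x, f_end=None, p_active=0.0)
            for x in (0.5, 1.0, 2.0)
        ]
        with pytest.raises(DegenerateDataError):
            fit_alpha(pts, population)

    def test_too_few_points_rejected(self, population):
        pts = _points_from_model(1e-3, [1.0, 2.0], population)
        with pytest.raises(ValueError):
            fit_alpha(pts, population)
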