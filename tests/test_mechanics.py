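import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trogoscale import mechanics as mech
from trogoscale.mechanics import MechanicalParams


class TestEffectiveStress:
    def test_normalization_at_reference_density(self, default_params):
        assert mech.effective_stress(default_params.rho_ref, default_params) == pytest.approx(
            default_params.sigma_ref)

    def test_linearity(self, default_params):
        assert mech.effective_stress(2 * default_params.rho_ref, default_params) == pytest.approx(
            2 * default_params.sigma_ref)

    def test_half_reference(self):
        p = MechanicalParams(sigma_ref=100.0, rho_ref=400.0)
        assert mech.effective_stress(200.0, p) == pytest.approx(50.0)

    def test_negative_rho_rejected(self, default_params):
        with pytest.raises(ValueError):
            mech.effective_stress(-1.0, default_params)


class TestRMin:
    def test_upper_tension_gives_one_micron(self, default_params):
        # gamma = 0.1 mN/m, sigma_eff = 100 Pa -> 1 um
        assert mech.r_min(0.1, 400.0, default_params) == pytest.approx(1.0)

    def test_lower_tension_gives_tenth_micron(self, default_params):
        assert mech.r_min(0.01, 400.0, default_params) == pytest.approx(0.1)

    def test_zero_density_sentinel(self, default_params):
        assert mech.r_min(0.1, 0.0, default_params) == np.inf

    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_homogeneity_in_gamma_and_rho(self, c):
        p = MechanicalParams()
        base = mech.r_min(0.1, 400.0, p)
        assert mech.r_min(c * 0.1, 400.0, p) == pytest.approx(c * base, rel=1e-12)
        assert mech.r_min(0.1, c * 400.0, p) == pytest.approx(base / c, rel=1e-12)


class TestLBend:
    def test_cube_root_form(self):
        # kappa = 1e-19 J, sigma = 100 Pa -> (1e-21 m^3)^(1/3) = 0.1 um
        p = MechanicalParams(bending_stiffness=1e-19)
        assert mech.l_bend(p.rho_ref, p) == pytest.approx(0.1)

    def test_decreasing_in_rho(self, default_params):
        rhos = np.geomspace(50, 5000, 20)
        vals = mech.l_bend(rhos, default_params)
        assert np.all(np.diff(vals) < 0)

    def test_smaller_than_r_min_when_tension_dominates(self, default_params):
        # l_bend < R_min iff gamma > kappa^(1/3) * sigma_eff^(2/3), checked on a grid
        kappa = default_params.bending_stiffness
        for gamma in np.geomspace(0.01, 1.0, 8):      # mN/m
            for rho in np.geomspace(100, 4000, 8):
                sigma = mech.effective_stress(rho, default_params)
                lhs = gamma * 1e-3
                rhs = kappa ** (1 / 3) * sigma ** (2 / 3)
                smaller = mech.l_bend(rho, default_params) < mech.r_min(gamma, rho, default_params)
                assert smaller == (lhs > rhs)


class TestClassifyRegime:
    def test_below_floor_no_engagement(self, default_params):
        assert mech.classify_regime(0.1, 50.0, default_params) == "no_engagement"

    def test_low_tension_trogocytosis(self, default_params):
        # R_min = 0.5 um < R = 1 um
        assert mech.r_min(0.05, 400.0, default_params) == pytest.approx(0.5)
        assert mech.classify_regime(0.05, 400.0, default_params) == "trogocytosis"

    def test_high_tension_phagocytosis(self, default_params):
        assert mech.r_min(0.2, 400.0, default_params) == pytest.approx(2.0)
        assert mech.classify_regime(0.2, 400.0, default_params) == "phagocytosis"

    def test_boundary_is_phagocytosis(self, default_params):
        gamma_crit = mech.critical_tension(400.0, default_params)
        assert mech.classify_regime(gamma_crit, 400.0, default_params) == "phagocytosis"


class TestCriticalDensity:
    def test_linear_in_gamma(self, default_params):
        g = 0.07
        assert mech.critical_density(2 * g, default_params) == pytest.approx(
            2 * mech.critical_density(g, default_params), rel=1e-12)

    def test_reference_point(self, default_params):
        assert mech.critical_density(0.1, default_params) == pytest.approx(400.0)

    @pytest.mark.parametrize("gamma", [0.05, 0.1, 0.3, 1.0])
    def test_boundary_consistency(self, gamma, default_params):
        rho_c = mech.critical_density(gamma, default_params)
        if rho_c <= default_params.rho_min:
            pytest.skip("boundary below engagement floor")
        eps = 1e-9 * rho_c
        assert mech.classify_regime(gamma, rho_c + eps, default_params) == "trogocytosis"
        assert mech.classify_regime(gamma, rho_c - eps, default_params) == "phagocytosis"


class TestCriticalTension:
    def test_reference_point(self, default_params):
        # sigma_eff = 100 Pa, R = 1 um -> 0.1 mN/m
        assert mech.critical_tension(400.0, default_params) == pytest.approx(0.1)

    @given(gamma=st.floats(min_value=1e-3, max_value=10.0))
    def test_inverse_identity(self, gamma):
        p = MechanicalParams()
        rho = mech.critical_density(gamma, p)
        assert mech.critical_tension(rho, p) == pytest.approx(gamma, rel=1e-12)

    def test_monotone_in_rho_and_radius(self, default_params):
        rhos = np.geomspace(100, 4000, 10)
        assert np.all(np.diff(mech.critical_tension(rhos, default_params)) > 0)
        bigger = MechanicalParams(interface_radius=2.0)
        assert mech.critical_tension(400.0, bigger) > mech.critical_tension(
            400.0, default_params)


class TestPhaseDiagram:
    def test_grid_matches_pointwise_classification(self, default_params):
        gammas = np.geomspace(0.01, 1.0, 7)
        rhos = np.geomspace(20, 2000, 7)
        grid = mech.phase_diagram(gammas, rhos, default_params)
        assert len(grid) == 49
        for row in grid.itertuples(index=False):
            assert row.regime == mech.classify_regime(
                row.gamma_mN_per_m, row.rho_per_um2, default_params)

    def test_single_transition_along_gamma(self, default_params):
        gammas = np.geomspace(0.001, 10.0, 200)
        for rho in [150.0, 400.0, 1500.0]:
            grid = mech.phase_diagram(gammas, [rho], default_params)
            regimes = grid.sort_values("gamma_mN_per_m")["regime"].tolist()
            assert "no_engagement" not in regimes
            switches = sum(a != b for a, b in zip(regimes, regimes[1:]))
            assert switches == 1
            assert regimes[0] == "trogocytosis" and regimes[-1] == "phagocytosis"

    def test_boundary_curves(self, default_params):
        gammas = np.array([0.05, 0.1, 0.2])
        b = mech.boundary_curves(gammas, default_params)
        np.testing.assert_allclose(b["rho_crit_per_um2"],
                                   mech.critical_density(gammas, default_params))
        assert (b["rho_min_per_um2"] == default_params.rho_min).all()

    def test_empty_grid_rejected(self, default_params):
        with pytest.raises(ValueError):
            mech.phase_diagram([], [100.0], default_params)


class TestCompareBiteSizes:
    def test_exact_match(self):
        res = mech.compare_bite_sizes([1.0, 1.0, 1.0], 1.0)
        assert res.ratio == pytest.approx(1.0)
        assert res.within_order_of_magnitude

    def test_order_of_magnitude_violation(self):
        res = mech.compare_bite_sizes([12.0] * 10, 1.0)
        assert res.ratio == pytest.approx(12.0)
        assert not res.within_order_of_magnitude

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mech.compare_bite_sizes([], 1.0)


class TestCalibration:
    def test_switch_tension_calibration(self, default_params):
        p = mech.calibrate_to_switch_tension(1.0, 400.0, default_params)
        assert mech.critical_tension(400.0, p) == pytest.approx(1.0, rel=1e-12)
        # vesicle switch observations straddle the calibrated boundary
        assert mech.classify_regime(0.27, 400.0, p) == "trogocytosis"
        assert mech.classify_regime(3.68, 400.0, p) == "phagocytosis"

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MechanicalParams(sigma_ref=-1.0)
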