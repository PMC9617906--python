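import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from activegel.mechanics import (
    ElastomerParams,
    FluidLimitError,
    UnboundedGrowthError,
    classify_regime,
    critical_activity_ratio,
    free_energy,
    growth_rate_in_plane,
    growth_rate_out_of_plane,
    most_unstable_mode,
)

from conftest import brute_force_mode


def params(zeta=0.0, mu=0.0, kappa=0.0, K=0.0, gamma=1.0, nu=0.0):
    return ElastomerParams(zeta=zeta, mu=mu, kappa=kappa, K=K, gamma=gamma,
                           nu=nu)


class TestDispersionRelations:
    @pytest.mark.parametrize("zeta,mu,K,gamma,q,expected", [
        (2.0, 1.0, 1.0, 1.0, 1.0, 0.0),
        (5.0, 1.0, 2.0, 1.0, 0.0, 0.0),        # uniform translation neutral
        (2.0, 1.0, 1.0, 2.0, 1.0, 0.0),
        (3.0, 1.0, 1.0, 1.0, 1.0, 1.0),        # (3-1)*1 - 1
    ])
    def test_in_plane_values(self, zeta, mu, K, gamma, q, expected):
        p = params(zeta=zeta, mu=mu, K=K, gamma=gamma)
        assert growth_rate_in_plane(p, q) == pytest.approx(expected)

    @pytest.mark.parametrize("zeta,kappa,K,q,expected", [
        (2.0, 1.0, 1.0, 1.0, 0.0),
        (2.0, 1.0, 1.0, 0.5, 0.375),
        (0.0, 1.0, 1.0, 0.3, -(1.0 + 1.0) * 0.3 ** 4),
    ])
    def test_out_of_plane_values(self, zeta, kappa, K, q, expected):
        p = params(zeta=zeta, kappa=kappa, K=K)
        assert growth_rate_out_of_plane(p, q) == pytest.approx(expected)

    def test_passive_sheet_stable_at_all_q(self):
        p = params(zeta=0.0, mu=1.0, K=1.0)
        q = np.linspace(1e-3, 10.0, 500)
        assert np.all(growth_rate_in_plane(p, q) < 0)

    def test_in_plane_never_positive_below_critical_activity(self):
        # the critical activity for the bend instability is zeta* = mu
        q = np.linspace(1e-4, 50.0, 4000)
        for zeta, mu in [(0.5, 1.0), (1.0, 1.0), (3.0, 3.0), (0.0, 0.1)]:
            p = params(zeta=zeta, mu=mu, K=0.7)
            assert np.all(growth_rate_in_plane(p, q) <= 0)

    @given(st.floats(1e-3, 1e3), st.floats(1e-3, 1e2), st.floats(1e-3, 1e2))
    def test_out_of_plane_always_unstable_somewhere(self, zeta, kappa, K):
        # any non-zero activity destabilises some height mode
        p = params(zeta=zeta, kappa=kappa, K=K)
        q = math.sqrt(zeta / (2.0 * (K + kappa)))  # probe near the optimum
        assert growth_rate_out_of_plane(p, q) > 0

    def test_rejects_negative_and_nonfinite_q(self):
        p = params(zeta=1.0, K=1.0)
        with pytest.raises(ValueError):
            growth_rate_in_plane(p, -1.0)
        with pytest.raises(ValueError):
            growth_rate_out_of_plane(p, np.nan)


class TestMostUnstableMode:
    def test_in_plane_example(self):
        m = most_unstable_mode(params(zeta=2, mu=1, K=1), "in_plane")
        assert m.unstable
        assert m.q_star == pytest.approx(math.sqrt(0.5), rel=1e-12)
        assert m.sigma_star == pytest.approx(0.25, rel=1e-12)
        assert m.lambda_star * m.q_star == pytest.approx(2 * math.pi)

    def test_out_of_plane_example(self):
        m = most_unstable_mode(params(zeta=2, mu=1, kappa=1, K=1),
                               "out_of_plane")
        assert m.q_star == pytest.approx(math.sqrt(0.5), rel=1e-12)
        assert m.sigma_star == pytest.approx(0.5, rel=1e-12)

    def test_marginal_activity_is_stable(self):
        m = most_unstable_mode(params(zeta=1, mu=1, K=1), "in_plane")
        assert not m.unstable and m.sigma_star == 0.0

    def test_vanishing_stiffness_is_an_error(self):
        with pytest.raises(UnboundedGrowthError):
            most_unstable_mode(params(zeta=2, mu=1, K=0), "in_plane")
        with pytest.raises(UnboundedGrowthError):
            most_unstable_mode(params(zeta=2, kappa=0, K=0), "out_of_plane")

    def test_closed_form_matches_grid_argmax(self, rng):
        for _ in range(50):
            zeta = 10 ** rng.uniform(-1, 2)
            p = params(zeta=zeta, mu=zeta * rng.uniform(0.05, 0.95),
                       kappa=10 ** rng.uniform(-2, 2),
                       K=10 ** rng.uniform(-2, 2),
                       gamma=10 ** rng.uniform(-1, 1))
            for branch in ("in_plane", "out_of_plane"):
                q_bf, sig_bf = brute_force_mode(p, branch)
                m = most_unstable_mode(p, branch)
                assert m.q_star == pytest.approx(q_bf, rel=1e-4)
                assert m.sigma_star == pytest.approx(sig_bf, rel=1e-4)


class TestCriticalActivityRatio:
    @pytest.mark.parametrize("x,expected", [
        (3.0, 2.0),
        (1.0, 1.0 / (1.0 - 2 ** -0.5)),
        (math.inf, 1.0),
    ])
    def test_values(self, x, expected):
        assert critical_activity_ratio(x) == pytest.approx(expected,
                                                           rel=1e-12)

    def test_domain_errors(self):
        for bad in (0.0, -1.0, math.nan):
            with pytest.raises(ValueError):
                critical_activity_ratio(bad)

    def test_strictly_decreasing_and_above_one(self):
        x = np.geomspace(1e-3, 1e4, 300)
        r = np.array([critical_activity_ratio(v) for v in x])
        assert np.all(np.diff(r) < 0)
        assert np.all(r > 1.0)

    def test_matches_growth_rate_equality_bisection(self):
        # the boundary is where the two maximal growth rates coincide
        from scipy.optimize import brentq

        for x in np.geomspace(0.1, 100.0, 25):
            mu, K = 1.0, 1.0
            kappa = x * K

            def gap(zeta):
                sy = most_unstable_mode(
                    params(zeta=zeta, mu=mu, kappa=kappa, K=K),
                    "in_plane").sigma_star
                sh = most_unstable_mode(
                    params(zeta=zeta, mu=mu, kappa=kappa, K=K),
                    "out_of_plane").sigma_star
                return sy - sh

            root = brentq(gap, mu * (1 + 1e-9), 1e4, xtol=1e-13, rtol=1e-12)
            assert critical_activity_ratio(x) == pytest.approx(root / mu,
                                                               rel=1e-6)


class TestClassifyRegime:
    @pytest.mark.parametrize("zeta,mu,kappa,K,regime,direction", [
        (0.5, 1.0, 3.0, 1.0, "i_out_only", "out_of_plane"),
        (1.5, 1.0, 3.0, 1.0, "ii_out_faster", "out_of_plane"),
        (3.0, 1.0, 3.0, 1.0, "iii_in_faster", "in_plane"),
        (2.0, 1.0, 3.0, 1.0, "ii_out_faster", "out_of_plane"),  # boundary tie
        (5.0, 1.0, 0.0, 1.0, "ii_out_faster", "out_of_plane"),  # kappa -> 0
    ])
    def test_examples(self, zeta, mu, kappa, K, regime, direction):
        label = classify_regime(params(zeta=zeta, mu=mu, kappa=kappa, K=K))
        assert label.regime == regime
        assert label.direction == direction

    def test_regime_matches_growth_rate_comparison(self, rng):
        for _ in range(100):
            p = params(zeta=10 ** rng.uniform(-1, 2),
                       mu=10 ** rng.uniform(-2, 2),
                       kappa=10 ** rng.uniform(-2, 2),
                       K=10 ** rng.uniform(-2, 2))
            label = classify_regime(p)
            sy = most_unstable_mode(p, "in_plane").sigma_star
            sh = most_unstable_mode(p, "out_of_plane").sigma_star
            assert (label.direction == "in_plane") == (sy > sh)

    def test_friction_invariance(self, rng):
        for _ in range(20):
            kw = dict(zeta=10 ** rng.uniform(-1, 2), mu=1.0,
                      kappa=10 ** rng.uniform(-1, 1), K=1.0)
            ref = classify_regime(params(**kw, gamma=1.0))
            for c in (1e-3, 7.0, 1e4):
                assert classify_regime(params(**kw, gamma=c)) == ref

    def test_fluid_limit_error(self):
        with pytest.raises(FluidLimitError):
            classify_regime(params(zeta=1.0, mu=0.0, kappa=1.0, K=1.0))


class TestFreeEnergy:
    def grid(self, n=256, length=2 * math.pi):
        return np.arange(n) * (length / n)

    def field(self, x, u_y=None, h=None, u_x=None):
        from activegel.dynamics import DeformationField

        zero = np.zeros_like(x)
        return DeformationField(
            x=x, u_y=zero if u_y is None else u_y,
            h=zero if h is None else h, u_x=zero if u_x is None else u_x)

    def test_flat_state_has_zero_energy(self):
        x = self.grid()
        p = params(zeta=1, mu=2, kappa=3, K=4, nu=5)
        assert free_energy(self.field(x), p) == 0.0

    def test_in_plane_sine(self):
        x = self.grid()
        p = params(zeta=0, mu=1.0, kappa=2.0, K=1.0, nu=3.0)
        f = self.field(x, u_y=np.sin(x))
        assert free_energy(f, p) == pytest.approx(math.pi, rel=1e-10)

    def test_height_sine(self):
        x = self.grid()
        p = params(zeta=0, mu=5.0, kappa=1.0, K=1.0)
        f = self.field(x, h=np.sin(x))
        assert free_energy(f, p) == pytest.approx(math.pi, rel=1e-10)

    def test_nonnegative_for_random_fields(self, rng):
        x = self.grid(128, 37.0)
        p = params(zeta=9.0, mu=0.3, kappa=1.7, K=0.2, nu=0.9)
        for _ in range(10):
            f = self.field(x, u_y=rng.normal(size=128),
                           h=rng.normal(size=128), u_x=rng.normal(size=128))
            assert free_energy(f, p) >= 0.0

    def test_small_grid_rejected(self):
        x = np.arange(3) * 0.1
        with pytest.raises(ValueError):
            free_energy(self.field(x), params(zeta=0, mu=1, K=1))


class TestParamValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            params(zeta=-1.0)
        with pytest.raises(ValueError):
            params(zeta=1.0, mu=-0.5)
        with pytest.raises(ValueError):
            params(zeta=1.0, gamma=0.0)
        with pytest.raises(ValueError):
            params(zeta=math.inf)
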