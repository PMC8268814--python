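"""Mass-action equilibrium core: solver, derivative, cmc conventions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bilemic.exceptions import ValidationError
from bilemic.mass_action import (
    MassActionParams,
    cmc_from_params,
    equilibrium_state,
    monomer_concentration,
    monomer_derivative,
    params_from_cmc,
)


def bisection_oracle(s_total, n, K, iters=200):
    """Independent log-space bisection of s + nK s^n = s_total."""
    if s_total == 0:
        return 0.0
    log_nk = math.log(n) + math.log(K)
    hi = min(math.log(s_total), (math.log(s_total) - log_nk) / n)
    lo = hi - 800.0

    def f(u):
        return math.exp(u) + math.exp(log_nk + n * u) - s_total

    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return math.exp(0.5 * (lo + hi))


class TestMonomerConcentration:
    @pytest.mark.parametrize(
        "n,K,s_total,expected",
        [
            (2.0, 1.0, 1.0, 0.5),       # closed form: root of 2s^2 + s - 1
            (7.0, 3.3, 0.0, 0.0),       # empty system
            (5.0, 1e-300, 5.0, 5.0),    # K -> 0: monomers only
        ],
    )
    def test_reference_values(self, n, K, s_total, expected):
        s = monomer_concentration(s_total, MassActionParams(n, K))
        assert s == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_matches_bisection_oracle_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            n = rng.uniform(2.0, 60.0)
            K = 10.0 ** rng.uniform(-3.0, 30.0)
            s_total = 10.0 ** rng.uniform(-3.0, 3.0)
            p = MassActionParams(n, K)
            s = monomer_concentration(s_total, p)
            assert s == pytest.approx(bisection_oracle(s_total, n, K), rel=1e-9)
            # mass-balance residual, relative to the total
            resid = abs(s + n * K * math.exp(n * math.log(s)) - s_total)
            assert resid <= 1e-10 * s_total

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n=st.floats(2.0, 40.0),
        logk=st.floats(-3.0, 12.0),
        a=st.floats(1e-3, 50.0),
        b=st.floats(1e-3, 50.0),
    )
    def test_monotone_in_total_concentration(self, n, logk, a, b):
        p = MassActionParams(n, 10.0**logk)
        lo, hi = sorted((a, b))
        assert monomer_concentration(lo, p) <= monomer_concentration(hi, p) + 1e-15

    def test_negative_total_rejected(self):
        with pytest.raises(ValidationError):
            monomer_concentration(-1.0, MassActionParams(3, 1.0))


class TestMonomerDerivative:
    @pytest.mark.parametrize(
        "n,K,s,expected",
        [
            (2.0, 1.0, 0.5, 1.0 / 3.0),     # 1/(1 + 4*1*0.5)
            (3.0, 1e-300, 2.0, 1.0),        # K -> 0: ds/dStot -> 1
            (10.0, 0.09, 1.0, 0.1),         # n^2 K s^(n-1) = 9
        ],
    )
    def test_reference_values(self, n, K, s, expected):
        assert monomer_derivative(s, MassActionParams(n, K)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_matches_finite_difference_of_solver(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = rng.uniform(2.5, 30.0)
            K = 10.0 ** rng.uniform(-2.0, 8.0)
            p = MassActionParams(n, K)
            s_total = 10.0 ** rng.uniform(-2.0, 2.0)
            h = 1e-6 * s_total
            fd = (
                monomer_concentration(s_total + h, p)
                - monomer_concentration(s_total - h, p)
            ) / (2.0 * h)
            s = monomer_concentration(s_total, p)
            assert monomer_derivative(s, p) == pytest.approx(fd, rel=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        n=st.floats(2.0, 40.0),
        logk=st.floats(-3.0, 15.0),
        logst=st.floats(-2.5, 2.5),
    )
    def test_log_derivative_identity(self, n, logk, logst):
        """d ln{(ds/dStot)^-1 - 1}/d ln Stot == (n-1)/n + ((n-1)^2/n) ds/dStot.

        The analytic left side is (n-1) * (Stot/s) * ds/dStot; this exact
        identity is the foundation of the enthalpogram linearization.
        """
        p = MassActionParams(n, 10.0**logk)
        s_total = 10.0**logst
        s = monomer_concentration(s_total, p)
        u = monomer_derivative(s, p)
        lhs = (n - 1.0) * (s_total / s) * u
        rhs = (n - 1.0) / n + (n - 1.0) ** 2 / n * u
        assert lhs == pytest.approx(rhs, rel=1e-6, abs=1e-9)

    def test_state_bundle_invariants(self):
        st_ = equilibrium_state(2.0, MassActionParams(8, 30.0))
        assert 0.0 <= st_.s_monomer <= st_.s_total
        assert 0.0 <= st_.micellar_fraction < 1.0
        assert 0.0 < st_.ds_dstot <= 1.0


class TestCmcConventions:
    @pytest.mark.parametrize("n,cmc", [(10.0, 0.44), (10.0, 0.182), (6.16, 0.323)])
    def test_round_trip(self, n, cmc):
        p = params_from_cmc(n, cmc)
        assert cmc_from_params(p) == pytest.approx(cmc, rel=1e-6)

    def test_mole_fraction_convention_round_trip(self):
        p = params_from_cmc(10.0, 0.44, convention="mole_fraction")
        assert cmc_from_params(p, convention="mole_fraction") == pytest.approx(
            0.44, rel=1e-9
        )

    def test_larger_k_gives_smaller_cmc(self):
        c1 = cmc_from_params(MassActionParams(10, 1e8))
        c2 = cmc_from_params(MassActionParams(10, 1e10))
        assert c2 < c1

    def test_matches_numeric_inflection_search(self):
        """Grid + finite-difference location of extremal d2[S]/dStot2 agrees
        with the closed-form criterion."""
        p = params_from_cmc(10.0, 0.45)
        grid = np.geomspace(0.01, 10.0, 4001)
        s = monomer_concentration(grid, p)
        u = monomer_derivative(s, p)
        dudc = np.gradient(u, grid)
        numeric = grid[int(np.argmin(dudc))]
        assert numeric == pytest.approx(cmc_from_params(p), rel=1e-2)

    def test_flat_criterion_at_n_two_reported(self):
        with pytest.raises(ValidationError):
            cmc_from_params(MassActionParams(2.0, 5.0))
        with pytest.raises(ValidationError):
            params_from_cmc(2.0, 0.4)


@pytest.mark.parametrize("n,K", [(1.5, 1.0), (5.0, -1.0), (float("nan"), 1.0)])
def test_invalid_params_rejected(n, K):
    with pytest.raises(ValidationError):
        MassActionParams(n, K)
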