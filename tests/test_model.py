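"""Unit and property tests for the ODE right-hand sides and integrator."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import violencedyn as vd
from violencedyn.model import NEG_FLOOR


def rational_rhs(state, p, gamma_F=None, delta_A=None):
    """Independent oracle: evaluate the model algebra in exact rationals.

    Every float is converted exactly (Fraction(float) is lossless), the
    four compartment balances are evaluated symbolically and returned as
    floats; shares no code with the package kernel.
    """
    gF = Fraction(p.gamma_F if gamma_F is None else gamma_F)
    dA_rate = Fraction(p.delta_A if delta_A is None else delta_A)
    A, S, VM, VF = (Fraction(x) for x in (state.A, state.S, state.V_M, state.V_F))
    rA, kA, rS, kS = (Fraction(x) for x in (p.r_A, p.k_A, p.r_S, p.k_S))
    bF, bM, aF, aM = (Fraction(x) for x in (p.beta_F, p.beta_M, p.alpha_F, p.alpha_M))
    dA = rA * A * (1 - A / kA) - dA_rate * A
    dS = rS * S * (1 - S / kS) - (bM + bF) * A * S + gF * VF + dA_rate * A
    dVM = bM * A * S - aM * VM
    dVF = bF * A * S - aF * VF - gF * VF
    return np.array([float(dA), float(dS), float(dVM), float(dVF)])


def random_params(rng) -> vd.ModelParams:
    return vd.ModelParams(
        r_A=rng.uniform(0.01, 1.0), k_A=rng.uniform(1.0, 50.0),
        r_S=rng.uniform(0.01, 1.0), k_S=rng.uniform(1.0, 100.0),
        beta_F=10 ** rng.uniform(-7, -3), beta_M=10 ** rng.uniform(-7, -3),
        alpha_F=rng.uniform(0.01, 1.0), alpha_M=rng.uniform(0.01, 1.0),
        gamma_F=rng.uniform(0, 1.0), delta_A=rng.uniform(0, 0.5),
    )


def random_state(rng) -> vd.StateVec:
    return vd.StateVec(rng.uniform(0, 50), rng.uniform(0, 100),
                       rng.uniform(0, 1), rng.uniform(0, 1))


class TestRhs:
    def test_origin_is_fixed_point(self, family_params):
        zero = vd.StateVec(0, 0, 0, 0)
        for rhs in (vd.base_rhs, vd.female_recovery_rhs, vd.complete_recovery_rhs):
            assert np.all(rhs(zero, family_params.replace(gamma_F=0.3, delta_A=0.1)) == 0)

    def test_aggressor_logistic_equilibrium(self, family_params):
        state = vd.StateVec(family_params.k_A, 10.0, 0.1, 0.1)
        assert vd.base_rhs(state, family_params)[0] == 0.0

    def test_victims_decay_without_contact(self, family_params):
        p = family_params.replace(beta_F=0.0, beta_M=0.0)
        state = vd.StateVec(5.0, 10.0, 0.4, 0.7)
        d = vd.base_rhs(state, p)
        assert d[2] == pytest.approx(-p.alpha_M * 0.4, rel=1e-14)
        assert d[3] == pytest.approx(-p.alpha_F * 0.7, rel=1e-14)

    def test_base_rhs_against_rational_oracle(self, family_params):
        # state on the saturation manifold: A at capacity, S at its
        # steady state, victims near their published saturation levels
        state = vd.StateVec(30.325876, 60.65, 0.009988, 0.145262)
        got = vd.base_rhs(state, family_params)
        expected = rational_rhs(state, family_params, gamma_F=0, delta_A=0)
        # dS suffers catastrophic cancellation (~5e-7 from terms ~5e-2),
        # so the check needs an absolute floor at the term round-off scale
        np.testing.assert_allclose(got, expected, rtol=1e-9, atol=1e-15)
        # frozen values from exact rational arithmetic on the decimal strings
        np.testing.assert_allclose(
            expected,
            [0.0, 5.255001817506136e-07, -9.16274698e-05, 6.062798752e-04],
            rtol=1e-9, atol=1e-15,
        )
        # dV_F/dt is near zero: the state sits close to the equilibrium
        assert abs(got[3]) < 1e-3

    def test_female_recovery_rhs_on_2020_state(self, family_params):
        """Recovery derivative at the 2020 point of the model trajectory."""
        state0 = vd.StateVec(22.468, 44.936, 0.002395, 0.016240)
        grid = vd.TimeGrid.annual(2010, 2020)
        state_2020 = vd.StateVec.from_array(
            vd.integrate("base", state0, family_params, grid).iloc[-1].to_numpy()
        )
        p = family_params.replace(gamma_F=0.5)
        got = vd.female_recovery_rhs(state_2020, p)
        np.testing.assert_allclose(got, rational_rhs(state_2020, p, delta_A=0),
                                   rtol=1e-12, atol=1e-18)

    def test_recovery_terms_cancel_in_column_sums(self, family_params):
        """gamma_F and delta_A only transfer mass between compartments."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            p = random_params(rng)
            s = random_state(rng)
            base = vd.base_rhs(s, p)
            fem = vd.female_recovery_rhs(s, p)
            comp = vd.complete_recovery_rhs(s, p)
            assert fem[1] + fem[3] == pytest.approx(base[1] + base[3], abs=1e-15, rel=1e-12)
            assert comp[0] + comp[1] + comp[3] == pytest.approx(
                base[0] + base[1] + base[3], abs=1e-15, rel=1e-12)

    def test_reduction_chain_exact(self):
        """With zero recovery rates all three systems coincide exactly."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            p = random_params(rng).replace(gamma_F=0.0, delta_A=0.0)
            s = random_state(rng)
            b = vd.base_rhs(s, p)
            assert np.array_equal(vd.female_recovery_rhs(s, p), b)
            assert np.array_equal(vd.complete_recovery_rhs(s, p), b)

    def test_rehabilitation_dominates_growth(self, family_params):
        """delta_A >= r_A drives aggressors down from any positive level."""
        p = family_params.replace(delta_A=family_params.r_A * 1.5)
        for a in np.linspace(1e-6, p.k_A, 50):
            d = vd.complete_recovery_rhs(vd.StateVec(a, 1.0, 0.0, 0.0), p)
            assert d[0] < 0

    def test_negative_state_rejected(self, family_params):
        with pytest.raises(ValueError):
            vd.StateVec(-1.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            vd.base_rhs(vd.StateVec.from_array(np.array([0, 1, 0, 0.0])),
                        family_params.replace(r_A=np.nan))


class TestClosedForm:
    def test_fixed_point_and_limit(self, family_params):
        p = family_params
        assert vd.aggressor_closed_form(p.k_A, p, 17.0) == pytest.approx(p.k_A, rel=1e-14)
        t_long = 10.0 / p.r_A * np.log(1e6)
        assert vd.aggressor_closed_form(1.0, p, t_long) == pytest.approx(p.k_A, rel=1e-9)
        t = np.linspace(0, 200, 50)
        vals = vd.aggressor_closed_form(1.0, p, t)
        assert np.all(np.diff(vals) > 0) and np.all(vals < p.k_A)

    def test_edge_cases(self, family_params):
        assert vd.aggressor_closed_form(0.0, family_params, 5.0) == 0.0
        with pytest.raises(ValueError):
            vd.aggressor_closed_form(-1.0, family_params, 5.0)
        with pytest.raises(ValueError):
            vd.aggressor_closed_form(1.0, family_params.replace(delta_A=0.1), 5.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a0=st.floats(0.01, 60.0), t=st.floats(0.0, 100.0))
    def test_monotone_toward_capacity(self, family_params, a0, t):
        """A(t) stays between A0 and k_A and moves toward the capacity."""
        p = family_params
        val = vd.aggressor_closed_form(a0, p, t)
        lo, hi = min(a0, p.k_A), max(a0, p.k_A)
        assert lo - 1e-12 <= val <= hi + 1e-12


class TestIntegrate:
    def test_constant_at_fixed_point(self, family_params):
        rep = vd.recovery_equilibrium(family_params)
        grid = vd.TimeGrid.annual(2010, 2030)
        traj = vd.integrate("base", rep.state, family_params, grid)
        np.testing.assert_allclose(traj.to_numpy(),
                                   np.tile(rep.state.to_array(), (len(grid.times), 1)),
                                   rtol=1e-8, atol=1e-12)

    def test_matches_logistic_closed_form(self, family_params):
        state0 = vd.StateVec(22.468, 44.936, 0.002395, 0.016240)
        grid = vd.TimeGrid.annual(2010, 2034)
        traj = vd.integrate("base", state0, family_params, grid)
        expected = vd.aggressor_closed_form(
            state0.A, family_params, np.asarray(grid.times) - 2010.0)
        np.testing.assert_allclose(traj["A"].to_numpy(), expected, rtol=1e-8)

    def test_self_convergence_under_tolerance_halving(self, family_params):
        state0 = vd.StateVec(22.468, 44.936, 0.002395, 0.016240)
        grid = vd.TimeGrid.annual(2010, 2034)
        rtol = 1e-8
        coarse = vd.integrate("base", state0, family_params, grid, rtol=rtol, atol=1e-10)
        fine = vd.integrate("base", state0, family_params, grid, rtol=rtol / 2, atol=5e-11)
        diff = np.abs(coarse.to_numpy() - fine.to_numpy())
        scale = np.abs(fine.to_numpy()) + 1e-10
        assert np.max(diff / scale) < 10 * rtol

    def test_forward_invariance_random_draws(self):
        """Trajectories stay (numerically) nonnegative from random starts."""
        rng = np.random.default_rng(7)
        grid = vd.TimeGrid.fine(0.0, 20.0, 1.0)
        for _ in range(100):
            p = random_params(rng)
            s = random_state(rng)
            traj = vd.integrate("complete_recovery", s, p, grid,
                                rtol=1e-8, atol=1e-10)
            assert traj.to_numpy().min() >= -NEG_FLOOR

    def test_aggressor_monotonicity(self, family_params):
        grid = vd.TimeGrid.fine(0.0, 100.0, 0.5)
        for a0, sign in ((1.0, 1), (50.0, -1)):
            traj = vd.integrate("base", vd.StateVec(a0, 1.0, 0.0, 0.0),
                                family_params, grid)
            assert np.all(sign * np.diff(traj["A"].to_numpy()) >= -1e-12)

    def test_unknown_variant_rejected(self, family_params):
        with pytest.raises(ValueError, match="unknown rhs"):
            vd.integrate("sir", vd.StateVec(1, 1, 0, 0), family_params,
                         vd.TimeGrid.annual(0, 1))


class TestTimeGridAndParams:
    def test_grid_validation(self):
        with pytest.raises(ValueError):
            vd.TimeGrid(t0=2010, times=(2009.0,))
        with pytest.raises(ValueError):
            vd.TimeGrid(t0=2010, times=(2010.0, 2010.0))
        grid = vd.TimeGrid.annual(2010, 2023)
        assert len(grid.times) == 14

    def test_params_validation_and_io(self, tmp_path, family_params):
        with pytest.raises(ValueError):
            family_params.replace(alpha_F=-0.1)
        with pytest.raises(ValueError):
            vd.ModelParams.from_mapping({"r_A": 1.0, "bogus": 2.0})
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            family_params.to_file(path)
            assert vd.ModelParams.from_file(path) == family_params

    def test_trajectory_csv_roundtrip(self, tmp_path, family_params):
        import pandas as pd
        grid = vd.TimeGrid.annual(2010, 2015)
        traj = vd.integrate("base", vd.StateVec(22.0, 44.0, 0.002, 0.016),
                            family_params, grid)
        path = tmp_path / "traj.csv"
        vd.trajectory_to_csv(traj, path)
        back = pd.read_csv(path, index_col="year")
        assert list(back.columns) == ["A", "S", "V_M", "V_F"]
        np.testing.assert_allclose(back.to_numpy(), traj.to_numpy(), rtol=1e-5)
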