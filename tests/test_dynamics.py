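"""Mass-action dynamics against closed forms and conservation identities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import fsolve

from bclswitch.dynamics import (
    CompiledModel,
    SimulationError,
    mac_abundance,
    simulate,
    steady_state,
    time_derivative,
)
from bclswitch.network import (
    build_toy_network,
    initial_state,
    monomer_weights,
)


def total_production(net, params):
    return sum(params[s.production_param] for s in net.produced_species)


class TestTimeDerivative:
    def test_zero_state_gives_pure_production(self, net, params):
        dx = time_derivative(np.zeros(len(net.species)), net, params)
        for i, s in enumerate(net.species):
            expected = params[s.production_param] if s.produced else 0.0
            assert dx[i] == pytest.approx(expected)

    def test_dimension_mismatch(self, net, params):
        with pytest.raises(SimulationError):
            time_derivative(np.zeros(3), net, params)

    def test_bax_derivative_matches_hand_expansion(self, net, params, rng):
        """Free Bax only enters production, degradation and the two
        catalytic activations, so dBax/dt = kpBax - (kdeg + ka*(tBid+Bim))*Bax."""
        x = rng.uniform(0.0, 50.0, len(net.species))
        dx = time_derivative(x, net, params)
        i = net.index
        bax, tbid, bim = x[i("Bax")], x[i("tBid")], x[i("Bim")]
        hand = params["kpBax"] - (params["kdeg"] + params["ka"] * (tbid + bim)) * bax
        assert dx[i("Bax")] == pytest.approx(hand, rel=1e-12)

    def test_mcl1_derivative_matches_hand_expansion(self, net, params, rng):
        """Mcl-1 binds Puma/Bim (strong), Noxa (intermediate) and the two
        activated effectors (strong), each complex dissociating at km."""
        x = rng.uniform(0.0, 50.0, len(net.species))
        dx = time_derivative(x, net, params)
        i = net.index
        ks, ki, km = params["ks"], params["ki"], params["km"]
        mcl1 = x[i("Mcl1")]
        on = mcl1 * (
            ks * (x[i("Puma")] + x[i("Bim")] + x[i("aBax")] + x[i("aBak")])
            + ki * x[i("Noxa")]
        )
        off = km * sum(
            x[i(f"Mcl1~{p}")] for p in ("Puma", "Bim", "Noxa", "aBax", "aBak")
        )
        hand = params["kpMcl1"] - params["kdeg"] * mcl1 - on + off
        assert dx[i("Mcl1")] == pytest.approx(hand, rel=1e-12)

    def test_analytic_jacobian_matches_finite_differences(self, net, params, rng):
        model = CompiledModel(net, params)
        x = rng.uniform(0.5, 30.0, len(net.species))
        J = model.jacobian(x)
        eps = 1e-6
        for col in rng.choice(len(x), size=6, replace=False):
            dx = np.zeros_like(x)
            dx[col] = eps
            fd = (model.rhs(x + dx) - model.rhs(x - dx)) / (2 * eps)
            assert np.allclose(J[:, col], fd, rtol=1e-5, atol=1e-7)


class TestToyClosedForms:
    def test_production_degradation_trajectory(self):
        toy, p = build_toy_network("production_degradation")
        kp, kdeg = p["kpA"], p["kdeg"]
        traj = simulate(toy, p, np.zeros(1), t_end=40.0, n_points=80)
        expected = (kp / kdeg) * (1.0 - np.exp(-kdeg * traj.times))
        assert np.allclose(traj.states[:, 0], expected, rtol=1e-6, atol=1e-8)

    def test_production_degradation_steady_state(self):
        toy, p = build_toy_network("production_degradation")
        ss = steady_state(toy, p, np.zeros(1))
        assert ss.converged and ss.stable
        assert ss.state[0] == pytest.approx(p["kpA"] / p["kdeg"], rel=1e-9)

    def test_single_binding_matches_algebraic_root(self):
        toy, p = build_toy_network("single_binding")
        kf, km, kdeg = p["kf"], p["km"], p["kdeg"]
        kpA, kpB = p["kpA"], p["kpB"]

        def equations(v):  # independently written steady-state algebra
            A, B, C = v
            return [
                kpA - kdeg * A - kf * A * B + km * C,
                kpB - kdeg * B - kf * A * B + km * C,
                kf * A * B - (km + kdeg) * C,
            ]

        oracle = fsolve(equations, [kpA / kdeg, kpB / kdeg, 0.0], full_output=False)
        ss = steady_state(toy, p, initial_state(toy, p))
        assert ss.converged
        assert np.allclose(ss.state, oracle, rtol=1e-8)

    def test_single_binding_equilibrium_is_stationary(self):
        toy, p = build_toy_network("single_binding")
        ss = steady_state(toy, p, initial_state(toy, p))
        dx = time_derivative(ss.state, toy, p)
        assert np.abs(dx).max() < 1e-6

    def test_activation_dimerization_matches_root_search(self):
        toy, p = build_toy_network("activation_dimerization")
        ka, kd, km, kdeg = p["ka"], p["kd"], p["km"], p["kdeg"]
        kpT, kpB = p["kpT"], p["kpB"]

        def equations(v):
            T, B, aB, D = v
            return [
                kpT - kdeg * T,
                kpB - kdeg * B - ka * T * B,
                ka * T * B - kdeg * aB - 2 * kd * aB**2 + 2 * km * D,
                kd * aB**2 - (km + kdeg) * D,
            ]

        oracle = fsolve(equations, [10.0, 10.0, 1.0, 1.0])
        ss = steady_state(toy, p, initial_state(toy, p))
        assert ss.converged
        assert np.allclose(ss.state, oracle, rtol=1e-7)


class TestSteadyStateProtocol:
    def test_default_model_converges_from_initial_state(self, net, params, model):
        ss = steady_state(net, params, initial_state(net, params), model=model)
        assert ss.converged and ss.stable
        assert ss.residual <= model.default_tolerance()

    def test_branch_consistency(self, net, params, model):
        """Re-solving from a converged state reproduces it."""
        ss = steady_state(net, params, initial_state(net, params), model=model)
        again = steady_state(net, params, ss.state, model=model)
        assert np.allclose(again.state, ss.state, rtol=1e-6, atol=1e-6)

    def test_monomer_balance_at_default(self, net, params, model):
        ss = steady_state(net, params, initial_state(net, params), model=model)
        w = monomer_weights(net)
        expected = total_production(net, params) / params["kdeg"]
        assert w @ ss.state == pytest.approx(expected, rel=1e-6)

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.2, max_value=5.0), min_size=16, max_size=16
        )
    )
    def test_monomer_balance_under_random_production(self, net, params, model, qs):
        """sum(w*x) = sum(kp)/kdeg at any converged steady state."""
        names = [s.production_param for s in net.produced_species]
        p = params.updated(**{n: params[n] * q for n, q in zip(names, qs)})
        m = model.with_params(p)
        ss = steady_state(net, p, initial_state(net, p), model=m)
        if not ss.converged:
            return
        w = monomer_weights(net)
        assert w @ ss.state == pytest.approx(
            total_production(net, p) / p["kdeg"], rel=1e-6
        )

    def test_trajectory_monomer_total_obeys_closed_form(self, net, params, model):
        """The monomer-weighted total follows dM/dt = sum(kp) - kdeg*M."""
        x0 = initial_state(net, params)
        traj = simulate(net, params, x0, t_end=30.0, n_points=60, model=model)
        w = monomer_weights(net)
        M = traj.states @ w
        kdeg = params["kdeg"]
        Minf = total_production(net, params) / kdeg
        M0 = w @ x0
        expected = Minf + (M0 - Minf) * np.exp(-kdeg * traj.times)
        assert np.allclose(M, expected, rtol=1e-6)

    def test_nonnegativity_along_trajectory(self, net, params, model):
        traj = simulate(net, params, initial_state(net, params), t_end=200.0, model=model)
        assert traj.states.min() >= 0.0

    def test_bad_t_end_rejected(self, net, params):
        with pytest.raises(SimulationError):
            simulate(net, params, initial_state(net, params), t_end=0.0)


class TestMacReadout:
    def test_sum_of_three_dimers(self, net):
        x = np.zeros(len(net.species))
        x[net.index("aBax~aBax")] = 100.0
        x[net.index("aBak~aBak")] = 200.0
        x[net.index("aBax~aBak")] = 50.0
        x[net.index("Bax")] = 777.0  # monomers do not count
        assert mac_abundance(net, x) == pytest.approx(350.0)

    def test_zero_state(self, net):
        assert mac_abundance(net, np.zeros(len(net.species))) == 0.0

    def test_monomers_only(self, net, params):
        x0 = initial_state(net, params)
        assert mac_abundance(net, x0) == 0.0
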