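"""Mass-action dynamics: time derivative, stiff integration, steady states.

The network is compiled once into flat arrays (per-channel rate constants,
reactant indices, stoichiometry), after which the right-hand side and the
analytic Jacobian are plain numpy expressions.  Deterministic concentration
semantics are used throughout: the homodimerization flux is kd*x^2, not the
combinatorial x(x-1)/2.

The steady-state protocol integrates in exponentially growing time chunks
until the residual max|dx/dt| falls below a scale-aware tolerance (default
1e-9 times the total monomer pool sum(kp)/kdeg), with a Newton polish
attempted once the integrator is close; integration rather than root search
alone guarantees the *attracting* branch is found, which is what the
hysteresis sweeps rely on.  Stability is classified from the eigenvalues of
the analytic Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import root

from .network import (
    RateParams,
    ReactionNetwork,
    expand_channels,
    monomer_weights,
    stoichiometry,
)

__all__ = [
    "CompiledModel",
    "SteadyState",
    "Trajectory",
    "time_derivative",
    "simulate",
    "steady_state",
    "mac_abundance",
    "MAC_DIMERS",
    "SimulationError",
]

#: The MAC readout: activated-effector dimer species.
MAC_DIMERS = ("aBax~aBax", "aBak~aBak", "aBax~aBak")

#: Integration cap for steady-state searches, hours.
T_MAX = 1.0e4

#: Entries more negative than this are treated as solver failures rather
#: than roundoff; anything in (-NEGATIVITY_TOL, 0) is clamped to zero.
NEGATIVITY_TOL = 1.0e-9


class SimulationError(RuntimeError):
    """Integrator or root-finder failure with diagnostics."""


class CompiledModel:
    """A network + parameter set flattened for fast evaluation.

    Production rates can be swapped cheaply via :meth:`with_params`, reusing
    the structural arrays (used heavily by the Monte-Carlo driver).
    """

    def __init__(self, net: ReactionNetwork, params: RateParams):
        self.net = net
        self.params = params
        self.n_species = len(net.species)
        channels = expand_channels(net)
        self.rate_names = tuple(c.rate_name for c in channels)
        self.S = stoichiometry(net)
        self._ST = np.ascontiguousarray(self.S.T)
        n_ch = len(channels)
        r1 = np.zeros(n_ch, dtype=np.intp)
        r2 = np.zeros(n_ch, dtype=np.intp)
        has1 = np.zeros(n_ch, dtype=bool)
        has2 = np.zeros(n_ch, dtype=bool)
        for j, c in enumerate(channels):
            if len(c.reactant_indices) >= 1:
                r1[j], has1[j] = c.reactant_indices[0], True
            if len(c.reactant_indices) >= 2:
                r2[j], has2[j] = c.reactant_indices[1], True
        self._r1, self._r2, self._has1, self._has2 = r1, r2, has1, has2
        self._rows = np.arange(n_ch)
        self.rates = np.array([params[name] for name in self.rate_names])
        self._mac_idx = np.array(
            [i for i, s in enumerate(net.species) if s.name in MAC_DIMERS], dtype=np.intp
        )
        self.monomer_weights = monomer_weights(net)

    def with_params(self, params: RateParams) -> "CompiledModel":
        clone = object.__new__(CompiledModel)
        clone.__dict__.update(self.__dict__)
        clone.params = params
        clone.rates = np.array([params[name] for name in self.rate_names])
        return clone

    # -- core evaluations ---------------------------------------------
    def fluxes(self, x: np.ndarray) -> np.ndarray:
        f1 = np.where(self._has1, x[self._r1], 1.0)
        f2 = np.where(self._has2, x[self._r2], 1.0)
        return self.rates * f1 * f2

    def rhs(self, x: np.ndarray) -> np.ndarray:
        return self.fluxes(x) @ self._ST

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        f1 = np.where(self._has1, x[self._r1], 1.0)
        f2 = np.where(self._has2, x[self._r2], 1.0)
        dv = np.zeros((len(self.rates), self.n_species))
        m1, m2 = self._has1, self._has2
        np.add.at(dv, (self._rows[m1], self._r1[m1]), (self.rates * f2)[m1])
        np.add.at(dv, (self._rows[m2], self._r2[m2]), (self.rates * f1)[m2])
        return self.S @ dv

    def mac(self, x: np.ndarray) -> float:
        return float(x[self._mac_idx].sum())

    def production_total(self) -> float:
        return float(sum(self.params[s.production_param] for s in self.net.produced_species))

    def default_tolerance(self) -> float:
        """Scale-aware residual tolerance: 1e-9 of the monomer pool."""
        return 1.0e-9 * self.production_total() / self.params["kdeg"]


def time_derivative(
    state: np.ndarray, net: ReactionNetwork, params: RateParams
) -> np.ndarray:
    """dx/dt = S.v(x) for the given abundances (molecules per volume, h^-1)."""
    state = np.asarray(state, dtype=float)
    if state.shape != (len(net.species),):
        raise SimulationError(
            f"state has shape {state.shape}, expected ({len(net.species)},)"
        )
    return CompiledModel(net, params).rhs(state)


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    species: tuple[str, ...]

    def final(self) -> np.ndarray:
        return self.states[-1]


@dataclass
class SteadyState:
    state: np.ndarray
    residual: float
    stable: bool
    converged: bool
    t_elapsed: float
    polish_used: bool = False

    def __post_init__(self) -> None:
        if self.converged and not np.isfinite(self.residual):
            raise SimulationError("converged steady state with non-finite residual")


def _clamp(x: np.ndarray) -> np.ndarray:
    if x.min() < -NEGATIVITY_TOL * max(1.0, float(np.abs(x).max())):
        raise SimulationError(
            f"integrator produced significantly negative abundance (min={x.min():.3e})"
        )
    return np.maximum(x, 0.0)


def _integrate(model: CompiledModel, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    sol, info = odeint(
        lambda x, t: model.rhs(x),
        x0,
        times,
        Dfun=lambda x, t: model.jacobian(x),
        rtol=1.0e-8,
        atol=1.0e-8,
        mxstep=50000,
        full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise SimulationError(f"stiff integration failed: {info['message']}")
    if not np.all(np.isfinite(sol)):
        raise SimulationError("integration produced non-finite values")
    return sol


def simulate(
    net: ReactionNetwork,
    params: RateParams,
    x0: np.ndarray,
    t_end: float,
    n_points: int = 200,
    model: CompiledModel | None = None,
) -> Trajectory:
    """Integrate the mass-action ODE from ``x0`` over [0, t_end] hours."""
    if t_end <= 0:
        raise SimulationError("t_end must be positive")
    model = model if model is not None else CompiledModel(net, params)
    times = np.linspace(0.0, t_end, max(2, n_points))
    sol = _integrate(model, np.asarray(x0, dtype=float), times)
    sol = np.maximum(sol, 0.0)
    return Trajectory(times=times, states=sol, species=net.species_names)


def _try_polish(model: CompiledModel, x: np.ndarray, tol: float) -> np.ndarray | None:
    """Newton polish near the attractor; rejected if it strays or goes negative."""
    sol = root(model.rhs, x, jac=model.jacobian, method="hybr", tol=tol * 1e-3)
    if not sol.success:
        return None
    xn = sol.x
    scale = max(1.0, float(np.abs(x).max()))
    if xn.min() < -NEGATIVITY_TOL * scale:
        return None
    if np.abs(xn - x).max() > 0.05 * scale + 1.0:
        return None  # moved too far: might have left the attracting branch
    xn = np.maximum(xn, 0.0)
    if np.abs(model.rhs(xn)).max() > tol:
        return None
    return xn


def steady_state(
    net: ReactionNetwork,
    params: RateParams,
    x0: np.ndarray,
    tol: float | None = None,
    model: CompiledModel | None = None,
    t_max: float = T_MAX,
    polish: bool = True,
) -> SteadyState:
    """Attracting steady state reached from ``x0``.

    Integrates in chunks growing by 2.5x from 50 h until max|dx/dt| <= tol
    or the time cap; ``x0`` selects the branch in bistable regimes.  On
    non-convergence the last state is returned with ``converged=False``.
    """
    model = model if model is not None else CompiledModel(net, params)
    if tol is None:
        tol = model.default_tolerance()
    if tol <= 0:
        raise SimulationError("tolerance must be positive")
    x = _clamp(np.asarray(x0, dtype=float).copy())
    t, chunk = 0.0, 50.0
    polish_used = False
    while True:
        sol = _integrate(model, x, np.array([0.0, chunk]))
        x = _clamp(sol[-1])
        t += chunk
        residual = float(np.abs(model.rhs(x)).max())
        if polish and residual < 1e3 * tol:
            xn = _try_polish(model, x, tol)
            if xn is not None:
                x, polish_used = xn, True
                residual = float(np.abs(model.rhs(x)).max())
        if residual <= tol or t >= t_max:
            break
        chunk *= 2.5
    converged = residual <= tol
    eig = np.linalg.eigvals(model.jacobian(x))
    stable = bool(np.all(eig.real < 0.0))
    return SteadyState(
        state=x,
        residual=residual,
        stable=stable,
        converged=converged,
        t_elapsed=t,
        polish_used=polish_used,
    )


def mac_abundance(net: ReactionNetwork, state: np.ndarray) -> float:
    """MAC readout: total abundance of the three activated-effector dimers.

    Toy networks without effector dimers read out as zero.
    """
    names = net.species_names
    total = 0.0
    for s in MAC_DIMERS:
        if s in names:
            total += float(state[names.index(s)])
    return total
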