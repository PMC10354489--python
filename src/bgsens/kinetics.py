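"""Potentials, mass-action fluxes, ODE integration and steady states.

The flux law is the Marcelin–de Donder form ``f = kappa*(exp(Phi_f) -
exp(Phi_r))`` with ``Phi_f = Nf.T @ phi`` and ``Phi_r = Nr.T @ phi`` built
from the species potentials ``phi = ln(K*x)``.  For unimolecular steps this
reduces to ordinary mass action, e.g. ``f = kappa*(KA*xA - KB*xB)``.

Integration is performed in log-amounts ``z = ln x`` of the dynamic
(non-chemostat) species so positivity is structural; a stiff implicit
method is used because disparate rate constants make the exponential flux
law stiff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model_core import ReactionNetwork, conserved_moieties

__all__ = [
    "Trajectory",
    "SteadyState",
    "potentials",
    "reaction_flux",
    "simulate",
    "steady_state",
]

_RTOL = 1e-10
_ATOL = 1e-12


@dataclass
class Trajectory:
    """Time course of species amounts and reaction flows.

    ``states`` is (n_times, n_species), ``flows`` is (n_times, n_reactions);
    both follow the network's declaration order.
    """

    t: np.ndarray
    states: np.ndarray
    flows: np.ndarray
    species: list[str]
    reactions: list[str]

    def state(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def flow(self, name: str) -> np.ndarray:
        return self.flows[:, self.reactions.index(name)]


@dataclass
class SteadyState:
    """A root of the open-system dynamics ``Nc @ f = 0``."""

    x: np.ndarray
    f: np.ndarray
    residual: float


def potentials(network: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Per-species potential phi_i = ln(K_i * x_i)."""
    x = np.asarray(x, dtype=float)
    bad = np.nonzero(x <= 0)[0]
    if bad.size:
        names = [network.species_names[i] for i in bad]
        raise ValueError(f"nonpositive amount for species {names}: potential undefined")
    return np.log(network.K * x)


def reaction_flux(network: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Per-reaction flow f = kappa*(exp(Nf.T phi) - exp(Nr.T phi))."""
    phi = potentials(network, x)
    Phi_f = network.Nf.T @ phi
    Phi_r = network.Nr.T @ phi
    return network.kappa * (np.exp(Phi_f) - np.exp(Phi_r))


def flux_jacobian(network: ReactionNetwork, x: np.ndarray) -> np.ndarray:
    """Analytic d f / d x (reactions x species).

    From ``d Phi_f / d x_i = Nf[i, :]/x_i`` (and likewise for the reverse),
    ``df_r/dx_i = kappa_r*(Nf[i,r]*exp(Phi_f_r) - Nr[i,r]*exp(Phi_r_r))/x_i``.
    """
    phi = potentials(network, x)
    ef = np.exp(network.Nf.T @ phi)  # (n_r,)
    er = np.exp(network.Nr.T @ phi)
    x = np.asarray(x, dtype=float)
    J = network.kappa[:, None] * (network.Nf.T * ef[:, None] - network.Nr.T * er[:, None])
    return J / x[None, :]


def _flux_of(network, x, flux):
    return reaction_flux(network, x) if flux is None else flux(network, x)


def simulate(
    network: ReactionNetwork,
    x_init: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
    *,
    t_end: float = 10.0,
    n_points: int = 201,
    flux=None,
    rtol: float = _RTOL,
    atol: float = _ATOL,
) -> Trajectory:
    """Integrate ``xdot = Nc @ f(x)`` and return states and flows on a grid.

    Chemostat amounts are constant by construction (their rows of ``Nc``
    are zero).  ``flux`` may replace the nominal flux law — the sensitivity
    system uses this hook to apply perturbed kinetics.
    """
    if x_init is None:
        x_init = network.x_init
    x_init = np.asarray(x_init, dtype=float)
    if np.any(x_init <= 0):
        raise ValueError("initial amounts must be strictly positive")
    if t_grid is None:
        t_grid = np.linspace(0.0, t_end, n_points)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be 1-D and strictly increasing")

    dyn = ~network.chemostat_mask
    Nc_dyn = network.Nc[dyn, :]
    x_full = x_init.copy()

    def rhs(t, z):
        x_full[dyn] = np.exp(z)
        f = _flux_of(network, x_full, flux)
        return (Nc_dyn @ f) / x_full[dyn]

    if dyn.any():
        sol = solve_ivp(
            rhs,
            (t_grid[0], t_grid[-1]),
            np.log(x_init[dyn]),
            t_eval=t_grid,
            method="LSODA",
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        states = np.tile(x_init, (len(t_grid), 1))
        states[:, dyn] = np.exp(sol.y.T)
    else:
        states = np.tile(x_init, (len(t_grid), 1))

    flows = np.array([_flux_of(network, s, flux) for s in states])
    return Trajectory(
        t=t_grid,
        states=states,
        flows=flows,
        species=network.species_names,
        reactions=network.reaction_names,
    )


def _independent_dynamic(network: ReactionNetwork):
    """Split dynamic species into independent states and moiety-dependent ones.

    Moieties of the open system restricted to dynamic species give affine
    constraints ``L @ x_dyn = const``.  For each constraint one species (the
    one with the largest initial amount, for conditioning) is eliminated.
    Returns (dyn_idx, indep_idx, dep_idx, L) with indices into the full
    species order; L has one row per eliminated species.
    """
    dyn = np.nonzero(~network.chemostat_mask)[0]
    M = conserved_moieties(network, closed=False)
    # rows touching only dynamic species constrain them; rows touching a
    # chemostat are either trivial (unit chemostat moieties) or involve fixed
    # amounts and reduce to the same dynamic constraint.
    L_rows = []
    for row in M:
        sub = row[dyn]
        if np.any(sub):
            L_rows.append(row)
    if not L_rows:
        return dyn, dyn, np.array([], dtype=int), np.zeros((0, network.n_species), dtype=int)
    L = np.array(L_rows, dtype=int)
    # independent rows only (moiety basis may overlap chemostat trivials)
    dep: list[int] = []
    keep_rows: list[int] = []
    x0 = network.x_init
    for ri, row in enumerate(L):
        candidates = [i for i in dyn if row[i] != 0 and i not in dep]
        if not candidates:
            continue
        pivot = max(candidates, key=lambda i: x0[i])
        dep.append(pivot)
        keep_rows.append(ri)
    L = L[keep_rows]
    dep_arr = np.array(sorted(dep), dtype=int)
    indep = np.array([i for i in dyn if i not in dep], dtype=int)
    return dyn, indep, dep_arr, L


def steady_state(
    network: ReactionNetwork,
    x_guess: np.ndarray | None = None,
    *,
    flux=None,
    tol: float = 1e-12,
) -> SteadyState:
    """Solve ``Nc @ f(x) = 0`` within the stoichiometric subspace of ``x_guess``.

    Newton iteration (scipy root with analytic Jacobian) on the independent
    dynamic species after conserved-moiety elimination, so moiety totals of
    the result match those of the guess exactly.  Falls back to long-time
    integration if Newton fails to converge.  Multiple or unstable steady
    states are not detected; the root reached from the guess is returned.
    """
    if x_guess is None:
        x_guess = network.x_init
    x_guess = np.asarray(x_guess, dtype=float)
    if np.any(x_guess <= 0):
        raise ValueError("x_guess must be strictly positive")

    dyn, indep, dep, L = _independent_dynamic(network)
    totals = L @ x_guess if len(L) else np.zeros(0)

    def full_state(z):
        x = x_guess.copy()
        x[indep] = np.exp(z)
        if len(dep):
            # solve L[:, dep] * x_dep = totals - L[:, rest] * x_rest (triangular by construction)
            rhs = totals - L[:, :] @ x + L[:, dep] @ x[dep]
            x[dep] = np.linalg.solve(L[:, dep].astype(float), rhs)
        return x

    if len(indep) == 0:
        f = _flux_of(network, x_guess, flux)
        res = float(np.linalg.norm(network.Nc @ f))
        return SteadyState(x=x_guess, f=f, residual=res)

    def residual(z):
        x = full_state(z)
        if np.any(x[dyn] <= 0):
            return np.full(len(indep), 1e6)
        f = _flux_of(network, x, flux)
        return network.Nc[indep, :] @ f

    sol = root(residual, np.log(x_guess[indep]), method="hybr", tol=1e-14)
    x = full_state(sol.x)
    ok = sol.success and np.all(x[dyn] > 0)
    if ok:
        f = _flux_of(network, x, flux)
        res = float(np.linalg.norm(network.Nc @ f))
        ok = res < max(tol, 1e-9)
    if not ok:
        traj = simulate(network, x_guess, t_end=1e4, n_points=10, flux=flux)
        x = traj.states[-1]
        f = _flux_of(network, x, flux)
        res = float(np.linalg.norm(network.Nc @ f))
        if res > 1e-8:
            raise RuntimeError(f"steady state did not converge (residual {res:.3e})")
    else:
        f = _flux_of(network, x, flux)
        res = float(np.linalg.norm(network.Nc @ f))
    return SteadyState(x=x, f=f, residual=res)
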