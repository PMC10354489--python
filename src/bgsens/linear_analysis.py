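"""Linearization of the sensitivity system and channel summaries.

About a steady state the sensitivity system reduces to a standard LTI
state-space model::

    dx~/dt = a x~ + b L~        f~ = c x~ + d L~

whose inputs ``L~ = lambda - 1`` are the parameter-perturbation deviations
and whose outputs are selected flows.  Conserved moieties are eliminated
before linearization (one species per moiety expressed through the others),
so the realization has no uncontrollable or unobservable modes and the
per-channel transfer functions ``G(s) = c (sI - a)^{-1} b + d`` carry no
cancelling pole/zero pairs.

Each input -> output channel is summarized by three numbers: the
instantaneous gain ``g0 = G(inf) = d``, the DC gain ``ginf = G(0)``, and a
representative time constant ``tau`` — zero when the response has a direct
feedthrough, otherwise the time constant of the order-1 balanced truncation
of the channel.

Jacobians are closed-form derivatives of the exponential flux law; finite
differences appear only as test oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, signal

from .kinetics import SteadyState, _independent_dynamic, flux_jacobian, steady_state
from .model_core import ReactionNetwork, SpeciesSpec, build_network
from .sensitivity import SensitivitySystem

__all__ = [
    "LinearizedSensitivity",
    "TransferSummary",
    "linearize",
    "transfer_function",
    "dc_gain",
    "initial_gain",
    "time_constant",
    "step_response",
    "gain_vs_operating_point",
]

# g0 treated as nonzero (instantaneous channel) when |g0| > ABS + REL*|ginf|
_G0_ABS = 1e-9
_G0_REL = 1e-6


@dataclass
class LinearizedSensitivity:
    """Reduced state-space model of the sensitivity system about a steady state."""

    steady: SteadyState
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    state_labels: list[str]
    input_labels: list[str]
    output_labels: list[str]

    @property
    def n_states(self) -> int:
        return self.a.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.b.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.c.shape[0]

    @property
    def poles(self) -> np.ndarray:
        return np.linalg.eigvals(self.a)

    @property
    def is_stable(self) -> bool:
        return bool(np.all(self.poles.real < 0)) if self.n_states else True

    def channel_index(self, output, inp) -> tuple[int, int]:
        i = output if isinstance(output, int) else self.output_labels.index(output)
        j = inp if isinstance(inp, int) else self.input_labels.index(inp)
        return i, j


@dataclass
class TransferSummary:
    """Per-channel rational transfer functions of a linearization.

    ``num[i][j]`` / ``den`` are polynomial coefficient arrays (highest power
    first); all channels share the characteristic polynomial of ``a`` as
    denominator (the realization is minimal, so no cancellations hide in it).
    """

    num: list[list[np.ndarray]]
    den: np.ndarray
    input_labels: list[str]
    output_labels: list[str]

    def channel(self, output, inp) -> tuple[np.ndarray, np.ndarray]:
        i = output if isinstance(output, int) else self.output_labels.index(output)
        j = inp if isinstance(inp, int) else self.input_labels.index(inp)
        return self.num[i][j], self.den

    def evaluate(self, output, inp, s: complex) -> complex:
        n, d = self.channel(output, inp)
        return np.polyval(n, s) / np.polyval(d, s)


def _reduction(sys: SensitivitySystem):
    return _independent_dynamic(sys.network)


def _state_transform(network: ReactionNetwork, indep, dep, L) -> np.ndarray:
    """T (n_species x n_indep) with dx_full = T dx_indep (chemostat rows zero)."""
    n = network.n_species
    T = np.zeros((n, len(indep)))
    for col, i in enumerate(indep):
        T[i, col] = 1.0
    if len(dep):
        Ldep = L[:, dep].astype(float)
        Lind = L[:, indep].astype(float)
        T[dep, :] = -np.linalg.solve(Ldep, Lind)
    return T


def _input_jacobian(sys: SensitivitySystem, x: np.ndarray, f: np.ndarray) -> np.ndarray:
    """d f / d lambda at nominal (reactions x targets).

    A species lambda shifts that species' potential by ln(lambda), so at
    lambda = 1 the column is x_i times the i-th column of df/dx; a reaction
    lambda scales the flow, so the column is f_r on its own reaction.
    """
    net = sys.network
    Jx = flux_jacobian(net, x)
    dfdl = np.zeros((net.n_reactions, len(sys.targets)))
    for j, tgt in enumerate(sys.targets):
        if tgt.kind == "reaction-kappa":
            r = net.reaction_index(tgt.name)
            dfdl[r, j] = f[r]
        else:
            i = net.species_index(tgt.name)
            dfdl[:, j] = Jx[:, i] * x[i]
    return dfdl


def _parse_outputs(network: ReactionNetwork, outputs):
    """Output selector: reaction names give reaction flows; 'ext:<species>'
    gives the external flow absorbed by a chemostat (its row of N @ f)."""
    if outputs is None:
        outputs = list(network.reaction_names)
    rows = []
    labels = []
    for out in outputs:
        if isinstance(out, str) and out.startswith("ext:"):
            name = out[4:]
            i = network.species_index(name)
            if not network.species[i].is_chemostat:
                raise ValueError(f"external flow requested for non-chemostat {name!r}")
            rows.append(("ext", i))
        else:
            rows.append(("rxn", network.reaction_index(out)))
        labels.append(out)
    return rows, labels


def linearize(
    sys: SensitivitySystem,
    steady: SteadyState | None = None,
    outputs=None,
    *,
    residual_tol: float = 1e-6,
) -> LinearizedSensitivity:
    """Linearize the sensitivity system about a steady state.

    States are a maximal independent subset of the dynamic species after
    conserved-moiety elimination; inputs are the lambda deviations in target
    order; outputs are selected flows (default: all reaction flows).
    """
    net = sys.network
    if steady is None:
        steady = steady_state(net)
    if steady.residual > residual_tol:
        raise ValueError(
            f"linearization point is not steady (residual {steady.residual:.3e})"
        )
    x, f = steady.x, steady.f
    dyn, indep, dep, L = _reduction(sys)
    T = _state_transform(net, indep, dep, L)
    Jx = flux_jacobian(net, x)
    dfdl = _input_jacobian(sys, x, f)

    a = net.Nc[indep, :] @ Jx @ T
    b = net.Nc[indep, :] @ dfdl
    out_rows, labels = _parse_outputs(net, outputs)
    c = np.zeros((len(out_rows), len(indep)))
    d = np.zeros((len(out_rows), len(sys.targets)))
    for k, (kind, idx) in enumerate(out_rows):
        if kind == "rxn":
            c[k, :] = Jx[idx, :] @ T
            d[k, :] = dfdl[idx, :]
        else:  # external chemostat flow
            c[k, :] = net.N[idx, :] @ Jx @ T
            d[k, :] = net.N[idx, :] @ dfdl

    lin = LinearizedSensitivity(
        steady=steady,
        a=a,
        b=b,
        c=c,
        d=d,
        state_labels=[net.species_names[i] for i in indep],
        input_labels=sys.input_labels,
        output_labels=labels,
    )
    if not lin.is_stable:
        warnings.warn(
            "linearization is not Hurwitz: steady state is not asymptotically stable",
            stacklevel=2,
        )
    return lin


def transfer_function(lin: LinearizedSensitivity) -> TransferSummary:
    """Exact rational transfer functions G(s) = c (sI - a)^{-1} b + d."""
    if lin.n_states == 0:
        den = np.array([1.0])
        num = [[np.atleast_1d(lin.d[i, j]) for j in range(lin.n_inputs)]
               for i in range(lin.n_outputs)]
        return TransferSummary(num, den, lin.input_labels, lin.output_labels)
    den = None
    num: list[list[np.ndarray]] = [[None] * lin.n_inputs for _ in range(lin.n_outputs)]
    for j in range(lin.n_inputs):
        nj, den = signal.ss2tf(lin.a, lin.b[:, j : j + 1], lin.c, lin.d[:, j : j + 1])
        for i in range(lin.n_outputs):
            num[i][j] = np.trim_zeros(nj[i], "f") if np.any(nj[i]) else np.zeros(1)
    return TransferSummary(num, np.asarray(den), lin.input_labels, lin.output_labels)


def dc_gain(lin: LinearizedSensitivity) -> np.ndarray:
    """Steady-state gain matrix ginf = G(0) = -c a^{-1} b + d."""
    if lin.n_states == 0:
        return lin.d.copy()
    if not lin.is_stable:
        raise ValueError("DC gain undefined: linearization is not Hurwitz")
    return lin.d - lin.c @ np.linalg.solve(lin.a, lin.b)


def initial_gain(lin: LinearizedSensitivity) -> np.ndarray:
    """Instantaneous gain matrix g0 = G(inf) = d."""
    return lin.d.copy()


def _hankel_balance(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Hankel singular values and balanced a-matrix of a strictly proper SISO channel."""
    P = linalg.solve_continuous_lyapunov(a, -np.outer(b, b))
    Q = linalg.solve_continuous_lyapunov(a.T, -np.outer(c, c))
    # symmetric square root of P (robust to semidefiniteness)
    w, V = np.linalg.eigh((P + P.T) / 2)
    w = np.clip(w, 0.0, None)
    R = V * np.sqrt(w)
    M = R.T @ ((Q + Q.T) / 2) @ R
    hw, U = np.linalg.eigh((M + M.T) / 2)
    order = np.argsort(hw)[::-1]
    hw = np.clip(hw[order], 0.0, None)
    hsv = np.sqrt(hw)
    U = U[:, order]
    return hsv, R, U


def time_constant(
    lin: LinearizedSensitivity, output, inp, *, zero_tol: float = 1e-12
) -> float:
    """Representative time constant tau of one input -> output channel.

    If the channel has a direct feedthrough (|g0| above threshold) the
    response is instantaneous and tau = 0.  Otherwise the strictly proper
    channel is reduced to order 1 by balanced truncation and tau is minus
    the reciprocal of the surviving pole.  Identically zero channels have no
    timescale and report NaN.
    """
    i, j = lin.channel_index(output, inp)
    if not lin.is_stable:
        raise ValueError("time constant undefined for an unstable channel")
    ginf = dc_gain(lin)[i, j]
    g0 = lin.d[i, j]
    if abs(g0) > _G0_ABS + _G0_REL * abs(ginf):
        return 0.0
    if lin.n_states == 0:
        return float("nan")
    a, b, c = lin.a, lin.b[:, j], lin.c[i, :]
    hsv, R, U = _hankel_balance(a, b, c)
    if hsv[0] <= zero_tol:
        return float("nan")  # channel identically zero
    # balancing transform restricted to the dominant Hankel direction
    T1 = R @ U[:, :1] / np.sqrt(hsv[0])
    Tinv1 = (U[:, :1].T @ np.linalg.pinv(R)) * np.sqrt(hsv[0])
    a_red = (Tinv1 @ a @ T1).item()
    if a_red >= 0:
        raise RuntimeError("balanced order-1 reduction produced an unstable pole")
    return -1.0 / a_red


def step_response(
    lin: LinearizedSensitivity, t_grid: np.ndarray
) -> np.ndarray:
    """Unit-step response matrix g(t), shape (n_times, n_outputs, n_inputs).

    Exact matrix-exponential evaluation: g(t) = c a^{-1}(e^{at} - I) b + d,
    so g(0) = g0 and, for stable a, g(t -> inf) = ginf.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    n_t = len(t_grid)
    out = np.empty((n_t, lin.n_outputs, lin.n_inputs))
    if lin.n_states == 0:
        out[:] = lin.d[None, :, :]
        return out
    a_inv_b = np.linalg.solve(lin.a, lin.b)
    for k, t in enumerate(t_grid):
        E = linalg.expm(lin.a * t)
        out[k] = lin.c @ (E - np.eye(lin.n_states)) @ a_inv_b + lin.d
    return out


def _with_amount(network: ReactionNetwork, name: str, value: float) -> ReactionNetwork:
    """Copy of the network with one species amount replaced."""
    species = [
        SpeciesSpec(s.name, s.K, value if s.name == name else s.x_init, s.is_chemostat)
        for s in network.species
    ]
    return build_network(species, list(network.reactions))


def gain_vs_operating_point(
    sys: SensitivitySystem,
    sweep_species: str,
    amounts,
    *,
    output_flow: str | None = None,
    channels=None,
) -> pd.DataFrame:
    """Sweep a chemostat amount and tabulate steady flow and DC gains.

    One row per sweep point with the steady amounts, the steady flow of
    ``output_flow`` (default: first reaction) and the DC gain of each
    requested channel (default: all targets).  Points where the steady-state
    solve fails are kept with NaN entries so the sweep continues.
    """
    from .sensitivity import augment

    net = sys.network
    i_sp = net.species_index(sweep_species)
    if not net.species[i_sp].is_chemostat:
        raise ValueError(f"sweep species {sweep_species!r} must be a chemostat")
    if output_flow is None:
        output_flow = net.reaction_names[0]
    if channels is None:
        channels = list(sys.targets)
    rows = []
    x_prev = None
    for amount in np.asarray(amounts, dtype=float):
        swept = _with_amount(net, sweep_species, amount)
        row = {sweep_species: amount}
        try:
            guess = x_prev.copy() if x_prev is not None else None
            if guess is not None:
                guess[i_sp] = amount
            ss = steady_state(swept, guess)
            x_prev = ss.x
            sub = augment(swept, list(sys.targets))
            lin = linearize(sub, ss, outputs=[output_flow])
            g = dc_gain(lin)[0]
            row["flow"] = ss.f[swept.reaction_index(output_flow)]
            for tgt in channels:
                row[tgt.label] = g[sys.targets.index(tgt)]
            row["converged"] = True
        except (RuntimeError, ValueError):
            row["flow"] = np.nan
            for tgt in channels:
                row[tgt.label] = np.nan
            row["converged"] = False
        rows.append(row)
    return pd.DataFrame(rows)
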