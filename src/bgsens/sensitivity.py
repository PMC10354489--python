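"""The nonlinear sensitivity system: parameter perturbations as inputs.

Each parameter of the network — a species thermodynamic constant ``K``, a
chemostat amount, or a reaction rate constant ``kappa`` — is perturbed
multiplicatively by a factor ``lambda``.  Because potentials are
logarithmic, every such perturbation enters the flux law as an *additive*
potential ``ln lambda``, i.e. as an extra chemostat feeding the original
component.  The network augmented with these perturbation chemostats is the
sensitivity system: a bona-fide reaction network whose extra inputs are the
``lambda`` values, with nominal behaviour recovered at ``lambda = 1``.

Stoichiometrically the augmentation stacks the species blocks and appends a
reaction-count identity::

    Nsf = [Nf; Nf; I]    Nsr = [Nr; Nr; I]    Ns = [N; N; 0]

with all sensitivity states held as chemostats of the augmented system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kinetics import SteadyState, Trajectory, simulate, steady_state
from .model_core import ReactionNetwork

__all__ = [
    "PerturbationTarget",
    "PerturbationAssignment",
    "SensitivitySystem",
    "LinearizationErrorReport",
    "augment",
    "perturbed_flux",
    "step_perturbation_response",
    "linearization_error",
]

_KINDS = ("species-K", "chemostat-amount", "reaction-kappa")


@dataclass(frozen=True)
class PerturbationTarget:
    """One perturbable parameter: (kind, name).

    ``species-K`` and ``chemostat-amount`` both multiply the ``K*x`` product
    of a species and are therefore dynamically identical; the distinction is
    bookkeeping about which physical parameter is meant.
    """

    kind: str
    name: str

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}; expected one of {_KINDS}")

    @property
    def label(self) -> str:
        return f"lambda[{self.name}]"

    def __str__(self) -> str:
        return f"{self.kind}:{self.name}"


class PerturbationAssignment:
    """Ordered map of perturbation targets to multiplicative lambda values."""

    def __init__(self, values: Mapping[PerturbationTarget, float]):
        for tgt, lam in values.items():
            if lam <= 0:
                raise ValueError(f"lambda for {tgt} must be > 0, got {lam}")
        self._values = dict(values)

    @property
    def targets(self) -> list[PerturbationTarget]:
        return list(self._values)

    @property
    def Lambda(self) -> np.ndarray:
        """Vector of lambda values in target order."""
        return np.array(list(self._values.values()), dtype=float)

    @property
    def deviation(self) -> np.ndarray:
        """lambda - 1 in target order (zero everywhere at nominal)."""
        return self.Lambda - 1.0

    def __getitem__(self, tgt: PerturbationTarget) -> float:
        return self._values[tgt]

    def is_nominal(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.deviation) <= tol))


def default_targets(network: ReactionNetwork) -> list[PerturbationTarget]:
    """One lambda per species plus one per reaction.

    Chemostats get a ``chemostat-amount`` target, dynamic species a
    ``species-K`` target (the two act identically on a chemostat; only one
    is kept so the input vector matches the species count).
    """
    out = []
    for s in network.species:
        kind = "chemostat-amount" if s.is_chemostat else "species-K"
        out.append(PerturbationTarget(kind, s.name))
    for r in network.reactions:
        out.append(PerturbationTarget("reaction-kappa", r.name))
    return out


@dataclass
class SensitivitySystem:
    """A network plus ordered perturbation targets and augmented stoichiometry."""

    network: ReactionNetwork
    targets: list[PerturbationTarget]
    Nsf: np.ndarray = field(init=False)
    Nsr: np.ndarray = field(init=False)
    Ns: np.ndarray = field(init=False)
    Nsc: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        seen = set()
        for tgt in self.targets:
            key = (tgt.kind, tgt.name)
            if key in seen:
                raise ValueError(f"duplicate perturbation target {tgt}")
            seen.add(key)
            if tgt.kind == "reaction-kappa":
                self.network.reaction_index(tgt.name)
            else:
                i = self.network.species_index(tgt.name)
                if tgt.kind == "chemostat-amount" and not self.network.species[i].is_chemostat:
                    raise ValueError(
                        f"chemostat-amount target {tgt.name!r} is not a chemostat"
                    )
        # reject K + amount targets on the same species: dynamically identical
        names = [t.name for t in self.targets if t.kind != "reaction-kappa"]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"species {dupes} targeted by both species-K and chemostat-amount; "
                "the two perturbations are identical — keep one"
            )
        net = self.network
        n_r = net.n_reactions
        eye = np.eye(n_r, dtype=int)
        zero = np.zeros((n_r, n_r), dtype=int)
        self.Nsf = np.vstack([net.Nf, net.Nf, eye])
        self.Nsr = np.vstack([net.Nr, net.Nr, eye])
        self.Ns = np.vstack([net.N, net.N, zero])
        self.Nsc = np.vstack(
            [net.Nc, np.zeros((net.n_species, n_r), dtype=int), zero]
        )

    @property
    def input_labels(self) -> list[str]:
        return [t.label for t in self.targets]

    def nominal(self) -> PerturbationAssignment:
        return PerturbationAssignment({t: 1.0 for t in self.targets})

    def assignment(self, overrides: Mapping[PerturbationTarget, float] | None = None
                   ) -> PerturbationAssignment:
        """All-ones assignment with sparse overrides."""
        vals = {t: 1.0 for t in self.targets}
        if overrides:
            for tgt, lam in overrides.items():
                if tgt not in vals:
                    raise KeyError(f"{tgt} is not a target of this sensitivity system")
                vals[tgt] = lam
        return PerturbationAssignment(vals)

    # -- per-species / per-reaction lambda vectors -----------------------
    def lambda_vectors(self, Lambda: PerturbationAssignment) -> tuple[np.ndarray, np.ndarray]:
        """(species lambdas, reaction lambdas) in network order; 1 where untargeted."""
        lam_s = np.ones(self.network.n_species)
        lam_r = np.ones(self.network.n_reactions)
        for tgt, lam in zip(Lambda.targets, Lambda.Lambda):
            if tgt.kind == "reaction-kappa":
                lam_r[self.network.reaction_index(tgt.name)] *= lam
            else:
                lam_s[self.network.species_index(tgt.name)] *= lam
        return lam_s, lam_r


def augment(
    network: ReactionNetwork, targets: Iterable[PerturbationTarget] | None = None
) -> SensitivitySystem:
    """Build the sensitivity system for the given (or default) targets."""
    if targets is None:
        targets = default_targets(network)
    return SensitivitySystem(network, list(targets))


def perturbed_flux(
    sys: SensitivitySystem, x: np.ndarray, Lambda: PerturbationAssignment
) -> np.ndarray:
    """Reaction flows under shifted potentials.

    Species perturbations shift ``phi_i`` to ``ln lambda_i + ln(K_i x_i)``;
    a reaction perturbation adds ``ln lambda_r`` to both the forward and
    reverse reaction potentials, i.e. multiplies the flow by ``lambda_r``.
    With all lambda = 1 this is exactly the nominal flux law.
    """
    from .kinetics import potentials

    lam_s, lam_r = sys.lambda_vectors(Lambda)
    phi = np.log(lam_s) + potentials(sys.network, x)
    net = sys.network
    f = net.kappa * (np.exp(net.Nf.T @ phi) - np.exp(net.Nr.T @ phi))
    return lam_r * f


def _flux_hook(sys: SensitivitySystem, Lambda: PerturbationAssignment):
    def flux(network, x):
        return perturbed_flux(sys, x, Lambda)

    return flux


def step_perturbation_response(
    sys: SensitivitySystem,
    Lambda_step: PerturbationAssignment,
    t_grid: np.ndarray | None = None,
    *,
    x_start: np.ndarray | None = None,
    t_end: float = 2.0,
    n_points: int = 201,
) -> Trajectory:
    """Simulate the network from its nominal steady state under a lambda step.

    The step is applied at t = 0; flows in the returned trajectory are the
    perturbed flows.  Flows that depend directly on a stepped lambda jump at
    t = 0+, the others move only through the states.
    """
    if x_start is None:
        x_start = steady_state(sys.network).x
    return simulate(
        sys.network,
        x_start,
        t_grid,
        t_end=t_end,
        n_points=n_points,
        flux=_flux_hook(sys, Lambda_step),
    )


def perturbed_steady_state(
    sys: SensitivitySystem,
    Lambda: PerturbationAssignment,
    x_guess: np.ndarray | None = None,
) -> SteadyState:
    """Steady state of the lambda-perturbed dynamics, continued from the nominal."""
    if x_guess is None:
        x_guess = steady_state(sys.network).x
    return steady_state(sys.network, x_guess, flux=_flux_hook(sys, Lambda))


@dataclass
class LinearizationErrorReport:
    """Finite-perturbation gains vs the linearized DC gain for one channel.

    ``gain_nonlinear[k] = (perturbed steady flow - nominal flow)/dlambda[k]``
    and ``rel_error = (gain_nonlinear - g_inf)/g_inf``.
    """

    target: PerturbationTarget
    output_flow: str
    dlambda: np.ndarray
    gain_nonlinear: np.ndarray
    g_inf: float
    rel_error: np.ndarray


def linearization_error(
    sys: SensitivitySystem,
    target: PerturbationTarget,
    output_flow: str,
    dlambda_list: Sequence[float],
    *,
    g_inf: float | None = None,
) -> LinearizationErrorReport:
    """Quantify how the local (linearized) gain degrades with perturbation size.

    For each finite step ``dlambda`` the perturbed steady state is found by
    Newton continuation from the nominal one, and the secant gain
    ``(f_perturbed - f_nominal)/dlambda`` is compared with the DC gain of
    the linearization (computed here if not supplied).
    """
    if target not in sys.targets:
        raise KeyError(f"{target} is not a target of this sensitivity system")
    j_out = sys.network.reaction_index(output_flow)
    nominal = steady_state(sys.network)
    if g_inf is None:
        from .linear_analysis import dc_gain, linearize

        lin = linearize(sys, nominal)
        g_inf = float(dc_gain(lin)[lin.output_labels.index(output_flow),
                                  sys.targets.index(target)])
    if abs(g_inf) < 1e-14:
        raise ValueError(
            f"channel ({target} -> {output_flow}) has zero DC gain; relative error undefined"
        )
    dl = np.asarray(dlambda_list, dtype=float)
    gains = np.empty_like(dl)
    for k, d in enumerate(dl):
        if 1.0 + d <= 0:
            raise ValueError(f"dlambda = {d} drives lambda nonpositive")
        pert = sys.assignment({target: 1.0 + d})
        ss = perturbed_steady_state(sys, pert, x_guess=nominal.x)
        gains[k] = (ss.f[j_out] - nominal.f[j_out]) / d
    rel = (gains - g_inf) / g_inf
    return LinearizationErrorReport(
        target=target,
        output_flow=output_flow,
        dlambda=dl,
        gain_nonlinear=gains,
        g_inf=g_inf,
        rel_error=rel,
    )
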