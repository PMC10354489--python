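"""Network declaration, stoichiometry and unit normalization.

A biochemical network is declared as energy-storing species (bond-graph
``Ce`` components) and dissipative reactions (``Re`` components).  Each
species carries a dimensionless thermodynamic constant ``K`` and a
dimensionless amount ``x``; its chemical potential is ``phi = ln(K*x)``.
Each reaction carries a dimensionless rate constant ``kappa`` and integer
forward/reverse stoichiometry.  Species flagged as chemostats have fixed
amounts and represent the system boundary.

All model quantities are dimensionless.  :class:`NormalizationScheme`
converts between physical units (J/mol, mol/s, mol, s — or volts and
amperes via the Faraday constant) and the dimensionless quantities; it is
never applied implicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "FARADAY_CONSTANT",
    "NormalizationScheme",
    "SpeciesSpec",
    "ReactionSpec",
    "ReactionNetwork",
    "make_normalization",
    "build_network",
    "conserved_moieties",
]

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
FARADAY_CONSTANT = 96485.0  # C mol^-1


@dataclass(frozen=True)
class NormalizationScheme:
    """Reference scales linking physical and dimensionless quantities.

    Potentials are normalized by the thermal energy ``mu0 = R*T``, flows by
    ``v0 = P0/mu0`` (so that potential times flow is measured in units of
    the reference power ``P0``), amounts by ``x0 = v0*t0`` and time by
    ``t0``.  The electrical-unit view divides potential by the Faraday
    constant (``phi0 = mu0/F`` volts) and multiplies flow by it
    (``f0 = F*v0`` amperes); both pairs multiply back to ``P0``.
    """

    T: float
    P0: float = 1e-3
    t0: float = 1.0
    R: float = GAS_CONSTANT
    F: float = FARADAY_CONSTANT
    mu0: float = field(init=False)
    v0: float = field(init=False)
    x0: float = field(init=False)
    phi0: float = field(init=False)
    f0: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("T", "P0", "t0", "R", "F"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        object.__setattr__(self, "mu0", self.R * self.T)
        object.__setattr__(self, "v0", self.P0 / self.mu0)
        object.__setattr__(self, "x0", self.v0 * self.t0)
        object.__setattr__(self, "phi0", self.mu0 / self.F)
        object.__setattr__(self, "f0", self.F * self.v0)

    # conversions physical -> dimensionless
    def normalize_potential(self, mu: float) -> float:
        """phi = mu/mu0 for mu in J/mol."""
        return mu / self.mu0

    def normalize_flow(self, v: float) -> float:
        """f = v/v0 for v in mol/s."""
        return v / self.v0

    def normalize_amount(self, x_mol: float) -> float:
        return x_mol / self.x0

    def normalize_time(self, t_s: float) -> float:
        return t_s / self.t0

    # dimensionless -> physical
    def potential(self, phi: float) -> float:
        return phi * self.mu0

    def flow(self, f: float) -> float:
        return f * self.v0

    def amount(self, x: float) -> float:
        return x * self.x0

    def time(self, t: float) -> float:
        return t * self.t0


def make_normalization(T: float, P0: float = 1e-3, t0: float = 1.0) -> NormalizationScheme:
    """Build a :class:`NormalizationScheme` from temperature, power and time scales.

    Parameters
    ----------
    T : float
        Absolute temperature in kelvin.
    P0 : float
        Reference power in watts (default 1 mW).
    t0 : float
        Reference time in seconds (default 1 s).
    """
    return NormalizationScheme(T=T, P0=P0, t0=t0)


@dataclass(frozen=True)
class SpeciesSpec:
    """A species (``Ce`` component): phi = ln(K*x)."""

    name: str
    K: float = 1.0
    x_init: float = 1.0
    is_chemostat: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("species name must be non-empty")
        if self.K <= 0:
            raise ValueError(f"species {self.name!r}: K must be > 0")
        if self.x_init <= 0:
            raise ValueError(f"species {self.name!r}: x_init must be > 0")


def _validate_stoich(name: str, side: str, stoich: Mapping[str, int]) -> dict[str, int]:
    out: dict[str, int] = {}
    for sp, coeff in stoich.items():
        if coeff != int(coeff):
            raise ValueError(
                f"reaction {name!r}: non-integer {side} coefficient {coeff!r} for {sp!r}"
            )
        coeff = int(coeff)
        if coeff < 0:
            raise ValueError(f"reaction {name!r}: negative {side} coefficient for {sp!r}")
        if coeff > 0:
            out[sp] = coeff
    return out


@dataclass(frozen=True)
class ReactionSpec:
    """A reaction (``Re`` component): f = kappa*(exp(Phi_f) - exp(Phi_r)).

    ``forward`` and ``reverse`` map species names to nonnegative integer
    stoichiometric coefficients; zero entries are dropped.
    """

    name: str
    kappa: float
    forward: Mapping[str, int]
    reverse: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("reaction name must be non-empty")
        if self.kappa <= 0:
            raise ValueError(f"reaction {self.name!r}: kappa must be > 0")
        fwd = _validate_stoich(self.name, "forward", self.forward)
        rev = _validate_stoich(self.name, "reverse", self.reverse)
        if not fwd:
            raise ValueError(f"reaction {self.name!r}: empty forward stoichiometry")
        if not rev:
            raise ValueError(f"reaction {self.name!r}: empty reverse stoichiometry")
        object.__setattr__(self, "forward", fwd)
        object.__setattr__(self, "reverse", rev)


class ReactionNetwork:
    """An ordered collection of species and reactions with derived stoichiometry.

    Matrices (all species x reactions, declaration order):

    - ``Nf`` / ``Nr``: forward / reverse stoichiometry, nonnegative integers;
    - ``N = Nr - Nf``: net stoichiometry, giving ``xdot = N f`` for a closed
      system;
    - ``Nc``: ``N`` with chemostat rows zeroed, giving ``xdot = Nc f`` for
      the open system.
    """

    def __init__(self, species: Sequence[SpeciesSpec], reactions: Sequence[ReactionSpec]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate species names: {dupes}")
        rnames = [r.name for r in reactions]
        if len(set(rnames)) != len(rnames):
            dupes = sorted({n for n in rnames if rnames.count(n) > 1})
            raise ValueError(f"duplicate reaction names: {dupes}")
        index = {n: i for i, n in enumerate(names)}

        self.species = tuple(species)
        self.reactions = tuple(reactions)
        n_s, n_r = len(species), len(reactions)
        Nf = np.zeros((n_s, n_r), dtype=int)
        Nr = np.zeros((n_s, n_r), dtype=int)
        for j, rxn in enumerate(reactions):
            for side, mat in ((rxn.forward, Nf), (rxn.reverse, Nr)):
                for sp, coeff in side.items():
                    if sp not in index:
                        raise ValueError(
                            f"reaction {rxn.name!r} references unknown species {sp!r}"
                        )
                    mat[index[sp], j] = coeff
            if rxn.forward == rxn.reverse:
                warnings.warn(
                    f"reaction {rxn.name!r} has identical forward and reverse "
                    "stoichiometry (zero net conversion)",
                    stacklevel=3,
                )
        self.Nf = Nf
        self.Nr = Nr
        self.N = Nr - Nf
        Nc = self.N.copy()
        Nc[self.chemostat_mask, :] = 0
        self.Nc = Nc

    # -- lookups ---------------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def reaction_names(self) -> list[str]:
        return [r.name for r in self.reactions]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def chemostat_mask(self) -> np.ndarray:
        return np.array([s.is_chemostat for s in self.species], dtype=bool)

    @property
    def chemostats(self) -> list[str]:
        return [s.name for s in self.species if s.is_chemostat]

    @property
    def K(self) -> np.ndarray:
        return np.array([s.K for s in self.species], dtype=float)

    @property
    def kappa(self) -> np.ndarray:
        return np.array([r.kappa for r in self.reactions], dtype=float)

    @property
    def x_init(self) -> np.ndarray:
        return np.array([s.x_init for s in self.species], dtype=float)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def reaction_index(self, name: str) -> int:
        try:
            return self.reaction_names.index(name)
        except ValueError:
            raise KeyError(f"unknown reaction {name!r}") from None

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork({self.n_species} species, {self.n_reactions} reactions, "
            f"chemostats={self.chemostats})"
        )


def build_network(
    species: Sequence[SpeciesSpec], reactions: Sequence[ReactionSpec]
) -> ReactionNetwork:
    """Assemble a validated :class:`ReactionNetwork` in declaration order."""
    return ReactionNetwork(species, reactions)


def _integer_left_nullspace(A: np.ndarray) -> np.ndarray:
    """Primitive-integer basis of the left null space of an integer matrix.

    Computed by exact rational row reduction of ``A.T`` (no floating-point
    rank decisions), each basis vector scaled to coprime integers with a
    positive leading entry.
    """
    m = A.shape[0]
    # Row-reduce A.T x = 0 over Fraction.
    rows = [[Fraction(int(v)) for v in row] for row in A.T]
    n_rows, n_cols = len(rows), m
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        piv = next((i for i in range(r, n_rows) if rows[i][c] != 0), None)
        if piv is None:
            continue
        rows[r], rows[piv] = rows[piv], rows[r]
        inv = rows[r][c]
        rows[r] = [v / inv for v in rows[r]]
        for i in range(n_rows):
            if i != r and rows[i][c] != 0:
                fac = rows[i][c]
                rows[i] = [vi - fac * vr for vi, vr in zip(rows[i], rows[r])]
        pivots.append(c)
        r += 1
        if r == n_rows:
            break
    free = [c for c in range(n_cols) if c not in pivots]
    basis = []
    for fc in free:
        vec = [Fraction(0)] * n_cols
        vec[fc] = Fraction(1)
        for ri, pc in enumerate(pivots):
            vec[pc] = -rows[ri][fc]
        denom = np.lcm.reduce([v.denominator for v in vec]) if vec else 1
        ints = np.array([int(v * denom) for v in vec], dtype=int)
        g = np.gcd.reduce(np.abs(ints[ints != 0])) if np.any(ints) else 1
        ints = ints // g
        lead = ints[np.nonzero(ints)[0][0]]
        if lead < 0:
            ints = -ints
        basis.append(ints)
    if not basis:
        return np.zeros((0, m), dtype=int)
    return np.vstack(basis)


def conserved_moieties(network: ReactionNetwork, closed: bool = False) -> np.ndarray:
    """Integer basis of conserved moieties (moieties x species).

    Each row ``m`` satisfies ``m @ N == 0`` (closed system) or
    ``m @ Nc == 0`` (open system): the weighted amount ``m @ x`` is constant
    along any trajectory.  For an open network every chemostat contributes a
    trivial unit moiety since its row of ``Nc`` is zero.
    """
    mat = network.N if closed else network.Nc
    return _integer_left_nullspace(mat)
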