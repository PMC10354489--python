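"""Built-in example networks.

``abc_chain`` is the open two-reaction chain A <-> B <-> C with unit
thermodynamic constants, rate constants (1, 9) and chemostatted A (x = 2)
and C (x = 1); its nominal steady state has xB = 1.1 and both flows equal
to 0.9.  ``abc_closed`` is the same chain with no chemostats (one conserved
moiety, total amount 4).  ``enzyme_module`` is an enzyme-catalysed reaction
with competitive activation/inhibition: substrate A binds free enzyme E to
form the complex C which releases product B, while a modulating reaction
exchanges inactive enzyme E0 (driven by activator Act against inhibitor
Inh) into the active pool; the enzyme moiety xE + xC + xE0 = 10 is
conserved.  The modulated topology is a reconstruction consistent with the
conserved total and the antisymmetric activator/inhibitor response.
"""

from __future__ import annotations

from .model_core import ReactionNetwork, ReactionSpec, SpeciesSpec, build_network

__all__ = ["fixture", "FIXTURES"]


def abc_chain() -> ReactionNetwork:
    species = [
        SpeciesSpec("A", K=1.0, x_init=2.0, is_chemostat=True),
        SpeciesSpec("B", K=1.0, x_init=1.0),
        SpeciesSpec("C", K=1.0, x_init=1.0, is_chemostat=True),
    ]
    reactions = [
        ReactionSpec("r1", kappa=1.0, forward={"A": 1}, reverse={"B": 1}),
        ReactionSpec("r2", kappa=9.0, forward={"B": 1}, reverse={"C": 1}),
    ]
    return build_network(species, reactions)


def abc_closed() -> ReactionNetwork:
    species = [
        SpeciesSpec("A", K=1.0, x_init=2.0),
        SpeciesSpec("B", K=1.0, x_init=1.0),
        SpeciesSpec("C", K=1.0, x_init=1.0),
    ]
    reactions = [
        ReactionSpec("r1", kappa=1.0, forward={"A": 1}, reverse={"B": 1}),
        ReactionSpec("r2", kappa=9.0, forward={"B": 1}, reverse={"C": 1}),
    ]
    return build_network(species, reactions)


def enzyme_module() -> ReactionNetwork:
    # all parameters and amounts unity except xB = 1e-3 and the enzyme pool:
    # xE + xC + xE0 = 10 initially (8 + 1 + 1)
    species = [
        SpeciesSpec("A", x_init=1.0, is_chemostat=True),
        SpeciesSpec("B", x_init=1e-3, is_chemostat=True),
        SpeciesSpec("E", x_init=8.0),
        SpeciesSpec("C", x_init=1.0),
        SpeciesSpec("E0", x_init=1.0),
        SpeciesSpec("Act", x_init=1.0, is_chemostat=True),
        SpeciesSpec("Inh", x_init=1.0, is_chemostat=True),
    ]
    reactions = [
        ReactionSpec("r1", kappa=1.0, forward={"A": 1, "E": 1}, reverse={"C": 1}),
        ReactionSpec("r2", kappa=1.0, forward={"C": 1}, reverse={"E": 1, "B": 1}),
        ReactionSpec("rm", kappa=1.0, forward={"E0": 1, "Act": 1}, reverse={"E": 1, "Inh": 1}),
    ]
    return build_network(species, reactions)


FIXTURES = {
    "abc_chain": abc_chain,
    "abc_closed": abc_closed,
    "enzyme_module": enzyme_module,
}


def fixture(name: str) -> ReactionNetwork:
    """Construct a built-in fixture network by name."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
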