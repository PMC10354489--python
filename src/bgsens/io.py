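"""Model-description files (YAML/JSON) and result serialization.

Schema (one YAML or JSON document)::

    species:
      - {name: A, K: 1.0, x0: 2.0, chemostat: true}
      - ...
    reactions:
      - {name: r1, kappa: 1.0, forward: {A: 1}, reverse: {B: 1}}
      - ...
    normalization: {T: 310.15, P0: 1.0e-3, t0: 1.0}   # optional

Amounts and constants are dimensionless; the optional normalization block
only records the physical scales (defaults T = 310.15 K, P0 = 1 mW,
t0 = 1 s).
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .model_core import (
    NormalizationScheme,
    ReactionNetwork,
    ReactionSpec,
    SpeciesSpec,
    build_network,
    make_normalization,
)

__all__ = ["load_model", "save_model", "network_to_dict", "network_from_dict"]

_DEFAULT_NORMALIZATION = {"T": 310.15, "P0": 1e-3, "t0": 1.0}


class ModelFileError(ValueError):
    """A model file violates the schema; the message names the offending field."""


def _require(mapping, key, where):
    if key not in mapping:
        raise ModelFileError(f"{where}: missing required field {key!r}")
    return mapping[key]


def network_from_dict(doc: dict) -> tuple[ReactionNetwork, NormalizationScheme]:
    if not isinstance(doc, dict):
        raise ModelFileError("model document must be a mapping")
    species = []
    for k, entry in enumerate(_require(doc, "species", "model")):
        where = f"species[{k}]"
        try:
            species.append(
                SpeciesSpec(
                    name=str(_require(entry, "name", where)),
                    K=float(entry.get("K", 1.0)),
                    x_init=float(entry.get("x0", 1.0)),
                    is_chemostat=bool(entry.get("chemostat", False)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ModelFileError(f"{where}: {exc}") from exc
    reactions = []
    for k, entry in enumerate(_require(doc, "reactions", "model")):
        where = f"reactions[{k}]"
        try:
            reactions.append(
                ReactionSpec(
                    name=str(_require(entry, "name", where)),
                    kappa=float(_require(entry, "kappa", where)),
                    forward=dict(_require(entry, "forward", where)),
                    reverse=dict(_require(entry, "reverse", where)),
                )
            )
        except ModelFileError:
            raise
        except (TypeError, ValueError) as exc:
            raise ModelFileError(f"{where}: {exc}") from exc
    norm_doc = {**_DEFAULT_NORMALIZATION, **(doc.get("normalization") or {})}
    try:
        norm = make_normalization(**norm_doc)
    except (TypeError, ValueError) as exc:
        raise ModelFileError(f"normalization: {exc}") from exc
    try:
        net = build_network(species, reactions)
    except (KeyError, ValueError) as exc:
        raise ModelFileError(str(exc)) from exc
    return net, norm


def network_to_dict(
    network: ReactionNetwork, normalization: NormalizationScheme | None = None
) -> dict:
    doc = {
        "species": [
            {"name": s.name, "K": s.K, "x0": s.x_init, "chemostat": s.is_chemostat}
            for s in network.species
        ],
        "reactions": [
            {
                "name": r.name,
                "kappa": r.kappa,
                "forward": dict(r.forward),
                "reverse": dict(r.reverse),
            }
            for r in network.reactions
        ],
    }
    if normalization is not None:
        doc["normalization"] = {
            "T": normalization.T,
            "P0": normalization.P0,
            "t0": normalization.t0,
        }
    return doc


def load_model(path) -> ReactionNetwork:
    """Read a model file; see :func:`load_model_with_normalization` for scales."""
    return load_model_with_normalization(path)[0]


def load_model_with_normalization(path) -> tuple[ReactionNetwork, NormalizationScheme]:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return network_from_dict(doc)


def save_model(
    network: ReactionNetwork,
    path,
    normalization: NormalizationScheme | None = None,
) -> None:
    path = Path(path)
    doc = network_to_dict(network, normalization)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
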