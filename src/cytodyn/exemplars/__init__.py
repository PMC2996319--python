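"""Shipped exemplar parameter sets, one per dynamical regime.

Each exemplar is a YAML config produced by a seeded parameter-space
search (:func:`cytodyn.regimes.search_regimes`) and, where noted in the
file header, refined by a one-parameter continuation to sit deep inside
its regime.  The YAML headers document the seed, bounds and refinement
used, so every file is reproducible from the package itself.
"""

from __future__ import annotations

from importlib import resources

from ..io import parameters_from_dict

import yaml

__all__ = ["list_exemplars", "load_exemplar"]


def list_exemplars() -> list[str]:
    """Names of the shipped exemplar parameter sets."""
    out = []
    for entry in resources.files(__package__).iterdir():
        if entry.name.endswith(".yaml"):
            out.append(entry.name[: -len(".yaml")])
    return sorted(out)


def load_exemplar(name: str):
    """Load a shipped exemplar :class:`~cytodyn.params.ModelParameters`."""
    ref = resources.files(__package__) / f"{name}.yaml"
    if not ref.is_file():
        raise KeyError(f"no exemplar {name!r}; available: {list_exemplars()}")
    return parameters_from_dict(yaml.safe_load(ref.read_text()))
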