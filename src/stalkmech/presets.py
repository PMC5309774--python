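"""Loader for the curated selection presets shipped with the package.

The YAML data file mirrors the published residue lists (static rRNA
cores, the H75/H76 domain definitions, displacement markers, groove
atoms, base-pair lists and interaction catalogs).  Presets are
chain-agnostic; bind them to a chain id with ``get_selection(name,
chain_id)``.  Structures that do not follow E. coli numbering need a
per-structure numbering offset (see the dataset manifest), never a
guessed mapping.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .errors import ConfigError
from .structure_io import ResidueSelection


@lru_cache(maxsize=1)
def load_presets() -> dict:
    """Parsed contents of the packaged presets file."""
    text = resources.files("stalkmech.data").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def selection_names() -> list:
    return sorted(load_presets()["selections"])


def get_selection(name: str, chain_id: str, atom_filter=None) -> ResidueSelection:
    """A named preset selection bound to ``chain_id``."""
    presets = load_presets()["selections"]
    if name not in presets:
        raise ConfigError(f"unknown selection preset {name!r}; have {sorted(presets)}")
    return ResidueSelection.from_ranges(chain_id, presets[name], atom_filter)


def get_marker(name: str, chain_id: str) -> tuple:
    """A named (chain, residue, atom) displacement marker."""
    markers = load_presets()["markers"]
    if name not in markers:
        raise ConfigError(f"unknown marker {name!r}; have {sorted(markers)}")
    m = markers[name]
    return (chain_id, int(m["residue"]), str(m["atom"]))


def get_groove_atoms(name: str, chain_id: str) -> tuple:
    """The two (chain, residue, atom) endpoints of a named groove width."""
    grooves = load_presets()["groove"]
    if name not in grooves:
        raise ConfigError(f"unknown groove definition {name!r}; have {sorted(grooves)}")
    g = grooves[name]
    return (
        (chain_id, int(g["a"]["residue"]), str(g["a"]["atom"])),
        (chain_id, int(g["b"]["residue"]), str(g["b"]["atom"])),
    )


def get_base_pairs(name: str, chain_id: str) -> tuple:
    """A named base-pair list bound to one chain (intra-chain duplex)."""
    bps = load_presets()["base_pairs"]
    if name not in bps:
        raise ConfigError(f"unknown base-pair list {name!r}; have {sorted(bps)}")
    return tuple(((chain_id, int(a)), (chain_id, int(b))) for a, b in bps[name])


def get_catalog(name: str) -> list:
    """A named interaction catalog (roles unresolved; see bridge_report)."""
    catalogs = load_presets()["catalogs"]
    if name not in catalogs:
        raise ConfigError(f"unknown catalog {name!r}; have {sorted(catalogs)}")
    return catalogs[name]


def default_boundaries() -> tuple:
    return tuple(load_presets()["classification"]["boundaries"])
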