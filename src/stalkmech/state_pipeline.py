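"""Per-structure metric aggregation and four-state classification.

For every entry of a dataset manifest the pipeline computes, relative
to a reference conformer (the most open stalk, by convention PDB 4GD2,
with 4V9D accepted as an alias): the stalk rotation (screw-axis angle
of the H76 mobile domain after static-core superposition), the
displacement of the stalk-head marker phosphate, optional 30S body and
head rotations (if 16S domain selections are configured), and a stalk
state label.  Classification uses three ascending rotation boundaries;
the defaults (9.2, 17.4, 23.5 degrees) are the midpoints between the
published group means (open 4.0, intermediate 2 14.4, intermediate 1
20.4, closed 26.5 degrees).  Intervals are left-closed: a rotation
exactly on a boundary takes the higher state.

Per-entry failures are logged and skipped; only a failing reference
aborts the run.  The summary table reports per-tRNA-state group mean,
standard deviation and N, recomputable from the per-structure records.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, StalkmechError
from .structure_io import (
    BACKBONE_ATOMS,
    ResidueSelection,
    StructureModel,
    read_structure,
)
from .er_kinematics import displacement_at, domain_rotation

logger = logging.getLogger("stalkmech")

STALK_STATES = ("open", "intermediate2", "intermediate1", "closed")
TRNA_STATES = ("vacant", "P/E", "pe/E", "E/E", "unknown")
DEFAULT_BOUNDARIES = (9.2, 17.4, 23.5)
REFERENCE_ALIASES = {"4GD2": ("4V9D",), "4V9D": ("4GD2",)}


def classify_state(rotation: float, boundaries: Sequence[float] = DEFAULT_BOUNDARIES) -> str:
    """Stalk-state label for a rotation magnitude (degrees, >= 0)."""
    b = tuple(float(x) for x in boundaries)
    if len(b) != 3 or not (b[0] < b[1] < b[2]):
        raise ConfigError(f"boundaries must be 3 ascending values, got {boundaries}")
    if rotation < 0:
        raise ConfigError(f"rotation must be >= 0, got {rotation}")
    if rotation < b[0]:
        return "open"
    if rotation < b[1]:
        return "intermediate2"
    if rotation < b[2]:
        return "intermediate1"
    return "closed"


@dataclass(frozen=True)
class StateRecord:
    source_id: str
    stalk_rotation: float
    stalk_displacement: float
    stalk_state: str
    trna_state: str = "unknown"
    body_rotation: float | None = None
    head_rotation: float | None = None


@dataclass(frozen=True)
class ManifestEntry:
    source_id: str
    trna_state: str = "unknown"
    species_tag: str = "bacterial"
    path: str | None = None
    model: StructureModel | None = None
    chain_map: Mapping[str, str] = field(default_factory=dict)
    numbering_offsets: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.trna_state not in TRNA_STATES:
            raise ConfigError(f"unknown trna_state {self.trna_state!r}")
        if self.path is None and self.model is None:
            raise ConfigError(f"entry {self.source_id}: need a path or an in-memory model")

    def load(self) -> StructureModel:
        if self.model is not None:
            return self.model
        return read_structure(self.path, source_id=self.source_id, species_tag=self.species_tag)


@dataclass(frozen=True)
class DatasetManifest:
    entries: tuple

    def __post_init__(self):
        ids = [e.source_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate source_ids in manifest")

    def get(self, source_id: str) -> ManifestEntry | None:
        for e in self.entries:
            if e.source_id == source_id:
                return e
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetManifest":
        doc = yaml.safe_load(Path(path).read_text())
        entries = []
        for raw in doc["entries"]:
            entries.append(
                ManifestEntry(
                    source_id=str(raw["source_id"]),
                    trna_state=raw.get("trna_state", "unknown"),
                    species_tag=raw.get("species_tag", "bacterial"),
                    path=raw.get("path"),
                    chain_map=raw.get("chain_map", {}),
                    numbering_offsets=raw.get("numbering_offsets", {}),
                )
            )
        return cls(tuple(entries))


@dataclass(frozen=True)
class PipelineConfig:
    """Selections and parameters driving the per-entry computation.

    Selections are given in the reference structure's chain/numbering
    convention; per-entry numbering offsets from the manifest are
    applied on top.  Body/head selections (16S domains) are optional —
    they are site-specific and not shipped as a preset; provide your
    own to populate the body/head rotation columns.
    """

    core_sel: ResidueSelection
    static_sel: ResidueSelection
    mobile_sel: ResidueSelection
    marker: tuple
    boundaries: Sequence[float] = DEFAULT_BOUNDARIES
    body_sel: ResidueSelection | None = None
    head_sel: ResidueSelection | None = None
    body_static_sel: ResidueSelection | None = None
    backbone_atoms: frozenset = BACKBONE_ATOMS


def _entry_selection(sel: ResidueSelection, entry: ManifestEntry) -> ResidueSelection:
    if entry.numbering_offsets:
        return sel.shifted(entry.numbering_offsets)
    return sel


def run_dataset(
    manifest: DatasetManifest,
    config: PipelineConfig,
    reference_id: str = "4GD2",
) -> tuple[list, pd.DataFrame]:
    """Compute one StateRecord per manifest entry plus the group summary.

    Returns (records, summary); the summary has per-tRNA-state rows
    with mean/sd/N of stalk rotation and displacement.
    """
    ref_entry = manifest.get(reference_id)
    if ref_entry is None:
        for alias in REFERENCE_ALIASES.get(reference_id, ()):
            ref_entry = manifest.get(alias)
            if ref_entry is not None:
                logger.warning(
                    "reference %s not in manifest; using alias %s", reference_id, alias
                )
                break
    if ref_entry is None:
        raise ConfigError(f"reference {reference_id!r} (or alias) not found in manifest")

    reference = ref_entry.load()

    records: list[StateRecord] = []
    for entry in manifest.entries:
        t0 = time.perf_counter()
        try:
            model = entry.load()
            rotation = domain_rotation(
                model,
                reference,
                _entry_selection(config.static_sel, entry),
                _entry_selection(config.mobile_sel, entry),
                config.backbone_atoms,
            ).angle
            displacement = displacement_at(
                model,
                reference,
                config.marker,
                core_sel=_entry_selection(config.core_sel, entry),
                backbone_atoms=config.backbone_atoms,
            )
            body = head = None
            if config.body_sel is not None and config.body_static_sel is not None:
                body = domain_rotation(
                    model, reference, config.body_static_sel, config.body_sel,
                    config.backbone_atoms,
                ).angle
            if config.head_sel is not None and config.body_static_sel is not None:
                head = domain_rotation(
                    model, reference, config.body_static_sel, config.head_sel,
                    config.backbone_atoms,
                ).angle
            records.append(
                StateRecord(
                    entry.source_id,
                    rotation,
                    displacement,
                    classify_state(rotation, config.boundaries),
                    entry.trna_state,
                    body,
                    head,
                )
            )
            logger.info(
                "%s: rotation %.2f deg, displacement %.2f A (%.2f s)",
                entry.source_id, rotation, displacement, time.perf_counter() - t0,
            )
        except (StalkmechError, FileNotFoundError) as exc:
            if entry.source_id == ref_entry.source_id:
                raise
            logger.warning("skipping %s: %s", entry.source_id, exc)
    return records, summarize(records)


def records_frame(records: Sequence[StateRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "source_id": r.source_id,
                "trna_state": r.trna_state,
                "stalk_state": r.stalk_state,
                "stalk_rotation_deg": r.stalk_rotation,
                "stalk_displacement_A": r.stalk_displacement,
                "body_rotation_deg": r.body_rotation,
                "head_rotation_deg": r.head_rotation,
            }
            for r in records
        ]
    )


def summarize(records: Sequence[StateRecord]) -> pd.DataFrame:
    """Group means +/- sd and N per tRNA binding state."""
    df = records_frame(records)
    if df.empty:
        return df
    grouped = df.groupby("trna_state", sort=False)
    out = grouped.agg(
        stalk_rotation_mean=("stalk_rotation_deg", "mean"),
        stalk_rotation_sd=("stalk_rotation_deg", "std"),
        stalk_displacement_mean=("stalk_displacement_A", "mean"),
        stalk_displacement_sd=("stalk_displacement_A", "std"),
        n=("source_id", "count"),
    ).reset_index()
    return out
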