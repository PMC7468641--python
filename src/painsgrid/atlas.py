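"""Discretized body grid (atlas) over which all pain scores are computed.

The atlas is a partition of the body surface into square cells arranged on
per-segment 2D charts (head, neck, trunk, arm, hand, leg, foot).  Every cell
belongs to exactly one named region, and every region is lateralized (left /
right; a midline category exists for charts that need it).  The default
atlas is a count-faithful reconstruction of the grid used by cell-based
pain-mapping apps: 2026 cells in total, 382 in the head-and-neck area, 322
in the head alone, 54 lateralized regions collapsing to 27 region names.
The published grid geometry is proprietary, so segment charts are laid out
as rectangular patches; all downstream scores depend only on counts,
membership and within-chart coordinates, not on anatomical shape.

Cells are stored in a :class:`pandas.DataFrame` (one row per cell), which is
the natural container for the vectorized scoring and simulation code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import AtlasIntegrityError, AtlasSchemaError, ScopeError

SIDES = ("left", "right", "midline")
SEGMENTS = ("head", "neck", "trunk", "arm", "hand", "leg", "foot")

#: physical edge length of one grid cell on the reference adult model, in cm.
#: Metadata only -- the cell size rescales with body type and never enters
#: any computation.
CELL_SIZE_CM = 1.6

ATLAS_VERSION = "default-2026"

# (region name, segment, cells per side).  Chosen so that the printed totals
# hold: head 161/side (322), neck 30/side (382 head+neck), full body
# 1013/side (2026); 27 names -> 54 lateralized regions.
_REGION_SPEC: tuple[tuple[str, str, int], ...] = (
    ("forehead", "head", 24),
    ("temple", "head", 20),
    ("eye", "head", 15),
    ("nose", "head", 12),
    ("cheek", "head", 24),
    ("ear", "head", 14),
    ("jaw", "head", 22),
    ("mouth", "head", 14),
    ("scalp", "head", 16),
    ("neck", "neck", 30),
    ("chest", "trunk", 80),
    ("abdomen", "trunk", 70),
    ("upper_back", "trunk", 80),
    ("lower_back", "trunk", 70),
    ("shoulder", "arm", 40),
    ("upper_arm", "arm", 60),
    ("elbow", "arm", 20),
    ("forearm", "arm", 60),
    ("wrist", "arm", 16),
    ("palm", "hand", 30),
    ("hand_dorsum", "hand", 30),
    ("fingers", "hand", 40),
    ("hip", "leg", 36),
    ("thigh", "leg", 70),
    ("knee", "leg", 20),
    ("lower_leg", "leg", 60),
    ("foot", "foot", 40),
)

# chart width (columns per side) for each segment's rectangular layout
_SEGMENT_WIDTH = {
    "head": 7,
    "neck": 6,
    "trunk": 10,
    "arm": 6,
    "hand": 5,
    "leg": 8,
    "foot": 5,
}

_CELL_COLUMNS = ["cell_id", "region_id", "side", "segment", "row", "col"]
_REGION_COLUMNS = ["region_id", "name", "side"]


@dataclass
class BodyAtlas:
    """A validated body grid: cell table, region table, and metadata.

    Parameters
    ----------
    cells
        One row per cell with columns ``cell_id, region_id, side, segment,
        row, col``.
    regions
        One row per lateralized region with columns ``region_id, name, side``.
    version
        Free-form version string carried through serialization.
    cell_size_cm
        Nominal physical cell edge on the reference model (metadata only).
    """

    cells: pd.DataFrame
    regions: pd.DataFrame
    version: str = ATLAS_VERSION
    cell_size_cm: float = CELL_SIZE_CM

    def __post_init__(self) -> None:
        self.cells = pd.DataFrame(self.cells)[_CELL_COLUMNS].reset_index(drop=True)
        self.regions = pd.DataFrame(self.regions)[_REGION_COLUMNS].reset_index(drop=True)
        _validate_atlas(self.cells, self.regions)

    # -- basic queries ----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_region_names(self) -> int:
        """Number of region names when left/right are merged."""
        return self.regions["name"].nunique()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cells["cell_id"].to_numpy()

    def cell(self, cell_id: int) -> pd.Series:
        rows = self.cells.loc[self.cells["cell_id"] == cell_id]
        if rows.empty:
            raise ScopeError(f"cell_id {cell_id} not in atlas")
        return rows.iloc[0]

    def region_id(self, name: str, side: str) -> int:
        rows = self.regions.loc[
            (self.regions["name"] == name) & (self.regions["side"] == side)
        ]
        if rows.empty:
            raise ScopeError(f"no region named {name!r} on side {side!r}")
        return int(rows["region_id"].iloc[0])

    def segment_diagonal(self, segment: str) -> float:
        """Diagonal extent of a segment chart (used as cross-chart penalty)."""
        sub = self.cells.loc[self.cells["segment"] == segment]
        if sub.empty:
            raise ScopeError(f"unknown segment {segment!r}")
        dr = sub["row"].max() - sub["row"].min() + 1
        dc = sub["col"].max() - sub["col"].min() + 1
        return math.hypot(float(dr), float(dc))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BodyAtlas):
            return NotImplemented
        return (
            self.version == other.version
            and self.cell_size_cm == other.cell_size_cm
            and self.cells.sort_values("cell_id").reset_index(drop=True).equals(
                other.cells.sort_values("cell_id").reset_index(drop=True)
            )
            and self.regions.sort_values("region_id").reset_index(drop=True).equals(
                other.regions.sort_values("region_id").reset_index(drop=True)
            )
        )


def _validate_atlas(cells: pd.DataFrame, regions: pd.DataFrame) -> None:
    if regions["region_id"].duplicated().any():
        dup = regions.loc[regions["region_id"].duplicated(), "region_id"].iloc[0]
        raise AtlasIntegrityError(f"duplicate region_id {dup}")
    bad_side = set(regions["side"]) - set(SIDES)
    if bad_side:
        raise AtlasSchemaError(f"invalid region side value(s): {sorted(bad_side)}")

    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise AtlasIntegrityError(f"duplicate cell_id {dup}")
    bad_side = set(cells["side"]) - set(SIDES)
    if bad_side:
        raise AtlasSchemaError(f"invalid cell side value(s): {sorted(bad_side)}")
    bad_seg = set(cells["segment"]) - set(SEGMENTS)
    if bad_seg:
        raise AtlasSchemaError(f"invalid segment value(s): {sorted(bad_seg)}")
    if (cells["row"] < 0).any() or (cells["col"] < 0).any():
        raise AtlasSchemaError("cell grid coordinates must be non-negative")
    if cells.duplicated(subset=["segment", "side", "row", "col"]).any():
        raise AtlasIntegrityError("duplicate (segment, side, row, col) coordinate")
    unknown = set(cells["region_id"]) - set(regions["region_id"])
    if unknown:
        raise AtlasIntegrityError(
            f"cells reference unknown region_id(s): {sorted(unknown)}"
        )


def build_default_atlas() -> BodyAtlas:
    """Construct the default 2026-cell full-body atlas.

    Deterministic: region names and per-region cell counts are fixed module
    constants; each segment chart packs its regions as consecutive rows of a
    rectangular grid, left side in columns ``[0, w)`` and right side in
    ``[w, 2w)`` of the same chart.
    """
    region_rows = []
    cell_rows = []
    region_id = 0
    cell_id = 0
    # running row cursor per (segment, side) so regions stack vertically
    cursor: dict[tuple[str, str], int] = {}
    for name, segment, count in _REGION_SPEC:
        width = _SEGMENT_WIDTH[segment]
        for side_idx, side in enumerate(("left", "right")):
            region_id += 1
            region_rows.append({"region_id": region_id, "name": name, "side": side})
            row0 = cursor.get((segment, side), 0)
            col0 = side_idx * width
            for k in range(count):
                cell_id += 1
                cell_rows.append(
                    {
                        "cell_id": cell_id,
                        "region_id": region_id,
                        "side": side,
                        "segment": segment,
                        "row": row0 + k // width,
                        "col": col0 + k % width,
                    }
                )
            cursor[(segment, side)] = row0 + math.ceil(count / width)
    return BodyAtlas(
        cells=pd.DataFrame(cell_rows),
        regions=pd.DataFrame(region_rows),
        version=ATLAS_VERSION,
        cell_size_cm=CELL_SIZE_CM,
    )


# -- serialization ---------------------------------------------------------

def save_atlas(atlas: BodyAtlas, path) -> None:
    """Write an atlas to ``path`` as a JSON document (schema in the docs)."""
    doc = {
        "version": atlas.version,
        "cell_size_cm": atlas.cell_size_cm,
        "regions": atlas.regions.to_dict(orient="records"),
        "cells": atlas.cells.to_dict(orient="records"),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_atlas(path) -> BodyAtlas:
    """Read and validate an atlas JSON document.

    Raises
    ------
    AtlasSchemaError
        If a required field is missing or has the wrong type; the message
        names the offending cell/region.
    AtlasIntegrityError
        If a structural invariant (unique ids, coordinate uniqueness,
        region references) is violated.
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("version", "cell_size_cm", "regions", "cells"):
        if key not in doc:
            raise AtlasSchemaError(f"atlas document missing top-level field {key!r}")
    regions = _records_to_frame(doc["regions"], _REGION_COLUMNS, "region")
    cells = _records_to_frame(doc["cells"], _CELL_COLUMNS, "cell")
    return BodyAtlas(
        cells=cells,
        regions=regions,
        version=str(doc["version"]),
        cell_size_cm=float(doc["cell_size_cm"]),
    )


def _records_to_frame(records, columns: list[str], kind: str) -> pd.DataFrame:
    if not isinstance(records, list):
        raise AtlasSchemaError(f"{kind} list must be a JSON array")
    for i, rec in enumerate(records):
        if not isinstance(rec, dict):
            raise AtlasSchemaError(f"{kind} entry {i} is not an object")
        missing = [c for c in columns if c not in rec]
        if missing:
            ident = rec.get(f"{kind}_id", f"index {i}")
            raise AtlasSchemaError(
                f"{kind} {ident} missing field(s): {', '.join(missing)}"
            )
    if not records:
        raise AtlasSchemaError(f"atlas has no {kind} entries")
    return pd.DataFrame.from_records(records)[columns]


# -- scopes ----------------------------------------------------------------

def scope_cells(atlas: BodyAtlas, scope) -> set[int]:
    """Resolve a scope expression to the set of cell_ids it contains.

    A scope is a string, or an iterable of strings combined by
    *intersection*.  Atomic scopes::

        full                 all cells
        head                 the head segment
        head_neck            head and neck segments
        neck                 the neck segment
        segment:<name>       any single segment chart
        region:<id>          one lateralized region by integer id
        region:<name>        both sides of a named region
        side:left|right|midline

    Strings may also combine atoms inline with ``&``
    (e.g. ``"head_neck&side:right"``).
    """
    if isinstance(scope, str):
        tokens: Iterable[str] = scope.split("&")
    else:
        tokens = [t for part in scope for t in str(part).split("&")]
    cells = atlas.cells
    mask = np.ones(len(cells), dtype=bool)
    for token in tokens:
        token = token.strip()
        mask &= _atom_mask(atlas, token)
    return set(cells.loc[mask, "cell_id"].tolist())


def _atom_mask(atlas: BodyAtlas, token: str) -> np.ndarray:
    cells = atlas.cells
    if token == "full":
        return np.ones(len(cells), dtype=bool)
    if token == "head_neck":
        return cells["segment"].isin(["head", "neck"]).to_numpy()
    if token in SEGMENTS:
        return (cells["segment"] == token).to_numpy()
    if token.startswith("segment:"):
        seg = token.split(":", 1)[1]
        if seg not in SEGMENTS:
            raise ScopeError(f"unknown segment {seg!r}")
        return (cells["segment"] == seg).to_numpy()
    if token.startswith("side:"):
        side = token.split(":", 1)[1]
        if side not in SIDES:
            raise ScopeError(f"unknown side {side!r} (allowed: {', '.join(SIDES)})")
        return (cells["side"] == side).to_numpy()
    if token.startswith("region:"):
        ident = token.split(":", 1)[1]
        if ident.isdigit():
            rid = int(ident)
            if rid not in set(atlas.regions["region_id"]):
                raise ScopeError(f"unknown region_id {rid}")
            return (cells["region_id"] == rid).to_numpy()
        rids = atlas.regions.loc[atlas.regions["name"] == ident, "region_id"]
        if rids.empty:
            raise ScopeError(f"unknown region name {ident!r}")
        return cells["region_id"].isin(rids).to_numpy()
    raise ScopeError(f"cannot parse scope token {token!r}")
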