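"""Domain types for forest-census co-occurrence data.

The unit of observation is an individual tree (>= 10 cm dbh) inside a
20 x 20 m plot nested in a forest patch.  Lianas (woody climbers,
stem diameter >= 1 cm) and vascular epiphytes are recorded per host
tree; epiphyte abundance uses the modified Braun-Blanquet cover scale
(1 = 1-5%, 2 = 6-25%, 3 = 26-50%, 4 = 51-75%, 5 = 76-100%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ValidationError, ReferentialIntegrityError

ZONES = ("trunk", "crown")
MECHANISMS = ("specialized", "leaning")
FOREST_TYPES = ("successional", "mature")

#: census threshold for tree inclusion, cm dbh
MIN_TREE_DBH = 10.0
#: minimum liana stem diameter at 130 cm, cm
MIN_LIANA_DIAMETER = 1.0


@dataclass(frozen=True)
class TreeRecord:
    tree_id: str
    patch_id: str
    plot_id: str
    species: str
    dbh: float
    x: Optional[float] = None
    y: Optional[float] = None

    @property
    def mapped(self) -> bool:
        return self.x is not None and self.y is not None


@dataclass(frozen=True)
class LianaRecord:
    tree_id: str
    species: str
    diameter: float
    mechanism: str  # "specialized" | "leaning"
    zone: str  # "trunk" | "crown"


@dataclass(frozen=True)
class EpiphyteRecord:
    tree_id: str
    species: str
    cover_class: int  # 1..5
    zones: frozenset  # non-empty subset of {"trunk", "crown"}


def basal_area(diameter: float) -> float:
    """Cross-sectional stem area in m^2 for a diameter in cm.

    ``pi * (d / 200)**2`` — the abundance currency for lianas.

    Raises
    ------
    ValueError
        If ``diameter`` is not strictly positive.
    """
    d = np.asarray(diameter, dtype=float)
    if np.any(d <= 0):
        raise ValueError("basal_area requires a strictly positive diameter")
    out = math.pi * (d / 200.0) ** 2
    return float(out) if np.isscalar(diameter) else out


@dataclass(frozen=True)
class DbhClassScheme:
    """Ordered dbh breakpoints (cm) defining k+1 size classes.

    The default breakpoints are the size-class quartile bounds used for
    the tree-scale association tables.  Classes are half-open on the
    left, ``[b_{i-1}, b_i)``, so every dbh maps to exactly one class;
    class indices are 1-based.
    """

    breakpoints: tuple = (13.15, 19.75, 33.76)

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        object.__setattr__(self, "breakpoints", bp)

    @property
    def n_classes(self) -> int:
        return len(self.breakpoints) + 1

    def labels(self) -> list:
        bp = self.breakpoints
        labs = [f"<{bp[0]:g}"]
        labs += [f"{a:g}-{b:g}" for a, b in zip(bp, bp[1:])]
        labs.append(f">={bp[-1]:g}")
        return labs

    def assign(self, dbh) -> np.ndarray:
        """1-based class index for each dbh (scalar or array)."""
        d = np.asarray(dbh, dtype=float)
        idx = np.searchsorted(np.asarray(self.breakpoints), d, side="right") + 1
        return int(idx) if np.isscalar(dbh) else idx


def dbh_class(dbh: float, scheme: DbhClassScheme = DbhClassScheme()) -> int:
    """Size class (1..k+1) of a single dbh under ``scheme``."""
    if dbh < MIN_TREE_DBH:
        raise ValueError(f"dbh {dbh} below census threshold {MIN_TREE_DBH}")
    return int(scheme.assign(dbh))


@dataclass
class ForestDataset:
    """A full census: trees plus liana and epiphyte records.

    ``patch_meta`` maps every patch id to its forest type
    ("successional" or "mature").  Trees may legitimately carry zero
    liana and zero epiphyte records; absence is encoded by absence.
    """

    trees: list = field(default_factory=list)
    lianas: list = field(default_factory=list)
    epiphytes: list = field(default_factory=list)
    patch_meta: dict = field(default_factory=dict)

    # -- validation ---------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ValidationError` listing every invariant breach."""
        problems = []
        seen = set()
        for t in self.trees:
            key = (t.patch_id, t.plot_id, t.tree_id)
            if key in seen:
                problems.append(f"duplicate tree key {key}")
            seen.add(key)
            if t.dbh < MIN_TREE_DBH:
                problems.append(f"tree {t.tree_id}: dbh {t.dbh} < {MIN_TREE_DBH}")
            if (t.x is None) != (t.y is None):
                problems.append(f"tree {t.tree_id}: x and y must both be present or both absent")
            if t.patch_id not in self.patch_meta:
                problems.append(f"tree {t.tree_id}: patch {t.patch_id} missing from patch_meta")
        ids = {t.tree_id for t in self.trees}
        ref_problems = []
        for i, l in enumerate(self.lianas):
            if l.tree_id not in ids:
                ref_problems.append(f"liana row {i}: unknown tree_id {l.tree_id!r}")
            if l.diameter < MIN_LIANA_DIAMETER:
                problems.append(f"liana row {i}: diameter {l.diameter} < {MIN_LIANA_DIAMETER}")
            if l.mechanism not in MECHANISMS:
                problems.append(f"liana row {i}: unknown mechanism {l.mechanism!r}")
            if l.zone not in ZONES:
                problems.append(f"liana row {i}: unknown zone {l.zone!r}")
        for i, e in enumerate(self.epiphytes):
            if e.tree_id not in ids:
                ref_problems.append(f"epiphyte row {i}: unknown tree_id {e.tree_id!r}")
            if not (1 <= int(e.cover_class) <= 5):
                problems.append(f"epiphyte row {i}: cover_class {e.cover_class} outside 1..5")
            if not e.zones or not set(e.zones) <= set(ZONES):
                problems.append(f"epiphyte row {i}: invalid zones {set(e.zones)}")
        for p, meta in self.patch_meta.items():
            ft = meta.get("forest_type") if isinstance(meta, dict) else meta
            if ft not in FOREST_TYPES:
                problems.append(f"patch {p}: forest_type {ft!r} not in {FOREST_TYPES}")
        if ref_problems:
            raise ReferentialIntegrityError(ref_problems + problems)
        if problems:
            raise ValidationError(problems)

    # -- convenience accessors ---------------------------------------

    def forest_type(self, patch_id: str) -> str:
        meta = self.patch_meta[patch_id]
        return meta["forest_type"] if isinstance(meta, dict) else meta

    @property
    def patch_ids(self) -> list:
        return sorted(self.patch_meta)

    def liana_hosts(self) -> set:
        return {l.tree_id for l in self.lianas}

    def epiphyte_hosts(self) -> set:
        return {e.tree_id for e in self.epiphytes}

    def trees_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree_id": [t.tree_id for t in self.trees],
                "patch_id": [t.patch_id for t in self.trees],
                "plot_id": [t.plot_id for t in self.trees],
                "species": [t.species for t in self.trees],
                "dbh": [t.dbh for t in self.trees],
                "x": [t.x for t in self.trees],
                "y": [t.y for t in self.trees],
            }
        )

    def lianas_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree_id": [l.tree_id for l in self.lianas],
                "species": [l.species for l in self.lianas],
                "diameter": [l.diameter for l in self.lianas],
                "mechanism": [l.mechanism for l in self.lianas],
                "zone": [l.zone for l in self.lianas],
            }
        )

    def epiphytes_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree_id": [e.tree_id for e in self.epiphytes],
                "species": [e.species for e in self.epiphytes],
                "cover_class": [int(e.cover_class) for e in self.epiphytes],
                "zones": ["|".join(sorted(e.zones)) for e in self.epiphytes],
            }
        )

    def tree_table(self) -> pd.DataFrame:
        """Per-tree analysis table with host flags and aggregates.

        Columns: tree_id, patch_id, plot_id, species, dbh, x, y,
        forest_type, liana_host, epi_host, liana_richness, liana_ba
        (summed basal area, m^2), epi_richness, epi_cover (max recorded
        cover class, 0 for non-hosts).
        """
        tf = self.trees_frame()
        tf["forest_type"] = [self.forest_type(p) for p in tf["patch_id"]]
        lr, lba = {}, {}
        lsp = {}
        for l in self.lianas:
            lsp.setdefault(l.tree_id, set()).add(l.species)
            lba[l.tree_id] = lba.get(l.tree_id, 0.0) + basal_area(l.diameter)
        lr = {k: len(v) for k, v in lsp.items()}
        esp, ecv = {}, {}
        for e in self.epiphytes:
            esp.setdefault(e.tree_id, set()).add(e.species)
            ecv[e.tree_id] = max(ecv.get(e.tree_id, 0), int(e.cover_class))
        er = {k: len(v) for k, v in esp.items()}
        ids = tf["tree_id"]
        tf["liana_host"] = ids.isin(lr).to_numpy()
        tf["epi_host"] = ids.isin(er).to_numpy()
        tf["liana_richness"] = ids.map(lr).fillna(0).astype(int)
        tf["liana_ba"] = ids.map(lba).fillna(0.0)
        tf["epi_richness"] = ids.map(er).fillna(0).astype(int)
        tf["epi_cover"] = ids.map(ecv).fillna(0).astype(int)
        return tf

    def subset_patch(self, patch_id: str) -> "ForestDataset":
        keep = {t.tree_id for t in self.trees if t.patch_id == patch_id}
        return ForestDataset(
            trees=[t for t in self.trees if t.patch_id == patch_id],
            lianas=[l for l in self.lianas if l.tree_id in keep],
            epiphytes=[e for e in self.epiphytes if e.tree_id in keep],
            patch_meta={patch_id: self.patch_meta[patch_id]},
        )
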