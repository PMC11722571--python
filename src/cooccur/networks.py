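"""Weighted bipartite interaction matrices.

Three flavors of species x species matrix summarize who occurs on
whom:

* liana x tree, weighted by total liana basal area (m^2);
* epiphyte x tree, weighted by the number of (record, zone)
  occupancies — each record contributes |zones| in {1, 2};
* epiphyte x liana, weighted by the number of trees hosting both
  species (only trees carrying both guilds can contribute).

Matrices are pandas DataFrames (rows = first guild, columns =
second); all-zero rows and columns are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ForestDataset, basal_area

__all__ = [
    "BipartiteMatrix",
    "liana_tree_matrix",
    "epiphyte_tree_matrix",
    "epiphyte_liana_matrix",
    "network_report",
]


@dataclass
class BipartiteMatrix:
    """A labeled non-negative species x species weight matrix."""

    weights: pd.DataFrame  # rows: row guild species, cols: column guild
    weight_kind: str  # basal_area_m2 | zone_count | shared_tree_count

    def __post_init__(self):
        w = self.weights
        if (w.to_numpy() < 0).any():
            raise ValueError("bipartite weights must be non-negative")
        # drop empty rows/columns, keep deterministic (sorted) ordering
        w = w.loc[w.sum(axis=1) > 0, w.sum(axis=0) > 0]
        self.weights = w.sort_index(axis=0).sort_index(axis=1)

    @property
    def row_species(self):
        return list(self.weights.index)

    @property
    def col_species(self):
        return list(self.weights.columns)

    @property
    def total(self) -> float:
        return float(self.weights.to_numpy().sum())

    def is_empty(self) -> bool:
        return self.weights.size == 0


def _pivot(pairs: dict, kind: str) -> BipartiteMatrix:
    if not pairs:
        return BipartiteMatrix(pd.DataFrame(dtype=float), kind)
    rows = sorted({r for r, _ in pairs})
    cols = sorted({c for _, c in pairs})
    w = pd.DataFrame(0.0, index=rows, columns=cols)
    for (r, c), v in pairs.items():
        w.loc[r, c] = v
    return BipartiteMatrix(w, kind)


def liana_tree_matrix(ds: ForestDataset) -> BipartiteMatrix:
    """Liana x tree species matrix of summed liana basal area (m^2)."""
    tree_sp = {t.tree_id: t.species for t in ds.trees}
    acc = {}
    for l in ds.lianas:
        key = (l.species, tree_sp[l.tree_id])
        acc[key] = acc.get(key, 0.0) + basal_area(l.diameter)
    return _pivot(acc, "basal_area_m2")


def epiphyte_tree_matrix(ds: ForestDataset) -> BipartiteMatrix:
    """Epiphyte x tree species matrix of zone-occupancy counts."""
    tree_sp = {t.tree_id: t.species for t in ds.trees}
    acc = {}
    for e in ds.epiphytes:
        key = (e.species, tree_sp[e.tree_id])
        acc[key] = acc.get(key, 0.0) + len(e.zones)
    return _pivot(acc, "zone_count")


def epiphyte_liana_matrix(ds: ForestDataset,
                          weight: str = "shared_tree_count") -> BipartiteMatrix:
    """Epiphyte x liana species matrix over trees hosting both guilds.

    With the default ``shared_tree_count`` weighting, a cell counts
    the trees on which both species occur.  ``occurrence_product``
    instead sums, per shared tree, the product of the two species'
    record counts there (an occurrence-weighted alternative).
    """
    if weight not in ("shared_tree_count", "occurrence_product"):
        raise ValueError(f"unknown weight scheme {weight!r}")
    epi_on = {}
    for e in ds.epiphytes:
        epi_on.setdefault(e.tree_id, []).append(e.species)
    liana_on = {}
    for l in ds.lianas:
        liana_on.setdefault(l.tree_id, []).append(l.species)
    acc = {}
    for tid in set(epi_on) & set(liana_on):
        ecnt = pd.Series(epi_on[tid]).value_counts()
        lcnt = pd.Series(liana_on[tid]).value_counts()
        for esp, ne in ecnt.items():
            for lsp, nl in lcnt.items():
                v = 1.0 if weight == "shared_tree_count" else float(ne * nl)
                acc[(esp, lsp)] = acc.get((esp, lsp), 0.0) + v
    return _pivot(acc, weight)


def network_report(m: BipartiteMatrix, top_k: int = 10) -> dict:
    """Marginal totals and top-k species rankings.

    Species are ranked by marginal weight descending, ties broken
    alphabetically.  An empty matrix yields an empty report.
    """
    if m.is_empty():
        return {"weight_kind": m.weight_kind, "row_totals": {}, "col_totals": {},
                "top_rows": [], "top_cols": []}

    def ranked(s: pd.Series):
        df = s.rename("w").reset_index().rename(columns={"index": "species"})
        df = df.sort_values(["w", "species"], ascending=[False, True])
        return list(df.itertuples(index=False, name=None))

    rows = ranked(m.weights.sum(axis=1))
    cols = ranked(m.weights.sum(axis=0))
    return {
        "weight_kind": m.weight_kind,
        "row_totals": dict(rows),
        "col_totals": dict(cols),
        "top_rows": [sp for sp, _ in rows[:top_k]],
        "top_cols": [sp for sp, _ in cols[:top_k]],
    }
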