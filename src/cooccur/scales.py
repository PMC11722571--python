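"""Occurrence summaries and association tests at three ecological scales.

Tree scale: 2x2 presence/absence tables of lianas x epiphytes per tree
size class, tested with a continuity-corrected (Yates) chi-square.
Zone scale: per-plot occurrence counts on trunks and crowns.  Patch
scale: host counts and shared-host percentages per forest patch.

A "host" is a tree with at least one record of the guild, regardless
of zone.  Shared-host percentages use the union of hosts as the
denominator: ``100 * shared / (liana_hosts + epi_hosts - shared)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DbhClassScheme, ForestDataset
from .errors import DegenerateTableError

__all__ = [
    "ContingencyTable2x2",
    "contingency_by_class",
    "yates_chi2",
    "shared_pct",
    "zone_occurrences",
    "patch_summaries",
    "class_cooccurrence_table",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Liana x epiphyte presence counts over a set of trees."""

    n_both: int
    n_liana_only: int
    n_epi_only: int
    n_neither: int

    def __post_init__(self):
        if min(self.n_both, self.n_liana_only, self.n_epi_only, self.n_neither) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.n_both + self.n_liana_only + self.n_epi_only + self.n_neither

    @property
    def n_liana_hosts(self) -> int:
        return self.n_both + self.n_liana_only

    @property
    def n_epi_hosts(self) -> int:
        return self.n_both + self.n_epi_only

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.n_both, self.n_liana_only], [self.n_epi_only, self.n_neither]],
            dtype=float,
        )

    @classmethod
    def from_margins(cls, n_trees: int, n_liana_hosts: int, n_epi_hosts: int,
                     n_shared: int) -> "ContingencyTable2x2":
        """Reconstruct cells from the counts a summary table prints."""
        return cls(
            n_both=n_shared,
            n_liana_only=n_liana_hosts - n_shared,
            n_epi_only=n_epi_hosts - n_shared,
            n_neither=n_trees - (n_liana_hosts + n_epi_hosts - n_shared),
        )


def yates_chi2(t: ContingencyTable2x2, correction: bool = True):
    """Chi-square test of independence on a 2x2 table (1 df).

    With ``correction`` (default) the Yates continuity correction is
    applied, clamped at zero: ``sum(max(|O - E| - 0.5, 0)^2 / E)``, so
    a perfectly proportional table scores exactly 0.

    Returns ``(chi2, p)``; raises :class:`DegenerateTableError` when a
    margin is zero (expected counts undefined).
    """
    obs = t.as_array()
    if t.total <= 0:
        raise DegenerateTableError("empty table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DegenerateTableError("zero margin: expected counts undefined")
    expected = np.outer(rows, cols) / t.total
    dev = np.abs(obs - expected)
    if correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def shared_pct(n_liana_hosts: int, n_epi_hosts: int, n_shared: int) -> Optional[float]:
    """Shared hosts as a percentage of the union of hosts.

    Returns ``None`` (not applicable) when no tree hosts either guild.
    """
    union = n_liana_hosts + n_epi_hosts - n_shared
    if n_shared > min(n_liana_hosts, n_epi_hosts) or n_shared < 0:
        raise ValueError("n_shared exceeds a host margin")
    if union == 0:
        return None
    return 100.0 * n_shared / union


def contingency_by_class(ds: ForestDataset,
                         scheme: DbhClassScheme = DbhClassScheme()):
    """One liana x epiphyte presence table per dbh size class.

    Returns a list of ``(class_index, ContingencyTable2x2)`` covering
    every class 1..k+1; empty classes yield all-zero tables.
    """
    tt = ds.tree_table()
    cls = scheme.assign(tt["dbh"].to_numpy())
    out = []
    for c in range(1, scheme.n_classes + 1):
        sub = tt[cls == c]
        both = int((sub.liana_host & sub.epi_host).sum())
        lo = int((sub.liana_host & ~sub.epi_host).sum())
        eo = int((~sub.liana_host & sub.epi_host).sum())
        ne = int((~sub.liana_host & ~sub.epi_host).sum())
        out.append((c, ContingencyTable2x2(both, lo, eo, ne)))
    return out


def class_cooccurrence_table(ds: ForestDataset,
                             scheme: DbhClassScheme = DbhClassScheme()) -> pd.DataFrame:
    """Per-size-class co-occurrence report (one row per dbh class).

    Columns: class_label, n_trees, n_liana_hosts, n_epi_hosts,
    n_shared, shared_pct, chi2, p.  The chi-square columns are NaN for
    degenerate (zero-margin) classes.
    """
    labels = scheme.labels()
    rows = []
    for (c, t), lab in zip(contingency_by_class(ds, scheme), labels):
        try:
            chi2, p = yates_chi2(t)
        except DegenerateTableError:
            chi2 = p = np.nan
        pct = shared_pct(t.n_liana_hosts, t.n_epi_hosts, t.n_both)
        rows.append(
            {
                "class_label": lab,
                "n_trees": t.total,
                "n_liana_hosts": t.n_liana_hosts,
                "n_epi_hosts": t.n_epi_hosts,
                "n_shared": t.n_both,
                "shared_pct": np.nan if pct is None else pct,
                "chi2": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def zone_occurrences(ds: ForestDataset) -> pd.DataFrame:
    """Occurrence counts per plot and tree zone.

    One row per (patch_id, plot_id) with columns ``liana_trunk``,
    ``liana_crown``, ``epi_trunk``, ``epi_crown``.  A liana record
    counts once in its zone; an epiphyte record counts once per zone it
    occupies ((record, zone) pairs).
    """
    plot_of = {t.tree_id: (t.patch_id, t.plot_id) for t in ds.trees}
    keys = sorted({(t.patch_id, t.plot_id) for t in ds.trees})
    counts = {k: {"liana_trunk": 0, "liana_crown": 0, "epi_trunk": 0, "epi_crown": 0}
              for k in keys}
    for l in ds.lianas:
        counts[plot_of[l.tree_id]][f"liana_{l.zone}"] += 1
    for e in ds.epiphytes:
        for z in e.zones:
            counts[plot_of[e.tree_id]][f"epi_{z}"] += 1
    df = pd.DataFrame(
        [{"patch_id": k[0], "plot_id": k[1], **counts[k]} for k in keys]
    )
    return df


def patch_summaries(ds: ForestDataset) -> pd.DataFrame:
    """Host counts and shared-host percentage per forest patch.

    Columns: patch_id, forest_type, n_trees, n_liana_hosts,
    n_epi_hosts, n_shared, shared_pct (NaN where no tree hosts either
    guild).
    """
    tt = ds.tree_table()
    rows = []
    for pid in ds.patch_ids:
        sub = tt[tt.patch_id == pid]
        nl = int(sub.liana_host.sum())
        ne = int(sub.epi_host.sum())
        ns = int((sub.liana_host & sub.epi_host).sum())
        pct = shared_pct(nl, ne, ns)
        rows.append(
            {
                "patch_id": pid,
                "forest_type": ds.forest_type(pid),
                "n_trees": len(sub),
                "n_liana_hosts": nl,
                "n_epi_hosts": ne,
                "n_shared": ns,
                "shared_pct": np.nan if pct is None else pct,
            }
        )
    return pd.DataFrame(rows)
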