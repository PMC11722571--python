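"""Reading and writing the four delimited-text census tables.

Column dialect: CSV with a header row, UTF-8, "." decimal separator.

======== =====================================================
table    columns
======== =====================================================
trees    tree_id, patch_id, plot_id, species, dbh, x, y
lianas   tree_id, species, diameter, mechanism, zone
epiphytes tree_id, species, cover_class, zones  (pipe-joined)
patches  patch_id, forest_type
======== =====================================================
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd

from .datamodel import (
    EpiphyteRecord,
    ForestDataset,
    LianaRecord,
    TreeRecord,
)
from .errors import ValidationError

TREE_COLS = ["tree_id", "patch_id", "plot_id", "species", "dbh", "x", "y"]
LIANA_COLS = ["tree_id", "species", "diameter", "mechanism", "zone"]
EPI_COLS = ["tree_id", "species", "cover_class", "zones"]
PATCH_COLS = ["patch_id", "forest_type"]


def _read(path, required, optional=()):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError([f"{path.name}: missing columns {missing}"])
    for c in optional:
        if c not in df.columns:
            df[c] = None
    return df


def load_dataset(tree_path, liana_path, epiphyte_path, patch_meta_path) -> ForestDataset:
    """Read the four CSV tables and return a validated ForestDataset.

    Rows violating invariants are rejected collectively: a single
    :class:`~cooccur.errors.ValidationError` names every offending row.
    """
    tdf = _read(tree_path, TREE_COLS[:5], optional=("x", "y"))
    ldf = _read(liana_path, LIANA_COLS)
    edf = _read(epiphyte_path, EPI_COLS)
    pdf = _read(patch_meta_path, PATCH_COLS)

    problems = []
    trees = []
    for i, r in tdf.iterrows():
        try:
            x = None if pd.isna(r["x"]) or r["x"] in (None, "") else float(r["x"])
            y = None if pd.isna(r["y"]) or r["y"] in (None, "") else float(r["y"])
            trees.append(
                TreeRecord(
                    tree_id=str(r["tree_id"]),
                    patch_id=str(r["patch_id"]),
                    plot_id=str(r["plot_id"]),
                    species=str(r["species"]),
                    dbh=float(r["dbh"]),
                    x=x,
                    y=y,
                )
            )
        except (TypeError, ValueError) as exc:
            problems.append(f"trees row {i}: {exc}")
    lianas = []
    for i, r in ldf.iterrows():
        try:
            lianas.append(
                LianaRecord(
                    tree_id=str(r["tree_id"]),
                    species=str(r["species"]),
                    diameter=float(r["diameter"]),
                    mechanism=str(r["mechanism"]).strip(),
                    zone=str(r["zone"]).strip(),
                )
            )
        except (TypeError, ValueError) as exc:
            problems.append(f"lianas row {i}: {exc}")
    epiphytes = []
    for i, r in edf.iterrows():
        try:
            zones = frozenset(z.strip() for z in str(r["zones"]).split("|") if z.strip())
            epiphytes.append(
                EpiphyteRecord(
                    tree_id=str(r["tree_id"]),
                    species=str(r["species"]),
                    cover_class=int(r["cover_class"]),
                    zones=zones,
                )
            )
        except (TypeError, ValueError) as exc:
            problems.append(f"epiphytes row {i}: {exc}")
    patch_meta = {
        str(r["patch_id"]): {"forest_type": str(r["forest_type"]).strip()}
        for _, r in pdf.iterrows()
    }
    if problems:
        raise ValidationError(problems)
    ds = ForestDataset(trees=trees, lianas=lianas, epiphytes=epiphytes, patch_meta=patch_meta)
    ds.validate()
    return ds


def load_dataset_dir(directory) -> ForestDataset:
    """Load ``trees.csv``/``lianas.csv``/``epiphytes.csv``/``patches.csv``."""
    d = Path(directory)
    return load_dataset(d / "trees.csv", d / "lianas.csv", d / "epiphytes.csv", d / "patches.csv")


def write_dataset(ds: ForestDataset, directory) -> None:
    """Write the four CSV tables under ``directory`` (created if absent)."""
    d = Path(directory)
    os.makedirs(d, exist_ok=True)
    ds.trees_frame().to_csv(d / "trees.csv", index=False)
    ds.lianas_frame().to_csv(d / "lianas.csv", index=False)
    ds.epiphytes_frame().to_csv(d / "epiphytes.csv", index=False)
    pd.DataFrame(
        {
            "patch_id": ds.patch_ids,
            "forest_type": [ds.forest_type(p) for p in ds.patch_ids],
        }
    ).to_csv(d / "patches.csv", index=False)


def validation_report(directory) -> str:
    """Human-readable validation summary for a dataset directory."""
    try:
        ds = load_dataset_dir(directory)
    except ValidationError as exc:
        lines = ["INVALID dataset:"] + [f"  - {p}" for p in exc.problems]
        return "\n".join(lines)
    except FileNotFoundError as exc:
        return f"INVALID dataset: missing file {exc}"
    tt = ds.tree_table()
    return "\n".join(
        [
            "valid dataset",
            f"  patches: {len(ds.patch_ids)}",
            f"  trees: {len(ds.trees)}",
            f"  liana records: {len(ds.lianas)} on {int(tt.liana_host.sum())} host trees",
            f"  epiphyte records: {len(ds.epiphytes)} on {int(tt.epi_host.sum())} host trees",
            f"  mapped trees: {int(tt.x.notna().sum())}",
        ]
    )
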