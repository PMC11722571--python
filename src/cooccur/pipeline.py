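"""End-to-end orchestration: one config, one seeded, reproducible run.

``run_all`` executes the five analysis stages in order — occurrence
scales, count-model contrasts, host models, interaction networks,
spatial association — writing every stage's tables under the output
directory plus a single ``summary.json``.  Identical config + seed
give identical outputs.  No stage computes anything the corresponding
module function would not: the pipeline only routes data and writes
files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import countmodels, hostmodels, networks, scales, spatial
from .datamodel import DbhClassScheme, ForestDataset
from .errors import CooccurError, InsufficientPointsError
from .io import load_dataset_dir, write_dataset
from .synthetic import StandParams, generate_stand

__all__ = ["RunConfig", "run_all", "StageError"]

HOST_RESPONSES = tuple(hostmodels.FAMILY_OF_RESPONSE)


class StageError(CooccurError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage, exc):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {exc}")


@dataclass
class RunConfig:
    """Settings for a full pipeline run (defaults echo the survey design)."""

    input_dir: Optional[str] = None  # read CSVs here; None = simulate
    output_dir: str = "cooccur_out"
    seed: int = 0
    dbh_breakpoints: tuple = (13.15, 19.75, 33.76)
    # host models
    host_responses: tuple = HOST_RESPONSES
    chains: int = 4
    iterations: int = 8000
    # spatial
    n_sim: int = 10000
    alpha: float = 0.05
    ring_width: float = 2.0
    max_radius: float = 14.0
    spatial_patch: Optional[str] = None  # None = all mapped trees
    skip: tuple = ()  # stage names to skip
    stand: StandParams = field(default_factory=StandParams)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a config from YAML; unknown keys raise, ``stand`` keys
        override StandParams scalar fields."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stand_raw = raw.pop("stand", {})
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise CooccurError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        if stand_raw:
            sknown = {f.name for f in dataclasses.fields(StandParams)}
            sbad = set(stand_raw) - sknown
            if sbad:
                raise CooccurError(f"unknown stand keys: {sorted(sbad)}")
            cfg.stand = dataclasses.replace(cfg.stand, **stand_raw)
        for tup_key in ("dbh_breakpoints", "host_responses", "skip"):
            setattr(cfg, tup_key, tuple(getattr(cfg, tup_key)))
        return cfg


def _stage(summary, name, skip, fn):
    if name in skip:
        summary["stages"][name] = "skipped: by config"
        return None
    try:
        out = fn()
    except InsufficientPointsError as exc:
        summary["stages"][name] = f"skipped: {exc}"
        return None
    except Exception as exc:  # noqa: BLE001 - re-raised with stage name
        raise StageError(name, exc) from exc
    summary["stages"][name] = "ok"
    return out


def _contrast_row(res):
    if res is None:
        return {"estimate": np.nan, "z": np.nan, "p": np.nan, "theta": np.nan}
    return {"estimate": res.estimate, "z": res.z, "p": res.p, "theta": res.theta}


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns the summary dict (also written to
    ``summary.json``)."""
    out = Path(cfg.output_dir)
    os.makedirs(out, exist_ok=True)
    summary = {"seed": cfg.seed, "stages": {}, "inputs": {}}

    if cfg.input_dir:
        ds = load_dataset_dir(cfg.input_dir)
        summary["inputs"]["source"] = str(cfg.input_dir)
    else:
        ds = generate_stand(cfg.stand, seed=cfg.seed)
        summary["inputs"]["source"] = "simulated"
        write_dataset(ds, out / "dataset")
    tt = ds.tree_table()
    summary["inputs"].update(
        {
            "n_trees": len(ds.trees),
            "n_liana_records": len(ds.lianas),
            "n_epiphyte_records": len(ds.epiphytes),
            "liana_host_frac": round(float(tt.liana_host.mean()), 4),
            "epi_host_frac": round(float(tt.epi_host.mean()), 4),
        }
    )

    scheme = DbhClassScheme(cfg.dbh_breakpoints)

    def stage_scales():
        ct = scales.class_cooccurrence_table(ds, scheme)
        ct.to_csv(out / "scales_by_dbh_class.csv", index=False)
        ps = scales.patch_summaries(ds)
        ps.to_csv(out / "scales_by_patch.csv", index=False)
        scales.zone_occurrences(ds).to_csv(out / "zone_occurrences.csv", index=False)
        summary["scales"] = {
            "total_shared": int(ct.n_shared.sum()),
            "shared_pct_overall": round(
                float(100.0 * ct.n_shared.sum() / max(ct.n_trees.sum(), 1)), 2
            ),
        }

    def stage_counts():
        rows = [
            {"analysis": "patch", "unit": pid, **_contrast_row(r)}
            for pid, r in countmodels.patch_contrasts(ds)
        ]
        rows += [
            {"analysis": "zone", "unit": k, **_contrast_row(r)}
            for k, r in countmodels.zone_contrasts(ds).items()
        ]
        try:
            rows.append(
                {
                    "analysis": "mechanism",
                    "unit": "specialized_vs_leaning",
                    **_contrast_row(countmodels.mechanism_contrast(ds)),
                }
            )
        except CooccurError:
            pass
        pd.DataFrame(rows).to_csv(out / "count_contrasts.csv", index=False)

    def stage_hosts():
        frames, diag = [], {}
        for i, resp in enumerate(cfg.host_responses):
            f = hostmodels.fit(
                hostmodels.HostModelSpec(resp),
                ds,
                chains=cfg.chains,
                iterations=cfg.iterations,
                seed=cfg.seed + 1000 * (i + 1),
            )
            s = f.summary()
            s.insert(0, "response", resp)
            frames.append(s)
            diag[resp] = {
                "converged": bool(f.converged),
                "max_rhat": round(max(f.rhat.values()), 4),
                "min_ess": round(min(f.ess.values()), 1),
            }
        pd.concat(frames).to_csv(out / "host_models.csv", index=False)
        summary["host_models"] = diag

    def stage_networks():
        reports = {}
        for name, m in [
            ("liana_tree", networks.liana_tree_matrix(ds)),
            ("epiphyte_tree", networks.epiphyte_tree_matrix(ds)),
            ("epiphyte_liana", networks.epiphyte_liana_matrix(ds)),
        ]:
            m.weights.to_csv(out / f"network_{name}.csv")
            rep = networks.network_report(m)
            reports[name] = {
                "total": round(m.total, 6),
                "top_rows": rep["top_rows"][:5],
                "top_cols": rep["top_cols"][:5],
            }
        summary["networks"] = reports

    def stage_spatial():
        pat = spatial.MappedPattern.from_dataset(ds, patch_id=cfg.spatial_patch)
        radii = spatial.default_radii(cfg.ring_width, cfg.max_radius)
        half = 0.5 * min(*pat.side_lengths)
        radii = radii[radii <= half]
        for label, frm, to in [
            ("epi_around_liana", "liana_host", "epi_host"),
            ("liana_around_epi", "epi_host", "liana_host"),
        ]:
            env = spatial.covariate_null_envelope(
                pat, frm, to, radii=radii, ring_width=cfg.ring_width,
                n_sim=cfg.n_sim, alpha=cfg.alpha, seed=cfg.seed,
            )
            env.to_frame().to_csv(out / f"spatial_{label}.csv", index=False)
            summary.setdefault("spatial", {})[label] = {
                "n_points": pat.n,
                "exceed_radii": [float(r) for r in env.radii[env.exceed != 0]],
            }

    _stage(summary, "scales", cfg.skip, stage_scales)
    _stage(summary, "count_models", cfg.skip, stage_counts)
    _stage(summary, "host_models", cfg.skip, stage_hosts)
    _stage(summary, "networks", cfg.skip, stage_networks)
    _stage(summary, "spatial", cfg.skip, stage_spatial)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
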