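"""Synthetic forest-stand generator.

Emulates a census of 12 forest patches (8 successional, 4 mature),
each with ten 20 x 20 m plots, trees >= 10 cm dbh, and liana/epiphyte
colonization probabilities that rise with tree diameter and differ
between species and forest types.  One patch carries a contiguous
block of mapped plots (x-y coordinates) for point-pattern analyses.

The generative model mirrors the statistical models fitted downstream,
so parameter-recovery studies are well posed:

* presence of each guild on a tree is Bernoulli with a logistic
  probability in standardized dbh, a mature-forest offset and a
  tree-species effect (the hurdle part);
* species richness on colonized trees is zero-truncated Poisson with a
  log-linear rate in the same covariates (the positive Poisson part);
* total liana basal area on colonized trees is lognormal with a linear
  log-scale predictor (the positive lognormal part);
* epiphyte cover class comes from a latent-logistic variable cut at
  ``cover_cutpoints`` (the cumulative-logit model).

Standardized dbh always means ``(dbh - dbh_ref[0]) / dbh_ref[1]`` with
the fixed reference constants in :class:`StandParams`, so generator
coefficients have a well-defined scale independent of any one sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit, ndtr, ndtri

from .datamodel import (
    EpiphyteRecord,
    ForestDataset,
    LianaRecord,
    TreeRecord,
    basal_area,
)
from .errors import ConfigurationError

__all__ = [
    "TreeSpeciesDef",
    "LianaSpeciesDef",
    "EpiphyteSpeciesDef",
    "Colonization",
    "StandParams",
    "generate_stand",
    "generate_mapped_block",
]


@dataclass(frozen=True)
class TreeSpeciesDef:
    name: str
    abund_successional: float
    abund_mature: float
    #: additive tree-species effect on every liana linear predictor
    liana_effect: float = 0.0
    #: additive tree-species effect on every epiphyte linear predictor
    epi_effect: float = 0.0


@dataclass(frozen=True)
class LianaSpeciesDef:
    name: str
    abundance: float
    mechanism: str  # "specialized" | "leaning"


@dataclass(frozen=True)
class EpiphyteSpeciesDef:
    name: str
    abundance: float


@dataclass(frozen=True)
class Colonization:
    """Logistic colonization model on standardized dbh."""

    intercept: float
    dbh_slope: float
    mature_offset: float


def _default_tree_pool():
    # canopy dominants first; negative effects mark small understorey
    # species rarely reached by epiphytes
    return [
        TreeSpeciesDef("Ocotea porphyria", 0.04, 0.22, 0.30, 0.50),
        TreeSpeciesDef("Blepharocalyx salicifolius", 0.03, 0.18, 0.10, 0.30),
        TreeSpeciesDef("Pisonia zapallo", 0.03, 0.12, 0.20, 0.20),
        TreeSpeciesDef("Terminalia triflora", 0.05, 0.12, 0.30, 0.30),
        TreeSpeciesDef("Parapiptadenia excelsa", 0.10, 0.08, 0.00, 0.40),
        TreeSpeciesDef("Eugenia uniflora", 0.08, 0.12, 0.20, -0.40),
        TreeSpeciesDef("Piper tucumanum", 0.07, 0.10, 0.20, -0.50),
        TreeSpeciesDef("Allophylus edulis", 0.05, 0.06, 0.00, -0.20),
        TreeSpeciesDef("Ligustrum lucidum", 0.25, 0.05, -0.30, -0.30),
        TreeSpeciesDef("Tecoma stans", 0.15, 0.03, -0.20, -0.40),
        TreeSpeciesDef("Morus alba", 0.15, 0.02, 0.10, -0.10),
    ]


def _default_liana_pool():
    return [
        LianaSpeciesDef("Cissus striata", 0.22, "specialized"),
        LianaSpeciesDef("Celtis iguanaea", 0.20, "specialized"),
        LianaSpeciesDef("Dolichandra unguis-cati", 0.15, "specialized"),
        LianaSpeciesDef("Acacia tucumanensis", 0.08, "specialized"),
        LianaSpeciesDef("Serjania meridionalis", 0.05, "specialized"),
        LianaSpeciesDef("Chamissoa altissima", 0.12, "leaning"),
        LianaSpeciesDef("Quechualia fulta", 0.13, "leaning"),
        LianaSpeciesDef("Ipomoea bonariensis", 0.05, "leaning"),
    ]


def _default_epiphyte_pool():
    return [
        EpiphyteSpeciesDef("Pleopeltis tweediana", 0.22),
        EpiphyteSpeciesDef("Microgramma squamulosa", 0.20),
        EpiphyteSpeciesDef("Aechmea distichantha", 0.15),
        EpiphyteSpeciesDef("Peperomia tetraphylla", 0.12),
        EpiphyteSpeciesDef("Peperomia theodori", 0.08),
        EpiphyteSpeciesDef("Tillandsia tenuifolia", 0.08),
        EpiphyteSpeciesDef("Serpocaulon gilliesii", 0.07),
        EpiphyteSpeciesDef("Rhipsalis floccosa", 0.06),
        EpiphyteSpeciesDef("Tillandsia capillaris", 0.05),
        EpiphyteSpeciesDef("Campyloneurum aglaolepis", 0.04),
        EpiphyteSpeciesDef("Lepismium lumbricoides", 0.03),
        EpiphyteSpeciesDef("Tradescantia fluminensis", 0.02),
    ]


def _default_patch_types():
    # 8 successional + 4 mature patches, labelled after the survey design
    succ = [
        "Guaran", "Nativo", "Reserva", "Mora",
        "NogalCebil", "Cedro", "Sismografo", "Frontino",
    ]
    mat = ["CuestaVieja", "Laderas", "Ha1", "Ha6"]
    d = {p: "successional" for p in succ}
    d.update({p: "mature" for p in mat})
    return d


@dataclass
class StandParams:
    """Everything the stand generator needs; defaults emulate the survey.

    The default colonization intercepts are calibrated so that, over a
    full default stand (~2100 trees), about 34% of trees host at least
    one liana and about 52% host at least one epiphyte — the documented
    host fractions for this census design.
    """

    n_patches: int = 12
    plots_per_patch: int = 10
    plot_side: float = 20.0
    patch_types: dict = field(default_factory=_default_patch_types)

    #: truncated-lognormal dbh parameters (meanlog, sdlog) per forest type
    dbh_lognormal: dict = field(
        default_factory=lambda: {"successional": (2.75, 0.45), "mature": (3.00, 0.55)}
    )
    #: fixed (mean, sd) used to standardize dbh inside the generator
    dbh_ref: tuple = (21.0, 11.0)
    #: expected trees per 20x20 plot, per forest type
    tree_intensity: dict = field(
        default_factory=lambda: {"successional": 18.0, "mature": 17.8}
    )

    tree_species_pool: list = field(default_factory=_default_tree_pool)
    liana_species_pool: list = field(default_factory=_default_liana_pool)
    epiphyte_species_pool: list = field(default_factory=_default_epiphyte_pool)

    colonization: dict = field(
        default_factory=lambda: {
            "liana": Colonization(-0.90, 0.80, 0.40),
            "epi": Colonization(0.05, 1.10, 0.70),
        }
    )

    # positive-part (colonized trees only) coefficient triples
    # (intercept, dbh_slope, mature_offset); tree-species effects from
    # the pool are added to every predictor
    liana_richness_coef: tuple = (-0.60, 0.25, 0.25)
    liana_ba_coef: tuple = (math.log(1.2e-3), 0.80, 0.30)
    liana_ba_sigma: float = 0.90
    epi_richness_coef: tuple = (0.10, 0.30, 0.30)
    #: latent cover predictor (dbh_slope, mature_offset); intercept 0
    epi_cover_coef: tuple = (0.90, 0.50)
    cover_cutpoints: tuple = (1.6, 3.2, 4.4, 5.4)

    #: extra Poisson mean for stems beyond one per liana species per tree
    liana_stems_extra: float = 0.3
    #: added dbh slope for choosing specialized-mechanism liana species
    specialized_dbh_bonus: float = 0.5
    liana_zone_p_trunk: float = 0.55
    epi_zone_p_trunk: float = 0.40
    epi_zone_p_crown: float = 0.80

    #: patch that carries mapped coordinates, with its own density
    mapped_patch: str = "Cedro"
    mapped_plots: int = 9
    #: expected trees per mapped plot (~120 trees per 0.36 ha block)
    mapped_intensity: float = 120.0 / 9.0
    #: "poisson" or ("thomas", {"kappa": per m^2, "sigma": m, "mu": count})
    spatial_process: object = "poisson"

    seed: int = 0

    def validate(self) -> None:
        if self.n_patches != len(self.patch_types):
            raise ConfigurationError(
                f"n_patches={self.n_patches} but patch_types has {len(self.patch_types)}"
            )
        if self.plot_side <= 0:
            raise ConfigurationError("plot_side must be positive")
        for pool, label in [
            (self.tree_species_pool, "tree"),
            (self.liana_species_pool, "liana"),
            (self.epiphyte_species_pool, "epiphyte"),
        ]:
            if not pool:
                raise ConfigurationError(f"empty {label} species pool")
        if any(
            b2 <= b1 for b1, b2 in zip(self.cover_cutpoints, self.cover_cutpoints[1:])
        ):
            raise ConfigurationError("cover_cutpoints must be strictly increasing")
        for ft in set(self.patch_types.values()):
            if ft not in self.dbh_lognormal or ft not in self.tree_intensity:
                raise ConfigurationError(f"missing dbh/intensity settings for {ft!r}")


# ---------------------------------------------------------------------
# sampling helpers


def _sample_dbh(rng, n, meanlog, sdlog, lower=10.0, upper=90.0):
    """Lognormal(meanlog, sdlog) truncated to [lower, upper], inverse CDF.

    The upper bound mirrors the largest stems a montane field census
    records; it also keeps species richness within the species pool.
    """
    if n == 0:
        return np.empty(0)
    alpha = ndtr((math.log(lower) - meanlog) / sdlog)
    beta = ndtr((math.log(upper) - meanlog) / sdlog)
    u = rng.uniform(alpha, beta, size=n)
    return np.exp(meanlog + sdlog * ndtri(u))


def _sample_ztp(rng, lam, kmax=60):
    """One draw from a zero-truncated Poisson by inverse CDF."""
    lam = max(float(lam), 1e-12)
    u = rng.random() * -math.expm1(-lam)  # U(0, 1 - e^-lam)
    cdf = 0.0
    term = math.exp(-lam)
    for k in range(1, kmax + 1):
        term *= lam / k
        cdf += term
        if cdf >= u:
            return k
    return kmax


def _thomas_points(rng, width, height, kappa, sigma, mu):
    """Thomas cluster process on [0,width]x[0,height] (parents in a
    4-sigma dilation so edge clusters are represented)."""
    pad = 4.0 * sigma
    w, h = width + 2 * pad, height + 2 * pad
    n_par = rng.poisson(kappa * w * h)
    px = rng.uniform(-pad, width + pad, n_par)
    py = rng.uniform(-pad, height + pad, n_par)
    xs, ys = [], []
    for cx, cy in zip(px, py):
        m = rng.poisson(mu)
        if m == 0:
            continue
        ox = cx + rng.normal(0.0, sigma, m) if sigma > 0 else np.full(m, cx)
        oy = cy + rng.normal(0.0, sigma, m) if sigma > 0 else np.full(m, cy)
        keep = (ox >= 0) & (ox <= width) & (oy >= 0) & (oy <= height)
        xs.append(ox[keep])
        ys.append(oy[keep])
    if not xs:
        return np.empty(0), np.empty(0)
    return np.concatenate(xs), np.concatenate(ys)


# ---------------------------------------------------------------------
# per-tree attachment of liana / epiphyte records


def _attach_lianas(rng, p: StandParams, tree: TreeRecord, z: float, mature: int,
                   sp_eff: float, out: list) -> None:
    col = p.colonization["liana"]
    prob = expit(col.intercept + col.dbh_slope * z + col.mature_offset * mature + sp_eff)
    if rng.random() >= prob:
        return
    ri, rs, rm = p.liana_richness_coef
    lam = math.exp(ri + rs * z + rm * mature + sp_eff)
    richness = min(_sample_ztp(rng, lam), len(p.liana_species_pool))
    bi, bs, bm = p.liana_ba_coef
    total_ba = math.exp(rng.normal(bi + bs * z + bm * mature + sp_eff, p.liana_ba_sigma))

    w = np.array(
        [
            s.abundance
            * math.exp(p.specialized_dbh_bonus * z if s.mechanism == "specialized" else 0.0)
            for s in p.liana_species_pool
        ]
    )
    w = w / w.sum()
    idx = rng.choice(len(w), size=richness, replace=False, p=w)
    stems_per_sp = 1 + rng.poisson(p.liana_stems_extra, size=richness)
    n_stems = int(stems_per_sp.sum())
    shares = rng.dirichlet(np.ones(n_stems)) * total_ba
    k = 0
    min_ba = basal_area(1.0)
    for sp_i, n_st in zip(idx, stems_per_sp):
        sp = p.liana_species_pool[sp_i]
        for _ in range(n_st):
            ba = max(shares[k], min_ba)  # stems cannot be thinner than 1 cm
            k += 1
            d = 200.0 * math.sqrt(ba / math.pi)
            zone = "trunk" if rng.random() < p.liana_zone_p_trunk else "crown"
            out.append(LianaRecord(tree.tree_id, sp.name, d, sp.mechanism, zone))


def _attach_epiphytes(rng, p: StandParams, tree: TreeRecord, z: float, mature: int,
                      sp_eff: float, out: list) -> None:
    col = p.colonization["epi"]
    prob = expit(col.intercept + col.dbh_slope * z + col.mature_offset * mature + sp_eff)
    if rng.random() >= prob:
        return
    ri, rs, rm = p.epi_richness_coef
    lam = math.exp(ri + rs * z + rm * mature + sp_eff)
    richness = min(_sample_ztp(rng, lam), len(p.epiphyte_species_pool))

    # tree-level cover class from a latent-logistic variable
    cs, cm = p.epi_cover_coef
    latent = cs * z + cm * mature + sp_eff + rng.logistic()
    cover = int(np.searchsorted(np.asarray(p.cover_cutpoints), latent) + 1)

    w = np.array([s.abundance for s in p.epiphyte_species_pool])
    w = w / w.sum()
    idx = rng.choice(len(w), size=richness, replace=False, p=w)
    for sp_i in idx:
        zones = set()
        if rng.random() < p.epi_zone_p_crown:
            zones.add("crown")
        if rng.random() < p.epi_zone_p_trunk:
            zones.add("trunk")
        if not zones:
            zones.add("crown")
        out.append(
            EpiphyteRecord(tree.tree_id, p.epiphyte_species_pool[sp_i].name,
                           cover, frozenset(zones))
        )


# ---------------------------------------------------------------------
# stand assembly


def _grid_shape(n_plots: int):
    nx = max(d for d in range(1, int(math.isqrt(n_plots)) + 1) if n_plots % d == 0)
    return nx, n_plots // nx


def _populate_trees(rng, p, patch_id, ft, plot_labels, counts, coords=None):
    """Create TreeRecords for one patch.  ``coords`` maps plot label ->
    (x0, y0) block-global plot origin for mapped plots, else None."""
    meanlog, sdlog = p.dbh_lognormal[ft]
    abund = np.array(
        [
            s.abund_mature if ft == "mature" else s.abund_successional
            for s in p.tree_species_pool
        ]
    )
    abund = abund / abund.sum()
    trees = []
    for plot, n in zip(plot_labels, counts):
        if n == 0:
            continue
        dbhs = _sample_dbh(rng, n, meanlog, sdlog)
        sp_idx = rng.choice(len(abund), size=n, p=abund)
        if coords is not None and plot in coords:
            x0, y0 = coords[plot]
            xs = x0 + rng.uniform(0, p.plot_side, n)
            ys = y0 + rng.uniform(0, p.plot_side, n)
        else:
            xs = ys = [None] * n
        for i in range(n):
            trees.append(
                TreeRecord(
                    tree_id=f"{patch_id}-{plot}-t{i + 1:03d}",
                    patch_id=patch_id,
                    plot_id=plot,
                    species=p.tree_species_pool[sp_idx[i]].name,
                    dbh=float(dbhs[i]),
                    x=None if xs[i] is None else float(xs[i]),
                    y=None if ys[i] is None else float(ys[i]),
                )
            )
    return trees


def _mapped_tree_positions(rng, p, ft, nx, ny):
    """Tree positions for a contiguous mapped block, as (x, y, plot_label)."""
    width, height = nx * p.plot_side, ny * p.plot_side
    n_plots = nx * ny
    if p.spatial_process == "poisson":
        n = rng.poisson(p.mapped_intensity * n_plots)
        xs = rng.uniform(0, width, n)
        ys = rng.uniform(0, height, n)
    else:
        kind, opts = p.spatial_process
        if kind != "thomas":
            raise ConfigurationError(f"unknown spatial process {kind!r}")
        xs, ys = _thomas_points(rng, width, height, opts["kappa"], opts["sigma"], opts["mu"])
    ix = np.minimum((xs / p.plot_side).astype(int), nx - 1)
    iy = np.minimum((ys / p.plot_side).astype(int), ny - 1)
    labels = [f"p{int(j * nx + i + 1):02d}" for i, j in zip(ix, iy)]
    return xs, ys, labels


def _finish_dataset(rng, p, trees, patch_meta):
    ref_mean, ref_sd = p.dbh_ref
    eff = {s.name: (s.liana_effect, s.epi_effect) for s in p.tree_species_pool}
    lianas, epiphytes = [], []
    for t in trees:
        z = (t.dbh - ref_mean) / ref_sd
        mature = 1 if patch_meta[t.patch_id]["forest_type"] == "mature" else 0
        le, ee = eff[t.species]
        _attach_lianas(rng, p, t, z, mature, le, lianas)
        _attach_epiphytes(rng, p, t, z, mature, ee, epiphytes)
    ds = ForestDataset(trees=trees, lianas=lianas, epiphytes=epiphytes, patch_meta=patch_meta)
    ds.validate()
    return ds


def generate_stand(params: StandParams, seed: Optional[int] = None) -> ForestDataset:
    """Generate a full multi-patch census.

    ``seed`` overrides ``params.seed``; identical parameters and seed
    give an identical dataset.  The mapped patch (``params.mapped_patch``,
    if present among ``patch_types``) gets block-contiguous coordinates
    on its first ``params.mapped_plots`` plots.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    patch_meta = {
        pid: {"forest_type": ft} for pid, ft in params.patch_types.items()
    }
    all_trees = []
    for pid in params.patch_types:  # insertion order: deterministic
        ft = params.patch_types[pid]
        labels = [f"p{i + 1:02d}" for i in range(params.plots_per_patch)]
        if pid == params.mapped_patch:
            nmap = min(params.mapped_plots, params.plots_per_patch)
            nx, ny = _grid_shape(nmap)
            xs, ys, plab = _mapped_tree_positions(rng, params, ft, nx, ny)
            per_plot = {}
            for x, y, lab in zip(xs, ys, plab):
                per_plot.setdefault(lab, []).append((x, y))
            trees = []
            for lab in labels[:nmap]:
                pts = per_plot.get(lab, [])
                meanlog, sdlog = params.dbh_lognormal[ft]
                dbhs = _sample_dbh(rng, len(pts), meanlog, sdlog)
                abund = np.array(
                    [
                        s.abund_mature if ft == "mature" else s.abund_successional
                        for s in params.tree_species_pool
                    ]
                )
                abund = abund / abund.sum()
                sp_idx = rng.choice(len(abund), size=len(pts), p=abund)
                for i, (x, y) in enumerate(pts):
                    trees.append(
                        TreeRecord(
                            tree_id=f"{pid}-{lab}-t{i + 1:03d}",
                            patch_id=pid,
                            plot_id=lab,
                            species=params.tree_species_pool[sp_idx[i]].name,
                            dbh=float(dbhs[i]),
                            x=float(x),
                            y=float(y),
                        )
                    )
            # remaining unmapped plots of the mapped patch
            rest = labels[nmap:]
            counts = rng.poisson(params.tree_intensity[ft], size=len(rest))
            trees += _populate_trees(rng, params, pid, ft, rest, counts)
        else:
            counts = rng.poisson(params.tree_intensity[ft], size=len(labels))
            trees = _populate_trees(rng, params, pid, ft, labels, counts)
        all_trees += trees
    return _finish_dataset(rng, params, all_trees, patch_meta)


def generate_mapped_block(params: StandParams, n_plots: int = 9,
                          seed: Optional[int] = None) -> ForestDataset:
    """Generate a single fully-mapped contiguous block of plots.

    Plots are arranged on the most nearly square rectangle dividing
    ``n_plots``; every tree carries coordinates inside the block
    rectangle.  Expected density is ``params.mapped_intensity`` trees
    per plot (~120 trees on a 9-plot, 0.36 ha block).
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    pid = params.mapped_patch
    ft = params.patch_types.get(pid, "successional")
    nx, ny = _grid_shape(n_plots)
    xs, ys, plab = _mapped_tree_positions(rng, params, ft, nx, ny)
    meanlog, sdlog = params.dbh_lognormal[ft]
    dbhs = _sample_dbh(rng, len(xs), meanlog, sdlog)
    abund = np.array(
        [
            s.abund_mature if ft == "mature" else s.abund_successional
            for s in params.tree_species_pool
        ]
    )
    abund = abund / abund.sum()
    sp_idx = rng.choice(len(abund), size=len(xs), p=abund)
    trees = [
        TreeRecord(
            tree_id=f"{pid}-m-t{i + 1:04d}",
            patch_id=pid,
            plot_id=plab[i],
            species=params.tree_species_pool[sp_idx[i]].name,
            dbh=float(dbhs[i]),
            x=float(xs[i]),
            y=float(ys[i]),
        )
        for i in range(len(xs))
    ]
    patch_meta = {pid: {"forest_type": ft}}
    return _finish_dataset(rng, params, trees, patch_meta)
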