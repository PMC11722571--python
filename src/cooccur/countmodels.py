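"""Negative-binomial log-link group contrasts.

The same two-group NB2 GLM is used three ways: liana-host vs
epiphyte-host counts per forest patch (over that patch's plots),
trunk vs crown occurrence counts per guild (and guild contrasts per
zone), and epiphyte occurrences on trees hosting specialized-climbing
vs leaning liana species.

Because the design is a single group factor with a log link, the NB2
maximum-likelihood estimate of the contrast coefficient equals
``log(mean(alt) / mean(ref))`` exactly, whatever the dispersion; the
dispersion only moves the Wald z.  When the ML dispersion collapses to
zero (under-dispersed counts) the fit reduces to a Poisson GLM and is
reported with ``theta = inf``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .datamodel import ForestDataset
from .errors import DegenerateDesignError, SeparationError
from .scales import zone_occurrences

__all__ = [
    "GroupContrastResult",
    "nb_group_contrast",
    "patch_contrasts",
    "zone_contrasts",
    "mechanism_contrast",
]

_ALPHA_FLOOR = 1e-6  # below this the NB2 dispersion is numerically Poisson


@dataclass(frozen=True)
class GroupContrastResult:
    """alt-vs-ref coefficient of a two-group NB2 log-link GLM."""

    estimate: float  # log mean ratio, alt vs ref
    z: float
    p: float
    theta: float  # NB size parameter (1/alpha); inf = Poisson limit

    def __iter__(self):
        return iter((self.estimate, self.z, self.p, self.theta))


def _poisson_fit(y, X):
    res = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    return res.params[1], res.bse[1]


def nb_group_contrast(counts_ref, counts_alt) -> GroupContrastResult:
    """Fit ``count ~ group`` with NB2 errors and a log link.

    Parameters
    ----------
    counts_ref, counts_alt : sequences of non-negative integers
        Observation-level counts for the reference and alternative
        groups (e.g. per-plot host counts).

    Returns
    -------
    GroupContrastResult
        ``estimate`` is the alt-vs-ref log mean ratio; ``z``/``p``
        from the Wald statistic; ``theta`` the ML NB size parameter.

    Raises
    ------
    SeparationError
        If either group is all zeros (the log mean ratio is infinite).
    ValueError
        On negative counts or an empty group.
    """
    yr = np.asarray(counts_ref, dtype=float)
    ya = np.asarray(counts_alt, dtype=float)
    if yr.size == 0 or ya.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.any(yr < 0) or np.any(ya < 0):
        raise ValueError("counts must be non-negative")
    if yr.sum() == 0 or ya.sum() == 0:
        raise SeparationError("an all-zero group gives an infinite log-ratio")

    y = np.concatenate([yr, ya])
    group = np.concatenate([np.zeros(yr.size), np.ones(ya.size)])
    X = sm.add_constant(group)

    closed_form = float(np.log(ya.mean() / yr.mean()))
    start = [float(np.log(yr.mean())), closed_form, 0.5]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = NegativeBinomial(y, X, loglike_method="nb2").fit(
                start_params=start, disp=0, maxiter=500, gtol=1e-10
            )
            est, se, alpha = res.params[1], res.bse[1], res.params[2]
            ok = np.isfinite(se) and alpha > _ALPHA_FLOOR
        except Exception:
            ok = False
    if not ok:
        # dispersion at (or past) the Poisson boundary
        est, se = _poisson_fit(y, X)
        alpha = 0.0
    z = est / se
    from scipy.stats import norm

    return GroupContrastResult(
        estimate=float(est),
        z=float(z),
        p=float(2 * norm.sf(abs(z))),
        theta=float(np.inf if alpha <= _ALPHA_FLOOR else 1.0 / alpha),
    )


def _per_plot_host_counts(ds: ForestDataset, patch_id: str):
    """(liana_host_counts, epi_host_counts) arrays over a patch's plots."""
    tt = ds.tree_table()
    sub = tt[tt.patch_id == patch_id]
    plots = sorted(sub.plot_id.unique())
    g = sub.groupby("plot_id")
    liana = g["liana_host"].sum().reindex(plots).fillna(0).to_numpy()
    epi = g["epi_host"].sum().reindex(plots).fillna(0).to_numpy()
    return liana.astype(int), epi.astype(int)


def patch_contrasts(ds: ForestDataset):
    """Liana-host vs epiphyte-host contrast per patch.

    Returns a list of ``(patch_id, GroupContrastResult | None)``;
    ``None`` marks patches where the contrast is degenerate (a guild
    absent from every plot).  The alternative group is the liana
    counts, so negative estimates mean fewer liana than epiphyte hosts.
    """
    out = []
    for pid in ds.patch_ids:
        liana, epi = _per_plot_host_counts(ds, pid)
        try:
            out.append((pid, nb_group_contrast(epi, liana)))
        except (SeparationError, ValueError):
            out.append((pid, None))
    return out


def zone_contrasts(ds: ForestDataset) -> dict:
    """The four zone-scale contrasts on per-plot occurrence counts.

    Keys: ``trunk_liana_vs_epi`` and ``crown_liana_vs_epi`` (alt =
    liana), ``liana_trunk_vs_crown`` and ``epi_trunk_vs_crown`` (alt =
    trunk).  A negative ``epi_trunk_vs_crown`` estimate means epiphytes
    occur more in crowns than on trunks.
    """
    zo = zone_occurrences(ds)
    lt, lc = zo["liana_trunk"].to_numpy(), zo["liana_crown"].to_numpy()
    et, ec = zo["epi_trunk"].to_numpy(), zo["epi_crown"].to_numpy()
    return {
        "trunk_liana_vs_epi": nb_group_contrast(et, lt),
        "crown_liana_vs_epi": nb_group_contrast(ec, lc),
        "liana_trunk_vs_crown": nb_group_contrast(lc, lt),
        "epi_trunk_vs_crown": nb_group_contrast(ec, et),
    }


def mechanism_contrast(ds: ForestDataset) -> GroupContrastResult:
    """Epiphyte occurrences by liana climbing mechanism.

    For each liana species, the response is the total number of
    epiphyte records on the trees hosting that species; species are
    grouped by their climbing mechanism.  The alternative group is
    ``specialized``, so a positive estimate means more epiphyte
    co-occurrences with specialized climbers than with leaning species.
    """
    mech = {}
    hosts_of = {}
    for l in ds.lianas:
        mech[l.species] = l.mechanism
        hosts_of.setdefault(l.species, set()).add(l.tree_id)
    if len(set(mech.values())) < 2:
        raise DegenerateDesignError(
            "both climbing mechanisms must be present for a contrast"
        )
    epi_per_tree = {}
    for e in ds.epiphytes:
        epi_per_tree[e.tree_id] = epi_per_tree.get(e.tree_id, 0) + 1
    counts = {"specialized": [], "leaning": []}
    for sp in sorted(hosts_of):
        total = sum(epi_per_tree.get(t, 0) for t in hosts_of[sp])
        counts[mech[sp]].append(total)
    return nb_group_contrast(counts["leaning"], counts["specialized"])
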