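"""Ring-differenced Ripley K analysis of marked tree patterns.

Tree locations are treated as fixed; the marks (hosting a liana,
hosting an epiphyte) are the random element.  The association between
guilds is measured with a cross-type K in which trees of one mark act
as foci and trees of the other as targets, edge-corrected by the
translation correction (exact on rectangular windows).  To suppress
the cumulative autocorrelation of K, every statistic is reported as
the annulus ("ring") difference ``K(r) - K(r - w)`` with a default
ring width of 2 m.

The null model is random labeling adjusted for covariates: a logistic
regression of mark presence on dbh and tree species supplies per-tree
probabilities, and each simulation reassigns the observed number of
marks by weighted sampling without replacement (Bernoulli resampling
is available as an option).  Pointwise envelopes are the alpha/2 and
1 - alpha/2 quantiles over simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import ForestDataset
from .errors import InsufficientPointsError

__all__ = [
    "MappedPattern",
    "RingKEnvelope",
    "ring_k",
    "ring_cross_k",
    "covariate_null_envelope",
    "default_radii",
]


def default_radii(ring_width: float = 2.0, r_max: float = 14.0, step: float = 1.0):
    """Radii grid from ``ring_width`` to ``r_max`` in ``step`` metres."""
    return np.arange(ring_width, r_max + 0.5 * step, step)


@dataclass
class MappedPattern:
    """A marked, covariate-tagged point pattern on a rectangular window."""

    points: np.ndarray  # (n, 2)
    window: tuple  # (xmin, xmax, ymin, ymax)
    marks: dict  # name -> boolean array of length n
    covariates: pd.DataFrame = None  # columns: dbh, species

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        xmin, xmax, ymin, ymax = self.window
        if self.points.size and (
            self.points[:, 0].min() < xmin - 1e-9
            or self.points[:, 0].max() > xmax + 1e-9
            or self.points[:, 1].min() < ymin - 1e-9
            or self.points[:, 1].max() > ymax + 1e-9
        ):
            raise ValueError("points outside window")
        for name, m in self.marks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape[0] != len(self.points):
                raise ValueError(f"mark {name!r} not aligned with points")
            self.marks[name] = m

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        xmin, xmax, ymin, ymax = self.window
        return (xmax - xmin) * (ymax - ymin)

    @property
    def side_lengths(self):
        xmin, xmax, ymin, ymax = self.window
        return xmax - xmin, ymax - ymin

    @classmethod
    def from_dataset(cls, ds: ForestDataset, patch_id: Optional[str] = None,
                     plot_side: float = 20.0) -> "MappedPattern":
        """Build the pattern of mapped trees, marked by guild hosting.

        Uses trees with coordinates (optionally restricted to one
        patch).  Mapped blocks are plot-aligned and anchored at the
        origin, so the window is [0, W] x [0, H] with W and H the
        coordinate maxima rounded up to the next ``plot_side``
        multiple.
        """
        tt = ds.tree_table()
        if patch_id is not None:
            tt = tt[tt.patch_id == patch_id]
        tt = tt[tt.x.notna() & tt.y.notna()]
        if len(tt) == 0:
            raise InsufficientPointsError("no mapped trees")
        pts = tt[["x", "y"]].to_numpy(dtype=float)
        window = (
            0.0,
            float(np.ceil(pts[:, 0].max() / plot_side) * plot_side),
            0.0,
            float(np.ceil(pts[:, 1].max() / plot_side) * plot_side),
        )
        return cls(
            points=pts,
            window=window,
            marks={
                "liana_host": tt.liana_host.to_numpy(),
                "epi_host": tt.epi_host.to_numpy(),
            },
            covariates=tt[["dbh", "species"]].reset_index(drop=True),
        )


@dataclass
class RingKEnvelope:
    """Observed ring-K curve with Monte Carlo envelope bounds."""

    radii: np.ndarray
    ring_width: float
    observed: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_sim: int
    alpha: float
    exceed: np.ndarray = field(default=None)  # -1 below, 0 inside, +1 above

    def __post_init__(self):
        if self.exceed is None:
            self.exceed = np.where(
                self.observed > self.upper + 1e-12,
                1,
                np.where(self.observed < self.lower - 1e-12, -1, 0),
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r": self.radii,
                "observed": self.observed,
                "lower": self.lower,
                "upper": self.upper,
                "exceed": self.exceed,
            }
        )


# ---------------------------------------------------------------------
# K estimation (translation edge correction)


def _translation_weights(points: np.ndarray, window) -> np.ndarray:
    """|A| / ((W - |dx|)(H - |dy|)) for every ordered pair (diag = 0)."""
    xmin, xmax, ymin, ymax = window
    W, H = xmax - xmin, ymax - ymin
    dx = np.abs(points[:, 0, None] - points[None, :, 0])
    dy = np.abs(points[:, 1, None] - points[None, :, 1])
    w = (W * H) / ((W - dx) * (H - dy))
    np.fill_diagonal(w, 0.0)
    return w


def _pair_distances(points: np.ndarray) -> np.ndarray:
    d = points[:, None, :] - points[None, :, :]
    return np.sqrt((d**2).sum(axis=-1))


def _k_from_pairs(dist, wts, radii, norm):
    """Cumulative K at each radius from pair distances and weights."""
    flat_d = dist.ravel()
    flat_w = wts.ravel()
    order = np.argsort(flat_d)
    cum = np.concatenate([[0.0], np.cumsum(flat_w[order])])
    idx = np.searchsorted(flat_d[order], np.asarray(radii, dtype=float), side="right")
    return cum[idx] / norm


def _check_radii(pattern, radii):
    W, H = pattern.side_lengths
    rmax = float(np.max(radii))
    if rmax > 0.5 * min(W, H) + 1e-9:
        raise ValueError(
            f"max radius {rmax} exceeds half the window's shorter side ({0.5 * min(W, H)})"
        )


def ring_k(pattern: MappedPattern, which: str, radii, ring_width: float = 2.0):
    """Ring-differenced univariate K of the ``which``-marked subpattern.

    Computes the translation-corrected K of the marked points and
    returns ``K(r) - K(r - ring_width)`` per radius (``K(r) = 0`` for
    ``r <= 0``).  Requires at least two marked points.
    """
    sel = np.asarray(pattern.marks[which], dtype=bool)
    m = int(sel.sum())
    if m < 2:
        raise InsufficientPointsError(f"need >= 2 points marked {which!r}, got {m}")
    radii = np.asarray(radii, dtype=float)
    _check_radii(pattern, radii)
    pts = pattern.points[sel]
    dist = _pair_distances(pts)
    wts = _translation_weights(pts, pattern.window)
    norm = m * (m - 1) / pattern.area
    k_hi = _k_from_pairs(dist, wts, radii, norm)
    k_lo = _k_from_pairs(dist, wts, np.maximum(radii - ring_width, 0.0), norm)
    return k_hi - k_lo


def _cross_k_curves(dist, wts, from_sel, to_sel, radii, ring_width, area):
    """Ring cross-K given precomputed full pair matrices."""
    sub_d = dist[np.ix_(from_sel, to_sel)]
    sub_w = wts[np.ix_(from_sel, to_sel)]
    n1, n2 = int(from_sel.sum()), int(to_sel.sum())
    n_shared = int((from_sel & to_sel).sum())
    # shared trees appear in both sets but never pair with themselves
    # (the full-matrix diagonal is zeroed), so the count of ordered
    # focus-target pairs is n1*n2 - n_shared; with identical mark sets
    # this reduces to the univariate m*(m-1) normalization
    norm = (n1 * n2 - n_shared) / area
    k_hi = _k_from_pairs(sub_d, sub_w, radii, norm)
    k_lo = _k_from_pairs(sub_d, sub_w, np.maximum(radii - ring_width, 0.0), norm)
    return k_hi - k_lo


def ring_cross_k(pattern: MappedPattern, from_mark: str, to_mark: str, radii,
                 ring_width: float = 2.0):
    """Ring-differenced cross-type K between two mark sets.

    Points with ``from_mark`` act as foci and points with ``to_mark``
    as targets; a tree carrying both marks enters both sets but never
    pairs with itself.  With identical mark sets this reduces exactly
    to :func:`ring_k` of that set.
    """
    f = np.asarray(pattern.marks[from_mark], dtype=bool)
    t = np.asarray(pattern.marks[to_mark], dtype=bool)
    if f.sum() == 0 or t.sum() == 0:
        raise InsufficientPointsError("both mark sets must be non-empty")
    if f.sum() < 2 and t.sum() < 2 and np.array_equal(f, t):
        raise InsufficientPointsError("need >= 2 marked points")
    radii = np.asarray(radii, dtype=float)
    _check_radii(pattern, radii)
    dist = _pair_distances(pattern.points)
    wts = _translation_weights(pattern.points, pattern.window)
    return _cross_k_curves(dist, wts, f, t, radii, ring_width, pattern.area)


# ---------------------------------------------------------------------
# covariate-adjusted random-labeling envelope


def fit_presence_model(pattern: MappedPattern, mark: str):
    """Logistic presence ~ dbh + species; returns fitted probabilities.

    Falls back to the dbh-only model (with a warning) when the species
    factor separates the data or the fit fails to converge.
    """
    y = np.asarray(pattern.marks[mark], dtype=float)
    cov = pattern.covariates
    if cov is None or "dbh" not in cov:
        raise ValueError("pattern has no dbh covariate")
    dbh = cov["dbh"].to_numpy(dtype=float)
    dbh_z = (dbh - dbh.mean()) / (dbh.std() or 1.0)
    if y.sum() == 0 or y.sum() == len(y):
        return np.full(len(y), y.mean())

    def _fit(X):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        p = np.asarray(res.fittedvalues)
        if not np.all(np.isfinite(p)):
            raise ValueError("non-finite fitted probabilities")
        return p

    X_full = [np.ones(len(y)), dbh_z]
    species = cov["species"] if "species" in cov else None
    if species is not None and species.nunique() > 1:
        dummies = pd.get_dummies(species.astype(str), drop_first=True).to_numpy(float)
        # a species level observed with only one mark value separates
        per_sp = pd.DataFrame({"s": species.to_numpy(), "y": y}).groupby("s")["y"].mean()
        separated = ((per_sp == 0) | (per_sp == 1)).any()
        if not separated:
            try:
                return _fit(np.column_stack(X_full + [dummies]))
            except Exception:
                pass
        warnings.warn(
            f"species factor separates mark {mark!r}; using dbh-only null model",
            stacklevel=2,
        )
    return _fit(np.column_stack(X_full))


def covariate_null_envelope(
    pattern: MappedPattern,
    from_mark: str,
    to_mark: str,
    radii=None,
    ring_width: float = 2.0,
    n_sim: int = 10000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    scheme: str = "weighted_permutation",
) -> RingKEnvelope:
    """Monte Carlo envelope for the ring cross-K under adjusted labeling.

    The ``to_mark`` labels are reassigned in every simulation using
    probabilities from :func:`fit_presence_model`:

    * ``weighted_permutation`` (default): weighted sampling without
      replacement preserving the observed number of marked trees;
    * ``bernoulli``: independent draws from the fitted probabilities
      (marked-tree count varies between simulations).

    Foci (``from_mark``) stay fixed.  Bounds are the pointwise
    ``alpha/2`` and ``1 - alpha/2`` quantiles over simulations.
    """
    if radii is None:
        radii = default_radii(ring_width)
    radii = np.asarray(radii, dtype=float)
    _check_radii(pattern, radii)
    if scheme not in ("weighted_permutation", "bernoulli"):
        raise ValueError(f"unknown reshuffle scheme {scheme!r}")
    rng = np.random.default_rng(seed)

    f = np.asarray(pattern.marks[from_mark], dtype=bool)
    t_obs = np.asarray(pattern.marks[to_mark], dtype=bool)
    n, m = pattern.n, int(t_obs.sum())
    if f.sum() == 0 or m == 0:
        raise InsufficientPointsError("both mark sets must be non-empty")

    probs = fit_presence_model(pattern, to_mark)
    dist = _pair_distances(pattern.points)
    wts = _translation_weights(pattern.points, pattern.window)
    observed = _cross_k_curves(dist, wts, f, t_obs, radii, ring_width, pattern.area)

    deterministic = np.all((probs < 1e-12) | (probs > 1 - 1e-12))
    sims = np.empty((n_sim, len(radii)))
    p_norm = probs / probs.sum()
    for s in range(n_sim):
        if deterministic:
            t_sim = probs > 0.5
        elif scheme == "weighted_permutation":
            idx = rng.choice(n, size=m, replace=False, p=p_norm)
            t_sim = np.zeros(n, dtype=bool)
            t_sim[idx] = True
        else:
            t_sim = rng.random(n) < probs
            if t_sim.sum() == 0:
                t_sim[np.argmax(probs)] = True
        sims[s] = _cross_k_curves(dist, wts, f, t_sim, radii, ring_width, pattern.area)

    lower = np.quantile(sims, alpha / 2, axis=0)
    upper = np.quantile(sims, 1 - alpha / 2, axis=0)
    return RingKEnvelope(
        radii=radii,
        ring_width=ring_width,
        observed=observed,
        lower=lower,
        upper=upper,
        n_sim=n_sim,
        alpha=alpha,
    )
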