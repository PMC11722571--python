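"""Bayesian mixed-effects host models.

Four models relate what grows on a tree to forest type and tree size,
with a tree-species random intercept:

=================  =================  ==================================
response           family             support
=================  =================  ==================================
liana_richness     hurdle_poisson     0, 1, 2, ...
epi_richness       hurdle_poisson     0, 1, 2, ...
liana_ba           hurdle_lognormal   0 or positive reals (m^2)
epi_cover          cumulative_logit   cover classes 1..5 (hosts only)
=================  =================  ==================================

Hurdle families put a logistic colonization sub-model on presence
(``Pr(y > 0) = logistic(h0 + h1*mature + h2*dbh_z)``) and a
zero-truncated density on positive outcomes whose linear predictor is
``b0 + b1*mature + b2*dbh_z + u[species]`` with ``u ~ N(0, sigma_sp^2)``.
The cumulative model is a proportional-odds logit on the 1-5 cover
classes of colonized trees (the cover scale is undefined for bare
trees), with four ordered cutpoints absorbing the intercept.

Posteriors are sampled with an affine-invariant ensemble sampler
(emcee) initialized at the posterior mode; each walker is treated as a
chain for split-Rhat/ESS diagnostics (arviz).  Priors are weakly
informative: normal(0, 2.5) on coefficients (dbh standardized),
half-normal(1) on the random-effect and lognormal scales, normal(0, 5)
on the first cutpoint and lognormal(0, 1) on cutpoint gaps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, gammaln

from .datamodel import ForestDataset

__all__ = [
    "FAMILY_OF_RESPONSE",
    "HostModelSpec",
    "HostParams",
    "loglik",
    "fit",
    "HostModelFit",
    "marginal_curves",
]

FAMILY_OF_RESPONSE = {
    "liana_richness": "hurdle_poisson",
    "epi_richness": "hurdle_poisson",
    "liana_ba": "hurdle_lognormal",
    "epi_cover": "cumulative_logit",
}

N_COVER_CLASSES = 5


@dataclass(frozen=True)
class HostModelSpec:
    """Which response to model, and with which family."""

    response: str
    family: str = ""

    def __post_init__(self):
        if self.response not in FAMILY_OF_RESPONSE:
            raise ValueError(f"unknown response {self.response!r}")
        fam = self.family or FAMILY_OF_RESPONSE[self.response]
        if fam != FAMILY_OF_RESPONSE[self.response]:
            raise ValueError(f"family {fam!r} does not match response {self.response!r}")
        object.__setattr__(self, "family", fam)


@dataclass
class HostParams:
    """A full set of parameter values for one family."""

    fixed: tuple = (0.0, 0.0, 0.0)  # (b0, b1 mature, b2 dbh_z)
    hurdle: tuple = (0.0, 0.0, 0.0)  # (h0, h1 mature, h2 dbh_z), presence scale
    sigma_obs: float = 1.0  # lognormal scale
    cutpoints: tuple = (-2.0, -0.5, 0.5, 2.0)
    sigma_sp: float = 0.0


def _eta(coefs, mature, dbh_z, species_effect):
    b0, b1, b2 = coefs
    return b0 + b1 * np.asarray(mature) + b2 * np.asarray(dbh_z) + species_effect


def loglik(family: str, params: HostParams, y, mature=0, dbh_z=0.0,
           species_effect=0.0):
    """Pointwise log-probability of ``y`` under one family.

    Vectorized over ``y`` (and the covariates, broadcasting).  Raises
    ``ValueError`` for responses outside the family's support.
    """
    y = np.asarray(y, dtype=float)
    if family in ("hurdle_poisson", "hurdle_lognormal"):
        if np.any(y < 0):
            raise ValueError("hurdle responses must be >= 0")
        if family == "hurdle_poisson" and np.any(y != np.floor(y)):
            raise ValueError("hurdle-Poisson responses must be integers")
        p_pos = expit(_eta(params.hurdle, mature, dbh_z, species_effect))
        eta = _eta(params.fixed, mature, dbh_z, species_effect)
        out = np.where(y == 0, np.log1p(-np.minimum(p_pos, 1 - 1e-300)), 0.0)
        pos = y > 0
        if np.any(pos):
            yp = y[pos] if y.ndim else y
            e = np.broadcast_to(eta, y.shape)[pos] if y.ndim else eta
            pp = np.broadcast_to(p_pos, y.shape)[pos] if y.ndim else p_pos
            if family == "hurdle_poisson":
                lam = np.exp(e)
                # zero-truncated Poisson: renormalized by 1 - e^-lam
                lp = (
                    yp * e - lam - gammaln(yp + 1.0)
                    - np.log(-np.expm1(-lam))
                )
            else:
                s = params.sigma_obs
                ly = np.log(yp)
                lp = (
                    -ly - 0.5 * math.log(2 * math.pi) - math.log(s)
                    - 0.5 * ((ly - e) / s) ** 2
                )
            val = np.log(pp) + lp
            if y.ndim:
                out[pos] = val
            else:
                out = val
        return out if y.ndim else float(out)

    if family == "cumulative_logit":
        yi = y.astype(int)
        if np.any((yi < 1) | (yi > N_COVER_CLASSES)) or np.any(y != np.floor(y)):
            raise ValueError(f"cover classes must be integers 1..{N_COVER_CLASSES}")
        c = np.concatenate([[-np.inf], np.asarray(params.cutpoints, float), [np.inf]])
        if np.any(np.diff(params.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")
        eta = np.broadcast_to(
            _eta(params.fixed, mature, dbh_z, species_effect), y.shape if y.ndim else ()
        )
        hi = expit(c[yi] - eta)
        lo = expit(c[yi - 1] - eta)
        out = np.log(np.maximum(hi - lo, 1e-300))
        return out if y.ndim else float(out)

    raise ValueError(f"unknown family {family!r}")


# ---------------------------------------------------------------------
# response extraction


def _model_frame(spec: HostModelSpec, ds: ForestDataset):
    tt = ds.tree_table()
    col = {
        "liana_richness": "liana_richness",
        "epi_richness": "epi_richness",
        "liana_ba": "liana_ba",
        "epi_cover": "epi_cover",
    }[spec.response]
    if spec.family == "cumulative_logit":
        tt = tt[tt[col] > 0]  # cover is defined for colonized trees only
    y = tt[col].to_numpy(dtype=float)
    mature = (tt["forest_type"] == "mature").to_numpy(dtype=float)
    dbh = tt["dbh"].to_numpy(dtype=float)
    species = tt["species"].astype(str).to_numpy()
    return y, mature, dbh, species


# ---------------------------------------------------------------------
# posterior


class _Posterior:
    """Packed-vector log posterior for one family."""

    def __init__(self, family, y, mature, dbh_z, sp_codes, n_sp, drop_mature=False):
        self.family = family
        self.y = y
        self.mature = mature
        self.dbh_z = dbh_z
        self.sp = sp_codes
        self.n_sp = n_sp
        self.drop_mature = drop_mature
        self.is_zero = y == 0
        self.is_pos = ~self.is_zero
        if family == "hurdle_poisson":
            self.ypos = y[self.is_pos]
            self.gam = gammaln(self.ypos + 1.0)
        elif family == "hurdle_lognormal":
            self.ly = np.log(y[self.is_pos])
        else:
            self.yi = y.astype(int)
        self.names = self._names()
        self.ndim = len(self.names)

    def _names(self):
        n = []
        if self.family != "cumulative_logit":
            n += ["h_intercept", "h_mature", "h_dbh", "intercept"]
        n += ["mature", "dbh"]
        n += [f"u[{i}]" for i in range(self.n_sp)]
        n += ["log_sigma_sp"]
        if self.family == "hurdle_lognormal":
            n += ["log_sigma_obs"]
        if self.family == "cumulative_logit":
            n += ["c1", "log_gap2", "log_gap3", "log_gap4"]
        return n

    def unpack(self, x):
        i = 0
        d = {}
        if self.family != "cumulative_logit":
            d["hurdle"] = x[i : i + 3]
            i += 3
            d["b0"] = x[i]
            i += 1
        else:
            d["b0"] = 0.0
        d["b1"] = x[i]
        d["b2"] = x[i + 1]
        i += 2
        d["u_raw"] = x[i : i + self.n_sp]
        i += self.n_sp
        d["log_sigma_sp"] = x[i]
        i += 1
        if self.family == "hurdle_lognormal":
            d["log_sigma_obs"] = x[i]
            i += 1
        if self.family == "cumulative_logit":
            c1 = x[i]
            gaps = np.exp(x[i + 1 : i + 4])
            d["cutpoints"] = np.concatenate([[c1], c1 + np.cumsum(gaps)])
            d["log_gaps"] = x[i + 1 : i + 4]
        return d

    def __call__(self, x):
        d = self.unpack(x)
        sigma_sp = math.exp(min(d["log_sigma_sp"], 8.0))
        # non-centered species effects: u = sigma_sp * u_raw keeps the
        # posterior density bounded as sigma_sp -> 0
        u = sigma_sp * d["u_raw"]
        eff = u[self.sp]
        b1 = 0.0 if self.drop_mature else d["b1"]
        eta = d["b0"] + b1 * self.mature + d["b2"] * self.dbh_z + eff

        lp = 0.0
        # priors: N(0, 2.5) coefficients, half-normal(1) scales
        # (sampled on the log scale, hence the +log sigma Jacobian)
        for c in ([d["b0"], d["b1"], d["b2"]] if self.family != "cumulative_logit"
                  else [d["b1"], d["b2"]]):
            lp += -0.5 * (c / 2.5) ** 2
        lp += -0.5 * sigma_sp**2 + d["log_sigma_sp"]
        lp += -0.5 * np.sum(d["u_raw"] ** 2)

        if self.family == "cumulative_logit":
            lp += -0.5 * (d["cutpoints"][0] / 5.0) ** 2
            lp += -0.5 * np.sum(d["log_gaps"] ** 2)
            c = np.concatenate([[-np.inf], d["cutpoints"], [np.inf]])
            pk = expit(c[self.yi] - eta) - expit(c[self.yi - 1] - eta)
            return lp + float(np.sum(np.log(np.maximum(pk, 1e-300))))

        h = d["hurdle"]
        for c in h:
            lp += -0.5 * (c / 2.5) ** 2
        zeta = h[0] + h[1] * self.mature + h[2] * self.dbh_z
        # Bernoulli presence: log(1-p) on zeros, log(p) on positives
        lp += -float(np.sum(np.logaddexp(0.0, zeta[self.is_zero])))
        lp += -float(np.sum(np.logaddexp(0.0, -zeta[self.is_pos])))

        eta_p = eta[self.is_pos]
        if self.family == "hurdle_poisson":
            # clip eta so lam stays inside (0, inf): log(-expm1(-lam))
            # would hit log(0) for underflowing rates
            lam = np.exp(np.clip(eta_p, -30.0, 30.0))
            eta_p = np.clip(eta_p, -30.0, 30.0)
            ll = self.ypos * eta_p - lam - self.gam - np.log(-np.expm1(-lam))
        else:
            sigma = math.exp(min(d["log_sigma_obs"], 8.0))
            lp += -0.5 * sigma**2 + d["log_sigma_obs"]
            ll = (
                -self.ly - 0.5 * math.log(2 * math.pi) - math.log(sigma)
                - 0.5 * ((self.ly - eta_p) / sigma) ** 2
            )
        out = lp + float(np.sum(ll))
        return out if np.isfinite(out) else -np.inf

    def start_point(self):
        x = np.zeros(self.ndim)
        x[self.names.index("log_sigma_sp")] = math.log(0.3)
        if self.family == "hurdle_lognormal":
            x[self.names.index("log_sigma_obs")] = math.log(
                max(np.std(self.ly), 0.2)
            )
            x[self.names.index("intercept")] = float(np.mean(self.ly))
        elif self.family == "hurdle_poisson":
            x[self.names.index("intercept")] = math.log(max(np.mean(self.y[self.is_pos]), 1.05) - 1 + 0.5)
        else:
            # spread initial cutpoints over the empirical class range
            x[self.names.index("c1")] = -1.0
        return x


@dataclass
class HostModelFit:
    """Posterior draws, summaries and diagnostics for one host model."""

    spec: HostModelSpec
    names: list
    samples: np.ndarray  # (n_draws, ndim), post burn-in, flattened
    chain_samples: np.ndarray  # (n_walkers, n_steps, ndim)
    rhat: dict
    ess: dict
    species: list
    dbh_mean: float
    dbh_sd: float
    dropped_mature: bool = False
    rhat_threshold: float = 1.01
    ess_threshold: float = 1000.0

    @property
    def converged(self) -> bool:
        """Convergence per the Rhat < 1.01 and ESS > 1000 rule."""
        return (
            max(self.rhat.values()) < self.rhat_threshold
            and min(self.ess.values()) > self.ess_threshold
        )

    def draws(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]

    def interval(self, name: str, level: float = 0.95):
        """Equal-tailed posterior credible interval for a parameter.

        ``dbh_per_cm`` and ``sigma_sp`` are accepted as derived names.
        """
        x = self._derived(name)
        a = (1 - level) / 2
        return float(np.quantile(x, a)), float(np.quantile(x, 1 - a))

    def posterior_mean(self, name: str) -> float:
        return float(np.mean(self._derived(name)))

    def _derived(self, name):
        if name == "dbh_per_cm":
            return self.draws("dbh") / self.dbh_sd
        if name == "sigma_sp":
            return np.exp(self.draws("log_sigma_sp"))
        if name == "sigma_obs":
            return np.exp(self.draws("log_sigma_obs"))
        return self.draws(name)

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, n in enumerate(self.names):
            x = self.samples[:, i]
            rows.append(
                {
                    "param": n,
                    "mean": np.mean(x),
                    "sd": np.std(x),
                    "q2.5": np.quantile(x, 0.025),
                    "q97.5": np.quantile(x, 0.975),
                    "rhat": self.rhat[n],
                    "ess": self.ess[n],
                }
            )
        for n in ["dbh_per_cm", "sigma_sp"] + (
            ["sigma_obs"] if "log_sigma_obs" in self.names else []
        ):
            x = self._derived(n)
            rows.append(
                {
                    "param": n,
                    "mean": np.mean(x),
                    "sd": np.std(x),
                    "q2.5": np.quantile(x, 0.025),
                    "q97.5": np.quantile(x, 0.975),
                    "rhat": np.nan,
                    "ess": np.nan,
                }
            )
        return pd.DataFrame(rows)


def fit(
    spec: HostModelSpec,
    ds: ForestDataset,
    chains: int = 4,
    iterations: int = 8000,
    seed: Optional[int] = None,
    rhat_threshold: float = 1.01,
    ess_threshold: float = 1000.0,
) -> HostModelFit:
    """Sample the posterior of one host model.

    ``iterations`` is the number of ensemble steps; the first half is
    discarded as warm-up.  The walker count is ``max(2*ndim + 2,
    8*chains)`` and every walker is diagnosed as a chain.
    Non-convergence (any Rhat >= 1.01 or ESS <= 1000) is flagged on the
    returned fit, not fatal.
    """
    y, mature, dbh, species = _model_frame(spec, ds)
    sp_names = sorted(set(species))
    if len(sp_names) < 2:
        raise ValueError("need >= 2 tree species for a species random effect")
    codes = np.array([sp_names.index(s) for s in species])
    drop_mature = len(set(mature)) < 2
    if drop_mature:
        warnings.warn("only one forest type present; forest effect dropped")
    dbh_mean, dbh_sd = float(np.mean(dbh)), float(np.std(dbh))
    dbh_z = (dbh - dbh_mean) / dbh_sd

    post = _Posterior(spec.family, y, mature, dbh_z, codes, len(sp_names), drop_mature)
    x0 = post.start_point()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(lambda x: -post(x), x0, method="L-BFGS-B")
    xmap = res.x if np.isfinite(res.fun) else x0

    rng = np.random.default_rng(seed)
    nwalkers = max(2 * post.ndim + 2, 8 * chains)
    p0 = xmap + 0.02 * rng.standard_normal((nwalkers, post.ndim))
    sampler = emcee.EnsembleSampler(
        nwalkers,
        post.ndim,
        post,
        moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
    )
    sampler.random_state = np.random.RandomState(rng.integers(2**31 - 1)).get_state()
    sampler.run_mcmc(p0, iterations, progress=False, skip_initial_state_check=True)
    burn = iterations // 2
    chain = np.swapaxes(sampler.get_chain(discard=burn), 0, 1)  # walkers, steps, ndim

    idata = az.from_dict(
        posterior={n: chain[:, :, i] for i, n in enumerate(post.names)}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = {n: float(az.rhat(idata, var_names=[n]).to_array().item())
                for n in post.names}
        ess = {n: float(az.ess(idata, var_names=[n]).to_array().item())
               for n in post.names}

    return HostModelFit(
        spec=spec,
        names=post.names,
        samples=chain.reshape(-1, post.ndim),
        chain_samples=chain,
        rhat=rhat,
        ess=ess,
        species=sp_names,
        dbh_mean=dbh_mean,
        dbh_sd=dbh_sd,
        dropped_mature=drop_mature,
        rhat_threshold=rhat_threshold,
        ess_threshold=ess_threshold,
    )


def marginal_curves(fit_: HostModelFit, dbh_grid, forest_type: str,
                    level: float = 0.95, max_draws: int = 400) -> pd.DataFrame:
    """Posterior expected response over a dbh grid for one forest type.

    Species effects are set to zero (a typical species).  Returns a
    frame with columns dbh, mean, lower, upper.
    """
    dbh_grid = np.asarray(dbh_grid, dtype=float)
    z = (dbh_grid - fit_.dbh_mean) / fit_.dbh_sd
    mat = 1.0 if forest_type == "mature" else 0.0
    n = len(fit_.samples)
    take = np.linspace(0, n - 1, min(max_draws, n)).astype(int)
    fam = fit_.spec.family
    names = fit_.names
    idx = {nm: i for i, nm in enumerate(names)}
    curves = np.empty((len(take), len(dbh_grid)))
    for j, t in enumerate(take):
        x = fit_.samples[t]
        b1 = 0.0 if fit_.dropped_mature else x[idx["mature"]]
        if fam == "cumulative_logit":
            eta = b1 * mat + x[idx["dbh"]] * z
            c1 = x[idx["c1"]]
            cuts = np.concatenate(
                [[c1], c1 + np.cumsum(np.exp([x[idx["log_gap2"]],
                                              x[idx["log_gap3"]],
                                              x[idx["log_gap4"]]]))]
            )
            c = np.concatenate([[-np.inf], cuts, [np.inf]])
            pk = expit(c[1:, None] - eta[None, :]) - expit(c[:-1, None] - eta[None, :])
            curves[j] = (np.arange(1, N_COVER_CLASSES + 1)[:, None] * pk).sum(axis=0)
            continue
        eta = x[idx["intercept"]] + b1 * mat + x[idx["dbh"]] * z
        zeta = (
            x[idx["h_intercept"]]
            + (0.0 if fit_.dropped_mature else x[idx["h_mature"]]) * mat
            + x[idx["h_dbh"]] * z
        )
        p = expit(zeta)
        if fam == "hurdle_poisson":
            lam = np.exp(eta)
            curves[j] = p * lam / (-np.expm1(-lam))
        else:
            sig = math.exp(x[idx["log_sigma_obs"]])
            curves[j] = p * np.exp(eta + 0.5 * sig**2)
    a = (1 - level) / 2
    return pd.DataFrame(
        {
            "dbh": dbh_grid,
            "mean": curves.mean(axis=0),
            "lower": np.quantile(curves, a, axis=0),
            "upper": np.quantile(curves, 1 - a, axis=0),
        }
    )
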