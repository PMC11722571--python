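import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

from cooccur.hostmodels import (
    HostModelFit,
    HostModelSpec,
    HostParams,
    fit,
    loglik,
    marginal_curves,
)
from cooccur.synthetic import generate_stand


class TestLoglik:
    def test_zero_outcome_ignores_positive_part(self):
        # Pr(zero) = 0.3 regardless of the positive-part parameters
        h = (logit(0.7), 0.0, 0.0)
        for fam in ("hurdle_poisson", "hurdle_lognormal"):
            a = loglik(fam, HostParams(fixed=(0.1, 0, 0), hurdle=h), 0)
            b = loglik(fam, HostParams(fixed=(5.0, 1, -2), hurdle=h), 0)
            assert a == pytest.approx(math.log(0.3), abs=1e-12)
            assert a == b

    def test_hurdle_poisson_value(self):
        # pi = 0.5, lambda = 1, y = 2
        p = HostParams(fixed=(0.0, 0, 0), hurdle=(0.0, 0, 0))
        assert loglik("hurdle_poisson", p, 2) == pytest.approx(-1.9276, abs=1e-4)

    def test_truncated_poisson_matches_summation_oracle(self):
        rng = np.random.default_rng(0)
        ks = np.arange(1, 400)
        for _ in range(20):
            b0 = rng.uniform(-1.5, 2.0)
            h0 = rng.uniform(-2, 2)
            y = rng.integers(1, 8)
            got = loglik("hurdle_poisson", HostParams((b0, 0, 0), (h0, 0, 0)), y)
            lam = math.exp(b0)
            pmf = stats.poisson.pmf(ks, lam)
            want = math.log(expit(h0)) + math.log(
                stats.poisson.pmf(y, lam) / pmf.sum()
            )
            assert got == pytest.approx(want, abs=1e-8)

    def test_hurdle_poisson_normalizes(self):
        ys = np.arange(0, 201)
        p = HostParams(fixed=(1.2, 0, 0), hurdle=(0.3, 0, 0))
        total = np.exp(loglik("hurdle_poisson", p, ys)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_hurdle_lognormal_normalizes(self):
        p = HostParams(fixed=(-6.0, 0, 0), hurdle=(-0.4, 0, 0), sigma_obs=0.8)
        from scipy.integrate import quad

        dens, _ = quad(
            lambda y: math.exp(loglik("hurdle_lognormal", p, y)), 1e-9, 10.0
        )
        assert dens + math.exp(loglik("hurdle_lognormal", p, 0)) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_cumulative_normalizes_and_symmetry(self):
        p = HostParams(fixed=(0.0, 0, 0), cutpoints=(-3.0, -1.0, 1.0, 3.0))
        probs = np.exp(loglik("cumulative_logit", p, np.arange(1, 6)))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert probs[0] == pytest.approx(probs[4], abs=1e-12)
        assert probs[1] == pytest.approx(probs[3], abs=1e-12)

    @pytest.mark.parametrize(
        "fam, y",
        [
            ("hurdle_poisson", -1),
            ("hurdle_poisson", 1.5),
            ("cumulative_logit", 0),
            ("cumulative_logit", 6),
        ],
    )
    def test_out_of_support_rejected(self, fam, y):
        with pytest.raises(ValueError):
            loglik(fam, HostParams(), y)

    def test_spec_rejects_family_mismatch(self):
        with pytest.raises(ValueError):
            HostModelSpec("liana_ba", family="hurdle_poisson")


class TestConvergenceRule:
    def _fit(self, rhat, ess):
        names = ["a"]
        return HostModelFit(
            spec=HostModelSpec("liana_richness"),
            names=names,
            samples=np.zeros((10, 1)),
            chain_samples=np.zeros((2, 5, 1)),
            rhat={"a": rhat},
            ess={"a": ess},
            species=["x", "y"],
            dbh_mean=20.0,
            dbh_sd=10.0,
        )

    def test_declared_iff_rhat_below_and_ess_above(self):
        assert self._fit(1.005, 1500.0).converged
        assert not self._fit(1.01, 1500.0).converged
        assert not self._fit(1.005, 1000.0).converged


def _manual_fit(samples_row, names, dbh_sd=10.0):
    n = 200
    samples = np.tile(samples_row, (n, 1))
    return HostModelFit(
        spec=HostModelSpec("liana_richness"),
        names=names,
        samples=samples,
        chain_samples=samples.reshape(2, n // 2, -1),
        rhat={k: 1.0 for k in names},
        ess={k: 2000.0 for k in names},
        species=["x", "y"],
        dbh_mean=25.0,
        dbh_sd=dbh_sd,
    )


class TestMarginalCurves:
    NAMES = [
        "h_intercept", "h_mature", "h_dbh", "intercept", "mature", "dbh",
        "u[0]", "u[1]", "log_sigma_sp",
    ]

    def test_zero_slope_flat(self):
        f = _manual_fit(np.array([0.5, 0, 0, 0.2, 0, 0.0, 0, 0, -1]), self.NAMES)
        c = marginal_curves(f, np.linspace(10, 60, 6), "successional")
        assert np.allclose(c["mean"], c["mean"].iloc[0])

    def test_positive_slope_monotone(self):
        f = _manual_fit(np.array([0.5, 0, 0.3, 0.2, 0, 0.4, 0, 0, -1]), self.NAMES)
        c = marginal_curves(f, np.linspace(10, 60, 8), "successional")
        assert (np.diff(c["mean"]) > 0).all()

    def test_mature_offset_shifts_curve_up(self):
        f = _manual_fit(np.array([0.5, 0.3, 0.3, 0.2, 0.5, 0.4, 0, 0, -1]), self.NAMES)
        grid = np.linspace(10, 60, 8)
        cm = marginal_curves(f, grid, "mature")
        cs = marginal_curves(f, grid, "successional")
        assert (cm["mean"].to_numpy() > cs["mean"].to_numpy()).all()


class TestFit:
    def test_smoke_fit_summary_and_intervals(self, recovery_params):
        import dataclasses

        small = dataclasses.replace(recovery_params, plots_per_patch=2)
        ds = generate_stand(small, seed=2)
        f = fit(HostModelSpec("liana_richness"), ds, iterations=400, seed=0)
        s = f.summary()
        assert {"intercept", "mature", "dbh", "dbh_per_cm", "sigma_sp"} <= set(s.param)
        lo, hi = f.interval("dbh")
        assert np.isfinite([lo, hi]).all() and lo < hi
        assert isinstance(f.converged, bool)

    def test_zero_species_variance_recovered(self, zeroed_effects_params):
        """With no true species effects the sigma_sp posterior piles up
        near zero."""
        ds = generate_stand(zeroed_effects_params, seed=5)
        f = fit(HostModelSpec("epi_richness"), ds, iterations=1200, seed=3)
        _, hi = f.interval("sigma_sp")
        assert hi < 0.5

    def test_single_forest_type_drops_effect(self, recovery_params):
        import dataclasses

        mono = dataclasses.replace(
            recovery_params,
            n_patches=2,
            plots_per_patch=3,
            patch_types={"S0": "successional", "S1": "successional"},
        )
        ds = generate_stand(mono, seed=1)
        with pytest.warns(UserWarning, match="forest type"):
            f = fit(HostModelSpec("liana_richness"), ds, iterations=200, seed=0)
        assert f.dropped_mature
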