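import numpy as np
import pytest
from scipy import stats

from cooccur.countmodels import (
    mechanism_contrast,
    nb_group_contrast,
    patch_contrasts,
    zone_contrasts,
)
from cooccur.datamodel import (
    EpiphyteRecord,
    ForestDataset,
    LianaRecord,
    TreeRecord,
)
from cooccur.errors import DegenerateDesignError, SeparationError


def even_split(total, n=10):
    base, rem = divmod(total, n)
    return [base + 1] * rem + [base] * (n - rem)


def nb2_loglik(y, mu, alpha):
    """Independent NB2 log-likelihood via scipy's nbinom."""
    size = 1.0 / alpha
    return float(stats.nbinom.logpmf(y, size, size / (size + mu)).sum())


class TestNbGroupContrast:
    # patch label -> (liana hosts, epiphyte hosts, printed alt-vs-ref estimate)
    PUBLISHED = {
        "Reserva": (7, 120, -2.84),
        "Frontino": (32, 134, -1.43),
        "Cedro": (73, 55, 0.28),
        "Sismografo": (53, 61, -0.14),
        "Ha6": (103, 86, 0.18),
    }

    @pytest.mark.parametrize("label", sorted(PUBLISHED))
    def test_published_patch_estimates(self, label):
        liana, epi, printed = self.PUBLISHED[label]
        res = nb_group_contrast(even_split(epi), even_split(liana))
        assert res.estimate == pytest.approx(printed, abs=0.005)

    def test_estimate_is_log_mean_ratio(self):
        rng = np.random.default_rng(0)
        for _ in range(8):
            a = rng.poisson(rng.uniform(2, 15), 10)
            b = rng.negative_binomial(3, 0.3, 10)
            if a.sum() == 0 or b.sum() == 0:
                continue
            res = nb_group_contrast(a, b)
            assert res.estimate == pytest.approx(
                np.log(b.mean() / a.mean()), abs=1e-6
            )

    def test_estimate_invariant_to_split(self):
        for alt in ([7, 0, 0], [3, 2, 2], [1, 1, 5]):
            res = nb_group_contrast([40, 40, 40], alt)
            assert res.estimate == pytest.approx(np.log(7 / 120), abs=1e-6)

    def test_label_swap_negates(self):
        a, b = [3, 5, 9, 2], [7, 1, 4, 4]
        r1 = nb_group_contrast(a, b)
        r2 = nb_group_contrast(b, a)
        assert r1.estimate == pytest.approx(-r2.estimate, abs=1e-8)
        assert r1.z == pytest.approx(-r2.z, rel=1e-6)

    def test_identical_groups_estimate_zero(self):
        res = nb_group_contrast([4, 7, 2], [4, 7, 2])
        assert res.estimate == pytest.approx(0.0, abs=1e-10)

    def test_all_zero_group_is_separation(self):
        with pytest.raises(SeparationError):
            nb_group_contrast([0, 0, 0], [1, 2, 3])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_group_contrast([1, -2], [3, 4])

    def test_underdispersed_data_reduces_to_poisson(self):
        import statsmodels.api as sm

        a, b = [12] * 10, even_split(7)
        res = nb_group_contrast(a, b)
        assert res.theta == np.inf
        y = np.array(a + b, dtype=float)
        X = sm.add_constant(np.r_[np.zeros(10), np.ones(10)])
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert res.z == pytest.approx(ref.tvalues[1], rel=1e-8)

    def test_mle_beats_likelihood_grid(self):
        """The fitted (means, dispersion) maximize the NB2 likelihood."""
        rng = np.random.default_rng(3)
        a = rng.negative_binomial(2, 0.25, 12)
        b = rng.negative_binomial(2, 0.45, 12)
        res = nb_group_contrast(a, b)
        y = np.concatenate([a, b])
        mu_hat = np.r_[np.full(12, a.mean()), np.full(12, b.mean())]
        assert np.isfinite(res.theta)
        best = nb2_loglik(y, mu_hat, 1.0 / res.theta)
        for alpha in np.linspace(0.05, 3.0, 40):
            for shift in (-0.05, 0.0, 0.05):
                mu = np.r_[
                    np.full(12, a.mean() * np.exp(shift)),
                    np.full(12, b.mean() * np.exp(-shift)),
                ]
                assert nb2_loglik(y, mu, alpha) <= best + 1e-6


def _contrast_fixture():
    """Two plots; liana occurrences trunk=(2,2), crown=(4,4)."""
    trees, lianas, epis = [], [], []
    for p, plot in enumerate(["p01", "p02"]):
        for i in range(8):
            tid = f"T{p}{i}"
            trees.append(TreeRecord(tid, "A", plot, "sp", 20.0))
        for i in range(2):
            lianas.append(LianaRecord(f"T{p}{i}", "L1", 2.0, "specialized", "trunk"))
        for i in range(4):
            lianas.append(LianaRecord(f"T{p}{i + 2}", "L1", 2.0, "specialized", "crown"))
        for i in range(3):
            epis.append(
                EpiphyteRecord(f"T{p}{i}", f"E{i}", 1, frozenset({"trunk", "crown"}))
            )
    return ForestDataset(trees, lianas, epis, {"A": {"forest_type": "successional"}})


class TestDatasetContrasts:
    def test_zone_contrast_closed_form(self):
        ds = _contrast_fixture()
        res = zone_contrasts(ds)["liana_trunk_vs_crown"]
        assert res.estimate == pytest.approx(np.log(2 / 4), abs=1e-6)

    def test_crown_biased_epiphytes_give_negative_trunk_estimate(self, small_stand):
        res = zone_contrasts(small_stand)["epi_trunk_vs_crown"]
        assert res.estimate < 0

    def test_patch_contrasts_match_host_ratios(self, small_stand):
        tt = small_stand.tree_table()
        for pid, res in patch_contrasts(small_stand):
            sub = tt[tt.patch_id == pid]
            expected = np.log(sub.liana_host.sum() / sub.epi_host.sum())
            assert res.estimate == pytest.approx(expected, abs=1e-6)

    def test_mechanism_contrast_closed_form(self):
        trees = [TreeRecord(f"T{i}", "A", "p01", "sp", 20.0) for i in range(2)]
        lianas = [
            LianaRecord("T0", "Lspec", 2.0, "specialized", "trunk"),
            LianaRecord("T1", "Llean", 2.0, "leaning", "trunk"),
        ]
        epis = [
            EpiphyteRecord("T0", f"E{k}", 1, frozenset({"crown"})) for k in range(8)
        ] + [EpiphyteRecord("T1", f"E{k}", 1, frozenset({"crown"})) for k in range(2)]
        ds = ForestDataset(trees, lianas, epis, {"A": {"forest_type": "mature"}})
        res = mechanism_contrast(ds)
        assert res.estimate == pytest.approx(np.log(4.0), abs=1e-6)

    def test_specialized_bonus_gives_positive_mechanism_estimate(self, small_stand):
        assert mechanism_contrast(small_stand).estimate > 0

    def test_single_mechanism_degenerate(self):
        trees = [TreeRecord("T0", "A", "p01", "sp", 20.0)]
        lianas = [LianaRecord("T0", "L", 2.0, "leaning", "trunk")]
        ds = ForestDataset(trees, lianas, [], {"A": {"forest_type": "mature"}})
        with pytest.raises(DegenerateDesignError):
            mechanism_contrast(ds)
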