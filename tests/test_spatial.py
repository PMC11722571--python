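import math

import numpy as np
import pytest

from cooccur.errors import InsufficientPointsError
from cooccur.spatial import (
    MappedPattern,
    covariate_null_envelope,
    default_radii,
    ring_cross_k,
    ring_k,
)
from cooccur.synthetic import StandParams, generate_mapped_block

WINDOW = (0.0, 60.0, 0.0, 60.0)


def brute_ring_k(points, window, sel_from, sel_to, radii, ring_width):
    """Slow double-loop translation-corrected ring cross-K."""
    xmin, xmax, ymin, ymax = window
    W, H = xmax - xmin, ymax - ymin
    area = W * H
    fi = np.flatnonzero(sel_from)
    ti = np.flatnonzero(sel_to)
    n_pairs = len(fi) * len(ti) - len(set(fi) & set(ti))

    def K(r):
        if r <= 0:
            return 0.0
        s = 0.0
        for i in fi:
            for j in ti:
                if i == j:
                    continue
                dx = abs(points[i, 0] - points[j, 0])
                dy = abs(points[i, 1] - points[j, 1])
                if math.hypot(dx, dy) <= r:
                    s += area / ((W - dx) * (H - dy))
        return s * area / n_pairs

    return np.array([K(r) - K(r - ring_width) for r in radii])


def _uniform_pattern(rng, n, marks=None):
    pts = rng.uniform(0, 60, (n, 2))
    if marks is None:
        marks = {"all": np.ones(n, dtype=bool)}
    return MappedPattern(pts, WINDOW, marks)


class TestRingK:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            n = 30
            pts = rng.uniform(0, 60, (n, 2))
            liana = rng.random(n) < 0.5
            epi = rng.random(n) < 0.5
            liana[:2] = epi[:2] = True
            pat = MappedPattern(pts, WINDOW, {"l": liana, "e": epi})
            radii = default_radii()
            got = ring_k(pat, "l", radii)
            want = brute_ring_k(pts, WINDOW, liana, liana, radii, 2.0)
            np.testing.assert_allclose(got, want, atol=1e-10)
            got_x = ring_cross_k(pat, "l", "e", radii)
            want_x = brute_ring_k(pts, WINDOW, liana, epi, radii, 2.0)
            np.testing.assert_allclose(got_x, want_x, atol=1e-10)

    def test_two_points_mass_in_correct_ring(self):
        pts = np.array([[30.0, 30.0], [33.0, 30.0]])
        pat = MappedPattern(pts, WINDOW, {"m": np.ones(2, bool)})
        vals = ring_k(pat, "m", [2.0, 4.0, 6.0])
        assert vals[0] == 0.0
        assert vals[1] > 0.0
        assert vals[2] == 0.0

    def test_wide_ring_equals_plain_k(self):
        rng = np.random.default_rng(1)
        pat = _uniform_pattern(rng, 40)
        radii = default_radii()
        wide = ring_k(pat, "all", radii, ring_width=1000.0)
        # telescoping: unit rings accumulate to the plain K
        unit = ring_k(pat, "all", np.arange(1.0, 15.0), ring_width=1.0)
        np.testing.assert_allclose(np.cumsum(unit)[-1], wide[-1], rtol=1e-12)

    def test_csr_expectation_closed_form(self):
        rng = np.random.default_rng(11)
        radii = default_radii()
        vals = np.array(
            [ring_k(_uniform_pattern(rng, 50), "all", radii) for _ in range(200)]
        )
        expected = np.pi * (radii**2 - (radii - 2.0) ** 2)
        se = vals.std(axis=0) / np.sqrt(len(vals))
        assert np.all(np.abs(vals.mean(axis=0) - expected) < 4 * se + 1e-9)

    def test_insufficient_points_rejected(self):
        pat = MappedPattern(
            np.array([[1.0, 1.0], [2.0, 2.0]]),
            WINDOW,
            {"m": np.array([True, False])},
        )
        with pytest.raises(InsufficientPointsError):
            ring_k(pat, "m", [2.0])

    def test_radius_beyond_half_window_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            ring_k(_uniform_pattern(rng, 10), "all", [40.0])


class TestCrossK:
    def test_identical_mark_sets_reduce_to_univariate(self):
        rng = np.random.default_rng(5)
        n = 40
        pts = rng.uniform(0, 60, (n, 2))
        m = rng.random(n) < 0.4
        m[:3] = True
        pat = MappedPattern(pts, WINDOW, {"a": m, "b": m.copy()})
        radii = default_radii()
        np.testing.assert_allclose(
            ring_cross_k(pat, "a", "b", radii), ring_k(pat, "a", radii), rtol=1e-12
        )

    def test_pair_at_5m_lands_in_4_6_ring(self):
        pts = np.array([[30.0, 30.0], [35.0, 30.0]])
        pat = MappedPattern(
            pts, WINDOW, {"l": np.array([True, False]), "e": np.array([False, True])}
        )
        vals = ring_cross_k(pat, "l", "e", [2.0, 4.0, 6.0])
        assert vals[0] == 0.0 and vals[1] == 0.0 and vals[2] > 0.0


class TestEnvelope:
    def _marked_pattern(self, seed=0, n=100):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 60, (n, 2))
        dbh = rng.lognormal(3.0, 0.4, n).clip(10)
        liana = rng.random(n) < 0.4
        epi = rng.random(n) < 0.4
        liana[:2] = epi[:2] = True
        import pandas as pd

        cov = pd.DataFrame({"dbh": dbh, "species": ["sp"] * n})
        return MappedPattern(pts, WINDOW, {"liana_host": liana, "epi_host": epi}, cov)

    def test_seeded_envelope_is_reproducible(self):
        pat = self._marked_pattern()
        kw = dict(n_sim=99, seed=21)
        a = covariate_null_envelope(pat, "liana_host", "epi_host", **kw)
        b = covariate_null_envelope(pat, "liana_host", "epi_host", **kw)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)
        np.testing.assert_array_equal(a.observed, b.observed)

    def test_envelope_monotone_in_alpha(self):
        pat = self._marked_pattern(seed=2)
        tight = covariate_null_envelope(
            pat, "liana_host", "epi_host", n_sim=499, alpha=0.05, seed=3
        )
        wide = covariate_null_envelope(
            pat, "liana_host", "epi_host", n_sim=499, alpha=0.01, seed=3
        )
        assert np.all(wide.lower <= tight.lower + 1e-12)
        assert np.all(wide.upper >= tight.upper - 1e-12)

    def test_deterministic_marks_collapse_envelope(self):
        rng = np.random.default_rng(4)
        n = 40
        pts = rng.uniform(0, 60, (n, 2))
        epi = np.zeros(n, bool)
        epi[:15] = True
        liana = np.zeros(n, bool)
        liana[20:30] = True
        import pandas as pd

        # dbh separates the mark perfectly -> fitted probabilities 0/1
        dbh = np.where(epi, 80.0, 12.0)
        cov = pd.DataFrame({"dbh": dbh, "species": ["sp"] * n})
        pat = MappedPattern(pts, WINDOW, {"liana_host": liana, "epi_host": epi}, cov)
        env = covariate_null_envelope(pat, "liana_host", "epi_host", n_sim=49, seed=0)
        np.testing.assert_allclose(env.upper, env.lower, atol=1e-9)
        assert np.all(env.exceed == 0)

    def test_generator_block_runs_end_to_end(self):
        import warnings

        ds = generate_mapped_block(StandParams(), seed=9)
        pat = MappedPattern.from_dataset(ds)
        with warnings.catch_warnings():
            # rare species levels may separate the mark (dbh-only fallback)
            warnings.simplefilter("ignore")
            env = covariate_null_envelope(
                pat, "liana_host", "epi_host", n_sim=199, seed=1
            )
        assert env.to_frame().notna().all().all()
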