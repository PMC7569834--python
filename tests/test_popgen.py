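import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from criollo import (
    WindowSpec,
    fst_site_components,
    impute_missing,
    site_pi,
    tajima_constants,
    windowed_fst,
    windowed_pi,
    windowed_tajima_d,
)
from criollo.io import MISSING, PopulationMap
from criollo.popgen import tajima_d_from_summary

from conftest import random_panel


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_window_pi(g, samples, size):
    """Enumerate chromosome pairs per site, count mismatches, divide by
    pairs and window length."""
    sub = g.subset_samples(samples)
    out = {}
    for s in range(sub.n_sites):
        calls = [d for d in sub.dosage[:, s] if d != MISSING]
        alleles = []
        for d in calls:
            alleles += [1] * d + [0] * (2 - d)
        n = len(alleles)
        if n < 2:
            continue
        mism = sum(a != b for a, b in itertools.combinations(alleles, 2))
        pi = mism / (n * (n - 1) / 2)
        key = (sub.chrom[s], (sub.pos[s] - 1) // size)
        out[key] = out.get(key, 0.0) + pi
    return {k: v / size for k, v in out.items()}


def textbook_wc84(n1, p1, h1, n2, p2, h2):
    """Scalar evaluation of the 1984 two-population variance components."""
    r = 2
    ns = [n1, n2]
    ps = [p1, p2]
    hs = [h1, h2]
    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


# ---------------------------------------------------------------------------
# per-site pi
# ---------------------------------------------------------------------------

class TestSitePi:
    @pytest.mark.parametrize(
        "alt,n,expected",
        [
            (0, 10, 0.0),
            (2, 4, 4 / 6),  # brute force: 4 of 6 chromosome pairs differ
            (4, 10, 24 / 45),  # 24 of 45 pairs differ
            (10, 10, 0.0),
        ],
    )
    def test_known_values(self, alt, n, expected):
        assert site_pi(alt, n) == pytest.approx(expected, abs=1e-12)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(2, 12))
            alt = int(rng.integers(0, n + 1))
            alleles = [1] * alt + [0] * (n - alt)
            mism = sum(
                a != b for a, b in itertools.combinations(alleles, 2)
            )
            assert site_pi(alt, n) == pytest.approx(
                mism / (n * (n - 1) / 2), abs=1e-12
            )

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(2, 200), st.data())
    def test_bounds_and_allele_symmetry(self, n, data):
        alt = data.draw(st.integers(0, n))
        pi = site_pi(alt, n)
        assert 0.0 <= pi <= 1.0
        assert pi == site_pi(n - alt, n)  # ref/alt relabeling

    def test_too_few_chromosomes(self):
        with pytest.raises(ValueError):
            site_pi(0, 1)


# ---------------------------------------------------------------------------
# Tajima constants and D
# ---------------------------------------------------------------------------

class TestTajima:
    def test_constants_n4(self):
        c = tajima_constants(4)
        assert c.a1 == pytest.approx(11 / 6, abs=1e-12)
        assert c.b1 == pytest.approx(5 / 9, abs=1e-12)
        assert c.e1 == pytest.approx(0.005510, abs=1e-6)

    def test_constants_invalid_n(self):
        with pytest.raises(ValueError):
            tajima_constants(1)

    def test_single_segregating_site_n4(self):
        # k_hat = 0.6667, theta_W = 0.5455, Var = e1*S
        d = tajima_d_from_summary(site_pi(2, 4), S=1, n_chrom=4)
        assert d == pytest.approx(1.633, abs=1e-3)

    def test_undefined_without_segregating_sites(self):
        assert math.isnan(tajima_d_from_summary(0.0, 0, 10))

    def test_window_size_invariance(self):
        # D depends only on the contained sites, not the window span
        rng = np.random.default_rng(5)
        g = random_panel(rng, n_samples=8, n_sites=20, n_chrom=1,
                         max_pos=900_000)
        small = windowed_tajima_d(g, spec=WindowSpec(size=1_000_000))
        big = windowed_tajima_d(g, spec=WindowSpec(size=100_000_000))
        assert len(small) == len(big) == 1
        assert small[0].tajima_d == pytest.approx(big[0].tajima_d, abs=1e-12)


# ---------------------------------------------------------------------------
# windowed pi
# ---------------------------------------------------------------------------

class TestWindowedPi:
    def test_single_site_window(self):
        g = random_panel(np.random.default_rng(1), 2, 1, missing_rate=0.0,
                         n_chrom=1, max_pos=900_000)
        g.dosage[:, 0] = [1, 1]  # alt=2 of n=4 chromosomes
        (w,) = windowed_pi(g, spec=WindowSpec(size=1_000_000))
        assert w.pi == pytest.approx(site_pi(2, 4) / 1e6, rel=1e-12)

    def test_monomorphic_window_pi_zero(self):
        g = random_panel(np.random.default_rng(2), 5, 8, missing_rate=0.0,
                         n_chrom=1, max_pos=900_000)
        g.dosage[:] = 2
        (w,) = windowed_pi(g)
        assert w.pi == 0.0
        assert w.S == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        g = random_panel(
            rng,
            n_samples=int(rng.integers(3, 11)),
            n_sites=int(rng.integers(10, 51)),
            missing_rate=0.1,
        )
        size = 1_000_000
        oracle = brute_force_window_pi(g, g.sample_ids, size)
        wins = windowed_pi(g, spec=WindowSpec(size=size))
        got = {
            (w.interval.chrom, w.interval.start // size): w.pi for w in wins
        }
        assert set(got) == set(oracle)
        for k in oracle:
            assert got[k] == pytest.approx(oracle[k], abs=1e-15)

    def test_k_hat_conserved_under_partition(self):
        rng = np.random.default_rng(9)
        g = random_panel(rng, 6, 40, missing_rate=0.05)
        total = sum(w.k_hat for w in windowed_pi(g, spec=WindowSpec(10**9)))
        parts = sum(w.k_hat for w in windowed_pi(g, spec=WindowSpec(100_000)))
        assert parts == pytest.approx(total, rel=1e-12)

    def test_magnitude_of_sparse_array_windows(self):
        # ~6 intermediate-frequency SNPs per 1 Mb gives pi of order 1e-6
        g = random_panel(np.random.default_rng(3), 10, 6, missing_rate=0.0,
                         n_chrom=1, max_pos=999_999)
        g.dosage[:5, :] = 0
        g.dosage[5:, :] = 2
        (w,) = windowed_pi(g)
        assert 1e-7 < w.pi < 1e-5


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

class TestFstComponents:
    def test_identical_populations_have_nonpositive_a(self):
        a, b, c = fst_site_components((10, 0.3, 0.0), (10, 0.3, 0.0))
        assert a <= 0

    def test_fixed_difference_is_one(self):
        a, b, c = fst_site_components((10, 1.0, 0.0), (10, 0.0, 0.0))
        assert a / (a + b + c) == pytest.approx(1.0, abs=1e-12)

    def test_inbred_strong_gap_exceeds_half(self):
        a, b, c = fst_site_components((20, 0.95, 0.0), (20, 0.05, 0.0))
        assert a / (a + b + c) > 0.5

    def test_matches_textbook_evaluation(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n1, n2 = rng.integers(2, 6, 2)
            p1, p2 = rng.random(2)
            h1 = rng.uniform(0, 2 * min(p1, 1 - p1))
            h2 = rng.uniform(0, 2 * min(p2, 1 - p2))
            got = fst_site_components((n1, p1, h1), (n2, p2, h2))
            exp = textbook_wc84(n1, p1, h1, n2, p2, h2)
            assert got == pytest.approx(exp, abs=1e-10)

    def test_too_small_population_raises(self):
        with pytest.raises(ValueError):
            fst_site_components((1, 0.5, 0.0), (5, 0.5, 0.0))


def _two_group_map(g, k):
    groups = {s: ("A" if i < k else "B") for i, s in enumerate(g.sample_ids)}
    return PopulationMap(group=groups)


class TestWindowedFst:
    def test_opposite_fixation_everywhere(self):
        g = random_panel(np.random.default_rng(4), 10, 20, missing_rate=0.0)
        g.dosage[:5, :] = 0
        g.dosage[5:, :] = 2
        pm = _two_group_map(g, 5)
        recs = windowed_fst(g, pm, "A", "B")
        assert recs
        assert all(r.fst_weighted == pytest.approx(1.0, abs=1e-12) for r in recs)

    def test_panmictic_split_near_zero(self):
        rng = np.random.default_rng(11)
        # one pool: same frequency law for everyone
        g = random_panel(rng, 40, 300, missing_rate=0.0)
        p = rng.uniform(0.2, 0.8, g.n_sites)
        g.dosage[:] = rng.binomial(2, p, (40, g.n_sites)).astype(np.int8)
        pm = _two_group_map(g, 20)
        recs = windowed_fst(g, pm, "A", "B", WindowSpec(size=10**9))
        mean_fst = np.mean([r.fst_weighted for r in recs])
        assert abs(mean_fst) < 0.02

    def test_invariant_to_relabeling_within_groups(self):
        rng = np.random.default_rng(12)
        g = random_panel(rng, 10, 30, missing_rate=0.05)
        pm = _two_group_map(g, 5)
        recs = windowed_fst(g, pm, "A", "B")
        shuffled = g.subset_samples(
            g.sample_ids[4::-1] + g.sample_ids[:4:-1]
        )
        recs2 = windowed_fst(shuffled, pm, "A", "B")
        for r1, r2 in zip(recs, recs2):
            assert r1.fst_weighted == pytest.approx(r2.fst_weighted, abs=1e-12)

    def test_invariant_to_allele_swap(self):
        rng = np.random.default_rng(13)
        g = random_panel(rng, 10, 30, missing_rate=0.05)
        pm = _two_group_map(g, 5)
        recs = windowed_fst(g, pm, "A", "B")
        swapped = g.subset_sites(np.ones(g.n_sites, bool))
        typed = swapped.dosage != MISSING
        swapped.dosage[typed] = 2 - swapped.dosage[typed]
        recs2 = windowed_fst(swapped, pm, "A", "B")
        for r1, r2 in zip(recs, recs2):
            assert r1.fst_weighted == pytest.approx(r2.fst_weighted, abs=1e-12)

    def test_small_group_raises(self):
        g = random_panel(np.random.default_rng(14), 4, 10)
        pm = _two_group_map(g, 1)
        with pytest.raises(ValueError):
            windowed_fst(g, pm, "A", "B")


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

class TestImputeMissing:
    def _panel(self, col):
        g = random_panel(np.random.default_rng(6), len(col), 3,
                         missing_rate=0.0)
        g.dosage[:, 0] = col
        return g

    def test_mode_fills_missing(self):
        g = self._panel([0, 0, MISSING])
        assert list(impute_missing(g).dosage[:, 0]) == [0, 0, 0]

    def test_identity_without_missing(self):
        g = random_panel(np.random.default_rng(8), 6, 20, missing_rate=0.0)
        assert np.array_equal(impute_missing(g).dosage, g.dosage)

    def test_tie_breaks_to_lower_dosage(self):
        g = self._panel([0, 2, MISSING])
        assert impute_missing(g).dosage[2, 0] == 0

    def test_all_missing_site_dropped(self):
        g = random_panel(np.random.default_rng(10), 4, 5, missing_rate=0.0)
        g.dosage[:, 2] = MISSING
        out = impute_missing(g)
        assert out.n_sites == 4
        assert g.pos[2] not in out.pos
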