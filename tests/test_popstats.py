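"""π, Weir–Cockerham F_ST and LD decay against independent oracles."""

import itertools

import numpy as np
import pytest

from curdscan import popstats
from curdscan.model import GenotypeMatrix, MISSING
from curdscan.popstats import LdBin

from conftest import build_matrix, two_group_assignment


# -------------------------------------------------------------------------
# independent oracles

def wc_oracle(calls_a, calls_b):
    """Scalar transcription of the Weir & Cockerham (1984) two-population
    variance components, written directly from the published equations."""
    def summarise(column):
        genotyped = [g for g in column if g != MISSING]
        n = len(genotyped)
        if n == 0:
            return None
        p = sum(genotyped) / (2.0 * n)  # alt-allele frequency
        h = sum(1 for g in genotyped if g == 1) / n  # observed het proportion
        return n, p, h

    s1, s2_ = summarise(calls_a), summarise(calls_b)
    if s1 is None or s2_ is None:
        return None
    (n1, p1, h1), (n2, p2, h2) = s1, s2_
    r = 2.0
    n_bar = (n1 + n2) / r
    if n_bar <= 1:
        return None
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    if p_bar == 0.0 or p_bar == 1.0:
        return None
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, a + b + c


def pi_oracle(calls, window_length):
    """Mean pairwise allele difference per bp, enumerating all allele pairs."""
    total = 0.0
    for j in range(calls.shape[1]):
        alleles = []
        for g in calls[:, j]:
            if g != MISSING:
                alleles.extend([1] * int(g) + [0] * (2 - int(g)))
        n = len(alleles)
        if n < 2:
            continue
        diffs = sum(x != y for x, y in itertools.combinations(alleles, 2))
        total += diffs / (n * (n - 1) / 2)
    return total / window_length


# -------------------------------------------------------------------------

class TestPi:
    def test_hand_value_two_samples(self):
        """0/0 and 1/1 at one site: term 2*2*2/(4*3) = 8/12 ≈ 0.667."""
        m = build_matrix([[0], [2]], positions=[50], contig_length=100_000)
        groups = two_group_assignment(m, 2)
        (w,) = popstats.pi_windows(m, groups, "A", 100_000)
        assert w.value == pytest.approx((8 / 12) / 100_000, rel=1e-12)
        assert w.n_sites == 1

    def test_monomorphic_window_zero(self):
        m = build_matrix([[0, 0], [0, 0]], contig_length=1000)
        groups = two_group_assignment(m, 2)
        (w,) = popstats.pi_windows(m, groups, "A", 1000)
        assert w.value == 0.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, size=(12, 50)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.1] = MISSING
        pos = np.sort(rng.choice(np.arange(1, 10_001), size=50, replace=False))
        m = build_matrix(calls, positions=pos.tolist(), contig_length=10_000)
        groups = two_group_assignment(m, 12)
        (w,) = popstats.pi_windows(m, groups, "A", 10_000)
        assert w.value == pytest.approx(pi_oracle(m.calls, 10_000), rel=1e-12)

    def test_ref_alt_swap_invariance(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        m1 = build_matrix(calls, contig_length=5000)
        swapped = np.where(calls == MISSING, MISSING, 2 - calls).astype(np.int8)
        m2 = build_matrix(swapped, contig_length=5000)
        g = two_group_assignment(m1, 8)
        assert popstats.mean_pi(m1, g, "A", 5000) == pytest.approx(
            popstats.mean_pi(m2, g, "A", 5000), rel=1e-12
        )

    def test_mean_pi_arithmetic(self):
        calls = np.zeros((4, 2), dtype=np.int8)
        calls[:2, 0] = 2  # site in window 1 polymorphic
        m = build_matrix(calls, positions=[500, 1500], contig_length=2000)
        g = two_group_assignment(m, 4)
        windows = popstats.pi_windows(m, g, "A", 1000)
        vals = [w.value for w in windows]
        assert popstats.mean_pi(m, g, "A", 1000) == pytest.approx(np.mean(vals))
        assert vals[1] == 0.0

    def test_requires_two_samples(self):
        m = build_matrix([[0, 1]])
        g = two_group_assignment(m, 1)
        with pytest.raises(ValueError):
            popstats.pi_windows(m, g, "A")


def _positions(rng, n, upper):
    return np.sort(rng.choice(np.arange(1, upper + 1), size=n, replace=False))


class TestFst:
    def test_complete_fixation(self):
        calls = np.array([[0]] * 10 + [[2]] * 10, dtype=np.int8)
        m = build_matrix(calls)
        g = two_group_assignment(m, 10)
        comp = popstats.fst_site(m, g, "A", "B", 0)
        assert comp.ratio == pytest.approx(1.0)

    def test_identical_groups_near_zero(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=50).astype(np.int8)
        calls = np.vstack([col[:, None], col[:, None]])
        m = build_matrix(calls)
        g = two_group_assignment(m, 50)
        comp = popstats.fst_site(m, g, "A", "B", 0)
        assert comp.ratio <= 0.05

    def test_monomorphic_site_skipped(self):
        m = build_matrix(np.zeros((12, 1), dtype=np.int8))
        g = two_group_assignment(m, 6)
        assert popstats.fst_site(m, g, "A", "B", 0) is None

    def test_matches_independent_transcription(self):
        """200 random 6+6-diploid sites agree with the equation
        transcription to 1e−12 relative."""
        rng = np.random.default_rng(42)
        calls = rng.integers(0, 3, size=(12, 200)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.08] = MISSING
        m = build_matrix(calls, positions=_positions(rng, 200, 10**6).tolist())
        g = two_group_assignment(m, 6)
        checked = 0
        for j in range(200):
            expected = wc_oracle(calls[:6, j], calls[6:, j])
            got = popstats.fst_site(m, g, "A", "B", j)
            if expected is None:
                assert got is None
                continue
            assert got.a == pytest.approx(expected[0], rel=1e-12, abs=1e-15)
            assert got.denominator == pytest.approx(expected[1], rel=1e-12, abs=1e-15)
            checked += 1
        assert checked > 100

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(12, 20)).astype(np.int8)
        m = build_matrix(calls)
        g = two_group_assignment(m, 6)
        for j in range(20):
            ab = popstats.fst_site(m, g, "A", "B", j)
            ba = popstats.fst_site(m, g, "B", "A", j)
            if ab is None:
                assert ba is None
            else:
                assert ab.ratio == pytest.approx(ba.ratio, rel=1e-12)

    def test_windowed_ratio_of_sums_oracle(self):
        """Sliding 10-kb/5-kb windows equal brute-force recomputation."""
        rng = np.random.default_rng(9)
        n_sites = 120
        pos = _positions(rng, n_sites, 50_000)
        calls = rng.integers(0, 3, size=(12, n_sites)).astype(np.int8)
        m = build_matrix(calls, positions=pos.tolist(), contig_length=50_000)
        g = two_group_assignment(m, 6)
        windows = popstats.fst_windows(m, g, "A", "B", 10_000, 5_000)
        for w in windows:
            num = den = 0.0
            n_used = 0
            for j in range(n_sites):
                if not (w.region.start <= pos[j] <= w.region.end):
                    continue
                comp = wc_oracle(calls[:6, j], calls[6:, j])
                if comp is None:
                    continue
                num += comp[0]
                den += comp[1]
                n_used += 1
            assert w.n_sites == n_used
            if n_used == 0 or den == 0:
                assert not w.defined
            else:
                assert w.value == pytest.approx(num / den, rel=1e-12)

    def test_window_split_merge_invariance(self):
        """Ratio-of-sums is unchanged by splitting sites into sub-lists and
        re-merging their components."""
        rng = np.random.default_rng(13)
        calls = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        m = build_matrix(calls, positions=(np.arange(40) * 10 + 1).tolist(),
                         contig_length=400)
        g = two_group_assignment(m, 6)
        (whole,) = [w for w in popstats.fst_windows(m, g, "A", "B", 400, 400)
                    if w.region.start == 1]
        num = den = 0.0
        for j in range(40):
            comp = popstats.fst_site(m, g, "A", "B", j)
            if comp is not None:
                num += comp.a
                den += comp.denominator
        assert whole.value == pytest.approx(num / den, rel=1e-12)

    def test_planted_block_recovery(self, sweep_cohort):
        """Mean windowed F_ST inside a planted gap-0.8 block exceeds the
        background by at least 0.3."""
        matrix, groups, config = sweep_cohort
        block = config.sweep_blocks[0]
        windows = popstats.fst_windows(
            matrix, groups, "Curdless", "WhiteCurd", 100_000, 10_000
        )
        inside = [w.value for w in windows if w.defined
                  and w.region.start >= block.start and w.region.end <= block.end]
        outside = [w.value for w in windows if w.defined
                   and (w.region.end < block.start or w.region.start > block.end)]
        assert np.mean(inside) - np.mean(outside) >= 0.3


class TestLd:
    def test_perfect_covariation(self):
        calls = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [2, 2]], dtype=np.int8)
        m = build_matrix(calls, positions=[100, 350], contig_length=1000)
        g = two_group_assignment(m, 5)
        bins = popstats.ld_decay(m, g, "A", max_dist=1000)
        (bin_250,) = [b for b in bins if b.n_pairs > 0]
        assert bin_250.lower == 200  # separation 250 falls in (200, 300]
        assert bin_250.mean_r2 == pytest.approx(1.0)
        assert bin_250.n_pairs == 1

    def test_dosage_flip_invariance(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
        m1 = build_matrix(calls, positions=[10, 40, 90, 160, 250, 360],
                          contig_length=1000)
        flipped = calls.copy()
        flipped[:, 2] = 2 - flipped[:, 2]
        m2 = build_matrix(flipped, positions=[10, 40, 90, 160, 250, 360],
                          contig_length=1000)
        g = two_group_assignment(m1, 10)
        b1 = popstats.ld_decay(m1, g, "A", max_dist=1000)
        b2 = popstats.ld_decay(m2, g, "A", max_dist=1000)
        for x, y in zip(b1, b2):
            if x.n_pairs:
                assert x.mean_r2 == pytest.approx(y.mean_r2, rel=1e-12)

    def test_independent_sites_low_r2(self):
        """With 2,000 samples, r² between independent sites is tiny."""
        rng = np.random.default_rng(7)
        calls = rng.binomial(2, 0.5, size=(2000, 2)).astype(np.int8)
        m = build_matrix(calls, positions=[100, 200], contig_length=1000)
        g = two_group_assignment(m, 2000)
        bins = popstats.ld_decay(m, g, "A", max_dist=1000)
        (occupied,) = [b for b in bins if b.n_pairs > 0]
        assert occupied.mean_r2 < 0.01


class TestHalfDecay:
    def test_exact_hit(self):
        bins = [LdBin(0, 0.8, 10), LdBin(100, 0.4, 10)]
        assert popstats.half_decay_distance(bins) == pytest.approx(150.0)

    def test_constant_curve_undefined(self):
        bins = [LdBin(i * 100, 0.5, 5) for i in range(10)]
        assert np.isnan(popstats.half_decay_distance(bins))

    def test_all_empty_raises(self):
        with pytest.raises(ValueError):
            popstats.half_decay_distance([LdBin(0, float("nan"), 0)])

    def test_exponential_curve_recovers_tau_ln2(self):
        """m(d) = 0.8·e^(−d/τ) sampled per bin: the crossing point sits at
        τ·ln2 from the maximum, within one bin width."""
        tau = 20_000.0
        bins = [
            LdBin(i * 100, 0.8 * np.exp(-(i * 100 + 50) / tau), 100)
            for i in range(1000)
        ]
        d = popstats.half_decay_distance(bins)
        assert abs(d - (50 + tau * np.log(2))) <= 100
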