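"""Weir-Cockerham F_ST, Z-scores, region calling and overlap rates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feralscan import (
    IntervalSet,
    call_candidate_regions,
    fst_windows,
    overlap_rate,
    wc_fst_site,
    z_transform,
)
from feralscan.diversity import SiteFreqs

from conftest import make_gm


def wc_oracle_from_genotypes(genos_a, genos_b):
    """Literal scalar transcription of the two-population Weir-Cockerham
    (1984) variance components, computed directly from genotype lists.

    Kept deliberately naive and separate from the vectorised
    implementation: counts alleles and heterozygotes itself, then
    evaluates n_bar, n_c, p_bar, s^2 and h_bar exactly as published.
    """
    r = 2
    pops = [list(genos_a), list(genos_b)]
    n = [len(g) for g in pops]  # called diploids
    p = [sum(g) / (2 * len(g)) for g in pops]  # alt allele frequency
    h = [sum(1 for x in g if x == 1) / len(g) for g in pops]  # het fraction
    n_bar = sum(n) / r
    n_c = (r * n_bar - sum(ni * ni for ni in n) / (r * n_bar)) / (r - 1)
    p_bar = sum(ni * pi for ni, pi in zip(n, p)) / (r * n_bar)
    s2 = sum(ni * (pi - p_bar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * n_bar)
    h_bar = sum(ni * hi for ni, hi in zip(n, h)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def freqs_from_genotypes(genos):
    g = np.asarray(genos)[:, None]
    called = (g >= 0).sum(axis=0)
    return SiteFreqs(
        n_hap=2 * called,
        alt_count=np.where(g >= 0, g, 0).sum(axis=0),
        alt_freq=np.where(g >= 0, g, 0).sum(axis=0) / (2 * called),
        het_count=(g == 1).sum(axis=0),
    )


class TestWcFstSite:
    def test_fixed_difference(self):
        """Opposite fixation in two pops of 10: a=0.5, b=c=0, theta=1."""
        fa = freqs_from_genotypes([2] * 10)
        fb = freqs_from_genotypes([0] * 10)
        a, b, c = wc_fst_site(fa, fb)
        assert a[0] == pytest.approx(0.5, abs=1e-12)
        assert b[0] == pytest.approx(0.0, abs=1e-12)
        assert c[0] == pytest.approx(0.0, abs=1e-12)
        assert a[0] / (a + b + c)[0] == pytest.approx(1.0)

    def test_all_heterozygotes(self):
        """Both pops entirely heterozygous: a=0, theta=0 with denominator 0.25."""
        fa = freqs_from_genotypes([1] * 8)
        fb = freqs_from_genotypes([1] * 8)
        a, b, c = wc_fst_site(fa, fb)
        assert a[0] == pytest.approx(0.0, abs=1e-12)
        assert (a + b + c)[0] == pytest.approx(0.25, abs=1e-12)

    def test_same_allele_fixed_in_both(self):
        fa = freqs_from_genotypes([0] * 5)
        fb = freqs_from_genotypes([0] * 6)
        a, b, c = wc_fst_site(fa, fb)
        assert (a[0], b[0], c[0]) == (0.0, 0.0, 0.0)

    def test_matches_oracle_on_random_sites(self):
        """Vectorised components equal the literal transcription to 1e-12
        on 10,000 random small sites."""
        rng = np.random.default_rng(1984)
        for _ in range(10_000):
            nA, nB = rng.integers(2, 11, size=2)
            ga = rng.integers(0, 3, size=nA)
            gb = rng.integers(0, 3, size=nB)
            a_o, b_o, c_o = wc_oracle_from_genotypes(ga, gb)
            a, b, c = wc_fst_site(freqs_from_genotypes(ga), freqs_from_genotypes(gb))
            assert abs(a[0] - a_o) < 1e-12
            assert abs(b[0] - b_o) < 1e-12
            assert abs(c[0] - c_o) < 1e-12

    @given(st.data())
    @settings(derandomize=True, max_examples=50)
    def test_symmetry_and_relabelling(self, data):
        """theta is symmetric in population order and invariant to
        swapping which allele is called ref."""
        ga = data.draw(st.lists(st.integers(0, 2), min_size=2, max_size=8))
        gb = data.draw(st.lists(st.integers(0, 2), min_size=2, max_size=8))
        fa, fb = freqs_from_genotypes(ga), freqs_from_genotypes(gb)
        fa2 = freqs_from_genotypes([2 - g for g in ga])
        fb2 = freqs_from_genotypes([2 - g for g in gb])

        def theta(x, y):
            a, b, c = wc_fst_site(x, y)
            d = (a + b + c)[0]
            return a[0] / d if d != 0 else np.nan

        t = theta(fa, fb)
        np.testing.assert_allclose(t, theta(fb, fa), atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(t, theta(fa2, fb2), atol=1e-12, equal_nan=True)


class TestFstWindows:
    def test_single_fixed_difference_window(self):
        calls = np.array([[2, 2], [2, 2], [0, 0], [0, 0]], dtype=np.int8)
        G = make_gm(calls, pos=[100, 200])
        tab = fst_windows(
            G, ["s00", "s01"], ["s02", "s03"], window=1000, step=1000,
            min_sites=1, chrom_lengths={"chr1": 1000},
        )
        assert tab["fst"][0] == pytest.approx(1.0)

    def test_ratio_of_sums_not_mean_of_ratios(self):
        """A window mixing a fixed-difference site (theta=1) and an
        all-heterozygote site (theta=0) gives sum(a)/sum(a+b+c) =
        0.5/0.75, not the mean of per-site ratios."""
        calls = np.array(
            [[2, 1], [2, 1], [2, 1], [2, 1], [2, 1],
             [0, 1], [0, 1], [0, 1], [0, 1], [0, 1]],
            dtype=np.int8,
        )
        G = make_gm(calls, pos=[100, 200])
        popA = [f"s{i:02d}" for i in range(5)]
        popB = [f"s{i:02d}" for i in range(5, 10)]
        tab = fst_windows(G, popA, popB, window=1000, step=1000,
                          min_sites=1, chrom_lengths={"chr1": 1000})
        assert tab["fst"][0] == pytest.approx(0.5 / 0.75)
        assert tab["fst"][0] != pytest.approx(0.5)

    def test_overlapping_populations_rejected(self):
        G = make_gm(np.zeros((4, 3), dtype=np.int8))
        with pytest.raises(ValueError, match="overlap"):
            fst_windows(G, ["s00", "s01"], ["s01", "s02"])

    def test_min_sites_masks_sparse_windows(self):
        calls = np.array([[2, 2], [2, 2], [0, 0], [0, 0]], dtype=np.int8)
        G = make_gm(calls, pos=[100, 200])
        tab = fst_windows(G, ["s00", "s01"], ["s02", "s03"], window=1000,
                          step=1000, min_sites=5, chrom_lengths={"chr1": 1000})
        assert np.isnan(tab["fst"][0])

    def test_panmictic_split_gives_near_zero_fst(self):
        """Two halves of one panmictic population: mean window F_ST ~ 0."""
        rng = np.random.default_rng(99)
        p = rng.uniform(0.1, 0.9, size=1000)
        calls = rng.binomial(2, p, size=(40, 1000)).astype(np.int8)
        G = make_gm(calls, pos=np.arange(1, 1001) * 100)
        half = [f"s{i:02d}" for i in range(20)]
        other = [f"s{i:02d}" for i in range(20, 40)]
        tab = fst_windows(G, half, other, window=100_000, step=100_000)
        assert abs(np.nanmean(tab["fst"])) < 0.02


class TestZTransform:
    def test_hand_computed(self):
        z = z_transform(np.array([0.0, 0.0, 0.0, 4.0]))
        np.testing.assert_allclose(
            z, [-1 / np.sqrt(3)] * 3 + [3 / np.sqrt(3)], atol=1e-12
        )

    def test_mean_maps_to_zero_and_affine_invariance(self):
        x = np.array([1.0, 2.0, 3.0, 6.0])  # mean is 3
        z = z_transform(x)
        assert z[2] == pytest.approx(0.0, abs=1e-15)
        np.testing.assert_allclose(z_transform(3 * x + 7), z, atol=1e-12)

    def test_nan_passthrough(self):
        z = z_transform(np.array([1.0, np.nan, 3.0]))
        assert np.isnan(z[1]) and np.isfinite(z[[0, 2]]).all()

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero spread"):
            z_transform(np.array([2.0, 2.0, 2.0]))
        with pytest.raises(ValueError):
            z_transform(np.array([1.0]))


class TestCandidateRegions:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "z_fst"])

    def test_merges_overlapping_windows(self):
        t = self._table([("chr1", 0, 100_000, 4.0), ("chr1", 10_000, 110_000, 3.5)])
        regions = call_candidate_regions(t, z_threshold=3.0)
        assert regions.regions[["start", "end"]].values.tolist() == [[0, 110_000]]
        assert regions.regions["peak_z"][0] == 4.0
        assert regions.regions["n_windows"][0] == 2

    def test_no_significant_windows(self):
        t = self._table([("chr1", 0, 100_000, 1.0)])
        assert len(call_candidate_regions(t, z_threshold=3.0)) == 0

    def test_threshold_is_strict(self):
        t = self._table([("chr1", 0, 100_000, 3.0)])
        assert len(call_candidate_regions(t, z_threshold=3.0)) == 0


class TestOverlapRate:
    def test_partial_overlap(self):
        # candidates cover 200 bp; [50,250) intersects [0,100) in 50 bp
        # and [200,300) in 50 bp -> 100/200 = 50%
        cand = IntervalSet.from_tuples([("chr1", 0, 100), ("chr1", 200, 300)])
        dom = IntervalSet.from_tuples([("chr1", 50, 250)])
        assert overlap_rate(cand, dom) == pytest.approx(50.0)

    def test_disjoint_and_subset(self):
        cand = IntervalSet.from_tuples([("chr1", 0, 100)])
        assert overlap_rate(cand, IntervalSet.from_tuples([("chr2", 0, 50)])) == 0.0
        assert overlap_rate(cand, IntervalSet.from_tuples([("chr1", 0, 1000)])) == 100.0

    def test_empty_candidates(self):
        assert overlap_rate(IntervalSet(), IntervalSet.from_tuples([("chr1", 0, 9)])) == 0.0

    @given(
        st.lists(st.tuples(st.integers(0, 50), st.integers(1, 20)), min_size=1, max_size=8),
        st.lists(st.tuples(st.integers(0, 50), st.integers(1, 20)), min_size=1, max_size=8),
        st.tuples(st.integers(0, 50), st.integers(1, 20)),
    )
    @settings(derandomize=True, max_examples=60)
    def test_bounded_and_monotone_in_domestication(self, cand, dom, extra):
        """Rate is within [0, 100] and never decreases as the
        domestication set grows by union."""
        c = IntervalSet.from_tuples(("chr1", s, s + w) for s, w in cand)
        d = IntervalSet.from_tuples(("chr1", s, s + w) for s, w in dom)
        d_plus = d.union(IntervalSet.from_tuples([("chr1", extra[0], extra[0] + extra[1])]))
        r, r_plus = overlap_rate(c, d), overlap_rate(c, d_plus)
        assert 0.0 <= r <= 100.0
        assert r_plus >= r - 1e-9


def test_window_overlap_rate_counts_windows():
    from feralscan.scan import window_overlap_rate

    table = pd.DataFrame(
        [
            ("chr1", 0, 100_000, 4.0),
            ("chr1", 500_000, 600_000, 5.0),
            ("chr1", 900_000, 1_000_000, 1.0),  # not significant
        ],
        columns=["chrom", "start", "end", "z_fst"],
    )
    dom = IntervalSet.from_tuples([("chr1", 50_000, 80_000)])
    # one of the two significant windows touches a domestication region
    assert window_overlap_rate(table, dom, z_threshold=3.0) == 50.0
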