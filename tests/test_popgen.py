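"""Window geometry, nucleotide diversity, and the Weir-Cockerham FST
estimator against independent scalar oracles."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from invasweep import (WindowSpec, compare_distributions, fst_components,
                       make_windows, median_stat, site_pi, windowed_fst,
                       windowed_pi)
from invasweep.popgen import pop_site_stats

from conftest import make_gm


class TestMakeWindows:
    def test_stated_convention(self):
        spec = WindowSpec(5000, 2500, {"c": 12500})
        w = make_windows(spec, "c")
        assert w.tolist() == [[0, 5000], [2500, 7500], [5000, 10000],
                              [7500, 12500], [10000, 12500]]

    def test_short_chromosome_single_window(self):
        assert make_windows(WindowSpec(5000, 2500, {"c": 4000}), "c").tolist() \
            == [[0, 4000], [2500, 4000]]

    def test_zero_length_empty(self):
        assert len(make_windows(WindowSpec(5000, 2500, {"c": 0}), "c")) == 0

    def test_unknown_chrom_raises(self):
        with pytest.raises(KeyError):
            make_windows(WindowSpec(5000, 2500, {}), "c")


class TestSitePi:
    @pytest.mark.parametrize("j,n,expected", [
        (2, 4, 2 / 3), (0, 4, 0.0), (1, 2, 1.0), (3, 6, 0.6)])
    def test_formula(self, j, n, expected):
        assert site_pi(j, n) == pytest.approx(expected)

    def test_maximal_at_half(self):
        n = 20
        vals = [site_pi(j, n) for j in range(n + 1)]
        assert np.argmax(vals) == n // 2

    def test_undefined_below_two_copies(self):
        with pytest.raises(ValueError):
            site_pi(0, 1)


class TestWindowedPi:
    def test_single_site_example(self):
        # one het in one diploid: j=1, n=2 -> site pi 1.0; span 5000
        gm = make_gm(np.array([[1]], dtype=np.int8), pos=[100])
        spec = WindowSpec(5000, 5000, {"chr1": 5000})
        out = windowed_pi(gm, np.array([0]), spec)
        assert out.pi.iloc[0] == pytest.approx(1 / 5000)

    def test_empty_window_flagged(self):
        gm = make_gm(np.array([[1]], dtype=np.int8), pos=[100])
        spec = WindowSpec(5000, 5000, {"chr1": 10000})
        out = windowed_pi(gm, np.array([0]), spec)
        assert out.n_variants.tolist() == [1, 0]
        assert np.isnan(out.pi.iloc[1])

    def test_denominator_is_window_span(self):
        gm = make_gm(np.array([[1]], dtype=np.int8), pos=[100])
        wide = windowed_pi(gm, np.array([0]),
                           WindowSpec(10000, 10000, {"chr1": 10000}))
        narrow = windowed_pi(gm, np.array([0]),
                             WindowSpec(5000, 5000, {"chr1": 5000}))
        assert wide.pi.iloc[0] == pytest.approx(narrow.pi.iloc[0] / 2)

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.choice(5000, 50, replace=False)) + 1
        gm = make_gm(rng.integers(0, 3, (50, 6)).astype(np.int8), pos=pos)
        spec = WindowSpec(5000, 2500, {"chr1": 5000})
        a = windowed_pi(gm, np.array([0, 1, 2, 3]), spec)
        b = windowed_pi(gm, np.array([3, 1, 0, 2]), spec)
        np.testing.assert_allclose(a.pi, b.pi)


class TestFstComponents:
    def test_fixed_difference(self):
        a, b, c = fst_components(4, 0.0, 0.0, 4, 1.0, 0.0)
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_derived_het_example(self):
        a, b, c = fst_components(4, 0.5, 0.5, 4, 0.5, 0.5)
        assert a == pytest.approx(-1 / 24)
        assert b == pytest.approx(1 / 24)
        assert c == pytest.approx(1 / 4)
        assert a / (a + b + c) == pytest.approx(-1 / 6)

    def test_population_exchange_symmetry(self):
        x = fst_components(6, 0.3, 0.2, 4, 0.7, 0.4)
        y = fst_components(4, 0.7, 0.4, 6, 0.3, 0.2)
        assert x == pytest.approx(y)

    def test_unusable_site_raises(self):
        with pytest.raises(ValueError):
            fst_components(0, 0.0, 0.0, 4, 0.5, 0.5)
        with pytest.raises(ValueError):
            fst_components(1, 0.0, 0.0, 1, 1.0, 0.0)


class TestWindowedFst:
    def test_all_fixed_differences_give_one(self):
        d = np.zeros((10, 8), dtype=np.int8)
        d[:, 4:] = 2
        gm = make_gm(d)
        spec = WindowSpec(5000, 5000, {"chr1": 5000})
        out = windowed_fst(gm, np.arange(4), np.arange(4, 8), spec)
        assert out.fst.iloc[0] == pytest.approx(1.0)

    def test_single_site_window_matches_scalar(self):
        # each population: 1 hom-ref, 2 hets, 1 hom-alt -> p=0.5, h=0.5
        d = np.array([[0, 1, 1, 2, 0, 1, 1, 2]], dtype=np.int8)
        gm = make_gm(d)
        spec = WindowSpec(5000, 5000, {"chr1": 5000})
        out = windowed_fst(gm, np.arange(4), np.arange(4, 8), spec)
        assert out.fst.iloc[0] == pytest.approx(-1 / 6)

    def test_site_order_within_window_irrelevant(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (40, 10)).astype(np.int8)
        gm1 = make_gm(d, pos=np.arange(1, 41))
        gm2 = make_gm(d[::-1], pos=np.arange(1, 41))
        spec = WindowSpec(5000, 5000, {"chr1": 5000})
        f1 = windowed_fst(gm1, np.arange(5), np.arange(5, 10), spec)
        f2 = windowed_fst(gm2, np.arange(5), np.arange(5, 10), spec)
        assert f1.fst.iloc[0] == pytest.approx(f2.fst.iloc[0])

    @given(st.integers(0, 200))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_window_value_equals_scalar_component_oracle(self, seed):
        """Ratio-of-sums window FST must equal the per-site scalar
        implementation summed by hand (independent path, with missingness)."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 25))
        d = rng.integers(-1, 3, (m, 9)).astype(np.int8)
        gm = make_gm(d, pos=np.arange(1, m + 1))
        idx_a, idx_b = np.arange(4), np.arange(4, 9)
        spec = WindowSpec(5000, 5000, {"chr1": 5000})
        out = windowed_fst(gm, idx_a, idx_b, spec)

        n1, p1, h1 = pop_site_stats(gm, idx_a)
        n2, p2, h2 = pop_site_stats(gm, idx_b)
        num = den = 0.0
        usable = 0
        for i in range(m):
            try:
                a, b, c = fst_components(n1[i], p1[i], h1[i],
                                         n2[i], p2[i], h2[i])
            except ValueError:
                continue
            num += a
            den += a + b + c
            usable += 1
        if usable == 0 or den <= 0:
            assert np.isnan(out.fst.iloc[0])
        else:
            assert out.fst.iloc[0] == pytest.approx(num / den)


class TestMedianAndRankSum:
    def test_median(self):
        assert median_stat([0.1, 0.2, 0.3]) == pytest.approx(0.2)
        assert median_stat([0.1, 0.3]) == pytest.approx(0.2)
        assert median_stat([0.7]) == 0.7
        with pytest.raises(ValueError):
            median_stat([np.nan])

    def test_identical_samples_p_near_one(self):
        _, p = compare_distributions([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p > 0.9

    def test_complete_separation_minimal_p(self):
        u, p = compare_distributions(np.arange(1, 11), np.arange(11, 21))
        assert u == 0.0
        assert p < 1e-3

    def test_exact_enumeration_n3(self):
        """p-values at nA=nB=3 match enumeration over all 20 rank splits."""
        a, b = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0]
        ranks = {1.0: 1, 2.0: 2, 3.0: 3, 4.0: 4, 5.0: 5, 6.0: 6}
        obs_r = sum(ranks[x] for x in a)
        all_r = [sum(c) for c in itertools.combinations(range(1, 7), 3)]
        # two-sided: as or more extreme rank sums under the null
        mu = np.mean(all_r)
        p_exact = np.mean([abs(r - mu) >= abs(obs_r - mu) - 1e-12
                           for r in all_r])
        _, p = compare_distributions(a, b)
        assert p == pytest.approx(p_exact)
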