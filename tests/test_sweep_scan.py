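"""sweep_scan: per-site and windowed statistics, standardization, regions."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ovisweep import sweep_scan as ss
from ovisweep.io_formats import GeneInterval, PooledSiteFrequency


def site(pos, pa, pb, chrom="17"):
    return PooledSiteFrequency(chrom, pos, pa, pb, 60, 118)


freqs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestSiteStatistics:
    @pytest.mark.parametrize(
        "pa,pb,expected",
        [(0.3, 0.3, 0.0), (1.0, 0.0, 1.0), (0.9, 0.1, 0.64)],
    )
    def test_site_fst_values(self, pa, pb, expected):
        assert ss.site_fst(site(1, pa, pb)) == pytest.approx(expected, abs=1e-12)

    def test_site_fst_monomorphic_defined_as_zero(self):
        assert ss.site_fst(site(1, 0.0, 0.0)) == 0.0
        assert ss.site_fst(site(1, 1.0, 1.0)) == 0.0

    @pytest.mark.parametrize(
        "pa,pb,expected", [(0.5, 0.5, 0.0), (1.0, 0.0, 1.0), (0.33, 0.76, 0.43)]
    )
    def test_delta_af(self, pa, pb, expected):
        assert ss.delta_af(site(1, pa, pb)) == pytest.approx(expected, abs=1e-12)

    @given(freqs, freqs)
    def test_group_swap_symmetry(self, pa, pb):
        assert ss.site_fst(site(1, pa, pb)) == pytest.approx(ss.site_fst(site(1, pb, pa)))
        assert ss.delta_af(site(1, pa, pb)) == ss.delta_af(site(1, pb, pa))

    @given(freqs, freqs)
    def test_ref_alt_relabel_invariance(self, pa, pb):
        flipped = site(1, 1.0 - pa, 1.0 - pb)
        assert ss.site_fst(site(1, pa, pb)) == pytest.approx(ss.site_fst(flipped), abs=1e-12)
        assert ss.delta_af(site(1, pa, pb)) == pytest.approx(ss.delta_af(flipped), abs=1e-12)


class TestWindowFst:
    def test_no_differentiation_gives_zero_everywhere(self, rng):
        sites = [site(int(p), 0.4, 0.4) for p in np.sort(rng.choice(200_000, 50, replace=False)) + 1]
        for w in ss.window_fst(sites):
            if w.x is not None:
                assert w.x == 0.0

    def test_single_site_window_reduces_to_site_fst(self):
        sites = [site(10_000, 0.9, 0.1)]
        windows = ss.window_fst(sites, min_sites=1)
        defined = [w for w in windows if w.x is not None]
        assert defined and all(w.x == pytest.approx(0.64) for w in defined)

    def test_empty_input_gives_empty_output(self):
        assert ss.window_fst([]) == []

    def test_sparse_windows_undefined(self, rng):
        sites = [site(1, 0.9, 0.1), site(2, 0.8, 0.2)]  # 2 < min_sites=3
        assert all(w.x is None for w in ss.window_fst(sites))

    def test_matches_brute_force_interval_oracle(self, rng):
        """Ratio-of-sums per window equals an independent per-window recount."""
        pos = np.sort(rng.choice(1_000_000, size=500, replace=False)) + 1
        sites = [site(int(p), float(rng.random()), float(rng.random())) for p in pos]
        windows = ss.window_fst(sites, window_size=50_000, step=25_000, min_sites=3)
        for w in windows:
            members = [s for s in sites if w.start <= s.pos <= w.end]
            assert w.n_sites == len(members)
            if len(members) < 3:
                assert w.x is None
                continue
            num = sum(ss._fst_components(s.p_ref_a, s.p_ref_b)[0] for s in members)
            den = sum(ss._fst_components(s.p_ref_a, s.p_ref_b)[1] for s in members)
            assert w.x == pytest.approx(num / den, abs=1e-12)

    def test_interior_site_hits_window_per_step(self, rng):
        """Every interior site falls in exactly window_size/step windows."""
        pos = np.sort(rng.choice(500_000, size=200, replace=False)) + 100_000
        sites = [site(int(p), 0.5, 0.5) for p in pos]
        windows = ss.window_fst(sites, window_size=50_000, step=25_000, min_sites=1)
        last = max(p for p in pos)
        for s in sites:
            hits = sum(1 for w in windows if w.start <= s.pos <= w.end)
            if s.pos <= last - 50_000:  # interior: full window span available
                assert hits == 2

    def test_window_size_must_be_multiple_of_step(self):
        with pytest.raises(ValueError, match="multiple"):
            ss.window_fst([site(1, 0.5, 0.5)], window_size=50_000, step=30_000)


class TestPooledHeterozygosity:
    def test_all_half_frequencies_give_h_half(self):
        sites = [site(i * 1000 + 1, 0.5, 0.2) for i in range(10)]
        for w in ss.pooled_heterozygosity(sites, group="a"):
            if w.x is not None:
                assert w.x == pytest.approx(0.5)

    def test_fixed_sites_give_zero(self):
        sites = [site(i * 1000 + 1, 1.0, 0.5) for i in range(10)]
        for w in ss.pooled_heterozygosity(sites, group="a"):
            if w.x is not None:
                assert w.x == 0.0

    def test_direct_formula_evaluation(self):
        # major frequencies 0.9 and 0.6: H = 2*1.5*0.5/4 = 0.375
        sites = [site(100, 0.9, 0.5), site(200, 0.6, 0.5)]
        windows = ss.pooled_heterozygosity(sites, group="a", window_size=20_000, step=10_000)
        assert windows[0].x == pytest.approx(0.375, abs=1e-12)

    def test_minor_allele_assignment_is_per_site(self):
        # p_ref 0.1 has major frequency 0.9, same H as p_ref 0.9
        a = ss.pooled_heterozygosity([site(100, 0.9, 0.5), site(200, 0.6, 0.5)], group="a")
        b = ss.pooled_heterozygosity([site(100, 0.1, 0.5), site(200, 0.4, 0.5)], group="a")
        assert a[0].x == pytest.approx(b[0].x, abs=1e-12)

    def test_group_selector(self):
        sites = [site(100, 0.9, 0.6), site(200, 0.9, 0.6)]
        ha = ss.pooled_heterozygosity(sites, group="a")[0].x
        hb = ss.pooled_heterozygosity(sites, group="b")[0].x
        assert ha == pytest.approx(2 * 1.8 * 0.2 / 4.0)
        assert hb == pytest.approx(2 * 1.2 * 0.8 / 4.0)


class TestZStandardize:
    def test_hand_computation_with_population_sd(self):
        windows = [
            ss.WindowStat("17", 1, 100, 5, x=1.0),
            ss.WindowStat("17", 101, 200, 5, x=3.0),
        ]
        zs = [w.z for w in ss.z_standardize(windows)]
        assert zs == pytest.approx([1.0, 1.0])

    def test_degenerate_sd_warns_and_zeroes(self):
        windows = [ss.WindowStat("17", 1, 100, 5, x=0.2)] * 3
        with pytest.warns(UserWarning, match="identical"):
            out = ss.z_standardize(windows)
        assert all(w.z == 0.0 for w in out)

    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=20), st.floats(-5, 5))
    def test_location_invariance(self, xs, shift):
        if np.std(xs) == 0:
            return
        w1 = [ss.WindowStat("17", i, i + 9, 5, x=x) for i, x in enumerate(xs)]
        w2 = [ss.WindowStat("17", i, i + 9, 5, x=x + shift) for i, x in enumerate(xs)]
        z1 = [w.z for w in ss.z_standardize(w1)]
        z2 = [w.z for w in ss.z_standardize(w2)]
        assert z1 == pytest.approx(z2, rel=1e-9, abs=1e-9)

    def test_undefined_windows_excluded_from_moments(self):
        windows = [
            ss.WindowStat("17", 1, 100, 5, x=1.0),
            ss.WindowStat("17", 101, 200, 0, x=None),
            ss.WindowStat("17", 201, 300, 5, x=3.0),
        ]
        out = ss.z_standardize(windows)
        assert out[1].z is None
        assert [out[0].z, out[2].z] == pytest.approx([1.0, 1.0])


def wstat(start, z, x=1.0, chrom="17"):
    return ss.WindowStat(chrom, start, start + 49_999, 10, x=x, z=z)


class TestCallRegions:
    def test_nothing_significant_gives_empty_list(self):
        windows = [wstat(1, 0.5), wstat(25_001, 1.0)]
        assert ss.call_regions(windows, z_threshold=5.0) == []

    def test_overlapping_windows_merge(self):
        windows = [wstat(1, 6.0, x=2.0), wstat(25_001, 7.0, x=2.0), wstat(75_001, 0.1, x=0.1)]
        regions = ss.call_regions(windows, z_threshold=5.0)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end, r.peak_z, r.n_windows) == (1, 75_000, 7.0, 2)

    def test_above_mean_restriction_drops_low_divergence_outliers(self):
        # one window far BELOW the mean also has a large |z|
        windows = [wstat(1 + i * 50_000, 0.0, x=0.5) for i in range(20)]
        windows.append(wstat(10_000_001, 6.0, x=0.0))
        assert ss.call_regions(windows, z_threshold=5.0, require_above_mean=True) == []
        low = ss.call_regions(windows, z_threshold=5.0, require_above_mean=False)
        assert len(low) == 1

    def test_chromosomes_never_merge(self):
        windows = [wstat(1, 6.0, x=2.0, chrom="17"), wstat(1, 6.0, x=2.0, chrom="18")]
        windows += [wstat(100_001 + i * 50_000, 0.1, x=0.1) for i in range(5)]
        assert len(ss.call_regions(windows, z_threshold=5.0)) == 2

    def test_matches_connected_components_oracle(self, rng):
        """Region spans equal a brute-force connected-components pass."""
        import networkx as nx

        zs = rng.exponential(2.0, size=80)
        windows = [wstat(1 + i * 25_000, float(z), x=float(z)) for i, z in enumerate(zs)]
        regions = ss.call_regions(windows, z_threshold=4.0, require_above_mean=False)

        sig = [w for w in windows if w.z > 4.0]
        g = nx.Graph()
        g.add_nodes_from(range(len(sig)))
        for i, a in enumerate(sig):
            for j, b in enumerate(sig):
                if i < j and a.start <= b.end + 1 and b.start <= a.end + 1:
                    g.add_edge(i, j)
        comps = [
            (min(sig[i].start for i in c), max(sig[i].end for i in c))
            for c in nx.connected_components(g)
        ]
        assert sorted((r.start, r.end) for r in regions) == sorted(comps)


class TestAnnotateRegions:
    def region(self, start, end):
        return ss.SweepRegion("17", start, end, 6.0, 2)

    def test_gene_inside_region_listed(self):
        genes = [GeneInterval("17", 150, 160, "HIRA")]
        (r,) = ss.annotate_regions([self.region(100, 200)], genes)
        assert r.genes == ("HIRA",)

    def test_gene_ending_before_region_not_listed(self):
        genes = [GeneInterval("17", 50, 99, "X")]
        (r,) = ss.annotate_regions([self.region(100, 200)], genes)
        assert r.genes == ()

    def test_single_bp_overlap_counts(self):
        genes = [GeneInterval("17", 50, 100, "X"), GeneInterval("17", 200, 300, "Y")]
        (r,) = ss.annotate_regions([self.region(100, 200)], genes)
        assert set(r.genes) == {"X", "Y"}

    def test_matches_quadratic_all_pairs_oracle(self, rng):
        genes = [
            GeneInterval("17", int(s), int(s) + int(l), f"g{i}")
            for i, (s, l) in enumerate(
                zip(rng.integers(1, 900_000, 100), rng.integers(1, 30_000, 100))
            )
        ]
        regions = [
            ss.SweepRegion("17", int(s), int(s) + 50_000, 6.0, 2)
            for s in rng.integers(1, 900_000, 30)
        ]
        annotated = ss.annotate_regions(regions, genes)
        for r, out in zip(regions, annotated):
            expected = {g.name for g in genes if g.start <= r.end and g.end >= r.start}
            assert set(out.genes) == expected
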