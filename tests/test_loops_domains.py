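"""Donut loop caller, insulation boundaries, ADA rescaling, anchor stats."""

import numpy as np
import pandas as pd
import pytest

from carloops import genome_model as gm
from carloops import residency as rs
from carloops import contacts as ct
from carloops import loops_domains as ld
from carloops.errors import AnalysisError


def planted_chain(n_cars=26, spacing=9_000, seed=1, noise=False):
    """Occupancy-1 chain whose adjacent loops are the planted truth."""
    pos = 20_000 + spacing * np.arange(n_cars)
    m = gm.CARMap("chrS", pos[-1] + 20_000, pos, np.ones(n_cars))
    pop = rs.simulate_population(m, 10, seed=seed)
    params = ct.RenderParams(total_reads=2e7, noise=noise, seed=seed)
    return m, ct.render_map(pop, m, params, bin_size=200)


class TestCallLoops:
    def test_background_only_map_yields_no_calls(self):
        m = gm.CARMap("chrS", 400_000, np.empty(0, dtype=int), np.empty(0))
        z = np.empty(0, dtype=np.int64)
        pop = rs.PopulationLoops(z, z, np.empty(0), n_cells=10)
        mat = ct.render_map(pop, m, ct.RenderParams(total_reads=1e7, seed=3),
                            bin_size=200)
        calls = ld.call_loops(mat)
        assert calls.n_loops <= 1  # BH at FDR 0.1 over the band: ~no speckle

    def test_planted_loops_recovered_perfectly_noise_free(self):
        m, mat = planted_chain()
        calls = ld.call_loops(mat)
        truth = {(int(a // 200), int(b // 200))
                 for a, b in zip(m.car_positions[:-1], m.car_positions[1:])}
        got = list(zip(calls.table["bin_i"], calls.table["bin_j"]))
        assert len(got) == len(truth) == 25

        def near(p, pool):
            return any(abs(p[0] - q[0]) <= 1 and abs(p[1] - q[1]) <= 1
                       for q in pool)
        assert all(near(c, truth) for c in got)     # precision 1
        assert all(near(t, got) for t in truth)     # recall 1

    def test_loop_below_min_dist_not_called(self):
        pos = np.array([50_000, 53_000])  # 3 kb apart, below min_dist 5 kb
        m = gm.CARMap("chrS", 200_000, pos, np.ones(2))
        pop = rs.simulate_population(m, 10, seed=1)
        mat = ct.render_map(pop, m, ct.RenderParams(total_reads=1e7,
                                                    noise=False), bin_size=200)
        calls = ld.call_loops(mat, min_dist=5_000)
        assert calls.n_loops == 0

    def test_calls_sorted_with_q_values_in_unit_interval(self):
        _, mat = planted_chain(noise=True)
        calls = ld.call_loops(mat)
        t = calls.table
        assert t["q_value"].between(0, 1).all()
        assert (t.sort_values(["bin_i", "bin_j"]).index == t.index).all()


def calls_from_pairs(pairs, bin_size=200):
    rows = [(i, j, 10.0, 1.0, 10.0, 1e-9, 1e-6, 4) for i, j in pairs]
    table = pd.DataFrame(rows, columns=["bin_i", "bin_j", "observed",
                                        "local_expected", "fold", "p_value",
                                        "q_value", "n_pixels"])
    return ld.LoopCalls(table, bin_size)


class TestAnchorStats:
    def test_chain_counts_one_rightward_partner_each(self):
        calls = calls_from_pairs([(100, 150), (150, 200)])
        stats = ld.loops_per_anchor(calls)
        assert sorted(stats.counts.tolist()) == [1, 1]
        assert stats.histogram == {1: 100.0}

    def test_empty_calls_give_empty_histogram(self):
        stats = ld.loops_per_anchor(calls_from_pairs([]))
        assert stats.histogram == {}

    def test_shared_anchor_counts_two_partners(self):
        calls = calls_from_pairs([(100, 150), (100, 200), (100, 251)])
        stats = ld.loops_per_anchor(calls)
        assert max(stats.counts) == 3

    def test_nearby_anchor_bins_merge_within_tolerance(self):
        calls = calls_from_pairs([(100, 150), (101, 200)])
        stats = ld.loops_per_anchor(calls, anchor_merge_tol=2)
        assert max(stats.counts) == 2  # bins 100/101 are one anchor


class TestLoopSizeVsInterval:
    def test_regular_peaks_have_interval_median_8kb(self):
        summits = 5_000 + 8_000.0 * np.arange(20)
        peaks = gm.PeakSet(summits, np.ones(20), np.full(20, 1_000.0))
        cmp_ = ld.loop_size_vs_interval(calls_from_pairs([]), peaks)
        assert cmp_.median_interval == 8_000

    def test_adjacent_only_calls_match_interval_median(self):
        summits = 5_000 + 8_000.0 * np.arange(20)
        peaks = gm.PeakSet(summits, np.ones(20), np.full(20, 1_000.0))
        pairs = [(int(a // 200), int(b // 200))
                 for a, b in zip(summits[:-1], summits[1:])]
        cmp_ = ld.loop_size_vs_interval(calls_from_pairs(pairs), peaks)
        assert cmp_.median_loop == pytest.approx(cmp_.median_interval, abs=200)


class TestInsulation:
    def _balanced(self, counts, bin_size=2_000):
        mat = ct.ContactMatrix(bin_size, counts, "chrS",
                               bin_size * counts.shape[0])
        return ct.ice_balance(mat, mask_low_coverage=0.0)

    def test_uniform_matrix_has_flat_profile_and_no_boundaries(self):
        prof = ld.insulation(self._balanced(np.ones((60, 60))), window=16_000)
        mid = prof.scores[10:-10]
        assert np.allclose(mid[np.isfinite(mid)], 0.0, atol=1e-9)
        assert prof.boundary_bins.size == 0

    def test_two_dense_blocks_give_single_boundary_at_junction(self):
        n = 60
        counts = np.full((n, n), 0.05)
        counts[:30, :30] = 1.0
        counts[30:, 30:] = 1.0
        prof = ld.insulation(self._balanced(counts), window=16_000,
                             min_prominence=0.2)
        assert prof.boundary_bins.size == 1
        assert abs(int(prof.boundary_bins[0]) - 30) <= 1

    def test_boundary_in_masked_region_is_suppressed(self):
        n = 60
        counts = np.full((n, n), 0.05)
        counts[:30, :30] = 1.0
        counts[30:, 30:] = 1.0
        counts[29:32, :] = 0.0  # junction bins unmappable
        counts[:, 29:32] = 0.0
        mat = ct.ContactMatrix(2_000, counts, "chrS", 2_000 * n)
        prof = ld.insulation(ct.ice_balance(mat), window=16_000,
                             min_prominence=0.2)
        assert all(abs(int(b) - 30) > 1 for b in prof.boundary_bins)

    def test_window_larger_than_chromosome_raises(self):
        with pytest.raises(AnalysisError):
            ld.insulation(self._balanced(np.ones((10, 10))), window=30_000)


class TestAggregateDomains:
    def test_identity_rescale_reproduces_submatrix(self, rng):
        vals = rng.random((100, 100))
        oe = ct.OEMatrix(vals, 1_000, np.ones(100))
        d = ld.DomainSet(np.array([20_000]), np.array([50_000]))  # 30 bins
        ada = ld.aggregate_domains(oe, d, pseudo_size=30, flank=0.0)
        assert np.allclose(ada.matrix, vals[20:50, 20:50], atol=1e-12)

    def test_domain_edges_map_to_rescaled_zero_and_one(self):
        vals = np.zeros((100, 100))
        vals[20, 49] = 7.0  # contact at (D_start, D_end) bins
        oe = ct.OEMatrix(vals, 1_000, np.ones(100))
        d = ld.DomainSet(np.array([20_000]), np.array([50_000]))
        ada = ld.aggregate_domains(oe, d, pseudo_size=30, flank=0.0)
        assert ada.matrix[0, 29] == 7.0

    def test_matches_naive_percontact_remapping(self, rng):
        vals = rng.random((150, 150))
        oe = ct.OEMatrix(vals, 1_000, np.ones(150))
        starts = np.sort(rng.choice(np.arange(5, 100) * 1_000, 10, replace=False))
        ends = starts + rng.integers(10, 40, 10) * 1_000
        d = ld.DomainSet(starts, ends)
        S, flank = 20, 0.5
        ada = ld.aggregate_domains(oe, d, pseudo_size=S, flank=flank)
        grid = int(round(S * 2))
        acc = np.zeros((grid, grid))
        wgt = np.zeros((grid, grid))
        for ds, de in zip(starts, ends):  # naive re-mapping oracle
            length = de - ds
            for bi in range(150):
                ci = (bi + 0.5) * 1_000
                ni = (ci - ds) / length
                pi = int(np.floor((ni + flank) / 2.0 * grid))
                if not 0 <= pi < grid:
                    continue
                for bj in range(150):
                    cj = (bj + 0.5) * 1_000
                    nj = (cj - ds) / length
                    pj = int(np.floor((nj + flank) / 2.0 * grid))
                    if 0 <= pj < grid:
                        acc[pi, pj] += vals[bi, bj]
                        wgt[pi, pj] += 1
        with np.errstate(invalid="ignore"):
            oracle = np.where(wgt > 0, acc / wgt, np.nan)
        assert np.allclose(np.nan_to_num(ada.matrix), np.nan_to_num(oracle),
                           atol=1e-10)

    def test_zero_domains_raise(self):
        oe = ct.OEMatrix(np.ones((10, 10)), 1_000, np.ones(10))
        with pytest.raises(AnalysisError):
            ld.aggregate_domains(
                oe, ld.DomainSet(np.empty(0, dtype=int), np.empty(0, dtype=int)))


class TestBoundaryChip:
    def test_boundaries_at_cars_give_center_peaked_profile(self):
        m = gm.build_car_map(20, 300_000, seed=6)
        track = gm.synthesize_chip(m, depth=0.0, noise=False)
        res = ld.boundary_chip_enrichment(m.car_positions[5:15], track)
        c = res.profile.size // 2
        assert res.profile[c] == res.profile.max()
        assert res.profile[c] > 3 * res.profile[0]

    def test_flat_track_gives_flat_profile(self):
        track = gm.ChIPTrack(100, np.full(3_000, 2.0), 300_000)
        res = ld.boundary_chip_enrichment([100_000, 150_000, 200_000], track)
        assert np.allclose(res.profile, 2.0)

    def test_empty_boundaries_raise(self):
        track = gm.ChIPTrack(100, np.ones(1_000), 100_000)
        with pytest.raises(AnalysisError):
            ld.boundary_chip_enrichment([], track)

    def test_edge_boundaries_dropped_and_counted(self):
        track = gm.ChIPTrack(100, np.ones(1_000), 100_000)
        res = ld.boundary_chip_enrichment([1_000, 50_000], track, flank=5_000)
        assert res.n_dropped_edge == 1


class TestAnchorOverlap:
    def test_anchors_at_peaks_give_full_overlap(self):
        summits = np.array([20_100.0, 30_100.0, 40_100.0])
        peaks = gm.PeakSet(summits, np.ones(3), np.full(3, 1_000.0))
        calls = calls_from_pairs([(100, 150), (150, 200)])
        assert ld.anchor_overlap(calls, peaks) == 1.0

    def test_no_peaks_give_zero_overlap(self):
        peaks = gm.PeakSet(np.empty(0), np.empty(0), np.empty(0))
        calls = calls_from_pairs([(100, 150)])
        assert ld.anchor_overlap(calls, peaks) == 0.0
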