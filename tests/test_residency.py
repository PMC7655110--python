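"""Per-cell occupancy sampling, loop formation rules, scenarios, span laws."""

from itertools import product

import numpy as np
import pytest

from carloops import genome_model as gm
from carloops import residency as rs
from carloops.errors import ConfigError


def uniform_map(p, n=12, spacing=8_000):
    pos = 10_000 + spacing * np.arange(n)
    return gm.CARMap("chrS", pos[-1] + 10_000, pos, np.full(n, float(p)))


class TestSampleOccupancy:
    def test_certain_occupancy_all_true(self):
        m = uniform_map(1.0)
        assert rs.sample_occupancy(m, 0, seed=1).occupied.all()

    def test_zero_occupancy_all_false(self):
        m = uniform_map(0.0)
        assert not rs.sample_occupancy(m, 0, seed=1).occupied.any()

    def test_occupied_fraction_matches_probability(self):
        m = uniform_map(0.5, n=30)
        hits = np.zeros(30)
        n_cells = 10_000
        for c in range(n_cells):
            hits += rs.sample_occupancy(m, c, seed=3).occupied
        assert np.all(np.abs(hits / n_cells - 0.5) < 0.02)

    def test_reproducible_given_seed_and_cell(self):
        m = uniform_map(0.5, n=30)
        a = rs.sample_occupancy(m, 7, seed=9).occupied
        b = rs.sample_occupancy(m, 7, seed=9).occupied
        assert np.array_equal(a, b)


class TestFormLoopsConsecutive:
    @pytest.mark.parametrize("pattern,expected", [
        ([1, 1, 1, 1], [(0, 1), (1, 2), (2, 3)]),
        ([1, 0, 0, 1, 1], [(0, 3), (3, 4)]),
        ([0, 0, 0], []),
        ([1, 0, 0], []),
    ])
    def test_loop_pairs_follow_consecutive_occupied_rule(self, pattern, expected):
        m = uniform_map(0.5, n=len(pattern))
        state = rs.OccupancyState(np.array(pattern, dtype=bool), cell_id=0)
        cell = rs.form_loops_consecutive(state, m)
        assert list(zip(cell.left_car, cell.right_car)) == expected

    def test_enumeration_matches_independent_oracle(self):
        """Package enumeration vs a from-scratch itertools enumeration."""
        p = 0.4
        n = 10
        ours = rs.enumerate_consecutive_spans(np.full(n, p))
        oracle = np.zeros(n - 1)
        for pat in product((0, 1), repeat=n):
            w = np.prod([p if b else 1 - p for b in pat])
            occ = [i for i, b in enumerate(pat) if b]
            for a, b in zip(occ[:-1], occ[1:]):
                oracle[b - a - 1] += w
        assert np.allclose(ours, oracle, atol=1e-12)

    def test_simulated_spans_match_enumeration_at_12_cars(self):
        p = 0.5
        m = uniform_map(p, n=12)
        pop = rs.simulate_population(m, 10_000, seed=5)
        sd = rs.span_histogram(pop, m)
        exact = rs.enumerate_consecutive_spans(np.full(12, p))
        exact = exact / exact.sum()
        emp = np.zeros(exact.size)
        for k, pr in zip(sd.ks, sd.probs):
            emp[k - 1] = pr
        assert 0.5 * np.abs(emp - exact).sum() < 0.02


class TestExtrudeCell:
    def test_no_occupied_cars_gives_unpositioned_loops_of_processivity_span(self):
        m = uniform_map(0.0, n=5)
        state = rs.OccupancyState(np.zeros(5, dtype=bool), 0)
        cell = rs.extrude_cell(state, m, n_extruders=50, processivity=10_000,
                               seed=3)
        spans = cell.right - cell.left
        interior = (cell.left > 0) & (cell.right < m.chrom_length - 1)
        assert np.all(cell.left_car == -1) and np.all(cell.right_car == -1)
        assert np.allclose(spans[interior], 10_000, atol=2)

    def test_all_occupied_anchors_at_flanking_cars(self):
        m = uniform_map(1.0, n=10)
        state = rs.OccupancyState(np.ones(10, dtype=bool), 0)
        cell = rs.extrude_cell(state, m, n_extruders=100, processivity=500_000,
                               seed=4)
        pos = m.car_positions
        for left, right, lc, rc in zip(cell.left, cell.right,
                                       cell.left_car, cell.right_car):
            if lc >= 0 and rc >= 0:
                assert rc == lc + 1  # flanking CARs of the load point
                assert left == pos[lc] and right == pos[rc]

    def test_single_occupied_car_matches_closed_form(self):
        """One-sided positioned anchors at c; other side at P - |u - c|."""
        n = 9
        m = uniform_map(0.0, n=n, spacing=20_000)
        occupied = np.zeros(n, dtype=bool)
        occupied[4] = True
        c = float(m.car_positions[4])
        P = 60_000.0
        state = rs.OccupancyState(occupied, 0)
        cell = rs.extrude_cell(state, m, n_extruders=4_000, processivity=P,
                               seed=8)
        at_c = (cell.left_car == 4) | (cell.right_car == 4)
        # closed form: positioned at c iff 2|u - c| <= P, u ~ U(0, L)
        expect = min(P, 2 * min(c, m.chrom_length - c)) / m.chrom_length
        assert at_c.mean() == pytest.approx(expect, abs=0.02)
        # for positioned loops the far anchor sits P - |u-c| from the load,
        # i.e. the total span equals exactly P (both phases spend the budget)
        spans = (cell.right - cell.left)[at_c]
        inner = spans[(cell.left[at_c] > 0) &
                      (cell.right[at_c] < m.chrom_length - 1)]
        assert np.allclose(inner, P, atol=2)

    def test_exponential_budgets_have_requested_mean(self):
        m = uniform_map(0.0, n=5, spacing=100_000)
        state = rs.OccupancyState(np.zeros(5, dtype=bool), 0)
        cell = rs.extrude_cell(state, m, n_extruders=3_000, processivity=8_000,
                               seed=2, processivity_distribution="exponential")
        spans = (cell.right - cell.left)
        inner = spans[(cell.left > 0) & (cell.right < m.chrom_length - 1)]
        assert inner.mean() == pytest.approx(8_000, rel=0.1)


class TestScenarios:
    def test_wt_and_brn1_are_identity(self, small_map):
        for name in ("WT", "BRN1"):
            out = rs.apply_scenario(small_map, rs.get_scenario(name))
            assert np.array_equal(out.occupancy, small_map.occupancy)

    def test_mcd1_zeroes_occupancy(self, small_map):
        out = rs.apply_scenario(small_map, rs.get_scenario("MCD1"))
        assert np.all(out.occupancy == 0)

    def test_wpl1_halves_occupancy(self):
        m = gm.CARMap("chrS", 40_000, np.array([10_000, 30_000]),
                      np.array([0.8, 0.4]))
        out = rs.apply_scenario(m, rs.get_scenario("WPL1"))
        assert np.allclose(out.occupancy, [0.4, 0.2])

    def test_pds5_depletes_arms_keeps_centromere(self, small_map):
        out = rs.apply_scenario(small_map, rs.get_scenario("PDS5"))
        ci = small_map.centromere_index
        cen_pos = small_map.car_positions[ci]
        dist = np.abs(small_map.car_positions - cen_pos)
        arm = dist > 30_000
        assert np.allclose(out.occupancy[arm], 0.05 * small_map.occupancy[arm])
        assert out.occupancy[ci] == small_map.occupancy[ci]
        peri = (~arm) & (np.arange(small_map.n_cars) != ci)
        assert np.allclose(out.occupancy[peri], 0.7 * small_map.occupancy[peri])

    def test_unknown_scenario_raises(self):
        with pytest.raises(ConfigError):
            rs.get_scenario("SCC2")


class TestSimulatePopulation:
    def test_full_occupancy_gives_adjacent_loops_at_frequency_one(self):
        m = uniform_map(1.0, n=15)
        pop = rs.simulate_population(m, 50, seed=2)
        assert pop.n_pairs == 14
        assert np.all(pop.frequency == 1.0)
        assert np.all(pop.spans() == 1)

    def test_zero_occupancy_gives_empty_table(self):
        m = uniform_map(0.0, n=15)
        pop = rs.simulate_population(m, 50, seed=2)
        assert pop.n_pairs == 0

    def test_adjacent_pair_frequency_close_to_p_squared(self):
        m = uniform_map(0.5, n=20)
        pop = rs.simulate_population(m, 10_000, seed=6)
        freqs = [pop.pair_frequency(i, i + 1) for i in range(5, 15)]
        assert np.all(np.abs(np.array(freqs) - 0.25) < 0.02)

    def test_identical_seeds_give_identical_populations(self):
        m = uniform_map(0.4, n=25)
        a = rs.simulate_population(m, 300, seed=11)
        b = rs.simulate_population(m, 300, seed=11)
        assert np.array_equal(a.left_car, b.left_car)
        assert np.array_equal(a.frequency, b.frequency)
        assert np.array_equal(a.unpositioned, b.unpositioned)


class TestSpanHistogram:
    def test_saturated_population_has_all_mass_at_span_one(self):
        m = uniform_map(1.0, n=10)
        sd = rs.span_histogram(rs.simulate_population(m, 20, seed=1), m)
        assert sd.prob(1) == 1.0

    def test_empty_population_gives_empty_distribution(self):
        m = uniform_map(0.0, n=10)
        sd = rs.span_histogram(rs.simulate_population(m, 20, seed=1), m)
        assert sd.ks.size == 0

    def test_span_distribution_is_truncated_geometric(self):
        p = 0.5
        n = 100
        m = uniform_map(p, n=n)
        pop = rs.simulate_population(m, 5_000, seed=4)
        sd = rs.span_histogram(pop, m)
        ks = np.arange(1, 15)
        # finite-chain law: P(k) proportional to (n - k) p^2 (1-p)^(k-1)
        law = (n - ks) * p * p * (1 - p) ** (ks - 1)
        law = law / ((n - np.arange(1, n)) * p * p *
                     (1 - p) ** (np.arange(1, n) - 1)).sum()
        emp = np.array([sd.prob(k) for k in ks])
        assert 0.5 * np.abs(emp - law).sum() < 0.02

    def test_halving_occupancy_increases_mean_span(self):
        for seed in range(5):
            m = gm.build_car_map(60, 700_000, seed=seed)
            half = m.with_occupancy(m.occupancy * 0.5)
            s_full = rs.span_histogram(
                rs.simulate_population(m, 2_000, seed=seed + 50), m).mean_span
            s_half = rs.span_histogram(
                rs.simulate_population(half, 2_000, seed=seed + 50), half).mean_span
            assert s_half > s_full


class TestOccupancyFromLoops:
    def test_sqrt_adjacent_frequency_recovers_uniform_occupancy(self):
        m = uniform_map(0.6, n=50)
        pop = rs.simulate_population(m, 5_000, seed=9)
        est = rs.occupancy_from_adjacent_loops(pop, m.n_cars)
        ok = np.isfinite(est)
        assert np.sqrt(np.mean((est[ok] - 0.6) ** 2)) < 0.05

    def test_positioned_anchor_counts_sum_matches_loops(self):
        m = uniform_map(0.7, n=20)
        pop = rs.simulate_population(m, 500, seed=3)
        counts = rs.positioned_anchor_counts(pop, m.n_cars)
        assert counts.sum() == pytest.approx(2 * (pop.frequency * pop.n_cells).sum())
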