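"""Standard study conditions and compound experiments.

The functions here fix the desk-scale study conditions — a 750 kb yeast-like
chromosome with 90 CARs (median spacing 8 kb), a 3,000-cell population,
200 bp contact-map bins and a 2x10^7-read budget — and run the compound
analyses the drivers, tests and acceptance script all share: scenario maps,
planted-loop benchmarks, occupancy-recovery round trips and boundary
statistics.  Everything is deterministic given the seed passed in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from . import genome_model as gm
from . import residency as rs
from . import contacts as ct
from . import map_stats as ms
from . import loops_domains as ld

#: desk-scale study conditions (one toy chromosome)
CHROM_LENGTH = 750_000
N_CARS = 90
CENTROMERE = 375_000
N_CELLS = 3_000
BIN_SIZE = 200
TOTAL_READS = 20_000_000.0


def toy_car_map(seed: int = 0, n_cars: int = N_CARS,
                chrom_length: int = CHROM_LENGTH,
                centromere: Optional[int] = CENTROMERE) -> gm.CARMap:
    """The standard toy chromosome, with high-residency flags set by occupancy."""
    car_map = gm.build_car_map(n_cars, chrom_length, centromere=centromere,
                               seed=seed)
    return car_map.with_high_residency(gm.classify_high_residency(car_map, 0.10))


def uniform_car_map(p: float, seed: int = 0, n_cars: int = N_CARS,
                    chrom_length: int = CHROM_LENGTH) -> gm.CARMap:
    """Toy chromosome with homogeneous occupancy ``p`` (no centromere)."""
    car_map = gm.build_car_map(n_cars, chrom_length, centromere=None, seed=seed)
    return car_map.with_occupancy(np.full(n_cars, float(p)))


@dataclass
class ScenarioMap:
    """A rendered, balanced scenario map with its ingredients."""

    car_map: gm.CARMap
    scenario_map: gm.CARMap
    pop: rs.PopulationLoops
    matrix: ct.ContactMatrix
    oe: ct.OEMatrix
    peaks: gm.PeakSet
    hr_flags: np.ndarray


def scenario_contact_map(
    scenario: str,
    seed: int = 0,
    mode: str = "consecutive",
    n_cells: int = N_CELLS,
    total_reads: float = TOTAL_READS,
    noise: bool = True,
    render_kwargs: Optional[dict] = None,
) -> ScenarioMap:
    """Simulate and render one scenario at the standard study conditions.

    ChIP peaks (noise-free track) stand in for the Mcd1 peak list; the
    high-residency flags come from the top decile of peak heights.
    """
    car_map = toy_car_map(seed=seed)
    track = gm.synthesize_chip(car_map, depth=0.0, noise=False)
    calib = gm.chip_calibration(1_000.0)
    peaks = gm.call_peaks(track, min_height=0.02 * calib, min_separation=2_000)
    hr_flags = gm.classify_high_residency(peaks, 0.10)

    sc = rs.get_scenario(scenario)
    sc_map = rs.apply_scenario(car_map, sc)
    params: Dict[str, float] = {}
    if mode == "extruder":
        params["processivity"] = rs.DEFAULT_PROCESSIVITY * \
            sc.extruder_overrides.get("processivity_factor", 1.0)
        for key in ("processivity_distribution", "loading"):
            if key in sc.extruder_overrides:
                params[key] = sc.extruder_overrides[key]
    pop = rs.simulate_population(sc_map, n_cells, mode=mode, params=params,
                                 seed=seed + 1)
    rp = ct.RenderParams(total_reads=total_reads, seed=seed + 2, noise=noise,
                         **(render_kwargs or {}))
    matrix = ct.ice_balance(ct.render_map(pop, sc_map, rp, bin_size=BIN_SIZE))
    oe = ct.observed_over_expected(matrix)
    return ScenarioMap(car_map, sc_map, pop, matrix, oe, peaks, hr_flags)


def adjacent_car_pairs(car_map: gm.CARMap) -> list:
    """Anchor-pair coordinates of all adjacent CAR pairs."""
    p = car_map.car_positions
    return [(float(a), float(b)) for a, b in zip(p[:-1], p[1:])]


def occupancy_recovery_chip(seed: int = 0, n_cars: int = 100,
                            depth: float = 2.0) -> float:
    """RMSE of ChIP-based occupancy recovery on a noisy synthetic track."""
    car_map = gm.build_car_map(n_cars, 1_000_000, seed=seed)
    track = gm.synthesize_chip(car_map, depth=depth, noise=depth > 0,
                               noise_seed=seed + 1)
    calib = gm.chip_calibration(1_000.0)
    peaks = gm.call_peaks(track, min_height=depth + 0.05 * calib,
                          min_separation=2_000)
    est = gm.estimate_occupancy(peaks, calib, car_map, background=depth)
    ok = np.isfinite(est.values)
    return float(np.sqrt(np.mean((est.values[ok] - car_map.occupancy[ok]) ** 2)))


def occupancy_recovery_loops(seed: int = 0, p: float = 0.5,
                             n_cells: int = 5_000) -> float:
    """RMSE of sqrt(adjacent-loop frequency) occupancy recovery at uniform p."""
    car_map = uniform_car_map(p, seed=seed)
    pop = rs.simulate_population(car_map, n_cells, seed=seed + 1)
    est = rs.occupancy_from_adjacent_loops(pop, car_map.n_cars)
    ok = np.isfinite(est)
    return float(np.sqrt(np.mean((est[ok] - p) ** 2)))


def planted_loop_benchmark(sm: ScenarioMap, calls: ld.LoopCalls,
                           min_dist: int = 0) -> Dict[str, float]:
    """Precision/recall of loop calls against the planted adjacent CAR pairs.

    The planted truth is every adjacent pair of the scenario map's occupied
    CAR chain with separation above ``min_dist``; a call matches a planted
    loop when both anchors are within one bin of its anchors.
    """
    p = sm.scenario_map.car_positions
    truth = [(a, b) for a, b in zip(p[:-1], p[1:]) if b - a > min_dist]
    bs = calls.bin_size
    truth_bins = {(int(a // bs), int(b // bs)) for a, b in truth}
    call_bins = list(zip(calls.table["bin_i"], calls.table["bin_j"]))

    def matched(pair, pool):
        return any(abs(pair[0] - q[0]) <= 1 and abs(pair[1] - q[1]) <= 1
                   for q in pool)

    tp_calls = sum(matched(c, truth_bins) for c in call_bins)
    recovered = sum(matched(t, call_bins) for t in truth_bins)
    precision = tp_calls / len(call_bins) if call_bins else float("nan")
    recall = recovered / len(truth_bins) if truth_bins else float("nan")
    return {"precision": precision, "recall": recall,
            "n_calls": len(call_bins), "n_truth": len(truth_bins)}


def boundary_hr_fraction(sm: ScenarioMap, insulation_res: int = 2_000,
                         window: int = 15_000, tol: float = 2_000.0):
    """Insulation boundaries and their proximity to high-residency CARs.

    Returns (fraction of boundaries within ``tol`` of a high-residency CAR,
    boundary positions, profile).  NaN fraction when no boundaries.
    """
    factor = insulation_res // sm.matrix.bin_size
    coarse = ct.ice_balance(ct.coarsen(sm.matrix, factor))
    profile = ld.insulation(coarse, window=window)
    b_bp = profile.boundaries_bp()
    hr_pos = sm.car_map.car_positions[sm.car_map.high_residency]
    if b_bp.size == 0 or hr_pos.size == 0:
        return float("nan"), b_bp, profile
    d = np.abs(b_bp[:, None] - hr_pos[None, :]).min(axis=1)
    return float((d <= tol).mean()), b_bp, profile


def permuted_boundary_fraction(b_bp: np.ndarray, hr_pos: np.ndarray,
                               chrom_length: int, seed: int,
                               n_perm: int = 200, tol: float = 2_000.0) -> np.ndarray:
    """Null distribution: fraction near a high-residency CAR for random boundaries."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for k in range(n_perm):
        fake = rng.uniform(0, chrom_length, size=b_bp.size)
        d = np.abs(fake[:, None] - hr_pos[None, :]).min(axis=1)
        out[k] = (d <= tol).mean()
    return out


def wt_wpl1_seed_summary(seed: int) -> Dict[str, dict]:
    """Loop-expansion summary for a WT/WPL1 pair at one seed.

    Computes, per scenario: population mean span (CAR intervals), called-loop
    count, mean loop partners per anchor, and the largest CAR interval k with
    pile-up enrichment > 1.5; for WT additionally the barrier contrast and
    insulation-boundary statistics.  Maps are discarded after summarizing.
    """
    out: Dict[str, dict] = {}
    for name in ("WT", "WPL1"):
        sm = scenario_contact_map(name, seed=seed)
        calls = ld.call_loops(sm.matrix)
        series = ms.interval_pileup_series(sm.oe, sm.peaks)
        span = rs.span_histogram(sm.pop, sm.scenario_map)
        d = {
            "mean_span": span.mean_span,
            "median_span_bp": span.bp_quantiles.get(0.5, float("nan")),
            "n_calls": calls.n_loops,
            "mean_partners": ld.loops_per_anchor(calls).mean_partners,
            "max_k": series.max_k_above(1.5),
            "ratio_k1": float(series.ratios[0]),
            "anchor_overlap": ld.anchor_overlap(calls, sm.peaks),
        }
        if name == "WT":
            r_across, r_plain, n_a, n_p = ms.barrier_contrast(
                sm.oe, sm.peaks, sm.hr_flags)
            d.update(barrier_across=r_across, barrier_no=r_plain,
                     n_across=n_a, n_no=n_p)
            frac, b_bp, _ = boundary_hr_fraction(sm)
            hr_pos = sm.car_map.car_positions[sm.car_map.high_residency]
            n_near = int((np.abs(b_bp[:, None] - hr_pos[None, :]).min(axis=1)
                          <= 2_000).sum()) if b_bp.size else 0
            pos = sm.car_map.car_positions
            is_boundary_car = np.zeros(pos.size, dtype=bool)
            if b_bp.size:
                is_boundary_car = np.abs(pos[:, None] - b_bp[None, :]).min(axis=1) <= 2_000
            d.update(n_boundaries=int(b_bp.size), n_boundaries_at_hr=n_near,
                     boundary_car_occ=sm.car_map.occupancy[is_boundary_car].tolist(),
                     other_car_occ=sm.car_map.occupancy[~is_boundary_car].tolist())
        out[name] = d
    return out


def mcd1_null_summary(seed: int) -> dict:
    """Cohesin-null (MCD1) checks: call count, APA at former anchors, decay slope."""
    sm = scenario_contact_map("MCD1", seed=seed)
    calls = ld.call_loops(sm.matrix)
    pairs = adjacent_car_pairs(sm.car_map)
    apa = ms.enrichment_ratio(ms.pileup_at_pairs(sm.oe, pairs))
    curve = ms.contact_decay(sm.matrix)
    slope = ms.fit_decay_exponent(curve, 1e4, 1e5)
    frac, b_bp, _ = boundary_hr_fraction(sm)
    return {"n_calls": calls.n_loops, "apa_ratio": apa, "decay_slope": slope,
            "n_boundaries": int(b_bp.size), "boundary_hr_fraction": frac}


def saturated_recovery_summary(seed: int) -> dict:
    """p = 1 limit: caller recovers exactly the n_cars - 1 adjacent loops.

    The map is rendered noise-free (expected counts); the caller runs with
    min_dist 2 kb so adjacent pairs down to the 3 kb spacing floor stay in
    the tested band.
    """
    um = uniform_car_map(1.0, seed=seed)
    pop = rs.simulate_population(um, 100, seed=seed + 1)
    rp = ct.RenderParams(total_reads=TOTAL_READS, noise=False)
    mat = ct.render_map(pop, um, rp, bin_size=BIN_SIZE)
    calls = ld.call_loops(mat, min_dist=2_000)
    sm = ScenarioMap(um, um, pop, mat, None, None, None)  # type: ignore[arg-type]
    bench = planted_loop_benchmark(sm, calls)
    bench["n_cars"] = um.n_cars
    return bench


def pds5_stripe_summary(seed: int) -> dict:
    """PDS5 extruder mode: anchor concentration at the centromere and stripe extent."""
    sm = scenario_contact_map("PDS5", seed=seed, mode="extruder")
    counts = rs.positioned_anchor_counts(sm.pop, sm.car_map.n_cars)
    cen = sm.car_map.centromere_index
    cen_frac = float(counts[cen] / counts.sum()) if counts.sum() else float("nan")
    cen_pos = sm.car_map.car_positions[cen]
    peri = np.abs(sm.car_map.car_positions - cen_pos) <= rs.PERICENTRIC_RADIUS
    peri_frac = float(counts[peri].sum() / counts.sum()) if counts.sum() else float("nan")
    # stripe: longest contiguous O/E > 1.5 run along the centromere row at 2 kb
    coarse = ct.ice_balance(ct.coarsen(sm.matrix, 10))
    oe2 = ct.observed_over_expected(coarse)
    cb = coarse.bin_of(cen_pos)
    row = np.nan_to_num(oe2.values[cb], nan=1.0)

    def longest_run(arr):
        run = best = 0
        for v in arr:
            run = run + 1 if v > 1.5 else 0
            best = max(best, run)
        return best

    extent = max(longest_run(row[cb + 3:]), longest_run(row[:cb - 3][::-1]))
    return {"centromeric_anchor_fraction": cen_frac,
            "pericentric_anchor_fraction": peri_frac,
            "stripe_extent_bp": float(extent * coarse.bin_size)}
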