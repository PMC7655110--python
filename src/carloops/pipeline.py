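"""End-to-end scenario pipeline: simulate -> render -> analyze -> report.

Wires the stages together for one named scenario: build the chromosome,
emulate and call the cohesin ChIP track, apply the depletion, simulate the
loop population, render and balance the contact map, then run the map
statistics (decay curve, loop calls, interval series, barrier contrast,
insulation boundaries, ADA, boundary-ChIP overlap) and write every product
in its standard text form plus a JSON report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import genome_model as gm
from . import residency as rs
from . import contacts as ct
from . import map_stats as ms
from . import loops_domains as ld
from . import io as cio
from .config import RunConfig
from .errors import AnalysisError, PipelineStageError

logger = logging.getLogger("carloops")

# fixed per-stage seed offsets expanding the single run seed
STAGE_SEED_OFFSETS = {"genome": 11, "chip": 23, "population": 37, "render": 53}


def stage_seed(seed: int, stage: str) -> int:
    return (int(seed) + STAGE_SEED_OFFSETS[stage]) % (2 ** 31)


@dataclass
class ScenarioReport:
    """Summary numbers and file paths of one scenario run."""

    scenario: str
    seed: int
    n_called_loops: int = 0
    loops_per_anchor_hist: dict = field(default_factory=dict)
    mean_partners_per_anchor: float = float("nan")
    median_loop_size: float = float("nan")
    median_peak_interval: float = float("nan")
    mean_span_cars: float = float("nan")
    interval_series_k: list = field(default_factory=list)
    interval_series_ratio: list = field(default_factory=list)
    barrier_ratio_across: float = float("nan")
    barrier_ratio_no_barrier: float = float("nan")
    n_boundaries: int = 0
    boundary_hr_car_fraction: float = float("nan")
    anchor_peak_overlap: float = float("nan")
    apa_ratio_adjacent: float = float("nan")
    decay_slope_10_100kb: float = float("nan")
    files: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = asdict(self)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> ScenarioReport:
    """Execute the full scenario pipeline described by ``config``.

    Any stage failure raises :class:`PipelineStageError` naming the stage;
    files written by earlier stages are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = ScenarioReport(scenario=config.scenario, seed=config.seed)
    g, sim, rd, an = config.genome, config.simulation, config.render, config.analysis

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("run config: %s", json.dumps({"schema_version": 1, **asdict(config)}))

    def record(name, path):
        report.files[name] = str(path)
        logger.info("wrote %s sha256=%s", path, _sha256(path))

    try:
        stage = "genome"
        car_map = gm.build_car_map(
            g.n_cars, g.chrom_length, spacing_median=g.spacing_median,
            spacing_sigma=g.spacing_sigma,
            occupancy_shape=((g.occupancy_a, g.occupancy_b)
                             if g.occupancy_distribution == "beta"
                             else g.occupancy_distribution),
            centromere=g.centromere, seed=stage_seed(config.seed, "genome"),
            chrom_name=g.chrom_name)

        stage = "chip"
        track = gm.synthesize_chip(
            car_map, depth=g.chip_depth, peak_width=g.chip_peak_width,
            peak_gain=g.chip_peak_gain, noise_seed=stage_seed(config.seed, "chip"),
            bin_size=g.chip_bin_size)
        calibration = gm.chip_calibration(g.chip_peak_gain, g.chip_peak_width,
                                          g.chip_bin_size)
        peaks = gm.call_peaks(track, min_height=g.chip_depth + 0.1 * calibration,
                              min_separation=2_000)
        hr_flags = gm.classify_high_residency(peaks, g.high_residency_fraction)
        # carry the ChIP-derived flags onto the CAR map (nearest CAR per peak)
        car_flags = np.zeros(car_map.n_cars, dtype=bool)
        for s, f in zip(peaks.summits, hr_flags):
            if f:
                car_flags[int(np.argmin(np.abs(car_map.car_positions - s)))] = True
        car_map = car_map.with_high_residency(car_flags)
        cio.write_carmap(car_map, out / "car_map.bed")
        record("car_map", out / "car_map.bed")
        cio.write_bedgraph(track, out / "chip.bedgraph")
        record("chip", out / "chip.bedgraph")

        stage = "scenario"
        scenario = rs.get_scenario(config.scenario)
        sc_map = rs.apply_scenario(car_map, scenario)

        stage = "population"
        params = {"processivity": sim.processivity}
        if sim.n_extruders:
            params["n_extruders"] = sim.n_extruders
        if "processivity_factor" in scenario.extruder_overrides:
            params["processivity"] = (sim.processivity *
                                      scenario.extruder_overrides["processivity_factor"])
        for key in ("processivity_distribution", "loading"):
            if key in scenario.extruder_overrides:
                params[key] = scenario.extruder_overrides[key]
        pop = rs.simulate_population(sc_map, sim.n_cells, mode=sim.mode,
                                     params=params,
                                     seed=stage_seed(config.seed, "population"))
        cio.write_population_bedpe(pop, sc_map, out / "population_loops.bedpe")
        record("population_loops", out / "population_loops.bedpe")
        span = rs.span_histogram(pop, sc_map)
        report.mean_span_cars = span.mean_span

        stage = "render"
        rp = ct.RenderParams(alpha=rd.alpha, s0=rd.s0, focal_weight=rd.focal_weight,
                             domain_weight=rd.domain_weight,
                             anchor_sigma=rd.anchor_sigma,
                             total_reads=rd.total_reads,
                             seed=stage_seed(config.seed, "render"),
                             noise=rd.noise)
        matrix = ct.render_map(pop, sc_map, rp, bin_size=rd.bin_size)
        cio.write_matrix_tsv(matrix, out / "matrix.tsv")
        record("matrix", out / "matrix.tsv")

        stage = "balance"
        matrix = ct.ice_balance(matrix)
        oe = ct.observed_over_expected(matrix)

        stage = "decay"
        curve = ms.contact_decay(matrix)
        centers, slopes = ms.decay_slope(curve, window=an.decay_slope_window)
        with open(out / "decay.tsv", "w") as fh:
            fh.write("distance_bp\tmass\tdensity\n")
            for c, m_, d_ in zip(curve.centers, curve.mass, curve.density):
                fh.write(f"{c:.6g}\t{m_:.6g}\t{d_:.6g}\n")
        record("decay", out / "decay.tsv")
        try:
            report.decay_slope_10_100kb = ms.fit_decay_exponent(curve, 1e4, 1e5)
        except AnalysisError:
            pass

        stage = "loop_calls"
        calls = ld.call_loops(matrix, min_dist=an.loop_min_dist,
                              max_dist=an.loop_max_dist,
                              donut_inner=an.donut_inner, donut_outer=an.donut_outer,
                              fold_min=an.loop_fold_min, fdr=an.loop_fdr)
        cio.write_loopcalls_bedpe(calls, out / "loop_calls.bedpe")
        record("loop_calls", out / "loop_calls.bedpe")
        report.n_called_loops = calls.n_loops
        anchor_stats = ld.loops_per_anchor(calls)
        report.loops_per_anchor_hist = anchor_stats.histogram
        report.mean_partners_per_anchor = anchor_stats.mean_partners
        size_cmp = ld.loop_size_vs_interval(calls, peaks)
        report.median_loop_size = size_cmp.median_loop
        report.median_peak_interval = size_cmp.median_interval
        report.anchor_peak_overlap = ld.anchor_overlap(calls, peaks)

        stage = "interval_series"
        series = ms.interval_pileup_series(
            oe, peaks, k_range=range(1, an.max_interval_k + 1),
            half_width=an.pileup_half_width, res=rd.bin_size,
            corner_size=an.corner_size)
        report.interval_series_k = [int(k) for k in series.ks]
        report.interval_series_ratio = [float(r) for r in series.ratios]
        if np.isfinite(series.ratios[0]):
            report.apa_ratio_adjacent = float(series.ratios[0])
        with open(out / "interval_series.tsv", "w") as fh:
            fh.write("k\tratio\tn_pairs\n")
            for k, r, np_ in zip(series.ks, series.ratios, series.n_pairs):
                fh.write(f"{k}\t{r:.6g}\t{np_}\n")
        record("interval_series", out / "interval_series.tsv")

        stage = "barrier"
        r_across, r_plain, _, _ = ms.barrier_contrast(
            oe, peaks, hr_flags, half_width=an.pileup_half_width, res=rd.bin_size,
            corner_size=an.corner_size)
        report.barrier_ratio_across = float(r_across)
        report.barrier_ratio_no_barrier = float(r_plain)

        stage = "insulation"
        factor = an.insulation_res // rd.bin_size
        coarse = ct.ice_balance(ct.coarsen(matrix, factor))
        profile = ld.insulation(coarse, window=an.insulation_window,
                                min_prominence=an.boundary_prominence)
        cio.write_insulation_bedgraph(profile, g.chrom_length,
                                      out / "insulation.bedgraph", g.chrom_name)
        record("insulation", out / "insulation.bedgraph")
        b_bp = profile.boundaries_bp()
        report.n_boundaries = int(b_bp.size)
        cio.write_bed_intervals(g.chrom_name,
                                np.maximum(0, b_bp - an.insulation_res / 2),
                                b_bp + an.insulation_res / 2,
                                [f"boundary{k}" for k in range(b_bp.size)],
                                out / "boundaries.bed")
        record("boundaries", out / "boundaries.bed")
        hr_pos = car_map.car_positions[car_map.high_residency]
        if b_bp.size and hr_pos.size:
            d = np.abs(b_bp[:, None] - hr_pos[None, :]).min(axis=1)
            report.boundary_hr_car_fraction = float((d <= 2_000).mean())

        stage = "ada"
        if b_bp.size >= 2:
            domains = ld.domains_from_boundaries(profile, g.chrom_length)
            if domains.n_domains:
                coarse_oe = ct.observed_over_expected(coarse)
                ada = ld.aggregate_domains(coarse_oe, domains,
                                           pseudo_size=an.ada_pseudo_size)
                np.savetxt(out / "ada.tsv", ada.matrix, fmt="%.6g", delimiter="\t")
                record("ada", out / "ada.tsv")

        stage = "report"
        report.to_json(out / "report.json")
        record("report", out / "report.json")
    except Exception as exc:
        logger.removeHandler(handler)
        handler.close()
        raise PipelineStageError(stage, exc) from exc
    logger.removeHandler(handler)
    handler.close()
    return report
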