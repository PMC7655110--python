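"""Synthetic chromosome model: CAR positions, occupancy, emulated cohesin ChIP.

A CAR (cohesin associated region) is a ~1 kb locus of stable cohesin
enrichment.  The model represents each CAR by a point coordinate (its peak
summit) and a per-cell occupancy probability in [0, 1]: the chance that the
CAR carries stably bound cohesin in any one cell of a population.  The
emulated ChIP-seq track makes peak height proportional to occupancy, so that
occupancy can be re-estimated from the track — the forward/inverse pair used
throughout the parameter-recovery tests.

Coordinates are 0-based, half-open (BED convention); one chromosome per map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .errors import ParameterError, SizingError

#: minimum enforced gap between CARs, bp
MIN_CAR_GAP = 2_000

#: default clip range for inter-CAR spacings, bp
SPACING_CLIP = (3_000, 40_000)


@dataclass
class CARMap:
    """A single synthetic chromosome with its CARs.

    Attributes
    ----------
    chrom_name : str
    chrom_length : int
        Chromosome length in bp.
    car_positions : np.ndarray
        Strictly increasing CAR center coordinates (bp).
    occupancy : np.ndarray
        Per-CAR probability in [0, 1] of stable cohesin binding in a cell.
    centromere_index : int or None
        Index of the CAR designated centromeric.
    high_residency : np.ndarray
        Per-CAR boolean flags (top decile of occupancy/ChIP height).
    """

    chrom_name: str
    chrom_length: int
    car_positions: np.ndarray
    occupancy: np.ndarray
    centromere_index: Optional[int] = None
    high_residency: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.car_positions = np.asarray(self.car_positions, dtype=np.int64)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.high_residency is None:
            self.high_residency = np.zeros(self.n_cars, dtype=bool)
        self.high_residency = np.asarray(self.high_residency, dtype=bool)
        if self.car_positions.ndim != 1 or self.occupancy.shape != self.car_positions.shape:
            raise ParameterError("positions and occupancy must be 1-D and aligned")
        if self.high_residency.shape != self.car_positions.shape:
            raise ParameterError("high_residency flags must match the number of CARs")
        if self.n_cars:
            if np.any(np.diff(self.car_positions) <= 0):
                raise ParameterError("CAR positions must be strictly increasing")
            if self.car_positions[0] < 0 or self.car_positions[-1] >= self.chrom_length:
                raise ParameterError("CAR positions must lie in [0, chrom_length)")
        if np.any((self.occupancy < 0) | (self.occupancy > 1)):
            raise ParameterError("occupancy values must lie in [0, 1]")
        if self.centromere_index is not None and not (0 <= self.centromere_index < self.n_cars):
            raise ParameterError("centromere_index out of range")

    @property
    def n_cars(self) -> int:
        return int(self.car_positions.size)

    @property
    def spacings(self) -> np.ndarray:
        """Successive inter-CAR distances in bp."""
        return np.diff(self.car_positions)

    def spacing_summary(self) -> dict:
        """Median and quartiles of the inter-CAR spacing distribution."""
        if self.n_cars < 2:
            return {"median": np.nan, "q25": np.nan, "q75": np.nan, "n": 0}
        q25, med, q75 = np.percentile(self.spacings, [25, 50, 75])
        return {"median": float(med), "q25": float(q25), "q75": float(q75),
                "n": self.n_cars - 1}

    def with_occupancy(self, occupancy: np.ndarray) -> "CARMap":
        return replace(self, occupancy=np.asarray(occupancy, dtype=float))

    def with_high_residency(self, flags: np.ndarray) -> "CARMap":
        return replace(self, high_residency=np.asarray(flags, dtype=bool))


@dataclass
class ChIPTrack:
    """Binned, emulated cohesin ChIP-seq coverage."""

    bin_size: int
    coverage: np.ndarray
    chrom_length: int
    chrom_name: str = "chrS"

    def __post_init__(self):
        self.coverage = np.asarray(self.coverage, dtype=float)
        expected = -(-self.chrom_length // self.bin_size)
        if self.coverage.size != expected:
            raise ParameterError(
                f"coverage length {self.coverage.size} != ceil(L/bin) = {expected}")
        if not np.all(np.isfinite(self.coverage)) or np.any(self.coverage < 0):
            raise ParameterError("coverage must be finite and non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.coverage.size)

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size


@dataclass
class PeakSet:
    """Called peaks on a ChIP track: summit (bp), height (signal), width (bp)."""

    summits: np.ndarray
    heights: np.ndarray
    widths: np.ndarray

    def __post_init__(self):
        self.summits = np.asarray(self.summits, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.n_peaks:
            if np.any(np.diff(self.summits) <= 0):
                raise ParameterError("peak summits must be strictly increasing")
            if np.any(self.heights <= 0) or np.any(self.widths <= 0):
                raise ParameterError("peak heights and widths must be positive")

    @property
    def n_peaks(self) -> int:
        return int(self.summits.size)


def _draw_occupancy(rng: np.random.Generator, n: int, shape) -> np.ndarray:
    if isinstance(shape, (tuple, list)):
        return rng.beta(*shape, size=n)
    if shape == "residency-mixture":
        # exactly one CAR in ten is high-residency, so the top decile by
        # occupancy coincides with the generator's high class
        occ = 0.05 + 0.65 * rng.beta(3.0, 2.8, size=n)
        k = int(np.ceil(0.10 * n))
        high_idx = rng.choice(n, size=k, replace=False)
        occ[high_idx] = rng.uniform(0.88, 0.98, size=k)
        return occ
    raise ParameterError(f"unknown occupancy distribution {shape!r}")


def build_car_map(
    n_cars: int,
    chrom_length: int,
    spacing_median: float = 8_000.0,
    spacing_sigma: float = 0.45,
    spacing_clip: tuple = SPACING_CLIP,
    occupancy_shape="residency-mixture",
    centromere: Optional[int] = None,
    seed: int = 0,
    chrom_name: str = "chrS",
    edge_margin: int = 5_000,
) -> CARMap:
    """Generate a synthetic chromosome with CARs.

    Spacings between successive CARs are drawn from a log-normal with the
    requested median (right-skewed, like the observed peak-interval
    histogram), resampled until inside ``spacing_clip``.  Occupancies are
    drawn i.i.d. from ``occupancy_shape``: either a ``(a, b)`` tuple for a
    plain Beta, or the default ``"residency-mixture"`` — 90% of CARs from a
    Beta-shaped bulk confined to [0.05, 0.8] and 10% high-residency CARs in
    [0.85, 0.98] (overall mean ~0.5).  The two-class mixture mirrors the
    heavy-tailed cohesin peak heights in which the top decile of CARs stands
    clearly apart from the bulk.  If ``centromere`` is given, the nearest
    CAR is marked centromeric and assigned the maximum occupancy of the map.
    """
    if n_cars < 0:
        raise ParameterError("n_cars must be >= 0")
    if spacing_median < MIN_CAR_GAP:
        raise ParameterError(
            f"spacing_median {spacing_median} below minimum CAR gap {MIN_CAR_GAP}")
    if n_cars == 0:
        return CARMap(chrom_name, chrom_length, np.empty(0, dtype=np.int64),
                      np.empty(0), centromere_index=None)
    lo, hi = spacing_clip
    if chrom_length < 2 * edge_margin + n_cars * lo:
        raise SizingError(
            f"chromosome of {chrom_length} bp cannot host {n_cars} CARs "
            f"at minimum spacing {lo} bp")

    rng = np.random.default_rng(seed)
    mu = np.log(spacing_median)

    def draw_spacings(k: int) -> np.ndarray:
        out = rng.lognormal(mu, spacing_sigma, size=k)
        bad = (out < lo) | (out > hi)
        while bad.any():
            out[bad] = rng.lognormal(mu, spacing_sigma, size=int(bad.sum()))
            bad = (out < lo) | (out > hi)
        return out

    for _ in range(500):
        spacings = draw_spacings(n_cars)
        positions = edge_margin + np.cumsum(np.round(spacings)).astype(np.int64)
        if positions[-1] < chrom_length - edge_margin:
            break
    else:
        raise SizingError(
            f"could not place {n_cars} CARs with median spacing {spacing_median} "
            f"on a {chrom_length} bp chromosome")

    occupancy = _draw_occupancy(rng, n_cars, occupancy_shape)
    cen_index = None
    if centromere is not None:
        cen_index = int(np.argmin(np.abs(positions - centromere)))
        occupancy[cen_index] = occupancy.max()
    return CARMap(chrom_name, chrom_length, positions, occupancy,
                  centromere_index=cen_index)


def synthesize_chip(
    car_map: CARMap,
    depth: float = 2.0,
    peak_width: float = 1_000.0,
    peak_gain: float = 1_000.0,
    noise: bool = True,
    noise_seed: int = 0,
    bin_size: int = 100,
) -> ChIPTrack:
    """Emulate a cohesin ChIP-seq track from a CAR map.

    Each CAR contributes a Gaussian bump of full-width-at-half-maximum
    ``peak_width`` (~1 kb, the observed average peak width) whose *area* is
    ``peak_gain * occupancy`` — peak intensity reflects the probability of
    the CAR being occupied in a cell.  Background is Poisson around ``depth``
    per bin (constant ``depth`` with ``noise=False``).
    """
    if bin_size < 10:
        raise ParameterError("bin_size must be >= 10 bp")
    if depth < 0 or peak_width <= 0 or peak_gain < 0:
        raise ParameterError("depth/peak_width/peak_gain out of range")
    n_bins = -(-car_map.chrom_length // bin_size)
    if noise and depth > 0:
        rng = np.random.default_rng(noise_seed)
        coverage = rng.poisson(depth, size=n_bins).astype(float)
    else:
        coverage = np.full(n_bins, float(depth))

    sigma = peak_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # FWHM -> sigma
    edges = np.arange(n_bins + 1) * bin_size
    half_span = int(np.ceil(5 * sigma / bin_size))
    for pos, occ in zip(car_map.car_positions, car_map.occupancy):
        if occ == 0:
            continue
        b = int(pos // bin_size)
        b0, b1 = max(0, b - half_span), min(n_bins, b + half_span + 1)
        cdf = norm.cdf(edges[b0:b1 + 1], loc=pos, scale=sigma)
        coverage[b0:b1] += peak_gain * occ * np.diff(cdf)
    return ChIPTrack(bin_size, coverage, car_map.chrom_length, car_map.chrom_name)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="same")


def call_peaks(
    track: ChIPTrack,
    min_height: float,
    min_separation: float,
    smooth_bins: int = 3,
) -> PeakSet:
    """Threshold-and-local-maximum peak detector on a (smoothed) track.

    Local maxima above ``min_height`` are accepted greedily from the highest
    down, enforcing a summit separation of at least ``min_separation`` bp;
    ties go to the leftmost summit.  Width is the span above half-height.
    A flat track yields an empty PeakSet.
    """
    if min_separation < track.bin_size:
        raise ParameterError("min_separation must be >= bin_size")
    s = _smooth(track.coverage, smooth_bins)
    prev = np.concatenate([[-np.inf], s[:-1]])
    nxt = np.concatenate([s[1:], [-np.inf]])
    cand = np.flatnonzero((s > prev) & (s >= nxt) & (s >= min_height))
    if cand.size == 0:
        return PeakSet(np.empty(0), np.empty(0), np.empty(0))
    # greedy: highest first, leftmost wins ties
    order = np.lexsort((cand, -s[cand]))
    accepted: list = []
    min_sep_bins = min_separation / track.bin_size
    for idx in cand[order]:
        if all(abs(idx - a) >= min_sep_bins for a in accepted):
            accepted.append(int(idx))
    accepted.sort()

    summits, heights, widths = [], [], []
    for idx in accepted:
        h = s[idx]
        half = h / 2.0
        left = idx
        while left > 0 and s[left - 1] >= half:
            left -= 1
        right = idx
        while right < s.size - 1 and s[right + 1] >= half:
            right += 1
        summits.append((idx + 0.5) * track.bin_size)
        heights.append(float(h))
        widths.append((right - left + 1) * track.bin_size)
    return PeakSet(np.array(summits), np.array(heights), np.array(widths))


def classify_high_residency(obj, fraction: float = 0.10) -> np.ndarray:
    """Flag the top ``fraction`` of peaks (by height) or CARs (by occupancy).

    Exactly ``ceil(fraction * n)`` entries are flagged; ties are broken by
    the leftmost coordinate.  The top decile defines high-residency CARs,
    which act as barriers to loop expansion.
    """
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    if isinstance(obj, PeakSet):
        values, coords = obj.heights, obj.summits
    elif isinstance(obj, CARMap):
        values, coords = obj.occupancy, obj.car_positions
    else:
        raise ParameterError(f"cannot classify object of type {type(obj).__name__}")
    n = values.size
    flags = np.zeros(n, dtype=bool)
    if n == 0:
        return flags
    k = int(np.ceil(fraction * n))
    order = np.lexsort((coords, -values))
    flags[order[:k]] = True
    return flags


@dataclass
class OccupancyEstimate:
    """Per-CAR occupancy estimates recovered from ChIP peak heights."""

    values: np.ndarray        # NaN where no peak matched a CAR
    orphan_peaks: np.ndarray  # indices of peaks >2 kb from every CAR

    @property
    def n_matched(self) -> int:
        return int(np.isfinite(self.values).sum())


def estimate_occupancy(
    peaks: PeakSet,
    calibration: float,
    car_map: CARMap,
    background: float = 0.0,
    max_match_dist: float = 2_000.0,
) -> OccupancyEstimate:
    """Invert ChIP peak heights to occupancy: (height - background)/calibration.

    Each peak is matched to its nearest CAR; peaks beyond ``max_match_dist``
    of any CAR are reported as orphans and excluded.  Estimates are clipped
    to [0, 1]; CARs without a matched peak get NaN.
    """
    if calibration <= 0:
        raise ParameterError("calibration must be > 0")
    values = np.full(car_map.n_cars, np.nan)
    orphans = []
    if peaks.n_peaks == 0 or car_map.n_cars == 0:
        return OccupancyEstimate(values, np.array(orphans, dtype=int))
    dist_to_car = np.abs(peaks.summits[:, None] - car_map.car_positions[None, :])
    nearest_car = np.argmin(dist_to_car, axis=1)
    nearest_dist = dist_to_car[np.arange(peaks.n_peaks), nearest_car]
    # closest peaks claim their CAR first, so a CAR keeps its nearest match
    for p in np.argsort(nearest_dist, kind="stable"):
        if nearest_dist[p] > max_match_dist:
            orphans.append(int(p))
            continue
        c = nearest_car[p]
        if np.isnan(values[c]):
            est = (peaks.heights[p] - background) / calibration
            values[c] = float(np.clip(est, 0.0, 1.0))
    orphans.sort()
    return OccupancyEstimate(values, np.array(orphans, dtype=int))


def chip_calibration(
    peak_gain: float,
    peak_width: float = 1_000.0,
    bin_size: int = 100,
    smooth_bins: int = 3,
    n_offsets: int = 16,
) -> float:
    """Expected smoothed peak height per unit occupancy for given track settings.

    Computed by placing a unit-occupancy bump at several sub-bin offsets,
    applying the same binning and smoothing as the peak caller, and averaging
    the maxima.  This is the ``calibration`` constant for estimate_occupancy.
    """
    sigma = peak_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    span = int(np.ceil(10 * sigma / bin_size))
    edges = np.arange(2 * span + 1) * bin_size
    heights = []
    for off in np.linspace(0, bin_size, n_offsets, endpoint=False):
        center = span * bin_size + off
        prof = peak_gain * np.diff(norm.cdf(edges, loc=center, scale=sigma))
        heights.append(_smooth(prof, smooth_bins).max())
    return float(np.mean(heights))
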