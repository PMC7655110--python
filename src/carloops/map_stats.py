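"""Aggregate contact-map statistics.

Contact-decay curves (log-spaced distance bins, 100 bp - 1 Mb, with sliding
log-log slopes), pile-ups at anchor pairs (APA) with the center-over-corner
enrichment ratio, the CAR-interval (+1 ... +10) pile-up series, and the
high-residency barrier contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np

from .errors import AnalysisError, ParameterError
from .contacts import ContactMatrix, OEMatrix, observed_over_expected
from .genome_model import PeakSet

#: pairing separation cap applied in all peak-pair operations, bp
MAX_PAIR_SEPARATION = 100_000


@dataclass
class DecayCurve:
    """Normalized contact probability vs genomic distance.

    ``mass`` is the fraction of retained contacts per log-spaced bin (sums
    to 1); ``density`` is mass divided by bin width in bp — the quantity
    whose log-log slope is the decay exponent.
    """

    edges: np.ndarray
    mass: np.ndarray
    density: np.ndarray
    n_contacts: float

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    @property
    def n_bins(self) -> int:
        return int(self.mass.size)


def log_bin_edges(d_min: float = 100.0, d_max: float = 1e6,
                  bins_per_decade: int = 8) -> np.ndarray:
    """Exponentially increasing distance-bin edges from ``d_min`` to ``d_max``."""
    n = int(np.ceil(np.log10(d_max / d_min) * bins_per_decade))
    return d_min * 10 ** (np.arange(n + 1) / bins_per_decade)


def contact_decay(
    source: Union[ContactMatrix, np.ndarray],
    min_dist: float = 100.0,
    edges: Optional[np.ndarray] = None,
) -> DecayCurve:
    """Histogram intra-chromosomal contact distances into log-spaced bins.

    ``source`` is either a ContactMatrix (distances taken per diagonal,
    weighted by summed counts) or a 1-D array of contact distances in bp.
    Contacts closer than ``min_dist`` (default 100 bp) are removed to
    suppress self-ligation artifacts; an empty result is an error.
    """
    if edges is None:
        edges = log_bin_edges()
    if isinstance(source, ContactMatrix):
        n = source.n_bins
        dists = np.arange(1, n) * float(source.bin_size)
        weights = np.array([np.diagonal(source.counts, d).sum() for d in range(1, n)])
    else:
        dists = np.asarray(source, dtype=float)
        weights = np.ones_like(dists)
    keep = (dists >= min_dist) & (dists >= edges[0]) & (dists < edges[-1])
    dists, weights = dists[keep], weights[keep]
    total = weights.sum()
    if total <= 0:
        raise AnalysisError("no contacts left after distance filtering")
    hist, _ = np.histogram(dists, bins=edges, weights=weights)
    mass = hist / total
    density = mass / np.diff(edges)
    return DecayCurve(edges, mass, density, float(total))


def decay_slope(curve: DecayCurve, window: int = 5) -> Tuple[np.ndarray, np.ndarray]:
    """Sliding-window log-log slopes of the decay curve.

    Least-squares slope of log10(density) vs log10(distance) in each window
    of ``window`` consecutive bins, assigned to the window's (geometric)
    center.  Windows containing empty bins give NaN.
    """
    if window < 2:
        raise ParameterError("window must be >= 2")
    if window > curve.n_bins:
        raise AnalysisError(f"window {window} exceeds {curve.n_bins} curve bins")
    x = np.log10(curve.centers)
    with np.errstate(divide="ignore"):
        y = np.log10(curve.density)
    n_out = curve.n_bins - window + 1
    centers = np.empty(n_out)
    slopes = np.empty(n_out)
    for i in range(n_out):
        xs, ys = x[i:i + window], y[i:i + window]
        centers[i] = 10 ** xs.mean()
        if np.all(np.isfinite(ys)):
            slopes[i] = np.polyfit(xs, ys, 1)[0]
        else:
            slopes[i] = np.nan
    return centers, slopes


def fit_decay_exponent(curve: DecayCurve, s_min: float, s_max: float) -> float:
    """Single log-log slope of density over the distance range [s_min, s_max]."""
    c = curve.centers
    keep = (c >= s_min) & (c <= s_max) & (curve.density > 0)
    if keep.sum() < 2:
        raise AnalysisError("fewer than two usable bins in the fit range")
    return float(np.polyfit(np.log10(c[keep]), np.log10(curve.density[keep]), 1)[0])


@dataclass
class Pileup:
    """Aggregate sub-matrix stacked at anchor pairs."""

    matrix: np.ndarray
    n_stacked: int
    res: int
    half_width: int
    norm: str
    n_dropped_edge: int = 0
    n_dropped_diag: int = 0

    @property
    def side(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def center(self) -> int:
        return self.side // 2


def _oe_values(source, norm: str) -> Tuple[np.ndarray, int]:
    if isinstance(source, OEMatrix):
        return source.values, source.bin_size
    if isinstance(source, ContactMatrix):
        if norm == "distance":
            return observed_over_expected(source).values, source.bin_size
        if norm == "balanced":
            return source.balanced(), source.bin_size
        raise ParameterError(f"unknown pileup norm {norm!r}")
    raise ParameterError("source must be a ContactMatrix or OEMatrix")


def pileup_at_pairs(
    source: Union[ContactMatrix, OEMatrix],
    pairs: Sequence[Tuple[float, float]],
    half_width: int = 5_000,
    res: int = 200,
    norm: str = "distance",
) -> Pileup:
    """Mean of normalized sub-matrices centered at each anchor pair.

    Windows span +/- ``half_width`` around each pair on a grid of ``res``
    (default +/-5 kb at 200 bp -> 51 x 51, odd side so the center pixel is
    defined).  Pairs whose separation is <= ``half_width`` (too close to the
    diagonal) and pairs whose window leaves the matrix are dropped and
    counted.  Zero usable pairs is an error.
    """
    values, bin_size = _oe_values(source, norm)
    if bin_size != res:
        raise ParameterError(f"matrix bin size {bin_size} != requested res {res}")
    w = int(round(half_width / res))
    n = values.shape[0]
    stack = []
    n_edge = n_diag = 0
    for a, b in pairs:
        a, b = (a, b) if a <= b else (b, a)
        if b - a <= half_width:
            n_diag += 1
            continue
        bi, bj = int(a // res), int(b // res)
        if bi - w < 0 or bj - w < 0 or bi + w >= n or bj + w >= n:
            n_edge += 1
            continue
        stack.append(values[bi - w:bi + w + 1, bj - w:bj + w + 1])
    if not stack:
        raise AnalysisError("no usable anchor pairs for the pile-up")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.stack(stack), axis=0)
    return Pileup(mean, len(stack), res, half_width, norm, n_edge, n_diag)


def enrichment_ratio(p: Pileup, corner_size: int = 14,
                     center: str = "pixel") -> float:
    """Center pixel over the mean of the four corner sub-matrices.

    ``corner_size`` x ``corner_size`` blocks are taken flush with the four
    corners of the pile-up window.  Returns NaN when the corner mean is zero
    or undefined.  ``center='mean3'`` averages the 3x3 block around the
    center instead of the single central pixel.
    """
    cs = corner_size
    if 2 * cs >= p.side:
        raise ParameterError("corner blocks overlap; reduce corner_size")
    c = p.center
    if center == "pixel":
        center_val = p.matrix[c, c]
    elif center == "mean3":
        center_val = np.nanmean(p.matrix[c - 1:c + 2, c - 1:c + 2])
    else:
        raise ParameterError(f"unknown center mode {center!r}")
    corners = np.concatenate([
        p.matrix[:cs, :cs].ravel(), p.matrix[:cs, -cs:].ravel(),
        p.matrix[-cs:, :cs].ravel(), p.matrix[-cs:, -cs:].ravel()])
    corner_mean = np.nanmean(corners) if np.isfinite(corners).any() else np.nan
    if not np.isfinite(corner_mean) or corner_mean == 0 or not np.isfinite(center_val):
        return float("nan")
    return float(center_val / corner_mean)


@dataclass
class IntervalSeries:
    """Enrichment-ratio curve over CAR-interval pile-ups (+1 ... +k)."""

    ks: np.ndarray
    ratios: np.ndarray      # NaN where no usable pairs
    n_pairs: np.ndarray
    pileups: list

    def max_k_above(self, threshold: float) -> int:
        """Largest k whose ratio exceeds ``threshold`` (0 if none)."""
        above = np.flatnonzero(np.nan_to_num(self.ratios) > threshold)
        return int(self.ks[above.max()]) if above.size else 0


def interval_pileup_series(
    source: Union[ContactMatrix, OEMatrix],
    peaks: PeakSet,
    k_range: Iterable[int] = range(1, 11),
    half_width: int = 5_000,
    res: int = 200,
    norm: str = "distance",
    max_separation: float = MAX_PAIR_SEPARATION,
    corner_size: int = 14,
) -> IntervalSeries:
    """Pile-up and enrichment ratio for peak pairs k intervals apart.

    For each k the pile-up stacks all (peak_i, peak_{i+k}) pairs with
    separation below ``max_separation`` (100 kb cap); entries with no usable
    pairs yield NaN ratios and None pile-ups.
    """
    summits = peaks.summits
    ks, ratios, n_pairs, pileups = [], [], [], []
    for k in k_range:
        ks.append(k)
        if k < 1 or k >= peaks.n_peaks:
            ratios.append(np.nan)
            n_pairs.append(0)
            pileups.append(None)
            continue
        cand = [(summits[i], summits[i + k]) for i in range(peaks.n_peaks - k)
                if summits[i + k] - summits[i] <= max_separation]
        try:
            p = pileup_at_pairs(source, cand, half_width, res, norm)
        except AnalysisError:
            ratios.append(np.nan)
            n_pairs.append(0)
            pileups.append(None)
            continue
        ratios.append(enrichment_ratio(p, corner_size))
        n_pairs.append(p.n_stacked)
        pileups.append(p)
    return IntervalSeries(np.array(ks), np.array(ratios), np.array(n_pairs), pileups)


def barrier_contrast(
    source: Union[ContactMatrix, OEMatrix],
    peaks: PeakSet,
    flags: np.ndarray,
    half_width: int = 5_000,
    res: int = 200,
    norm: str = "distance",
    max_separation: float = MAX_PAIR_SEPARATION,
    corner_size: int = 14,
) -> Tuple[float, float, int, int]:
    """Pile-up enrichment of +2 pairs with vs without a high-residency middle.

    Returns ``(ratio_across_barrier, ratio_no_barrier, n_across, n_no)``;
    an empty class yields NaN for its ratio.  A lower across-barrier ratio
    means high-residency CARs block loop expansion.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size != peaks.n_peaks:
        raise ParameterError("flags must align with peaks")
    across, plain = [], []
    for i in range(peaks.n_peaks - 2):
        if peaks.summits[i + 2] - peaks.summits[i] > max_separation:
            continue
        pair = (peaks.summits[i], peaks.summits[i + 2])
        (across if flags[i + 1] else plain).append(pair)

    def ratio_of(pairs):
        if not pairs:
            return float("nan"), 0
        try:
            p = pileup_at_pairs(source, pairs, half_width, res, norm)
        except AnalysisError:
            return float("nan"), 0
        return enrichment_ratio(p, corner_size), p.n_stacked

    r_across, n_across = ratio_of(across)
    r_plain, n_plain = ratio_of(plain)
    return r_across, r_plain, n_across, n_plain
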