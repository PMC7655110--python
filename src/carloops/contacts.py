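"""Render a loop population into a Micro-C-like binned contact matrix.

The expected matrix is a sum of three ingredients:

* a distance-decay background, contact probability proportional to
  ``(s + s0) ** -alpha`` with genomic separation ``s``;
* a focal Gaussian spot at every loop's anchor pair, of spread
  ``anchor_sigma`` (default 500 bp, so ~90% of spot mass falls within
  +/- 1 kb — anchors are confined within a 1 kb region) and mass
  proportional to loop frequency;
* a "loop domain" square: sequences inside a loop interact more, modeled as
  a multiplicative boost of the background over the intra-loop block.

Counts are Poisson-sampled around the expected matrix scaled to a total
read budget, symmetrized, and can then be ICE-balanced and
distance-normalized (observed over expected).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.stats import norm

from .errors import BalanceError, ParameterError
from .genome_model import CARMap
from .residency import PopulationLoops


@dataclass
class RenderParams:
    """Free parameters of the contact-map renderer.

    alpha, s0
        Background decay exponent and softening offset (bp).
    focal_weight
        Fraction of total reads contributed by one loop of frequency 1.
    domain_weight
        Multiplicative intra-loop boost of the background per unit loop
        frequency.
    anchor_sigma
        Gaussian spread (bp) of each focal spot.
    total_reads
        Total sampled contact pairs (sum over the upper triangle).
    seed
        Poisson sampling seed; ``noise=False`` returns expected values.
    """

    alpha: float = 1.0
    s0: float = 1_000.0
    focal_weight: float = 0.002
    domain_weight: float = 0.3
    anchor_sigma: float = 500.0
    total_reads: float = 20_000_000.0
    seed: int = 0
    noise: bool = True

    def __post_init__(self):
        if self.alpha <= 0:
            raise ParameterError("alpha must be > 0")
        if self.focal_weight < 0 or self.domain_weight < 0:
            raise ParameterError("weights must be >= 0")
        if self.total_reads <= 0:
            raise ParameterError("total_reads must be > 0")


@dataclass
class ContactMatrix:
    """Binned symmetric contact counts for one chromosome."""

    bin_size: int
    counts: np.ndarray
    chrom_name: str
    chrom_length: int
    weights: Optional[np.ndarray] = None   # per-bin balancing weights, NaN = masked
    balance_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        expected = -(-self.chrom_length // self.bin_size)
        if self.counts.shape != (expected, expected):
            raise ParameterError(
                f"counts shape {self.counts.shape} != ({expected}, {expected})")
        if np.any(self.counts < 0):
            raise ParameterError("contact counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.counts.shape[0])

    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    def balanced(self) -> np.ndarray:
        """Counts scaled by balancing weights; masked bins become NaN."""
        if self.weights is None:
            raise BalanceError("matrix has no balancing weights; run ice_balance")
        return self.counts * np.outer(self.weights, self.weights)

    def mask(self) -> np.ndarray:
        """Boolean mask of blocked (low-coverage) bins."""
        if self.weights is None:
            return np.zeros(self.n_bins, dtype=bool)
        return ~np.isfinite(self.weights)

    def bin_of(self, pos: float) -> int:
        return min(self.n_bins - 1, int(pos // self.bin_size))


def _gauss_bin_mass(positions_bp: np.ndarray, center: float, sigma: float,
                    bin_size: int) -> np.ndarray:
    """Exact per-bin mass of a unit Gaussian, via CDF differences."""
    edges = np.append(positions_bp, positions_bp[-1] + bin_size)
    cdf = norm.cdf(edges, loc=center, scale=sigma)
    return np.diff(cdf)


def render_map(
    pop: PopulationLoops,
    car_map: CARMap,
    params: RenderParams = RenderParams(),
    bin_size: int = 200,
) -> ContactMatrix:
    """Render a loop population into a binned contact matrix.

    An empty population yields a background-only matrix (the cohesin-null
    case).  With ``params.noise`` the upper triangle is Poisson-sampled so
    that the expected upper-triangle total equals ``params.total_reads``;
    otherwise the scaled expected matrix is returned.  Symmetric by
    construction and deterministic given ``params.seed``.
    """
    n = -(-car_map.chrom_length // bin_size)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :]) * float(bin_size)
    background = (sep + params.s0) ** (-params.alpha)
    background /= background.sum()

    expected = background.copy()

    # loop-domain squares: multiplicative boost of background inside each loop
    if params.domain_weight > 0:
        for li, ri, f in zip(pop.left_car, pop.right_car, pop.frequency):
            b0 = int(car_map.car_positions[li] // bin_size)
            b1 = int(car_map.car_positions[ri] // bin_size)
            blk = slice(b0, min(b1 + 1, n))
            expected[blk, blk] += params.domain_weight * f * background[blk, blk]

    # focal anchor-anchor spots (positioned loops and unpositioned records)
    bp = (idx * bin_size).astype(float)
    w = int(np.ceil(4 * params.anchor_sigma / bin_size))

    def add_focal(a: float, b: float, mass: float) -> None:
        bi, bj = int(a // bin_size), int(b // bin_size)
        i0, i1 = max(0, bi - w), min(n, bi + w + 1)
        j0, j1 = max(0, bj - w), min(n, bj + w + 1)
        gi = _gauss_bin_mass(bp[i0:i1], a, params.anchor_sigma, bin_size)
        gj = _gauss_bin_mass(bp[j0:j1], b, params.anchor_sigma, bin_size)
        expected[i0:i1, j0:j1] += mass * np.outer(gi, gj)

    if params.focal_weight > 0:
        for li, ri, f in zip(pop.left_car, pop.right_car, pop.frequency):
            add_focal(float(car_map.car_positions[li]),
                      float(car_map.car_positions[ri]),
                      f * params.focal_weight)
        if pop.unpositioned.size and pop.n_cells > 0:
            for lb, rb, _, _ in pop.unpositioned:
                add_focal(float(lb), float(rb),
                          params.focal_weight / pop.n_cells)

    # focal spots were added above the diagonal only: mirror the upper triangle
    upper = np.triu(expected)
    expected = upper + upper.T - np.diag(np.diag(expected))

    upper_mask = np.triu(np.ones((n, n), dtype=bool))
    scale = params.total_reads / expected[upper_mask].sum()
    lam = expected * scale
    if params.noise:
        rng = np.random.default_rng(params.seed)
        counts = np.zeros((n, n))
        counts[upper_mask] = rng.poisson(lam[upper_mask])
        counts = counts + np.triu(counts, 1).T
    else:
        counts = lam
    return ContactMatrix(bin_size, counts, car_map.chrom_name, car_map.chrom_length)


def ice_balance(
    m: ContactMatrix,
    tol: float = 1e-9,
    max_iter: int = 500,
    mask_low_coverage: float = 0.02,
) -> ContactMatrix:
    """Iterative correction: per-bin weights equalizing unmasked row sums.

    Bins with zero coverage, and bins below the ``mask_low_coverage``
    quantile of nonzero coverage, are blocked before normalization and get
    NaN weights.  Iterates until the maximum relative row-sum deviation
    falls below ``tol`` or ``max_iter`` is reached (non-convergence is
    recorded in ``balance_info``, not raised).
    """
    counts = m.counts
    if counts.sum() == 0:
        raise BalanceError("cannot balance an all-zero matrix")
    coverage = counts.sum(axis=0)
    masked = coverage == 0
    nonzero = coverage[coverage > 0]
    if mask_low_coverage > 0 and nonzero.size:
        cut = np.quantile(nonzero, mask_low_coverage)
        masked |= coverage < cut
    active = ~masked
    if not active.any():
        raise BalanceError("all bins masked; nothing to balance")

    sub = counts[np.ix_(active, active)]
    b = np.ones(int(active.sum()))
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        s = b * (sub @ b)
        mean = s.mean()
        if mean == 0:
            raise BalanceError("balancing degenerated to zero row sums")
        d = s / mean
        b /= np.where(d > 0, np.sqrt(d), 1.0)
        if np.abs(d - 1).max() < tol:
            converged = True
            break
    # normalize so balanced row sums are ~1 on unmasked rows
    s = b * (sub @ b)
    b /= np.sqrt(s.mean())
    weights = np.full(m.n_bins, np.nan)
    weights[active] = b
    info = {"converged": converged, "n_iter": n_iter,
            "max_dev": float(np.abs(s / s.mean() - 1).max()),
            "n_masked": int(masked.sum())}
    return replace(m, weights=weights, balance_info=info)


@dataclass
class OEMatrix:
    """Distance-normalized (observed over expected) contact values."""

    values: np.ndarray              # NaN where undefined/masked
    bin_size: int
    expected_by_distance: np.ndarray
    chrom_name: str = "chrS"

    @property
    def n_bins(self) -> int:
        return int(self.values.shape[0])


def expected_by_distance(matrix: np.ndarray) -> np.ndarray:
    """Mean contact value per diagonal |i - j|, NaN-aware."""
    n = matrix.shape[0]
    out = np.empty(n)
    for d in range(n):
        diag = np.diagonal(matrix, offset=d)
        out[d] = np.nanmean(diag) if np.isfinite(diag).any() else np.nan
    return out


def observed_over_expected(m: ContactMatrix, use_balanced: bool = True) -> OEMatrix:
    """Divide each entry by the mean of its diagonal.

    Uses balanced values when weights are present (recommended); diagonals
    whose mean is zero or undefined yield NaN, never infinities.
    """
    base = m.balanced() if (use_balanced and m.is_balanced) else m.counts.astype(float)
    exp = expected_by_distance(base)
    n = m.n_bins
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    denom = exp[sep]
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = np.where(denom > 0, base / denom, np.nan)
    return OEMatrix(oe, m.bin_size, exp, m.chrom_name)


def coarsen(m: ContactMatrix, factor: int) -> ContactMatrix:
    """Sum counts into bins ``factor`` times larger (last bin may be partial)."""
    if factor < 1:
        raise ParameterError("factor must be >= 1")
    if factor == 1:
        return replace(m, weights=None, balance_info={})
    n_new = -(-m.chrom_length // (m.bin_size * factor))
    pad = n_new * factor - m.n_bins
    c = np.pad(m.counts, ((0, pad), (0, pad)))
    c = c.reshape(n_new, factor, n_new, factor).sum(axis=(1, 3))
    return ContactMatrix(m.bin_size * factor, c, m.chrom_name, m.chrom_length)
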