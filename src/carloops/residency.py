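"""Generative cohesin-residency loop model.

In each cell every CAR is independently occupied by stably bound cohesin
with its occupancy probability.  Loop-extruding cohesin then forms a
positioned loop between every pair of *consecutive occupied* CARs: an
unoccupied CAR does not stop extrusion, so in cells where an intermediate
CAR is cohesin-free the loop expands to the next occupied CAR further down.
Aggregating loops over a population turns per-cell configurations into a
loop -> frequency table whose focal spots, squares and stripes are rendered
by :mod:`carloops.contacts`.

Two loop-formation modes exist:

* ``consecutive`` (default): the endpoint rule above, applied directly.
* ``extruder``: explicit extruders load uniformly, grow symmetrically with a
  finite processivity, and halt per side at the first occupied CAR.  Anchors
  that stop at an occupied CAR are *positioned*; a side that exhausts its
  processivity (or hits a chromosome end) leaves an *unpositioned* anchor.
  This mode produces the centromeric stripes of the Pds5-depletion scenario.

Named scenarios transform occupancies to emulate protein depletions:
WT/BRN1 identity, MCD1 total loss, WPL1 halving, PDS5 arm depletion with
pericentric retention and raised processivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .errors import ConfigError, ParameterError
from .genome_model import CARMap

SCENARIO_NAMES = ("WT", "MCD1", "BRN1", "WPL1", "PDS5")

#: default distance from the centromere that counts as pericentric, bp
PERICENTRIC_RADIUS = 30_000

#: default extruder processivity (total extruded length per extruder), bp
DEFAULT_PROCESSIVITY = 50_000

#: default extruder density: one per this many bp of chromosome
EXTRUDER_SPACING = 30_000


@dataclass
class OccupancyState:
    """Boolean cohesin occupancy of every CAR in one cell."""

    occupied: np.ndarray
    cell_id: int

    def __post_init__(self):
        self.occupied = np.asarray(self.occupied, dtype=bool)


@dataclass
class CellLoopSet:
    """Loops formed in a single cell.

    Anchors are bp coordinates; ``left_car``/``right_car`` hold the CAR index
    for positioned anchors and -1 for unpositioned ones.
    """

    left: np.ndarray
    right: np.ndarray
    left_car: np.ndarray
    right_car: np.ndarray

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=np.int64)
        self.right = np.asarray(self.right, dtype=np.int64)
        self.left_car = np.asarray(self.left_car, dtype=np.int64)
        self.right_car = np.asarray(self.right_car, dtype=np.int64)
        if np.any(self.left >= self.right):
            raise ParameterError("loop anchors must satisfy left < right")

    @property
    def n_loops(self) -> int:
        return int(self.left.size)

    @classmethod
    def empty(cls) -> "CellLoopSet":
        z = np.empty(0, dtype=np.int64)
        return cls(z, z, z, z)


@dataclass
class PopulationLoops:
    """Per-cell loops aggregated over a simulated population.

    ``pair_index`` maps (left_car, right_car) -> frequency in (0, 1] for
    loops with both anchors positioned.  Loops with at least one
    unpositioned anchor are kept as individual coordinate records.
    """

    left_car: np.ndarray
    right_car: np.ndarray
    frequency: np.ndarray
    n_cells: int
    unpositioned: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_loops_total: int = 0

    def __post_init__(self):
        self.left_car = np.asarray(self.left_car, dtype=np.int64)
        self.right_car = np.asarray(self.right_car, dtype=np.int64)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if self.unpositioned is None:
            self.unpositioned = np.empty((0, 4), dtype=np.int64)
        self.unpositioned = np.asarray(self.unpositioned, dtype=np.int64).reshape(-1, 4)
        if self.frequency.size and (np.any(self.frequency <= 0) or np.any(self.frequency > 1)):
            raise ParameterError("loop frequencies must lie in (0, 1]")

    @property
    def n_pairs(self) -> int:
        return int(self.left_car.size)

    def pair_frequency(self, i: int, j: int) -> float:
        hit = (self.left_car == i) & (self.right_car == j)
        return float(self.frequency[hit][0]) if hit.any() else 0.0

    def spans(self) -> np.ndarray:
        """CAR-interval span of every positioned pair."""
        return self.right_car - self.left_car


@dataclass
class Scenario:
    """A named depletion: an occupancy transform plus extruder overrides."""

    name: str
    occupancy_transform: Callable[[CARMap], np.ndarray]
    extruder_overrides: Dict[str, float] = field(default_factory=dict)


def sample_occupancy(car_map: CARMap, cell_id: int, seed: int = 0) -> OccupancyState:
    """Occupy each CAR independently with its occupancy probability."""
    rng = np.random.default_rng([seed, cell_id])
    occupied = rng.random(car_map.n_cars) < car_map.occupancy
    return OccupancyState(occupied, cell_id)


def form_loops_consecutive(state: OccupancyState, car_map: CARMap) -> CellLoopSet:
    """One loop between every pair of consecutive occupied CARs."""
    occ = np.flatnonzero(state.occupied)
    if occ.size < 2:
        return CellLoopSet.empty()
    li, ri = occ[:-1], occ[1:]
    return CellLoopSet(car_map.car_positions[li], car_map.car_positions[ri], li, ri)


def extrude_cell(
    state: OccupancyState,
    car_map: CARMap,
    n_extruders: int,
    processivity: float,
    seed=0,
    processivity_distribution: str = "fixed",
    loading: str = "uniform",
    loading_center: Optional[float] = None,
    loading_sigma: float = 5_000.0,
) -> CellLoopSet:
    """Explicit loop extrusion in one cell.

    Each extruder loads at a random position and grows symmetrically; each
    side halts permanently at the first occupied CAR it reaches (or at a
    chromosome end), and growth stops when the total extruded length reaches
    the extruder's processivity budget.  Extruders act independently (no
    collisions) and are not blocked by unoccupied CARs.

    ``processivity_distribution`` is ``"fixed"`` (every extruder gets exactly
    ``processivity``) or ``"exponential"`` (budgets drawn exponentially with
    mean ``processivity``, as for a constant detachment rate — this is what
    spreads unpositioned anchors into continuous stripes).

    ``loading`` is ``"uniform"`` over the chromosome or ``"centromeric"``
    (Gaussian around ``loading_center`` with spread ``loading_sigma``), the
    latter modeling extrusion emanating from the centromere.
    """
    if n_extruders < 0:
        raise ParameterError("n_extruders must be >= 0")
    if processivity <= 0:
        raise ParameterError("processivity must be > 0")
    if processivity_distribution not in ("fixed", "exponential"):
        raise ParameterError(
            f"unknown processivity distribution {processivity_distribution!r}")
    if n_extruders == 0:
        return CellLoopSet.empty()
    rng = np.random.default_rng(seed if np.ndim(seed) else [int(seed)])
    L = car_map.chrom_length
    occ_idx = np.flatnonzero(state.occupied)
    occ_pos = car_map.car_positions[occ_idx]

    if loading == "uniform":
        loads = rng.uniform(0, L, size=n_extruders)
    elif loading == "centromeric":
        if loading_center is None:
            raise ParameterError("centromeric loading needs loading_center")
        loads = np.clip(rng.normal(loading_center, loading_sigma, size=n_extruders),
                        1, L - 2)
    else:
        raise ParameterError(f"unknown loading mode {loading!r}")
    if processivity_distribution == "exponential":
        budgets = rng.exponential(processivity, size=n_extruders)
    else:
        budgets = np.full(n_extruders, float(processivity))
    lefts = np.empty(n_extruders, dtype=np.int64)
    rights = np.empty(n_extruders, dtype=np.int64)
    lcar = np.full(n_extruders, -1, dtype=np.int64)
    rcar = np.full(n_extruders, -1, dtype=np.int64)

    ins = np.searchsorted(occ_pos, loads)
    for e in range(n_extruders):
        u = loads[e]
        k = ins[e]
        proc = budgets[e]
        # distance to the nearest occupied CAR on each side (inf if none)
        if k > 0:
            dl, cl = u - occ_pos[k - 1], occ_idx[k - 1]
        else:
            dl, cl = np.inf, -1
        if k < occ_pos.size:
            dr, cr = occ_pos[k] - u, occ_idx[k]
        else:
            dr, cr = np.inf, -1
        cap_l = min(dl, u)          # chromosome start also stops growth
        cap_r = min(dr, L - 1 - u)  # chromosome end likewise
        # phase 1: both sides grow together
        m = min(cap_l, cap_r, proc / 2.0)
        ext_l = ext_r = m
        budget = proc - 2.0 * m
        # phase 2: if one side halted with budget left, the other continues
        if budget > 0:
            if cap_l <= cap_r and ext_l >= cap_l:
                ext_r = min(cap_r, m + budget)
            elif cap_r < cap_l and ext_r >= cap_r:
                ext_l = min(cap_l, m + budget)
        lefts[e] = int(round(u - ext_l))
        rights[e] = int(round(u + ext_r))
        if ext_l == dl:
            lcar[e] = cl
        if ext_r == dr:
            rcar[e] = cr
    good = lefts < rights  # zero-span extrusions (loaded exactly on a CAR pair) dropped
    return CellLoopSet(lefts[good], rights[good], lcar[good], rcar[good])


def default_n_extruders(chrom_length: int) -> int:
    """Order-of-magnitude extruder count: one per 30 kb of chromosome."""
    return max(1, int(round(chrom_length / EXTRUDER_SPACING)))


def simulate_population(
    car_map: CARMap,
    n_cells: int,
    mode: str = "consecutive",
    params: Optional[dict] = None,
    seed: int = 0,
) -> PopulationLoops:
    """Simulate ``n_cells`` independent cells and aggregate their loops.

    ``params`` (extruder mode) may set ``n_extruders`` and ``processivity``.
    Deterministic given ``seed``; cell ``c`` reuses the stream of
    :func:`sample_occupancy` with ``(seed, c)``.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if mode not in ("consecutive", "extruder"):
        raise ConfigError(f"unknown simulation mode: {mode!r}")
    params = dict(params or {})
    n_ext = int(params.get("n_extruders", default_n_extruders(car_map.chrom_length)))
    proc = float(params.get("processivity", DEFAULT_PROCESSIVITY))
    proc_dist = str(params.get("processivity_distribution", "fixed"))
    loading = str(params.get("loading", "uniform"))
    loading_center = params.get("loading_center")
    if loading == "centromeric" and loading_center is None:
        if car_map.centromere_index is None:
            raise ConfigError("centromeric loading needs a centromere")
        loading_center = float(car_map.car_positions[car_map.centromere_index])
    loading_sigma = float(params.get("loading_sigma", 5_000.0))

    counts: Dict[Tuple[int, int], int] = {}
    unpositioned: List[Tuple[int, int, int, int]] = []
    total = 0
    for c in range(n_cells):
        state = sample_occupancy(car_map, cell_id=c, seed=seed)
        if mode == "consecutive":
            cell = form_loops_consecutive(state, car_map)
        else:
            cell = extrude_cell(state, car_map, n_ext, proc, seed=[seed, c, 977],
                                processivity_distribution=proc_dist,
                                loading=loading, loading_center=loading_center,
                                loading_sigma=loading_sigma)
        total += cell.n_loops
        seen = set()  # frequency = fraction of cells containing the pair
        for li, ri, lb, rb in zip(cell.left_car, cell.right_car, cell.left, cell.right):
            if li >= 0 and ri >= 0:
                key = (int(li), int(ri))
                if key not in seen:
                    seen.add(key)
                    counts[key] = counts.get(key, 0) + 1
            else:
                unpositioned.append((int(lb), int(rb), int(li), int(ri)))
    if counts:
        keys = sorted(counts)
        left = np.array([k[0] for k in keys], dtype=np.int64)
        right = np.array([k[1] for k in keys], dtype=np.int64)
        freq = np.array([counts[k] / n_cells for k in keys])
    else:
        left = right = np.empty(0, dtype=np.int64)
        freq = np.empty(0)
    upos = np.array(unpositioned, dtype=np.int64).reshape(-1, 4)
    return PopulationLoops(left, right, freq, n_cells, upos, total)


def _pds5_transform(car_map: CARMap, pericentric_radius: float,
                    arm_factor: float, pericentric_factor: float) -> np.ndarray:
    if car_map.centromere_index is None:
        raise ConfigError("PDS5 scenario requires a CAR map with a centromere")
    cen_pos = car_map.car_positions[car_map.centromere_index]
    dist = np.abs(car_map.car_positions - cen_pos)
    occ = car_map.occupancy.copy()
    arm = dist > pericentric_radius
    occ[arm] *= arm_factor
    peri = (~arm) & (np.arange(car_map.n_cars) != car_map.centromere_index)
    occ[peri] *= pericentric_factor
    return occ


def get_scenario(
    name: str,
    pericentric_radius: float = PERICENTRIC_RADIUS,
    arm_factor: float = 0.05,
    pericentric_factor: float = 0.7,
    processivity_factor: float = 10.0,
) -> Scenario:
    """Look up a named depletion scenario.

    WT and BRN1 (condensin) leave occupancy untouched; MCD1 removes all
    cohesin; WPL1 halves every occupancy; PDS5 depletes chromosome arms
    (> ``pericentric_radius`` from the centromere) to ``arm_factor``, scales
    pericentric CARs by ``pericentric_factor``, keeps the centromeric CAR
    unchanged, raises extruder processivity by ``processivity_factor`` and
    draws per-extruder processivity exponentially (constant detachment rate),
    which spreads the centromere-anchored loops into continuous stripes.
    """
    key = name.upper()
    if key in ("WT", "BRN1"):
        return Scenario(key, lambda m: m.occupancy.copy())
    if key == "MCD1":
        return Scenario(key, lambda m: np.zeros(m.n_cars))
    if key == "WPL1":
        return Scenario(key, lambda m: m.occupancy * 0.5)
    if key == "PDS5":
        return Scenario(
            key,
            lambda m: _pds5_transform(m, pericentric_radius, arm_factor,
                                      pericentric_factor),
            extruder_overrides={"processivity_factor": processivity_factor,
                                "processivity_distribution": "exponential",
                                "loading": "centromeric"},
        )
    raise ConfigError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")


def apply_scenario(car_map: CARMap, scenario: Scenario) -> CARMap:
    """Return a new CARMap with the scenario's occupancy transform applied."""
    occ = np.clip(scenario.occupancy_transform(car_map), 0.0, 1.0)
    return car_map.with_occupancy(occ)


@dataclass
class SpanDistribution:
    """Distribution of positioned-loop spans in CAR intervals."""

    ks: np.ndarray        # span in CAR intervals, k = 1, 2, ...
    probs: np.ndarray     # normalized frequency per k
    bp_quantiles: dict    # base-pair span quantiles (weighted)
    mean_span: float      # mean span in CAR intervals

    def prob(self, k: int) -> float:
        hit = self.ks == k
        return float(self.probs[hit][0]) if hit.any() else 0.0


def span_histogram(pop: PopulationLoops, car_map: CARMap) -> SpanDistribution:
    """Normalized span distribution (in CAR intervals) of positioned loops."""
    if pop.n_pairs == 0:
        return SpanDistribution(np.empty(0, dtype=int), np.empty(0), {}, np.nan)
    spans = pop.spans()
    weights = pop.frequency * pop.n_cells
    ks = np.arange(1, spans.max() + 1)
    mass = np.array([weights[spans == k].sum() for k in ks])
    probs = mass / mass.sum()
    bp = (car_map.car_positions[pop.right_car] - car_map.car_positions[pop.left_car])
    order = np.argsort(bp)
    cw = np.cumsum(weights[order]) / weights.sum()
    quantiles = {q: float(bp[order][np.searchsorted(cw, q)])
                 for q in (0.25, 0.5, 0.75)}
    mean_span = float((ks * probs).sum())
    return SpanDistribution(ks, probs, quantiles, mean_span)


def enumerate_consecutive_spans(occupancy: np.ndarray) -> np.ndarray:
    """Exact span distribution of the consecutive-occupied rule by enumeration.

    Sums over all 2**n occupancy patterns with their product probabilities;
    returns expected loop counts per span k (index 0 == span 1), which can be
    normalized into the exact span distribution.  Exponential in n — intended
    for n <= ~15 as an oracle for the stochastic simulator.
    """
    occupancy = np.asarray(occupancy, dtype=float)
    n = occupancy.size
    if n > 20:
        raise ParameterError("enumeration is exponential; use n <= 20")
    expected = np.zeros(max(n - 1, 0))
    for pattern in product((0, 1), repeat=n):
        arr = np.array(pattern, dtype=bool)
        w = np.prod(np.where(arr, occupancy, 1.0 - occupancy))
        if w == 0.0:
            continue
        occ = np.flatnonzero(arr)
        for a, b in zip(occ[:-1], occ[1:]):
            expected[b - a - 1] += w
    return expected


def positioned_anchor_counts(pop: PopulationLoops, n_cars: int) -> np.ndarray:
    """How many positioned anchors (loop ends across all cells) sit at each CAR.

    Counts both fully positioned loops (weighted by frequency x n_cells) and
    the positioned ends of mixed positioned/unpositioned extruder loops.
    """
    counts = np.zeros(n_cars)
    w = pop.frequency * pop.n_cells
    np.add.at(counts, pop.left_car, w)
    np.add.at(counts, pop.right_car, w)
    for _, _, li, ri in pop.unpositioned:
        if li >= 0:
            counts[li] += 1
        if ri >= 0:
            counts[ri] += 1
    return counts


def occupancy_from_adjacent_loops(pop: PopulationLoops, n_cars: int) -> np.ndarray:
    """Estimate occupancy from adjacent-loop frequencies under the consecutive model.

    For adjacent CARs the loop frequency is exactly p_i * p_{i+1}, so
    sqrt(frequency) estimates the pair's geometric-mean occupancy; per CAR we
    average the estimates from its (up to two) adjacent pairs.  The estimator
    identifies per-CAR occupancy exactly when occupancy is homogeneous.
    """
    est = np.full(n_cars, np.nan)
    adj = pop.spans() == 1
    root = np.sqrt(pop.frequency[adj])
    lefts = pop.left_car[adj]
    acc = np.zeros(n_cars)
    cnt = np.zeros(n_cars)
    np.add.at(acc, lefts, root)
    np.add.at(cnt, lefts, 1)
    np.add.at(acc, lefts + 1, root)
    np.add.at(cnt, lefts + 1, 1)
    has = cnt > 0
    est[has] = acc[has] / cnt[has]
    return est
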