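"""Readers/writers for the package's external file forms.

All interval formats are 0-based, half-open (BED convention).  CAR maps go
to BED plus a JSON sidecar (centromere, flags, chromosome size); ChIP and
insulation tracks to bedGraph; loop tables to BEDPE; contact matrices to a
dense TSV with a commented header.  Malformed lines raise
:class:`FileFormatError` naming the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .errors import FileFormatError, ParameterError
from .contacts import ContactMatrix
from .genome_model import CARMap, ChIPTrack
from .loops_domains import LoopCalls
from .residency import PopulationLoops

CAR_HALF_WIDTH = 500  # BED intervals span center +/- 500 bp (~1 kb CAR width)


def write_carmap(car_map: CARMap, bed_path) -> None:
    """Write a CAR map as BED (score = round(1000 x occupancy)) + JSON sidecar."""
    bed_path = Path(bed_path)
    with open(bed_path, "w") as fh:
        for k, (pos, occ) in enumerate(zip(car_map.car_positions, car_map.occupancy)):
            start = max(0, int(pos) - CAR_HALF_WIDTH)
            end = min(car_map.chrom_length, int(pos) + CAR_HALF_WIDTH)
            fh.write(f"{car_map.chrom_name}\t{start}\t{end}\tCAR{k}\t"
                     f"{round(1000 * occ)}\n")
    sidecar = {
        "chrom_name": car_map.chrom_name,
        "chrom_length": int(car_map.chrom_length),
        "car_positions": [int(p) for p in car_map.car_positions],
        "occupancy": [float(o) for o in car_map.occupancy],
        "centromere_index": (None if car_map.centromere_index is None
                             else int(car_map.centromere_index)),
        "high_residency": [bool(f) for f in car_map.high_residency],
    }
    with open(bed_path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_carmap(bed_path) -> CARMap:
    """Read a CAR map written by :func:`write_carmap` (sidecar is authoritative)."""
    sidecar = Path(bed_path).with_suffix(".json")
    if not sidecar.exists():
        raise FileFormatError(sidecar, 0, "missing CAR map sidecar file")
    with open(sidecar) as fh:
        d = json.load(fh)
    return CARMap(d["chrom_name"], d["chrom_length"],
                  np.array(d["car_positions"], dtype=np.int64),
                  np.array(d["occupancy"], dtype=float),
                  centromere_index=d["centromere_index"],
                  high_residency=np.array(d["high_residency"], dtype=bool))


def write_bedgraph(track: ChIPTrack, path) -> None:
    with open(path, "w") as fh:
        for b, v in enumerate(track.coverage):
            start = b * track.bin_size
            end = min((b + 1) * track.bin_size, track.chrom_length)
            fh.write(f"{track.chrom_name}\t{start}\t{end}\t{v:.17g}\n")


def read_bedgraph(path) -> ChIPTrack:
    chrom = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FileFormatError(path, lineno, "bedGraph needs 4 columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise FileFormatError(path, lineno, str(exc)) from exc
            if end <= start:
                raise FileFormatError(path, lineno, f"interval end {end} <= start {start}")
            chrom = chrom or parts[0]
            rows.append((start, end, value))
    if not rows:
        raise FileFormatError(path, 0, "empty bedGraph")
    rows.sort()
    bin_size = rows[0][1] - rows[0][0]
    chrom_length = rows[-1][1]
    coverage = np.zeros(-(-chrom_length // bin_size))
    for start, _, value in rows:
        coverage[start // bin_size] = value
    return ChIPTrack(bin_size, coverage, chrom_length, chrom or "chrS")


def write_population_bedpe(pop: PopulationLoops, car_map: CARMap, path,
                           anchor_half: int = 500) -> None:
    """Positioned loops as BEDPE with score = frequency; name encodes CAR pair."""
    with open(path, "w") as fh:
        c = car_map.chrom_name
        for li, ri, f in zip(pop.left_car, pop.right_car, pop.frequency):
            a, b = int(car_map.car_positions[li]), int(car_map.car_positions[ri])
            fh.write(f"{c}\t{max(0, a - anchor_half)}\t{a + anchor_half}\t"
                     f"{c}\t{max(0, b - anchor_half)}\t{b + anchor_half}\t"
                     f"L{li}_{ri}\t{f:.17g}\n")


def read_bedpe(path) -> pd.DataFrame:
    """Generic BEDPE reader -> DataFrame; validates coordinates per line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise FileFormatError(path, lineno, "BEDPE needs 8 columns")
            try:
                s1, e1, s2, e2 = map(int, (parts[1], parts[2], parts[4], parts[5]))
                score = float(parts[7])
            except ValueError as exc:
                raise FileFormatError(path, lineno, str(exc)) from exc
            if e1 <= s1 or e2 <= s2:
                raise FileFormatError(path, lineno, "interval end <= start")
            rows.append((parts[0], s1, e1, parts[3], s2, e2, parts[6], score))
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2",
                                       "start2", "end2", "name", "score"])


def write_loopcalls_bedpe(calls: LoopCalls, path, anchor_half: int = 500) -> None:
    """Loop calls as BEDPE with score = -log10(q)."""
    a, b = calls.anchors_bp()
    q = calls.table["q_value"].to_numpy()
    with open(path, "w") as fh:
        c = calls.chrom_name
        for k, (ai, bi_) in enumerate(zip(a, b)):
            score = -np.log10(max(q[k], 1e-300))
            fh.write(f"{c}\t{int(ai) - anchor_half}\t{int(ai) + anchor_half}\t"
                     f"{c}\t{int(bi_) - anchor_half}\t{int(bi_) + anchor_half}\t"
                     f"loop{k}\t{score:.6g}\n")


def write_bed_intervals(chrom: str, starts, ends, names, path) -> None:
    with open(path, "w") as fh:
        for s, e, n in zip(starts, ends, names):
            fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{n}\n")


def write_matrix_tsv(m: ContactMatrix, path) -> None:
    """Dense matrix TSV with a commented header; bit-exact round trip."""
    with open(path, "w") as fh:
        fh.write(f"# chrom\t{m.chrom_name}\n")
        fh.write(f"# chrom_length\t{m.chrom_length}\n")
        fh.write(f"# bin_size\t{m.bin_size}\n")
        np.savetxt(fh, m.counts, fmt="%.17g", delimiter="\t")


def read_matrix_tsv(path) -> ContactMatrix:
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        for lineno in range(1, 4):
            line = fh.readline()
            if not line.startswith("# "):
                raise FileFormatError(path, lineno, "missing matrix header line")
            key, value = line[2:].rstrip("\n").split("\t")
            header[key] = value
        counts = np.loadtxt(fh, delimiter="\t", ndmin=2)
    try:
        return ContactMatrix(int(header["bin_size"]), counts, header["chrom"],
                             int(header["chrom_length"]))
    except (KeyError, ValueError) as exc:
        raise FileFormatError(path, 0, f"bad matrix header: {exc}") from exc


def write_insulation_bedgraph(profile, chrom_length: int, path,
                              chrom: str = "chrS") -> None:
    with open(path, "w") as fh:
        for b, v in enumerate(profile.scores):
            if not np.isfinite(v):
                continue
            start = b * profile.res
            end = min((b + 1) * profile.res, chrom_length)
            fh.write(f"{chrom}\t{start}\t{end}\t{v:.17g}\n")
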