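"""Quadripartite partition detection and IR/SC junction analysis.

Land-plant plastomes are circular molecules with two near-identical
inverted-repeat copies (IRB, IRA) separating a large and a small
single-copy region (LSC, SSC).  Records are analysed as linearised in
the deposited orientation, with the origin inside the LSC, so the
expected layout along the sequence is LSC - IRB - SSC - IRA.  IR
detection does not wrap the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plastome import Plastome, revcomp

__all__ = [
    "RegionPartition",
    "PartitionError",
    "AmbiguousIRError",
    "detect_quadripartite",
    "JunctionRow",
    "JunctionReport",
    "junction_distances",
]


class PartitionError(ValueError):
    """No acceptable inverted-repeat pair, or unsupported orientation."""


class AmbiguousIRError(PartitionError):
    """More than one non-nested maximal inverted-repeat pair of equal length."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(f"ambiguous IR detection; candidates: {candidates}")


@dataclass(frozen=True)
class RegionPartition:
    """1-based inclusive intervals of the four plastome regions."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    ir_length: int
    mismatches: int

    def __post_init__(self):
        if self.irb[1] - self.irb[0] != self.ira[1] - self.ira[0]:
            raise PartitionError("IRB and IRA lengths differ")
        if self.ir_length != self.irb[1] - self.irb[0] + 1:
            raise PartitionError("ir_length inconsistent with IRB interval")

    @property
    def total_length(self) -> int:
        return sum(e - s + 1 for s, e in (self.lsc, self.irb, self.ssc, self.ira))

    def region_of(self, pos: int) -> str:
        for label in ("lsc", "irb", "ssc", "ira"):
            s, e = getattr(self, label)
            if s <= pos <= e:
                return label.upper()
        raise ValueError(f"position {pos} outside [1, {self.total_length}]")

    def to_dict(self) -> dict:
        return {
            "lsc": list(self.lsc),
            "irb": list(self.irb),
            "ssc": list(self.ssc),
            "ira": list(self.ira),
            "ir_length": self.ir_length,
            "mismatches": self.mismatches,
        }


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _diagonal_candidates(s_codes, r_codes, diagonal, min_len, max_mismatch_frac):
    """Maximal near-identical intervals on one diagonal of S vs R.

    Exact match runs are chained greedily across mismatch gaps while the
    overall mismatch fraction stays within budget.  With a zero budget
    this reduces to the exact maximal runs, which is what the brute-force
    oracle enumerates.
    """
    n = len(s_codes)
    lo = max(0, diagonal)
    hi = min(n, n + diagonal)
    if hi - lo < min_len:
        return []
    eq = s_codes[lo:hi] == r_codes[lo - diagonal : hi - diagonal]
    # exact runs of True
    idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
    starts, ends = idx[0::2], idx[1::2] - 1  # inclusive, relative to lo
    runs = list(zip(starts.tolist(), ends.tolist()))
    out = []
    i = 0
    while i < len(runs):
        cs, ce = runs[i]
        mism = 0
        j = i
        while j + 1 < len(runs):
            ns, ne = runs[j + 1]
            gap = ns - ce - 1
            span = ne - cs + 1
            if mism + gap <= max_mismatch_frac * span:
                mism += gap
                ce = ne
                j += 1
            else:
                break
        if ce - cs + 1 >= min_len:
            out.append((lo + cs, lo + ce, mism))
        i = j + 1
    return out


def detect_quadripartite(
    p: Plastome, min_ir_len: int = 10000, max_mismatch_frac: float = 0.001
) -> RegionPartition:
    """Locate the maximal pair of near-identical inverted segments.

    Returns the implied LSC/IRB/SSC/IRA labelling (the larger single-copy
    interval is the LSC, and the IR copy that follows it is IRB).  Raises
    :class:`PartitionError` if no inverted pair of at least ``min_ir_len``
    exists, and :class:`AmbiguousIRError` when several non-nested maximal
    pairs tie for the maximal length.
    """
    seq = p.sequence
    n = len(seq)
    s_codes = _encode(seq)
    r_codes = _encode(revcomp(seq))

    # seed shared k-mers between S and revcomp(S) to restrict diagonals
    k = min(21, max(4, min_ir_len // 4))
    pos_in_s: dict[str, list[int]] = {}
    for i in range(0, n - k + 1):
        pos_in_s.setdefault(seq[i : i + k], []).append(i)
    rseq = revcomp(seq)
    diagonals: set[int] = set()
    for pidx in range(0, n - k + 1):
        hits = pos_in_s.get(rseq[pidx : pidx + k])
        if hits:
            for i in hits:
                diagonals.add(i - pidx)

    candidates = []  # (first_start0, second_start0, length, mismatches)
    for d in sorted(diagonals):
        for s0, e0, mism in _diagonal_candidates(
            s_codes, r_codes, d, min_ir_len, max_mismatch_frac
        ):
            length = e0 - s0 + 1
            # partner segment of S[s0:e0+1] under reverse complement
            p_start = s0 - d  # start within revcomp(S)
            j0 = n - (p_start + length)
            a, b = sorted((s0, j0))
            if a + length > b:  # overlapping self-pair
                continue
            candidates.append((a, b, length, mism))

    if not candidates:
        raise PartitionError(
            f"no inverted repeat pair of length >= {min_ir_len} found in {p.id}"
        )
    candidates = sorted(set(candidates), key=lambda c: (-c[2], c[0], c[1]))
    best_len = candidates[0][2]
    best = [c for c in candidates if c[2] == best_len]
    # drop exact mirror duplicates; distinct coordinate pairs are ambiguous
    distinct = sorted({(a, b) for a, b, _, _ in best})
    if len(distinct) > 1:
        raise AmbiguousIRError([(a + 1, b + 1, best_len) for a, b in distinct])

    a, b, length, mism = best[0]
    irb0 = (a, a + length - 1)
    ira0 = (b, b + length - 1)
    pre = a  # bases before first IR copy
    mid = b - (a + length)  # bases between the copies
    post = n - (b + length)  # bases after second IR copy
    if post > 0:
        raise PartitionError(
            f"{p.id}: {post} bp follow the second IR copy; expected the "
            "deposited orientation LSC-IRB-SSC-IRA (origin inside LSC)"
        )
    if pre <= mid:
        raise PartitionError(
            f"{p.id}: the leading single-copy region ({pre} bp) is not the "
            "larger one; record is not oriented LSC-first"
        )
    return RegionPartition(
        lsc=(1, pre),
        irb=(irb0[0] + 1, irb0[1] + 1),
        ssc=(irb0[1] + 2, ira0[0]),
        ira=(ira0[0] + 1, ira0[1] + 1),
        ir_length=length,
        mismatches=mism,
    )


JUNCTION_NAMES = ("LSC/IRB", "IRB/SSC", "SSC/IRA", "IRA/LSC")


@dataclass
class JunctionRow:
    gene: str
    junction: str
    distance: int
    distance_circular: int
    side: str  # inside-SC | inside-IR | straddling
    overhangs: tuple[int, int] | None = None  # (left flank, right flank) when straddling


@dataclass
class JunctionReport:
    rows: list[JunctionRow] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [
            {
                "gene": r.gene,
                "junction": r.junction,
                "distance": r.distance,
                "distance_circular": r.distance_circular,
                "side": r.side,
                "overhang_left": r.overhangs[0] if r.overhangs else None,
                "overhang_right": r.overhangs[1] if r.overhangs else None,
            }
            for r in self.rows
        ]


def junction_distances(p: Plastome, part: RegionPartition) -> JunctionReport:
    """Distances from the genes nearest each IR/SC junction.

    For every junction the nearest gene on each side is reported along
    with its distance (0 when the gene ends exactly at the border) and,
    for genes straddling a junction, the flank lengths on either side
    (which sum to the gene span).  ``distance_circular`` additionally
    measures the gene-to-junction distance the other way around the
    circle, which matters for genes adjacent to the origin.
    """
    n = len(p.sequence)
    junctions = {
        "LSC/IRB": (part.lsc[1], "inside-SC", "inside-IR"),
        "IRB/SSC": (part.irb[1], "inside-IR", "inside-SC"),
        "SSC/IRA": (part.ssc[1], "inside-SC", "inside-IR"),
        "IRA/LSC": (part.ira[1], "inside-IR", "inside-SC"),
    }
    report = JunctionReport()
    genes = p.genes()
    if not genes:
        return report
    for name, (boundary, left_side, right_side) in junctions.items():
        straddlers = [g for g in genes if g.start <= boundary and g.end >= boundary + 1]
        for g in straddlers:
            left = boundary - g.start + 1
            right = g.end - boundary
            report.rows.append(
                JunctionRow(g.name, name, 0, 0, "straddling", (left, right))
            )
        left_genes = [g for g in genes if g.end <= boundary]
        right_genes = [g for g in genes if g.start >= boundary + 1]
        if left_genes:
            g = max(left_genes, key=lambda g: g.end)
            d = boundary - g.end
            d_circ = min(d, (g.start - 1) + (n - boundary)) if p.circular else d
            report.rows.append(JunctionRow(g.name, name, d, d_circ, left_side))
        if right_genes:
            g = min(right_genes, key=lambda g: g.start)
            d = g.start - boundary - 1
            d_circ = min(d, (n - g.end) + boundary) if p.circular else d
            report.rows.append(JunctionRow(g.name, name, d, d_circ, right_side))
        elif p.circular and genes:
            # junction at the linearisation point: the right neighbour wraps
            g = min(genes, key=lambda g: g.start)
            d = (g.start - 1) + (n - boundary)
            report.rows.append(JunctionRow(g.name, name, d, d, right_side))
    return report
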