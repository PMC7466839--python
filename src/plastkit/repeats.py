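"""Repeat detection: SSRs, imperfect tandem arrays, and dispersed repeats.

Three detector families cover the repeat classes commonly surveyed in
plastome studies:

* :func:`find_ssrs` — perfect microsatellites under MISA-style class
  minima (10 copies for mononucleotides, 6 for dinucleotides, 5 for
  tri- through hexanucleotides), with nearby hits merged into composite
  SSRs.
* :func:`find_tandem_repeats` — imperfect tandem arrays of a unit in a
  configurable length range, scored by identity against the best-fitting
  perfect tandem (the column-majority consensus of the array).
* :func:`find_dispersed_repeats` — maximal pairs of similar segments in
  forward, reverse, complement, and palindromic (reverse-complement)
  orientation within a Hamming-distance budget, found by exact
  pigeonhole seeding and extension so that no pair within the budget is
  missed.

All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plastome import revcomp

__all__ = [
    "SSRHit",
    "TandemHit",
    "DispersedHit",
    "find_ssrs",
    "find_tandem_repeats",
    "find_dispersed_repeats",
    "classify_locations",
    "DEFAULT_SSR_MINIMA",
]

DEFAULT_SSR_MINIMA = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

_N = ord("N")
_COMP = str.maketrans("ACGTN", "TGCAN")


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation (mononucleotides stay literal)."""
    if len(motif) <= 1:
        return motif
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for p in range(1, m):
        if m % p == 0 and motif == motif[:p] * (m // p):
            return False
    return True


@dataclass
class SSRHit:
    motif: str  # canonical rotation; components joined with '-' for composites
    start: int
    end: int
    copies: int
    ssr_class: str  # p1..p6 or composite
    components: list["SSRHit"] = field(default_factory=list)
    spacers: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _simple_ssrs(seq: str, minima: dict[int, int]) -> list[SSRHit]:
    n = len(seq)
    codes = _codes(seq)
    hits = []
    for m, min_copies in sorted(minima.items()):
        if n < m * min_copies:
            continue
        eq = (codes[:-m] == codes[m:]) & (codes[:-m] != _N)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for a, b_excl in zip(edges[0::2], edges[1::2]):
            a, b = int(a), int(b_excl) - 1  # eq run, inclusive
            total = (b - a + 1) + m
            copies = total // m
            if copies < min_copies:
                continue
            motif = seq[a : a + m]
            if "N" in motif or not _is_primitive(motif):
                continue
            hits.append(
                SSRHit(
                    motif=canonical_rotation(motif),
                    start=a + 1,
                    end=a + m * copies,
                    copies=copies,
                    ssr_class=f"p{m}",
                )
            )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def _trim_overlaps(group: list[SSRHit]) -> list[SSRHit]:
    """Make composite components disjoint by advancing whole motif copies."""
    out: list[SSRHit] = []
    prev_end = 0
    for h in group:
        if h.start <= prev_end:
            m = len(h.motif)
            shift_copies = math.ceil((prev_end - h.start + 1) / m)
            new_copies = h.copies - shift_copies
            if new_copies < 1:
                continue
            h = SSRHit(
                motif=h.motif,
                start=h.start + shift_copies * m,
                end=h.end,
                copies=new_copies,
                ssr_class=h.ssr_class,
            )
        out.append(h)
        prev_end = h.end
    return out


def find_ssrs(
    seq: str,
    minima: dict[int, int] | None = None,
    join_distance: int = 100,
    merge_composites: bool = True,
) -> list[SSRHit]:
    """MISA-rule SSR scan.

    Maximal perfect runs of primitive 1–6 bp motifs meeting the per-class
    copy minima are reported; trailing partial copies are not included,
    so ``end - start + 1 == len(motif) * copies``.  A run qualifying at
    several motif lengths is reported at the smallest (non-primitive
    motifs are never reported).  Hits separated by at most
    ``join_distance`` bases — including overlapping hits — are merged
    into one composite SSR whose components are trimmed to be disjoint.
    N breaks runs.
    """
    if minima is None:
        minima = DEFAULT_SSR_MINIMA
    simple = _simple_ssrs(seq, minima)
    if not simple:
        return []
    if not merge_composites:
        return simple
    out: list[SSRHit] = []
    group = [simple[0]]
    for h in simple[1:]:
        if h.start - max(g.end for g in group) - 1 <= join_distance:
            group.append(h)
        else:
            out.append(_finalise_group(group))
            group = [h]
    out.append(_finalise_group(group))
    return [h for h in out if h is not None]


def _finalise_group(group: list[SSRHit]) -> SSRHit | None:
    if len(group) == 1:
        return group[0]
    comps = _trim_overlaps(sorted(group, key=lambda h: (h.start, h.end)))
    if not comps:
        return None
    if len(comps) == 1:
        return comps[0]
    spacers = [b.start - a.end - 1 for a, b in zip(comps, comps[1:])]
    return SSRHit(
        motif="-".join(c.motif for c in comps),
        start=comps[0].start,
        end=comps[-1].end,
        copies=sum(c.copies for c in comps),
        ssr_class="composite",
        components=comps,
        spacers=spacers,
    )


# ---------------------------------------------------------------------------
# Imperfect tandem repeats
# ---------------------------------------------------------------------------


@dataclass
class TandemHit:
    unit: str  # column-majority consensus unit
    unit_len: int
    start: int
    end: int
    copies: float
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


_BASE_IDX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_IDX[_b] = _i


def _consensus_matches(codes: np.ndarray, s: int, e: int, u: int) -> int:
    """Matches of [s, e] (0-based incl.) against its best perfect tandem."""
    idx = _BASE_IDX[codes[s : e + 1]]
    matches = 0
    for col in range(u):
        colvals = idx[col::u]
        counts = np.bincount(colvals[colvals < 4], minlength=4)
        matches += int(counts.max()) if counts.size else 0
    return matches


def _consensus_unit(codes: np.ndarray, s: int, e: int, u: int) -> str:
    idx = _BASE_IDX[codes[s : e + 1]]
    unit = []
    for col in range(u):
        colvals = idx[col::u]
        counts = np.bincount(colvals[colvals < 4], minlength=4)
        unit.append("ACGT"[int(counts.argmax())] if counts.sum() else "N")
    return "".join(unit)


def _max_candidates(
    codes: np.ndarray,
    u: int,
    lo: int,
    hi: int,
    min_identity: float,
    min_copies: float,
    max_array_len: int,
):
    """Containment-maximal qualifying arrays of unit length ``u`` in [lo, hi].

    For each start the extension keeps per-column base counts and updates
    the consensus match total in O(1); the candidate kept for a start is
    its farthest qualifying end, and starts dominated by an earlier start
    with an equal-or-farther end are discarded (containment maximality).
    """
    minlen = int(math.ceil(min_copies * u - 1e-9))
    out = []
    best_e = -1
    thr = min_identity / 100.0
    idx_all = _BASE_IDX[codes]
    for s in range(lo, hi - minlen + 2):
        counts = np.zeros((u, 5), dtype=np.int32)
        matches = 0
        colmax = np.zeros(u, dtype=np.int32)
        last_e = -1
        last_matches = 0
        hilim = min(hi, s + max_array_len - 1)
        for e in range(s, hilim + 1):
            col = (e - s) % u
            b = idx_all[e]
            if b < 4:
                counts[col, b] += 1
                if counts[col, b] > colmax[col]:
                    matches += counts[col, b] - colmax[col]
                    colmax[col] = counts[col, b]
            length = e - s + 1
            if length >= minlen and matches >= thr * length - 1e-9:
                last_e = e
                last_matches = matches
            # infeasibility: even a perfect tail cannot reach the threshold
            if matches + (hilim - e) < thr * (hilim - s + 1) - 1e-9:
                break
        if last_e > best_e:
            out.append((s, last_e, last_matches))
            best_e = last_e
    return out


def _tandem_regions(codes: np.ndarray, u: int) -> list[tuple[int, int]]:
    """Candidate regions for seeded genome-scale scanning.

    Flags u-windows of the lag-u self-match profile with few mismatches
    (a near-perfect adjacent copy pair) and expands them by 2 units on
    each side.  Arrays whose copies never align this well are outside the
    seeded scan's reach; sequences below the exhaustive-size cutoff are
    scanned completely instead.
    """
    n = len(codes)
    if n < 2 * u:
        return []
    eq = (codes[:-u] == codes[u:]) & (codes[:-u] != _N)
    mism = (~eq).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(mism)))
    window = cs[u:] - cs[:-u]  # mismatches in lag-window [j, j+u)
    limit = max(1, int(0.25 * u))
    flagged = np.flatnonzero(window <= limit)
    regions: list[tuple[int, int]] = []
    for j in flagged.tolist():
        lo, hi = max(0, j - 2 * u), min(n - 1, j + 3 * u)
        if regions and lo <= regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], max(regions[-1][1], hi))
        else:
            regions.append((lo, hi))
    return regions


def find_tandem_repeats(
    seq: str,
    unit_min: int = 7,
    unit_max: int = 95,
    min_identity: float = 85.0,
    min_copies: float = 2.0,
    max_array_len: int = 500,
    exhaustive: bool | None = None,
) -> list[TandemHit]:
    """Detect imperfect tandem arrays.

    An array is a window whose identity against the best-fitting perfect
    tandem of its unit (the column-majority consensus) is at least
    ``min_identity`` percent, with at least ``min_copies`` (fractional)
    copies.  Candidates are containment-maximal per unit length, and
    overlaps are resolved greedily by score (array length x identity),
    ties to the smaller unit, then leftmost.

    Sequences up to 2 kbp are scanned exhaustively; longer sequences use
    a seeded scan (see :func:`_tandem_regions`) unless ``exhaustive`` is
    forced.
    """
    n = len(seq)
    codes = _codes(seq)
    if exhaustive is None:
        exhaustive = n <= 2000
    cands: set[tuple[int, int, int, int]] = set()
    for u in range(unit_min, min(unit_max, n // 2) + 1):
        minlen = int(math.ceil(min_copies * u - 1e-9))
        if minlen > n:
            break
        regions = [(0, n - 1)] if exhaustive else _tandem_regions(codes, u)
        for lo, hi in regions:
            for s, e, matches in _max_candidates(
                codes, u, lo, hi, min_identity, min_copies, max_array_len
            ):
                cands.add((s, e, u, matches))
    # greedy overlap resolution: score = length * identity = 100 * matches
    ordered = sorted(cands, key=lambda c: (-c[3], c[2], c[0], c[1]))
    chosen: list[tuple[int, int, int, int]] = []
    occupied: list[tuple[int, int]] = []
    for s, e, u, matches in ordered:
        if any(s <= oe and e >= os_ for os_, oe in occupied):
            continue
        chosen.append((s, e, u, matches))
        occupied.append((s, e))
    hits = [
        TandemHit(
            unit=_consensus_unit(codes, s, e, u),
            unit_len=u,
            start=s + 1,
            end=e + 1,
            copies=(e - s + 1) / u,
            identity=100.0 * matches / (e - s + 1),
        )
        for s, e, u, matches in sorted(chosen)
    ]
    return hits


# ---------------------------------------------------------------------------
# Dispersed repeats
# ---------------------------------------------------------------------------


@dataclass
class DispersedHit:
    kind: str  # forward | reverse | complement | palindromic
    len: int
    pos1: int  # 1-based start of the left copy
    pos2: int  # 1-based start of the right copy
    mismatches: int

    @property
    def midpoint(self) -> int:
        return self.pos1 + self.len // 2


# classification priority when a pair qualifies under several orientations
_ORIENTATIONS = (
    ("forward", False, False),
    ("palindromic", True, True),
    ("reverse", True, False),
    ("complement", False, True),
)


def _transform(seq: str, rev: bool, comp: bool) -> str:
    t = seq.translate(_COMP) if comp else seq
    return t[::-1] if rev else t


def find_dispersed_repeats(
    seq: str, min_len: int = 21, max_hamming: int = 2
) -> list[DispersedHit]:
    """Maximal dispersed repeat pairs within a Hamming budget.

    A pair of equal-length, non-overlapping segments qualifies when the
    left copy matches the (possibly reversed / complemented /
    reverse-complemented) right copy with at most ``max_hamming``
    mismatches, the pair is at least ``min_len`` long, and it cannot be
    extended on either side within the budget.  Exact seeds of length
    ``ceil(min_len / (max_hamming + 1))`` guarantee by pigeonhole that no
    qualifying pair is missed.  Each pair is reported under exactly one
    orientation (priority forward, palindromic, reverse, complement).
    """
    n = len(seq)
    h = max_hamming
    w = max(1, math.ceil(min_len / (h + 1)))
    if n < min_len:
        return []
    s_index: dict[str, list[int]] = {}
    useq = seq.upper()
    for i in range(n - w + 1):
        kmer = useq[i : i + w]
        if "N" not in kmer:
            s_index.setdefault(kmer, []).append(i)

    found: dict[tuple[int, int, int], DispersedHit] = {}
    for kind, rev, comp in _ORIENTATIONS:
        t = _transform(useq, rev, comp)
        run_cache: dict[int, tuple[int, int]] = {}
        for p in range(n - w + 1):
            kmer = t[p : p + w]
            hits = s_index.get(kmer)
            if not hits:
                continue
            for i in hits:
                d = i - p
                if kind == "forward" and d == 0:
                    continue
                cached = run_cache.get(d)
                if cached and cached[0] <= i and i + w - 1 <= cached[1]:
                    continue
                lo = max(0, d)
                hi = min(n, n + d) - 1  # inclusive S-range of this diagonal

                def eqat(x: int) -> bool:
                    a, b = useq[x], t[x - d]
                    return a == b and a != "N"

                leftm = []
                x = i - 1
                while x >= lo and len(leftm) <= h:
                    if not eqat(x):
                        leftm.append(x)
                    x -= 1
                rightm = []
                x = i + w
                while x <= hi and len(rightm) <= h:
                    if not eqat(x):
                        rightm.append(x)
                    x += 1
                run_cache[d] = (
                    (leftm[0] + 1) if leftm else lo,
                    (rightm[0] - 1) if rightm else hi,
                )
                intervals = set()
                for k in range(h + 1):
                    start = leftm[k] + 1 if len(leftm) > k else lo
                    used_left = min(k, len(leftm))
                    kr = h - used_left
                    end = rightm[kr] - 1 if len(rightm) > kr else hi
                    intervals.add((start, end))
                # drop intervals nested in another (boundary-limited splits)
                maximal = [
                    (s0, e0)
                    for s0, e0 in intervals
                    if not any(
                        (s1 <= s0 and e0 <= e1) and (s1, e1) != (s0, e0)
                        for s1, e1 in intervals
                    )
                ]
                for start, end in maximal:
                    length = end - start + 1
                    if length < min_len:
                        continue
                    mism = sum(1 for m in leftm if m >= start) + sum(
                        1 for m in rightm if m <= end
                    )
                    # map the T-side segment back to S coordinates
                    tp = start - d
                    if rev:
                        q0 = n - (tp + length)
                    else:
                        q0 = tp
                    a, b = sorted((start, q0))
                    if a + length > b:
                        continue  # self-overlapping pair
                    key = (a + 1, b + 1, length)
                    if key not in found:
                        found[key] = DispersedHit(
                            kind=kind, len=length, pos1=a + 1, pos2=b + 1, mismatches=mism
                        )
    return sorted(found.values(), key=lambda r: (r.pos1, r.pos2, r.len))


# ---------------------------------------------------------------------------
# Location classification
# ---------------------------------------------------------------------------


def _midpoint(hit) -> int:
    if hasattr(hit, "midpoint"):
        return hit.midpoint
    return (hit.start + hit.end) // 2


def classify_locations(hits, part, features) -> pd.DataFrame:
    """Counts of repeat hits by region (LSC/SSC/IR) and context (CDS/intron/IGS).

    Each hit is assigned by the midpoint of its (left) copy; the two IR
    copies are pooled into one ``IR`` row.  Context is CDS when the
    midpoint lies inside an annotated gene part, intron when it is inside
    a gene span but between parts, and IGS otherwise.
    """
    gene_feats = [f for f in features if f.kind in ("CDS", "tRNA", "rRNA")]
    rows = []
    for hit in hits:
        mid = _midpoint(hit)
        region = part.region_of(mid)
        if region in ("IRB", "IRA"):
            region = "IR"
        context = "IGS"
        for f in gene_feats:
            if f.start <= mid <= f.end:
                context = "intron"
                for s, e in f.parts:
                    if s <= mid <= e:
                        context = "CDS"
                        break
                break
        rows.append((region, context))
    table = pd.DataFrame(rows, columns=["region", "context"])
    counts = (
        table.groupby(["region", "context"]).size().unstack(fill_value=0)
        if rows
        else pd.DataFrame()
    )
    counts = counts.reindex(
        index=["LSC", "SSC", "IR"], columns=["CDS", "intron", "IGS"], fill_value=0
    )
    return counts.fillna(0).astype(int)
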