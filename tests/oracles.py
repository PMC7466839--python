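"""Independent brute-force oracles used to verify the detectors and
statistics.  Each oracle re-derives its result from first principles
(exhaustive enumeration, naive scans, closed forms) without sharing code
with the implementation under test."""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
from Bio.Seq import Seq

COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


# ---------------------------------------------------------------------------
# Maximal inverted repeat pairs (quadripartite oracle)
# ---------------------------------------------------------------------------


def maximal_inverted_pairs(seq: str, min_len: int):
    """All maximal exact inverted (reverse-complement) segment pairs.

    Enumerates every diagonal of seq vs revcomp(seq) and returns maximal
    exact runs of length >= min_len as (first_start0, second_start0, length),
    excluding self-overlapping pairs, deduplicated over mirror images.
    """
    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    r = np.frombuffer(rc(seq).encode(), dtype=np.uint8)
    out = set()
    for d in range(-(n - 1), n):
        lo, hi = max(0, d), min(n, n + d)
        if hi - lo < min_len:
            continue
        eq = s[lo:hi] == r[lo - d : hi - d]
        edges = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for a, b_ in zip(edges[0::2], edges[1::2]):
            length = int(b_ - a)
            if length < min_len:
                continue
            i = lo + int(a)
            p = i - d
            j = n - (p + length)
            x, y = sorted((i, j))
            if x + length <= y:
                out.add((x, y, length))
    return sorted(out)


# ---------------------------------------------------------------------------
# SSR oracle
# ---------------------------------------------------------------------------


def ssr_scan(seq: str, minima: dict[int, int]):
    """Naive SSR scan: explicit motif comparison at every start.

    Returns (motif_literal, start0, end0, copies) for maximal runs of
    primitive motifs meeting the class minimum, reported at the start of
    the run (phase-maximal on the left).
    """
    n = len(seq)
    hits = []
    for m, min_copies in sorted(minima.items()):
        for i in range(n - m * min_copies + 1):
            motif = seq[i : i + m]
            if "N" in motif:
                continue
            if any(m % p == 0 and motif == motif[:p] * (m // p) for p in range(1, m)):
                continue  # non-primitive
            if i >= 1 and seq[i - 1] == seq[i + m - 1]:
                continue  # run extends left
            c = 1
            while seq[i + c * m : i + (c + 1) * m] == motif:
                c += 1
            if c >= min_copies:
                hits.append((motif, i, i + c * m - 1, c))
    return sorted(hits, key=lambda h: (h[1], h[2]))


# ---------------------------------------------------------------------------
# Tandem repeat oracle
# ---------------------------------------------------------------------------


def _consensus_matches_naive(seq: str, s: int, e: int, u: int) -> int:
    matches = 0
    for col in range(u):
        counts = Counter()
        for pos in range(s + col, e + 1, u):
            if seq[pos] in "ACGT":
                counts[seq[pos]] += 1
        if counts:
            matches += max(counts.values())
    return matches


def tandem_enumerate(
    seq: str,
    unit_min: int,
    unit_max: int,
    min_identity: float,
    min_copies: float = 2.0,
    max_array_len: int = 500,
):
    """Exhaustive tandem-array enumeration with the same published
    semantics as the detector: qualifying = consensus identity >=
    threshold and >= min_copies copies; containment-maximal per unit;
    greedy overlap resolution by (score, smaller unit, leftmost).
    Returns (start0, end0, u, matches)."""
    n = len(seq)
    thr = min_identity / 100.0
    all_cands = set()
    for u in range(unit_min, min(unit_max, n // 2) + 1):
        minlen = math.ceil(min_copies * u - 1e-9)
        qual = []
        for s in range(n - minlen + 1):
            for e in range(s + minlen - 1, min(n, s + max_array_len)):
                matches = _consensus_matches_naive(seq, s, e, u)
                if matches >= thr * (e - s + 1) - 1e-9:
                    qual.append((s, e, matches))
        maximal = [
            (s, e, mt)
            for s, e, mt in qual
            if not any(
                (s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2, _ in qual
            )
        ]
        for s, e, mt in maximal:
            all_cands.add((s, e, u, mt))
    ordered = sorted(all_cands, key=lambda c: (-c[3], c[2], c[0], c[1]))
    chosen = []
    for s, e, u, mt in ordered:
        if not any(s <= ce and e >= cs for cs, ce, _, _ in chosen):
            chosen.append((s, e, u, mt))
    return sorted(chosen)


# ---------------------------------------------------------------------------
# Dispersed repeat oracle
# ---------------------------------------------------------------------------


def dispersed_enumerate(seq: str, min_len: int, max_hamming: int):
    """All-pairs maximal dispersed pairs by direct diagonal scanning.

    For every orientation and every diagonal, enumerates the maximal
    windows with <= max_hamming mismatches by two-pointer sweep, maps to
    sequence coordinates, drops self-overlapping pairs and assigns each
    (pos1, pos2, len) to one orientation by the documented priority.
    Returns {(pos1_1based, pos2_1based, length): kind}.
    """
    n = len(seq)
    orientations = [
        ("forward", seq),
        ("palindromic", rc(seq)),
        ("reverse", seq[::-1]),
        ("complement", seq.translate(COMP)),
    ]
    found: dict[tuple[int, int, int], str] = {}
    for kind, t in orientations:
        reversed_t = kind in ("palindromic", "reverse")
        for d in range(-(n - 1), n):
            lo, hi = max(0, d), min(n, n + d)
            if hi - lo < min_len:
                continue
            mism = [
                x
                for x in range(lo, hi)
                if not (seq[x] == t[x - d] and seq[x] != "N")
            ]
            # b(a) = farthest end with <= h mismatches in [a, b]
            bend = {}
            mi = 0
            for a in range(lo, hi):
                while mi < len(mism) and mism[mi] < a:
                    mi += 1
                if mi + max_hamming < len(mism):
                    bend[a] = mism[mi + max_hamming] - 1
                else:
                    bend[a] = hi - 1
            for a in range(lo, hi):
                b = bend[a]
                if b < a or b - a + 1 < min_len:
                    continue
                if a > lo and bend[a - 1] >= b:
                    continue  # extendable left within budget: not maximal
                length = b - a + 1
                tp = a - d
                q0 = n - (tp + length) if reversed_t else tp
                x, y = sorted((a, q0))
                if x + length <= y:
                    key = (x + 1, y + 1, length)
                    if key not in found:
                        found[key] = kind
    return found


# ---------------------------------------------------------------------------
# Rank statistics oracles
# ---------------------------------------------------------------------------


def spearman_rho_oracle(x, y) -> float:
    """Spearman rho via scipy's independent implementation."""
    from scipy.stats import spearmanr

    return float(spearmanr(x, y).statistic)


def spearman_exact_p(x, y) -> float:
    """Exact two-sided permutation p for |rho| (full enumeration)."""
    from scipy.stats import spearmanr

    x = list(x)
    y = list(y)
    obs = abs(spearman_rho_oracle(x, y))
    count = total = 0
    for perm in itertools.permutations(y):
        r = abs(spearman_rho_oracle(x, perm))
        if r >= obs - 1e-9:
            count += 1
        total += 1
    return count / total


def mwu_oracle(a, b):
    """U by direct pairwise comparison; exact two-sided p by enumeration
    of all group assignments, measuring deviation of U from its mean."""
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)

    def u_of(g1, g2):
        return sum(
            (1.0 if x > y else 0.5 if x == y else 0.0) for x in g1 for y in g2
        )

    u_obs = u_of(a, b)
    mean_u = n1 * n2 / 2
    pooled = a + b
    count = total = 0
    for comb in itertools.combinations(range(n1 + n2), n1):
        g1 = [pooled[i] for i in comb]
        g2 = [pooled[i] for i in range(n1 + n2) if i not in comb]
        if abs(u_of(g1, g2) - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count += 1
        total += 1
    return u_obs, count / total


# ---------------------------------------------------------------------------
# NG86 single-codon oracle
# ---------------------------------------------------------------------------

_STOPS_11 = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def ng86_codon_sites(codon: str) -> float:
    """Synonymous site count of one codon by explicit mutation trials."""
    syn = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in _STOPS_11:
                continue
            if _aa(alt) == _aa(codon):
                syn += 1
    return syn / 3.0


def ng86_codon_paths(c1: str, c2: str):
    """(sd, nd) averaged over stop-free minimal pathways (all pathways if
    every one is blocked)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    blocked_paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS_11 and nxt != c2:
                blocked = True
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked_paths if blocked else paths).append((sd, nd))
    use = paths or blocked_paths
    return (
        sum(p[0] for p in use) / len(use),
        sum(p[1] for p in use) / len(use),
    )


# ---------------------------------------------------------------------------
# Pi and p-distance oracles
# ---------------------------------------------------------------------------


def pi_pairwise_deletion(rows):
    n = len(rows)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            L = d = 0
            for a, b in zip(rows[i], rows[j]):
                if a in "ACGT" and b in "ACGT":
                    L += 1
                    if a != b:
                        d += 1
            total += d / L
    return 2.0 * total / (n * (n - 1))


def p_distance_scan(s1: str, s2: str) -> float:
    L = d = 0
    for a, b in zip(s1.upper(), s2.upper()):
        if a in "ACGT" and b in "ACGT":
            L += 1
            if a != b:
                d += 1
    return d / L


# ---------------------------------------------------------------------------
# Random additive trees for NJ consistency
# ---------------------------------------------------------------------------


def random_additive_tree(rng, n_taxa: int):
    """Random unrooted binary tree; returns (taxa, distance matrix,
    bipartition->length dict for internal edges)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    # node -> set of descendant taxa; build by random joins
    clusters = {i: frozenset([t]) for i, t in enumerate(taxa)}
    # adjacency with branch lengths
    edges = []
    nodes = list(clusters)
    next_id = n_taxa
    leafset = {i: clusters[i] for i in nodes}
    active = nodes[:]
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        la = round(float(rng.uniform(0.05, 1.0)), 3)
        lb = round(float(rng.uniform(0.05, 1.0)), 3)
        edges.append((a, next_id, la))
        edges.append((b, next_id, lb))
        leafset[next_id] = leafset[a] | leafset[b]
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    center = next_id
    for a in active:
        edges.append((a, center, round(float(rng.uniform(0.05, 1.0)), 3)))
    # distances via shortest paths
    import networkx as nx

    g = nx.Graph()
    for a, b, ln in edges:
        g.add_edge(a, b, weight=ln)
    dmat = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            dmat[i, j] = dmat[j, i] = nx.shortest_path_length(
                g, i, j, weight="weight"
            )
    # non-trivial bipartitions with the internal edge lengths
    all_taxa = frozenset(taxa)
    bip = {}
    for a, b, ln in edges:  # edges are (child, parent)
        side = leafset[a]
        if 1 < len(side) < n_taxa - 1:
            other = all_taxa - side
            bip[min(side, other, key=lambda s: (len(s), sorted(s)))] = ln
    return taxa, dmat, bip
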