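"""Per-locus nucleotide diversity and pairwise Ka/Ks (Nei-Gojobori 1986).

Nucleotide diversity (Pi) is the average pairwise proportion of
differing sites among aligned sequences, computed with pairwise deletion
of gapped/ambiguous columns by default.  Ka/Ks follows the NG86 counting
method: synonymous/nonsynonymous site fractions are averaged over both
sequences, multi-hit codons are averaged over all minimal substitution
pathways with equal weights (pathways through stop codons excluded), and
the Jukes-Cantor correction is applied to both proportions.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass

import edlib
import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "LocusAlignment",
    "PiResult",
    "KaKsResult",
    "align_locus",
    "nucleotide_diversity",
    "rank_hotspots",
    "kaks_ng86",
    "GENETIC_CODE_ID",
]

GENETIC_CODE_ID = 11  # bacterial/plastid code

_table = CodonTable.unambiguous_dna_by_id[GENETIC_CODE_ID]
CODON_AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    CODON_AA[_stop] = "*"
STOP_CODONS = frozenset(_table.stop_codons)
_BASES = "ACGT"


@dataclass
class LocusAlignment:
    locus: str
    klass: str  # gene | intergenic | intron
    region: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"locus {self.locus}: need >= 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"locus {self.locus}: rows differ in length")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def ncols(self) -> int:
        return len(self.rows[0])


def _kmer_profile(seq: str, k: int = 4) -> np.ndarray:
    prof = np.zeros(4**k)
    idx = {b: i for i, b in enumerate(_BASES)}
    code = 0
    valid = 0
    for ch in seq:
        if ch not in idx:
            valid = 0
            continue
        code = (code * 4 + idx[ch]) % (4**k)
        valid += 1
        if valid >= k:
            prof[code] += 1
    return prof


def _merge_center(master_c: str, rows: list[str], pair_c: str, pair_s: str):
    """Merge a (center, seq) pairwise alignment into the growing stack."""
    out_master = []
    out_rows = [[] for _ in rows]
    out_s = []
    i = j = 0
    while i < len(master_c) or j < len(pair_c):
        mc = master_c[i] if i < len(master_c) else None
        pc = pair_c[j] if j < len(pair_c) else None
        if mc == "-" and pc == "-":
            out_master.append("-")
            for r, row in zip(out_rows, rows):
                r.append(row[i])
            out_s.append(pair_s[j])
            i += 1
            j += 1
        elif mc == "-" and (pc != "-" or pc is None):
            out_master.append("-")
            for r, row in zip(out_rows, rows):
                r.append(row[i])
            out_s.append("-")
            i += 1
        elif pc == "-" and (mc != "-" or mc is None):
            out_master.append("-")
            for r in out_rows:
                r.append("-")
            out_s.append(pair_s[j])
            j += 1
        else:  # both consume the same center base
            out_master.append(mc)
            for r, row in zip(out_rows, rows):
                r.append(row[i])
            out_s.append(pair_s[j])
            i += 1
            j += 1
    return (
        "".join(out_master),
        ["".join(r) for r in out_rows],
        "".join(out_s),
    )


_CIGAR_RE = re.compile(r"(\d+)([=XMID])")


def _align_pair_global(a: str, b: str) -> tuple[str, str]:
    """Global pairwise alignment of two near-identical sequences (edlib)."""
    if a == b:
        return a, b
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    res = edlib.align(b, a, mode="NW", task="path")
    ra, rb = [], []
    ai = bi = 0
    for num, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(num)
        if op in "=XM":
            ra.append(a[ai : ai + n])
            rb.append(b[bi : bi + n])
            ai += n
            bi += n
        elif op == "D":  # gap in b
            ra.append(a[ai : ai + n])
            rb.append("-" * n)
            ai += n
        else:  # "I": gap in a
            ra.append("-" * n)
            rb.append(b[bi : bi + n])
            bi += n
    return "".join(ra), "".join(rb)


def align_locus(
    seqs: dict[str, str],
    locus: str = "",
    klass: str = "gene",
    region: str = "LSC",
) -> LocusAlignment:
    """Progressive center-star alignment of one locus across species.

    The center is the medoid by k-mer profile distance; every other
    sequence is aligned to the center with global edit-distance dynamic
    programming (plastome loci are near-identical, so unit costs and
    affine costs give the same alignments away from degenerate ties) and
    the pairwise alignments are merged on the center's gap pattern.
    Deterministic for fixed inputs (ties by sequence id).
    """
    if not seqs:
        raise ValueError("no sequences given")
    ids = sorted(seqs)
    if len(ids) == 1:
        raise ValueError("need >= 2 sequences")
    profiles = {i: _kmer_profile(seqs[i]) for i in ids}
    dist_sums = {
        i: sum(float(np.abs(profiles[i] - profiles[j]).sum()) for j in ids if j != i)
        for i in ids
    }
    center = min(ids, key=lambda i: (dist_sums[i], i))
    others = [i for i in ids if i != center]
    master_c = seqs[center]
    rows: list[str] = []
    row_ids: list[str] = []
    for oid in others:
        pair_c, pair_s = _align_pair_global(seqs[center], seqs[oid])
        master_c, rows, new_row = _merge_center(master_c, rows, pair_c, pair_s)
        rows.append(new_row)
        row_ids.append(oid)
    all_ids = [center] + row_ids
    all_rows = [master_c] + rows
    order = sorted(range(len(all_ids)), key=lambda k: all_ids[k])
    return LocusAlignment(
        locus=locus,
        klass=klass,
        region=region,
        ids=[all_ids[k] for k in order],
        rows=[all_rows[k] for k in order],
    )


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------


@dataclass
class PiResult:
    locus: str
    klass: str
    region: str
    pi: float
    sites_used: float
    n: int
    rank: int | None = None


def nucleotide_diversity(aln: LocusAlignment, complete_deletion: bool = False) -> PiResult:
    """Average pairwise differences per site.

    Pi = (2 / (n(n-1))) * sum_{i<j} d_ij / L_ij where d_ij counts
    differing columns and L_ij the columns where neither member has a
    gap or ambiguous base (pairwise deletion).  With
    ``complete_deletion`` only columns unambiguous in every row count.
    """
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in aln.rows]
    ok = [np.isin(a, np.frombuffer(b"ACGT", dtype=np.uint8)) for a in arrs]
    n = aln.n
    if complete_deletion:
        shared = np.logical_and.reduce(ok)
    total = 0.0
    lsum = 0.0
    npairs = 0
    for i, j in itertools.combinations(range(n), 2):
        mask = shared if complete_deletion else (ok[i] & ok[j])
        L = int(mask.sum())
        if L == 0:
            raise ValueError(
                f"locus {aln.locus}: pair ({aln.ids[i]}, {aln.ids[j]}) shares no "
                "ungapped columns"
            )
        d = int(np.sum(arrs[i][mask] != arrs[j][mask]))
        total += d / L
        lsum += L
        npairs += 1
    pi = 2.0 / (n * (n - 1)) * total
    return PiResult(
        locus=aln.locus,
        klass=aln.klass,
        region=aln.region,
        pi=pi,
        sites_used=lsum / npairs,
        n=n,
    )


def rank_hotspots(results: list[PiResult], top: int = 10):
    """Top polymorphic loci, genes and intergenic regions separately.

    Descending Pi; ties broken by locus name for determinism.  Rank
    fields of the returned results are filled in (1-based).
    """
    out = {}
    for klass in ("gene", "intergenic"):
        pool = [r for r in results if r.klass == klass]
        pool.sort(key=lambda r: (-r.pi, r.locus))
        ranked = []
        for rank, r in enumerate(pool[:top], start=1):
            r.rank = rank
            ranked.append(r)
        out[klass] = ranked
    return out["gene"], out["intergenic"]


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------


@dataclass
class KaKsResult:
    gene: str
    pair: tuple[str, str]
    ka: float
    ks: float
    ratio: float | None
    n_sites: float
    s_sites: float
    codons: int
    p_n: float = 0.0  # uncorrected nonsynonymous proportion Nd/N
    p_s: float = 0.0  # uncorrected synonymous proportion Sd/S


def _syn_fraction(codon: str) -> float:
    """Synonymous site count of one codon (mutations to stops count as nonsyn)."""
    aa = CODON_AA[codon]
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_AA[alt] == aa:
                syn += 1
    return syn / 3.0


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences over minimal pathways.

    Pathways passing through a stop codon are excluded; if every pathway
    is blocked, all pathways are used (steps into/out of stops count as
    nonsynonymous).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != c2 and not allow_stops:
                return None
            if CODON_AA[cur] == CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for r in (walk(o, False) for o in itertools.permutations(diff)) if r]
    if not results:
        results = [walk(o, True) for o in itertools.permutations(diff)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_ng86(
    cds_a: str, cds_b: str, gene: str = "", pair: tuple[str, str] = ("A", "B")
) -> KaKsResult:
    """Pairwise Ka/Ks by the NG86 counting method with JC correction.

    Both sequences are trimmed to whole codons; a shared terminal stop
    codon is excluded from counting; internal stop codons are rejected.
    Codon pairs containing ambiguous bases are skipped, so
    ``n_sites + s_sites == 3 x codons`` for the codons actually compared.
    The ratio is None when Ks = 0.
    """
    a = cds_a.upper()[: len(cds_a) - len(cds_a) % 3]
    b = cds_b.upper()[: len(cds_b) - len(cds_b) % 3]
    if len(a) != len(b):
        raise ValueError(
            f"{gene or 'CDS'}: lengths differ after codon trimming ({len(a)} vs {len(b)})"
        )
    if not a:
        raise ValueError("empty CDS")
    codons_a = [a[i : i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i : i + 3] for i in range(0, len(b), 3)]
    if codons_a[-1] in STOP_CODONS and codons_b[-1] in STOP_CODONS:
        codons_a, codons_b = codons_a[:-1], codons_b[:-1]
    for idx, (ca, cb) in enumerate(zip(codons_a, codons_b)):
        if ca in STOP_CODONS and set(ca) <= set(_BASES):
            raise ValueError(f"{gene or 'CDS'}: internal stop codon {ca} at codon {idx + 1}")
        if cb in STOP_CODONS and set(cb) <= set(_BASES):
            raise ValueError(f"{gene or 'CDS'}: internal stop codon {cb} at codon {idx + 1}")
    s_sites = 0.0
    sd = nd = 0.0
    ncod = 0
    for ca, cb in zip(codons_a, codons_b):
        if not (set(ca) <= set(_BASES) and set(cb) <= set(_BASES)):
            continue
        ncod += 1
        s_sites += (_syn_fraction(ca) + _syn_fraction(cb)) / 2
        psd, pnd = _pathway_counts(ca, cb)
        sd += psd
        nd += pnd
    if ncod == 0:
        raise ValueError("no unambiguous codon pairs to compare")
    n_sites = 3.0 * ncod - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    ratio = None if (not ks or math.isnan(ks)) else ka / ks
    return KaKsResult(
        gene=gene,
        pair=pair,
        ka=ka,
        ks=ks,
        ratio=ratio,
        n_sites=n_sites,
        s_sites=s_sites,
        codons=ncod,
        p_n=pn,
        p_s=ps,
    )
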