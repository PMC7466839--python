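"""Pairwise collinear alignment of plastomes and variant extraction.

Congeneric plastomes are typically >99% identical and collinear, so a
whole-genome alignment can be built by chaining unique shared k-mers and
filling the short inter-anchor segments with affine-gap global dynamic
programming.  Variant events (SNPs, multi-base substitution blocks,
insertions, deletions) are read off the alignment columns; indels are
left-normalised and anchored to the reference base immediately 5' of the
gap, as in VCF.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from Bio import Align

from .plastome import Plastome

__all__ = [
    "PairwiseAlignment",
    "VariantEvent",
    "NonCollinearError",
    "align_collinear",
    "call_variants",
    "tandem_overlap_fractions",
]


class NonCollinearError(ValueError):
    """The anchor chain implies an inversion or transposition."""


@dataclass
class PairwiseAlignment:
    ref_id: str
    qry_id: str
    ref_aln: str
    qry_aln: str
    anchors: list[tuple[int, int]]  # 0-based (ref, qry) anchor starts
    k: int

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.qry_aln):
            raise ValueError("aligned strings differ in length")
        for r, q in zip(self.ref_aln, self.qry_aln):
            if r == "-" and q == "-":
                raise ValueError("gap-in-both column")

    @property
    def ref_seq(self) -> str:
        return self.ref_aln.replace("-", "")

    @property
    def qry_seq(self) -> str:
        return self.qry_aln.replace("-", "")


@dataclass
class VariantEvent:
    kind: str  # SNP | substitution_block | insertion | deletion
    ref_pos: int  # 1-based; for indels the reference base immediately 5'
    length: int
    ref_allele: str
    qry_allele: str
    qry_id: str = ""


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] = -1 if seq[i : i + k] in counts else i
    return {kmer: pos for kmer, pos in counts.items() if pos >= 0}


def _lis_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain strictly increasing in the query coordinate.

    ``pairs`` must be sorted by reference position (strictly increasing).
    """
    import bisect

    tails: list[int] = []  # qry values
    tails_idx: list[int] = []
    parent = [-1] * len(pairs)
    for idx, (_, q) in enumerate(pairs):
        j = bisect.bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tails_idx.append(idx)
        else:
            tails[j] = q
            tails_idx[j] = idx
        parent[idx] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    cur = tails_idx[-1] if tails_idx else -1
    while cur != -1:
        chain.append(pairs[cur])
        cur = parent[cur]
    return chain[::-1]


def _segment_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    # gap of length g costs 5 + 2 g
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def _align_segment(aligner, a: str, b: str) -> tuple[str, str]:
    if not a and not b:
        return "", ""
    if not a:
        return "-" * len(b), b
    if not b:
        return a, "-" * len(a)
    aln = aligner.align(a, b)[0]
    # reconstruct gapped strings from the aligned coordinate blocks
    ra, qa = [], []
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        if sa > pa:
            ra.append(a[pa:sa])
            qa.append("-" * (sa - pa))
        if sb > pb:
            ra.append("-" * (sb - pb))
            qa.append(b[pb:sb])
        ra.append(a[sa:ea])
        qa.append(b[sb:eb])
        pa, pb = ea, eb
    if pa < len(a):
        ra.append(a[pa:])
        qa.append("-" * (len(a) - pa))
    if pb < len(b):
        ra.append("-" * (len(b) - pb))
        qa.append(b[pb:])
    return "".join(ra), "".join(qa)


def align_collinear(
    ref: Plastome, qry: Plastome, k: int = 21, max_gap_span: int = 5000
) -> PairwiseAlignment:
    """Anchored collinear global alignment of two plastomes.

    k-mers unique in both sequences are matched and chained by the
    longest strictly increasing chain; inter-anchor segments are aligned
    globally with affine gaps (match +1, mismatch -2, gap open -5, gap
    extend -2).  An inter-anchor span larger than ``max_gap_span`` on
    either sequence signals non-collinearity (inversion/transposition)
    and raises :class:`NonCollinearError`.
    """
    rseq, qseq = ref.sequence, qry.sequence
    ref_kmers = _unique_kmers(rseq, k)
    qry_kmers = _unique_kmers(qseq, k)
    shared = [(rp, qry_kmers[kmer]) for kmer, rp in ref_kmers.items() if kmer in qry_kmers]
    if not shared:
        raise NonCollinearError(
            f"no unique shared {k}-mers between {ref.id} and {qry.id}"
        )
    shared.sort()
    chain = _lis_chain(shared)
    if len(chain) < max(1, len(shared) // 2):
        raise NonCollinearError(
            f"{ref.id} vs {qry.id}: only {len(chain)} of {len(shared)} unique "
            "shared k-mers chain collinearly"
        )
    # enforce non-overlapping anchors (greedy left-to-right)
    anchors: list[tuple[int, int]] = []
    for rp, qp in chain:
        if not anchors or (rp >= anchors[-1][0] + k and qp >= anchors[-1][1] + k):
            anchors.append((rp, qp))
    aligner = _segment_aligner()
    ra_parts: list[str] = []
    qa_parts: list[str] = []
    pr = pq = 0
    bounds = anchors + [(len(rseq), len(qseq))]
    for rp, qp in bounds:
        seg_r = rseq[pr:rp]
        seg_q = qseq[pq:qp]
        if len(seg_r) > max_gap_span or len(seg_q) > max_gap_span:
            raise NonCollinearError(
                f"{ref.id} vs {qry.id}: inter-anchor span {max(len(seg_r), len(seg_q))} "
                f"exceeds {max_gap_span}; sequences are not collinear here"
            )
        ar, aq = _align_segment(aligner, seg_r, seg_q)
        ra_parts.append(ar)
        qa_parts.append(aq)
        if (rp, qp) != bounds[-1]:
            ra_parts.append(rseq[rp : rp + k])
            qa_parts.append(qseq[qp : qp + k])
            pr, pq = rp + k, qp + k
    aln = PairwiseAlignment(
        ref_id=ref.id,
        qry_id=qry.id,
        ref_aln="".join(ra_parts),
        qry_aln="".join(qa_parts),
        anchors=anchors,
        k=k,
    )
    if aln.ref_seq != rseq or aln.qry_seq != qseq:
        raise AssertionError("alignment does not round-trip its inputs")
    return aln


def _normalise_deletion(ref: str, pos: int, length: int) -> int:
    """Left-align a deletion of ref[pos..pos+length-1] (0-based start)."""
    while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
        pos -= 1
    return pos


def _normalise_insertion(ref: str, anchor: int, ins: str) -> tuple[int, str]:
    """Left-align an insertion occurring after 0-based ref index ``anchor``."""
    while anchor >= 0 and ins and ref[anchor] == ins[-1]:
        ins = ins[-1] + ins[:-1]
        anchor -= 1
    return anchor, ins


def call_variants(aln: PairwiseAlignment) -> list[VariantEvent]:
    """Extract SNPs, substitution blocks, insertions and deletions.

    Maximal gap runs in the query become one deletion each, maximal gap
    runs in the reference one insertion each (anchored at the reference
    base immediately 5', left-normalised).  Isolated mismatch columns are
    SNPs; runs of two or more contiguous mismatch columns form one
    substitution block.
    """
    ref = aln.ref_seq
    events: list[VariantEvent] = []
    i = 0
    ncols = len(aln.ref_aln)
    rpos = 0  # number of ref bases consumed
    while i < ncols:
        r, q = aln.ref_aln[i], aln.qry_aln[i]
        if q == "-":
            j = i
            while j < ncols and aln.qry_aln[j] == "-":
                j += 1
            length = j - i
            pos0 = _normalise_deletion(ref, rpos, length)
            events.append(
                VariantEvent(
                    kind="deletion",
                    ref_pos=pos0,  # 1-based base immediately 5' == 0-based start
                    length=length,
                    ref_allele=ref[pos0 : pos0 + length],
                    qry_allele="",
                    qry_id=aln.qry_id,
                )
            )
            rpos += length
            i = j
        elif r == "-":
            j = i
            while j < ncols and aln.ref_aln[j] == "-":
                j += 1
            ins = aln.qry_aln[i:j]
            anchor0, ins = _normalise_insertion(ref, rpos - 1, ins)
            events.append(
                VariantEvent(
                    kind="insertion",
                    ref_pos=anchor0 + 1,  # 1-based anchor base (0 if before start)
                    length=j - i,
                    ref_allele="",
                    qry_allele=ins,
                    qry_id=aln.qry_id,
                )
            )
            i = j
        elif r != q:
            j = i
            run_rpos = rpos
            while (
                j < ncols
                and aln.ref_aln[j] != "-"
                and aln.qry_aln[j] != "-"
                and aln.ref_aln[j] != aln.qry_aln[j]
            ):
                j += 1
            length = j - i
            events.append(
                VariantEvent(
                    kind="SNP" if length == 1 else "substitution_block",
                    ref_pos=run_rpos + 1,
                    length=length,
                    ref_allele=aln.ref_aln[i:j],
                    qry_allele=aln.qry_aln[i:j],
                    qry_id=aln.qry_id,
                )
            )
            rpos += length
            i = j
        else:
            rpos += 1
            i += 1
    return sorted(events, key=lambda e: (e.ref_pos, e.kind))


def tandem_overlap_fractions(events, tandems, flank: int = 0):
    """Fractions of insertions and deletions lying within tandem loci.

    An event is "within" a tandem when its anchor position lies inside
    ``[start - flank, end + flank]`` of any tandem hit.  Returns a dict
    with counts and fractions for insertions and deletions (fraction is
    None when there are no events of that class).
    """
    intervals = sorted((t.start - flank, t.end + flank) for t in tandems)
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    mstarts = [s for s, _ in merged]

    def inside(pos: int) -> bool:
        j = bisect_right(mstarts, pos) - 1
        return j >= 0 and merged[j][0] <= pos <= merged[j][1]

    out = {}
    for kind in ("insertion", "deletion"):
        evs = [e for e in events if e.kind == kind]
        n_in = sum(1 for e in evs if inside(e.ref_pos))
        out[kind] = {
            "n": len(evs),
            "n_in_tandem": n_in,
            "fraction": (n_in / len(evs)) if evs else None,
        }
    return out["insertion"]["fraction"], out["deletion"]["fraction"], out
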