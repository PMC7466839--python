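"""Collinear alignment and variant event extraction."""

import numpy as np
import pytest
from Bio import Align

from plastkit import (
    NonCollinearError,
    Plastome,
    align_collinear,
    call_variants,
    mutate_species,
    synthesize_reference,
    tandem_overlap_fractions,
    tiny_spec,
)
from plastkit.variants import PairwiseAlignment


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _plast(seq, pid="x"):
    return Plastome(id=pid, sequence=seq)


def test_identical_sequences_align_cleanly(rng):
    s = random_dna(rng, 3000)
    aln = align_collinear(_plast(s, "r"), _plast(s, "q"))
    assert "-" not in aln.ref_aln and "-" not in aln.qry_aln
    assert aln.ref_aln == aln.qry_aln
    assert call_variants(aln) == []


def test_planted_events_recovered_vs_full_dp(rng):
    """3 SNPs and one 5 bp deletion planted in a 2 kbp pair: the anchored
    aligner recovers exactly the planted events, and the event set equals
    the one read off a full Needleman-Wunsch alignment of the pair."""
    ref = random_dna(rng, 2000)
    qry = list(ref)
    for pos, base in ((300, "A"), (900, "C"), (1500, "G")):
        qry[pos] = base if qry[pos] != base else ("T" if base != "T" else "A")
    qry = "".join(qry[:1200] + qry[1205:])
    aln = align_collinear(_plast(ref, "r"), _plast(qry, "q"), k=15)
    events = call_variants(aln)
    assert sum(1 for e in events if e.kind == "SNP") == 3
    dels = [e for e in events if e.kind == "deletion"]
    assert len(dels) == 1 and dels[0].length == 5
    assert not any(e.kind == "insertion" for e in events)

    # full-DP oracle on the whole pair
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    full = aligner.align(ref, qry)[0]
    ra, qa = [], []
    pa = pb = 0
    for (sa, ea), (sb, eb) in zip(*full.aligned):
        ra += ["-" * (sb - pb), ref[pa:sa], ref[sa:ea]]
        qa += [qry[pb:sb], "-" * (sa - pa), qry[sb:eb]]
        pa, pb = ea, eb
    ra.append(ref[pa:] + "-" * (len(qry) - pb))
    qa.append("-" * (len(ref) - pa) + qry[pb:])
    oracle_aln = PairwiseAlignment(
        ref_id="r", qry_id="q", ref_aln="".join(ra), qry_aln="".join(qa),
        anchors=[], k=0,
    )
    oracle_events = call_variants(oracle_aln)
    key = lambda e: (e.kind, e.ref_pos, e.length, e.ref_allele, e.qry_allele)
    assert sorted(map(key, events)) == sorted(map(key, oracle_events))


def test_reversed_segment_raises_non_collinear(rng):
    s = random_dna(rng, 30_000)
    qry = s[:10_000] + s[10_000:20_000][::-1] + s[20_000:]
    with pytest.raises(NonCollinearError):
        align_collinear(_plast(s, "r"), _plast(qry, "q"))


def test_alignment_roundtrip_property(rng):
    for seed in range(10):
        r = np.random.default_rng(3300 + seed)
        ref = random_dna(r, 1500)
        qry = list(ref)
        # scatter a few SNPs and a small insertion
        for _ in range(5):
            p = int(r.integers(0, len(qry)))
            qry[p] = "ACGT"[int(r.integers(0, 4))]
        ins_at = int(r.integers(200, 1200))
        qry = qry[:ins_at] + list(random_dna(r, 3)) + qry[ins_at:]
        aln = align_collinear(_plast(ref, "r"), _plast("".join(qry), "q"), k=15)
        assert aln.ref_seq == ref
        assert aln.qry_seq == "".join(qry)
        # event conservation: gap columns match indel length totals
        events = call_variants(aln)
        del_total = sum(e.length for e in events if e.kind == "deletion")
        ins_total = sum(e.length for e in events if e.kind == "insertion")
        assert del_total == aln.qry_aln.count("-")
        assert ins_total == aln.ref_aln.count("-")


def test_snp_and_maximal_gap_run_semantics():
    aln = PairwiseAlignment(
        ref_id="r", qry_id="q",
        ref_aln="ACGTACGTAAATTT",
        qry_aln="ACTTAC---AATTT",
        anchors=[], k=0,
    )
    events = call_variants(aln)
    kinds = sorted(e.kind for e in events)
    assert kinds == ["SNP", "deletion"]
    snp = next(e for e in events if e.kind == "SNP")
    assert snp.ref_pos == 3 and snp.ref_allele == "G" and snp.qry_allele == "T"
    dele = next(e for e in events if e.kind == "deletion")
    assert dele.length == 3  # one event, not three


def test_substitution_block_vs_snps():
    aln = PairwiseAlignment(
        ref_id="r", qry_id="q",
        ref_aln="AAAACGTTTT",
        qry_aln="AAAGTGTTTT",
        anchors=[], k=0,
    )
    events = call_variants(aln)
    assert [e.kind for e in events] == ["substitution_block"]
    assert events[0].length == 2 and events[0].ref_pos == 4


def test_indel_left_normalisation():
    # deletion inside a homopolymer must be anchored at the run start
    aln = PairwiseAlignment(
        ref_id="r", qry_id="q",
        ref_aln="CGAAAAT",
        qry_aln="CGAA--T",
        anchors=[], k=0,
    )
    (e,) = call_variants(aln)
    assert e.kind == "deletion"
    assert e.ref_pos == 2  # anchored at the base before the first A
    assert e.ref_allele == "AA"


def test_tandem_overlap_fractions_closed_form():
    class T:
        def __init__(s, a, b):
            s.start, s.end = a, b

    class E:
        def __init__(s, kind, pos):
            s.kind, s.ref_pos = kind, pos

    events = [E("insertion", 50), E("insertion", 500), E("deletion", 60)]
    fi, fd, detail = tandem_overlap_fractions(events, [T(40, 70)])
    assert fi == 0.5
    assert fd == 1.0
    assert detail["insertion"]["n"] == 2
    fi, fd, _ = tandem_overlap_fractions(events, [])
    assert fi == 0.0 and fd == 0.0


def test_tandem_overlap_matches_containment_scan(rng):
    class T:
        def __init__(s, a, b):
            s.start, s.end = a, b

    class E:
        def __init__(s, kind, pos):
            s.kind, s.ref_pos = kind, pos

    tandems = []
    p = 1
    for _ in range(30):
        p += int(rng.integers(20, 200))
        tandems.append(T(p, p + int(rng.integers(5, 80))))
    events = [
        E("insertion" if rng.random() < 0.5 else "deletion", int(rng.integers(1, 6000)))
        for _ in range(200)
    ]
    fi, fd, detail = tandem_overlap_fractions(events, tandems)

    def brute(kind):
        evs = [e for e in events if e.kind == kind]
        n_in = sum(
            1 for e in evs if any(t.start <= e.ref_pos <= t.end for t in tandems)
        )
        return n_in / len(evs)

    assert fi == pytest.approx(brute("insertion"))
    assert fd == pytest.approx(brute("deletion"))


def test_pipeline_roundtrip_recovers_planted_events():
    """Planted truth events equal called events on synthetic species."""
    spec = tiny_spec(seed=21, snp_rate=0.15, indel_rate=0.06, min_event_spacing=50)
    ref, truth = synthesize_reference(spec)
    species, truth = mutate_species(ref, truth, spec)
    for sp in species:
        aln = align_collinear(ref, sp, k=15)
        called = {
            (e.kind, e.ref_pos, e.length) for e in call_variants(aln)
        }
        planted = {
            (e["kind"], e["ref_pos"], e["length"])
            for e in truth.species_events[sp.id]
        }
        assert called == planted
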