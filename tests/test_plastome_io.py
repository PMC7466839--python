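"""Plastome records, quadripartite detection, loci, junctions, tracks."""

import numpy as np
import pytest

from plastkit import (
    AmbiguousIRError,
    Feature,
    PartitionError,
    Plastome,
    PlastomeValidationError,
    detect_quadripartite,
    extract_loci,
    gc_content,
    junction_distances,
    read_genbank,
    read_tracks,
    revcomp,
    write_genbank,
    write_tracks,
)
from plastkit.partition import RegionPartition

from .oracles import maximal_inverted_pairs, rc


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

MINI_GB = """LOCUS       MINI                 300 bp    DNA     circular PLN 01-JAN-2020
DEFINITION  handcrafted two-exon record.
ACCESSION   MINI
VERSION     MINI.1
FEATURES             Location/Qualifiers
     CDS             join(11..19,31..39)
                     /gene="toyA"
ORIGIN
        1 {seq}
//
"""


def _mini_gb_text():
    rng = np.random.default_rng(0)
    seq = random_dna(rng, 300).lower()
    lines = []
    for i in range(0, 300, 60):
        chunk = " ".join(seq[j : j + 10] for j in range(i, i + 60, 10))
        lines.append(f"{i + 1:>9} {chunk}")
    body = MINI_GB.replace("        1 {seq}", "\n".join(lines))
    return body, seq.upper()


def test_read_genbank_compound_cds(tmp_path):
    """A two-exon forward CDS is captured with both parts preserved."""
    text, seq = _mini_gb_text()
    path = tmp_path / "mini.gb"
    path.write_text(text)
    p = read_genbank(path)
    assert len(p.sequence) == 300 and p.sequence == seq
    cds = [f for f in p.features if f.kind == "CDS"]
    assert len(cds) == 1
    assert cds[0].parts == [(11, 19), (31, 39)]
    assert cds[0].name == "toyA"
    assert not cds[0].trans_spliced


def test_read_genbank_trans_spliced(tmp_path):
    """A trans_splicing qualifier (rps12-style) sets the flag."""
    text, _ = _mini_gb_text()
    text = text.replace('/gene="toyA"', '/gene="rps12"\n                     /trans_splicing')
    path = tmp_path / "ts.gb"
    path.write_text(text)
    p = read_genbank(path)
    assert p.features[0].trans_spliced


def test_feature_interval_beyond_sequence_rejected():
    with pytest.raises(PlastomeValidationError, match="bad"):
        Plastome(
            id="bad",
            sequence="ACGT" * 10,
            features=[Feature(name="bad", kind="CDS", strand="+", parts=[(30, 60)])],
        )


def test_genbank_roundtrip_through_writer(tmp_path, tiny_genome):
    _, ref, _ = tiny_genome
    path = tmp_path / "synth.gb"
    write_genbank(ref, path)
    back = read_genbank(path)
    assert back.sequence == ref.sequence
    assert len(back.features) == len(ref.features)
    assert {(f.name, tuple(f.parts), f.strand) for f in back.features} == {
        (f.name, tuple(f.parts), f.strand) for f in ref.features
    }


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [("ATGC", 50.0), ("AAAA", 0.0), ("GGCC", 100.0), ("ATGCN", 50.0), ("GGGCA", 80.0)],
)
def test_gc_content_closed_form(seq, expected):
    assert gc_content(Plastome(id="x", sequence=seq)) == expected


def test_gc_content_all_n_undefined():
    with pytest.raises(ValueError):
        gc_content(Plastome(id="x", sequence="NNNN"))


# ---------------------------------------------------------------------------
# Quadripartite detection
# ---------------------------------------------------------------------------


def test_no_ir_raises(rng):
    seq = random_dna(rng, 2000)
    p = Plastome(id="r", sequence=seq)
    with pytest.raises(PartitionError):
        detect_quadripartite(p, min_ir_len=300)


def test_planted_ir_exact_recovery(rng):
    lsc = random_dna(rng, 1000)
    irb = random_dna(rng, 300)
    ssc = random_dna(rng, 200)
    p = Plastome(id="s", sequence=lsc + irb + ssc + revcomp(irb))
    part = detect_quadripartite(p, min_ir_len=250)
    assert part.lsc == (1, 1000)
    assert part.irb == (1001, 1300)
    assert part.ssc == (1301, 1500)
    assert part.ira == (1501, 1800)
    assert part.ir_length == 300 and part.mismatches == 0
    assert part.total_length == len(p.sequence)


def test_detection_matches_bruteforce_oracle_on_planted_genomes():
    """On 100 seeded random genomes with planted IRs the detected pair is
    the unique maximal inverted pair the all-pairs oracle finds."""
    for seed in range(100):
        r = np.random.default_rng(1000 + seed)
        lsc_n = int(r.integers(400, 900))
        ir_n = int(r.integers(150, 300))
        ssc_n = int(r.integers(100, 300))
        lsc, irb, ssc = (random_dna(r, n) for n in (lsc_n, ir_n, ssc_n))
        seq = lsc + irb + ssc + rc(irb)
        p = Plastome(id=f"g{seed}", sequence=seq)
        try:
            part = detect_quadripartite(p, min_ir_len=120)
        except AmbiguousIRError:
            pairs = maximal_inverted_pairs(seq, 120)
            best = max(length for _, _, length in pairs)
            assert sum(1 for c in pairs if c[2] == best) > 1
            continue
        pairs = maximal_inverted_pairs(seq, 120)
        best = max(pairs, key=lambda c: c[2])
        assert part.irb[0] - 1 == best[0]
        assert part.ira[0] - 1 == best[1]
        assert part.ir_length == best[2]
        # partition coverage and IR symmetry invariants
        assert part.total_length == len(seq)
        irb_seq = seq[part.irb[0] - 1 : part.irb[1]]
        ira_seq = seq[part.ira[0] - 1 : part.ira[1]]
        assert rc(ira_seq) == irb_seq


def test_near_identical_ir_mismatch_budget(rng):
    lsc = random_dna(rng, 3000)
    irb = random_dna(rng, 2500)
    ssc = random_dna(rng, 500)
    ira = list(revcomp(irb))
    ira[700] = "A" if ira[700] != "A" else "C"  # one substitution
    p = Plastome(id="m", sequence=lsc + irb + ssc + "".join(ira))
    part = detect_quadripartite(p, min_ir_len=2000, max_mismatch_frac=0.001)
    # the planted copy pair is recovered; the fuzzy boundary may extend a
    # base or two into chance-matching flank within the mismatch budget
    assert 2500 <= part.ir_length <= 2510
    assert part.mismatches <= part.ir_length * 0.001
    assert part.irb[0] <= 3001 <= part.irb[1]


def test_synthetic_partition_recovery(tiny_genome):
    spec, ref, truth = tiny_genome
    part = detect_quadripartite(ref, min_ir_len=spec.ir_len // 2)
    assert part.to_dict()["lsc"] == truth.partition["lsc"]
    assert part.to_dict()["ira"] == truth.partition["ira"]


# ---------------------------------------------------------------------------
# Locus extraction
# ---------------------------------------------------------------------------


def _flat_partition(n):
    return RegionPartition(
        lsc=(1, n - 30), irb=(n - 29, n - 20), ssc=(n - 19, n - 10), ira=(n - 9, n),
        ir_length=10, mismatches=0,
    )


def test_extract_forward_and_reverse_loci():
    seq = "N" * 10 + "ATGAAATGA" + "N" * 10 + "TTTCAT" + "N" * 15
    feats = [
        Feature(name="fw", kind="CDS", strand="+", parts=[(11, 19)]),
        Feature(name="rv", kind="tRNA", strand="-", parts=[(30, 35)]),
    ]
    p = Plastome(id="t", sequence=seq, features=feats)
    loci = extract_loci(p, _flat_partition(len(seq)))
    by_name = {l.name: l for l in loci}
    assert by_name["fw"].sequence == "ATGAAATGA"
    assert by_name["rv"].sequence == "ATGAAA"  # revcomp of TTTCAT
    ig = by_name["fw-rv"]
    assert ig.klass == "intergenic" and ig.start == 20 and ig.end == 29


def test_intergenic_gap_length():
    seq = "A" * 100
    feats = [
        Feature(name="geneA", kind="CDS", strand="+", parts=[(1, 30)]),
        Feature(name="geneB", kind="CDS", strand="+", parts=[(56, 90)]),
    ]
    p = Plastome(id="t", sequence=seq, features=feats)
    loci = extract_loci(p, _flat_partition(100))
    ig = [l for l in loci if l.klass == "intergenic"]
    assert len(ig) == 1
    assert ig[0].name == "geneA-geneB"
    assert ig[0].end - ig[0].start + 1 == 25


def test_intron_loci_from_compound_gene():
    seq = "ACGT" * 30
    f = Feature(name="g", kind="CDS", strand="+", parts=[(1, 12), (31, 45)])
    p = Plastome(id="t", sequence=seq, features=[f])
    loci = extract_loci(p, _flat_partition(120))
    introns = [l for l in loci if l.klass == "intron"]
    assert len(introns) == 1
    assert (introns[0].start, introns[0].end) == (13, 30)


# ---------------------------------------------------------------------------
# Junction distances
# ---------------------------------------------------------------------------


def _partitioned_plastome(gene_parts):
    seq = "A" * 500 + "C" * 200 + "G" * 100 + "T" * 200
    feats = [
        Feature(name=n, kind="CDS", strand="+", parts=[span]) for n, span in gene_parts
    ]
    p = Plastome(id="j", sequence=seq, features=feats)
    part = RegionPartition(
        lsc=(1, 500), irb=(501, 700), ssc=(701, 800), ira=(801, 1000),
        ir_length=200, mismatches=0,
    )
    return p, part


def test_gene_ending_exactly_at_border():
    p, part = _partitioned_plastome([("edge", (451, 500))])
    rows = junction_distances(p, part).rows
    row = next(r for r in rows if r.gene == "edge" and r.junction == "LSC/IRB")
    assert row.distance == 0 and row.side == "inside-SC"


def test_straddling_gene_overhangs():
    p, part = _partitioned_plastome([("str", (493, 520))])
    rows = junction_distances(p, part).rows
    row = next(r for r in rows if r.side == "straddling")
    assert row.junction == "LSC/IRB"
    assert row.overhangs == (8, 20)
    assert sum(row.overhangs) == 28  # the gene span length


def test_junction_distances_on_synthetic(tiny_genome):
    spec, ref, _ = tiny_genome
    part = detect_quadripartite(ref, min_ir_len=spec.ir_len // 2)
    report = junction_distances(ref, part)
    assert all(r.distance >= 0 for r in report.rows)
    junctions = {r.junction for r in report.rows}
    assert junctions <= {"LSC/IRB", "IRB/SSC", "SSC/IRA", "IRA/LSC"}


def test_empty_report_without_genes():
    p = Plastome(id="e", sequence="A" * 1000)
    part = RegionPartition(
        lsc=(1, 500), irb=(501, 700), ssc=(701, 800), ira=(801, 1000),
        ir_length=200, mismatches=0,
    )
    assert junction_distances(p, part).rows == []


# ---------------------------------------------------------------------------
# Track writing
# ---------------------------------------------------------------------------


def test_bed_is_zero_based_half_open(tmp_path):
    path = tmp_path / "t.bed"
    write_tracks([(1, 150, "x")], path, fmt="BED", chrom="chr")
    line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
    assert line.split("\t")[:3] == ["chr", "0", "150"]


def test_empty_track_is_header_only(tmp_path):
    path = tmp_path / "e.tsv"
    write_tracks([], path, fmt="TSV")
    lines = path.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("#")


def test_track_roundtrip_byte_identical(tmp_path, rng):
    items = []
    for _ in range(30):
        s = int(rng.integers(1, 5000))
        e = s + int(rng.integers(0, 300))
        items.append((s, e, f"el{s}"))
    p1 = tmp_path / "a.bed"
    p2 = tmp_path / "b.bed"
    write_tracks(items, p1, fmt="BED", chrom="c")
    write_tracks(read_tracks(p1, fmt="BED"), p2, fmt="BED")
    assert p1.read_bytes() == p2.read_bytes()
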