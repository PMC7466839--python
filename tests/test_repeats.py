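"""SSR, tandem, and dispersed repeat detectors vs brute-force oracles."""

import numpy as np
import pytest

from plastkit import (
    classify_locations,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
    revcomp,
)
from plastkit.partition import RegionPartition
from plastkit.plastome import Feature
from plastkit.repeats import DEFAULT_SSR_MINIMA, canonical_rotation

from .oracles import dispersed_enumerate, rc, ssr_scan, tandem_enumerate


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def test_mono_threshold_boundary(rng):
    bg = random_dna(rng, 60).replace("A", "C")
    assert find_ssrs(bg[:30] + "A" * 9 + bg[30:]) == []
    hits = find_ssrs(bg[:30] + "A" * 10 + bg[30:])
    assert len(hits) == 1
    h = hits[0]
    assert (h.motif, h.copies, h.ssr_class) == ("A", 10, "p1")
    assert h.end - h.start + 1 == 10


def test_two_ssrs_with_spacer_match_oracle(rng):
    spacer = random_dna(rng, 30).replace("A", "G").replace("T", "C")
    s = "ATATATATATAT" + spacer + "T" * 11
    simple = find_ssrs(s, merge_composites=False)
    oracle = ssr_scan(s, DEFAULT_SSR_MINIMA)
    assert len(simple) == 2
    assert [(h.start - 1, h.end - 1, h.copies) for h in simple] == [
        (a, b, c) for _, a, b, c in oracle
    ]
    # within the composite join distance the two merge into one composite
    merged = find_ssrs(s)
    assert len(merged) == 1 and merged[0].ssr_class == "composite"
    assert len(merged[0].components) == 2


def test_ssr_oracle_sweep():
    """Simple-run detection equals the naive motif scanner on seeded
    strings with planted runs."""
    for seed in range(60):
        r = np.random.default_rng(7000 + seed)
        s = random_dna(r, int(r.integers(100, 1000)))
        # plant a few runs to make positives common
        for _ in range(3):
            m = int(r.integers(1, 7))
            motif = random_dna(r, m)
            copies = int(r.integers(4, 14))
            pos = int(r.integers(0, len(s) - m * copies))
            s = s[:pos] + motif * copies + s[pos + m * copies :]
        got = [
            (h.start - 1, h.end - 1, h.copies)
            for h in find_ssrs(s, merge_composites=False)
        ]
        expected = [(a, b, c) for _, a, b, c in ssr_scan(s, DEFAULT_SSR_MINIMA)]
        assert got == expected, f"seed {seed}"


def test_simple_ssrs_never_overlap_and_composites_disjoint(rng):
    for seed in range(20):
        r = np.random.default_rng(8800 + seed)
        s = random_dna(r, 500) + "A" * 12 + "ATATATATATATAT" + random_dna(r, 100)
        hits = find_ssrs(s)
        spans = []
        for h in hits:
            spans.append((h.start, h.end))
            if h.ssr_class == "composite":
                comps = h.components
                assert all(
                    c1.end < c2.start for c1, c2 in zip(comps, comps[1:])
                )
        spans.sort()
        assert all(a2 > b1 for (_, b1), (a2, _) in zip(spans, spans[1:]))


def test_n_breaks_runs():
    pad = "GACTGCTAGTCAGCATCGAT"  # repeat-free pad
    s = pad + "AAAAANAAAAA" + pad
    assert find_ssrs(s) == []
    assert find_ssrs(pad + "A" * 10 + "N" + pad) != []


def test_canonical_rotation():
    assert canonical_rotation("TA") == "AT"
    assert canonical_rotation("GCA") == "AGC"
    assert canonical_rotation("A") == "A"


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------


def test_perfect_tandem_toy():
    hits = find_tandem_repeats("ACGTACGTACGTACG", unit_min=4, unit_max=8)
    assert len(hits) == 1
    h = hits[0]
    assert (h.unit, h.start, h.end) == ("ACGT", 1, 15)
    assert h.copies == pytest.approx(3.75)
    assert h.identity == pytest.approx(100.0)


def test_imperfect_tandem_identity_arithmetic(rng):
    unit = "ACGTTGCAAC"  # 10-mer, three copies, one substitution
    arr = list(unit * 3)
    arr[14] = "A" if arr[14] != "A" else "G"
    pad_l = random_dna(rng, 25)
    pad_r = random_dna(rng, 25)
    s = pad_l + "".join(arr) + pad_r
    hits = find_tandem_repeats(s, unit_min=8, unit_max=14)
    inner = [h for h in hits if h.start <= 26 + 5 and h.end >= 26 + 24]
    assert inner, hits
    h = max(inner, key=lambda x: x.length)
    assert h.unit_len == 10
    assert h.copies >= 2.9
    assert h.identity >= 85.0
    # hand-checked consensus arithmetic on the exact planted span: one
    # substitution among three copies leaves 29 of 30 positions matching
    # the column-majority consensus
    planted = s[25:55]
    matches = 0
    for col in range(10):
        from collections import Counter

        counts = Counter(planted[col::10])
        matches += max(counts.values())
    assert matches == 29


def test_tandem_oracle_sweep():
    """Exhaustive-mode detector equals full enumeration on short strings."""
    for seed in range(30):
        r = np.random.default_rng(9100 + seed)
        s = random_dna(r, int(r.integers(60, 130)))
        if seed % 2 == 0:  # plant an imperfect array
            u = int(r.integers(4, 10))
            unit = random_dna(r, u)
            copies = int(r.integers(2, 5))
            arr = list(unit * copies)
            if len(arr) > 8:
                arr[int(r.integers(0, len(arr)))] = "A"
            pos = int(r.integers(0, len(s) - len(arr)))
            s = s[:pos] + "".join(arr) + s[pos + len(arr) :]
        got = [
            (h.start - 1, h.end - 1, h.unit_len)
            for h in find_tandem_repeats(
                s, unit_min=4, unit_max=12, exhaustive=True
            )
        ]
        expected = [
            (a, b, u) for a, b, u, _ in tandem_enumerate(s, 4, 12, 85.0)
        ]
        assert sorted(got) == sorted(expected), f"seed {seed}"


def test_tandem_monotonicity_in_identity(rng):
    s = random_dna(rng, 400)
    loose = find_tandem_repeats(s, unit_min=5, unit_max=20, min_identity=80)
    strict = find_tandem_repeats(s, unit_min=5, unit_max=20, min_identity=95)
    # raising the identity threshold never adds covered sequence
    cov_loose = sum(h.length for h in loose)
    cov_strict = sum(h.length for h in strict)
    assert len(strict) <= len(loose) or cov_strict <= cov_loose


def test_tandem_hits_never_overlap(rng):
    s = random_dna(rng, 600) + "ACGTACG" * 6 + random_dna(rng, 100)
    hits = sorted(find_tandem_repeats(s, unit_min=5, unit_max=30), key=lambda h: h.start)
    for a, b in zip(hits, hits[1:]):
        assert a.end < b.start
    for h in hits:
        assert h.identity >= 85.0
        assert h.length >= 2 * h.unit_len


# ---------------------------------------------------------------------------
# Dispersed repeats
# ---------------------------------------------------------------------------


def test_planted_forward_pair_covered(rng):
    bg = random_dna(rng, 400)
    seg = random_dna(rng, 25)
    s = bg[:100] + seg + bg[125:300] + seg + bg[325:]
    hits = find_dispersed_repeats(s)
    fw = [h for h in hits if h.kind == "forward"]
    assert any(
        h.pos1 <= 101 and h.pos1 + h.len - 1 >= 125 and h.mismatches <= 2 for h in fw
    )


def test_planted_palindromic_pair_covered(rng):
    bg = random_dna(rng, 400)
    seg = random_dna(rng, 24)
    s = bg[:80] + seg + bg[104:300] + revcomp(seg) + bg[324:]
    hits = find_dispersed_repeats(s)
    assert any(h.kind == "palindromic" for h in hits)


def test_below_min_len_is_empty(rng):
    bg = "".join(
        c for c in random_dna(rng, 600)
    )
    seg = random_dna(rng, 20)
    s = bg[:100] + seg + bg[120:300] + seg + bg[320:]
    hits = find_dispersed_repeats(s, min_len=21, max_hamming=0)
    assert all(not (h.pos1 == 101 and h.len == 20) for h in hits)


def test_dispersed_oracle_sweep():
    """Seed-and-extend detector equals the all-pairs diagonal oracle."""
    for seed in range(30):
        r = np.random.default_rng(9500 + seed)
        s = random_dna(r, int(r.integers(120, 260)))
        seg = random_dna(r, int(r.integers(21, 30)))
        mode = seed % 4
        insert = [seg, rc(seg), seg[::-1], seg.translate(str.maketrans("ACGT", "TGCA"))][mode]
        p1 = int(r.integers(0, len(s) // 3))
        p2 = int(r.integers(len(s) // 2, len(s) - len(seg)))
        s = s[:p1] + seg + s[p1 + len(seg) : p2] + insert + s[p2 + len(insert) :]
        got = {
            (h.pos1, h.pos2, h.len): h.kind for h in find_dispersed_repeats(s)
        }
        expected = dispersed_enumerate(s, 21, 2)
        assert got == expected, f"seed {seed}"


def test_revcomp_equivariance(rng):
    """Reverse-complementing the input preserves kinds and reflects
    coordinates."""
    for seed in range(10):
        r = np.random.default_rng(9900 + seed)
        s = random_dna(r, 200)
        seg = random_dna(r, 24)
        s = s[:40] + seg + s[64:150] + seg + s[174:]
        n = len(s)
        fwd = find_dispersed_repeats(s)
        bwd = find_dispersed_repeats(revcomp(s))

        def reflect(h):
            a = n - (h.pos2 + h.len - 1) + 1
            b = n - (h.pos1 + h.len - 1) + 1
            return (a, b, h.len, h.kind)

        assert sorted(reflect(h) for h in fwd) == sorted(
            (h.pos1, h.pos2, h.len, h.kind) for h in bwd
        )


# ---------------------------------------------------------------------------
# Location classification
# ---------------------------------------------------------------------------


def _toy_partition():
    return RegionPartition(
        lsc=(1, 600), irb=(601, 750), ssc=(751, 850), ira=(851, 1000),
        ir_length=150, mismatches=0,
    )


class _Span:
    def __init__(self, start, end):
        self.start, self.end = start, end
        self.name = "x"


def test_classification_by_midpoint_and_context():
    part = _toy_partition()
    feats = [
        Feature(name="g1", kind="CDS", strand="+", parts=[(100, 200), (251, 300)]),
    ]
    hits = [
        _Span(120, 160),  # CDS
        _Span(205, 240),  # intron (between the parts, inside the span)
        _Span(400, 470),  # IGS in LSC
        _Span(590, 640),  # straddles LSC/IRB, midpoint 615 -> IR
        _Span(760, 790),  # SSC
    ]
    table = classify_locations(hits, part, feats)
    assert table.loc["LSC", "CDS"] == 1
    assert table.loc["LSC", "intron"] == 1
    assert table.loc["LSC", "IGS"] == 1
    assert table.loc["IR", "IGS"] == 1
    assert table.loc["SSC", "IGS"] == 1
    assert table.to_numpy().sum() == len(hits)


def test_classification_conserves_totals(rng, tiny_genome):
    spec, ref, _ = tiny_genome
    from plastkit import detect_quadripartite

    part = detect_quadripartite(ref, min_ir_len=spec.ir_len // 2)
    hits = [_Span(int(p), int(p) + 20) for p in rng.integers(1, len(ref) - 21, size=50)]
    table = classify_locations(hits, part, ref.features)
    assert table.to_numpy().sum() == 50
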