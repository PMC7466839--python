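"""Synthetic plastome generation with planted repeats and mutations.

The generator emulates the structure of a grass chloroplast genome: a
~136 kbp circular quadripartite sequence (LSC ~80 kbp, SSC ~12.8 kbp,
IRs ~21.6 kbp each, IRA the exact reverse complement of IRB), simple
CDS annotations tiled with intergenic gaps, planted SSRs and imperfect
tandem arrays at plastome-like densities, and derived "species"
sequences carrying SNPs and indels whose per-window rates are multiplied
by an enrichment factor beta in windows containing a planted tandem.
Everything is reproducible from a single integer seed, and the exact
planted truth (partition, repeats, per-species events) is returned
alongside the sequences.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
from Bio import SeqIO

from .plastome import Plastome, Feature, revcomp, write_fasta
from .variants import _normalise_deletion, _normalise_insertion

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "tiny_spec",
    "synthesize_reference",
    "mutate_species",
    "simulate_window_counts",
    "make_fixture_suite",
    "write_genbank",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SyntheticSpec:
    """Study conditions for the generator.

    Default region sizes and mutation rates mirror a typical oat-like
    plastome comparison: ~136 kbp AT-rich genomes (GC ~38.5%), twelve
    query species against one reference, tandem arrays with 7-95 bp
    units, and baseline rates chosen so that the *marginal* pooled event
    densities — about 1.1 SNPs and 0.27 indels per 150 bp window across
    all queries, once the beta-enrichment in the ~24% of windows
    carrying a tandem is averaged in — match a real congeneric plastome
    comparison.
    """

    seed: int = 0
    length: int = 136_000
    lsc_len: int = 80_000
    ir_len: int = 21_600
    gc: float = 0.385
    n_genes: int = 60
    gene_codon_range: tuple[int, int] = (120, 400)
    intergenic_gap_range: tuple[int, int] = (150, 600)
    n_tandems: int = 250
    tandem_unit_range: tuple[int, int] = (7, 95)
    tandem_copy_range: tuple[float, float] = (2.0, 5.0)
    tandem_sub_rate: float = 0.03
    n_ssrs: int = 25
    ssr_copy_range: tuple[int, int] = (10, 16)
    window: int = 150
    snp_rate: float = 0.059  # per single-copy window, per species
    indel_rate: float = 0.014  # per single-copy window, per species
    substitution_block_frac: float = 0.032  # point mutations drawn as 2-3 bp blocks
    beta: float = 5.0  # rate multiplier in tandem-bearing windows
    n_species: int = 12
    indel_mean_len: float = 4.0
    indel_max_len: int = 50
    min_event_spacing: int = 8

    @property
    def ssc_len(self) -> int:
        return self.length - self.lsc_len - 2 * self.ir_len

    def validate(self) -> None:
        if self.ssc_len <= 0:
            raise ValueError("region sizes exceed genome length")
        if self.beta < 1:
            raise ValueError("enrichment factor beta must be >= 1")
        if min(self.snp_rate, self.indel_rate) < 0:
            raise ValueError("rates must be >= 0")


def tiny_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A 2 kbp genome for fast oracle-scale tests."""
    defaults = dict(
        seed=seed,
        length=2000,
        lsc_len=1000,
        ir_len=300,
        n_genes=4,
        gene_codon_range=(30, 60),
        intergenic_gap_range=(40, 120),
        n_tandems=4,
        tandem_unit_range=(7, 20),
        n_ssrs=2,
        n_species=3,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


@dataclass
class SyntheticTruth:
    spec: SyntheticSpec
    partition: dict = field(default_factory=dict)
    tandems: list[dict] = field(default_factory=list)  # start/end/unit/identity (1-based)
    ssrs: list[dict] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    species_events: dict[str, list[dict]] = field(default_factory=dict)

    def tandem_windows(self, w: int | None = None) -> set[int]:
        w = w or self.spec.window
        out = set()
        for t in self.tandems:
            mid = (t["start"] + t["end"]) // 2
            out.add((mid + w - 1) // w)
        return out

    def to_json(self) -> str:
        payload = {
            "spec": asdict(self.spec),
            "partition": self.partition,
            "tandems": self.tandems,
            "ssrs": self.ssrs,
            "genes": self.genes,
            "species_events": self.species_events,
        }
        return json.dumps(payload, indent=1)


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Random CDS: ATG start, no internal stops, TAA stop."""
    probs = _base_probs(gc)
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), size=3, p=probs))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _overlaps(occupied: list[tuple[int, int]], s: int, e: int, pad: int = 10) -> bool:
    return any(s - pad <= oe and e + pad >= os_ for os_, oe in occupied)


def synthesize_reference(spec: SyntheticSpec) -> tuple[Plastome, SyntheticTruth]:
    """Build the reference plastome and its planted truth.

    Random LSC/SSC/IRB sequence with CDS annotations tiled through each
    region, planted tandem arrays and SSRs in intergenic space, and IRA
    set to the exact reverse complement of IRB (genes in IRB get
    mirrored IRA copies, so IR-duplicated genes appear twice as in real
    plastomes).  Byte-identical for a fixed spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.length
    probs = _base_probs(spec.gc)
    genome = rng.choice(_BASES, size=n, p=probs)  # uint8 array, 0-based

    lsc = (1, spec.lsc_len)
    irb = (lsc[1] + 1, lsc[1] + spec.ir_len)
    ssc = (irb[1] + 1, irb[1] + spec.ssc_len)
    ira = (ssc[1] + 1, n)
    truth = SyntheticTruth(spec=spec)
    truth.partition = {
        "lsc": list(lsc),
        "irb": list(irb),
        "ssc": list(ssc),
        "ira": list(ira),
        "ir_length": spec.ir_len,
    }

    # ---- genes: sequential tiling per region (quota ~ region length) ----
    features: list[Feature] = []
    occupied: list[tuple[int, int]] = []
    sc_regions = [lsc, ssc, irb]
    weights = np.array([e - s + 1 for s, e in sc_regions], dtype=float)
    quotas = np.maximum(1, np.round(spec.n_genes * weights / weights.sum())).astype(int)
    gi = 0
    for (rs, re_), quota in zip(sc_regions, quotas):
        cursor = rs + int(rng.integers(*spec.intergenic_gap_range))
        placed = 0
        while placed < quota:
            ncod = int(rng.integers(*spec.gene_codon_range))
            glen = 3 * ncod
            if cursor + glen - 1 > re_ - 50:
                break
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            cds = _random_cds(rng, ncod, spec.gc)
            oriented = cds if strand == "+" else revcomp(cds)
            genome[cursor - 1 : cursor - 1 + glen] = np.frombuffer(
                oriented.encode(), dtype=np.uint8
            )
            features.append(
                Feature(
                    name=f"g{gi:03d}",
                    kind="CDS",
                    strand=strand,
                    parts=[(cursor, cursor + glen - 1)],
                )
            )
            occupied.append((cursor, cursor + glen - 1))
            truth.genes.append(
                {"name": f"g{gi:03d}", "start": cursor, "end": cursor + glen - 1, "strand": strand}
            )
            placed += 1
            cursor += glen + int(rng.integers(*spec.intergenic_gap_range))

    # ---- planted tandem arrays (single-copy intergenic space only; IRs
    # evolve in concert and carry few repeats, so they stay repeat-free) ----
    def sc_position(size: int) -> int:
        lsc_room = lsc[1] - size
        ssc_room = (ssc[1] - size) - ssc[0] + 1
        if rng.random() < lsc_room / (lsc_room + max(1, ssc_room)):
            return int(rng.integers(2, lsc_room))
        return int(rng.integers(ssc[0], ssc[1] - size))

    planted = 0
    attempts = 0
    while planted < spec.n_tandems and attempts < spec.n_tandems * 60:
        attempts += 1
        u = int(rng.integers(spec.tandem_unit_range[0], spec.tandem_unit_range[1] + 1))
        copies = float(rng.uniform(*spec.tandem_copy_range))
        alen = int(round(u * copies))
        if alen < 2 * u:
            alen = 2 * u
        start = sc_position(alen + 2)
        end = start + alen - 1
        if _overlaps(occupied, start, end, pad=max(15, u)):
            continue
        unit = "".join(rng.choice(list("ACGT"), size=u, p=probs))
        array = (unit * math.ceil(alen / u))[:alen]
        arr = np.frombuffer(array.encode(), dtype=np.uint8).copy()
        max_subs = int(0.08 * alen)
        n_subs = min(int(rng.binomial(alen, spec.tandem_sub_rate)), max_subs)
        if n_subs:
            pos = rng.choice(alen, size=n_subs, replace=False)
            for pidx in pos:
                choices = _BASES[_BASES != arr[pidx]]
                arr[pidx] = rng.choice(choices)
        genome[start - 1 : end] = arr
        occupied.append((start, end))
        truth.tandems.append(
            {
                "start": start,
                "end": end,
                "unit": unit,
                "unit_len": u,
                "copies": alen / u,
                "identity": 100.0 * (alen - n_subs) / alen,
            }
        )
        planted += 1

    # ---- planted SSRs ----
    planted = 0
    attempts = 0
    while planted < spec.n_ssrs and attempts < spec.n_ssrs * 60:
        attempts += 1
        r = rng.random()
        if r < 0.85:
            motif = "A" if rng.random() < 0.5 else "T"
        elif r < 0.92:
            motif = "C" if rng.random() < 0.5 else "G"
        else:
            motif = "AT"
        copies = int(rng.integers(*spec.ssr_copy_range))
        run = motif * copies
        start = sc_position(len(run) + 2)
        end = start + len(run) - 1
        if _overlaps(occupied, start, end, pad=15):
            continue
        # the planted run must not extend by chance neighbours
        genome[start - 2] = ord("C") if motif[0] != "C" else ord("A")
        genome[end] = ord("C") if motif[-1] != "C" else ord("A")
        genome[start - 1 : end] = np.frombuffer(run.encode(), dtype=np.uint8)
        occupied.append((start, end))
        truth.ssrs.append(
            {"start": start, "end": end, "motif": motif, "copies": copies}
        )
        planted += 1

    # ---- IRA = reverse complement of IRB; mirror IRB gene annotations ----
    # break chance inward extension of the IR pair across the SSC: the
    # first and last SSC bases must not be reverse complements
    comp_map = {65: 84, 67: 71, 71: 67, 84: 65}
    ssc_first, ssc_last = ssc[0] - 1, ssc[1] - 1
    if genome[ssc_first] == comp_map[int(genome[ssc_last])]:
        if not _overlaps(occupied, ssc[1], ssc[1], pad=0):
            forbidden = comp_map[int(genome[ssc_first])]
            genome[ssc_last] = next(int(b) for b in _BASES if b != forbidden)
        else:
            forbidden = comp_map[int(genome[ssc_last])]
            genome[ssc_first] = next(int(b) for b in _BASES if b != forbidden)
    irb_seq = genome[irb[0] - 1 : irb[1]].tobytes().decode()
    ira_seq = revcomp(irb_seq)
    genome[ira[0] - 1 : ira[1]] = np.frombuffer(ira_seq.encode(), dtype=np.uint8)
    for f in list(features):
        if f.start >= irb[0] and f.end <= irb[1]:
            s2 = ira[0] + (irb[1] - f.end)
            e2 = ira[0] + (irb[1] - f.start)
            features.append(
                Feature(
                    name=f.name,
                    kind=f.kind,
                    strand="-" if f.strand == "+" else "+",
                    parts=[(s2, e2)],
                )
            )
            truth.genes.append(
                {"name": f.name, "start": s2, "end": e2, "strand": features[-1].strand}
            )

    ref = Plastome(
        id="synthref",
        sequence=genome.tobytes().decode(),
        circular=True,
        features=sorted(features, key=lambda f: f.start),
    )
    return ref, truth


# ---------------------------------------------------------------------------
# Derived species
# ---------------------------------------------------------------------------


def _geometric_len(rng, mean: float, cap: int) -> int:
    return min(int(rng.geometric(1.0 / mean)), cap)


def mutate_species(
    ref: Plastome, truth: SyntheticTruth, spec: SyntheticSpec
) -> tuple[list[Plastome], SyntheticTruth]:
    """Derive query species from the reference.

    SNP and indel counts are drawn per 150 bp window as Poisson with
    rate lambda * beta^[window has a planted tandem].  Mutations are
    confined to the single-copy regions: plastome IRs evolve in concert
    and are far more conserved than LSC/SSC, so holding them identical
    across species both mirrors that and preserves every species'
    quadripartite structure.  Indels fall in intergenic space only (so
    annotations lift over cleanly), with geometric lengths (configurable
    mean, capped); all events keep a minimum spacing so alignment
    recovers them individually.  Events are recorded in the truth in
    left-normalised, reference-anchored form — the same convention the
    variant caller reports.
    """
    rng = np.random.default_rng(spec.seed + 1_000_003)
    n = len(ref.sequence)
    w = spec.window
    nbins = (n + w - 1) // w
    tandem_bins = truth.tandem_windows(w)
    irb = truth.partition["irb"]
    ira = truth.partition["ira"]

    def in_ir(a: int, b: int) -> bool:
        return (a <= irb[1] and b >= irb[0]) or (a <= ira[1] and b >= ira[0])
    gene_parts = sorted(
        (s, e) for f in ref.features for (s, e) in f.parts
    )

    def in_gene(a: int, b: int) -> bool:
        from bisect import bisect_right

        i = bisect_right(gene_parts, (b, n + 1))
        for s, e in gene_parts[max(0, i - 3) : i + 1]:
            if s <= b and e >= a:
                return True
        return False

    species: list[Plastome] = []
    for si in range(1, spec.n_species + 1):
        sid = f"sp{si:02d}"
        events: list[dict] = []
        taken: list[tuple[int, int]] = []

        def clear(a: int, b: int) -> bool:
            pad = spec.min_event_spacing
            return not any(a - pad <= te and b + pad >= ts for ts, te in taken)

        for b in range(1, nbins + 1):
            mult = spec.beta if b in tandem_bins else 1.0
            lo, hi = (b - 1) * w + 1, min(b * w, n)
            if in_ir(lo, hi):
                continue
            for _ in range(rng.poisson(spec.snp_rate * mult)):
                blen = 1
                if rng.random() < spec.substitution_block_frac:
                    blen = int(rng.integers(2, 4))
                for _try in range(20):
                    pos = int(rng.integers(lo, hi + 1))
                    if pos + blen - 1 > n or not clear(pos, pos + blen - 1):
                        continue
                    old = ref.sequence[pos - 1 : pos + blen - 1]
                    if any(c not in "ACGT" for c in old):
                        continue
                    new = "".join(
                        str(rng.choice([c for c in "ACGT" if c != o])) for o in old
                    )
                    events.append(
                        {"kind": "SNP" if blen == 1 else "substitution_block",
                         "ref_pos": pos, "length": blen,
                         "ref_allele": old, "qry_allele": new}
                    )
                    taken.append((pos, pos + blen - 1))
                    break
            for _ in range(rng.poisson(spec.indel_rate * mult)):
                for _try in range(20):
                    pos = int(rng.integers(lo, hi + 1))
                    length = _geometric_len(rng, spec.indel_mean_len, spec.indel_max_len)
                    if rng.random() < 0.5:  # deletion of [pos, pos+length-1]
                        if pos + length - 1 > n or in_gene(pos, pos + length - 1):
                            continue
                        pos0 = _normalise_deletion(ref.sequence, pos - 1, length)
                        # reserve the left-normalised span as well
                        if in_gene(pos0 + 1, pos0 + length) or not clear(pos0, pos + length):
                            continue
                        events.append(
                            {"kind": "deletion", "ref_pos": pos0, "length": length,
                             "ref_allele": ref.sequence[pos0 : pos0 + length],
                             "qry_allele": ""}
                        )
                        taken.append((pos0, pos + length))
                    else:  # insertion after pos
                        if in_gene(pos, pos + 1):
                            continue
                        ins = "".join(rng.choice(list("ACGT"), size=length))
                        anchor0, ins = _normalise_insertion(ref.sequence, pos - 1, ins)
                        if not clear(anchor0, pos + 1):
                            continue
                        events.append(
                            {"kind": "insertion", "ref_pos": anchor0 + 1,
                             "length": length, "ref_allele": "", "qry_allele": ins}
                        )
                        taken.append((anchor0, pos + 1))
                    break

        events.sort(key=lambda e: (e["ref_pos"], e["kind"]))
        seq, feats = _apply_events(ref, events)
        species.append(Plastome(id=sid, sequence=seq, circular=True, features=feats))
        truth.species_events[sid] = events
    return species, truth


def _apply_events(ref: Plastome, events: list[dict]) -> tuple[str, list[Feature]]:
    """Apply reference-coordinate events and lift annotations over."""
    pieces: list[str] = []
    cursor = 0  # 0-based position in ref consumed so far
    breakpoints: list[tuple[int, int]] = []  # (ref_pos_0based_after, cumulative shift)
    shift = 0
    for e in sorted(events, key=lambda x: x["ref_pos"]):
        if e["kind"] in ("SNP", "substitution_block"):
            p0 = e["ref_pos"] - 1
            pieces.append(ref.sequence[cursor:p0])
            pieces.append(e["qry_allele"])
            cursor = p0 + e["length"]
        elif e["kind"] == "deletion":
            span0 = e["ref_pos"]  # 0-based start of the deleted span
            pieces.append(ref.sequence[cursor:span0])
            cursor = span0 + e["length"]
            shift -= e["length"]
            breakpoints.append((cursor, shift))
        else:  # insertion after 1-based anchor ref_pos
            p0 = e["ref_pos"]
            pieces.append(ref.sequence[cursor:p0])
            pieces.append(e["qry_allele"])
            cursor = p0
            shift += e["length"]
            breakpoints.append((cursor, shift))
    pieces.append(ref.sequence[cursor:])
    seq = "".join(pieces)

    def lift(pos: int) -> int:  # 1-based
        s = 0
        for bp, sh in breakpoints:
            if pos - 1 >= bp:
                s = sh
            else:
                break
        return pos + s

    feats = [
        Feature(
            name=f.name,
            kind=f.kind,
            strand=f.strand,
            parts=[(lift(s), lift(e)) for s, e in f.parts],
            trans_spliced=f.trans_spliced,
            codon_start=f.codon_start,
        )
        for f in ref.features
    ]
    return seq, feats


# ---------------------------------------------------------------------------
# Count-level view (used for statistical calibration at scale)
# ---------------------------------------------------------------------------


def simulate_window_counts(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
):
    """Window-count realisation of the generative model.

    Returns ``(tandem_counts, indel_counts, snp_counts)`` for one
    replicate: planted-tandem midpoints are Poisson per window at the
    planted density, and mutation counts are Poisson at
    ``rate * n_species * beta^[tandem present]``.  This is the
    count-level marginal of the sequence-level generator's single-copy
    compartment (IR windows carry neither tandems nor events there) and
    is what the power / type-I calibration sweeps use.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    nbins = (spec.length + spec.window - 1) // spec.window
    tandem = rng.poisson(spec.n_tandems / nbins, size=nbins)
    mult = np.where(tandem > 0, spec.beta, 1.0)
    indels = rng.poisson(spec.indel_rate * spec.n_species * mult)
    snps = rng.poisson(spec.snp_rate * spec.n_species * mult)
    return tandem, indels, snps


# ---------------------------------------------------------------------------
# Fixture suite
# ---------------------------------------------------------------------------


def write_genbank(p: Plastome, path) -> None:
    """Write a plastome with its CDS annotations as a GenBank flat-file."""
    rec = SeqRecord(Seq(p.sequence), id=p.id, name=p.id[:16], description="synthetic plastome")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if p.circular else "linear"
    for f in p.features:
        locs = [
            SimpleLocation(s - 1, e, strand=1 if f.strand == "+" else -1)
            for s, e in f.parts
        ]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        sf = SeqFeature(loc, type=f.kind)
        sf.qualifiers["gene"] = [f.name]
        if f.trans_spliced:
            sf.qualifiers["trans_splicing"] = [""]
        rec.features.append(sf)
    SeqIO.write([rec], str(path), "genbank")


def make_fixture_suite(out_dir, seeds=(1,), betas=(1.0, 2.0, 5.0)) -> list[Path]:
    """Write the standard test-fixture matrix.

    For each seed: one tiny (2 kbp) genome set for oracle-scale tests
    and, per beta, a reduced 30 kbp genome set (reference FASTA +
    GenBank, species FASTA, truth JSON).  Regenerates identically from
    the recorded seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for seed in seeds:
        for label, spec in [("tiny", tiny_spec(seed=seed))] + [
            (
                f"beta{beta:g}",
                SyntheticSpec(
                    seed=seed,
                    length=30_000,
                    lsc_len=18_000,
                    ir_len=4_000,
                    n_genes=14,
                    n_tandems=55,
                    n_ssrs=6,
                    beta=beta,
                    n_species=4,
                ),
            )
            for beta in betas
        ]:
            ref, truth = synthesize_reference(spec)
            species, truth = mutate_species(ref, truth, spec)
            base = out / f"seed{seed}_{label}"
            write_fasta([ref] + species, base.with_suffix(".fasta"))
            write_genbank(ref, base.with_suffix(".gb"))
            (base.parent / (base.name + ".truth.json")).write_text(truth.to_json())
            written += [
                base.with_suffix(".fasta"),
                base.with_suffix(".gb"),
                base.parent / (base.name + ".truth.json"),
            ]
    return written
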