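"""Plastome records: sequence, annotated features, and locus extraction.

A plastome is modelled as a (linearised) circular DNA sequence together
with its annotated features.  Coordinates are 1-based inclusive
throughout, matching the GenBank convention; the BED track writer is the
only 0-based surface in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "Feature",
    "Plastome",
    "PlastomeValidationError",
    "read_genbank",
    "read_fasta",
    "write_fasta",
    "gc_content",
    "extract_loci",
    "Locus",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PlastomeValidationError(ValueError):
    """An annotation or sequence violates a structural invariant."""


FEATURE_KINDS = {"CDS", "tRNA", "rRNA", "intron", "exon", "intergenic"}


@dataclass
class Feature:
    """One annotated element with a possibly compound location.

    ``parts`` is an ordered list of 1-based inclusive ``(start, end)``
    intervals; for a CDS the concatenated, strand-oriented part lengths
    are recorded as annotated, with no silent trimming.
    """

    name: str
    kind: str
    strand: str
    parts: list[tuple[int, int]]
    trans_spliced: bool = False
    codon_start: int = 1

    def __post_init__(self) -> None:
        if not self.parts:
            raise PlastomeValidationError(f"feature {self.name!r} has no parts")
        for s, e in self.parts:
            if s < 1 or e < s:
                raise PlastomeValidationError(
                    f"feature {self.name!r} has degenerate interval ({s}, {e})"
                )
        if self.strand not in "+-":
            raise PlastomeValidationError(f"feature {self.name!r}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.parts)

    def extract(self, sequence: str) -> str:
        """Strand-oriented, exon-joined sequence of this feature."""
        joined = "".join(sequence[s - 1 : e] for s, e in self.parts)
        if self.strand == "-":
            joined = revcomp(joined)
        return joined[self.codon_start - 1 :]


@dataclass
class Plastome:
    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise PlastomeValidationError("plastome id must be non-empty")
        if not self.sequence:
            raise PlastomeValidationError("plastome sequence must be non-empty")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise PlastomeValidationError(
                    f"feature {f.name!r} interval ends at {f.end} beyond sequence length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def genes(self) -> list[Feature]:
        """Gene-level features (CDS, tRNA, rRNA), in genome order."""
        return sorted(
            (f for f in self.features if f.kind in ("CDS", "tRNA", "rRNA")),
            key=lambda f: (f.start, f.end),
        )


def _location_parts(loc) -> list[tuple[int, int]]:
    return [(int(p.start) + 1, int(p.end)) for p in loc.parts]


def read_genbank(path) -> Plastome:
    """Read a GenBank flat-file into a :class:`Plastome`.

    Gene-level features (CDS, tRNA, rRNA) are captured with compound
    locations preserved; the sequence is upper-cased.  A record without
    ORIGIN sequence raises ``ValueError``; a feature interval outside the
    sequence raises :class:`PlastomeValidationError` naming the feature.
    """
    record = SeqIO.read(path, "genbank")
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"} and len(seq) == 0:
        raise ValueError(f"record {record.id} has no ORIGIN sequence")
    features = []
    for ft in record.features:
        if ft.type not in ("CDS", "tRNA", "rRNA"):
            continue
        name = (
            ft.qualifiers.get("gene", [None])[0]
            or ft.qualifiers.get("locus_tag", [None])[0]
            or ft.type
        )
        parts = _location_parts(ft.location)
        strands = {p.strand for p in ft.location.parts}
        trans = "trans_splicing" in ft.qualifiers or len(strands) > 1
        strand = "-" if ft.location.strand == -1 else "+"
        codon_start = int(ft.qualifiers.get("codon_start", ["1"])[0])
        features.append(
            Feature(
                name=name,
                kind=ft.type,
                strand=strand,
                parts=parts,
                trans_spliced=trans,
                codon_start=codon_start,
            )
        )
    circular = record.annotations.get("topology", "circular") == "circular"
    return Plastome(id=record.name or record.id, sequence=seq, circular=circular, features=features)


def read_fasta(path) -> list[Plastome]:
    """Read one or more plain sequences as unannotated plastomes."""
    return [
        Plastome(id=rec.id, sequence=str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]


def write_fasta(plastomes, path) -> None:
    with open(path, "w") as fh:
        for p in plastomes if isinstance(plastomes, (list, tuple)) else [plastomes]:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i : i + 70] + "\n")


def gc_content(p: Plastome) -> float:
    """GC content in percent, rounded half-up to two decimals.

    N is excluded from the denominator; an all-N sequence is undefined.
    """
    seq = p.sequence
    g = seq.count("G")
    c = seq.count("C")
    denom = g + c + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError(f"GC content undefined for {p.id}: no unambiguous bases")
    value = 100.0 * (g + c) / denom
    # round half-up at 2 decimals (Python's round() is banker's rounding)
    return int(value * 100 + 0.5) / 100


@dataclass
class Locus:
    name: str
    klass: str  # gene | intron | intergenic
    region: str  # LSC | SSC | IRB | IRA
    start: int
    end: int
    sequence: str


def _region_of(midpoint: int, part) -> str:
    for label in ("lsc", "irb", "ssc", "ira"):
        s, e = getattr(part, label)
        if s <= midpoint <= e:
            return label.upper()
    raise ValueError(f"position {midpoint} not covered by partition")


def extract_loci(p: Plastome, part) -> list[Locus]:
    """Extract gene, intron, and intergenic loci with oriented sequences.

    Gene sequences are strand-oriented and exon-joined.  Introns are the
    gaps between consecutive parts of a compound gene.  Intergenic loci
    are the gaps between consecutive gene spans, named ``geneA-geneB`` in
    genome order.  Each locus is assigned a region by its midpoint.
    """
    loci: list[Locus] = []
    genes = p.genes()
    seen: dict[tuple[str, str], int] = {}

    def unique_name(name: str, region: str) -> str:
        key = (name, region)
        n = seen.get(key, 0)
        seen[key] = n + 1
        if n:
            warnings.warn(f"duplicate locus name {name!r} in {region}; adding suffix")
            return f"{name}.{n + 1}"
        return name

    for g in genes:
        region = _region_of(g.midpoint, part)
        loci.append(
            Locus(
                name=unique_name(g.name, region),
                klass="gene",
                region=region,
                start=g.start,
                end=g.end,
                sequence=g.extract(p.sequence),
            )
        )
        if len(g.parts) > 1 and not g.trans_spliced:
            parts = sorted(g.parts)
            for i, ((_, e1), (s2, _)) in enumerate(zip(parts, parts[1:]), start=1):
                if s2 > e1 + 1:
                    istart, iend = e1 + 1, s2 - 1
                    iseq = p.sequence[istart - 1 : iend]
                    if g.strand == "-":
                        iseq = revcomp(iseq)
                    iregion = _region_of((istart + iend) // 2, part)
                    loci.append(
                        Locus(
                            name=unique_name(f"{g.name}-intron{i}", iregion),
                            klass="intron",
                            region=iregion,
                            start=istart,
                            end=iend,
                            sequence=iseq,
                        )
                    )
    # intergenic spacers between consecutive gene spans
    for g1, g2 in zip(genes, genes[1:]):
        gap_start, gap_end = g1.end + 1, g2.start - 1
        if gap_end >= gap_start:
            region = _region_of((gap_start + gap_end) // 2, part)
            loci.append(
                Locus(
                    name=unique_name(f"{g1.name}-{g2.name}", region),
                    klass="intergenic",
                    region=region,
                    start=gap_start,
                    end=gap_end,
                    sequence=p.sequence[gap_start - 1 : gap_end],
                )
            )
    return loci
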