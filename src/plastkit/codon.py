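"""Codon counting, RSCU, amino-acid usage, and positional base composition.

The plastid/bacterial genetic code (translation table 11) is used
throughout.  Codons are counted over every annotated CDS instance (IR
duplicates count per occurrence) including stop codons; reports use the
RNA alphabet (U) to match the conventional codon labels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import warnings

import pandas as pd

from .evorates import CODON_AA, STOP_CODONS
from .plastome import Plastome

__all__ = [
    "CodonCounts",
    "count_codons",
    "count_codons_from_seqs",
    "rscu",
    "positional_composition",
    "amino_acid_usage",
    "SYNONYMOUS_FAMILIES",
]

_AA_NAMES = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "stop",
}

# synonymous families under code 11; the three stop codons form one family
SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, []).append(_codon)


def _rna(codon: str) -> str:
    return codon.replace("T", "U")


@dataclass
class CodonCounts:
    genome_id: str
    counts: Counter = field(default_factory=Counter)  # DNA-alphabet codon -> count
    genetic_code_id: int = 11

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": _rna(c),
                "amino_acid": _AA_NAMES[CODON_AA[c]],
                "count": self.counts.get(c, 0),
            }
            for c in sorted(CODON_AA)
        ]
        return pd.DataFrame(rows)


def count_codons_from_seqs(cds_seqs, genome_id: str = "") -> CodonCounts:
    """Count codons over oriented CDS nucleotide sequences."""
    ct = CodonCounts(genome_id=genome_id)
    for seq in cds_seqs:
        seq = seq.upper()
        if len(seq) % 3:
            warnings.warn(
                f"{genome_id}: CDS length {len(seq)} not divisible by 3; "
                "dropping trailing partial codon"
            )
            seq = seq[: len(seq) - len(seq) % 3]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon in CODON_AA:
                ct.counts[codon] += 1
    return ct


def count_codons(p: Plastome) -> CodonCounts:
    """Count codons over every annotated CDS instance of a plastome."""
    seqs = [f.extract(p.sequence) for f in p.features if f.kind == "CDS"]
    return count_codons_from_seqs(seqs, genome_id=p.id)


def rscu(ct: CodonCounts) -> pd.DataFrame:
    """Relative synonymous codon usage.

    RSCU of a codon is its count divided by the mean count of its
    synonymous family, so family means are exactly 1; single-codon
    families (AUG, UGG) are identically 1.  An entirely unobserved
    family gets RSCU 0 for all members, flagged in the ``observed``
    column.
    """
    rows = []
    for aa, family in SYNONYMOUS_FAMILIES.items():
        fam_total = sum(ct.counts.get(c, 0) for c in family)
        for c in family:
            if fam_total == 0:
                value = 1.0 if len(family) == 1 else 0.0
            else:
                value = ct.counts.get(c, 0) * len(family) / fam_total
            if len(family) == 1:
                value = 1.0
            rows.append(
                {
                    "codon": _rna(c),
                    "amino_acid": _AA_NAMES[aa],
                    "count": ct.counts.get(c, 0),
                    "rscu": value,
                    "ending": "A/U" if c[2] in "AT" else "C/G",
                    "observed": fam_total > 0,
                }
            )
    return pd.DataFrame(rows).sort_values("codon").reset_index(drop=True)


def positional_composition(cds_seqs) -> pd.DataFrame:
    """AT% and GC% at codon positions 1, 2 and 3 over a CDS set."""
    at = [0, 0, 0]
    gc = [0, 0, 0]
    total = 0
    for seq in cds_seqs:
        seq = seq.upper()
        seq = seq[: len(seq) - len(seq) % 3]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if any(b not in "ACGT" for b in codon):
                continue
            total += 1
            for k, b in enumerate(codon):
                if b in "AT":
                    at[k] += 1
                else:
                    gc[k] += 1
    if total == 0:
        raise ValueError("no complete unambiguous codons")
    return pd.DataFrame(
        {
            "position": [1, 2, 3],
            "at_percent": [100.0 * a / total for a in at],
            "gc_percent": [100.0 * g / total for g in gc],
        }
    )


def amino_acid_usage(ct: CodonCounts) -> pd.DataFrame:
    """Percent usage per amino acid (stop codons reported as one row)."""
    if ct.total == 0:
        raise ValueError("empty codon table")
    rows = []
    for aa, family in SYNONYMOUS_FAMILIES.items():
        fam_total = sum(ct.counts.get(c, 0) for c in family)
        rows.append(
            {
                "amino_acid": _AA_NAMES[aa],
                "count": fam_total,
                "percent": 100.0 * fam_total / ct.total,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("percent", ascending=False)
        .reset_index(drop=True)
    )
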