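"""End-to-end orchestration: partition, repeats, variants, statistics,
diversity, codon usage and phylogeny, written as one report bundle.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import codon as codon_mod
from .cooccurrence import association_report, bin_counts
from .evorates import align_locus, kaks_ng86, nucleotide_diversity, rank_hotspots
from .partition import detect_quadripartite, junction_distances
from .phylo import nj_tree, p_distance_matrix, write_newick
from .plastome import Plastome, extract_loci, gc_content, read_genbank, read_fasta
from .repeats import (
    classify_locations,
    find_dispersed_repeats,
    find_ssrs,
    find_tandem_repeats,
)
from .tracks import write_tracks
from .variants import align_collinear, call_variants, tandem_overlap_fractions

logger = logging.getLogger("plastkit")

__all__ = ["RunConfig", "run_all", "load_inputs"]


@dataclass
class RunConfig:
    reference_id: str
    inputs: list[str] = field(default_factory=list)  # GenBank/FASTA paths
    out_dir: str = "plastkit_out"
    window: int = 150
    alpha: float = 0.01
    min_ir_len: int = 10000
    ssr_join_distance: int = 100
    tandem_unit_min: int = 7
    tandem_unit_max: int = 95
    tandem_identity: float = 85.0
    repeat_min_len: int = 21
    hamming: int = 2
    anchor_k: int = 21
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.window < 10:
            raise ValueError("window too small")
        for path in self.inputs:
            if not Path(path).exists():
                raise FileNotFoundError(path)


def load_inputs(cfg: RunConfig) -> list[Plastome]:
    plastomes: list[Plastome] = []
    for path in cfg.inputs:
        p = Path(path)
        if p.suffix.lower() in (".gb", ".gbk", ".genbank"):
            plastomes.append(read_genbank(p))
        else:
            plastomes.extend(read_fasta(p))
    # keep the first occurrence when the same record arrives twice
    # (e.g. an annotated GenBank reference plus a multi-FASTA that
    # includes it); GenBank inputs are listed first by convention
    seen: set[str] = set()
    unique = []
    for p in plastomes:
        if p.id not in seen:
            seen.add(p.id)
            unique.append(p)
    return unique


class _StageTracker:
    """Names the running stage for error reporting and logs transitions."""

    def __init__(self) -> None:
        self.name = "load"
        self._t0 = time.time()

    def enter(self, name: str) -> None:
        logger.info("stage %-12s done in %.1fs; starting %s",
                    self.name, time.time() - self._t0, name)
        self.name = name
        self._t0 = time.time()


def run_all(cfg: RunConfig, plastomes: list[Plastome] | None = None) -> dict:
    """Run the full comparative analysis and write the report bundle.

    Stages: quadripartite partition and junctions of the reference;
    SSR/tandem/dispersed repeat scans; per-query collinear alignment and
    variant calling; 150 bp window table and association statistics;
    per-locus Pi with hotspot ranking; pairwise Ka/Ks per gene; codon
    usage; whole-genome p-distances and NJ tree.  Any stage failure
    aborts with the stage name; partial outputs are retained alongside a
    FAILED marker.  Returns the manifest (also written as JSON).
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "artifacts": {}, "summary": {}}
    stage = _StageTracker()

    def artifact(key: str, path: Path):
        manifest["artifacts"][key] = str(path)

    try:
        if plastomes is None:
            plastomes = load_inputs(cfg)
        by_id = {p.id: p for p in plastomes}
        if cfg.reference_id not in by_id:
            raise ValueError(f"reference {cfg.reference_id!r} not among inputs")
        ref = by_id[cfg.reference_id]
        queries = [p for p in plastomes if p.id != cfg.reference_id]
        if not queries:
            raise ValueError("need at least one query genome besides the reference")

        stage.enter("partition")
        part = detect_quadripartite(ref, min_ir_len=cfg.min_ir_len)
        junc = junction_distances(ref, part)
        (out / "partition.json").write_text(
            json.dumps(
                {
                    "reference": ref.id,
                    "length": len(ref),
                    "gc_percent": gc_content(ref),
                    "partition": part.to_dict(),
                    "junctions": junc.to_records(),
                },
                indent=1,
            )
        )
        artifact("partition", out / "partition.json")

        stage.enter("repeats")
        ssrs = find_ssrs(ref.sequence, join_distance=cfg.ssr_join_distance)
        tandems = find_tandem_repeats(
            ref.sequence,
            unit_min=cfg.tandem_unit_min,
            unit_max=cfg.tandem_unit_max,
            min_identity=cfg.tandem_identity,
        )
        dispersed = find_dispersed_repeats(
            ref.sequence, min_len=cfg.repeat_min_len, max_hamming=cfg.hamming
        )
        pd.DataFrame(
            [
                {
                    "motif": h.motif,
                    "class": h.ssr_class,
                    "start": h.start,
                    "end": h.end,
                    "copies": h.copies,
                }
                for h in ssrs
            ]
        ).to_csv(out / "ssrs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "unit": h.unit,
                    "unit_len": h.unit_len,
                    "start": h.start,
                    "end": h.end,
                    "copies": round(h.copies, 2),
                    "identity": round(h.identity, 2),
                }
                for h in tandems
            ]
        ).to_csv(out / "tandems.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "kind": h.kind,
                    "len": h.len,
                    "pos1": h.pos1,
                    "pos2": h.pos2,
                    "mismatches": h.mismatches,
                }
                for h in dispersed
            ]
        ).to_csv(out / "dispersed.tsv", sep="\t", index=False)
        write_tracks(tandems, out / "tandems.bed", fmt="BED", chrom=ref.id)
        classify_locations(tandems, part, ref.features).to_csv(
            out / "tandem_context.tsv", sep="\t"
        )
        artifact("ssrs", out / "ssrs.tsv")
        artifact("tandems", out / "tandems.tsv")
        artifact("dispersed", out / "dispersed.tsv")
        artifact("tandem_track", out / "tandems.bed")
        artifact("tandem_context", out / "tandem_context.tsv")

        stage.enter("variants")
        all_events = []
        for q in queries:
            aln = align_collinear(ref, q, k=cfg.anchor_k)
            all_events.extend(call_variants(aln))
        pd.DataFrame(
            [
                {
                    "qry_id": e.qry_id,
                    "kind": e.kind,
                    "ref_pos": e.ref_pos,
                    "length": e.length,
                    "ref_allele": e.ref_allele,
                    "qry_allele": e.qry_allele,
                }
                for e in all_events
            ]
        ).to_csv(out / "variants.tsv", sep="\t", index=False)
        artifact("variants", out / "variants.tsv")

        stage.enter("windows")
        wt = bin_counts(all_events, tandems, ref_len=len(ref), w=cfg.window)
        wt.table.to_csv(out / "windows.tsv", sep="\t", index=False)
        artifact("windows", out / "windows.tsv")

        stage.enter("association")
        assoc = association_report(wt, alpha=cfg.alpha)
        frac_ins, frac_del, overlap = tandem_overlap_fractions(all_events, tandems)
        payload = assoc.to_dict()
        payload["tandem_overlap"] = overlap
        (out / "association.json").write_text(json.dumps(payload, indent=1))
        artifact("association", out / "association.json")

        stage.enter("diversity")
        part_by_id = {ref.id: part}
        loci_by_name: dict[str, dict] = {}
        for p in plastomes:
            if not p.features:
                continue
            pp = part_by_id.get(p.id)
            if pp is None:
                pp = detect_quadripartite(p, min_ir_len=cfg.min_ir_len)
                part_by_id[p.id] = pp
            for locus in extract_loci(p, pp):
                if locus.region == "IRA":
                    continue  # IR-duplicated loci analysed once, via the IRB copy
                entry = loci_by_name.setdefault(
                    locus.name, {"klass": locus.klass, "region": locus.region, "seqs": {}}
                )
                entry["seqs"][p.id] = locus.sequence
        pi_results = []
        for name, entry in sorted(loci_by_name.items()):
            seqs = {k: v for k, v in entry["seqs"].items() if v}
            if len(seqs) < 2:
                continue
            aln = align_locus(
                seqs, locus=name, klass=entry["klass"], region=entry["region"]
            )
            pi_results.append(nucleotide_diversity(aln))
        top_genes, top_igs = rank_hotspots(pi_results)
        pd.DataFrame(
            [
                {
                    "locus": r.locus,
                    "class": r.klass,
                    "region": r.region,
                    "n": r.n,
                    "sites": round(r.sites_used, 1),
                    "pi": round(r.pi, 5),
                }
                for r in sorted(pi_results, key=lambda r: (-r.pi, r.locus))
            ]
        ).to_csv(out / "diversity.tsv", sep="\t", index=False)
        artifact("diversity", out / "diversity.tsv")

        stage.enter("kaks")
        kaks_rows = []
        ref_cds = {f.name: f for f in ref.genes() if f.kind == "CDS"}
        for q in queries:
            q_cds = {f.name: f for f in q.genes() if f.kind == "CDS"}
            for name, rf in sorted(ref_cds.items()):
                qf = q_cds.get(name)
                if qf is None:
                    continue
                try:
                    res = kaks_ng86(
                        rf.extract(ref.sequence),
                        qf.extract(q.sequence),
                        gene=name,
                        pair=(ref.id, q.id),
                    )
                except ValueError as exc:
                    logger.warning("kaks skipped %s vs %s: %s", name, q.id, exc)
                    continue
                kaks_rows.append(
                    {
                        "gene": name,
                        "ref": ref.id,
                        "qry": q.id,
                        "ka": round(res.ka, 6),
                        "ks": round(res.ks, 6),
                        "ratio": None if res.ratio is None else round(res.ratio, 4),
                    }
                )
        pd.DataFrame(kaks_rows).to_csv(out / "kaks.tsv", sep="\t", index=False)
        artifact("kaks", out / "kaks.tsv")

        stage.enter("codon")
        cds_seqs = [f.extract(ref.sequence) for f in ref.features if f.kind == "CDS"]
        ct = codon_mod.count_codons(ref)
        if cds_seqs:
            codon_mod.rscu(ct).to_csv(out / "rscu.tsv", sep="\t", index=False)
            codon_mod.positional_composition(cds_seqs).to_csv(
                out / "codon_positions.tsv", sep="\t", index=False
            )
            codon_mod.amino_acid_usage(ct).to_csv(
                out / "amino_acids.tsv", sep="\t", index=False
            )
            artifact("rscu", out / "rscu.tsv")
            artifact("codon_positions", out / "codon_positions.tsv")
            artifact("amino_acids", out / "amino_acids.tsv")
        else:
            logger.warning("reference %s carries no CDS annotations; "
                           "codon-usage stage skipped", ref.id)

        stage.enter("phylogeny")
        aligned = _whole_genome_alignment(ref, queries, cfg)
        dm = p_distance_matrix(aligned)
        dm.to_frame().to_csv(out / "distances.tsv", sep="\t")
        tree = nj_tree(dm)
        write_newick(tree, out / "tree.nwk")
        artifact("distances", out / "distances.tsv")
        artifact("tree", out / "tree.nwk")

        manifest["summary"] = {
            "reference": ref.id,
            "n_genomes": len(plastomes),
            "genome_length": len(ref),
            "gc_percent": gc_content(ref),
            "ir_length": part.ir_length,
            "n_ssrs": len(ssrs),
            "n_tandems": len(tandems),
            "n_dispersed": len(dispersed),
            "n_snps": sum(1 for e in all_events if e.kind == "SNP"),
            "n_substitution_blocks": sum(
                1 for e in all_events if e.kind == "substitution_block"
            ),
            "n_insertions": sum(1 for e in all_events if e.kind == "insertion"),
            "n_deletions": sum(1 for e in all_events if e.kind == "deletion"),
            "insertion_fraction_in_tandem": frac_ins,
            "deletion_fraction_in_tandem": frac_del,
            "tandem_indel_rho": assoc.correlations["tandem-indel"].rho,
            "tandem_snp_rho": assoc.correlations["tandem-snp"].rho,
            "indel_snp_rho": assoc.correlations["indel-snp"].rho,
            "n_loci_pi": len(pi_results),
            "top_gene_hotspots": [r.locus for r in top_genes],
            "top_intergenic_hotspots": [r.locus for r in top_igs],
            "n_kaks_pairs": len(kaks_rows),
            "total_codons": ct.total,
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage.name}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage.name!r}: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _whole_genome_alignment(ref, queries, cfg) -> dict[str, str]:
    """Stack per-query collinear alignments onto reference coordinates.

    Query rows are projected onto ungapped reference columns (insertions
    relative to the reference are dropped), yielding a rectangular
    matrix suitable for p-distances.
    """
    rows = {ref.id: ref.sequence}
    for q in queries:
        aln = align_collinear(ref, q, k=cfg.anchor_k)
        row = []
        for r, qc in zip(aln.ref_aln, aln.qry_aln):
            if r != "-":
                row.append(qc)
        rows[q.id] = "".join(row)
    return rows
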