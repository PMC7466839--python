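# plastkit

Comparative chloroplast-genome (plastome) analysis for closely related
plant species, built around the questions a congeneric plastome survey
asks: where are the quadripartite region boundaries and which genes
flank them; where do microsatellites, tandem arrays and dispersed
repeats sit; where do SNPs and indels accumulate relative to the
reference; do mutations co-occur with tandem repeats; which loci are
diversity hotspots; are protein-coding genes under purifying selection;
how biased is codon usage; and how do the species group on a
distance-based tree.

It is aimed at researchers analysing sets of annotated plastome records
(GenBank flat-files or FASTA) from one genus — for example oat (*Avena*)
and its wild relatives — and at method developers who need a fully
synthetic, truth-annotated plastome benchmark: the package ships a
generator that emulates a ~136 kbp quadripartite genome (LSC ≈ 80 kbp,
SSC ≈ 12.8 kbp, IRs ≈ 21.6 kbp), plants SSRs and imperfect tandem
arrays at plastome-like densities, and derives "species" whose SNP and
indel rates are multiplied by an enrichment factor β in 150 bp windows
that carry a tandem repeat, so every stage of the pipeline is testable
without downloading anything.

## The statistics at the core

* **Quadripartite partition** — the maximal pair of near-identical
  inverted segments (mismatch fraction ≤ 10⁻³) splits the genome into
  LSC–IRB–SSC–IRA; gene distances to the four junctions diagnose IR
  expansion/contraction.
* **Repeat detection** — MISA-rule SSRs (minima 10/6/5/5/5/5 copies for
  motif lengths 1–6); imperfect tandem arrays of a 7–95 bp unit with
  identity ≥ 85% against the best-fitting perfect tandem (column-majority
  consensus); dispersed repeat pairs ≥ 21 bp within Hamming distance 2 in
  forward/reverse/complement/palindromic orientation, found exactly by
  pigeonhole seeding.
* **Variant mapping** — per-query collinear alignment (unique shared
  k-mer anchors + affine-gap DP between anchors), then SNPs, ≥2 bp
  substitution blocks, and left-normalised indels on reference
  coordinates.
* **Co-occurrence** — counts per non-overlapping 150 bp window; Spearman
  ρ between tandem, indel and SNP counts (exact permutation p for
  n ≤ 10, t approximation above) with Akoglu strength bands; Mann-Whitney
  U comparing mutation counts in tandem-present vs tandem-absent windows
  (exact enumeration for n₁+n₂ ≤ 12).
* **Diversity and selection** — per-locus Pi
  `Pi = 2/(n(n−1)) Σ_{i<j} d_ij / L_ij` with pairwise deletion, hotspot
  ranking; NG86 Ka/Ks (pathway-averaged codon counting, Jukes-Cantor
  correction), Ka/Ks < 1 ⇒ purifying selection.
* **Codon usage** — RSCU under the plastid genetic code (table 11; family
  means are exactly 1), amino-acid usage, AT%/GC% by codon position.
* **Phylogeny** — p-distances with pairwise deletion and Saitou-Nei
  neighbor joining with deterministic tie-breaks, Newick output, optional
  column-resampling bootstrap.

## Worked example

```python
from plastkit import (SyntheticSpec, synthesize_reference, mutate_species,
                      RunConfig, run_all)

spec = SyntheticSpec(seed=1, length=30_000, lsc_len=18_000, ir_len=4_000,
                     n_genes=14, n_tandems=55, n_ssrs=6, beta=5.0, n_species=4)
ref, truth = synthesize_reference(spec)
species, truth = mutate_species(ref, truth, spec)
manifest = run_all(RunConfig(reference_id=ref.id, out_dir="demo_out",
                             min_ir_len=2000),
                   [ref] + species)
print(manifest["summary"])
```

prints (seed 1) among other fields:

```
'genome_length': 30000, 'gc_percent': 39.19, 'ir_length': 4006,
'n_ssrs': 4, 'n_tandems': 146, 'n_snps': 72, 'n_insertions': 14,
'n_deletions': 8, 'insertion_fraction_in_tandem': 0.786,
'tandem_indel_rho': 0.165, ...
```

meaning: the quadripartite partition was recovered at the planted 4 kbp
IR (the boundary may shift a few bases where flanking sequence matches
by chance within the mismatch budget); 146 tandem arrays were detected
(55 planted, the rest chance near-threshold arrays, as in real
plastomes); 94 mutation events were mapped onto the reference pooled
over four species; 79% of insertions fall inside tandem loci and the
windowed tandem-indel Spearman correlation is positive — the planted
β = 5 enrichment is visible exactly the way tandem-mutation
co-occurrence shows up in real congeneric plastome comparisons. `demo_out/` holds the full report
bundle (partition and junction JSON, repeat and variant TSVs, the
window table, the association report, diversity and Ka/Ks tables, codon
usage, distance matrix and Newick tree, plus a manifest echoing the
exact configuration).

The `examples/` directory has one short script per capability
(partition/junctions, repeat scanning, variants + co-occurrence
statistics, diversity/Ka-Ks/codons, phylogeny, full pipeline); each
prints its numbers with a line on what they mean. A thin CLI mirrors
the pipeline: `plastkit partition genome.gb`, `plastkit repeats`,
`plastkit simulate`, `plastkit run-all --reference ID inputs...`.

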