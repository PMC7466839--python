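# Methods

This note records the models, conventions and numerical choices behind
plastkit, and what its synthetic benchmark does and does not establish
about real data.

## Coordinates and records

All internal coordinates are 1-based inclusive, matching GenBank; BED
export is the only 0-based half-open surface. Records are analysed as
linearised in the deposited orientation with the origin inside the LSC
(the convention of grass plastome deposits), so the expected layout is
LSC–IRB–SSC–IRA and inverted-repeat detection does not wrap the origin.
GenBank parsing (Biopython) keeps compound locations as annotated; a
trans-spliced gene (rps12-style) is flagged from its `trans_splicing`
qualifier or from mixed part strands, and its part gaps are not called
introns.

## Quadripartite partition

The partition is the maximal pair of near-identical inverted segments:
shared k-mers between the sequence and its reverse complement seed
candidate diagonals; on each diagonal, exact match runs are chained
greedily while the running mismatch fraction stays ≤ `max_mismatch_frac`
(default 10⁻³, i.e. ~21 mismatches allowed across a 21.6 kbp IR). With a
zero effective budget this reduces exactly to maximal exact runs, which
is what the brute-force all-diagonals oracle enumerates in the tests.
Consequences of the fraction-based budget: the reported IR boundary can
extend a handful of bases into flanking sequence that matches by chance,
so IR lengths are reproducible to a few bases rather than exactly; ties
between distinct maximal pairs raise an explicit ambiguity error. The
larger single-copy interval is labelled LSC and the IR copy that follows
it IRB. Features, repeats and loci are assigned to regions by midpoint;
junction-straddling genes are flagged with their flank lengths, and
junction distances are reported both linearly and around the circle
(the circular figure matters for genes adjacent to the origin, e.g. psbA
against the IRA/LSC border).

## Repeat detectors

**SSRs** follow the MISA rules: maximal perfect runs of primitive 1–6 bp
motifs with class minima 10/6/5/5/5/5 copies; trailing partial copies
are excluded, N breaks runs, and motifs of length ≥ 2 are reported as
their lexicographically smallest rotation. Hits within 100 bp —
including overlapping hits, which arise when a mononucleotide run feeds
into a dinucleotide run — are merged into a composite SSR whose
components are trimmed forward by whole motif copies to be disjoint
(the 100 bp join distance is MISA's default interruption).

**Imperfect tandem arrays.** An array of unit length u qualifies when
its identity against the best-fitting perfect tandem — the
column-majority consensus, ties to the alphabetically smaller base — is
≥ 85% with ≥ 2.0 (fractional) copies, unit lengths 7–95 bp by default.
Candidates are containment-maximal per unit length; overlaps across
unit lengths are resolved greedily by score (array length × identity,
equivalently consensus matches), ties to the smaller unit, then
leftmost. Arrays are capped at 500 bp (`max_array_len`), a practical
bound well above plastome tandem sizes. Sequences ≤ 2 kbp are scanned
exhaustively (the semantics the enumeration oracle verifies); longer
sequences use a seeded scan that only examines neighbourhoods where
some u-window of the lag-u self-match profile has at most
max(1, ⌊u/4⌋) mismatches — i.e. where two adjacent copies align nearly
perfectly. The seeded scan can therefore miss arrays whose copies are
uniformly sloppy; measured recall on planted arrays with identity ≥ 90%
is ≥ 95% (reported by the acceptance script as `tandem_recall_pct`).
Because the identity definition is substitution-only (no indels within
the array), absolute genome-wide tandem counts are comparable to, but
not identical with, gapped-scoring tools; counts on AT-rich 136 kbp
genomes land around 700, the density real congeneric surveys report.

**Dispersed repeats.** A pair of equal-length, non-overlapping segments
(forward, reverse, complement, or palindromic orientation) qualifies at
length ≥ 21 bp with ≤ 2 mismatches and is reported only when maximal —
not extendable on either side within the budget. Detection seeds on
exact 7-mers (⌈min_len/(h+1)⌉, pigeonhole-complete) and enumerates the
h+1 left/right budget splits around each seed, reallocating unused
budget at sequence boundaries and pruning nested intervals, so the
output equals the all-pairs diagonal-scan oracle. Several overlapping
maximal pairs can legitimately coexist around one planted repeat (their
mismatch blockers stagger); a pair qualifying under more than one
orientation (e.g. an AT-palindrome) is reported once, with priority
forward > palindromic > reverse > complement. The IR pair itself
surfaces as one long palindromic hit.

## Variant mapping

Each query is aligned to the single designated reference independently.
k-mers (k = 21) unique in both genomes are matched, chained by the
longest strictly increasing chain, filtered to non-overlap, and the
inter-anchor segments aligned globally with affine gaps (match +1,
mismatch −2, gap open −5, gap extend −2; Biopython's PairwiseAligner).
At >99% identity the event calls are insensitive to these constants,
which is why they are fixed rather than exposed. An inter-anchor span
exceeding 5 kbp on either sequence — an inversion or transposition —
aborts with a non-collinearity error rather than producing a misleading
alignment. Events are read off alignment columns: maximal query-gap
runs become one deletion, maximal reference-gap runs one insertion
(both anchored at the reference base immediately 5′ and left-normalised,
VCF-style, so window assignment is deterministic), isolated mismatch
columns are SNPs, and runs of ≥ 2 contiguous mismatch columns form one
substitution block. The SNP/substitution split is a contiguity
convention: it is the only reading that yields two disjoint classes
from one alignment, and it is stated here rather than claimed to match
any particular published tool.

## Windowed co-occurrence statistics

Counts use non-overlapping 150 bp windows over the reference; the short
final window is retained so column sums equal pooled event totals.
Events enter by their (left-normalised) anchor, tandems by midpoint;
counts are pooled over all query species. Spearman ρ uses average ranks
for ties; its two-sided p-value is a full permutation enumeration for
n ≤ 10 and the t approximation with n−2 df above (the switch point is
an argument). Mann-Whitney U compares mutation counts between
tandem-present and tandem-absent windows; for n₁+n₂ ≤ 12 the two-sided
p enumerates all group assignments and measures the deviation of U from
its null mean (handling ties exactly; the {1,2,3} vs {4,5,6} case gives
p = 0.1), otherwise the tie-corrected normal approximation with a 0.5
continuity correction is used. Strength labels follow the Akoglu bands
on |ρ| (0.1/0.2/0.3/0.4 cut points; ≥ 0.7 labelled "very strong" as a
documented extension, < 0.1 "none"). The association report always
contains exactly three correlations and two Mann-Whitney tests and
applies no multiple-testing correction, which it states in its output.

## Diversity and selection

Per-locus alignments are center-star: the medoid by 4-mer profile
distance is the center, every other sequence is aligned to it by global
edit-distance DP (edlib), and pairwise alignments are merged on the
center's gap pattern. Unit-cost rather than affine-gap scoring is used
in this step deliberately: plastome loci within a genus are >99%
identical, where both scoring schemes recover the same small indels,
and the edit-distance aligner is orders of magnitude faster, which is
what makes genome-wide per-locus scans practical on one CPU. Pi is the
average pairwise proportion of differing sites with pairwise deletion
(columns with a gap or ambiguous base in either member are dropped for
that pair; complete deletion is available as a flag); hotspots are
ranked by descending Pi with name ties broken alphabetically, genes and
intergenic regions separately. IR-duplicated loci are analysed once,
via the IRB copy.

Ka/Ks is NG86: per-codon synonymous site fractions averaged over both
sequences; multi-hit codons averaged over all minimal substitution
pathways with equal weights, excluding pathways through stop codons
(all pathways are used if every one is blocked — a rare degenerate
case); mutations *to* stop codons count as nonsynonymous; Jukes-Cantor
correction −(3/4)ln(1−4p/3) applied to both proportions, undefined
(NaN) at saturation p ≥ 3/4. Sequences are trimmed to whole codons, a
shared terminal stop codon is excluded, internal stops are rejected
with the codon position named, and codon pairs containing ambiguous
bases are skipped — so N sites + S sites = 3 × codons compared holds
exactly. The ratio is reported as missing when Ks = 0, which at
within-genus divergence affects many genes; per-gene ratios on real
data therefore carry wide sampling error and only the aggregate
purifying-selection pattern (ratios < 1) is a stable statement.

## Codon usage

The plastid/bacterial genetic code (translation table 11) defines
synonymous families; the three stop codons form one family (CodonW's
convention). Every annotated CDS instance is counted, so IR-duplicated
genes contribute twice, matching how published per-genome codon totals
(~19–20 k codons for a grass plastome) are computed. RSCU is count
divided by family mean, so family means are exactly 1 (asserted as an
identity in the tests) and single-codon families (AUG, UGG) are
identically 1; an unobserved family reports 0 with a flag. Reports use
the RNA alphabet; positional AT/GC content is computed per codon
position over complete unambiguous codons.

## Phylogeny

p-distances use pairwise deletion on reference-projected whole-genome
alignments (query insertions relative to the reference are dropped,
giving a rectangular matrix). Neighbor joining is the standard
Saitou-Nei agglomeration with the Q-criterion; ties are broken by the
sorted minimum leaf labels of the candidate pair, so the tree is
deterministic under taxon re-ordering; negative branch lengths are
clamped to zero and flagged. NJ is exact on additive matrices (verified
on random trees) and is used here as a topology-level surface — clade
membership questions — not as a substitute for likelihood inference,
which is out of scope. A column-resampling bootstrap is provided for
completeness; its supports are descriptive only.

## The synthetic benchmark

`SyntheticSpec` defaults encode the study conditions the package is
benchmarked under: a 136,000 bp genome with LSC 80,000, IR 21,600 × 2,
SSC 12,800; GC 38.5% (AT-rich draws for background, tandem units and
CDS codons alike); 60 CDS genes tiled with 150–600 bp intergenic gaps
through LSC, SSC and IRB, with IRB genes mirrored into IRA so
IR-duplicated genes exist; 250 tandem arrays (units 7–95 bp, 2–5
copies, ~3% substitutions capped so planted identity ≥ 92%) and 25
SSRs (mostly A/T mononucleotide runs of 10–15, occasionally C/G or AT
dinucleotide) planted in single-copy intergenic space; twelve derived
species. Mutations are drawn per 150 bp window as Poisson with rate
λ·β^[window has a planted tandem], with β = 5 by default; SNP rate
λ_s = 0.059 and indel rate λ_i = 0.014 per window per species were
derived by inverting the marginal: with ~619 single-copy windows, a
33% tandem-window fraction and β = 5 the pooled totals come to ~1,050
point mutations (3.2% of them drawn as 2–3 bp substitution blocks) and
~240 indels across twelve queries — the magnitudes a real congeneric
oat comparison reports. Indel lengths are geometric (mean 4, cap 50).

Three deliberate simplifications, and what they imply about the tests:
mutations and planted repeats are confined to the single-copy regions
(real IRs evolve in concert and are far more conserved, and holding
them identical keeps every derived species' quadripartite structure
intact — but it means IR-window behaviour is untested); indels fall
only in intergenic space, so annotation liftover is exact and CDS
frames never break, whereas real plastomes do carry occasional coding
indels; and events keep a minimum spacing (8 bp default), so the
benchmark does not probe the caller's behaviour on overlapping or
clustered events (a spacing of ≥ 50 bp is used where tests require
exact planted-event recovery). Planted events are recorded
left-normalised in reference coordinates — the caller's own convention
— so recovery comparisons are exact set comparisons. Passing on this
benchmark shows the machinery is correct under collinear, moderately
divergent, cleanly annotated genomes; it does not certify behaviour
under rearrangements, annotation errors, or saturation divergence.

The count-level view (`simulate_window_counts`) is the marginal of the
single-copy compartment: per-window tandem counts Poisson at planted
density, mutation counts Poisson at λ·n_species·β^[tandem present]. The
statistical calibration — type-I error of the tandem-indel test within
[0.5%, 2%] at α = 0.01 under β = 1, mean ρ monotone in β, rejection in
≥ 95% of replicates at β = 5 — runs on this view (1,000/500 replicates
at a 30 kbp / 200-window configuration for speed; the sequence-level
and count-level generators share their rate model by construction).

## Pipeline and reproducibility

`run_all` executes partition → repeats → per-query variants → windows →
association → Pi/hotspots → Ka/Ks → codon usage → distances/NJ, writes
TSV/JSON/BED/Newick artifacts plus a manifest echoing the exact
configuration, aborts with the stage name on failure (partial outputs
kept beside a FAILED marker), and is byte-reproducible for a fixed
config. Genes whose per-species copy acquired an internal stop (a
real possibility once SNPs land in codons) are skipped in the Ka/Ks
table with a logged warning rather than aborting the stage.
`scripts/acceptance.py` regenerates the full-scale study conditions
from a single seed and reports the pipeline's headline quantities plus
detector recall and the calibration sweeps; problem sizes (136 kbp ×
12 species for the pipeline, 30 kbp-equivalent windows × 1,000/500
replicates for calibration) are chosen to complete in minutes on one
CPU.

## Known limitations

Tandem counts are definitionally substitution-only and not exchangeable
with gapped-scoring tools; the seeded tandem scan trades a documented
class of uniformly-degenerate arrays for speed; IR boundary calls are
fuzzy at the mismatch tolerance; the collinear aligner refuses
rearranged genomes by design (rearrangement detection is a non-goal);
NJ/p-distance phylogeny is a topology surrogate, not an ML estimate;
and the Mann-Whitney normal approximation is used above 12 pooled
observations, where exactness is no longer guaranteed (tie-corrected
and continuity-corrected, cross-checked against scipy).
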