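# Methods

## Scope and model

`retroscan` identifies retrocopies — intronless, reverse-transcribed copies
of multi-exon genes — by translated homology of a peptide set against a
repeat-masked genome, and scores each surviving parent–retrocopy pair for
functionality along four axes: ORF intactness, purifying selection
(dN/dS), overlap with annotated genes, and expression. The package is
organised so that every stage is a pure function over explicit inputs, and a
synthetic-genome generator supplies ground-truthed test beds for all of
them.

## Screening

The built-in search translates both genome strands in three frames each,
seeds exact protein words (default word size 4) only where all three codon
bases are unmasked (soft masking = lowercase, hard masking = N), and extends
each seed gaplessly in both directions under an X-drop rule (default 20)
with BLOSUM62 scores, reporting hits with raw score ≥ 50. It implements the
contract of a translated homology search rather than any particular tool's
statistics; externally produced 12-column tabular hits can be imported
instead, with minus-strand hits (subject start > end) normalised to forward
coordinates.

Merging joins hits from the same peptide on the same scaffold and strand
whenever the number of bases strictly between them is below 40, transitively.
Merging is per query because joining hits of different peptides would corrupt
parent assignment. Thresholds at every stage are strict inequalities
(> 50 aa and > 30 % to keep a merged locus; the final filters exclude
≤ 50 aa and ≤ 70 %). Overlap resolution keeps the longest locus per
connected component of the interval-overlap graph (for intervals on a line,
the clusters of a coordinate sweep), breaking ties by lower start then
lexicographic query id.

## Parent assignment and realignment

Every peptide — including single-exon proteins — is scored against the locus
translation by local protein alignment (BLOSUM62, gap open −11 / extend −1).
If the single best-scoring peptide is single-exon, the locus is discarded as
a putative DNA-based duplication of an intronless gene; otherwise the best
multi-exon peptide becomes the parent, with ties logged and broken to the
lexicographically smaller id.

The realignment DP aligns the parent peptide (with its codons) to the locus
expanded by 10 kb on each flank, locally (Smith–Waterman convention), with
transitions per consumed residue of 3 nt (codon match/mismatch), 1/2/4/5 nt
(frameshifts, penalty 15; the 4/5 nt states still score the trailing
triplet), 0 nt (residue deletion, penalty 10), and within-row genomic jumps
of ≥ 30 nt at a fixed cost of 20 regardless of length, recorded as inferred
introns. The length-independent intron cost is what lets a parent gene's own
locus realign across its introns (and hence be excluded), while cheap gaps
cannot masquerade as introns; the defaults were chosen so that single-base
indels surface as frameshift events rather than intron calls on constructed
toys. Identity is computed over aligned codon columns only (gap and 1/2-nt
frameshift columns excluded) — identity denominators differ between
alignment tools, so this definition is stated explicitly. The reported locus
is the aligned span after realignment, not the expanded window.

"Retrocopy" acceptance requires, beyond length and identity: zero inferred
introns, a parent with ≥ 3 exons, and ≥ 2 parent intron positions strictly
inside the aligned residue range — the mechanistic reading of "the parent's
introns are demonstrably absent", which is the positive evidence of
retroposition. A `max_one_retained` mode implements the laxer reading
(at most one retained intron) for sensitivity analyses. Finally, any parent
claimed by more than one surviving copy is removed entirely, leaving
one-to-one pairs: without a resolution rule, shared parents would make
per-pair dN/dS non-independent.

## Evolutionary statistics

Codon columns containing gaps, frameshifted triplets or stop codons are
excluded (and counted) before estimation; at least 10 clean columns are
required. dN and dS use Nei–Gojobori (1986) counting: per-codon synonymous
site fractions from single-base mutation enumeration (changes to stop codons
excluded from each position's denominator, so S + N = 3 per codon),
multi-base differences averaged over minimal mutational pathways with
stop-traversing pathways excluded (all pathways used only if every one is
blocked), and the Jukes–Cantor correction d = −3/4·ln(1 − 4p/3). dS is
flagged undefined at saturation (p ≥ 3/4) and such records are kept but
excluded from dS-ordered summaries. Counting was chosen over a
maximum-likelihood distance for the point estimates because it is exactly
checkable against enumeration; the likelihood machinery below provides the
model-based inference.

The LRT uses a GY94-style codon model restricted to the 61 sense codons with
equal codon frequencies and fixed κ = 2 (matching the simulator, so
calibration checks are coherent; κ is a parameter). The rate matrix is
scaled to one expected substitution per codon site per unit branch length t.
With equal frequencies the matrix is symmetric, so transition probabilities
come from a cached eigendecomposition; the pairwise likelihood is maximised
over t with ω fixed at 0.5 (null) and over (t, ω) jointly via a profile over
ω (alternative). Because the null is nested, lnL_alt is clamped to
≥ lnL_null against optimiser tolerance; the statistic 2Δ is referred to χ²
with 1 df. The χ² test is two-sided in ω, so the "significant purifying
selection" call additionally requires the point estimate ω̂ < 0.5; the FDR
(Benjamini–Hochberg, over all tested pairs in one batch) threshold defaults
to q < 0.05. Both the cutoff and one-sidedness are configurable since
reasonable analyses differ here.

## Overlap, expression, GO, orthology

Gene overlap is strand-agnostic (retrocopies insert in either orientation)
with a 1 bp minimum, implemented as a per-scaffold sweep with an end-ordered
active set and verified against a quadratic scan. A copy overlapping several
genes is exon-overlapped if any exon of any of them intersects.

FPKM = count / ((length/10³)·(library/10⁶)). A copy is expressed in a tissue
when FPKM exceeds a threshold whose default is 0 (any evidence counts);
expression frequency is the number of such tissues. dS bins are half-open
[k·w, (k+1)·w) with default width 0.2, and log-expression uses log₁₀(FPKM+1).
Kruskal–Wallis is tie-corrected with the χ² (k−1 df) reference distribution
(matching R's `kruskal.test`); an exact enumeration mode exists for small
samples, where the asymptotic p can differ noticeably from the permutation
p. The 2×2 association tests are Pearson χ² without continuity correction
(configurable); degenerate margins return (0, 1).

GO enrichment is the "classic" per-term algorithm: annotations propagated to
all is_a ancestors (part_of off by default), one-sided hypergeometric tail
per term, raw p reported with a p < 0.01 inclusion threshold and no
multiple-testing correction, no minimum term size. Expected/annotated is
constant across terms for a fixed test set, a useful output invariant.

Lineage classification consumes a binary presence matrix with
focal/fish/tetrapod species groups: lineage-specific = absent in every
non-focal species; tetrapod-lost = present in ≥ 1 fish species (an all-fish
mode is available) and absent in every tetrapod. Only binary presence is
supported; ambiguous ortholog evidence must be resolved upstream.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical structure the analysis assumes:
multi-exon parent genes (default 40, 3–7 exons, 120–320 codons, introns
200–1200 bp with GT/AG ends) on five 200 kb scaffolds, a few intronless
genes so the peptide set contains single-exon proteins, ~8 % soft-masked
intergenic sequence, and 30 planted retrocopies. Copies evolve from the
parent CDS under the same GY94 process used for inference, with age t drawn
from a mixture concentrated below 0.3 (a burst of young copies, the regime
retrocopy screens face) and capped at 0.8, ω from a mixture below 1, a 0.3
per-copy probability each of one frameshift (1–2 nt indel) and one premature
stop (so about half the copies have intact ORFs), and insertion into
intergenic/intronic/exonic contexts at 0.5/0.3/0.2, either orientation.
Five decoys — verbatim genomic copies of multi-exon genes retaining ≥ 2
introns — test that DNA-based duplications are excluded. Expression gives
each copy a per-tissue Bernoulli expression probability increasing with age
rank (base 0.08) and multiplied by 3 in the testis, with negative-binomial
counts on expressed entries over seven tissues (testis last); the GO module
plants one enriched leaf term over a designated gene subset (capped at a
third of the universe, since a subset equal to the universe cannot be
enriched) in a three-level DAG; the presence matrix marks ~15 % of genes
focal-specific and ~10 % fish-only.

The generator does **not** simulate sequencing reads, LINE/L1 machinery,
transposable-element landscapes, codon-usage or GC heterogeneity,
rearrangements, or alignment uncertainty in expression quantification.
Passing tests therefore demonstrate correctness of the algorithms under the
stated model — recovery of planted signal, calibration of the tests, exact
agreement with combinatorial oracles — not performance on real genomes,
where repeat structure and annotation error dominate.

Determinism: every stage draws from seed-derived substreams
(`default_rng([seed, stage])`), and identical configurations produce
byte-identical output trees.

## Problem sizes and numerical choices

Default study conditions (the sizes the tests and the acceptance script
use): ~1 Mb genome, 40 parents, 30 copies, 5 decoys for the end-to-end
recovery run; 200 pairs of 300 codons for dS recovery (t ∈ [0.05, 1.5]);
500 replicates per LRT calibration scenario; 100 simulations of 500 copies
for testis-bias recovery. The DP uses float64 with a traceback tolerance of
1e-4; LRT optimisation brackets t ∈ [1e-9, 40] and ω ∈ [1e-4, 30] on log
scales (the tiny lower t bound keeps the boundary artifact of the nested
fit below 1e-6 for identical sequences). Ties are broken lexicographically
everywhere a choice is arbitrary, so outputs are order-independent.

## Known limitations

The built-in search has no e-value model and no gapped extension beyond the
merge rule — distant (t ≫ 1) copies are found only through the merge of
short conserved blocks, and copies whose amino-acid identity decays below
the 70 % acceptance rule are (correctly, per the screen's definition)
excluded, which biases the catalogue toward young or constrained copies.
Splice sites are not modelled in the realignment, so intron boundaries are
score-optimal rather than biological. κ is fixed rather than estimated by
default, and codon frequencies are uniform (no F3×4). Expression joining in
synthetic mode matches detected loci to planted copies by coordinate
overlap; real runs must supply counts keyed by retrocopy id.
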