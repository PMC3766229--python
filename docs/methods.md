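# Methods

## Scope and coordinate conventions

All modules share 0-based, half-open genomic coordinates with strand labels
`+`/`-`. Motifs are position-specific scoring matrices (PSSMs): per-column
base-frequency vectors over (A, C, G, T), every column summing to one within
1e-9 after normalisation. Site hits report the forward-strand coordinate of
the window start regardless of hit strand, with the matched word given in
the motif's orientation.

## Upstream control regions

A gene's UCR is the intergenic sequence upstream of its 5' boundary, capped
at a requested length (default 3000 bp) and trimmed back to the nearest
flanking gene. Two deliberate readings of "flanking open reading frame" are
baked in and documented rather than inferred:

* neighbours on **either strand** trim, because any annotated gene
  interrupts the intergenic stretch regardless of orientation;
* **gene boundaries stand in for ORF/TSS coordinates**, since the target
  gene sets carry no UTR annotation. Where 5' UTRs are long, the extracted
  region therefore includes transcribed leader sequence.

Regions shorter than `min_length` (default 30 bp, configurable — there is
no canonical treatment of degenerate short regions) are excluded
with a logged reason. Minus-strand extraction is defined — and
property-tested — as plus-strand extraction on the reverse-complemented
contig with mirrored coordinates. N bases are retained; motif scanning
assigns them zero column credit.

## The two percent scales

The pipeline deliberately keeps two distinct, documented similarity scales:

* **Site similarity** (word vs PSSM): `100 · mean_i f[b_i, i] / max_b f[b, i]`.
  Normalising by the column maximum makes a consensus-built PSSM reproduce
  mismatch-count semantics exactly: a word violating k of w degenerate
  consensus positions scores 100·(w−k)/w. This is the scale of the "70%
  similar to the consensus" site scans.
* **PSSM identity** (PSSM vs PSSM): per overlapping column the allele-sharing
  coefficient `1 − ½ Σ_b |f_a[b] − f_b[b]|` (bounded in [0, 1], symmetric,
  defined on zero-variance columns, unlike Pearson correlation), averaged
  over the overlap and maximised over all ungapped offsets and the reverse
  complement. The overlap floor is `max(4, ⌈0.75 · min(widths)⌉)` to forbid
  spurious single-column alignments. Ties resolve toward the forward
  orientation, then the smallest offset. This is the scale of the "70%
  identity" TF-matching rule.

## De novo discovery

A ZOOPS-style Gibbs sampler: per restart, each sequence is initialised with
a random candidate site (both strands are candidate space); sweeps then
rebuild the leave-one-out PSSM (pseudocount α = 0.25) and resample each
sequence's site from the posterior over all windows plus a "no site" option
with prior occupancy 0.8. The best configuration per restart is kept by MAP
score; restarts are deduplicated at 95% PSSM identity. Every random draw
comes from one seeded generator per invocation — no global state — so runs
are bit-reproducible.

The MAP score is defined explicitly (the original finders' internal scores
are not reproduced here):

    MAP = (1/ln 2) · Σ_sites ln[P(site|PSSM)/P(site|bg)]
          − n_sites · log2(total admissible positions)

with admissible positions counting every window on both strands of every
input sequence. The **background model defaults to order 1**, fitted on the
input set: with correlated (sticky) backgrounds an order-0 model rewards
homopolymer runs, and on the synthetic benchmark the sampler then locks onto
background artifacts instead of the planted motif (measured 47% vs 91%
identity on the same seed). Order 0 remains available for analytic tests.

Significance for internal motifs is a Monte-Carlo proxy: discovery is rerun
on dinucleotide-shuffled copies (exact Altschul–Erickson edge shuffling,
preserving dinucleotide counts and terminal characters) and the proxy is
`(1 + #{shuffled best MAP ≥ observed}) / (n_shuffles + 1)`, floor
`1/(n_shuffles+1)` at the default 19 shuffles. Imported MEME-minimal motifs
carry their genuine E-values instead. The filter cascade applies whichever
significance a motif has; a motif with none is filtered on MAP alone.

## Specificity statistics and the filter cascade

Presence (at least one scan hit in a sequence), not occurrence counts,
defines x and X — this keeps the hypergeometric model exact. The universe is
all genes with a valid UCR. With x of s group and X of N universe sequences
containing the motif:

* Church score = `P(K ≥ x)`, `K ~ Hypergeom(N, X, s)` (scipy `hypergeom.sf`);
* ROC-AUC = normalised Mann-Whitney U over per-sequence best-window
  similarities, midrank ties credited ½;
* enrichment = `P(B ≥ x)`, `B ~ Binomial(s, X/N)`. The binomial (rather than
  a second hypergeometric) reading of "enrichment" is a deliberate choice,
  flagged here because the source literature cites one reference for both.

Filter 1: `MAP > 5`, plus `E-value ≤ 1e-5` for imported motifs (internal
proxies are required at their floor by default). Filter 2:
`Church ≤ 1e-4 ∧ AUC ≥ 0.7 ∧ enrichment ≤ 0.01`. No multiple-testing
correction is applied across motifs — the cascade uses fixed thresholds and
reports raw values so users can correct downstream.

**Presence threshold.** Site scans for consensus motifs use 70%. Presence
counting for count-derived matrices defaults to **85%**: a count matrix
gives partial credit at every column, so at 70% an informative 8-mer is
"present" in nearly every 400 bp of background (measured x=s, X=N), which
voids the presence statistics entirely. 85% keeps background presence rare
while planted sequences still register.

## Synthetic data

The generator emulates the study design the pipeline targets: one contig of
low-order Markov background at an AT-rich insect composition (A=T=0.335,
C=G=0.165; honeybee regime), non-overlapping genes on both strands with
configurable intergenic spacing (the contig ends after the final spacer, so
flank regions also follow the configured distribution), a foreground
"upregulated" gene set (default one third of genes) whose UCRs carry planted
instances **sampled from the planted PSSM** (not consensus-only, to exercise
degenerate matching) at per-UCR occupancy 0.9, alternating CP/muscle
category labels on foreground genes, and a TRANSFAC-format library of the
planted motif plus random decoys (one dominant base per column at frequency
0.9–1.0, ≥ 1.3 bits/column — binding-site-like, not background-like).

Order-≥1 backgrounds are sticky chains: with probability 0.2 the previous
base repeats (order 2 splits that weight across the two preceding bases),
otherwise a fresh draw from the stationary composition — so the marginal
composition is preserved at any order. Planting avoids offsets already
covered by an earlier instance (adjacent opposite-strand genes share an
intergenic stretch), so ground-truth coordinates always recover the planted
word exactly through UCR extraction.

What the generator does **not** emulate: repeats and compositional
heterogeneity of real genomes, nucleosome/chromatin context, motif
clustering and homotypic runs, overlapping gene models, and UTR structure.
Passing the planted benchmark therefore demonstrates correctness of the
machinery and sane calibration of the cascade, not performance on real
promoters.

## Benchmark problem sizes

The standard planted benchmark uses 60 genes with fixed 400 bp spacers
(20 foreground UCRs of exactly 400 bp), discovery at 5 restarts × 200
sweeps; the null-calibration suite uses 200 datasets of 40 genes with
250 bp spacers at occupancy 0, discovery at 2 restarts × 60 sweeps. These
sizes make the whole suite run in about a minute while leaving the
statistics well away from their thresholds on planted data (Church p
typically 1e-6 or smaller, AUC 0.85–0.95).

## Known limitations

* **The MAP filter is scale- and composition-dependent.** At 20×400 bp the
  positional penalty is ≈ 14 bits per site, so AT-dominant motifs near the
  1.3 bits/column information floor can be *recovered* by the sampler at
  > 95% identity yet *rejected* by `MAP > 5` in an AT-rich background
  (their per-site log-likelihood ratio is ~10 bits). GC-dominant motifs of
  the same information content pass comfortably. The benchmark's recovery
  rate over random planted motifs reflects this honestly; the threshold is
  configurable.
* Reported Church/enrichment values are raw tail probabilities; with many
  candidate motifs they need multiple-testing correction downstream.
* PSSM identity is ungapped; motifs differing by an internal indel will
  under-score.
* The TRANSFAC parser handles the flat-file dialect only; no curated matrix
  data ships with the package.
* Reporting percentages reproduce printed conventions bit-exactly: array
  percentages round to 1 decimal, gene-set shares to 2, and concordance is
  floored to 1 decimal (58/72 → 80.5). GGYGG/GGY are amino-acid literals
  (Y = tyrosine), not nucleotide codes. Protein masses are average residue
  masses plus one water by default, monoisotopic on request; glycine content
  is reported for both precursor and mature form, since which of the two a
  printed figure refers to is often unstated.
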