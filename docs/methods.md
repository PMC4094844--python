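# Methods

This note documents the models, conventions and numerical choices behind
`alkatlas`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate conventions

All genomic coordinates are 1-based and inclusive (the GFF3 convention). A
feature's `start` is always the numerically smaller coordinate; on the minus
strand the biological 5′ end is therefore the larger coordinate. Transcript
length is |5′ − 3′| + 1. The exported BED rows convert to 0-based half-open
at the boundary only. This matches the way complement-strand positions are
reported for the *Synechocystis* locus (the 5′ anchors are numerically
larger than the 3′ anchors) and keeps every length identity exact:
5′UTR + ORF + trailer = transcript length, checked on all fixtures and as a
hypothesis property over random gene/transcript placements.

## The reconstructed Synechocystis locus

No genome download ships with the package. The *ado*/*aar* locus is
reconstructed from its published coordinate anchors (three TSS, ORF lengths
696 and 1023 nt, leader lengths, and the mapped 3′ ends); the chain of
printed numbers closes exactly (TSS3 − 72 − 1023 + 1 − 64 lands on the
mapped *aar* 3′ end), which is itself a test. `locus.build_demo_genome`
shifts the locus near the origin of a small synthetic contig — pairwise
distances, hence all lengths, are preserved — and back-translates the
synthetic seed proteins into the gene bodies so every pipeline stage
(including translation and element scanning) can run on it. The SyR9 sRNA 3′
end was never precisely mapped; its nominal 160 nt length is treated as
annotation, not ground truth.

## Ortholog survey

Protein screening is optimal local alignment (Smith–Waterman with affine
gaps; a gap of length L costs open + L·extend) under BLOSUM62 with the BLAST
default penalties 11/1, executed by Biopython's `PairwiseAligner`.
Significance uses the Karlin–Altschul form E = K·m·n·e^(−λS) with the
standard gapped-BLOSUM62 constants λ = 0.267, K = 0.041; the detection
threshold is E ≤ 1e−5. "Ortholog" means best one-way hit above threshold
(highest raw score, ties by smaller E-value then lexicographic gene id);
reciprocal-best checking exists but is off by default. Composition-based
score adjustment is not implemented, so E-values are cruder than a modern
BLAST's — adequate for thresholding planted homologs against
composition-preserving shuffled decoys, which is what the synthetic cohorts
exercise. For cohort-scale real screens, precomputed 12-column tabular hit
files can be ingested instead of running the built-in aligner, which is a
desk-scale tool.

## Arrangement classification

*ado* and *aar* count as a tandem pair when they share contig and strand,
with at most 1 intervening annotated gene and an intergenic gap ≤ 500 nt
(both configurable; annotations occasionally insert a small ORF into real
operons). The pair upgrades to a five-gene cluster when *accA* and the SDR
gene are detected within 5 annotation positions of it; GTP cyclohydrolase I
is recorded as an optional fifth member, present in most but not all real
clusters. Mixed-strand adjacency is reported as SPLIT with a note. A genome
with exactly one of the two core genes detected is labelled SPLIT with a
loud single-gene warning and counted in neither "both present" nor "absent"
— real surveys found no such genome, so it always signals either a broken
assembly or a detection failure. Cohort tandem prevalence counts tandem
pairs plus five-gene clusters, since a cluster contains the pair.
Classification is invariant under mirroring the genome (property test).

## Transcript units

A TSS is assigned to a gene when it lies on the same strand, 0–300 nt
upstream of the start codon (cap configurable; observed leaders at this
locus are 72–214 nt) with no intervening same-strand gene. The nearest TSS
of a gene is "proximal", the others "distal"; unassigned TSS are returned as
orphans, i.e. candidate sRNA starts.

The minimal-dicistron bound is the inclusive distance from the upstream
gene's start codon to the downstream gene's stop codon — a hard lower bound,
since a real dicistron adds a leader and trailer. Classification of a
transcript model: no ORF covered → SRNA; one ORF plus a 5′ leader containing
a listed sRNA locus → COTRANSCRIPT; with interval (northern-style) size
evidence, observed maximum below the bound → MONOCISTRONIC and observed
minimum at or above it → DICISTRON_COMPATIBLE; exact (RACE-derived) ends
covering exactly one ORF → MONOCISTRONIC, unless the leader is long enough
(≥ 150 nt, just under the smallest relevant sRNA) to hide an unlisted sRNA,
in which case AMBIGUOUS. The rule is monotone: growing the observed maximum
never moves a call toward MONOCISTRONIC.

## Regulatory elements

The −10 scanner scores hexamers with a log2-odds PSSM built from the σ70
TATAAT consensus (pseudocount 0.1, uniform background), sliding the hexamer
3′ edge across offsets −16…−4 relative to the +1; ties break toward the
canonical −7. The default score floor of 7.0 bits (~70 % of the 9.9-bit
consensus maximum) admits essentially only near-consensus hexamers; on
uniform random background the per-scan false-positive probability is ≈
13·4⁻⁶ ≈ 0.3 %. With a single-consensus PSSM this is deliberately strict —
degenerate natural promoters need a trained PSSM, which the scanner accepts.

The terminator finder exhaustively enumerates stem/loop placements
(stem 4–15 bp, loop 3–10 nt), requires arms fully complementary under
GC/AT/GT-wobble pairing, scores 3·GC + 2·AT + 1·GT − 0.5·loop, and demands
≥ 3 T within the 6 nt after the stem — the U-tract is mandatory, which is
what distinguishes an intrinsic terminator from an arbitrary hairpin. The
default score floor of 16 was calibrated once on uniform random 100-nt
background (measured false-call rates: 1.3 % at a floor of 14, 0 % at 16
over 300 spans) and verified at ≤ 5 % over 1000 spans in the test suite.
This is a pairing score, not a nearest-neighbor ΔG; it ranks placements, it
does not predict termination efficiency.

## Phylogenetics

Distances come from aligned sequences with pairwise gap deletion, as raw
p-distance or Jukes–Cantor d = −(3/4)·ln(1 − 4p/3) (default; error when
p ≥ 3/4). Neighbor joining follows Saitou–Nei with the standard Q-criterion;
ties break by the lexicographically smallest joined taxon pair so output is
deterministic and input-order invariant up to relabeling. Negative branch
estimates are clamped to zero with the deficit logged. On additive matrices
NJ provably recovers the generating tree; the tests verify exact topology
and branch-length recovery on random 4–8 taxon additive trees. No bootstrap
is computed. The presence overlay counts maximal all-ABSENT subtrees under
the NJ rooting: 1 when the alkane-negative strains form a single clade.

## Decay kinetics

First-order decay S(t) = S₀·e^(−kt) is fitted as OLS on ln S vs t
(scipy `linregress`); t½ = ln 2/k, with k clamped at 0 (infinite half-life)
for nonnegative slopes. Log-linear fitting matches densitometric practice
and makes noise-free generator→fitter round trips exact to machine
precision, which the tests assert at 1e−9. Normalising to the t = 0 sample
shifts only the intercept. The default sampling grid (0, 3, 5, 10, 15 min)
is the rifampicin experiment's design. Monte-Carlo recovery under lognormal
noise (σ_log = 0.1, 500 replicates) keeps the median estimate within 5 % of
truth.

## Expression meta-analysis

Fold-change tables are genes × conditions matrices of log2 values with
missing cells excluded pairwise. Sign concordance treats zero as positive —
an arbitrary documented choice; no zeros occur in the packaged table. The
packaged fixture holds the four novobiocin-combination conditions for
*ado*/*aar*. Reporter activity is (construct − control)/(reference −
control) on replicate means, clamped at 0 with a "close to background" flag.

## Synthetic data: what it shows and what it does not

Every generator is a pure function of spec + seed. Cohort genomes plant
homologs by mutating deterministic synthetic seed proteins (no real
sequences are redistributed) to a target identity under uniform
substitution without indels, and add decoys made by shuffling seed-protein
bodies — composition preserved, signal destroyed, so E-value thresholding is
genuinely exercised. Planted counts are rounded products of the requested
frequencies, adjusted on the most frequent class to hit the cohort size; the
default frequency vector (0.61 / 0.15 / 0.14 / 0.10) mirrors the prevalence
proportions observed at phylum scale. Read counts in TSS tables are
geometric and cosmetic. Sequence evolution on trees is per-site
Jukes–Cantor, gap-free.

Passing on this material shows the algorithms are correct on their stated
models; it does not show robustness to indels, domain shuffling,
composition-biased proteomes, annotation errors, degenerate promoters or
rate heterogeneity across sites — none of which the generators emulate.
Problem sizes used by the default test-and-acceptance runs (100-genome
cohorts, 200 alignment oracle pairs, 1000 background spans, 500 decay
replicates, 50 additive trees) were chosen as the smallest sizes at which
the statistical claims are stable.

## Pipeline

Stages run in dependency order (classify needs survey; the tree overlay
needs classify) from one YAML config; one global seed fans out to per-stage
seeds by CRC32 hashing (kept below 2³¹). All outputs are plain files
(TSV/JSON/GFF3/BED/newick/CSV/FASTA), each listed in a manifest with its
SHA-256, so reruns are byte-verifiable.
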