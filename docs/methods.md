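# Methods

## Co-expression statistics

Pairwise Pearson correlation is computed across compendium samples
(pairwise-complete with a minimum of 20 shared observations when values
are missing; zero-variance genes yield missing entries).  Mutual rank
follows the co-expression-database convention: each gene ranks all other
genes by descending ρ (self excluded, average ranks at ties) and
MR(a,b) = √(rank_a(b)·rank_b(a)).  MR ≥ 1 with equality exactly for
reciprocal top partners, and, being rank-based, it is invariant under any
strictly monotone transform of a gene's correlation profile.  Group
comparisons Fisher-transform ρ (z = atanh ρ, variance-stabilizing) and
use a one-sided Welch t-test (alternative: background smaller) plus a
one-sided Wilcoxon rank-sum test on MR.

## Target prediction

The K highest-correlating (seed, non-seed) pairs are selected, ranking by
|ρ| by default because both strong positive and strong negative
co-expression are informative for an oscillator whose limbs peak in
antiphase; a signed mode is available since "highest correlating" can
also be read as signed ranking.  Ties at the selection boundary are all
retained (deterministic under input permutation; K may be slightly
exceeded).  The selection report states the implied |ρ| cutoff, the
selected fraction 100·K/(n_seed·n_universe), and the cutoff in multiples
of the background-ρ SD.  The fraction denominator uses the full gene
universe; excluding seed–seed pairs is a flag (both roundings agree at
compendium scale).  Tightness is the number of distinct seed partners of
a candidate; the default filter keeps tightness ≥ 2, and a sweep utility
records candidate counts and per-term enrichment trajectories over
minimum-tightness 1…10.

## Overrepresentation

Per namespace, each term is tested with the one-sided hypergeometric
tail P(X ≥ Significant) for drawing |query ∩ universe| genes from the
namespace universe (default: all genes annotated in the namespace;
configurable to the expression universe).  Expected =
Annotated·|query|/|universe|; within one namespace Expected/Annotated is
therefore a constant sampling fraction, which lets the Expected column be
reconstructed for any term from a single known row.  q-values are
Benjamini–Hochberg step-up (via statsmodels).  Note BH is not idempotent:
re-applying it to q-values can only push them upward.  Graph-aware
decorrelation variants of term testing are out of scope; annotations are
taken as given in the GMT.

## ChIP-seq target calling

Peaks are anchored at their summit when the narrowPeak source provides
one, otherwise at the interval midpoint, and assigned to the gene with
the nearest TSS on the same chromosome; the exact association rule of
published target-caller packages is not specified in enough detail to
clone, so the simplest closest-TSS rule is used and documented.  A gene's
score is the sum of assigned peak signal values (1 when the source lacks
a score), so Σ_g S_g equals the total assigned signal and doubling all
weights shifts every log2 score by exactly 1.  Distance ties go to the
lexically smaller gene id to keep conservation exact.  Targets are called
at log2(S) ≥ 3 by default; `threshold_suggest` fits a two-component
Gaussian mixture to the log2 scores and proposes the density valley
between the component means, falling back (flagged) to mean + 1 SD when
the components merge — the right-shoulder rather than bimodal case.  TFs
with no public peak coordinates can bypass scoring through a
provided-target-list reader.

## Rhythm detection

The scan compares each series against cosine references on a period grid
(default 20–28 h, 1 h step — bracketing the circadian band) at phase
offsets spaced by the sampling interval, using Kendall's tau-b; the
statistic is the maximum tau over the grid.  Because the maximum over
many correlated references is not Kendall-distributed, per-reference
exact or normal tails would be anti-conservative for the best reference;
significance is instead calibrated against a seeded Monte-Carlo null
(random permutations of the series ranks pushed through the identical
scan, shared across genes), giving p = (1 + #{null ≥ tau})/(B + 1) with
B = 2000 by default and uniform null p-values by construction.  q-values
are BH across genes.  Constant series have undefined tau and are assigned
p = 1, flagged.  Both p- and q-columns are always emitted so either
thresholding policy (e.g. p < 0.009 or a q cutoff) can be applied; the
scan is invariant to increasing affine transforms of the data.

## Synthetic data: what it emulates and what it does not

The generator plays the role of every external input so the pipeline is
testable offline with known truth.  Samples draw independent uniform
phases θ_s ∈ [0, 24) — modelling a compendium aggregated from
unsynchronized experiments — so two clock genes with amplitude a and peak
offset Δφ have expected correlation cos(2πΔφ/24)/(1 + 2σ_n²/a²); with the
default σ_n = 1 this attenuates the 9 h BMAL–PER offset to ρ ≈ −0.24,
the weak-but-signed regime real compendia show, rather than ±cos Δφ.
Planted targets are noisy standardized mixes of their seed genes' values
with a configurable variance fraction (default 0.5).  Literature tables
emit every true edge with shifted-geometric sentence counts (heavy-tailed:
mean well above median, as in real text-mining support) and a
binomially-drawn number of random non-edges targeting a 10% false-pair
rate.  Peak sets give each true TF target 1–3 peaks nearer its TSS than
any other, with total weight drawn above the calling threshold, plus
uniform low-weight background peaks, producing a bimodal log2 score
distribution.  Time courses are cosines plus noise for rhythmic genes and
pure noise otherwise.

Deliberately not modelled: realistic transcriptome marginals, batch and
platform effects, tissue-specific modules, annotation DAG structure, and
correlated text-mining errors.  Passing recovery tests therefore
demonstrates that the pipeline's logic is correct under its stated model,
not that real compendia meet these assumptions.

### Reference conditions and problem sizes

The default synthetic universe is 200 samples × (14 clock genes + 40
planted targets + 1000 background genes); each target is wired to 2–3
seeds, so planted tightness is ≥ 2 by construction.  The pipeline K for
this universe is 200, chosen to match the published-scale selection
fraction (~1.2–1.4% of seed × non-seed pairs).  End-to-end recovery is
summarized as the median over 10 seeds of consensus precision/recall and
ChIP target recall.  All randomness flows from one integer seed through
explicit numpy Generators (per-artifact salted streams), so fixed seeds
give byte-identical output files.

## Shipped fixtures

`data/seed_network_nodes.tsv` / `data/seed_network_edges.tsv`: a 43-gene
seed clock network (14 core-clock genes plus 29 curated interactors with
signed edges).  It is a synthetic stand-in assembled from the canonical
circadian regulatory literature, shaped like a curated extended-clock
fixture; it is data, not computation.  `data/consensus_gene_annotations.tsv`
encodes a published consensus-gene annotation table (per-TF ChIP target
flags, circadian expression, RNAi phenotype classes high-A/long-T/short-T,
ML-similarity membership, disease annotation) used by the reporting layer
and the acceptance checks.

## Numerical choices and degenerate inputs

Average ranks at correlation ties keep MR symmetric and
permutation-consistent.  Selection uses stable mergesort with (seed,
gene) tie-breaks, so output is invariant to gene order.  Hypergeometric
tails come from scipy; enumeration oracles in the tests verify them
exhaustively for small universes.  Candidate tables, empty consensus
sets, peak-free score tables, and constant series all degrade to defined
outputs (empty frames, seed-only networks, zero scores, p = 1) rather
than errors; genuinely invalid inputs (duplicate gene ids, < 3 samples,
< 8 timepoints, malformed GMT/evidence tables, p outside [0, 1]) raise.

## Known limitations

Correlation-based edges carry no direction; the assembled graph stores
evidence edges undirected and only curated seed edges keep sign and
direction.  The closest-TSS rule ignores distal regulation and assigns
every peak to exactly one gene.  The rhythm scan's Monte-Carlo p-values
are discrete at resolution 1/(B+1), which bounds attainable significance
per gene.  The mixture-based threshold suggestion assumes at most two
log-score populations.
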