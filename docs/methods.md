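# Methods

`dccircuit` reverse-engineers stage-specific transcription-factor (TF)
regulatory networks along the dendritic-cell (DC) developmental sequence
MPP → CDP → cDC/pDC by integrating three data layers: differential gene
expression between consecutive cell states, differential PU.1 ChIP-seq
binding between states, and TF-motif enrichment inside the differential
PU.1 peaks. This note documents the models, the defaults and why they were
chosen, what the synthetic benchmark does and does not emulate, and the
numerical conventions.

## Expression analysis

**Differential expression.** For a contrast (a, b) the per-gene statistic
is a moderated two-sample t-test on log2 values: gene-wise pooled variances
s²_g are shrunk toward the median gene variance s²_med with a fixed prior
weight of d0 = 4 pseudo-degrees of freedom,

    s̃²_g = (d0 · s²_med + df · s²_g) / (d0 + df),   df = n_a + n_b − 2,

and t = (x̄_a − x̄_b) / √(s̃²_g (1/n_a + 1/n_b)) is referred to a
t-distribution with df + d0 degrees of freedom. This is a deliberately
simple empirical-Bayes scheme in the spirit of limma's moderated t; a plain
Welch t-test is available via `method="welch"`. A gene is called DE when
|log2FC| > log2(fc_threshold) (default fold change 2) **and** raw p < α
(default 0.05). Benjamini–Hochberg adjusted p-values are always reported,
and `gate="adjusted"` switches the call to the adjusted p — the raw-p gate
is the default because the fold-change + raw-p criterion is the
conventional two-filter rule this kind of microarray analysis uses, with
BH reported alongside.

**Clustering.** DE genes (union over the four consecutive contrasts
MPP–CDP, CDP–cDC, CDP–pDC, cDC–pDC) are clustered into six stage-specific
groups (MPP/CDP, MPP, CDP, pan-DC, cDC, pDC) with Bezdek fuzzy c-means
(fuzzifier m = 2.0, tolerance 1e-6 on the maximum centroid shift, ≤500
iterations, centroids initialized from distinct data rows under a fixed
seed). Input rows are the gene-by-state matrices of replicate-group means,
z-scored per gene so the clustering follows profile *shape* rather than
expression magnitude. c = 6 is used directly; c is configurable. Hard
labels are argmax memberships with ties broken toward the lowest cluster
index. Cluster-level chromatin summaries use the geometric mean
exp(mean(log(x + pc))) − pc with pseudocount pc = 1 so zero signals are
admissible; empty clusters are reported as missing, never as zero.

## ChIP-seq signal and differential peaks

Peak BED files are the input; no read-level processing happens here.
Gene-centric signal for a window of half-width w around the TSS is
Σ_peaks score × overlap_bp / (2w), with w = 1 kb for the promoter marks
(H3K4me3, H3K27me3) and w = 50 kb for the distal marks (H3K4me1, PU.1).
Windows clipped at chromosome ends keep the nominal 2w denominator so
near-telomeric genes are not inflated. All interval arithmetic is 0-based
half-open with overlap defined as ≥1 shared base.

PU.1 peaks are classified as *active promoters* (overlap both H3K4me1 and
H3K4me3), *enhancers* (H3K4me1 only) or neither; genes are *bivalent* when
both H3K4me3 and H3K27me3 overlap TSS ± 1 kb.

**Differential peaks** between two states are called on the merged peak
universe: scores are library-normalized to equal totals, summed per merged
region, and compared as (s_a + 0.5)/(s_b + 0.5); ratio ≥ 2 ⇒ a-specific,
≤ 1/2 ⇒ b-specific, else shared. The 0.5 pseudocount makes present/absent
regions fall out of the same rule. For cross-sample comparison and
ordination, peak-signal matrices are normalized by classic quantile
normalization (rank → mean of
sorted columns, ties receiving the mean of the values they would occupy)
before PCA; PCA is column-centered SVD with each component sign-fixed so
its largest-magnitude loading is positive, making outputs deterministic.

## Motif analysis

Motifs are position probability matrices over ACGT (JASPAR count or MEME
minimal input; counts smoothed as (c + pc)/(N + 4pc)). Scanning scores
every offset on both strands with the log2-odds Σ_i log2(p_i(b)/q(b))
against a 0-order background q (uniform by default); windows containing N
are skipped.

**Threshold calibration.** Each motif's hit threshold is the smallest score
t with P(score ≥ t | background) ≤ FPR, default FPR = 1e-4 per window and
strand. The null score distribution is computed by exact dynamic
programming after discretizing per-position scores to a 0.01-bit grid
(exact for motifs ≤ 20 bp; Monte-Carlo sampling beyond). The returned
threshold is therefore exact up to the stated discretization.

**Enrichment.** Enrichment of a motif in foreground vs background peak
sets is *region-level*: a region counts as hit when it contains ≥1
scan hit, which removes region-length bias from the statistic. Regions are
standardized to ±250 bp around the peak midpoint (a summit proxy) before
scanning. Significance is a one-sided Fisher's exact test on the
(hit/no-hit) × (fg/bg) table, BH-corrected across motifs within each
cell-state column, cut at adjusted p < 0.05. For each state s the
foreground is the s-specific differential PU.1 peaks; the background pools
the differential peaks specific to the *other three* states (both
contrasts). The pooled background was chosen over the single opposite
contrast side because it is three to four times larger at realistic peak
counts, which keeps the region-level Fisher test well powered and the
chance-hit noise (~3% of 500-bp regions contain a spurious hit at
FPR 1e-4) from dominating small backgrounds. A shuffled-coordinate or any
custom background can be passed to `motif_enrichment` directly. The same
machinery runs on TF footprints stratified by PU.1 overlap
(`footprint_enrichment`); footprint calling itself is consumed as input.

**Co-binding partners.** A TF is a PU.1 co-binding partner in state s iff
its motif is significantly enriched in s and its expression does not
oppose activity there: its state-mean expression in s is ≥ its median over
the four states, *or* it is significantly up in s in a DE contrast
involving s. This formalizes the exclusion of opposing
expression/enrichment patterns. Partners are grouped by their binary
enrichment signature across the four states.

## Network construction

A directed edge a → b in state s requires the conjunction of three
conditions: (i) a is a co-binding partner in s; (ii) b is DE in the stage
direction of s's contrast (up in s, because inferred edges model
activation); (iii) ≥1 hit of a's motif lies inside an s-specific
differential PU.1 peak assigned to b. Peaks are assigned to every gene
whose TSS ± 50 kb window they overlap (nearest-TSS-only mode available;
the window mode is the default because the association window matches the
distal signal window and the true assignment is unknown). Stage direction
convention: the MPP and CDP networks use the MPP–CDP contrast with up-in-
stage genes and stage-specific peaks; cDC and pDC use the cDC–pDC
contrast. Edges deduplicate on (source, target, state), merging supporting
hits. Self-edges are auto-regulatory loops. The four stage networks are
united into one circuitry; literature edges (TSV with source, target,
sign, citation) are appended with either sign — inhibition enters *only*
through literature edges and literature is never evidence for inferred
edges. Feedback cycles are simple directed cycles over activation edges
(length ≤ 4 by default), reported once with the lexicographically smallest
node first. Every inferred edge carries its evidence record, and an audit
operation rebuilds the network from the stored inputs and verifies each
edge re-satisfies all three conditions.

## Validation statistics

Predicted target sets are validated by the shift of per-gene expression
deltas (condition A − condition B) in targets versus background genes
(default: all measured non-targets, matching a genome-wide density-plot
comparison), tested with a Wilcoxon rank-sum: exact enumeration when
n + m ≤ 20 without ties, otherwise normal approximation with midranks, tie
correction and continuity correction. Binding-site prediction is scored by
a region-level ROC: each evaluation region takes the maximum motif-hit
score inside it (−∞ when none), positives are regions overlapping an
observed ChIP peak of the validated TF, and AUC is the trapezoidal
integral (equal to the normalized Mann–Whitney U). Network recovery
against synthetic truth is set-based precision/recall/F1 on
(source, target, state) triples, literature edges excluded, self-loops
additionally reported separately.

## The synthetic benchmark

The generator emulates the four-state study design with a planted,
fully-realized truth; its defaults are the study conditions and were fixed
before the recovery experiments:

- **Genome/annotation**: 2 chromosomes × 6 Mb of i.i.d. uniform ACGT;
  200 genes at ~60 kb spacing (±2 kb jitter). The spacing is chosen so a
  peak placed 2–8 kb downstream of a TSS lies inside the ±50 kb window of
  its own gene and (almost) no other, keeping peak→gene assignment
  unambiguous without requiring nearest-TSS mode.
- **Expression**: six fixed binary on/off archetypes over (MPP, CDP, cDC,
  pDC) — MPP/CDP (1100), MPP (1000), CDP (0100), pan-DC (0011), cDC
  (0010), pDC (0001) — at baseline 6.0 log2 units + effect 2.0 (i.e. a
  4-fold activation), Gaussian replicate noise sd 0.25, 4 replicates per
  state. 20% of genes are constitutively expressed ("flat") and serve as
  nulls for DE error-rate estimation. 20 TF genes sit in the four
  state-specific clusters (5 per state).
- **Chromatin**: active genes carry H3K4me3 at the TSS, inactive genes
  H3K27me3; 10 planted bivalent DC-cluster genes carry both in the
  progenitor states. Each active gene gets one distal PU.1 peak (400 bp,
  2–8 kb downstream of the TSS) present exactly in its active states;
  15% of state-specific genes instead carry the peak in both contrast
  states with a 3-fold score difference, exercising the fold-change route
  of the differential-peak caller. H3K4me1 co-occurs with each PU.1 peak
  with configurable probability (default 0.7, the mature-DC end of the
  overlap range).
- **Motifs/truth network**: each TF gets a distinct random consensus
  (length 12) as a near-deterministic PWM (p = 0.97 on the consensus
  base). Each TF regulates 10 genes of its own state cluster; for every
  true edge the TF's exact consensus is written into the target's
  state-specific PU.1 peak, so every edge satisfies the three-condition
  rule by construction. Two auto-regulatory loops (a TF's own consensus in
  its own peak) are planted by default. Optional decoy TFs are enriched in
  a state whose expression archetype is off there (on in two other
  states), so the opposing-pattern rule must exclude them.

What the benchmark does **not** emulate: read-level noise and mappability,
fragment-size effects, composite/overlapping peaks, correlated motif
content (motifs are distinct random words on an i.i.d. background),
realistic PWM degeneracy, and expression archetypes beyond clean on/off
patterns. Recovery results on it therefore demonstrate the correctness and
self-consistency of the inference logic — not expected performance on real
ChIP-seq, where peak calling, motif redundancy and indirect binding
dominate the error budget.

## Numerical conventions and degenerate inputs

- Coordinates 0-based half-open throughout; overlap ≥ 1 bp.
- Odds ratios with a zero cell use Haldane–Anscombe (+0.5 on all cells)
  for the reported OR only; p-values are untouched.
- Undefined-as-missing (NaN/None), never zero: overlap fraction of an
  empty query set, AUC with single-class labels, recall against empty
  truth, precision of an empty prediction, empty-cluster summaries,
  empty footprint strata.
- PCA of a constant matrix returns zero coordinates and zero variance
  fractions; FCM points coinciding with a centroid split membership over
  the coinciding centroids; non-convergent FCM returns the last iterate
  with a warning and `converged_ = False`.
- Identical samples in the Wilcoxon test return p = 1 (the tie-corrected
  variance is zero and the statistic carries no information).
- Problem sizes in the shipped tests and the acceptance script (200
  genes, 20 TFs, 12 Mb genome, ≤500-interval oracle fixtures, 300–500
  resampling rounds) are the package's default benchmark scale, chosen so
  the full verification runs in seconds while leaving every statistical
  margin wide.
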