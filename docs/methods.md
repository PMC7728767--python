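# Methods

This note documents the statistical models behind each `nfykit` stage, the
parameters that matter, what the synthetic generators do and do not
emulate, and the numerical conventions adopted where the underlying
procedures admit more than one reasonable reading.

## Differential expression

Each gene is tested with a Welch (unequal-variance) two-sample *t* on the
log2 scale, knockdown minus control; RNA-seq counts are transformed
log2(x + 1) first. P-values are Benjamini–Hochberg adjusted across all
tested genes, and direction calls use inclusive comparisons: a gene is
`down` iff log2FC ≤ −fc_min **and** q ≤ q_max, symmetrically for `up`.

Conventions for degenerate inputs: a gene with zero variance in both
groups gets p = 1 when the group means are equal and p = 0 when they are
not (the infinitely-confident limit of the *t* statistic); groups with
fewer than two samples are rejected outright.

Filters mirror the study design they implement:

- **Low expression.** Array mode removes genes whose mean across all
  samples falls strictly below the 20th percentile (linear-interpolation
  percentile) of all gene means; RNA-seq mode removes genes whose maximum
  count across samples is below 200. The RNA-seq variant is idempotent;
  the percentile variant is not (the percentile is recomputed on the
  surviving genes), which is why the pipeline applies it exactly once.
- **Non-neuronal genes.** With a +1 pseudocount on both linear-scale
  vectors, genes with log2((neuron+1)/(total+1)) < −log2(5) are removed.
  The pseudocount choice (also used before the log2 of counts) keeps
  zero-expression genes finite and is deliberately the simplest option.

Defaults: fc_min = 1.0 (a secondary low-cutoff configuration uses 0.58,
i.e. 1.5-fold), q_max = 0.05. The underlying vendor software of the
emulated workflow does not disclose its test, so the Welch/BH combination
is this package's own, stated choice; headline DEG counts from the
original deposited data are therefore not expected to reproduce exactly.

## Promoter motif centrality

Promoters are equal-length, strand-oriented TSS ± 1000 bp sequences (L =
2001, TSS at index (L−1)/2). PWMs are probability matrices over ACGT;
consensus-built PWMs floor each probability at the pseudocount (default
0.01) and renormalize, so a consensus base carries probability
1/(1 + 3·0.01) ≈ 0.9709. Scores are log2(p/0.25); N bases score 0 and an
all-N sequence has no site.

For each sequence the best site over all start positions and both strands
is identified (minus-strand windows are scored via the reverse-complemented
matrix). Sequences whose best score reaches the threshold — by default 60%
of the motif's maximum achievable score — contribute to the test. For each
odd window width w (defaults 11, 21, 51, 101, 201, 401, 801), the count k
of best-site centers with |offset| ≤ (w−1)/2 is compared against
Binomial(n_scored, w/S), S = L − m + 1, via the upper tail computed by
log-sum-exp over `binom.logpmf` terms — the interesting p-values (e.g.
~10⁻²²⁶ when every site is central) underflow double precision, so the
whole pipeline carries log10 p. The per-width p is Bonferroni-multiplied
by the number of widths tested and capped at 1; the best window is the
one with the smallest adjusted p (ties to the narrower window).

**Tied best sites.** Short consensus motifs are degenerate: a 5-bp CCAAT
has an expected ~3.9 exact, hence maximal-scoring, matches per 2-kb random
sequence, on one strand or the other. Any preferential tie-break (most
central, leftmost, plus-strand-first) would make the distribution of "the"
best-site center non-uniform under uniform site placement and destroy the
w/S null — preferring central ties drives the type-I rate to ~1. The test
therefore splits each sequence's unit count equally among all of its tied
best-site centers (scores within 10⁻⁹ of the maximum count as tied), which
restores E[k] = n_scored·w/S exactly under uniform placement; the
fractional k is ceiled before the binomial tail, a conservative rounding.
Measured on 1000 uniform-placement simulations the adjusted-p rejection
rate at α = 0.05 is ≈ 0.1% — conservative, as expected from the Bonferroni
step and the variance reduction of tie-averaging. The per-sequence
`best_site()` reporting function still returns a single deterministic
site (smallest |offset|, then + strand, then leftmost) for human-readable
output; only the enrichment count uses tie-splitting.

The reported "population" is 100·k_best/n_sequences, the percent of input
promoters contributing (possibly fractional) best-site mass to the best
window. Because it depends on the score threshold and the tie handling,
it is a descriptive statistic, not a calibrated estimate of the fraction
of truly bound promoters.

## Annotation populations, clustering, correlation

For a gene list of size n_list against a universe of size N, a term with K
annotated genes and k list hits has population 100·k/n_list, fold
enrichment (k/n_list)/(K/N), and a plain two-sided Fisher exact p from the
2×2 table (k, n_list−k; K−k, N−K−n_list+k). This is deliberately *not*
the jackknifed EASE variant some annotation servers use; for the list
sizes here (hundreds of genes) the difference is small, but p-values from
such servers will not match digit-for-digit.

Population matrices (terms × gene lists) are clustered with Ward linkage
on Euclidean distances between observation vectors — the squared-distance
(Ward.D2) convention, as implemented by `scipy.cluster.hierarchy.linkage
(method="ward")` — with no scaling of the population percentages. Cutting
the term dendrogram at exactly four groups yields the functional blocks;
block ids are assigned by first appearance in leaf order so they are
stable across relabelings. Correlations between population columns are
plain Pearson over shared finite rows, requiring ≥ 3 rows and non-zero
variance.

## ChIP consensus peaks and TSS targeting

Intervals are BED-convention 0-based half-open. A consensus peak exists
wherever one peak can be chosen from *every* input set such that all
pairwise gaps are ≤ max_gap (default 100 bp; overlap counts as gap 0);
the consensus interval is the union of the contributing peaks, and
overlapping candidate unions are merged. This "every pairwise gap" reading
of the max-gap rule is the strictest consistent one and is symmetric in
the input sets.

A gene is a proximal target when some peak center (midpoint of the
interval, strand ignored) lies within the closed window [TSS − 2000,
TSS + 2000]; a center at exactly TSS + 2000 is proximal. Genes whose
same-chromosome peaks all fall outside are classed distal-only; genes
with no peak on their chromosome are omitted from the calls. One TSS per
gene id is assumed — callers holding multi-TSS annotations must
pre-select a representative TSS.

## Splice-junction PSI

PSI = (n23 + n34)/(n23 + n34 + 2·n24). The doubling reflects junction
informativeness: one included transcript contributes two informative
junctions (2–3 and 3–4), one skipped transcript contributes one (2–4), so
equal isoform abundance yields equal numerator and (doubled) denominator
contributions and PSI = 0.5. A zero denominator leaves PSI undefined and
it propagates as missing, never as 0. Junction tables are matched to the
exon model by exact intron coordinates (end of the upstream exon, start of
the downstream exon, half-open); duplicate records for the same intron are
summed with a warning. Under the Poisson sampling model below the
estimator's mean recovers the true inclusion fraction to within 0.01 at
depth λ = 200 (checked at f = 0.2, 0.7, 0.9 over 500 replicates).

Per-cell long-isoform ratios L/(L+S) are Pearson-correlated with each
functional block's summed population across cells (≥ 3 shared cells
required); on the four-cell synthetic design the ER/Golgi-like blocks 1–2
correlate positively and the cell-cycle/mitochondrion-like blocks 3–4
negatively with the neuronal-style high ratios.

## Synthetic-data generators

All generators take an explicit integer seed, use `numpy.random.
default_rng` locally (no global state), and are bit-reproducible.

- **Expression** — per-gene baseline log2 intensity ~ Normal(8, 2);
  array replicates add Normal(0, noise_sd) noise (default 0.25); planted
  genes shift by ± effect_log2fc (default 2) in the knockdown group.
  RNA-seq counts are negative binomial around 2^baseline with dispersion
  0.1 (variance μ + 0.1μ²). The baseline and dispersion values are stated
  conventions, not calibrated to any particular platform.
- **Promoters** — i.i.d. background at a given GC fraction (default 0.5);
  in a planted_fraction of sequences one exact consensus copy *replaces*
  background bases (length invariant), on a fair random strand, at an
  offset drawn either Normal(0, sd_bp) rounded and clipped ("centered")
  or uniform over valid starts.
- **Annotation** — four equal term blocks; every universe gene joins every
  term independently at rate 0.05 (the map is drawn from `map_seed` so
  several cell types can share one annotation). A gene list is drawn
  without replacement with weights multiplicative in its terms' block
  boosts: ER-skew boosts blocks 1–2 (×2, ×3) and damps 3–4 (×0.5);
  cellcycle-skew mirrors this. With the default universe of 2000 genes and
  40 terms, list_size = 500 matches the scale of knockdown DEG lists
  (429–924 genes across the emulated cell types); at that size two
  same-profile lists drawn on a shared map correlate at r ≈ 0.92–0.95.
- **Peaks** — n_near peaks centered at a random gene's TSS + Normal(0,
  near_sd_bp) plus n_background centers uniform over the chromosome spans,
  all with fixed width 200 bp.
- **Junctions** — n23, n34 ~ Poisson(λf) independently and n24 ~
  Poisson(λ(1−f)). Poisson rather than multinomial sampling keeps the
  three counts independent while preserving the estimator's target; it
  slightly overstates the variance of the total depth, which the PSI
  ratio is insensitive to.

What the generators do **not** emulate: probe/fragment-level measurement
artifacts, normalization residuals, batch effects, correlated genes,
realistic genome composition (CpG islands, repeats), multi-TSS genes,
read-level errors, or overdispersed junction counts. Green tests therefore
demonstrate the correctness and calibration of the statistics under their
stated sampling assumptions — not robustness to every failure mode of real
array/sequencing data.

## Problem sizes and runtime

The test suite and the acceptance script run the study-condition
simulations at these sizes: 2000-gene matrices with 150 planted effects
over 20 seeds (null: 200 genes × 50 seeds); 500 promoters × 20 seeds for
centrality power and 200 promoters × 1000 seeds for the uniform null;
500 junction replicates per inclusion regime; 20 seeds of the four-cell
clustering design; 500-gene TSS tables with 400 near + 100 background
peaks. The full suite completes in ~3–4 minutes on one CPU, the
acceptance script in ~3 minutes, both dominated by the 1000-seed null
calibration.

## Known limitations

- The Welch/BH DEG caller is a stand-in for undisclosed vendor pipelines;
  absolute DEG counts from deposited raw data are out of reach by design.
- The centrality test assumes best-site centers are uniform under the
  null. Composition gradients across the promoter (e.g. a GC-rich core)
  violate this for GC-rich motifs — which is exactly the shared SP2-style
  signal the study treats as a composition artifact, and why motif
  conclusions rest on contrasts between gene sets rather than absolute p.
- Fisher p-values ignore inter-term dependence; no multiplicity
  correction is applied across terms (an optional BH column is the
  extent of it).
- Consensus peak construction enumerates one-peak-per-set tuples; it is
  exact but can emit wide unions when many peaks crowd within the gap
  tolerance.
- The PSI model treats junction reads as independent Poisson counts;
  mapping bias between the three junctions is not modelled.
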