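# nfykit

Analysis toolkit for NF-Y knockdown transcriptome studies.

NF-Y is a ubiquitous heterotrimeric transcription factor (subunits
NF-YA/-YB/-YC) that binds the CCAAT box in proximal promoters. Knockdown
studies across cell types show it drives *different* transcriptional
programs in neuronal cells (ER/lipid-metabolism genes) versus proliferative
cells (cell-cycle/mitochondrial genes), a difference that tracks the
splicing of NF-YA exon 3 (the long isoform NF-YA-L includes it, the short
NF-YA-S skips it) rather than differences in NF-Y's DNA binding.

`nfykit` packages the computational stages of such a study as a tested,
reusable pipeline for transcriptomics researchers who want to run the same
analyses on their own matrices, promoter sets, peak files and junction
tables — or on the bundled synthetic-data generators, which produce every
input with known ground truth so each stage's statistical behaviour can be
verified without any external downloads.

## The five stages and their statistics

1. **Differential expression** (`nfykit.expression`) — per-gene Welch
   two-sample *t* on log2 values with Benjamini–Hochberg FDR; a gene is a
   DEG when |log2FC| ≥ fc_min and q ≤ q_max (inclusive). Study-specific
   filters: genes below the 20th percentile of mean expression (arrays) or
   with max count < 200 (RNA-seq) are excluded; a fivefold
   neuron-versus-tissue depletion rule removes non-neuronal genes.
2. **Promoter motif centrality** (`nfykit.motifs`) — for each promoter
   (TSS ± 1000 bp, strand-oriented) the best PWM site over both strands is
   found; enrichment of best-site centers in a window of width *w* around
   the TSS is tested against the uniform null p₀ = w/S (S = L − m + 1 valid
   centers) with an upper binomial tail computed in log space, Bonferroni-
   adjusted over the tested widths (11 … 801 bp).
3. **Annotation populations** (`nfykit.annotation`) — per functional term,
   population = 100·k/n_list (percent of the list annotated), fold
   enrichment = (k/n_list)/(K/N), two-sided Fisher exact p. Population
   vectors across cell types are Pearson-correlated and clustered (Ward
   linkage, Euclidean distance); cutting the term dendrogram yields the
   functional blocks (CL #1–4 style).
4. **ChIP targets** (`nfykit.chip`) — consensus peaks supported by every
   ChIP experiment within a 100 bp max gap; a gene is a proximal NF-Y
   target when a peak center lies within ± 2000 bp of its TSS (closed
   interval).
5. **Exon-inclusion PSI** (`nfykit.splicing`) — from reads spanning the
   exon 2–3, 3–4 and 2–4 junctions,

   PSI = (n23 + n34) / (n23 + n34 + 2·n24),

   the skip count doubled because an included transcript yields two
   informative junctions where a skipped one yields one. Per-cell isoform
   ratios L/(L+S) are then correlated with each functional block's summed
   population.

## Worked example

```python
from nfykit import synthetic, expression, motifs, splicing

# two-group microarray-style matrix, 150 planted two-fold effects
matrix, truth = synthetic.gen_expression(
    n_genes=2000, n_per_group=4, n_down=100, n_up=50,
    effect_log2fc=2.0, noise_sd=0.25, mode="array", seed=1,
)
filtered = expression.filter_low_expression(matrix, 20)     # drop bottom 20%
degs = expression.call_degs(filtered, fc_min=1.0, q_max=0.05)
print("DEGs:", degs.counts())

# promoters with CCAAT planted near the TSS in 30% of sequences
promoters, _ = synthetic.gen_promoters(
    n=500, planted_fraction=0.3, placement="centered", sd_bp=50.0, seed=2,
)
ccaat = motifs.PWM.from_consensus("CCAAT", "CCAAT")
res = motifs.central_enrichment(promoters, ccaat)
bw = res.best_window
print(f"CCAAT best window +/-{(bw.width-1)//2} bp: k={bw.k:.1f}/{res.n_scored}, "
      f"log10 p_adj={bw.log10_p_adj:.1f}, population={res.population_pct:.1f}%")

# junction counts from a neuronal-style inclusion fraction of 0.9
counts, _ = synthetic.gen_junctions(true_fraction=0.9, depth=200.0, seed=3)
est = splicing.psi(counts)
print(f"junction counts n23={counts.n23} n34={counts.n34} n24={counts.n24} "
      f"-> PSI={est.value:.3f}")
```

prints

```
DEGs: {'down': 69, 'up': 47, 'total': 116}
CCAAT best window +/-100 bp: k=90.0/496, log10 p_adj=-6.9, population=18.0%
junction counts n23=158 n34=193 n24=13 -> PSI=0.931
```

The 20th-percentile filter leaves 116 of the 150 planted genes in the
matrix, and every one of them is called in the right direction with no
false calls. The centrality test finds the planted CCAAT concentration in
a ± 100 bp window around the TSS (adjusted p ≈ 10⁻⁷), and the PSI estimate
0.931 recovers the simulated inclusion fraction of 0.9 from 364 junction
reads.

The same stages are available from the shell:

```bash
nfykit run-all --seed 7 --outdir run/      # full synthetic pipeline
nfykit simulate --n-genes 2000 --seed 1 --out expr.tsv
nfykit deg --matrix expr.tsv --out degs.tsv
nfykit psi --junctions junc.tsv --exon-model model.tsv
```

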