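# ernakit

Enhancer RNAs (eRNAs) are non-coding transcripts produced from active
enhancers. `ernakit` identifies transcribed enhancers from strand-specific
RNA-seq, quantifies their dysregulation between two conditions (a
Huntington's-disease mouse striatum, "HD", versus wild type, "WT"), and
integrates the result with chromatin state — H3K27ac islands,
super-enhancers, RNA polymerase II (RNAPII) peaks — and transcription-factor
motif enrichment. It is aimed at epigenomics analysts who want each stage of
such an analysis as a tested, reusable Python function or shell command
rather than a chain of one-off tool invocations.

## The method

1. **Genic exclusion.** Gene spans (13 retained Ensembl biotypes) are
   extended 3 kb upstream of the TSS and 10 kb downstream of the gene end to
   absorb polymerase read-through. With first-strand library chemistry a
   read maps antisense to its source transcript, so split-mapped reads and
   reads overlapping an extended gene region on the *opposite* strand by
   ≥ 1 bp are removed; what survives is candidate eRNA signal.
2. **Detection.** Surviving reads are pooled per condition and run through a
   Poisson peak caller (tags shifted by half the cross-correlation fragment
   estimate and extended; per-position tail test against the genome-wide
   rate λ_BG at p < 10⁻⁴, duplicates kept). Per-condition candidates are
   union-merged, then gated on overlap with an H3K27ac island (SICER-style
   window/gap caller: 200 bp windows, 600 bp gaps, E-value 1000, effective
   genome fraction 0.77) in either condition. The result is the eRNA
   catalogue.
3. **Differential expression.** Reads are counted per catalogue region per
   sample, normalized with median-of-ratios size factors
   s_j = medianᵢ k_ij / (∏_v k_iv)^(1/m), and tested with a
   negative-binomial Wald test (method-of-moments dispersion shrunk 50/50
   toward an a₀/μ + a₁ trend; log-link GLM with size-factor offsets;
   Benjamini–Hochberg adjustment). eRNAs are classified down / up /
   unchanged at padj < 0.05.
4. **Integration.** Nearest-TSS gene assignment; observed-vs-expected χ²
   (1 df) enrichment of the down/up classes in super-enhancer overlap;
   RNAPII peak presence, loss and gain accounting per class; H3K27ac
   island-width profiles (Wilcoxon rank-sum between classes); GC content
   against size-matched random genomic spans.
5. **Motif enrichment.** FIMO-style PWM scanning (log-odds scores, exact
   score-to-p by dynamic programming, hits at p < 10⁻⁴ on both strands).
   The observed count x is compared with n = 100 size-matched random draws
   from the catalogue itself via **Z = (x − μ)/σ**, with upper-tail normal
   p-values BH-corrected across motifs.

A bundled generator (`ernakit.generate`) produces a fully specified
synthetic two-condition dataset — genome, genes, enhancers (typical and
broad/super), strand-specific reads with genic read-through, H3K27ac
islands, RNAPII peaks, planted fold changes and motifs — with a ground-truth
table, so the entire pipeline is testable without any downloads.

## Worked example

```python
import numpy as np
from ernakit import SimulationConfig, generate, run_memory, score_recovery, PWMotif
from ernakit.pipeline import PipelineParams

cfg = SimulationConfig(seed=17)          # 2 Mb genome, 40 genes, 60 enhancers
ds = generate(cfg)

def pwm(cons, name, p=0.85):
    m = np.full((len(cons), 4), (1 - p) / 3)
    for i, b in enumerate(cons):
        m[i, "ACGT".index(b)] = p
    return PWMotif(name, m)

res = run_memory(
    ds.genes, ds.sample_reads, ds.condition_of, ds.h3k27ac_islands,
    ds.chrom_sizes, params=PipelineParams(seed=17),
    rnapii_by_condition=ds.rnapii_peaks, super_enhancers=ds.super_enhancers,
    genome=ds.genome,
    motifs=[pwm(cfg.motif_consensus, "SRF_like"), pwm("TGACGTCA", "CREB_like")],
)
print(res.report["funnel"], res.report["status_counts"])
print(score_recovery(ds.truth, res.records))
print(res.motif_table.round(3))
```

Output (abridged):

```
funnel: {'candidates_HD': 62, 'candidates_WT': 61, 'merged_candidates': 62, 'catalogue': 60}
status_counts: {'down': 15, 'up': 8, 'unchanged': 37}
sensitivity 1.00  precision 1.00
rnapii down: {'n_with_wt_peak': 13, 'n_lost': 5, 'pct_lost': 38, ...}
            x    mu  sigma      z      p   padj  degenerate
SRF_like   16  9.65  2.157  2.943  0.002  0.003       False
CREB_like   1  2.63  2.097 -0.777  0.782  0.782       False
```

All 60 planted enhancers are recovered with no false entries; the 15
planted-down and 8 planted-up eRNAs are called correctly; 5 of the 13
down-class eRNAs with a WT RNAPII peak lose it in HD (38 %); and the motif
planted in half the down-enhancers is enriched (Z ≈ 2.9, padj ≈ 0.003) while
the decoy is not.

The same flow is available from the shell:

```sh
ernakit simulate --seed 17 -o simdir/
ernakit mask --gtf simdir/genes.gtf -o mask.bed
ernakit filter-reads --reads simdir/reads_WT_1.bed --mask mask.bed -o f.bed --report stats.json
ernakit run --config pipeline.yaml
```

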