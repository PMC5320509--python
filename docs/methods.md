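# Methods

This note records the models behind each stage, the defaults and why they
were chosen, the numerical decisions, and what the synthetic benchmark can
and cannot show. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and data model

All intervals are 0-based half-open (BED-native); GTF input (1-based,
closed) is converted on read, so every piece of interval arithmetic —
overlap, extension, merging — lives in one convention. A "gene" is its full
span (minimum start to maximum end over its feature rows); per-transcript
masking is not performed. Duplicate reads are retained throughout
(detection runs with keep-duplicates semantics); read deduplication happens
only inside the island caller, which has its own redundancy threshold.

## Genic exclusion and strand logic

Extended gene regions run from 3 kb upstream of the TSS to 10 kb downstream
of the gene end (strand-aware, clipped at contig bounds). The 10 kb
downstream extension is the defense against polymerase read-through, which
decays over kilobases past the gene end and otherwise mimics intergenic
transcription. The strand rule follows first-strand library chemistry:
sequenced reads map antisense to their source RNA, so a read overlapping an
extended gene region on the opposite strand (≥ 1 bp, full read span) is
genic signal and is removed; same-strand overlap is kept, because relative
to the gene it represents antisense transcription — candidate eRNA signal.
Only opposite-strand overlaps are removed; reads without strand are
rejected rather than guessed. Split-mapped reads (spliced alignments) are
removed unconditionally before any overlap logic.

## Poisson peak calling

Tag model: each read is reduced to its 5′ end, shifted by +s (+ strand) or
−s (− strand), and extended to a 2s tag, where s is half the lag maximizing
the +/− strand 5′-end cross-correlation over lags 0–1000 (ties to the
smallest lag; exact integer arithmetic, so ties are reproducible). If s = 0
the tag falls back to the read length, since a 0-width extension would
erase all coverage.

A position is significant when its pileup c has Poisson tail
P(X ≥ c; λ) < p (default 10⁻⁴) with λ_BG = N·2s / effective-genome-size.
Maximal significant runs separated by less than one tag width (2s) are
merged into one peak: sub-threshold dips shorter than a tag are sampling
noise of the same fragment stack, and without this merge the shoulder of a
strong peak sheds 1–2 bp satellite candidates. A consequence is that a
merged peak may contain gap positions that are not individually
significant; the summit (leftmost maximum) always is, and every significant
position lies inside some peak. In local-λ mode (used for RNAPII-style
calling, p < 10⁻⁵) a candidate is additionally required to be significant
against max(λ_BG, λ_1k, λ_5k, λ_10k) computed from tag counts in windows
centred on its summit — the classic guard against locally elevated
background. No peak-model building or iterative λ refinement is performed;
the published analyses this mirrors disabled them.

## Island calling

Reads are deduplicated to one per (position, strand), binned by midpoint
into fixed windows (200 bp), and a window is eligible when its count meets
the minimal value whose Poisson tail under the per-window rate
λ_w = N·window/(G·f) (f = 0.77 effective genome fraction) falls below 0.2 —
the candidate-window convention of window/gap island callers. Eligible
windows separated by at most `gap` (600 bp) of ineligible windows merge;
the island score is Σ −ln P(count; λ_w) over its eligible windows. The
E-value filter keeps islands whose score exceeds the threshold at which the
expected number of equal-or-better islands under a simulated Poisson null
is ≤ E (default 1000). The null is simulated (4 draws of the genome-wide
window-count process, fixed internal sub-seed, so calls are deterministic);
the exact island-probability recursion of the original algorithm is
deliberately not reimplemented — at these genome sizes the simulated
threshold is almost always 0, i.e. the window/gap geometry dominates. With
a control library, per-island chip-vs-scaled-control Poisson p-values are
BH-adjusted and islands kept at FDR 10⁻².

## Catalogue construction

Detection runs per condition on pooled replicates (one catalogue tested in
both genotypes, rather than per-sample voting). Candidate regions from all
conditions are union-merged (≥ 1 bp overlap merges to the span, provenance
recorded), and a merged candidate enters the catalogue only if it overlaps
an H3K27ac island in *either* condition — support is recorded per
condition, so a stricter both-conditions policy remains recoverable from
the records. Catalogue entries are unstranded: enhancer transcription is
frequently bidirectional and per-strand sub-quantification is out of scope.

## Counting, normalization, differential test

Counting assigns a read to the region with the larger overlap (leftmost on
ties) and refuses overlapping regions rather than double-counting.
Size factors are the median-of-ratios estimator over rows with all-positive
counts; if no such row exists the error asks for an explicit
pseudo-reference rather than silently changing estimator.

The differential test is a deliberately simple negative-binomial Wald
pipeline, calibrated by simulation rather than by replicating any
particular DE engine's shrinkage machinery:

* per-row dispersion by method of moments on normalized counts within each
  condition, pooled by degrees of freedom, floored at 10⁻⁸ (capped at 20);
* a mean–dispersion trend α(μ) = a₀/μ + a₁ fitted by least squares across
  rows, and the row estimate shrunk 50/50 toward it;
* a log-link NB GLM per row (intercept + condition, log size-factor
  offsets) fitted by Fisher scoring, vectorized across rows with the 2×2
  normal equations solved in closed form; coefficients clamped at ±30
  natural-log units so all-zero groups stay finite;
* Wald statistic log2fc/se referred to a t distribution with effective
  degrees of freedom 4×(n−2). The factor 4 is the Satterthwaite consequence
  of the 50/50 moderation: averaging the raw dispersion (residual df n−2)
  with the essentially noise-free trend quarters the estimator's variance,
  quadrupling its effective df. Null calibration simulations (see the
  acceptance suite) show the plain normal reference is anti-conservative at
  these sample sizes while this reference is near-nominal;
* Benjamini–Hochberg adjustment; classification down/up at padj < α = 0.05
  with no fold-change floor (the α is a package default; the published
  counts it emulates did not state one).

An externally produced DE table can be imported (`import_results`) to
bypass the built-in test while keeping every downstream stage.

## Integration statistics

Gene association is nearest TSS to the eRNA midpoint, any strand, ties to
the lexicographically smaller gene id. Class enrichment uses the 1-df
observed-vs-expected χ² on the (hit, non-hit) split of the class —
matching "observed vs expected" figure legends — with enrichment requiring
both p < 10⁻² and observed > expected; a full 2×2 test was considered and
rejected as answering a different question. RNAPII accounting defines
presence as ≥ 1 bp overlap with a condition's peak set; loss percentages
are over class members with a WT peak, gain percentages over the class
size, both rounded to integer percent (the granularity at which such
numbers are reported). Island-width profiles sum overlapping island widths
per eRNA per condition and compare classes with the rank-sum test.

## Motif enrichment

Scanning is log-odds against a 0-order background estimated from the
scanned sequences (pseudocount 10⁻³ of the background added to matrix
probabilities); the score-to-p map is exact dynamic programming over the
score distribution discretized to 1/1000 of the score range, hits are
positions with p < 10⁻⁴ on either strand, and windows containing N never
match. Note a width-w motif cannot produce hits when 4⁻ʷ-scale tail
probabilities cannot reach the threshold (w ≲ 7 at uniform background) —
the same property the reference scanner has.

The resampling null draws, for each target region, uniformly among unused
catalogue regions within 25 % of its size (nearest region as fallback),
without replacement, n = 100 times. A strictly deterministic nearest-size
assignment was rejected: with near-unique region sizes it redraws the
target set itself on every resample, forcing σ = 0 and making the Z
statistic undefined — the randomized-within-tolerance draw is what makes
the control a null while still matching the size distribution (and with it
the composition bias of eRNA sequence). Z = (x − μ)/σ uses the n−1
standard deviation; p is the upper normal tail (enrichment is one-sided;
depletion shows as negative Z), σ = 0 cases are flagged degenerate and
reported rather than dropped; BH correction is across motifs. GC content
is (G+C)/(A+C+G+T) per region, with group means against size-matched
random genomic spans.

## Synthetic data: what it emulates, what it does not

The generator plants, deterministically under a seed: a 2-contig 2 Mb
i.i.d. genome at GC 0.42 with enhancer spans rewritten at GC 0.55
(composition-exact, so observed GC matches to rounding); 40 stranded genes;
60 intergenic enhancers (12 broad/super with 8–15 kb H3K27ac islands, the
rest 0.5–2 kb), pairwise clear of each other and ≥ 15 kb from any gene
span, hence outside all default masks; strand-specific reads (50 bp from
200 bp fragments, 4×10⁵ per condition over 4 replicates) split ~25 %
uniform background, ~60 % genic — antisense to their gene, 15 % of them
continuing past the gene end with exponential decay (scale 2 kb) — and
enhancer transcription on both strands at 10× the background density,
scaled by planted fold changes (15 down at 0.25, 8 up at 4.0) with
negative-binomial replicate noise (dispersion 0.05); H3K27ac islands
centred on enhancers, shrunk ×0.6 in HD at down-enhancers; RNAPII peaks
present in 60 % of enhancers in WT, lost in HD at 40 % of down-enhancers
and gained at 5 % of up-enhancers; a 10 bp consensus motif embedded
centrally in half the down-enhancers; and 2 % of reads flagged
split-mapped solely to exercise the split filter. Down status is assigned
to 3/4 of the super class plus typical enhancers — SE-*enriched*, not
SE-exclusive, both because that is the biology being mirrored and because
an SE-exclusive down class makes size-matched resampling degenerate.
H3K27ac can be emitted as islands (default) or as reads, to exercise the
island caller.

What passing on this benchmark does **not** show: mappability and GC bias,
fragment-length variation, spliced non-coding transcripts, realistic gene
structure (transcripts, UTRs), chromatin input noise, or genome-scale
multiple-testing burdens — real catalogues (thousands of eRNAs over a
mammalian genome) will have lower precision than the planted benchmark and
require the documented parameters rather than anything tuned here. Problem
sizes in the test suite (400 kb unit fixtures, five 2 Mb end-to-end seeds,
20-seed power simulations, 10⁴ Z-score null draws) were chosen as the
smallest at which the quantities being checked are statistically stable.

## Known limitations

* The DE stage is a calibrated stand-in, not a reimplementation of
  empirical-Bayes shrinkage engines; use the import seam for production
  differential calls.
* The island E-value threshold is a simulation approximation; at large
  E-values it is almost always inactive.
* Nearest-TSS assignment ignores regulatory domain models and chromatin
  contacts.
* The motif scanner's background is 0-order; higher-order composition
  effects are only controlled through the catalogue-resampling null.
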