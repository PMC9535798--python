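# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open; the GTF reader/writer
converts the format's 1-based closed convention at the I/O boundary and
nowhere else. A transcript's TSS is its first transcribed base
(`interval.start` on +, `interval.end − 1` on −) and its TES the last.
Peaks are strandless; all strandedness in the classification comes from
the gene model.

## Promoter windows and binding classification

The promoter window of a TSS at t spans `upstream_bp` (default 350)
upstream to `downstream_bp` (default 100) downstream, the TSS base
counted on the downstream side, so the default window is exactly 450 bp
on either strand: `[t−350, t+100)` on + and `[t−99, t+351)` on −.
Windows are clipped at chromosome ends. A gene's promoter is the
**union** of the windows over all of its distinct transcript TSSs —
annotation is transcript-level and no single "canonical" TSS is
privileged; this is the most permissive reading and the window
parameters are configurable for stricter choices.

Classification precedence is promoter > nonpromoter_genic > unbound: a
single peak anywhere in any promoter window decides `promoter`
regardless of additional genic overlaps; otherwise any peak overlapping
the gene span (introns included — factors of this family show intronic
binding at some targets) gives `nonpromoter_genic`. One peak may
support calls for several genes. The classes always partition the
universe, and adding peaks can only promote a gene, never demote it.

Peak-to-TSS distance is 0 when a TSS lies inside the peak and the gap
between the TSS and the nearer peak boundary otherwise (half-open
arithmetic, so a TSS g bases past the end of a peak `[s, e)` is at
distance `g = t − e`). TSS-distance histogram bin edges are a required
configuration input; no default binning is asserted.

## Replicate reconciliation and the q-filter

Duplicate ChIP replicates are reconciled into **common peaks**: every
strictly overlapping rep1 × rep2 pair yields one output peak equal to
the pairwise intersection, with the smaller −log₁₀ q of the pair.
"Common, not merged": one rep1 peak overlapping two rep2 peaks yields
two common peaks, and abutting intervals do not count. Union-merged
peaks exist in the package only as the region set for the replicate
Pearson-correlation check.

The q-value filter removes peaks whose narrowPeak −log₁₀ q exceeds 100
(strict inequality; threshold configurable). The filter is directed at
hyper-significant pile-up artifacts. The opposite reading — removing
peaks with q above 10⁻¹⁰⁰, i.e. the *less* significant ones — would
discard nearly every genuine peak, so it is not the default; the
threshold and direction are deliberate, documented choices rather than
assertions about any external pipeline's intent.

## Differential expression

The test is a deliberately simple NB Wald test, not a DESeq2
re-implementation (no shrinkage, no Cook's filtering, no independent
filtering):

* **Size factors** are median-of-ratios over genes with all-positive
  counts, falling back to library-size scaling when fewer than 10 such
  genes exist.
* **Dispersion** per gene is method-of-moments within each condition,
  `α = max(α_floor, (s² − m)/m²)` with `α_floor = 1e−8`, pooled across
  conditions by a normalized-count-weighted average. All-zero genes are
  excluded from testing and reported as `unchanged` with p = q = 1.
* **Moderation.** With three replicates the raw MoM estimate collapses
  to the floor for roughly half of all genes (sample variance below the
  mean), which would make a per-gene Wald statistic grossly
  anti-conservative. `de_test` therefore uses
  `α_used = max(α_gene, median(α_gene over genes))` — the same
  information-sharing idea DESeq2/edgeR implement with empirical-Bayes
  machinery, reduced to its minimal form. Genuinely high-dispersion
  genes keep their own (larger) estimate. Null simulations at α = 0.05
  confirm the calibrated behaviour (positive rate at q < 0.01 well
  below 2 % over ten seeds) while power on four-fold effects at
  moderate counts stays above 95 %.
* **Statistic.** log₂FC = log₂((m_B + c)/(m_A + c)) with pseudocount
  c = 0.5; the delta-method variance of the log-ratio uses NB group
  variances (m + αm²)/n; p is two-sided normal; q is
  Benjamini–Hochberg (statsmodels). Classes: `up`/`down` at q < 0.01 by
  fold-change sign, no additional fold-change cutoff, everything else
  `unchanged`.

Because the test is a documented simplification, agreement with any
specific external DE tool on real data is approximate by design;
guarantees are stated (and tested) as simulation properties.

## Metaprofiles

Scale-regions matrices use 3 kb fixed flanks, a gene body rescaled to a
constant 5 kb, and 50 bp bins (60 + 100 + 60 = 220 columns). The body is
resampled by **fractional-base averaging**: bin i covers gene-local
range `[Li/100, L(i+1)/100)` and partial bases are weighted by covered
fraction via linear interpolation on the coverage cumulative sum. This
makes the mean of the body bins equal the body's per-base mean exactly
and avoids aliasing for genes shorter than one bin per base. Minus-
strand rows are orientation-flipped so column 0 is always 5′-most;
flank positions beyond chromosome ends contribute zeros. Heatmap row
order is descending row mean. bedGraph is the coverage exchange format
(dense float32 in memory); overlapping bedGraph intervals are rejected
as ill-formed.

## Co-IP candidate funnel

A protein passes when control/KD abundance ratio > 4 (strict) and
PSM > 1 (i.e. ≥ 2). KD abundance 0 with control > 0 counts as passing —
detection only in the presence of the bait is the strongest evidence —
configurable to skip-semantics. Protein-level abundances are used.
Ribosomal proteins and the bait are excluded after thresholding;
survivors are ranked by Sum Pep Score. Annotation tagging intersects
category labels with a target set; unannotated candidates are logged,
never silently dropped.

## Bookkeeping arithmetic

Class percentages are `round(100·k/n)` half-away-from-zero to one
decimal (`Decimal` quantization, not banker's rounding); this
convention reproduces every published (k, n, %) triple the package's
acceptance script recomputes. Genes absent from DE output default to
`unchanged` so the 3×3 table partitions the full universe. Enrichment
uses the upper-tail hypergeometric p (overlap or greater) with the
classification universe — not the whole annotation — as background,
and BH across tested terms.

## Synthetic studies

The generator emulates the structure of the study design it verifies:
duplicate ChIP replicates per factor, triplicate RNA-seq per condition,
and a 100-protein co-IP table. Defaults, fixed once:

* **Genome:** genes log-uniform 1–20 kb, ≥ 1 kb intergenic gaps,
  1–3 transcripts with ≤ 200 bp TSS jitter, Bernoulli(½) strands.
* **ChIP:** class mix 53.5 % promoter / 7.6 % genic / 38.9 % unbound
  (the observed genome-wide mix of this factor family); planted peaks
  150–600 bp wide with ≤ 20 bp independent replicate jitter; promoter
  peaks centred on the first transcript's TSS; genic peaks placed ≥
  350 bp inside the span so they cannot touch promoter windows; Poisson
  intergenic noise at 5 peaks/Mb per replicate, independent between
  replicates (so reconciliation removes most), 5 % of noise peaks
  hyper-significant (−log₁₀ q > 100) to exercise the q-filter.
* **Counts:** NB with α = 0.05, baselines log-normal (median ≈ 100
  counts); planted effects ±2 log₂ units at class-dependent rates
  (promoter 16 % up / 14 % down, genic 17 % up, unbound 4 % up — the
  last modelling indirect effects).
* **Proteomics:** 21 of 100 proteins pass thresholds, 4 of them
  ribosomal-or-bait, 7 of the surviving 17 chromatin-annotated.

Determinism: every generator draws from PCG64 seeded through
`numpy.random.SeedSequence((seed, stage_key, …))` with stable
CRC32-derived keys for names, so regeneration is bit-identical across
runs and platforms within a numpy major series.

What the generator does **not** emulate: read-level data (mapping
noise, duplicates, GC bias), overlapping genes, correlated binding
between factors, gene-length-dependent expression effects, and
peptide-level quantification. Passing the recovery suites therefore
demonstrates the correctness of the pipeline's logic and statistics
under the stated model, not performance on real libraries.

## Problem sizes

The verification suites run at desk scale, chosen as the smallest sizes
at which the statistical claims are meaningful: binding recovery on
2,000 genes (4 × 8 Mb chromosomes), DE calibration on 5,000 genes × 10
seeds and power on 500 planted effects, end-to-end studies of 150–2,000
genes. All complete in seconds on one CPU.

## Known limitations

* The DE test ignores between-sample technical covariates and does not
  shrink fold changes; very-low-count genes rely on a normal
  approximation that is only asymptotically valid.
* Binding classification is binary per window; no signal-strength
  weighting or input normalization is applied (peaks are consumed, not
  called).
* The hypergeometric enrichment treats terms independently (no DAG
  propagation).
* `percent_of_group` is a presentation convention; statistical
  comparisons should use the underlying counts.
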