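# Methods

## The analysis

`chipconcord` implements a ChIP-Seq occupancy-comparison analysis for the
situation where the same factor has been profiled in several related
experiments (e.g. an endogenous protein and tagged variants of it) and the
question is whether the experiments bind the same sites at comparable
strength. The analysis chain is:

1. **Read filtering.** Aligned reads are reduced to tags (chromosome, 5′
   position, strand). At most `max_per_start = 2` reads are kept per
   (chromosome, strand, start) and any start position with more than
   `censor_above = 7` reads is censored — removed entirely — as a PCR
   amplification artifact. Censoring is full removal, not trimming: a
   position so heavily duplicated is treated as unreliable evidence
   altogether. The duplicate key includes strand, since opposite-strand
   reads at one coordinate come from distinct fragments.
2. **Peak calling.** A deliberately simple stand-in caller: tag counts in
   sliding windows (300 bp, step 100 bp) are tested against a Poisson null
   whose rate is the larger of the genome-wide background and the
   depth-scaled control count in the same window; overlapping significant
   windows (p ≤ 10⁻⁵) merge into peaks. Each peak's empirical FDR is the
   swap ratio: the number of at-least-as-significant peaks found when
   treatment and control are exchanged, divided by the number found in the
   real comparison, as a step function of the peak's own p-value.
   Externally called peaks can be ingested instead; the caller exists so
   the pipeline is self-contained and its null behaviour testable.
3. **Peak selection.** Peaks with more than 100 tags (raw, post-filter
   counts) in *any* control library are excluded — the comparison is a
   strict `> 100`, so exactly 100 control tags keeps a peak. Peaks are then
   selected at FDR ≤ 0.001 (inclusive).
4. **Concordance.** Selected peak intervals from all datasets are unioned;
   book-ended and overlapping intervals merge into one region (the
   convention of per-base union connected components, as in `bedtools
   merge`). Each region gets a per-dataset tag count normalized to a
   20-million-read reference library. A fold tolerance k calls dataset d
   present in a region when `count_d ≥ max_count / k`; if all counts are
   zero the datasets that contributed peaks stand. Tallying regions by
   exact presence subset gives a Venn partition per k; because membership
   is monotone in k, the all-datasets cell can only grow as the tolerated
   fold difference grows.
5. **Summits.** Filtered tags from all datasets are pooled (reads, not
   rates — pooling precedes any normalization), elongated to 200 bp in the
   3′ direction, and piled up per base; the summit is the midpoint of the
   leftmost maximal plateau. ±150 bp windows around summits are exported as
   FASTA for motif tools.
6. **Annotation.** A peak associates with a gene when it overlaps the
   gene's TSS ± 1250 bp (the ±N window around a point p is the closed range
   [p−N, p+N]). Location categories are exclusive with priority
   TSS-proximal > intragenic > intergenic. Bound genes have ≥ 1 associated
   peak; cross-species comparisons use ± 10 kb, matching the coarser site
   lists typically available for the second species. The TSS metaprofile
   averages strand-oriented elongated-tag coverage in 25 bp bins over
   ± 2.5 kb around every TSS and scales to the 20-million-read reference.
7. **Homology.** Bound-gene sets from two species are compared through a
   strictly one-to-one ortholog map; bound genes with no one-to-one partner
   are counted as species-specific cells rather than dropped.
8. **Enrichment.** Each gene set is tested for over-representation among
   bound genes with the one-sided Fisher's exact test (upper-tail
   hypergeometric), after intersecting set members with the universe; raw
   p-values are converted to q-values with the Benjamini–Hochberg step-up
   rule. The default universe is the genes carrying at least one gene-set
   annotation.

## Coordinate conventions

All intervals are 0-based half-open. GTF input (1-based inclusive) is
converted on read. A − strand gene's TSS is `end − 1`, the last contained
base. A "± N bp" window around p is stored as `[p − N, p + N + 1)`, so a
summit window has length 2·150 + 1 = 301 away from chromosome edges.
Elongation of a − strand tag is `[five_prime − 200 + 1, five_prime + 1)`,
clipped at 0.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `max_per_start` | 2 | duplicate cap per (chrom, strand, start) |
| `censor_above` | 7 | reads above which a start position is censored |
| `extension` | 200 bp | presumed fragment length for elongation |
| `control_threshold` | 100 tags | strict exclusion bound in any control |
| `fdr` | 0.001 | inclusive peak selection cutoff |
| `tss_half_window` | 1250 bp | gene association / classification window |
| `cross_species_half_window` | 10 000 bp | bound-gene window for homology |
| `summit_half_width` | 150 bp | motif window export |
| `reference_reads` | 20 000 000 | depth-normalization reference |
| `folds` | 2, 3, 4 | Venn fold tolerances |
| caller `window`/`step`/`pvalue` | 300 / 100 / 10⁻⁵ | stand-in caller geometry |

## The synthetic-data generator

The generator (`simulate.SimulationDesign`) produces the study conditions
every stage assumes, with a ground-truth table. Defaults: one 500 kb
chromosome, 60 genes, 40 planted peaks of expected depth 100 tags per
dataset, background 0.02 tags/bp (≈ 10 000 background tags per library —
the same ~20× peak-to-background ratio as a deeply sequenced point-source
ChIP), three datasets (an "endogenous" profile and two tagged variants),
80% of peaks inside TSS ± 1250 bp, 25% of peaks discordant (8-fold
enriched in the endogenous dataset only; shared peaks differ by ≤ 1.33),
per-tag duplicate-burst probability 0.001 with burst size 12 (> 7, so
bursts are censored), three control-artifact hotspots, and a 70%
one-to-one ortholog rate for the second synthetic species.

Tag geometry: a peak's + strand tags are placed at `summit − 100 + ε` and
− strand tags at `summit + 99 + ε` with ε ~ N(0, 35 bp), so 200 bp
elongation piles both strands onto the summit. The 35 bp placement spread
matters: it is realistic fragment-position variability for ~200 bp
fragments, and it gives the pooled pileup a peaked top. With a much
smaller spread the pileup has a wide flat plateau whose maximal run is
shifted tens of bp by single background tags, and the plateau-midpoint
summit estimator loses its identifiability; with 35 bp the estimator
recovers planted summits to within ±25 bp for ≈ 99% of peaks at the
default depth.

Control hotspots are planted as *clusters*: 130–180 tags spread over
± 100 bp of a center, so that almost no single start position exceeds the
duplicate cap and the cluster survives read filtering with > 100 tags —
the form a genuine control artifact must take to be visible after
deduplication. The same loci get ordinary peak-depth enrichment in every
ChIP dataset and appear only in the mock-FLAG control, so the caller
(which tests against the IgG control) calls them and the control-exclusion
stage removes them: the full exclusion path is exercised end to end.

What the generator does *not* emulate: mappability structure, GC bias,
fragment-length variation, chromatin-state-dependent background, isoform
TSS multiplicity, and real ortholog divergence. Passing tests therefore
demonstrate the correctness of the bookkeeping, the estimators and the
decision rules under the stated stochastic model — not robustness to the
full messiness of real libraries.

## Numerical and design choices

- **Fold-tolerance rule.** "Within a k-fold difference" is operationalized
  as thresholding against the per-region maximum (`count ≥ max/k`) rather
  than all pairwise ratios: it yields a single well-defined membership set
  per region for a three-set Venn and reproduces the qualitative behaviour
  (larger tolerance → larger all-datasets cell). The rule is isolated in
  `fold_membership` so another reading is a one-function change.
- **Summit ties.** Fixed-length elongation guarantees coverage plateaus;
  the midpoint of the *leftmost* maximal plateau is used, which is
  deterministic and stable.
- **Swap FDR ties** are resolved by assigning each peak the ratio at its
  own p-value (a step function), the usual empirical-FDR convention.
- **Degenerate inputs.** Empty treatment → empty peak list with a warning;
  zero-coverage regions get a flagged summit at the region midpoint; a
  zero-count region falls back to its contributing datasets for
  membership; metaprofile windows truncated by a chromosome start
  contribute only their valid bases (per-base weights, not zero padding).
- **Merged regions** use the per-base union convention, so book-ended
  peaks merge.
- **Desk-scale sizes.** Default problem sizes (500 kb genome, 40 peaks,
  ~15–20 k tags per library, 10 seeds for replicated checks) are chosen so
  the statistical properties under test — Poisson null calibration,
  binomial fractions, recall/specificity at the fold thresholds — are
  measurable with comfortable margins while the whole suite stays fast.

## Known limitations

- The stand-in caller has no fragment-shift model, no local background
  hierarchy and no broad-peak mode; it is plumbing for end-to-end runs and
  a null-behaviour testbed, not a replacement for a production caller.
- One TSS per gene model; transcript isoforms are out of scope.
- The Benjamini–Hochberg step-up rule is not idempotent (re-adjusting
  q-values inflates them by m/j again); q-values are computed once from
  raw p-values.
- Depth normalization is linear scaling to a reference library; duplicate
  capping makes very deep discordant peaks sub-linear in true occupancy,
  which compresses extreme fold ratios (visible in the synthetic
  discordant class: a planted 8-fold difference measures ≈ 3-fold after
  filtering).
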