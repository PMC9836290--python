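# Methods

## Screen model

The screen measures, per gene, the change in relative abundance of its
insertion mutants across a lethal replication-arrest bottleneck. The
analysis assumes:

* insertion read counts per genomic coordinate are proportional to clone
  abundance within a library, up to library-wide distributional
  distortions that quantile normalization removes;
* an insertion anywhere in a gene body disrupts the gene, but only
  insertions in the 5–95% internal window are *counted*, because terminal
  insertions are sometimes tolerated even in essential genes;
* the treated pool is one division generation behind the control after a
  one-hour arrest, so the treated sample at *t* h is compared with the
  control at *t* − 1 h. Under this generation matching, growth-rate
  differences cancel and the log2 fold change (FC) estimates the
  log-ratio of survival probabilities through the bottleneck.

## Pipeline stages and conventions

All coordinates are 1-based inclusive (GFF3 convention); count maps are
sparse with absent = 0; counts are integers before normalization, reals
after (serialized with 6 significant digits).

1. **Position filter.** Positions with fewer than
   `min_reads_per_position` (default 3) reads are discarded per sample;
   the boundary count is retained.
2. **Quantile normalization** (rank means). Because the rank construction
   needs equal-length vectors, it runs over the union of positions
   retained in at least one sample, zero-filling samples that lack a
   position; each output profile keeps its own key set, so a zero-filled
   row never re-enters a sample's counts. Tied values receive the plain
   mean of the rank means their ranks span. Consequences worth knowing:
   column sums are exactly equalized; sorted vectors are identical across
   samples only in the absence of within-sample ties (tie averaging
   redistributes within a column while preserving its sum).
3. **Per-gene aggregation.** `internal_window` uses
   `win_start = start + floor(lower·L)`, `win_end = end − floor((1−upper)·L)`
   (defaults 0.05/0.95), strand-independent; a floor guard of 1e-9 absorbs
   float representation error in `fraction × L`. The window length can
   deviate from (upper−lower)·L by up to 2 bp (one truncated bp per
   margin); for tiny genes the window can be empty, in which case the gene
   contributes zero reads. A position inside two overlapping genes'
   windows counts for both. `frequency` divides the gene's window sum by
   the sample's genome-wide retained normalized total, making FCs
   depth-invariant (`use_frequency: false` compares raw normalized sums
   instead; after normalization the two differ only through the per-sample
   key sets).
4. **Pairing.** Each treated sample must have a control at
   `t − pairing_offset_h` (default 1 h) in the same replicate; an orphan
   treated sample is an error, an unpaired control is ignored. With
   replicates, per-gene FCs are averaged across replicates (mean of
   defined values) and the criterion-(ii) site count takes the
   across-replicate minimum; the single-replicate path is the plain
   scheme.
5. **Fold change.** log2 of the treated/control frequency ratio; +inf when
   only the control is zero, −inf when only the treated is zero, undefined
   (serialized `NA`) when both are. No pseudocount by default
   (`pseudocount` adds a constant to both frequencies when set); genes
   with a zero control almost always fail criterion (ii) anyway.
6. **Classification.** Thresholds are strict: length > 200 bp,
   control sites > 5 (distinct retained insertion sites, not reads, in
   the final pair's control), |FC| > 1 at `final_time_h` (default 4 h).
   The FC criterion uses |FC| because depletion and enrichment are both
   biologically meaningful and both directions occur among validated
   candidates. Criterion (iv), an "amplified" change over time, has no
   canonical formula; the default `final_max` mode requires all defined
   FCs to share the final FC's sign and the final |FC| to be the largest
   of the series within a 20% relative tolerance
   (|FC_final| ≥ 0.8·max|FC|). The tolerance acknowledges counting noise:
   at depth 5×10^5, a 10-fold-depleted ~700 bp gene retains only tens of
   treated reads, giving a per-pair FC standard error near 0.2 log2
   units, so demanding exactly monotone |FC| would reject genuine
   constant-magnitude effects most of the time. Exact `non_decreasing`
   and `strict_increase` modes are available for noise-free or
   strongly-amplifying settings. Genes failing (i) or (ii) are
   `excluded`; genes failing only (iii)/(iv) are `neutral`; otherwise the
   final FC's sign picks `depleted_hit` or `enriched_hit`.

Stage order is fixed (filter → normalize → aggregate → pair → FC →
classify), the run is deterministic given its inputs, and per-stage record
counts are reported.

## Simulator

`SimConfig` defaults are desk-scale but preserve the screen's insertion
densities — one site per 37 bp and ~19 sites per gene, which jointly
imply ~700 bp mean gene length:

| parameter | default | meaning |
|---|---|---|
| genome_length | 500 kb | single contig |
| n_genes | 200 | non-overlapping, normal lengths 700 ± 200 bp (min 120) |
| n_insertions | 13,500 | distinct sites, uniform (or TA-restricted) |
| abundance_sigma | 0.5 | log-normal initial clone abundances |
| bottleneck_cells | 10^7 | pool size at the split/arrest |
| baseline_survival | 0.1 | wild-type-like survival through the 1 h arrest |
| generations_per_hour | 1 | recovery growth rate |
| depth | 5×10^5 | reads per library (multinomial) |
| control/treated times | 1–4 h / 2–4 h | harvest schedule |

`SimConfig.full_scale()` keeps the same densities at full library size
(3.7 Mb, 4,200 genes, 10^5 sites). The baseline survival of 0.1 is of the
order measured for wild-type cells after prolonged arrest; planted
effects default to 10× above / below it, giving expected |FC| ≈ 3.3,
comfortably above the screen's threshold of 1.

The generative chain: the library is split into control and treated pools
(independent multinomial draws of `bottleneck_cells` from the clone
abundances); treated clones survive the arrest as a single binomial
thinning with per-gene probability s_g (deaths during recovery fold into
the per-gene growth multiplier g_g, default 1); both pools regrow
deterministically, `2^(g_g · generations)` with the treated pool one
generation behind; each harvested library is one multinomial draw of
`depth` reads. Sites in essential genes' internal windows are never
placed; intergenic sites take the baseline survival. An optional per-site
gamma dispersion (`read_dispersion`) roughens read sampling for
robustness tests. All randomness flows from one integer seed through
stage-local generators.

What the simulator deliberately does **not** model: PCR duplicates and
mapping noise, sequence-composition bias (TA restriction is available but
off by default, since the analysis is sequence-agnostic), SOS induction
or prophage killing, death kinetics during the arrest hour, and any
coupling between survival and regrowth. Passing recovery tests therefore
show that the pipeline correctly inverts this idealized generative
process at realistic depths and densities — not that it is robust to
alignment artifacts or batch structure in real sequencing data.

## Measured behavior at the standard conditions

With 200 genes, 10 protective (0.1× survival), 10 detrimental (10×) and
10 essential planted genes at depth 5×10^5 (the conditions
`scripts/acceptance.py` re-runs over 10 simulations), sensitivity is
typically ~0.93–0.95, specificity ≥ 0.99, and no sign errors occur.
The residual misses are genes from the short-length tail that the
screen's own criteria legitimately exclude — length ≤ 200 bp or ≤ 5
control sites — which is a property of the screen design, not of the
implementation. The rare false positive is driven by bottleneck
(binomial survival) noise in genes with few sites: that noise is shared
across all treated time points, so it passes the time-consistency
criterion, a failure mode real screens share. An all-neutral calibration
run yields zero hits in essentially all simulations.

## Degenerate inputs and tie-breaks

* Empty annotation → empty results table; header-only count tables →
  empty profiles; a gene on a contig with no counts → zeros, not an
  error.
* Undefined FCs are excluded from replicate averaging and the amplified
  check; a series whose final FC is undefined or exactly 0 cannot be a
  hit. Infinite FCs propagate (|±inf| passes the FC threshold; the gene
  still needs control sites).
* `match_samples` compares times after rounding to 1e-6 h to avoid float
  grid mismatches.
* Results tables serialize undefined values as the explicit token `NA`
  and infinities as `inf`/`-inf`; write-then-read reproduces integer
  columns exactly and reals to 6 significant digits.
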