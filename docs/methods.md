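# Methods

This note documents the models, conventions and numerical choices
behind `nucshift`, and what the synthetic-data tests do and do not
establish about real sequencing data.

## Coordinates and fragment ingest

All coordinates are 0-based half-open (BED convention); BAM positions
are converted on ingest. One fragment is emitted per sequenced
template: for BAM, from the leftmost properly paired mate and its
template length; for BEDPE, the span min(start1,start2)–max(end1,end2).
Unmapped, secondary and supplementary records are excluded before
pairing. Duplicates are fragments with identical (chrom, start, end),
strand-agnostic, collapsed to one. Mapping-quality filtering (default
≥ 20) applies only where a quality is recorded; BED input carries none.
Size selection is inclusive on both bounds — 120–200 bp for MNase
nucleosomal fragments, 0–200 bp for ChEC cleavage fragments.

## Dyad coverage and normalization

The dyad estimate of a fragment is its midpoint,
floor((start+end−1)/2): the left of the two central bases for
even-length fragments (a 0.5 bp convention the data cannot resolve).
The default center width is 3 bp — each fragment increments a 3 bp
window around its midpoint — which buffers the even-length ambiguity;
1 bp is available by flag. Tracks are 1 bp bins throughout.

CPM normalization multiplies every value by 1e6 over the number of
fragments whose centers fall on non-excluded chromosomes. The
mitochondrial chromosome is excluded from the denominator by default
(its copy number varies independently of the nuclear genome) but its
track is retained and scaled by the same factor. Raw totals equal
center_width × fragment count up to edge clipping; a cpm track with
the 3 bp convention totals 3e6. Re-normalizing an already-normalized
track is an error, not a no-op.

Replicates are combined as the unweighted mean of cpm tracks, not a
pooled recount, so each library contributes equally regardless of
depth. Difference and control-subtracted tracks keep negative values;
bedGraph export preserves sign and omits zero runs.

## Metagene matrices

Rows are extracted on [anchor − W, anchor + W] and reversed for
minus-strand genes, so +x is downstream in the transcription direction
for every row. Anchors whose window crosses a chromosome edge are
dropped (with a counted warning) rather than zero-padded — padding
would bias column means toward zero at the flanks.

**Enrichment over mean** divides each row by its mean over ±100 bp
around the dyad. The normalization window default (100 bp) matches the
plotted dyad neighborhood; rows whose window mean falls below
`min_mean` (default 1e-3 cpm) are dropped and counted, since dividing
by a near-zero mean turns empty rows into noise amplifiers. After
normalization every retained row's window mean is exactly 1 (checked
to 1e-9), and the transform is invariant to any positive scaling of
the input track — the property that makes few-percent-depth nascent
libraries comparable to steady state.

**Z-score profiles** standardize the signal-minus-input difference to
mean 0, sd 1 (population sd) over the plotted window unless a
narrower standardization window is given. A zero-variance difference
is an error. Note an intrinsic property of this readout: the argmax of
a difference of two overlapping unimodal distributions sits slightly
outside the subpopulation mode, by an amount that grows with
positional dispersion. At the dispersions simulated here this
displacement is ≤ 2–3 bp; on data with broader positioning it can be
larger, and the argmax should then be read as a bound, not an
estimate, of the modification offset.

**Single-end reanalysis** virtually extends each read to 150 bp from
its 5′ end and proceeds through the same midpoint machinery. Signal
and its input must be processed through the same path: the extension
introduces a small symmetric smear (±½·|true length − 150|), and
subtracting a paired-end-processed input from an extension-processed
signal converts that smear into a directional bias.

**Window statistics** are per-gene row means over a centered window
(20 bp at the +1 dyad for modification levels, 200 bp at the NDR
center for ChEC occupancy).

## Peak calling and shifts

Each metagene row is smoothed with a Gaussian kernel, sd 10 bp
(below the ~165 bp nucleosome repeat, above bp-level noise), truncated
at ±3 sd and renormalized where the kernel overhangs the row. The
peak is the argmax of the smoothed row within ±100 bp of the annotated
dyad; ties break toward the annotated dyad, then upstream. Quality
flags: `low_coverage` when the raw row mean is below 25% of the median
row mean (the gene's displacement would be dominated by shot noise),
`no_peak` when the smoothed search window is flat.

A shift is delta = rel_pos(condition) − rel_pos(reference), defined
only where both calls are `ok`; negative values are upstream shifts in
the transcription direction. Group summaries report the mean and a
normal-approximation 95% CI (mean ± 1.96·se). The shifted/nonshifted
maturation split applies a strict > 30 bp threshold to
rel_pos(nascent) − rel_pos(steady): only downstream-on-nascent
(right-to-left during maturation) genes are "shifted"; −40 bp is
nonshifted by construction. Target/nontarget definition clusters
difference-profile rows with k-means (Lloyd, Euclidean, 10 restarts,
seeded); the cluster with the larger mean |difference| is the target
set.

## Statistics

Plain comparisons are two-sided Mann–Whitney tests (exact enumeration
when both n ≤ 8 and tie-free, otherwise the tie-corrected normal
approximation with continuity correction). For genome-scale groups a
descriptive resampling scheme replaces the single test: 20 000
iterations, each drawing either |target| background genes (n-matched)
or 500 genes from each of two genome-wide sets (fixed-500), without
replacement — these are draws of genes, not bootstrap replicates of
residuals — and the mean of the per-iteration p-values is reported.
When the smaller group has fewer than 1500 values the plain test is
returned instead, exactly. Significance coding: ns > 0.05, then
*, **, ***, **** at ≤ 0.05, 0.01, 0.001, 0.0001. All randomness uses
counter-based Philox generators with mandatory seeds; there is no
hidden global RNG state.

The mean-p statistic is descriptive, not a combined test: it is
implemented exactly as specified and should not be interpreted as a
calibrated p-value.

Gene-set enrichment: with universe N, annotation M, cluster K and
overlap k, fold = (k/K)/(M/N) and p = P(X ≥ k) for
X ~ Hypergeometric(N, M, K). The universe is an explicit argument;
members outside it are dropped with a warning.

## Synthetic data generator

The generator emulates the data classes the pipeline consumes, not
sequence-level artifacts. Defaults (the simulated study conditions):

| parameter | default | rationale |
|---|---|---|
| genome | 2 × 200 kb, 200 genes | enough genes for group statistics at desk scale |
| −1/+1 dyad distance | 300 bp | canonical average NDR width of expressed genes |
| nucleosome repeat | 165 bp | budding-yeast spacing |
| fragment length | Normal(157, 12), truncated [100, 220] | straddles the 120–200 bp selection so the filter is exercised |
| positional jitter sd | 5 bp | tight +1 phasing of high-resolution MNase maps; also the regime in which the Z-profile argmax identifies a planted subpopulation offset to ±3 bp through both processing paths (see Z-score note above) |
| background fraction | 0.1 | non-nucleosomal digestion products |
| nascent thinning | 0.05 | purification retains a few percent of library depth |
| modified-pool offset | +15 bp | downstream acetyl-nucleosome displacement scale |
| free-MNase NDR enrichment | 3× | untethered nuclease prefers accessible promoter DNA |

Per-gene fragments are drawn uniformly over the −1, +1…+4 nucleosomes,
centers Normal(dyad + planted shift, jitter), with condition-specific
+1 shifts planted through a per-gene map. Nascent samples are
independent Bernoulli thinnings of a base condition. ChEC samples mix
planted cleavage peaks (NDR center, or flanking −1/+1 contacts) with
the same NDR-enriched background law as the free-nuclease control, so
control subtraction isolates the peaks. Everything is deterministic
given a seed.

What the generator does **not** model: sequence composition and GC
bias, mappability, MNase sequence preference, linker digestion
kinetics, replication-fork asymmetries, fuzzy multi-modal nucleosomes,
and inter-gene occupancy variation. Passing recovery tests therefore
demonstrates the correctness of the analysis chain — conventions,
orientation, normalization, peak arithmetic, statistics — under clean
positional signal at realistic depth, not robustness to every bias of
real libraries.

The gene lists used for the enrichment computation are synthetic
stand-ins generated with the set sizes of the real analysis (4701-gene
universe, 136 ribosomal-protein genes, 228-gene shifted cluster, 31
overlapping); only sizes and overlap enter the hypergeometric
computation.

## Problem sizes

Tests and the acceptance script run 200-gene genomes at 40 000–400 000
fragments per sample (≥ 30 +1 fragments per gene, the depth at which
per-group mean shifts are recoverable to ±2 bp), 1000-replicate null
calibrations, and full enumeration oracles up to N = 15. These sizes
were chosen so each end-to-end check completes in seconds while
keeping per-gene depth in the regime of a typical yeast MNase-seq
library.

## Known limitations

- Peak calls are grid-resolution (1 bp) argmaxes; no sub-bp
  interpolation, so a planted shift is recovered to ±1–2 bp, not
  exactly.
- The n-matched resampling loop calls the rank test per iteration;
  20 000 iterations on multi-thousand-gene groups take seconds, not
  milliseconds.
- `classify_maturation_shift` reproduces the thresholded-displacement
  definition of the shifted cluster; it is not a reimplementation of
  general-purpose nucleosome-map segmentation, and exact cluster
  membership from tools with unpublished settings is not reproducible
  bit-for-bit.
- bigWig output is not written; bedGraph is the canonical signal
  interchange format here.
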