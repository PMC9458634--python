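# Methods

## Model and procedure

`ramscan` segments each chromosome into regulation-associated modules (RAMs)
and module boundaries from the density of active histone-mark peaks, on the
premise that functional chromatin modules manifest as megabase-scale blocks
of dense peaks separated by peak-poor gaps. The procedure per sample:

1. **Density.** Peak midpoints are counted in a sliding window of fixed
   flank *w* on a step grid *s*: `raw_counts[i]` is the number of midpoints
   in `[i·s − w, i·s + w)`. Windows overlap whenever *w* > *s*/2, so no
   count conservation holds across bins. Counts are deliberately kept as
   counts (not per-bp densities); the midpoint rule makes each peak
   attributable to an unambiguous set of windows and keeps the brute-force
   test oracle exact.
2. **Smoothing.** The profile is smoothed by loess: at each bin, a
   polynomial (degree 1 by default) is fit by tricube-weighted least squares
   to the nearest `span·N` bins and evaluated there. No robustness
   iterations. Constant and linear profiles are reproduced exactly.
3. **Boundary calling.** Valleys (strict local minima; plateaus collapse to
   their middle bin, lower index on even ties; chromosome-end bins are never
   extrema) become boundary regions one grid bin wide,
   `[c − s/2, c + s/2)`. The complementary intervals are the RAMs, so
   boundaries and modules tile `[0, chrom_length)` exactly.
4. **Consensus.** Per-sample boundary regions are rasterized to the grid;
   a bin's occurrence is the fraction of cohort samples covering it. Bins
   with occurrence ≥ 25% (inclusive — the operational definition) are
   consensus bins; consensus regions with gaps < 250 kb merge; islands
   ≤ 250 kb between boundaries are absorbed into them, so consensus modules
   (cRAMs) always exceed 250 kb and the partition property is preserved.
   Merging is single-linkage and runs to a fixpoint, which makes the
   operation idempotent.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| step *s* | 250,000 | bp | grid resolution; the operating point where cross-sample module agreement plateaus |
| flank *w* | 500,000 | bp | window half-width of the density estimator |
| smoothing span | 3 Mb worth of bins | fraction | wide enough that loess does not track Poisson noise in the counts; narrow enough to resolve boundaries of 1.5-Mb modules. The single most influential free parameter; overridable everywhere |
| loess degree | 1 | — | a local quadratic overshoots on the shoulders of the deep valleys this method hunts for; because true valley positions repeat across samples, those side-dips replicate at identical genomic bins cohort-wide and contaminate the consensus. The local line has no such systematic lobe |
| min_prominence | 0.04 (pipeline); 0.0 (bare `find_extrema`) | relative depth | a valley must dip at least 4% below the lower of its flanking references. Smoothing wiggles dip a few percent; genuine boundaries dip tens of percent. The value errs toward sensitivity since the consensus step removes unreplicated noise |
| consensus threshold | 0.25, inclusive | fraction | cohort-occurrence cutoff for a consensus boundary bin |
| merge distance / min module | 250,000 / 250,000 | bp | consensus post-processing rules |
| contact log10 p cutoff | −10 | — | "significant contact" for degree counting; read as log base 10 (a natural-log −10 ≈ 4.5e−5 would be an implausibly weak cutoff for 10-kb data) |
| recall tolerance | one step | bp | boundary positions are only defined to grid resolution |

## Numerical choices

- **End-of-chromosome bias.** Windows truncate at chromosome ends, so raw
  counts ramp up over the first/last ~*w*/s bins. Left uncorrected, the
  loess fit at the ramp-to-plateau junction produces a small dip ~2 Mb from
  every chromosome end — in every sample, at the same bins — which the
  consensus step then promotes to false boundaries. `compute_density`
  therefore records each bin's actual window extent, and the smoother
  rescales end bins to their full-window equivalent while downweighting
  them in proportion (inverse variance for a scaled Poisson count).
  `raw_counts` itself stays uncorrected; profiles built without coverage
  information are smoothed as-is.
- **Poisson tails.** Contact significance is computed in log space via the
  stable survival-function path; where that underflows (p below ~1e−308)
  the tail is summed directly in log space, so log10 p stays finite
  arbitrarily deep into the tail. Fractional (VC-normalized) observed
  counts are ceiled: P(X ≥ o) for an integer-valued X.
- **Rank-sum test.** Exact enumeration for tie-free groups smaller than 10;
  midrank normal approximation with continuity correction otherwise.
- **Hypergeometric tail** via the log-space survival function; validated
  against exact rational-arithmetic sums for N ≤ 30.
- **Two-proportion z-test** uses the pooled variance and no continuity
  correction: intended inputs are counts in the 10³–10⁷ range. z² equals
  the uncorrected 2×2 chi-square statistic (checked algebraically in tests).
- **Degenerate inputs.** Occurrence thresholding compares with a 1e−12
  slack so exact rational fractions (e.g. 1/4) are never lost to float
  rounding. A degenerate leading eigen-spectrum (e.g. the identity matrix)
  yields an all-NA compartment track rather than an arbitrary vector.
  Ties in plateau extrema break to the lower index, deterministically.

## Synthetic cohort

The generator plants a known modular layout and emits every input the
pipeline consumes. Defaults describe the study conditions:

- three 80-Mb chromosomes; module lengths lognormal, median 3 Mb, minimum
  1.5 Mb; boundary gaps lognormal, median 750 kb, minimum 300 kb;
- 10 samples sharing 80% of boundaries; each non-shared boundary is carved
  per sample into a uniformly chosen module (≥ 1.5 Mb from other
  boundaries), so private positions are independent across samples;
- peak midpoints from a piecewise-homogeneous Poisson process: 10 peaks per
  100 kb inside modules, 1 per 100 kb inside boundaries (10:1 contrast);
  peak lengths lognormal, median 1 kb;
- 500 anchor pairs, intra-module with probability 0.95; 300 ecDNA-like
  intervals (lognormal, median 800 kb) placed inside modules with the same
  probability; 20,000 point variants with density 1.3× baseline inside
  boundaries; 10,000 contacts with flat expected counts and observed counts
  inflated 3× when an endpoint bin touches a boundary.

All draws are keyed on `(seed, stream, index)`, so each artifact is
bit-reproducible and independently re-drawable (e.g. fresh variant cohorts
for calibration loops).

**What the generator does not emulate** — read-level noise, peak-caller
artifacts, copy-number effects, centromeric deserts, chromosome-scale rate
gradients, and distance-dependent Hi-C decay. Passing recovery tests on
this data shows the pipeline is correct and well-calibrated under the
stated geometry; it does not certify performance on real ChIP-seq, where
boundary contrast and peak rates vary.

**Recovery evaluation.** Recall is the fraction of cohort-shared true
boundaries with a called consensus boundary center within one step. The
spurious fraction is measured against the ground-truth *consensus*: the
per-sample true boundary sets rasterized and thresholded at the same 25%.
The distinction matters because sample-private true boundaries occasionally
coincide in ≥ 25% of samples; by the consensus definition those are genuine
consensus boundaries, and an evaluator comparing only against shared-truth
centers would miscount their detection as an error. With the defaults,
across 30 generator seeds the pipeline recovers 94.7–100% of shared
boundaries (mean 98.6%) with 0–3.6% spurious calls (mean 0.8%) — figures
recomputed by `scripts/acceptance.py` and the test suite, not asserted.

## Design choices where the design was open

- **Midpoint vs any-overlap window assignment**: midpoint, for oracle
  unambiguity and because anchors/peaks are short relative to windows.
- **Pairs by midpoint, long intervals by full containment**: an
  enhancer–promoter anchor is essentially a point at module scale; an ecDNA
  is not, and "originates from a single module" is a containment statement.
- **Inclusive 25% threshold**: the operational definition of the consensus
  rule; with cohort sizes divisible by 4 the boundary case is common enough
  to matter.
- **Transitive merging**: chained merges are allowed (A–B and B–C closer
  than 250 kb collapse even if A–C is not), the standard single-linkage
  reading, and order-independent.
- **Cohorts are independent runs** over their own manifests; nothing is
  shared between a "normal" and a "cancer" consensus beyond code.
- **VC normalization rescale**: after dividing by the coverage product, one
  global constant restores the grand total over unmasked entries. The
  rescale does not affect p-value ranking; it keeps normalized counts on an
  interpretable scale.

## Known limitations

- Per-sample boundary regions are exactly one grid bin wide; wide boundary
  regions emerge only at the consensus stage through merging.
- The valley prominence filter is relative to the local density level; on
  profiles whose level varies by orders of magnitude within a chromosome, a
  single relative threshold may be too strict in the quietest regions.
- The Hi-C layer consumes text contact lists and small dense matrices only
  (no .hic/.cool parsing, no Knight–Ruiz/ICE balancing, no loop or TAD
  calling); TADs, LADs and compartment labels are consumed as BED/label
  inputs where needed.
- Boundary recall is center-to-center; two fragmented query regions
  flanking one reference boundary can both match it.
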