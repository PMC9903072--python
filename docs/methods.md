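# Methods

## The rIBD scan

The scan quantifies, window by window, how much more IBD sharing an admixed
breed has with one source breed than with the other. Inputs are pairwise IBD
segments (as produced by haplotype-based detectors in the Beagle family), a
sample-to-breed manifest, and chromosome lengths. Only segments pairing an
admixed sample with a source sample are informative: source–source and
admixed–admixed segments are discarded (and counted) at read time.

Each chromosome is tiled with consecutive windows of nominal size 10 kbp —
roughly the smallest span at which a single gene can still be localized. An
optional step smaller than the window size turns the tiling into a true
overlapping sliding grid; the default step equals the window size, one score
per window. Terminal windows are truncated to the chromosome length, scored
like any other window (coverage is measured relative to the actual window
length), and flagged so they can be excluded from the genome-wide summary.

**Per-unit calls.** The aggregation unit defaults to the admixed
*haplotype*, the finest unit on which IBD tracts are defined. For a unit
and a source breed, all tracts shared with *any* haplotype of any member of
that breed are merged (overlaps counted once); the unit is called IBD in a
window when the merged cover is at least `min_cov` (default 0.5) of the
window. Being IBD with a breed is thus a per-genome property — sharing with
one member suffices — rather than an average over members. Two alternative
units are provided: *individual* (called when either haplotype is called —
not when the pooled coverage of both passes, which would let two
sub-threshold haplotypes vote jointly) and *pairwise* (one call per admixed
haplotype × source haplotype pair, no cross-partner merging).

**Fractions and the score.** IBD_Sk is the fraction of admixed units called
against breed *k*; rIBD = IBD_S1 − IBD_S2 ∈ [−1, 1]. In the default
*normalized* mode the fractions are rescaled to sum to one wherever
IBD_S1 + IBD_S2 > 0, which makes the score a two-way ancestry contrast
(rIBD = 0.5 ⇔ 0.75 / 0.25) and is the scale on which the inversion
IBD_S1 = (1 + rIBD)/2 holds. Windows with no IBD evidence report 0/0/0
rather than missing values, keeping the genome-wide distribution defined
everywhere; they remain identifiable through their zero counts. *Raw* mode
(unrescaled fractions) is retained for diagnostics; monotonicity in the
evidence — adding a source-1 segment can only raise scores — holds exactly
there.

**Significance.** The pooled genome-wide scores are summarized by their mean
and sample SD (n − 1 denominator, treating the windows as a sample from the
score distribution), and windows strictly beyond mean ± k·SD are flagged
(k = 3 by default — a stringent threshold; the two-tailed normal mass beyond
3 SD is erfc(3/√2) ≈ 0.27%, conventionally quoted as 0.3%). Ties at the
cut-off are excluded as the conservative choice. One pair of cut-offs is
derived for the whole dataset; truncated and zero-evidence windows are
included by default with flags to exclude either. No multiple-testing
correction is applied beyond the k·SD rule: the procedure is an
empirical-normal outlier screen, not an FDR-controlled test. Significant
windows of one tail are merged into regions; runs separated by at most
`max_gap_windows` (default 0) non-significant windows coalesce, and each
region reports its window count, peak (most extreme), and mean score.

A worked consistency check on the cut-off arithmetic: moments printed as
mean 0.061 and SD 0.124 give 0.061 ± 3 × 0.124 = 0.433 / −0.311; thresholds
published from the unrounded moments as 0.432 / −0.310 agree to within one
unit in the third decimal, and the implementation does not force agreement
with rounding artefacts.

## Coordinate conventions

All internal intervals are 0-based half-open; conversion happens only at
I/O boundaries. Segment files are read as 1-based inclusive (the
Refined-IBD dialect). Window tables carry a mandatory header naming their
dialect (`bed0` or `one_based`) so a saved table can never be re-read under
the wrong convention, and floats are written with full `repr` precision so
write→read round-trips are lossless.

## The synthetic-data generator

The simulator emulates the post-admixture situation: each admixed haplotype
is a mosaic of source-1 and source-2 tracts. Tract boundaries form a
renewal process with exponential gaps (mean `mean_tract_bp`); each tract
draws source 1 with probability p(x), a piecewise-constant map equal to
`baseline_p` outside and `p_local` inside configured introgressed
intervals. Mosaic tracts are split at interval boundaries *before* the
source draw, so the expected normalized rIBD is exactly 2·p(x) − 1
everywhere — an analytic surface the validation tests exploit. (Assigning a
whole tract the p of its midpoint would instead blur the interval edges on
the scale of a tract length.)

Each tract is reported as an IBD segment spanning the tract with
`segments_per_tract` uniformly chosen haplotypes of its source breed.
Detector imperfection is modelled phenomenologically: true segments are
dropped independently with probability `drop_rate` (false negatives), and
spurious segments arrive as a Poisson process with `spurious_rate` expected
events per admixed haplotype per Mb, at uniform positions with
exponential lengths and a partner drawn uniformly from all source
haplotypes (false positives). LOD scores are exponential with mean
`lod_mean` and carry no information.

Defaults describe a modest desk-scale scan chosen to look like a small
livestock study: 10 + 10 source and 20 admixed individuals, one 5 Mb
chromosome (500 windows), balanced ancestry (`baseline_p` = 0.5), 500 kb
mean tracts (admixture a few generations back), 2 partners per tract, 5%
drop rate, 0.1 spurious segments/haplotype/Mb, LOD mean 10. All draws come
from a single seeded generator in a fixed documented order, so a config
reproduces its dataset byte for byte.

What the generator does **not** model: coalescent or recombination-map
realism (tract lengths are exponential and independent across haplotypes),
genotype emission, LD, phasing error, or the correlated error structure of
a real HMM-based IBD detector. Passing tests therefore demonstrate the
correctness of the windowing/scoring machinery and the recoverability of
planted signals under idealized detection — not the power of the scan on
any particular real dataset.

## Validation design

* **Per-base oracle.** On toy instances (≤ 5 samples per role, a few dozen
  windows) the pipeline must agree *exactly* with an independent brute-force
  implementation that marks covered base pairs one by one.
* **Degenerate extremes.** Pure-ancestry noise-free simulations must drive
  every window to rIBD = +1 (all source 1) or −1 (all source 2); this is
  also what `scripts/acceptance.py` recomputes.
* **Parameter recovery.** With a planted interval of p = 0.9 on a 0.5
  background (1 Mb, 50 admixed individuals, 100 kb tracts, noise-free,
  20 replicates), the mean window score must sit within 3 Monte-Carlo
  standard errors of 2p − 1 = 0.8 inside and 0 outside the interval. The
  noise-free regime is used because the closed form holds there exactly;
  drop and spurious noise attenuate scores toward 0 by design.
* **Distributional checks.** The empirical significant fraction under
  i.i.d. normal scores must approach erfc(k/√2) (cut-offs estimated from
  the same sample make this approximate; the tolerance is 3 binomial SDs at
  n = 100,000). The simulator's tract-length mean is checked with the
  censoring-aware estimator (total genome length / number of interior
  boundaries, pooled over replicates) — the naive pooled mean of observed
  pieces is length-biased because haplotypes with shorter tracts contribute
  more pieces.
* **Structural invariants.** Swapping the source labels negates every score
  exactly; scores stay in [−1, 1]; raw-mode scores are monotone in source-1
  evidence; region merging is idempotent and chunking-invariant; window
  tables round-trip losslessly in both coordinate dialects; chromosomes are
  processed independently (concatenating inputs equals concatenating
  outputs).

## Numerical and degenerate-input choices

* Coverage thresholding uses `covered ≥ min_cov × window_length` on exact
  integer covered lengths, so results carry no floating-point ambiguity.
* `min_lod` defaults to 3.0, the conventional reporting floor of
  Refined-IBD-style detectors; a minimum segment-length filter exists but is
  off by default.
* An SD of zero (all scores equal) collapses both cut-offs onto the mean;
  with strict inequalities, nothing is significant.
* Fewer than two windows after exclusions is an error rather than a
  meaningless summary.
* `merge_regions` refuses mixed positive/negative inputs and unsorted or
  duplicated windows.

## Known limitations

* Exactly two source breeds per run; comparisons among more breeds require
  one run per source pair.
* The scan consumes IBD segments; it does not infer them, and inherits any
  bias of the upstream detector (e.g. short tracts below the detector's
  resolution are invisible to both IBD_Sk fractions).
* The mean ± k·SD rule assumes approximate normality of the genome-wide
  score distribution; heavy autocorrelation (few, long tracts relative to
  genome size) or sparse data (many zero-evidence windows) distort it —
  hence the exclusion flags and the per-chromosome diagnostics left to the
  user.
* Gene-level annotation of significant regions is out of scope; the region
  lists are BED-compatible precisely so standard annotation tools can take
  over.
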