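# Methods

This note documents the models and procedures implemented in `cnvscape`,
the parameters that matter, and the design decisions taken where the
underlying workflow left choices open.

## Signal model

The observed quantity is the Log R Ratio (LRR): a log-scaled, normalised
probe intensity that is ~0 at two copies, negative under deletion and
positive under duplication.  The synthetic generator and the caller share
one shift map for the mean LRR at integer copy number:

| copy number | 0 | 1 | 2 | 3 | 4 |
|---|---|---|---|---|---|
| mean LRR | −3.0 | −0.45 | 0.0 | +0.30 | +0.58 |

These are the conventional array-LRR expectations (log2-type response with
saturation at zero copies); they are configurable through `NoiseModel`.
Marker noise is i.i.d. Gaussian per sample with default sd 0.15 — a
mid-range array value at which a one-copy event spanning ≥ 10 markers is
clearly detectable but not trivial.  An optional per-sample GC wave adds
`c_s · (gc_m − mean gc)` across markers, with `c_s ~ N(0, 0.05)` by
default: mild, realistic waviness that exercises the GC-wave QC statistic
without dominating the signal.

## Sample QC

* **DLRS** = `1.4826 · MAD(d) / √2` where `d` are successive LRR
  differences pooled within chromosomes (never across a boundary).  For
  i.i.d. Gaussian noise of sd σ the differences have sd σ√2 and
  1.4826·MAD is the consistent Gaussian scale estimate, so DLRS → σ.  The
  MAD form is used rather than a plain SD because the statistic is a QC
  screen and must not itself be dragged by the CNVs it is screening
  around; a plain-SD variant is available via `robust=False`.
* **GCWF** is the OLS slope of per-window median LRR on centred per-window
  mean GC, non-overlapping 1 Mb windows, ≥ 3 usable windows required.  The
  construction follows the wave-correction literature: the slope has the
  sign and magnitude of the GC-driven baseline fluctuation and is 0 for a
  wave-free file.
* **Exclusion**: call rate < 0.97 or Dish QC < 0.82 (array metadata
  thresholds), or DLRS (|GCWF|) above the cohort median + 3·IQR.  The
  robust fence is a reproducible reading of "high DLRS/GCWF"; the
  multiplier is configurable.

## Segmentation and CNV calling

Each (sample, chromosome) LRR series is segmented independently —
univariate segmentation with: minimum 3 markers per segment, at most 100
segments per 10,000-marker window, 2000 permutations per candidate, and
acceptance at p < 0.005.

The search is recursive binary splitting in the *circular* form used by
CBS-family callers.  Within a candidate segment of n markers the statistic
is the maximum over contiguous runs [i, j) (length L ≥ 3, every resulting
piece ≥ 3 markers) of

    T = |mean(run) − mean(rest)| / (σ̂ · √(1/L + 1/(n−L))),

with σ̂ the segment's overall sd.  A run-vs-rest contrast is essential for
power: a 10-marker event inside a 200-marker chromosome barely moves
either side mean of any single split point, so a plain split statistic
cannot see it, while the run contrast gives it T ≈ 6–10 against a noise
ceiling of ≈ 4.

Significance is a permutation test that shuffles the segment's values and
**re-maximises T over all runs** for every shuffle; the empirical p-value
uses the add-one estimator `(1 + #{T_perm ≥ T_obs}) / (B + 1)`.
Re-maximising makes the reference distribution account for best-run
selection; testing the chosen run as if it were fixed is anti-conservative
on pure noise and produces spurious short segments with extreme means.
Two exact shortcuts keep the test fast: for each run length the largest
deviation achievable by *any* rearrangement comes from the L most extreme
values, so provably unreachable lengths are skipped; and evaluation stops
early once the exceedance count already guarantees p ≥ cutoff (the
decision is identical to the full run).  A separate fixed-pair test
(`permutation_pvalue`) is exposed for comparing two given marker runs.

Accepted runs contribute their breakpoints (two for an interior run, one
for an edge run) and the pieces are re-examined, strongest candidate
first, until nothing passes or the breakpoint budget is exhausted.  The
segment-density cap is interpreted per 10,000-marker *window*: a series of
up to 10,000 markers may receive up to 100 segments.  Prorating the cap
down on short chromosomes (e.g. 2 breakpoints for a 200-marker chromosome)
would make a single interior CNV structurally unrecoverable, which is why
the window reading is used.

Segments become CNV calls at mean LRR ≤ −0.20 (loss) or ≥ +0.20 (gain) —
midpoints between the diploid baseline and the one-copy shifts; adjacent
same-state segments merge into one call.  Call coordinates are the
base-pair positions of the outermost markers of the called run.

**Permutation resolution floor.**  With B = 2000 and cutoff 0.005, a split
can only be accepted if fewer than ~10 of 2000 shuffles tie or beat the
observed statistic.  For a noise-free block of k markers among n, the
tying arrangements are those that keep the block's values contiguous, so
acceptance requires roughly `#contiguous placements / C(n, k) ≲ 0.005`.
In a 30-marker series this means blocks of ≥ ~8 markers; shorter clean
blocks are undetectable *by the stated test itself*, regardless of the
search.  The oracle-equivalence suite therefore enumerates noise-free
series with blocks ≥ 8 markers.

## CNVR consolidation and sharing

Within a population, calls merge by ≥ 1 bp overlap under transitive
closure (the `bedtools merge` semantics; bookended intervals do not
merge).  Region state is gain/loss when constituents agree and complex
otherwise; a region carried by exactly one individual is a singleton.
The carrier minimum is `max(2, round-half-up(0.05 · n_samples))` — the
only rounding rule that reproduces carrier minimums of 12, 5 **and** 2
for cohorts of 242, 100 and 19, including the sub-1 small-cohort case.

Across populations, regions are linked when their overlap is at least
half the *shorter* region (the denominator is a design decision; the rule
is configurable), components touching ≥ 2 populations are common_CNVRs,
and the non-redundant set counts each component once with span equal to
the union of member spans.  Both layers are verified against per-base
brute-force oracles on random toy instances.

Coordinates are 1-based inclusive in memory; all emitted interval files
use the BED dialect (0-based, half-open).

## Annotation

Gene assignment is interval intersection with ≥ 1 bp overlap (the
`bedtools intersect` default), reporting overlap extent so stricter
filters remain possible downstream.  QTL traits come from a user-supplied
TSV snapshot keyed by gene symbol, matched case-insensitively; a local
snapshot replaces live database queries for reproducibility.  Genes
missing from the table get empty annotations, never errors.

## Population structure

CNV states per sample and region are coded −1/0/+1 (deletion / normal /
duplication); when a sample has both loss and gain calls overlapping one
region, the state with the larger total overlap wins and an exact tie
falls back to 0 with a warning (the collision case has no canonical
answer; this rule is explicit and conservative).  The PCA centres columns
without scaling — the entries already share one scale — and decomposes by
SVD; a constant matrix is flagged rather than decomposed.

F_ST is the Weir–Cockerham (1984) estimator: per-locus variance
components a, b, c combined across loci as Σa / Σ(a+b+c).  It handles the
unequal sample sizes typical of livestock cohorts and is the standard
choice of the commercial pipelines this workflow mirrors.  Monomorphic
loci are skipped; the estimate is invariant to allele relabelling and can
be slightly negative under no differentiation.

## Synthetic data: what it does and does not emulate

The generator emulates: a 24-autosome genome of 2,478.74 Mb with marker
counts proportional to chromosome length; CNVRs with per-population
carrier frequencies (default 0.05–0.30, the range relevant to a
5%-of-cohort filter) and loss/gain/complex states with occasional
two-copy events; Gaussian marker noise; GC-linked baseline waves; QC
metadata with a small failure fraction; and SNP genotypes under the
Balding–Nichols divergence model with Uniform(0.05, 0.95) ancestral
frequencies.

It does **not** emulate: B-allele frequencies, raw intensities, linkage
disequilibrium between markers, correlated carrier status across regions,
batch effects, or mosaic (non-integer) copy numbers.  Passing tests
therefore demonstrate correctness of the statistics and interval algebra
and the detectability of idealised events at stated noise levels — not
calling performance on real arrays, where waves, LD and genotyping
artefacts matter.

## Reference benchmark sizes

The standard recovery benchmark uses three populations of 60/40/20
samples, 5,000 markers, 30 truth regions of 5–25 markers, noise sd 0.15
and default shifts; it completes in a few minutes on one core and
measures recall on events spanning ≥ 10 markers plus the median boundary
error in marker units.  F_ST recovery uses 5,000 loci and 100+100 samples
at F ∈ {0, 0.02, 0.05, 0.10}.  The CNVR oracle suite uses 200 random toy
instances with positions ≤ 10,000 bp.  These sizes are the package's
reference conditions; all are parameters of the corresponding
`cnvscape.benchmark` functions.

## Known limitations

* The segmentation is a reimplementation of the *stated parameter
  semantics* of the proprietary univariate CNAM workflow, not a clone;
  exact equivalence with that tool's output cannot be asserted.
* Very short events (< ~8 markers in short series) are below the
  permutation test's resolution floor at the default 2000 permutations.
* Single-copy gains (+0.30 at sd 0.15) sit 2σ from baseline: a small
  fraction of 10-marker gain segments fall below the +0.20 calling
  threshold by sampling noise.
* The GCWF window regression assumes GC varies smoothly at the megabase
  scale; for spatially unstructured GC the window median/mean distinction
  biases the slope.
* `detect_cnvs` processes samples independently on one core; no
  multi-sample joint segmentation is attempted.
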