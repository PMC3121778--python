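# Methods

This note records the models, conventions and numerical choices behind
each stage, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one defensible option
existed.

## Coordinates, tags and deduplication

All coordinates are 0-based half-open (BED-native) everywhere inside the
package; 1-based inputs must be converted at the boundary. A sequencing
tag is its 5′-most aligned coordinate plus strand — for a `-` strand BED
record the 5′ coordinate is `end − 1`. Tags are counted as points; the
nominal tag length (default 38 bp) is metadata used only as the gap
threshold when merging significant windows into peaks. Duplicate removal
collapses identical (chromosome, 5′ coordinate, strand) triples — the
standard single-end definition — and is idempotent. Whether `-` strand
coordinates should be shifted toward fragment centres before binning is
an open modelling question for enrichment data generally; this package
records unshifted 5′ ends, because any shift silently changes every
downstream number and the point-count convention keeps expectations
analytic.

## Binning, RPM and input subtraction

A tag at position p lands in bin ⌊p/B⌋; the last bin of a chromosome may
be short. RPM divides each bin by (library size / 10⁶), where library
size is the total non-duplicate read count, so the genome-wide RPM sum
equals 10⁶ times the in-bounds fraction. Input subtraction is elementwise
on identically binned, identically normalised tracks; negative values are
preserved (no clipping rule is applied — clipping would destroy the
invertibility of the subtraction and bias averages of profile matrices).
The reporting default is 10 kb bins; 1 kb and 5 kb are computed alongside
since bin size mostly rescales rather than reshapes genome-scale patterns.

Expected-by-chance chromosome densities are 10⁶·L_c/L_G reads per
million. The haploid-sex-chromosome halving (a male diploid sample
carries one X and one Y against two of each autosome) is a caller-supplied
set rather than a hard-coded {X, Y}: conventions differ on whether Y (or
neither) is halved, so both behaviours are reachable.

## Cross-mark correlation

The association between two marks is the square of the Pearson
correlation of their per-bin values (the r² of the genome-wide scatter),
not a rank statistic, because the quantity of interest is shared linear
signal in binned space. Bins missing in either track are dropped; by
default zero bins are retained, with a `both_nonzero` policy exposed for
sparse tracks where empty bins would dominate. Correlation is undefined
(raised as an error) below 3 shared bins or at zero variance.

Percent methylation per bin is coverage-weighted:
100·Σmethylated/Σtotal over the cytosine positions in the bin. This is
the only weighting per-position count data support — an unweighted mean
of per-site percentages would let a 1-read site count as much as a
30-read site. Bins with no covered cytosine are missing (NaN), never 0:
absence of data is not absence of methylation.

## Peak calling

The caller is a deliberately simple sliding-window scan in the
local-lambda Poisson family, not a reimplementation of any specific
tool's internals. Windows of width `bandwidth` (default 200 bp) slide at
`window_step` (default 10 bp, small relative to the bandwidth so peak
boundaries are not quantised coarsely). For each window the expected
count λ_local is the maximum of:

* a genome-wide background rate N·bandwidth/G, with G the smaller of the
  effective genome size (default 2.7 Gb, the mappable fraction of a
  human-scale genome) and the assembly length — so toy assemblies get a
  correct background while the conventional default is honoured at real
  scale; and
* local rates over each range in `lambda_ranges` (default 200 and
  1000 bp) centred on the window, estimated from the input library scaled
  to IP depth and window width.

Taking the maximum makes the test conservative against local background
structure (copy number, accessibility). Significance is the exact Poisson
upper tail P(X ≥ k; λ_local) via the regularised incomplete gamma
function; the default cutoff is p ≤ 10⁻⁸. Significant windows merge when
their gap is smaller than the tag length; a merged region reports its
smallest window p-value and the centre of its highest-count window as the
summit. Without an input library the local rates come from the IP library
itself, and ranges no wider than the bandwidth are excluded — otherwise
each window would serve as its own background (λ = k) and nothing could
ever be significant. There is no fragment-shift model, no dynamic
background switching, and no FDR layer (the raw p cutoff is the
contract); these are deliberate scope limits, not oversights.

## Feature association and overlaps

Overlap is ≥ 1 bp on half-open intervals (abutting intervals do not
overlap). A peak may count toward several annotation categories, which
are not mutually exclusive. The observed fraction of peaks hitting an
annotation is compared with the fraction expected by chance — the
annotation's union base coverage divided by genome length, i.e. the hit
probability of a random point — and reported as fold over expected. The
null is exact for point-like queries and slightly anti-conservative for
wide peaks (a wide interval hits a feature more often than a point); the
calibration tests therefore use point peaks, and the fold should be read
as enrichment relative to random placement of peak anchors. Overlap
queries run on sorted merged-union arrays with binary search; a quadratic
all-pairs oracle in the test suite guards the implementation.

Printed overlap percentages use half-up rounding (so 12.5% → 13%), with
the decimal count caller-chosen, matching how such percentages are
conventionally typeset.

## Sequence composition

Dinucleotide O/E follows the classical CpG-island convention: pooled over
the whole region set, O/E(XY) = (observed XY / W) / (freq(X)·freq(Y)),
with overlapping 2-mers (W = Σ(len−1)) and pooled mononucleotide
frequencies. Pooling (rather than averaging per-region ratios) is what
makes the statistic describe the set as one sequence population.
Ambiguous bases are excluded from both numerator and denominator counts.
Counting is single-given-strand by default, with a both-strands mode that
adds each region's reverse complement. GC content is (G+C)/(A+C+G+T) per
interval; intervals that are entirely ambiguous are reported missing.
Random-region nulls sample chromosomes proportional to length and
resample lengths from the query set by default — a length-matched null
avoids confounding composition with length — with a fixed-length mode
available.

## Positional profiles

All profile matrices share one set of conventions: counts per positional
bin by 5′ coordinate, normalised to reads per million of the library,
input (processed identically) subtracted when present, rows of `-` strand
features reversed exactly once at construction so column 0 is always the
most upstream bin, and out-of-chromosome bins missing (NaN) rather than
zero. The TES of a `-` strand gene is its interval start. Genes whose
windows overlap neighbours are not excluded (no such filter is part of
the contract; exclusion can be composed by the caller). Expression
strata are quartiles of a stable descending-RPKM sort with floor splits
at n/4, n/2, 3n/4 — ties keep input order, and the bottom stratum absorbs
the remainder.

Three layouts: anchored (±flank in fixed bins around the TSS or TES;
±5 kb/100 bp for heatmap-style matrices and ±2.5 kb/10 bp for stratum
curves are the same code path with different parameters); three-segment
(4-kb core in 100-bp bins centred on a feature midpoint, plus 4-kb flanks
— 120 columns); and scaled (site plus one-site-length flanking windows,
each in 40 proportional portions, column = ⌊portions·offset/length⌋, so
sites of different lengths align). The 40-portions-per-segment reading
(120 columns total) was chosen over 40-total; both are reachable through
the `portions` parameter. The flank length of the scaled layout equals
the site length so the three segments are visually comparable.

The bimodality classifier used in validation calls a profile row bimodal
when the mean over the central 5 columns is below half the mean over the
columns at ± the flanking-peak offset. It is a deliberately crude
detector of the TSS-depleted, flank-peaked architecture; its job is to
test whether planted promoter classes are recoverable from the matrices,
not to be a production classifier.

## Synthetic data: what it emulates, and what it does not

The generator plants, on a small multi-chromosome genome (default
2 × 5 Mb): non-overlapping 20-kb genes with lognormal RPKM (log-mean 1.0,
log-sd 1.5 — a heavy-tailed expression distribution spanning several
orders of magnitude, as RNA-seq RPKMs do); promoter classes P1
(bimodal: fold-6 intensity peaks at ±750 bp of the TSS with a fold-0.2
central depletion) and P2 (unimodal: fold-4 peak over ±500 bp) assigned
with probabilities 0.4/0.4/0.2; 100 fold-8 enhancers of 1 kb; gene-body
folds by expression stratum with intermediate strata above the top
stratum (3.5/3.0 vs 2.0, bottom 1.5), reproducing the non-monotone
expression relationship the profile machinery must resolve; CpG-island-
like 1-kb regions at half the promoters, built by suppressing CG
dinucleotides in the background sequence (retention 0.25, mimicking
vertebrate CpG depletion) while islands keep i.i.d. GC-rich (0.60)
sequence, so island CG O/E exceeds background by construction; and
methylation calls at CG positions (Poisson 20× coverage, binomial calls)
at 75% baseline and 15% inside islands.

Input libraries are uniform; IP libraries are drawn by inverse-CDF
sampling from the per-base product of all planted folds. Sampling is
position-level thinning of a piecewise-constant intensity, not read-level
resampling of real data — the point is that every downstream estimator
has a closed-form target (e.g. the measured enhancer fold converges to
f/(1+(f−1)q) for coverage fraction q, within 10% of f for small q).
Library sizes are exact (conditionally multinomial), so duplicate
positions can arise and deduplication is exercised realistically.

Not emulated: read sequences or qualities, mappability structure, GC
amplification bias, fragment-length distributions, copy-number
variation, biological replicate variance. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
sampling model, not robustness to the artefacts of real libraries.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 20 random
1000-interval instances for oracle agreement; 10⁴ replicates of 20
uniformly placed point peaks for fold calibration (mean fold 1 ± 0.05);
20 homogeneous-Poisson 1-Mb genomes (2 × 10⁶ windows total) for
false-positive calibration, where the 10⁻⁸ cutoff admits ~0.02 expected
significant windows so any called peak fails; fold recovery on a 10-Mb
genome with 50 enhancers (coverage fraction 0.005, keeping the
finite-coverage bias of the fold estimator under 4%) at 10⁵ tags,
averaged over 3 library draws; recall on 40 fold-20 1-kb blocks at ~725
expected tags per block; and promoter-class recovery on a 2-Mb, 40-gene,
2 × 10⁵-tag study. These sizes make every check analytic or tightly
concentrated while the full run stays around half a minute.

## Known limitations

* The peak caller's merge rule (gap < tag length) and step size are
  simple documented knobs, not optimised boundary estimators; peak edges
  are accurate to about one window step.
* The fold-over-expected statistic compares peak anchors to random
  points; for very wide peaks relative to feature spacing it overstates
  enrichment slightly (see above).
* Percent-methylation bins mix populations wherever a bin straddles a
  methylation-domain boundary; recovery of a planted island percentage
  requires bins contained in the island.
* `r²` is linear association in binned space; non-linear or
  scale-dependent coupling between marks will register weakly.
* The pipeline consumes aligned tags; alignment, base calling and
  library preparation are upstream of its contract, as are FDR control
  and peak-count reproduction at real-data scale.
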