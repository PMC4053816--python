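# Methods

This note records the models, conventions, and parameter choices behind
`biasassay`, including the decisions made where more than one reasonable
convention exists, and what the synthetic-data validation does and does
not demonstrate.

## Inclusion mask and coordinates

Every statistic is computed over an *inclusion mask*: the bases of the
contigs selected by a policy (all contigs, or a named subset such as
"chromosomal contigs only"), minus every ambiguous base.  Ambiguity means
any character outside A/C/G/T after upper-casing; soft-masking
(lower-case) is deliberately ignored because it encodes repeat
annotation, not sequence uncertainty.  Excluding by-policy contigs rather
than dropping them keeps alignments against them parseable.

Coordinates are 0-based half-open everywhere inside the package.  SAM's
1-based positions are converted at the I/O boundary (pysam does this);
BED files are read and written natively in the internal convention.

Published genome-size figures for finished references sometimes differ
slightly from "length minus ambiguous bases", implying an additional
exclusion convention that is not documented; we do not attempt to guess
it, and extent comparisons should be read with that caveat.

## Relative coverage

Coverage of a reference base is the number of read bases aligned to it
under CIGAR `M`/`=`/`X`; `D`/`N`/`I`/`S`/`H`/`P` contribute nothing.
Unmapped, secondary, supplementary, and duplicate-flagged records are
excluded; MAPQ-0 records are **kept**, because aligners that place
multi-mapping reads at a random best location must still contribute them
to coverage — dropping them would fabricate undercoverage at repeats.

Relative coverage is coverage divided by the mean over included bases,
so it averages to exactly 1 (a conservation property the tests assert to
1e-9).  The undercoverage threshold `t = 0` counts exact zeros; positive
thresholds count `r ≤ t`.  Because tail fractions depend on depth,
cross-data-set undercoverage comparisons must first downsample to a
common mean depth (see Mixing below).

The Poisson significance helper answers "could this tail be sampling
noise?": at mean depth μ, a base observed at `t·μ` when its true relative
coverage is 1 lies `(μ − t·μ)/√μ = (1−t)·√μ` standard deviations below
expectation under a Poisson depth model.  The printed arithmetic in the
source literature for this quantity is garbled (a linear ratio shown
equal to a z-score), but the √μ denominator reproduces every published
sigma value, so that is what we implement.

## Motifs

A motif is `(W, C, predicate, threshold)`: a W-base window hits when its
centered C-base core satisfies the predicate and the whole window is
unmasked.  Conventions chosen here:

* **Extent is the full window, not the core.**  The whole W-base region
  is what the motif names; published extent percentages for GC-rich
  genomes are only reachable with full-window extents.
* **Integer-count thresholds.**  A core passes `GC ≥ t%` iff
  `#G+#C ≥ ceil(t·C/100)` and `GC ≤ t%` iff `#G+#C ≤ floor(t·C/100)`,
  avoiding float comparisons at exact thresholds (75% of 100 bases is
  exactly 75).
* **(AT) repeats accept both phases.**  The core must alternate A/T with
  period 2, starting with either base; any other character disqualifies.
* **G|C homopolymer fraction** requires `#G ≥ ceil(t·C/100)` *or*
  `#C ≥ ceil(t·C/100)` in the core.
* Overlapping hit windows are merged into maximal intervals; extents
  count each included base once.

Bad promoters are an interval input (a BED), not a scanned motif.

The scanner is validated against a brute-force oracle (every window
start tested independently, no merging shortcuts) on random 5 kb
sequences spanning AT-extreme, GC-extreme, and balanced compositions,
with exact agreement required.

## GC windows and curves

GC-bias curves use 100-base sliding windows with step 1; windows that
cross a contig end or touch any masked base are dropped whole rather than
partially computed.  A window's relative coverage is the mean of its 100
per-base values — this composes exactly with the per-base statistic, so
an unbiased data set gives a flat curve at 1.  Bins are integer GC
percentages; a bin is reportable only when the genome holds at least
1,000 windows of that GC% (default `min_windows`), suppressing unstable
extremes.

## Error counting

Per reference base we count:

* **mismatch** — an aligned read base differing from the reference base.
  A read N over an unambiguous reference base counts as a mismatch (it is
  a non-matching call).
* **deletion** — one count per record whose `D` operator skips the base.
* **insertion** — an insertion of length L is charged, all L of it, to
  the reference base immediately after the inserted sequence.  At record
  edges, where no aligned base follows, it is charged to the nearest
  preceding aligned base; a record with no aligned bases at all has
  nowhere to charge and is ignored.  This keeps counts conserved.

Error rates are numerator counts over mapped (M/=/X) bases in the same
region — the coverage track accumulated in the same pass is the
denominator.  Records without a stored SEQ cannot be compared and are
skipped with a logged count.

Context profiles assign each base (a) the GC% of the 100-base window
centered on it — bases without a full unmasked centered window stay
unbinned, and GC bins obey the same ≥1,000-window reportability rule as
the curves — or (b) the length of its containing homopolymer run, capped
at 15 by default so sparse long-run bins aggregate ("15 and longer"); the
cap is configurable.  Length-1 runs are kept as runs so the binning
covers every included base.  Whether published GC-binned error plots
assigned errors per overlapping window or per centered base is not
documented; the centered-base convention used here counts every error
exactly once.

## Promoters

Each TSS gets `ratio = mean coverage of the surrounding 200 bases /
mean coverage of the surrounding 3,000 bases`.  Windows are TSS-centered
and strand-agnostic (no strand-aware offset is documented for the
published list); they clip at contig ends and average over included
bases only.  Genes with several TSS entries keep the lowest-ratio entry;
undefined ratios (zero far-window coverage) are dropped before ranking;
ties break lexicographically by gene name so selection is a total order.
The n lowest genes (n = 1,000 for a human-scale run) are emitted as
200-base TSS-centered intervals.

## Mixing and downsampling

Downsampling keeps or drops whole fragments: the decision is a
deterministic hash of (seed, QNAME), so mates are never split, the same
seed reproduces the byte-identical subset, and streams can be filtered
without buffering.  Whether published downsampling was read- or
fragment-level is not stated; fragment-level is chosen because mate
coverage is correlated.  Technology mixtures operate on coverage tracks
(post-alignment), added base-wise, with each pure component separately
downsampled to the mixture's total depth for a fair undercoverage
comparison.  Subsample-stability reps use derived seeds `seed + r`.

## Discovery pipeline

Starting from maximal runs of included bases with `r ≤ 0.1`, the
pipeline removes, in order: reference bases under `D` operators of
sample-assembly contig alignments (assembly gaps); bases inside any
100-base sliding window of contig-aligned sequence with **more than 5**
alignment errors (mismatches + deleted bases + inserted bases, attributed
as above) — the boundary is strict, 5 errors do not exclude; bases well
covered (`r ≥ 0.5`) in any diverse-population track while undercovered
(`r < 0.1`) in every sample track; and bases in the union of generalized
motifs and bad promoters.  Windows slide on reference coordinates of the
aligned spans (contig-side coordinates would be an alternative; the
reference side is what the exclusion applies to).  The filters are set
subtractions, so the surviving interval set is order-independent; only
per-base provenance labels depend on order (first category wins:
assembly gap, high-error window, diverse consistency, motif).  Survivors
are re-merged and annotated with GC fraction and homopolymer N50; the
report totals include the interval N50.  N50 is the length-weighted
median: the smallest L such that elements of length ≥ L cover at least
half the total bases.

Contig splitting for assembly alignment cuts contigs longer than 100 kb
into `ceil(L/100 kb)` near-equal pieces, which keeps every piece within
[50 kb, 100 kb].

## The simulator

`simdata` emulates the bias phenomenology the assays measure:

* the reference is a concatenation of tracts with chosen GC targets
  (per-base Bernoulli draws; realized GC concentrates within ~2
  percentage points for tracts ≥ 10 kb), plus optional spliced-in
  sequences (homopolymer tracts, AT repeats) and planted per-interval
  sampling-weight multipliers (bias loci, promoter dips);
* fragment starts are sampled with probability proportional to a
  tabulated weight per GC% of the 100-base window centered on the start
  (matching the assay's window convention); paired mode places two reads
  at the fragment ends with proper flags;
* errors are injected per aligned base from per-position probabilities
  (base rate × GC-context multiplier × homopolymer-context multiplier),
  with at most one event per read base.  Insertions are never placed at
  record edges and deletions never lead a record, so the emitted CIGARs
  exercise only interior attribution; the errbias edge rules are covered
  by hand-built records in the tests.  Consequently the realized
  genome-wide insertion rate is `rate × (read_length − 2)/read_length`,
  which the recovery tests account for.

Records are emitted as coordinate-sorted SAM at their **true** positions
— no aligner runs — so error counting can be checked for exact,
per-position equality with the event log, and coverage statistics are
isolated from aligner behavior.  This is also the simulator's main
limitation: passing tests demonstrate correctness of the measurement
conventions, not robustness to aligner artifacts (clipped or unmapped
reads over hard contexts, mismapping in repeats), base-quality effects,
PCR duplicates, or platform-specific error spectra, all of which real
data contain.  An optional FASTQ export exists for end-to-end runs
through a real aligner.

Everything is deterministic given the config seed (two independent
generator streams, one for the reference and one for the reads).

## Validation problem sizes

The standard validation scenarios, chosen to make the injected effects
statistically unambiguous while keeping the suite quick:

* biased scenario — 1 Mb across five tracts (30/45/55/65/75% GC), depth
  50, read length 100, 2-fold sampling depletion at GC ≥ 60, mismatch
  4e-3, deletion 2e-4 (×10 in runs ≥ 8), insertion 1e-4, with 300
  planted 12-base homopolymers so long-run bins have a usable
  denominator;
* null scenarios — the same 1 Mb shape unbiased and error-free, plus
  500 kb at depth 10 where the Poisson lower tail at `r ≤ 0.25` has
  non-trivial mass (tail comparisons use interior bases, since coverage
  ramps over the first/last read length, and inflate the binomial SE by
  √(read length) for the within-read correlation of neighboring bases);
* discovery scenario — 150 kb alternating 20 kb neutral / 6 kb GC-rich
  (85%) tracts, depth 30, ten planted 400-base bias loci (weight 0.004):
  five inside rich tracts where the generalized GC ≥ 70 motif explains
  them, five in neutral context that the pipeline must report;
* promoter scenario — 270 kb at depth 30 with twenty 200-base dips
  (weight 0.08) that the bad-promoter ranking must place above twenty
  control sites.

`scripts/acceptance.py` re-runs all of these from scratch under a
command-line seed and reports the recovered quantities as JSON.

## Known limitations

* Extent comparisons against published tables inherit the full-window
  convention and the undocumented genome-size exclusion noted above.
* Error rates conflate sequencing errors with true sample/reference
  variation; separating them is out of scope (the discovery pipeline
  addresses only the coverage side).
* The GC-bias curve is reported raw; no smoothing or confidence bands.
* Multi-contig simulation is not implemented (the generator emits one
  contig); all assays handle multi-contig references.
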