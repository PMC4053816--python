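# biasassay

Coverage-bias and error-bias assays for shotgun sequencing data.

Sequencing platforms do not sample a genome evenly: extreme base
composition (very high or very low GC), AT-dinucleotide repeats, G/C
homopolymer tracts, and many GC-rich promoters are systematically
undercovered, and error rates (mismatch, deletion, insertion) shift with
the same sequence contexts.  `biasassay` is a library + CLI for
quantifying these effects from a reference FASTA and read alignments
(SAM/BAM), aimed at people who evaluate sequencing platforms and library
construction protocols, or who need to know which parts of a genome their
data cannot see.

## The statistics

The core quantity is **relative coverage**.  With `c(i)` the number of
read bases aligned (CIGAR `M`/`=`/`X`) to reference base `i`, and
`μ = Σ c(i) / N` the mean over the `N` included bases,

```
r(i) = c(i) / μ
```

so `r = 1` means covered at the expected average rate.  Everything else
derives from it:

* **Motif relative coverage** — the mean of `r(i)` over all bases in a
  *bias motif*: a W-base window whose centered C-base core satisfies a
  composition predicate.  The standard set is GC ≤ 10%, GC ≥ 75%, GC ≥ 85%
  (200-base windows, 100-base cores), (AT)¹⁵ and G|C ≥ 80% (130-base
  windows, 30-base cores); a *generalized* set (GC ≤ 13%, GC ≥ 70%,
  (AT)¹⁰, G|C ≥ 75%) relaxes each threshold to roughly double its extent.
  Because motifs aggregate many loci, their relative coverage is stable
  even at 0.5× depth.
* **GC-bias curve** — every 100-base sliding window is binned by integer
  GC%; each bin reports the mean window relative coverage, suppressed when
  the genome holds fewer than 1,000 windows of that GC%.
* **Undercoverage fractions** — the proportion of the genome with
  `r = 0` or `r ≤ t` for `t ∈ {0.1, 0.25, 0.5}`, after downsampling data
  sets to a common depth.  A Poisson helper `(1−t)·√μ` states how many
  standard deviations such a tail sits below expectation, i.e. why deep
  data with `r ≤ 0.1` bases cannot be explained by sampling noise.
* **Error rates** — per-base mismatch/deletion/insertion counts from the
  CIGAR (an insertion of length L is charged to the reference base
  immediately after the inserted sequence), divided by mapped bases, and
  profiled genome-wide, by local GC, and by homopolymer run length.
* **Bad promoters** — transcription start sites ranked by the ratio of
  mean coverage in the surrounding 200 bases to the surrounding 3,000
  bases; the 1,000 lowest-ratio genes form the bad-promoter list.
* **Uncategorized-bias discovery** — the `r ≤ 0.1` fraction of a genome,
  minus probable sample/reference biological differences (assembly
  alignment gaps, high-local-error windows, diverse-population
  consistency) and regions similar to known motifs, reported as annotated
  intervals.

All computations run over an inclusion mask: selected contigs only, minus
every ambiguous base.

A bundled simulator (`biasassay.simdata`) generates references with
chosen GC landscapes and aligned reads with injected coverage bias and
context-dependent errors, together with an exact event log, so each assay
is validated against ground truth without external data.

## Worked example

Simulate 300 kb (half at 35% GC, half at 65% GC) at depth 40 with a
2-fold sampling depletion above 60% GC and a 0.4% mismatch rate, then
assay it:

```
$ biasassay simulate --config sim.yaml --out-prefix fix
reads   120000
$ biasassay undercoverage --ref fix.fa --aln fix.sam --out under.tsv
$ cat under.tsv
threshold  fraction          percent
0          4.333333333e-05   0.0043
0.1        0.0001166666667   0.012
0.25       0.0003533333333   0.035
0.5        0.05414666667     5.4
```

5.4% of the genome is two-fold undercovered or worse — the depleted
high-GC half dragging through the `r ≤ 0.5` threshold — while essentially
nothing is ten-fold undercovered at this moderate bias.  The GC-bias
curve localizes the problem (`biasassay gc-bias ... --out curve.tsv`,
reportable bins only):

```
gc_percent  n_windows  mean_relative_coverage
        25       1337                1.268840
        37      11184                1.283310
        58       4322                0.865958
        64      12233                0.700927
        70       6944                0.660102
```

Low-GC bins sit near 1.28 and high-GC bins near 0.66 — the injected
2-fold depletion, rescaled because relative coverage always averages to 1
genome-wide.  Error rates are recovered genome-wide:

```
$ biasassay errors --ref fix.fa --aln fix.sam --by genome --out rates.tsv
bin  mapped_bases  mismatch_rate  deletion_rate  insertion_rate  reportable
-1   12000000      0.00400942     0              0               1
```

Every output gets a `.manifest.json` beside it recording parameters,
input checksums, and the package version.

## Layout

```
src/biasassay/
  refseq.py     reference loading, inclusion masks, GC windows, homopolymers
  motifscan.py  bias-motif specs, scanning, genomic extents
  covbias.py    coverage, relative coverage, GC curves, undercoverage, Poisson sigma
  errbias.py    CIGAR-level error counting and context profiles
  promoters.py  TSS coverage ratios and bad-promoter selection
  mixing.py     downsampling, technology mixtures, subsample stability
  discovery.py  uncategorized-bias pipeline (filters + annotated report)
  simdata.py    ground-truth simulator (FASTA + SAM + event log)
  cli.py        `biasassay` subcommands
docs/methods.md  models, conventions, parameter choices, limitations
```
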