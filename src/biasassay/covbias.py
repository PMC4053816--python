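"""Per-base coverage and coverage-bias statistics.

The coverage of a reference base is the number of read bases aligned to it
under the CIGAR M/=/X operators; deletions, skips, insertions and clips
contribute nothing.  The fundamental statistic is *relative coverage*: a
base's coverage divided by the mean coverage over all included bases, so
that 1 means "covered at the expected average rate" and values near 0 flag
systematic undercoverage.

Read filter contract (shared with error counting): unmapped, secondary,
supplementary, and duplicate-flagged records are excluded; MAPQ-0 records
are kept, because aligners that place ambiguous reads randomly must still
contribute them to coverage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .refseq import GCWindows, GenomicInterval, ReferenceModel, _sliding_sum

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.0, 0.1, 0.25, 0.5)


def passes_filter(read: pysam.AlignedSegment) -> bool:
    """Shared alignment-record filter for all bias computations."""
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
    )


def open_alignments(path: str | Path) -> pysam.AlignmentFile:
    return pysam.AlignmentFile(str(path), check_sq=False)


def iter_filtered(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
) -> Iterator[pysam.AlignedSegment]:
    """Iterate records passing the filter contract from a path, file, or iterable."""
    if isinstance(alignments, (str, Path)):
        with open_alignments(alignments) as fh:
            for read in fh:
                if passes_filter(read):
                    yield read
    else:
        for read in alignments:
            if passes_filter(read):
                yield read


@dataclass
class CoverageTrack:
    """Per-base aligned-base counts over a reference."""

    ref: ReferenceModel
    counts: dict[str, np.ndarray]

    @property
    def mean_coverage(self) -> float:
        """Total aligned bases on included positions / included base count."""
        denom = self.ref.included_base_count
        if denom == 0:
            return 0.0
        total = sum(
            int(self.counts[c.name][c.included].sum()) for c in self.ref.contigs
        )
        return total / denom


@dataclass
class RelativeCoverageTrack:
    """Per-base coverage divided by the genome-wide mean coverage."""

    ref: ReferenceModel
    values: dict[str, np.ndarray]
    mean_coverage: float

    def included_values(self) -> np.ndarray:
        return np.concatenate(
            [self.values[c.name][c.included] for c in self.ref.contigs]
        )


@dataclass
class UndercoverageSummary:
    """Fraction of included bases at or below each relative-coverage threshold.

    The threshold 0 counts exact zeros (bases with no aligned reads at all).
    """

    thresholds: tuple[float, ...]
    fractions: tuple[float, ...]

    def as_percent(self) -> tuple[float, ...]:
        return tuple(100.0 * f for f in self.fractions)


@dataclass
class GCBiasCurve:
    """Mean relative coverage of 100-base windows, binned by integer GC%.

    A bin is reportable only when the genome holds at least ``min_windows``
    windows of that GC%, mirroring the plotting rule that suppresses
    unstable bins.
    """

    window: int
    min_windows: int
    n_windows: np.ndarray          # int64[101]
    mean_relative_coverage: np.ndarray  # float64[101], NaN where empty

    @property
    def reportable(self) -> np.ndarray:
        return self.n_windows >= self.min_windows


def _new_counts(ref: ReferenceModel) -> dict[str, np.ndarray]:
    return {c.name: np.zeros(len(c), dtype=np.int64) for c in ref.contigs}


def compute_coverage(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    ref: ReferenceModel,
) -> CoverageTrack:
    """Count aligned read bases (CIGAR M/=/X) per reference base.

    Raises on records aligned to contigs absent from the reference; records
    with malformed/absent CIGAR are skipped and counted in the log.
    """
    diffs = {c.name: np.zeros(len(c) + 1, dtype=np.int64) for c in ref.contigs}
    skipped = 0
    for read in iter_filtered(alignments):
        name = read.reference_name
        if name not in ref:
            raise ValueError(f"alignment references unknown contig {name!r}")
        if read.cigartuples is None:
            skipped += 1
            continue
        d = diffs[name]
        for start, end in read.get_blocks():
            d[start] += 1
            d[end] -= 1
    if skipped:
        logger.warning("compute_coverage: skipped %d records without CIGAR", skipped)
    counts = {name: np.cumsum(d[:-1]) for name, d in diffs.items()}
    return CoverageTrack(ref=ref, counts=counts)


def relative_coverage(track: CoverageTrack) -> RelativeCoverageTrack:
    """Normalize a coverage track by its mean over included bases."""
    mu = track.mean_coverage
    if mu <= 0:
        raise ValueError("no aligned bases on included positions: mean coverage is 0")
    values = {name: counts / mu for name, counts in track.counts.items()}
    return RelativeCoverageTrack(ref=track.ref, values=values, mean_coverage=mu)


def undercoverage_fractions(
    rel: RelativeCoverageTrack, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> UndercoverageSummary:
    """Fractions of included bases with relative coverage 0 (t=0) or <= t."""
    thresholds = tuple(thresholds)
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    v = rel.included_values()
    n = len(v)
    fractions = []
    for t in thresholds:
        if t == 0:
            fractions.append(float(np.count_nonzero(v == 0)) / n)
        else:
            fractions.append(float(np.count_nonzero(v <= t)) / n)
    return UndercoverageSummary(thresholds=thresholds, fractions=tuple(fractions))


def motif_relative_coverage(
    rel: RelativeCoverageTrack, intervals: list[GenomicInterval]
) -> float | None:
    """Mean relative coverage over the union of included bases in the intervals.

    Each base counts once no matter how many intervals cover it.  Returns
    None when the intervals contain no included bases.
    """
    mask = rel.ref.interval_mask(intervals)
    total = 0.0
    n = 0
    for contig in rel.ref.contigs:
        m = mask[contig.name] & contig.included
        k = int(m.sum())
        if k:
            total += float(rel.values[contig.name][m].sum())
            n += k
    if n == 0:
        return None
    return total / n


def gc_bias_curve(
    rel: RelativeCoverageTrack, gc_windows: GCWindows, min_windows: int = 1000
) -> GCBiasCurve:
    """Bin sliding windows by GC% and average their relative coverage.

    A window's relative coverage is the mean of its per-base values, so the
    curve composes exactly with the per-base statistic; an unbiased data set
    gives a flat line at 1.
    """
    w = gc_windows.window
    n_windows = np.zeros(101, dtype=np.int64)
    sums = np.zeros(101, dtype=np.float64)
    for contig in rel.ref.contigs:
        gc = gc_windows.gc[contig.name]
        if len(gc) == 0:
            continue
        win_mean = _sliding_window_mean(rel.values[contig.name], w)
        valid = gc >= 0
        gbin = gc[valid].astype(np.int64)
        n_windows += np.bincount(gbin, minlength=101)[:101]
        sums += np.bincount(gbin, weights=win_mean[valid], minlength=101)[:101]
    mean = np.full(101, np.nan)
    nz = n_windows > 0
    mean[nz] = sums[nz] / n_windows[nz]
    return GCBiasCurve(
        window=w, min_windows=min_windows, n_windows=n_windows,
        mean_relative_coverage=mean,
    )


def _sliding_window_mean(x: np.ndarray, w: int) -> np.ndarray:
    cs = np.concatenate(([0.0], np.cumsum(x, dtype=np.float64)))
    return (cs[w:] - cs[:-w]) / w


def poisson_sigma(mean_coverage: float, relative_threshold: float) -> float:
    """Poisson standard deviations between a relative threshold and the mean.

    At mean depth mu, observing t*mu reads at a base whose true relative
    coverage is 1 is (mu - t*mu)/sqrt(mu) = (1-t)*sqrt(mu) standard
    deviations below expectation under a Poisson depth model; large values
    mean the undercoverage cannot be a sampling accident.
    """
    if mean_coverage <= 0:
        raise ValueError("mean coverage must be positive")
    if not (0 <= relative_threshold < 1):
        raise ValueError("relative threshold must be in [0, 1)")
    return (1.0 - relative_threshold) * math.sqrt(mean_coverage)
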