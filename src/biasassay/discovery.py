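"""Discovery of uncategorized coverage bias.

Starting from the deeply undercovered fraction of the genome (relative
coverage <= 0.1), the pipeline strips away every explanation it can
attribute:

1. probable sample/reference biological differences, detected from an
   assembly of the sample aligned back to the reference (alignment gaps and
   high-local-error windows) and from a diverse-population consistency rule
   (well covered in diverse data, undercovered in all sample data sets);
2. regions similar to known bias motifs (the generalized motif supersets
   plus the bad-promoter list).

What remains is undercoverage with no known cause; it is reported as merged
intervals annotated with GC fraction and homopolymer N50, plus summary
totals including the interval N50.

Filters are set subtractions, so the final interval set does not depend on
application order; only the per-base provenance labels do (first-applied
category wins, in the order assembly gap, high-error window, diverse
consistency, generalized motif).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .covbias import RelativeCoverageTrack, iter_filtered
from .errbias import _ALIGNED_OPS
from .refseq import (
    GenomicInterval,
    ReferenceModel,
    _n50,
    _sliding_sum,
    encode,
    homopolymer_n50,
    interval_gc_fraction,
)

PROVENANCE = {
    0: "none",
    1: "assembly_gap",
    2: "high_error_window",
    3: "diverse_consistent",
    4: "generalized_motif",
}


@dataclass
class ExclusionMask:
    """Per-base exclusion flags with a provenance code per excluded base."""

    ref: ReferenceModel
    codes: dict[str, np.ndarray]   # uint8 per base, 0 = not excluded

    @classmethod
    def empty(cls, ref: ReferenceModel) -> "ExclusionMask":
        return cls(ref=ref, codes={c.name: np.zeros(len(c), dtype=np.uint8) for c in ref.contigs})

    def excluded(self, name: str) -> np.ndarray:
        return self.codes[name] > 0

    def add(self, name: str, where: np.ndarray, code: int) -> None:
        """Mark bases, keeping any earlier provenance (first category wins)."""
        c = self.codes[name]
        c[where & (c == 0)] = code

    def provenance_counts(self) -> dict[str, int]:
        out = {label: 0 for label in PROVENANCE.values() if label != "none"}
        for arr in self.codes.values():
            bc = np.bincount(arr, minlength=5)
            for code, label in PROVENANCE.items():
                if code:
                    out[label] += int(bc[code]) if code < len(bc) else 0
        return out


def _runs_to_intervals(low: np.ndarray, name: str, label: str = "") -> list[GenomicInterval]:
    if not low.any():
        return []
    d = np.diff(low.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if low[0]:
        starts = np.concatenate(([0], starts))
    if low[-1]:
        ends = np.concatenate((ends, [len(low)]))
    return [GenomicInterval(name, int(s), int(e), label) for s, e in zip(starts, ends)]


def undercovered_intervals(
    rel: RelativeCoverageTrack, threshold: float = 0.1
) -> list[GenomicInterval]:
    """Maximal runs of included bases with relative coverage <= threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    out: list[GenomicInterval] = []
    for contig in rel.ref.contigs:
        low = contig.included & (rel.values[contig.name] <= threshold)
        out.extend(_runs_to_intervals(low, contig.name, "undercovered"))
    return out


def split_contigs(
    contigs: Sequence[tuple[str, str]], max_len: int = 100_000, min_len: int = 50_000
) -> list[tuple[str, str]]:
    """Split long contigs into near-equal pieces within [min_len, max_len].

    Contigs of at most ``max_len`` pass through unchanged; a longer contig
    of length L is cut into k = ceil(L / max_len) near-equal pieces, which
    keeps every piece at or above ``min_len`` whenever min_len <= max_len/2
    (the aligner-friendly regime this exists for).
    """
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    out: list[tuple[str, str]] = []
    for name, seq in contigs:
        L = len(seq)
        if L <= max_len:
            out.append((name, seq))
            continue
        k = math.ceil(L / max_len)
        base, extra = divmod(L, k)
        pos = 0
        for i in range(k):
            ln = base + (1 if i < extra else 0)
            out.append((f"{name}.{i + 1}", seq[pos:pos + ln]))
            pos += ln
    return out


def assembly_variation_mask(
    contig_alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    ref: ReferenceModel,
    window: int = 100,
    max_errors: int = 5,
) -> ExclusionMask:
    """Exclude probable within-contig sample/reference differences.

    Reference bases skipped by D operators of the sample-assembly contig
    alignments are excluded as assembly gaps (the contig lacks that
    sequence).  Separately, any sliding ``window``-base reference window
    that lies within contig-aligned sequence and accumulates strictly more
    than ``max_errors`` alignment errors (mismatches + deleted bases +
    inserted bases, attributed exactly as for read alignments) is excluded
    wholesale, because reads over such locally polymorphic sequence may
    fail to align for purely biological reasons.
    """
    mask = ExclusionMask.empty(ref)
    gap = {c.name: np.zeros(len(c), dtype=bool) for c in ref.contigs}
    err = {c.name: np.zeros(len(c), dtype=np.int64) for c in ref.contigs}
    span = {c.name: np.zeros(len(c), dtype=bool) for c in ref.contigs}

    for read in iter_filtered(contig_alignments):
        name = read.reference_name
        if name not in ref:
            raise ValueError(f"contig alignment references unknown contig {name!r}")
        cig = read.cigartuples
        seq = read.query_sequence
        if cig is None or seq is None:
            continue
        contig = ref[name]
        qcode = encode(seq.upper())
        span[name][read.reference_start:read.reference_end] = True
        aligned_after = [False] * (len(cig) + 1)
        for k in range(len(cig) - 1, -1, -1):
            aligned_after[k] = aligned_after[k + 1] or (cig[k][0] in _ALIGNED_OPS)
        rpos, qpos = read.reference_start, 0
        seen_aligned = False
        for k, (op, ln) in enumerate(cig):
            if op in _ALIGNED_OPS:
                mm = contig.code[rpos:rpos + ln] != qcode[qpos:qpos + ln]
                np.add.at(err[name], rpos + np.flatnonzero(mm), 1)
                rpos += ln
                qpos += ln
                seen_aligned = True
            elif op == 1:
                if aligned_after[k + 1]:
                    err[name][rpos] += ln
                elif seen_aligned:
                    err[name][rpos - 1] += ln
                qpos += ln
            elif op == 2:
                gap[name][rpos:rpos + ln] = True
                err[name][rpos:rpos + ln] += 1
                rpos += ln
            elif op == 3:
                rpos += ln
            elif op == 4:
                qpos += ln

    for contig in ref.contigs:
        name = contig.name
        mask.add(name, gap[name], 1)
        n = len(contig) - window + 1
        if n <= 0:
            continue
        werr = _sliding_sum(err[name], window)
        wspan = _sliding_sum(span[name].astype(np.int8), window) == window
        bad_starts = np.flatnonzero(wspan & (werr > max_errors))
        if len(bad_starts):
            high = np.zeros(len(contig), dtype=bool)
            for s in bad_starts.tolist():
                high[s:s + window] = True
            mask.add(name, high, 2)
    return mask


def diverse_consistency_filter(
    diverse_tracks: Sequence[RelativeCoverageTrack],
    sample_tracks: Sequence[RelativeCoverageTrack],
    well_cov: float = 0.5,
    under: float = 0.1,
) -> ExclusionMask:
    """Exclude bases well covered in diverse-population data yet undercovered
    in every sample data set — coverage behavior that points to a sequence
    present in the population but absent (or diverged) in this sample.
    """
    if not diverse_tracks or not sample_tracks:
        raise ValueError("need at least one diverse and one sample track")
    ref = diverse_tracks[0].ref
    mask = ExclusionMask.empty(ref)
    for contig in ref.contigs:
        name = contig.name
        well = np.zeros(len(contig), dtype=bool)
        for t in diverse_tracks:
            well |= t.values[name] >= well_cov
        under_all = np.ones(len(contig), dtype=bool)
        for t in sample_tracks:
            under_all &= t.values[name] < under
        mask.add(name, well & under_all & contig.included, 3)
    return mask


@dataclass
class DiscoveryReport:
    """Unexplained undercovered intervals with composition annotations."""

    intervals: list[GenomicInterval]
    gc_fraction: list[float | None]
    homopolymer_n50: list[int | None]
    base_count: int
    genome_fraction: float
    interval_n50: int | None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "contig": [iv.contig for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "length": [iv.length for iv in self.intervals],
                "gc_fraction": self.gc_fraction,
                "homopolymer_n50": self.homopolymer_n50,
            }
        )


def interval_n50(intervals: Sequence[GenomicInterval]) -> int | None:
    """Length-weighted median interval size (same rule as homopolymer N50)."""
    return _n50([iv.length for iv in intervals])


def discover_uncategorized(
    rel: RelativeCoverageTrack,
    assembly_mask: ExclusionMask | None,
    diverse_mask: ExclusionMask | None,
    generalized_motifs: Sequence[GenomicInterval],
    bad_promoters: Sequence[GenomicInterval],
    ref: ReferenceModel,
    threshold: float = 0.1,
) -> DiscoveryReport:
    """Undercovered intervals that survive every known-cause filter.

    Starts from ``undercovered_intervals(rel, threshold)``, removes bases in
    either exclusion mask and in the union of generalized motifs and bad
    promoters, re-merges the survivors into maximal intervals, and
    annotates each with GC fraction and homopolymer N50.
    """
    motif_mask = ref.interval_mask(list(generalized_motifs) + list(bad_promoters))
    out_intervals: list[GenomicInterval] = []
    for contig in ref.contigs:
        name = contig.name
        low = contig.included & (rel.values[name] <= threshold)
        if assembly_mask is not None:
            low &= ~assembly_mask.excluded(name)
        if diverse_mask is not None:
            low &= ~diverse_mask.excluded(name)
        low &= ~motif_mask[name]
        out_intervals.extend(_runs_to_intervals(low, name, "uncategorized"))
    gc = [interval_gc_fraction(iv, ref) for iv in out_intervals]
    n50s = [homopolymer_n50(iv, ref) for iv in out_intervals]
    base_count = sum(iv.length for iv in out_intervals)
    denom = ref.included_base_count
    return DiscoveryReport(
        intervals=out_intervals,
        gc_fraction=gc,
        homopolymer_n50=n50s,
        base_count=base_count,
        genome_fraction=(base_count / denom if denom else 0.0),
        interval_n50=interval_n50(out_intervals),
    )
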