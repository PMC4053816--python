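"""Alignment error counting and context-dependent error-rate profiles.

Errors are attributed to reference bases from the CIGAR/SEQ of each
alignment record:

* mismatch — an M/=/X-aligned read base differing from the reference base,
  charged at that reference position (an N in the read over an unambiguous
  reference base is a non-matching call and counts as a mismatch);
* deletion — each reference base skipped by a D operator is charged one
  deletion per skipping record;
* insertion — inserted bases have no reference position, so an insertion of
  length L is charged (all L of it) to the reference base immediately after
  the inserted sequence; at record edges, where no aligned base follows, it
  is charged to the nearest preceding aligned base so counts are conserved.

Error rates are fractions: error count in a region divided by the mapped
(M/=/X) base count in that region — not per read, not per genome base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .covbias import CoverageTrack, iter_filtered
from .refseq import GCWindows, GenomicInterval, ReferenceModel, encode, homopolymer_length_track

logger = logging.getLogger(__name__)

_ALIGNED_OPS = {0, 7, 8}   # M, =, X


@dataclass
class ErrorTrack:
    """Per-base mismatch/deletion/insertion counts with their coverage denominator."""

    ref: ReferenceModel
    mismatch: dict[str, np.ndarray]
    deletion: dict[str, np.ndarray]
    insertion: dict[str, np.ndarray]
    coverage: CoverageTrack
    skipped_no_seq: int = 0


@dataclass
class ErrorRateProfile:
    """Binned error rates: genome-wide, by GC%, or by homopolymer run length.

    ``bins`` labels each row (GC percentage, run length, or the single label
    -1 for a genome-wide summary).  Rates are undefined (NaN) where the
    denominator is zero; ``reportable`` additionally suppresses GC bins with
    too few supporting windows genome-wide.
    """

    binning: str
    bins: np.ndarray
    mapped_bases: np.ndarray
    n_mismatch: np.ndarray
    n_deletion: np.ndarray
    n_insertion: np.ndarray
    reportable: np.ndarray

    def _rate(self, num: np.ndarray) -> np.ndarray:
        out = np.full(len(self.bins), np.nan)
        nz = self.mapped_bases > 0
        out[nz] = num[nz] / self.mapped_bases[nz]
        return out

    @property
    def mismatch_rate(self) -> np.ndarray:
        return self._rate(self.n_mismatch)

    @property
    def deletion_rate(self) -> np.ndarray:
        return self._rate(self.n_deletion)

    @property
    def insertion_rate(self) -> np.ndarray:
        return self._rate(self.n_insertion)

    @property
    def total_rate(self) -> np.ndarray:
        return self.mismatch_rate + self.deletion_rate + self.insertion_rate


def count_errors(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    ref: ReferenceModel,
) -> ErrorTrack:
    """Walk each record's CIGAR against the reference and tally errors.

    Uses the same record filter as coverage computation and accumulates the
    coverage denominator in the same pass.  Records without a stored
    sequence (SEQ "*") cannot be compared and are skipped with a logged
    count.
    """
    mism = {c.name: np.zeros(len(c), dtype=np.int64) for c in ref.contigs}
    dele = {c.name: np.zeros(len(c), dtype=np.int64) for c in ref.contigs}
    ins = {c.name: np.zeros(len(c), dtype=np.int64) for c in ref.contigs}
    cov_diff = {c.name: np.zeros(len(c) + 1, dtype=np.int64) for c in ref.contigs}
    skipped = 0

    for read in iter_filtered(alignments):
        name = read.reference_name
        if name not in ref:
            raise ValueError(f"alignment references unknown contig {name!r}")
        cig = read.cigartuples
        if cig is None:
            continue
        seq = read.query_sequence
        if seq is None:
            skipped += 1
            continue
        contig = ref[name]
        qcode = encode(seq.upper())
        m, d_arr, i_arr, cd = mism[name], dele[name], ins[name], cov_diff[name]
        # does any aligned op occur at or after op index k?
        aligned_after = [False] * (len(cig) + 1)
        for k in range(len(cig) - 1, -1, -1):
            aligned_after[k] = aligned_after[k + 1] or (cig[k][0] in _ALIGNED_OPS)
        rpos = read.reference_start
        qpos = 0
        seen_aligned = False
        first_aligned = None
        for k, (op, ln) in enumerate(cig):
            if op in _ALIGNED_OPS:
                if first_aligned is None:
                    first_aligned = rpos
                block_ref = contig.code[rpos:rpos + ln]
                block_read = qcode[qpos:qpos + ln]
                np.add.at(m, rpos + np.flatnonzero(block_ref != block_read), 1)
                cd[rpos] += 1
                cd[rpos + ln] -= 1
                rpos += ln
                qpos += ln
                seen_aligned = True
            elif op == 1:  # I
                if aligned_after[k + 1]:
                    i_arr[rpos] += ln
                elif seen_aligned:
                    i_arr[rpos - 1] += ln
                # else: record with no aligned base at all; nothing to charge
                qpos += ln
            elif op == 2:  # D
                d_arr[rpos:rpos + ln] += 1
                rpos += ln
            elif op == 3:  # N
                rpos += ln
            elif op == 4:  # S
                qpos += ln
            # H (5) and P (6) consume nothing we track

    if skipped:
        logger.warning("count_errors: skipped %d records without SEQ", skipped)
    counts = {name: np.cumsum(d[:-1]) for name, d in cov_diff.items()}
    return ErrorTrack(
        ref=ref, mismatch=mism, deletion=dele, insertion=ins,
        coverage=CoverageTrack(ref=ref, counts=counts),
        skipped_no_seq=skipped,
    )


def _region_mask(ref: ReferenceModel, region: list[GenomicInterval] | None) -> dict[str, np.ndarray]:
    if region is None:
        return {c.name: c.included.copy() for c in ref.contigs}
    mask = ref.interval_mask(region)
    return {c.name: mask[c.name] & c.included for c in ref.contigs}


def error_rates(
    track: ErrorTrack, region: list[GenomicInterval] | None = None
) -> ErrorRateProfile:
    """Genome-wide (or region-restricted) error rates over included bases."""
    mask = _region_mask(track.ref, region)
    nm = nd = ni = denom = 0
    for name, m in mask.items():
        nm += int(track.mismatch[name][m].sum())
        nd += int(track.deletion[name][m].sum())
        ni += int(track.insertion[name][m].sum())
        denom += int(track.coverage.counts[name][m].sum())
    return ErrorRateProfile(
        binning="genome",
        bins=np.array([-1]),
        mapped_bases=np.array([denom], dtype=np.int64),
        n_mismatch=np.array([nm], dtype=np.int64),
        n_deletion=np.array([nd], dtype=np.int64),
        n_insertion=np.array([ni], dtype=np.int64),
        reportable=np.array([denom > 0]),
    )


def error_profile(
    track: ErrorTrack,
    binning: str,
    gc_windows: GCWindows | None = None,
    min_windows: int = 1000,
    homopolymer_cap: int = 15,
) -> ErrorRateProfile:
    """Bin per-base error counts by sequence context.

    ``gc_percent``: each base is assigned the GC% of the window of
    ``gc_windows.window`` bases centered on it; bases lacking a full
    unmasked centered window are left unbinned.  A GC bin is reportable only
    when the genome holds >= ``min_windows`` windows of that GC%.

    ``homopolymer_length``: each base is assigned the length of its
    containing homopolymer run, capped at ``homopolymer_cap`` so sparse
    long-run bins aggregate into a single "cap and longer" bin.
    """
    ref = track.ref
    if binning == "gc_percent":
        if gc_windows is None:
            raise ValueError("gc_percent binning requires gc_windows")
        nbins = 101
        bins = np.arange(nbins)
        half = gc_windows.window // 2
    elif binning == "homopolymer_length":
        nbins = homopolymer_cap
        bins = np.arange(1, homopolymer_cap + 1)
        hlen = homopolymer_length_track(ref, cap=homopolymer_cap)
    else:
        raise ValueError(f"unknown binning {binning!r}")

    denom = np.zeros(nbins, dtype=np.int64)
    nm = np.zeros(nbins, dtype=np.int64)
    nd = np.zeros(nbins, dtype=np.int64)
    ni = np.zeros(nbins, dtype=np.int64)
    for contig in ref.contigs:
        n = len(contig)
        if binning == "gc_percent":
            # base i sits at the center of the window starting at i - half
            assign = np.full(n, -1, dtype=np.int64)
            gw = gc_windows.gc[contig.name]
            if len(gw):
                centers = np.arange(len(gw)) + half
                assign[centers] = gw
        else:
            assign = hlen[contig.name].astype(np.int64) - 1  # run length L -> bin L-1
            assign[~contig.included] = -1
        ok = (assign >= 0) & contig.included
        idx = assign[ok]
        denom += np.bincount(idx, weights=track.coverage.counts[contig.name][ok], minlength=nbins)[:nbins].astype(np.int64)
        nm += np.bincount(idx, weights=track.mismatch[contig.name][ok], minlength=nbins)[:nbins].astype(np.int64)
        nd += np.bincount(idx, weights=track.deletion[contig.name][ok], minlength=nbins)[:nbins].astype(np.int64)
        ni += np.bincount(idx, weights=track.insertion[contig.name][ok], minlength=nbins)[:nbins].astype(np.int64)

    if binning == "gc_percent":
        reportable = (gc_windows.bin_counts() >= min_windows) & (denom > 0)
    else:
        reportable = denom > 0
    return ErrorRateProfile(
        binning=binning, bins=bins, mapped_bases=denom,
        n_mismatch=nm, n_deletion=nd, n_insertion=ni, reportable=reportable,
    )
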