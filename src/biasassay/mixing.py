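"""Depth normalization, technology mixing, and subsample-stability assays.

Undercoverage tail fractions depend strongly on depth, so cross-data-set
comparisons first downsample every data set to a common mean coverage.
Downsampling is fragment-level: the keep/drop decision is a deterministic
function of the read name (QNAME) and the seed, so mate pairs are never
split and the same seed always selects the byte-identical read set.

Technology mixtures are formed post-alignment by adding coverage tracks of
per-component downsampled data, mirroring how mixed-platform data sets are
assembled from independently aligned components.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .covbias import (
    CoverageTrack,
    RelativeCoverageTrack,
    UndercoverageSummary,
    compute_coverage,
    iter_filtered,
    motif_relative_coverage,
    open_alignments,
    relative_coverage,
    undercoverage_fractions,
)
from .refseq import GenomicInterval, ReferenceModel

_SCALE = 2.0 ** 32


def _keep(qname: str, seed: int, p: float) -> bool:
    """Deterministic per-fragment Bernoulli(p) draw keyed by (seed, QNAME)."""
    if p >= 1.0:
        return True
    h = zlib.crc32(f"{seed}:{qname}".encode("ascii"))
    return h / _SCALE < p


def downsample(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    current_mean: float,
    target_mean: float,
    seed: int,
) -> Iterator[pysam.AlignedSegment]:
    """Yield a random subset of records approximating the target mean depth.

    Each fragment (all records sharing a QNAME) is retained independently
    with probability target/current; the retained set is a deterministic
    function of the seed.
    """
    if not (0 < target_mean <= current_mean):
        raise ValueError("require 0 < target_mean <= current_mean")
    p = target_mean / current_mean
    for read in iter_filtered(alignments):
        if _keep(read.query_name, seed, p):
            yield read


def downsample_to_file(
    in_path: str | Path, out_path: str | Path,
    current_mean: float, target_mean: float, seed: int,
) -> int:
    """File-to-file downsampling; returns the number of records written."""
    n = 0
    with open_alignments(in_path) as src:
        mode = "wb" if str(out_path).endswith(".bam") else "w"
        with pysam.AlignmentFile(str(out_path), mode, template=src) as dst:
            for read in downsample(src, current_mean, target_mean, seed):
                dst.write(read)
                n += 1
    return n


def combine_tracks(a: CoverageTrack, b: CoverageTrack) -> CoverageTrack:
    """Add two coverage tracks base-wise (a post-alignment data-set mixture)."""
    if a.ref is not b.ref:
        if a.ref.names != b.ref.names or any(
            not np.array_equal(a.ref[n].included, b.ref[n].included) for n in a.ref.names
        ):
            raise ValueError("coverage tracks computed on different references/masks")
    counts = {name: a.counts[name] + b.counts[name] for name in a.counts}
    return CoverageTrack(ref=a.ref, counts=counts)


@dataclass
class MixtureResult:
    """A 50/50-style technology mixture and its matched-depth components."""

    component_ids: tuple[str, str]
    per_component_depth: float
    merged: UndercoverageSummary
    components: tuple[UndercoverageSummary, UndercoverageSummary]


def mix_components(
    aln_a: str | Path,
    aln_b: str | Path,
    ref: ReferenceModel,
    per_component_depth: float,
    thresholds: Sequence[float] = (0.0, 0.1, 0.25, 0.5),
    seed: int = 0,
    ids: tuple[str, str] = ("A", "B"),
) -> MixtureResult:
    """Compare a two-component mixture with its pure components.

    Each component is downsampled to ``per_component_depth``; the merged
    track (sum of the two) therefore has twice that depth, and each pure
    component is separately downsampled to the same matched total depth for
    a fair undercoverage comparison.
    """
    total = 2.0 * per_component_depth

    def track_at(path: str | Path, target: float, sub_seed: int) -> CoverageTrack:
        full = compute_coverage(path, ref)
        mu = full.mean_coverage
        if target >= mu:
            return full
        return compute_coverage(downsample(path, mu, target, sub_seed), ref)

    half_a = track_at(aln_a, per_component_depth, seed)
    half_b = track_at(aln_b, per_component_depth, seed + 1)
    merged = combine_tracks(half_a, half_b)
    pure_a = track_at(aln_a, total, seed + 2)
    pure_b = track_at(aln_b, total, seed + 3)
    return MixtureResult(
        component_ids=ids,
        per_component_depth=per_component_depth,
        merged=undercoverage_fractions(relative_coverage(merged), thresholds),
        components=(
            undercoverage_fractions(relative_coverage(pure_a), thresholds),
            undercoverage_fractions(relative_coverage(pure_b), thresholds),
        ),
    )


def subsample_stability(
    alignments: str | Path,
    ref: ReferenceModel,
    motif_intervals: dict[str, list[GenomicInterval]],
    fraction: float,
    reps: int = 10,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Stability of motif relative coverage under shallow random subsets.

    Draws ``reps`` independent random subsets (each fragment kept with
    probability ``fraction``; rep r uses derived seed ``seed + r``),
    recomputes each motif's relative coverage per subset, and reports the
    per-motif (mean, sample sd) across reps.  Motifs with no included bases
    in a rep are skipped for that rep.
    """
    if reps < 2:
        raise ValueError("need at least 2 reps to estimate a standard deviation")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    # cache (qname, blocks) once; reps then only re-filter and re-accumulate
    cached: list[tuple[str, str, list[tuple[int, int]]]] = []
    for read in iter_filtered(alignments):
        if read.cigartuples is None:
            continue
        cached.append((read.query_name, read.reference_name, read.get_blocks()))

    masks = {
        name: ref.interval_mask(ivs) for name, ivs in motif_intervals.items()
    }
    per_motif: dict[str, list[float]] = {name: [] for name in motif_intervals}
    for r in range(reps):
        rep_seed = seed + r
        diffs = {c.name: np.zeros(len(c) + 1, dtype=np.int64) for c in ref.contigs}
        for qname, rname, blocks in cached:
            if _keep(qname, rep_seed, fraction):
                d = diffs[rname]
                for s, e in blocks:
                    d[s] += 1
                    d[e] -= 1
        track = CoverageTrack(
            ref=ref, counts={n: np.cumsum(d[:-1]) for n, d in diffs.items()}
        )
        rel = relative_coverage(track)
        for name, ivs in motif_intervals.items():
            v = motif_relative_coverage(rel, ivs)
            if v is not None:
                per_motif[name].append(v)
    out: dict[str, tuple[float, float]] = {}
    for name, vals in per_motif.items():
        arr = np.asarray(vals)
        out[name] = (float(arr.mean()), float(arr.std(ddof=1)))
    return out
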