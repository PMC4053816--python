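"""Bias-motif definitions and genome scanning.

A bias motif is a W-base window whose centered C-base core satisfies a base
composition predicate (e.g. "200-base regions in which the middle 100 bases
have >=75% GC content").  The standard set contains five motifs; a
generalized set relaxes each threshold so that each motif covers roughly
twice as many bases, for use when filtering out "similar to known motif"
regions.  Bad promoters are an empirically-derived interval list, not a
scanned motif, and enter downstream analyses as plain intervals.

A motif's genomic extent is the union of the *full* W-base windows of every
hit (not just their cores): the whole window is the region the motif names.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .refseq import A, C, G, T, GenomicInterval, ReferenceModel, _sliding_sum

PREDICATES = ("gc_max", "gc_min", "at_repeat", "gc_or_c_homopolymer_frac")


@dataclass(frozen=True)
class MotifSpec:
    """Window/core geometry plus a core composition predicate.

    ``threshold`` is a percentage of the core length for the GC predicates;
    it is ignored for ``at_repeat`` (which requires the whole core to be a
    perfect alternating A/T tract, in either phase).
    """

    name: str
    window_len: int
    core_len: int
    predicate: str
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.predicate not in PREDICATES:
            raise ValueError(f"unknown predicate {self.predicate!r}")
        if self.core_len > self.window_len:
            raise ValueError("core longer than window")
        if (self.window_len - self.core_len) % 2:
            raise ValueError("core must be centered: W - C must be even")

    @property
    def core_offset(self) -> int:
        return (self.window_len - self.core_len) // 2


def standard_motif_set(generalized: bool = False) -> list[MotifSpec]:
    """The five standard bias motifs, or the four generalized supersets.

    The generalized set has no bad-promoter entry because that list is an
    interval input, and each remaining motif is a relaxed superset of its
    standard counterpart (GC<=13 over GC<=10, GC>=70 over GC>=75/85, (AT)^10
    over (AT)^15, G|C>=75 over G|C>=80).
    """
    if generalized:
        return [
            MotifSpec("gc_le13", 200, 100, "gc_max", 13),
            MotifSpec("gc_ge70", 200, 100, "gc_min", 70),
            MotifSpec("at10", 130, 20, "at_repeat"),
            MotifSpec("gchomo75", 130, 30, "gc_or_c_homopolymer_frac", 75),
        ]
    return [
        MotifSpec("gc_le10", 200, 100, "gc_max", 10),
        MotifSpec("gc_ge75", 200, 100, "gc_min", 75),
        MotifSpec("gc_ge85", 200, 100, "gc_min", 85),
        MotifSpec("at15", 130, 30, "at_repeat"),
        MotifSpec("gchomo80", 130, 30, "gc_or_c_homopolymer_frac", 80),
    ]


def motif_by_name(name: str) -> MotifSpec:
    for spec in standard_motif_set(False) + standard_motif_set(True):
        if spec.name == name:
            return spec
    raise KeyError(name)


def _core_pass(code: np.ndarray, spec: MotifSpec) -> np.ndarray:
    """Boolean over core start positions: does [cs, cs+C) satisfy the predicate?

    Thresholds compare integer base counts (ceil for minima, floor for
    maxima) so that exact-threshold cores are decided without float equality.
    """
    cl = spec.core_len
    n = len(code) - cl + 1
    if n <= 0:
        return np.zeros(0, dtype=bool)
    if spec.predicate in ("gc_max", "gc_min"):
        gc = _sliding_sum(((code == G) | (code == C)).astype(np.int8), cl)
        if spec.predicate == "gc_min":
            return gc >= math.ceil(spec.threshold * cl / 100.0)
        return gc <= math.floor(spec.threshold * cl / 100.0)
    if spec.predicate == "gc_or_c_homopolymer_frac":
        need = math.ceil(spec.threshold * cl / 100.0)
        gs = _sliding_sum((code == G).astype(np.int8), cl)
        cs = _sliding_sum((code == C).astype(np.int8), cl)
        return (gs >= need) | (cs >= need)
    # at_repeat: every core base in {A,T} and adjacent bases alternate
    is_at = (code == A) | (code == T)
    if cl == 1:
        return is_at[:n]
    alt = is_at[:-1] & is_at[1:] & (code[:-1] != code[1:])
    return _sliding_sum(alt.astype(np.int8), cl - 1) == cl - 1


def scan_motif(ref: ReferenceModel, spec: MotifSpec) -> list[GenomicInterval]:
    """All merged motif hit windows on the included portion of the reference.

    A window start s is a hit when the centered core satisfies the predicate
    and the whole window [s, s+W) is unmasked; overlapping/adjacent hit
    windows are merged into maximal intervals.
    """
    w, off = spec.window_len, spec.core_offset
    out: list[GenomicInterval] = []
    for contig in ref.contigs:
        n = len(contig) - w + 1
        if n <= 0:
            continue
        core_ok = _core_pass(contig.code, spec)
        win_ok = _sliding_sum(contig.included.astype(np.int8), w) == w
        hits = win_ok & core_ok[off:off + n]
        starts = np.flatnonzero(hits)
        if len(starts) == 0:
            continue
        # windows all have length w: a new merged interval begins where the
        # gap to the previous hit start exceeds w
        breaks = np.flatnonzero(np.diff(starts) > w) + 1
        for group in np.split(starts, breaks):
            out.append(GenomicInterval(contig.name, int(group[0]), int(group[-1]) + w, spec.name))
    return out


def motif_extent(intervals: list[GenomicInterval], ref: ReferenceModel) -> tuple[int, float]:
    """Distinct included bases covered by the interval union, and the genome fraction."""
    total_included = ref.included_base_count
    if not intervals:
        return 0, 0.0
    mask = ref.interval_mask(intervals)
    count = sum(int((mask[c.name] & c.included).sum()) for c in ref.contigs)
    return count, (count / total_included if total_included else 0.0)
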