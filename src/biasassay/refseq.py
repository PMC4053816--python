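"""Reference sequences, inclusion masks, and composition annotations.

Every downstream bias statistic is computed over an *inclusion mask*: the
bases of the contigs selected by a policy (e.g. chromosomal contigs only),
minus any ambiguous bases.  Ambiguous bases (anything outside A/C/G/T after
upper-casing) are always excluded because reads cannot be mapped to them
unambiguously and their motif membership is undefined.

Coordinates are 0-based half-open throughout; SAM's 1-based positions are
converted at the I/O boundary (pysam already does this) and BED intervals
are emitted natively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

# base codes: A=0 C=1 G=2 T=3, ambiguous=4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
A, C, G, T, AMBIG = 0, 1, 2, 3, 4


def encode(seq: str) -> np.ndarray:
    """Encode an upper-case sequence as uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.contig}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HomopolymerRun:
    """A maximal run of identical unambiguous bases."""

    contig: str
    start: int
    end: int
    base: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Contig:
    name: str
    seq: str                  # upper-cased
    code: np.ndarray          # uint8 codes
    included: np.ndarray      # bool mask

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReferenceModel:
    """Loaded reference with its inclusion mask.

    ``policy`` records how contigs were selected ("all" or "named_subset");
    contigs excluded by the policy are retained (so alignments against them
    can still be parsed) but fully masked.
    """

    contigs: list[Contig]
    policy: str = "all"
    _index: dict[str, Contig] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {c.name: c for c in self.contigs}

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> Contig:
        return self._index[name]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.contigs]

    @property
    def included_base_count(self) -> int:
        return int(sum(int(c.included.sum()) for c in self.contigs))

    def interval_mask(self, intervals: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
        """Boolean per-contig arrays marking the union of ``intervals``."""
        mask = {c.name: np.zeros(len(c), dtype=bool) for c in self.contigs}
        for iv in intervals:
            m = mask[iv.contig]
            if iv.end > len(m):
                raise ValueError(f"interval {iv} exceeds contig length {len(m)}")
            m[iv.start:iv.end] = True
        return mask


def from_sequences(
    named_seqs: Sequence[tuple[str, str]], contig_policy: str | Iterable[str] = "all"
) -> ReferenceModel:
    """Build a ReferenceModel from in-memory (name, sequence) pairs.

    ``contig_policy`` is "all" or an iterable of contig names to include;
    everything else is fully masked.
    """
    if not named_seqs:
        raise ValueError("reference contains no contigs")
    names = [n for n, _ in named_seqs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate contig names in reference")
    if contig_policy == "all":
        selected = set(names)
        policy = "all"
    else:
        selected = set(contig_policy)
        policy = "named_subset"
        missing = selected - set(names)
        if missing:
            raise ValueError(f"policy names contigs absent from reference: {sorted(missing)}")
    contigs = []
    for name, seq in named_seqs:
        seq = seq.upper()
        code = encode(seq)
        if name in selected:
            included = code != AMBIG
        else:
            included = np.zeros(len(seq), dtype=bool)
        contigs.append(Contig(name, seq, code, included))
    return ReferenceModel(contigs, policy)


def load_reference(fasta_path: str | Path, contig_policy: str | Iterable[str] = "all") -> ReferenceModel:
    """Load a (multi-)FASTA and apply the region-selection policy.

    Sequences are upper-cased (soft-masking is ignored); every non-ACGT base
    is masked out, as are all bases of contigs not selected by the policy.
    """
    named_seqs: list[tuple[str, str]] = []
    with pysam.FastxFile(str(fasta_path)) as fh:
        for entry in fh:
            named_seqs.append((entry.name, entry.sequence))
    if not named_seqs:
        raise ValueError(f"no sequences found in {fasta_path}")
    return from_sequences(named_seqs, contig_policy)


@dataclass
class GCWindows:
    """Per-contig sliding-window GC percentages.

    ``gc[name][s]`` is the integer GC% of the window ``[s, s+window)``, or -1
    where the window is invalid (crosses a contig end or touches a masked
    base).  Windows slide with step 1.
    """

    window: int
    gc: dict[str, np.ndarray]

    def values(self) -> np.ndarray:
        """All valid GC% values, concatenated across contigs."""
        parts = [g[g >= 0] for g in self.gc.values()]
        return np.concatenate(parts) if parts else np.zeros(0, dtype=np.int16)

    def bin_counts(self) -> np.ndarray:
        """Number of valid windows per GC% bin 0..100."""
        v = self.values()
        return np.bincount(v, minlength=101)[:101]


def _sliding_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sums of every length-w window of x (len(x)-w+1 values)."""
    cs = np.concatenate(([0], np.cumsum(x, dtype=np.int64)))
    return cs[w:] - cs[:-w]


def gc_percent_windows(ref: ReferenceModel, window: int = 100) -> GCWindows:
    """Integer GC% of every fully-included sliding window of the given size."""
    if window < 1:
        raise ValueError("window must be >= 1")
    out: dict[str, np.ndarray] = {}
    for contig in ref.contigs:
        n = len(contig) - window + 1
        if n <= 0:
            out[contig.name] = np.zeros(0, dtype=np.int16)
            continue
        is_gc = ((contig.code == C) | (contig.code == G)).astype(np.int8)
        gc_counts = _sliding_sum(is_gc, window)
        ok = _sliding_sum(contig.included.astype(np.int8), window) == window
        gc = np.rint(100.0 * gc_counts / window).astype(np.int16)
        gc[~ok] = -1
        out[contig.name] = gc
    return GCWindows(window=window, gc=out)


def _run_boundaries(code: np.ndarray, included: np.ndarray) -> np.ndarray:
    """Indices where a new run starts (change of base or of mask state)."""
    if len(code) == 0:
        return np.zeros(0, dtype=np.int64)
    change = np.empty(len(code), dtype=bool)
    change[0] = True
    change[1:] = (code[1:] != code[:-1]) | (included[1:] != included[:-1])
    return np.flatnonzero(change)


def homopolymer_runs(ref: ReferenceModel) -> list[HomopolymerRun]:
    """Maximal homopolymer runs over the included, unambiguous bases.

    Runs of length 1 are kept, so the runs tile every included base exactly
    once.  Runs never span masked bases.
    """
    runs: list[HomopolymerRun] = []
    bases = "ACGT"
    for contig in ref.contigs:
        starts = _run_boundaries(contig.code, contig.included)
        ends = np.append(starts[1:], len(contig))
        for s, e in zip(starts.tolist(), ends.tolist()):
            if contig.included[s]:
                runs.append(HomopolymerRun(contig.name, s, e, bases[contig.code[s]]))
    return runs


def homopolymer_length_track(ref: ReferenceModel, cap: int | None = None) -> dict[str, np.ndarray]:
    """Per-base length of the containing homopolymer run (0 at masked bases).

    With ``cap`` set, lengths above the cap are reported as the cap, so sparse
    long-run bins aggregate into a single "cap+" bin.
    """
    out: dict[str, np.ndarray] = {}
    for contig in ref.contigs:
        track = np.zeros(len(contig), dtype=np.int32)
        starts = _run_boundaries(contig.code, contig.included)
        ends = np.append(starts[1:], len(contig))
        lengths = ends - starts
        if cap is not None:
            lengths = np.minimum(lengths, cap)
        for s, e, ln in zip(starts.tolist(), ends.tolist(), lengths.tolist()):
            if contig.included[s]:
                track[s:e] = ln
        out[contig.name] = track
    return out


def _n50(lengths: Sequence[int]) -> int | None:
    """Length-weighted median: smallest L with runs >= L covering half the bases."""
    if not lengths:
        return None
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half)])


def homopolymer_n50(interval: GenomicInterval, ref: ReferenceModel) -> int | None:
    """N50 of homopolymer run lengths clipped to the interval.

    Returns None for intervals with no included bases.
    """
    contig = ref[interval.contig]
    if interval.end > len(contig):
        raise ValueError(f"interval {interval} exceeds contig length {len(contig)}")
    code = contig.code[interval.start:interval.end]
    included = contig.included[interval.start:interval.end]
    starts = _run_boundaries(code, included)
    ends = np.append(starts[1:], len(code))
    lengths = [int(e - s) for s, e in zip(starts, ends) if included[s]]
    return _n50(lengths)


def interval_gc_fraction(interval: GenomicInterval, ref: ReferenceModel) -> float | None:
    """Fraction of the interval's included bases that are G or C."""
    contig = ref[interval.contig]
    code = contig.code[interval.start:interval.end]
    inc = contig.included[interval.start:interval.end]
    n = int(inc.sum())
    if n == 0:
        return None
    gc = int((((code == G) | (code == C)) & inc).sum())
    return gc / n


# ---------------------------------------------------------------------------
# Interval / mask I/O (BED, 0-based half-open — matches internal convention)

def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.label:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.label}\n")
            else:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = parts[3] if len(parts) > 3 else ""
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), label))
    return out


def excluded_regions(ref: ReferenceModel) -> list[GenomicInterval]:
    """The inclusion mask's complement, as mergeable BED-style intervals."""
    out: list[GenomicInterval] = []
    for contig in ref.contigs:
        excl = ~contig.included
        if not excl.any():
            continue
        d = np.diff(excl.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if excl[0]:
            starts = np.concatenate(([0], starts))
        if excl[-1]:
            ends = np.concatenate((ends, [len(contig)]))
        for s, e in zip(starts.tolist(), ends.tolist()):
            out.append(GenomicInterval(contig.name, s, e, "excluded"))
    return out


def write_fasta(ref: ReferenceModel, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in ref.contigs:
            fh.write(f">{contig.name}\n")
            for i in range(0, len(contig), width):
                fh.write(contig.seq[i:i + width] + "\n")
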