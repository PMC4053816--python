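"""Synthetic references and aligned reads with controllable bias.

The generator exists so that every bias assay in this package can be
exercised against known ground truth:

* the reference is a concatenation of tracts with chosen GC composition
  (plus optional spliced-in sequences such as homopolymer or AT-repeat
  tracts);
* fragment start positions are sampled with probability proportional to a
  tabulated weight function of local GC (the injected coverage bias),
  optionally modulated by planted per-interval weight multipliers
  (promoter-like depressions, bias loci);
* sequencing errors are injected per aligned base with configurable base
  rates and per-context multipliers (by local GC percentage and by
  homopolymer run length), and every injected event is recorded in an
  event log.

Records are emitted as already-aligned SAM at their true positions — no
aligner runs — so error counting can be checked for *exact* agreement with
the event log, and coverage statistics are isolated from aligner behavior.
Insertions are never placed at record edges and deletions never lead a
record, so ordinary simulations exercise only the unambiguous interior
attribution; edge-case attribution is tested with hand-built records.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .refseq import (
    GenomicInterval,
    ReferenceModel,
    from_sequences,
    gc_percent_windows,
    homopolymer_length_track,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
GC_WINDOW = 100          # window convention shared with the assays
_START_SLACK = 12        # head-room so deletion-extended reads stay on-contig


@dataclass(frozen=True)
class PlantedFeature:
    """A weight multiplier applied to fragments overlapping [start, end)."""

    start: int
    end: int
    weight: float
    label: str = ""


@dataclass
class ContextMultipliers:
    """Error-rate multipliers by local context.

    ``gc`` has 101 entries indexed by the GC% of the 100-base window
    centered on the base (bases without a full window use multiplier 1);
    ``homopolymer`` is indexed by min(run length, len-1).
    """

    gc: np.ndarray | None = None
    homopolymer: np.ndarray | None = None


@dataclass
class SimConfig:
    gc_landscape: list[tuple[int, float]] = field(default_factory=lambda: [(100_000, 50.0)])
    read_length: int = 100
    paired: bool = False
    fragment_length: int = 300
    target_depth: float = 30.0
    coverage_bias: np.ndarray | None = None      # 101 weights indexed by GC%
    mismatch_rate: float = 0.0
    deletion_rate: float = 0.0
    insertion_rate: float = 0.0
    insertion_length: int = 1
    mismatch_context: ContextMultipliers | None = None
    deletion_context: ContextMultipliers | None = None
    insertion_context: ContextMultipliers | None = None
    planted_features: list[PlantedFeature] = field(default_factory=list)
    planted_sequences: list[tuple[int, str]] = field(default_factory=list)
    contig_name: str = "sim"
    seed: int = 0

    @property
    def genome_length(self) -> int:
        return sum(ln for ln, _ in self.gc_landscape)

    def validate(self) -> None:
        if self.genome_length < self.read_length:
            raise ValueError("genome shorter than the read length")
        for ln, gc in self.gc_landscape:
            if not (0 <= gc <= 100):
                raise ValueError(f"infeasible GC target {gc}")
            if ln <= 0:
                raise ValueError("tract lengths must be positive")
        for r in (self.mismatch_rate, self.deletion_rate, self.insertion_rate):
            if not (0 <= r < 1):
                raise ValueError("error rates must be in [0, 1)")
        if self.coverage_bias is not None:
            cb = np.asarray(self.coverage_bias)
            if cb.shape != (101,) or (cb < 0).any():
                raise ValueError("coverage_bias must be 101 non-negative weights")
        if self.paired and self.fragment_length < self.read_length:
            raise ValueError("fragment shorter than read length")


# ---------------------------------------------------------------------------
# Event log

MISMATCH, DELETION, INSERTION = 0, 1, 2
_TYPE_NAMES = {MISMATCH: "mismatch", DELETION: "deletion", INSERTION: "insertion"}


@dataclass
class EventLog:
    """Ground truth for every injected error, sufficient to recompute all
    true per-base counts.  ``retained`` exists for downsampling experiments;
    the simulator itself drops nothing."""

    contig: str
    read_starts: np.ndarray
    retained: np.ndarray
    event_read: np.ndarray    # read index per event
    event_type: np.ndarray    # MISMATCH/DELETION/INSERTION
    event_pos: np.ndarray     # reference position charged
    event_len: np.ndarray     # 1 for mismatch/deletion; L for insertion

    def counts(self) -> dict[str, int]:
        out = {}
        for t, name in _TYPE_NAMES.items():
            sel = self.event_type == t
            out[name] = int(self.event_len[sel].sum())
        return out

    def tracks(self, ref: ReferenceModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """True per-base (mismatch, deletion, insertion) count arrays."""
        n = len(ref[self.contig])
        arrays = []
        for t in (MISMATCH, DELETION, INSERTION):
            a = np.zeros(n, dtype=np.int64)
            sel = self.event_type == t
            np.add.at(a, self.event_pos[sel], self.event_len[sel])
            arrays.append(a)
        return tuple(arrays)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_index\ttype\tposition\tlength\n")
            for r, t, p, ln in zip(
                self.event_read, self.event_type, self.event_pos, self.event_len
            ):
                fh.write(f"{r}\t{_TYPE_NAMES[int(t)]}\t{p}\t{ln}\n")


# ---------------------------------------------------------------------------
# Reference simulation

def simulate_reference(config: SimConfig) -> ReferenceModel:
    """Concatenated GC tracts (plus any spliced planted sequences)."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    parts = []
    for ln, gc in config.gc_landscape:
        is_gc = rng.random(ln) < gc / 100.0
        pick = rng.integers(0, 2, size=ln)
        code = np.where(is_gc, np.where(pick == 0, 1, 2), np.where(pick == 0, 0, 3))
        parts.append(_BASES[code])
    arr = np.concatenate(parts)
    for pos, seq in config.planted_sequences:
        ins = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        if pos < 0 or pos + len(ins) > len(arr):
            raise ValueError("planted sequence outside the genome")
        arr[pos:pos + len(ins)] = ins
    return from_sequences([(config.contig_name, arr.tobytes().decode("ascii"))])


# ---------------------------------------------------------------------------
# Alignment simulation

def _per_base_rate(
    base_rate: float,
    ctx: ContextMultipliers | None,
    base_gc: np.ndarray,
    run_len: np.ndarray,
) -> np.ndarray:
    """Per-reference-base event probability (float64 -> float32)."""
    n = len(base_gc)
    p = np.full(n, base_rate, dtype=np.float64)
    if ctx is not None and ctx.gc is not None:
        mult = np.ones(n)
        valid = base_gc >= 0
        mult[valid] = np.asarray(ctx.gc, dtype=np.float64)[base_gc[valid]]
        p *= mult
    if ctx is not None and ctx.homopolymer is not None:
        hm = np.asarray(ctx.homopolymer, dtype=np.float64)
        idx = np.minimum(run_len, len(hm) - 1)
        p *= hm[idx]
    return np.clip(p, 0.0, 0.999).astype(np.float32)


def _fragment_weights(config: SimConfig, ref: ReferenceModel, span: int) -> np.ndarray:
    contig = ref.contigs[0]
    L = len(contig)
    n_starts = L - span - _START_SLACK + 1
    if n_starts <= 0:
        raise ValueError("genome too short for the configured fragment span")
    gcw = gc_percent_windows(ref, GC_WINDOW).gc[contig.name]
    half = GC_WINDOW // 2
    w = np.ones(n_starts, dtype=np.float64)
    if config.coverage_bias is not None:
        cb = np.asarray(config.coverage_bias, dtype=np.float64)
        starts = np.arange(n_starts)
        centers = starts - half  # window centered on the fragment start
        ok = (centers >= 0) & (centers < len(gcw))
        gv = np.full(n_starts, -1, dtype=np.int64)
        gv[ok] = gcw[centers[ok]]
        valid = gv >= 0
        w[valid] = cb[gv[valid]]
    for f in config.planted_features:
        lo = max(f.start - span + 1, 0)
        hi = min(f.end, n_starts)
        if hi > lo:
            w[lo:hi] *= f.weight
    return w


def _compress_cigar(ops: list[tuple[str, int]]) -> str:
    out = []
    for op, ln in ops:
        if out and out[-1][0] == op:
            out[-1][1] += ln
        else:
            out.append([op, ln])
    return "".join(f"{ln}{op}" for op, ln in out)


def simulate_alignments(
    ref: ReferenceModel,
    config: SimConfig,
    out_sam: str | Path,
    event_log_tsv: str | Path | None = None,
) -> EventLog:
    """Sample reads under the configured bias, inject errors, write SAM.

    Only single-contig references are supported (the generator always makes
    one).  Output is coordinate-sorted SAM with true placements; returns the
    event log of injected errors.
    """
    config.validate()
    if len(ref.contigs) != 1:
        raise ValueError("simulate_alignments supports single-contig references")
    contig = ref.contigs[0]
    L = len(contig)
    rl = config.read_length
    rng = np.random.default_rng([config.seed, 1])

    # per-base error probabilities under context multipliers
    gcw = gc_percent_windows(ref, GC_WINDOW).gc[contig.name]
    half = GC_WINDOW // 2
    base_gc = np.full(L, -1, dtype=np.int64)
    if len(gcw):
        base_gc[half:half + len(gcw)] = gcw
    run_len = homopolymer_length_track(ref)[contig.name].astype(np.int64)
    p_del = _per_base_rate(config.deletion_rate, config.deletion_context, base_gc, run_len)
    p_ins = _per_base_rate(config.insertion_rate, config.insertion_context, base_gc, run_len)
    p_mis = _per_base_rate(config.mismatch_rate, config.mismatch_context, base_gc, run_len)

    # fragment sampling
    span = config.fragment_length if config.paired else rl
    w = _fragment_weights(config, ref, span)
    total_reads = int(round(config.target_depth * L / rl))
    if config.paired:
        n_frag = max(total_reads // 2, 1)
    else:
        n_frag = max(total_reads, 1)
    frag_starts = rng.choice(len(w), size=n_frag, p=w / w.sum())
    frag_starts.sort()

    # one record per read: (qname, flag, start, mate_start, tlen)
    if config.paired:
        r1 = frag_starts
        r2 = frag_starts + span - rl
        reads_start = np.concatenate([r1, r2])
        qnames = [f"frag{i}" for i in range(n_frag)] * 2
        flags = np.concatenate([np.full(n_frag, 99), np.full(n_frag, 147)])
        mate_start = np.concatenate([r2, r1])
        tlen = np.concatenate([np.full(n_frag, span), np.full(n_frag, -span)])
    else:
        reads_start = frag_starts
        qnames = [f"read{i}" for i in range(n_frag)]
        flags = np.zeros(n_frag, dtype=np.int64)
        mate_start = np.full(n_frag, -1)
        tlen = np.zeros(n_frag, dtype=np.int64)
    order = np.argsort(reads_start, kind="stable")
    reads_start = reads_start[order]
    qnames = [qnames[i] for i in order]
    flags = flags[order]
    mate_start = mate_start[order]
    tlen = tlen[order]
    n_reads = len(reads_start)

    ref_u8 = np.frombuffer(contig.seq.encode("ascii"), dtype=np.uint8)
    ev_read: list[np.ndarray] = []
    ev_type: list[np.ndarray] = []
    ev_pos: list[np.ndarray] = []
    ev_len: list[np.ndarray] = []

    def log_events(reads, types, poss, lens):
        ev_read.append(np.asarray(reads, dtype=np.int64))
        ev_type.append(np.asarray(types, dtype=np.int64))
        ev_pos.append(np.asarray(poss, dtype=np.int64))
        ev_len.append(np.asarray(lens, dtype=np.int64))

    with open(out_sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{contig.name}\tLN:{L}\n")
        chunk = 200_000
        for lo in range(0, n_reads, chunk):
            hi = min(lo + chunk, n_reads)
            _emit_chunk(
                fh, lo, hi, reads_start, qnames, flags, mate_start, tlen,
                contig.name, ref_u8, p_del, p_ins, p_mis, rl,
                config.insertion_length, rng, log_events, L,
            )

    def cat(parts, dtype=np.int64):
        return np.concatenate(parts) if parts else np.zeros(0, dtype=dtype)

    log = EventLog(
        contig=contig.name,
        read_starts=reads_start,
        retained=np.ones(n_reads, dtype=bool),
        event_read=cat(ev_read),
        event_type=cat(ev_type),
        event_pos=cat(ev_pos),
        event_len=cat(ev_len),
    )
    if event_log_tsv is not None:
        log.to_tsv(event_log_tsv)
    return log


def _emit_chunk(
    fh, lo, hi, reads_start, qnames, flags, mate_start, tlen,
    rname, ref_u8, p_del, p_ins, p_mis, rl, ins_len, rng, log_events, L,
):
    starts = reads_start[lo:hi].astype(np.int64)
    n = len(starts)
    P = starts[:, None] + np.arange(rl, dtype=np.int64)[None, :]
    U = rng.random((n, rl), dtype=np.float32)
    T = p_del[P]
    ev_del = U < T
    T = T + p_ins[P]
    ev_ins = (U < T) & ~ev_del
    T = T + p_mis[P]
    ev_mis = (U < T) & ~ev_del & ~ev_ins
    del T, U

    has_indel = (ev_del | ev_ins).any(axis=1)
    seqs = ref_u8[P]  # ascii codes; modified in place for mismatches

    # simple (indel-free) reads: vectorized mismatch substitution
    simple_mis = ev_mis & ~has_indel[:, None]
    rows, cols = np.nonzero(simple_mis)
    if len(rows):
        orig = seqs[rows, cols]
        # substitute with a uniformly random *different* base
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        shift = rng.integers(1, 4, size=len(rows))
        newcode = (lut[orig].astype(np.int64) + shift) % 4
        seqs[rows, cols] = _BASES[newcode]
        log_events(
            lo + rows, np.full(len(rows), MISMATCH), P[rows, cols], np.ones(len(rows)),
        )

    indel_rows = np.flatnonzero(has_indel)
    indel_records: dict[int, tuple[str, str]] = {}
    for r in indel_rows.tolist():
        seq, cigar = _build_indel_read(
            int(starts[r]), ref_u8, ev_del[r], ev_ins[r], ev_mis[r],
            rl, ins_len, rng, lo + r, log_events, L,
        )
        indel_records[r] = (seq, cigar)

    simple_cigar = f"{rl}M"
    for r in range(n):
        i = lo + r
        if r in indel_records:
            seq, cigar = indel_records[r]
        else:
            seq, cigar = seqs[r].tobytes().decode("ascii"), simple_cigar
        if mate_start[i] >= 0:
            rnext, pnext, tl = "=", int(mate_start[i]) + 1, int(tlen[i])
        else:
            rnext, pnext, tl = "*", 0, 0
        fh.write(
            f"{qnames[i]}\t{int(flags[i])}\t{rname}\t{int(starts[r]) + 1}\t60\t"
            f"{cigar}\t{rnext}\t{pnext}\t{tl}\t{seq}\t*\n"
        )


def _build_indel_read(
    start, ref_u8, row_del, row_ins, row_mis, rl, ins_len, rng, read_index,
    log_events, L,
):
    """Sequentially construct one read that carries indel events.

    Drawn events are indexed by offset within the read's nominal (indel-free)
    span; events whose placement would violate edge rules (leading indel,
    trailing insertion) are silently dropped.  Reference positions walked
    beyond the nominal span (after deletions) carry no events.
    """
    bases: list[int] = []
    ops: list[tuple[str, int]] = []
    reads, types, poss, lens = [], [], [], []
    rpos = start
    emitted = 0
    while emitted < rl and rpos < L:
        col = rpos - start
        in_span = 0 <= col < rl
        if in_span and row_del[col] and emitted > 0:
            ops.append(("D", 1))
            reads.append(read_index); types.append(DELETION); poss.append(rpos); lens.append(1)
            rpos += 1
            continue
        if in_span and row_ins[col] and emitted > 0 and emitted + ins_len < rl:
            ins_bases = rng.integers(0, 4, size=ins_len)
            bases.extend(int(_BASES[b]) for b in ins_bases)
            emitted += ins_len
            ops.append(("I", ins_len))
            reads.append(read_index); types.append(INSERTION); poss.append(rpos); lens.append(ins_len)
        b = int(ref_u8[rpos])
        if in_span and row_mis[col]:
            lut = {65: 0, 67: 1, 71: 2, 84: 3}
            newcode = (lut.get(b, 0) + int(rng.integers(1, 4))) % 4
            b = int(_BASES[newcode])
            reads.append(read_index); types.append(MISMATCH); poss.append(rpos); lens.append(1)
        bases.append(b)
        emitted += 1
        ops.append(("M", 1))
        rpos += 1
    if reads:
        log_events(reads, types, poss, lens)
    return bytes(bases).decode("ascii"), _compress_cigar(ops)


def write_fastq(sam_path: str | Path, fastq_path: str | Path) -> int:
    """Export simulated reads as FASTQ (constant quality) for end-to-end runs
    through a real aligner.  Returns the number of reads written."""
    import pysam

    n = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh, open(fastq_path, "w") as out:
        for read in fh:
            if read.is_secondary or read.is_supplementary:
                continue
            seq = read.query_sequence
            if seq is None:
                continue
            out.write(f"@{read.query_name}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n
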