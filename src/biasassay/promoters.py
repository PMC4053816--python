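"""Transcription-start-site coverage scoring and bad-promoter selection.

A promoter's score is the ratio of mean coverage in the 200 bases
surrounding its TSS to mean coverage in the surrounding 3,000 bases; a
ratio well below 1 marks a locally depressed ("bad") promoter even when the
broader neighborhood is sequenced normally.  Both windows are centered on
the TSS; strand is ignored for window placement.  The n lowest-ratio genes
(after keeping only each gene's lowest-ratio TSS entry) form the bad
promoter list, emitted as the 200-base windows around their TSSs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .covbias import CoverageTrack
from .refseq import GenomicInterval

NEAR_HALF = 100     # surrounding 200 bases
FAR_HALF = 1500     # surrounding 3,000 bases


@dataclass(frozen=True)
class PromoterRecord:
    gene: str
    contig: str
    tss: int
    near_mean: float
    far_mean: float

    @property
    def ratio(self) -> float | None:
        """near/far coverage ratio; None when the far window has no coverage."""
        if self.far_mean == 0:
            return None
        return self.near_mean / self.far_mean


def _window_mean(cov: CoverageTrack, contig_name: str, lo: int, hi: int) -> float:
    """Mean coverage over included bases of [lo, hi) clipped to the contig."""
    contig = cov.ref[contig_name]
    lo, hi = max(lo, 0), min(hi, len(contig))
    if hi <= lo:
        return 0.0
    inc = contig.included[lo:hi]
    n = int(inc.sum())
    if n == 0:
        return 0.0
    return float(cov.counts[contig_name][lo:hi][inc].sum()) / n


def promoter_ratios(
    cov: CoverageTrack, tss_list: list[tuple[str, str, int]]
) -> list[PromoterRecord]:
    """Score each (gene, contig, tss) site by its near/far coverage ratio."""
    out = []
    for gene, contig_name, tss in tss_list:
        if contig_name not in cov.ref:
            raise ValueError(f"TSS on unknown contig {contig_name!r}")
        if not (0 <= tss < len(cov.ref[contig_name])):
            raise ValueError(f"TSS {tss} outside contig {contig_name!r}")
        near = _window_mean(cov, contig_name, tss - NEAR_HALF, tss + NEAR_HALF)
        far = _window_mean(cov, contig_name, tss - FAR_HALF, tss + FAR_HALF)
        out.append(PromoterRecord(gene, contig_name, tss, near, far))
    return out


def select_bad_promoters(
    records: list[PromoterRecord], n: int = 1000, ref=None
) -> list[GenomicInterval]:
    """The n lowest-ratio genes, as 200-base TSS-centered intervals.

    Genes with multiple TSS entries keep only the lowest-ratio entry;
    records with an undefined ratio (no far coverage) are dropped before
    ranking.  Ties are broken by gene name so selection is a total order,
    independent of input order.
    """
    best: dict[str, PromoterRecord] = {}
    for rec in records:
        r = rec.ratio
        if r is None:
            continue
        prev = best.get(rec.gene)
        if prev is None or (r, rec.tss) < (prev.ratio, prev.tss):
            best[rec.gene] = rec
    ranked = sorted(best.values(), key=lambda rec: (rec.ratio, rec.gene))
    out = []
    for rec in ranked[:n]:
        lo = max(rec.tss - NEAR_HALF, 0)
        hi = rec.tss + NEAR_HALF
        if ref is not None:
            hi = min(hi, len(ref[rec.contig]))
        out.append(
            GenomicInterval(rec.contig, lo, hi, f"{rec.gene}|{rec.ratio:.6g}")
        )
    return out


def read_tss_bed(path: str | Path) -> list[tuple[str, str, int]]:
    """Read TSS sites from BED: name column = gene; the TSS is the interval
    start for length-1 (or strand-less) records, else the strand-aware 5' end."""
    out: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            gene = parts[3] if len(parts) > 3 else f"{contig}:{start}"
            strand = parts[5] if len(parts) > 5 else "+"
            tss = start if (end - start == 1 or strand != "-") else end - 1
            out.append((gene, contig, tss))
    return out
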