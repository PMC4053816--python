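"""Shared fixtures: hand-built SAM records and session-scoped simulations.

The heavyweight fixtures simulate full data sets once per session:

* ``sim_biased`` — 1 Mb genome spanning 30-75% GC tracts with planted
  homopolymer runs, sequenced at depth 50 with a 2-fold sampling depletion
  at GC >= 60 and context-dependent errors (deletions x10 inside runs of
  length >= 8).  Ground truth comes from the simulator's event log.
* ``sim_null`` — same genome shape, unbiased and error-free, for null
  (flatness/normalization) checks.
* ``sim_shallow_null`` — 500 kb unbiased at depth 10, where the Poisson
  lower tail is non-trivial.
"""

from __future__ import annotations

import numpy as np
import pytest

import biasassay as ba
from biasassay.refseq import ReferenceModel


# ---------------------------------------------------------------------------
# hand-built SAM helpers

def write_sam(path, ref: ReferenceModel, records: list[dict]) -> str:
    """Write a SAM file from simple record dicts.

    Keys: qname, flag (default 0), contig (default first), pos (0-based),
    mapq (default 60), cigar, seq.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for contig in ref.contigs:
            fh.write(f"@SQ\tSN:{contig.name}\tLN:{len(contig)}\n")
        for i, rec in enumerate(records):
            fh.write(
                "\t".join(
                    [
                        rec.get("qname", f"r{i}"),
                        str(rec.get("flag", 0)),
                        rec.get("contig", ref.contigs[0].name),
                        str(rec.get("pos", 0) + 1),
                        str(rec.get("mapq", 60)),
                        rec["cigar"],
                        "*", "0", "0",
                        rec.get("seq", "*"),
                        "*",
                    ]
                )
                + "\n"
            )
    return str(path)


@pytest.fixture
def make_sam(tmp_path):
    def _make(ref, records, name="reads.sam"):
        return write_sam(tmp_path / name, ref, records)

    return _make


# ---------------------------------------------------------------------------
# session simulations

GC_TRACTS = [(200_000, 30.0), (200_000, 45.0), (200_000, 55.0),
             (200_000, 65.0), (200_000, 75.0)]


def _planted_homopolymers() -> list[tuple[int, str]]:
    # 300 tracts of length 12 spread over the genome so homopolymer bins
    # >= 8 have a usable error-rate denominator
    plants = []
    for i in range(300):
        pos = 1_500 + 3_300 * i
        base = "TGAC"[i % 4]
        plants.append((pos, base * 12))
    return plants


class SimFixture:
    def __init__(self, config, ref, sam_path, log):
        self.config = config
        self.ref = ref
        self.sam = str(sam_path)
        self.log = log


def _simulate(tmp_dir, name, config) -> SimFixture:
    ref = ba.simulate_reference(config)
    sam = tmp_dir / f"{name}.sam"
    log = ba.simulate_alignments(ref, config, sam)
    return SimFixture(config, ref, sam, log)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("sims")


@pytest.fixture(scope="session")
def sim_biased(sim_dir) -> SimFixture:
    cb = np.ones(101)
    cb[60:] = 0.5
    config = ba.SimConfig(
        gc_landscape=GC_TRACTS,
        target_depth=50.0,
        coverage_bias=cb,
        mismatch_rate=0.004,
        deletion_rate=0.0002,
        insertion_rate=0.0001,
        deletion_context=ba.ContextMultipliers(
            homopolymer=np.array([1.0] * 8 + [10.0] * 8)
        ),
        planted_sequences=_planted_homopolymers(),
        seed=1234,
    )
    return _simulate(sim_dir, "biased", config)


@pytest.fixture(scope="session")
def sim_null(sim_dir) -> SimFixture:
    config = ba.SimConfig(gc_landscape=GC_TRACTS, target_depth=50.0, seed=4321)
    return _simulate(sim_dir, "null", config)


@pytest.fixture(scope="session")
def sim_shallow_null(sim_dir) -> SimFixture:
    config = ba.SimConfig(
        gc_landscape=[(500_000, 50.0)], target_depth=10.0, seed=555
    )
    return _simulate(sim_dir, "shallow", config)


PROMOTER_TSS = [7_000 + 13_000 * i for i in range(20)]  # dipped sites
NEUTRAL_TSS = [3_500 + 13_000 * i for i in range(20)]   # control sites


@pytest.fixture(scope="session")
def sim_promoter(sim_dir) -> SimFixture:
    """270 kb at depth 30 with 20 promoter-like coverage depressions."""
    dips = [
        ba.PlantedFeature(t - 100, t + 100, 0.08, label=f"dip{i}")
        for i, t in enumerate(PROMOTER_TSS)
    ]
    config = ba.SimConfig(
        gc_landscape=[(270_000, 50.0)],
        target_depth=30.0,
        planted_features=dips,
        seed=888,
    )
    return _simulate(sim_dir, "promoter", config)


# discovery fixture geometry: GC-rich (85%) tracts bracket and punctuate
# neutral (50%) tracts; half the planted bias loci sit inside rich tracts
# (where the generalized GC>=70 motif explains them), half in neutral context
RICH_LEN, NEUTRAL_LEN = 6_000, 20_000
N_BLOCKS = 5


def discovery_loci() -> tuple[list[ba.PlantedFeature], list[tuple[int, int]], list[tuple[int, int]]]:
    neutral, rich = [], []
    feats = []
    for i in range(N_BLOCKS):
        block = RICH_LEN + i * (NEUTRAL_LEN + RICH_LEN)
        n_start = block + 10_000
        r_start = block + NEUTRAL_LEN + 2_800
        neutral.append((n_start, n_start + 400))
        rich.append((r_start, r_start + 400))
        feats.append(ba.PlantedFeature(n_start, n_start + 400, 0.004, "neutral"))
        feats.append(ba.PlantedFeature(r_start, r_start + 400, 0.004, "gc"))
    return feats, neutral, rich


@pytest.fixture(scope="session")
def sim_discovery(sim_dir) -> SimFixture:
    feats, _, _ = discovery_loci()
    tracts = [(RICH_LEN, 85.0)]
    for _ in range(N_BLOCKS):
        tracts += [(NEUTRAL_LEN, 50.0), (RICH_LEN, 85.0)]
    config = ba.SimConfig(
        gc_landscape=tracts,
        target_depth=30.0,
        planted_features=feats,
        seed=777,
    )
    return _simulate(sim_dir, "discovery", config)


@pytest.fixture(scope="session")
def sim_paired(sim_dir) -> SimFixture:
    config = ba.SimConfig(
        gc_landscape=[(60_000, 50.0)],
        target_depth=20.0,
        paired=True,
        fragment_length=300,
        seed=31,
    )
    return _simulate(sim_dir, "paired", config)


@pytest.fixture(scope="session")
def biased_errors(sim_biased) -> ba.ErrorTrack:
    return ba.count_errors(sim_biased.sam, sim_biased.ref)


@pytest.fixture(scope="session")
def biased_rel(biased_errors) -> ba.RelativeCoverageTrack:
    return ba.relative_coverage(biased_errors.coverage)


@pytest.fixture(scope="session")
def null_rel(sim_null) -> ba.RelativeCoverageTrack:
    return ba.relative_coverage(ba.compute_coverage(sim_null.sam, sim_null.ref))
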