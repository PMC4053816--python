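"""The uncategorized-bias pipeline: undercovered intervals, filters, report."""

import numpy as np
import pytest

import biasassay as ba
from biasassay.covbias import CoverageTrack, compute_coverage, relative_coverage
from biasassay.discovery import (
    ExclusionMask,
    assembly_variation_mask,
    discover_uncategorized,
    diverse_consistency_filter,
    interval_n50,
    split_contigs,
    undercovered_intervals,
)
from biasassay.motifscan import standard_motif_set, scan_motif
from biasassay.refseq import GenomicInterval, from_sequences

from conftest import discovery_loci


def _rel(ref, values):
    return ba.RelativeCoverageTrack(
        ref=ref, values={"c": np.asarray(values, dtype=float)}, mean_coverage=1.0
    )


class TestUndercoveredIntervals:
    def test_low_run_merged(self):
        ref = from_sequences([("c", "AAAA")])
        rel = _rel(ref, [1, 0.05, 0.05, 1])
        assert [(iv.start, iv.end) for iv in undercovered_intervals(rel)] == [(1, 3)]

    def test_uniform_coverage_gives_empty(self):
        ref = from_sequences([("c", "AAAA")])
        assert undercovered_intervals(_rel(ref, [1, 1, 1, 1])) == []

    def test_masked_base_splits_runs(self):
        ref = from_sequences([("c", "AANAA")])
        rel = _rel(ref, [0.0, 0.0, 0.0, 0.0, 0.0])
        assert [(iv.start, iv.end) for iv in undercovered_intervals(rel)] == [(0, 2), (3, 5)]

    def test_threshold_is_inclusive(self):
        ref = from_sequences([("c", "AAA")])
        rel = _rel(ref, [0.1, 0.100001, 1])
        assert [(iv.start, iv.end) for iv in undercovered_intervals(rel, 0.1)] == [(0, 1)]


class TestSplitContigs:
    @pytest.mark.parametrize(
        "length,expected_sizes",
        [
            (100_000, [100_000]),
            (120_000, [60_000, 60_000]),
            (250_001, [83_334, 83_334, 83_333]),
            (49_000, [49_000]),
        ],
    )
    def test_piece_sizes(self, length, expected_sizes):
        pieces = split_contigs([("c", "A" * length)])
        assert [len(s) for _, s in pieces] == expected_sizes
        for _, s in pieces:
            if length > 100_000:
                assert 50_000 <= len(s) <= 100_000

    def test_sequence_content_preserved(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=150_000))
        pieces = split_contigs([("c", seq)])
        assert "".join(s for _, s in pieces) == seq
        assert [n for n, _ in pieces] == ["c.1", "c.2"]


class TestAssemblyVariationMask:
    def test_gap_bases_excluded(self, make_sam):
        ref = from_sequences([("c", "A" * 1200)])
        seq = "A" * 1000
        sam = make_sam(ref, [dict(pos=0, cigar="500M200D500M", seq=seq)])
        mask = assembly_variation_mask(sam, ref)
        assert mask.excluded("c")[500:700].all()
        # a 200-base deletion also trips the >5-errors rule in windows
        # overlapping the gap, so exclusion may extend < 100 bases into the
        # flanks — but no further
        assert not mask.excluded("c")[:401].any()
        assert not mask.excluded("c")[799:].any()
        assert mask.provenance_counts()["assembly_gap"] == 200

    def test_more_than_five_errors_rule_boundary(self, make_sam, tmp_path):
        ref = from_sequences([("c", "A" * 2000)])
        # contig alignment with exactly 5 mismatches in one 100-base window
        def contig_with(n_mismatch):
            seq = list("A" * 1500)
            for k in range(n_mismatch):
                seq[700 + 2 * k] = "C"
            return dict(pos=0, cigar="1500M", seq="".join(seq))

        m5 = assembly_variation_mask(make_sam(ref, [contig_with(5)], "m5.sam"), ref)
        m6 = assembly_variation_mask(make_sam(ref, [contig_with(6)], "m6.sam"), ref)
        assert not m5.excluded("c").any()
        assert m6.excluded("c").any()
        assert m6.provenance_counts()["high_error_window"] > 0

    def test_perfect_alignment_gives_empty_mask(self, make_sam):
        ref = from_sequences([("c", "ACGT" * 300)])
        sam = make_sam(ref, [dict(pos=0, cigar="1200M", seq="ACGT" * 300)])
        mask = assembly_variation_mask(sam, ref)
        assert not any(m.any() for m in (mask.excluded("c"),))

    def test_insertions_count_toward_window_errors(self, make_sam):
        ref = from_sequences([("c", "A" * 1000)])
        # 6 inserted bases at one point -> exceeds the 5-error window rule
        sam = make_sam(ref, [dict(pos=0, cigar="400M6I400M", seq="A" * 806)])
        mask = assembly_variation_mask(sam, ref)
        assert mask.excluded("c").any()
        assert mask.provenance_counts()["assembly_gap"] == 0


class TestDiverseConsistencyFilter:
    def _tracks(self, ref, diverse_vals, sample_vals):
        div = [_rel(ref, v) for v in diverse_vals]
        smp = [_rel(ref, v) for v in sample_vals]
        return div, smp

    def test_rule_truth_table(self):
        ref = from_sequences([("c", "A")])
        cases = [
            # (diverse, samples, excluded?)
            ([0.6], [0.05, 0.08, 0.02], True),
            ([0.6], [0.05, 0.2, 0.02], False),   # not undercovered in all
            ([0.3], [0.0, 0.0, 0.0], False),     # never well covered
            ([0.5], [0.09, 0.09, 0.09], True),   # thresholds inclusive/strict
            ([0.6], [0.1, 0.05, 0.05], False),   # 0.1 is not < 0.1
        ]
        for div_vals, samp_vals, want in cases:
            div, smp = self._tracks(ref, [[v] for v in div_vals],
                                    [[v] for v in samp_vals])
            mask = diverse_consistency_filter(div, smp)
            assert bool(mask.excluded("c")[0]) is want, (div_vals, samp_vals)

    def test_max_over_diverse_tracks(self):
        ref = from_sequences([("c", "AA")])
        div, smp = self._tracks(
            ref, [[0.1, 0.9], [0.6, 0.1]], [[0.0, 0.0]]
        )
        mask = diverse_consistency_filter(div, smp)
        assert mask.excluded("c").tolist() == [True, True]


class TestIntervalN50:
    def test_matches_sort_and_accumulate_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            lengths = rng.integers(1, 500, size=rng.integers(1, 40)).tolist()
            ivs = []
            pos = 0
            for ln in lengths:
                ivs.append(GenomicInterval("c", pos, pos + ln))
                pos += ln + 10
            # oracle: sort descending, accumulate to half the total
            want = None
            total = sum(lengths)
            acc = 0
            for ln in sorted(lengths, reverse=True):
                acc += ln
                if acc >= total / 2:
                    want = ln
                    break
            assert interval_n50(ivs) == want

    def test_empty_is_undefined(self):
        assert interval_n50([]) is None


class TestDiscoverUncategorized:
    def test_undercovered_inside_motif_vanishes(self):
        ref = from_sequences([("c", "A" * 100)])
        rel = _rel(ref, [0.0] * 100)
        report = discover_uncategorized(
            rel, None, None, [GenomicInterval("c", 0, 100)], [], ref
        )
        assert report.intervals == []
        assert report.base_count == 0

    def test_no_filters_reproduces_undercovered_intervals(self, sim_discovery):
        ref = sim_discovery.ref
        rel = relative_coverage(compute_coverage(sim_discovery.sam, ref))
        plain = undercovered_intervals(rel, 0.1)
        report = discover_uncategorized(rel, None, None, [], [], ref)
        assert [(iv.start, iv.end) for iv in report.intervals] == [
            (iv.start, iv.end) for iv in plain
        ]
        assert report.base_count == sum(iv.length for iv in plain)

    def test_filters_only_remove_bases(self, sim_discovery):
        ref = sim_discovery.ref
        rel = relative_coverage(compute_coverage(sim_discovery.sam, ref))
        motifs = []
        for spec in standard_motif_set(generalized=True):
            motifs.extend(scan_motif(ref, spec))
        unfiltered = discover_uncategorized(rel, None, None, [], [], ref)
        filtered = discover_uncategorized(rel, None, None, motifs, [], ref)
        assert filtered.base_count <= unfiltered.base_count
        # monotone subset property
        unf = ref.interval_mask(unfiltered.intervals)["sim"]
        fil = ref.interval_mask(filtered.intervals)["sim"]
        assert not (fil & ~unf).any()

    def test_planted_neutral_loci_recovered_and_gc_loci_filtered(self, sim_discovery):
        """Ten bias loci were planted: five inside GC-rich tracts (where the
        generalized GC motif explains them) and five in neutral sequence.
        The pipeline must report exactly the neutral five."""
        ref = sim_discovery.ref
        rel = relative_coverage(compute_coverage(sim_discovery.sam, ref))
        motifs = []
        for spec in standard_motif_set(generalized=True):
            motifs.extend(scan_motif(ref, spec))
        report = discover_uncategorized(rel, None, None, motifs, [], ref)
        _, neutral, rich = discovery_loci()

        def overlaps(iv, lo, hi):
            return iv.start < hi and iv.end > lo

        hit_neutral = [
            any(overlaps(iv, lo, hi) for iv in report.intervals) for lo, hi in neutral
        ]
        hit_rich = [
            any(overlaps(iv, lo, hi) for iv in report.intervals) for lo, hi in rich
        ]
        assert all(hit_neutral)
        assert not any(hit_rich)
        # nothing reported far away from the planted neutral loci
        for iv in report.intervals:
            assert any(iv.start < hi + 300 and iv.end > lo - 300 for lo, hi in neutral), iv

    def test_report_annotations_consistent(self, sim_discovery):
        ref = sim_discovery.ref
        rel = relative_coverage(compute_coverage(sim_discovery.sam, ref))
        report = discover_uncategorized(rel, None, None, [], [], ref)
        assert len(report.gc_fraction) == len(report.intervals)
        assert report.base_count == sum(iv.length for iv in report.intervals)
        assert report.genome_fraction == pytest.approx(
            report.base_count / ref.included_base_count
        )
        assert report.interval_n50 == interval_n50(report.intervals)
        df = report.to_dataframe()
        assert list(df.columns) == [
            "contig", "start", "end", "length", "gc_fraction", "homopolymer_n50"
        ]

    def test_provenance_first_category_wins(self):
        ref = from_sequences([("c", "A" * 10)])
        mask = ExclusionMask.empty(ref)
        where = np.zeros(10, dtype=bool)
        where[2:6] = True
        mask.add("c", where, 1)
        where2 = np.zeros(10, dtype=bool)
        where2[4:8] = True
        mask.add("c", where2, 3)
        counts = mask.provenance_counts()
        assert counts["assembly_gap"] == 4
        assert counts["diverse_consistent"] == 2
        assert int(mask.excluded("c").sum()) == 6
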