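"""Anchor aligner, PAF I/O, block merging and orientation classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sdlocus.core import GenomicInterval, LocusMap
from sdlocus import homology, synth
from conftest import match_planted_block


def random_dna(n, seed):
    rng = np.random.default_rng(seed)
    return synth.decode_sequence(rng.integers(0, 4, size=n, dtype=np.uint8))


class TestAnchorAlign:
    def test_identical_sequences_single_full_identity_record(self):
        seq = random_dna(10_000, 0)
        other = seq[:5000] + seq[5000:]  # equal content, distinct object
        records = homology.anchor_align(seq, other, qname="a", tname="b")
        assert len(records) == 1
        r = records[0]
        assert (r.strand, r.identity) == ("+", 1.0)
        assert (r.qstart, r.qend) == (0, 10_000)

    def test_reverse_complement_aligns_on_minus_strand(self):
        seq = random_dna(10_000, 1)
        rc = synth.decode_sequence(synth.revcomp_codes(synth.encode_sequence(seq)))
        records = homology.anchor_align(seq, rc, qname="a", tname="b")
        assert len(records) == 1
        assert records[0].strand == "-"
        assert records[0].identity == 1.0
        assert (records[0].tstart, records[0].tend) == (0, 10_000)

    def test_identity_counts_planted_mismatches_exactly(self):
        # two 1 kbp copies differing at exactly 10 evenly spaced sites
        src = random_dna(1000, 2)
        alt = {"A": "C", "C": "G", "G": "T", "T": "A"}
        copy = list(src)
        for pos in range(50, 1000, 95):
            copy[pos] = alt[copy[pos]]
        records = homology.anchor_align(
            src, "".join(copy), min_chain_bp=500, qname="a", tname="b"
        )
        assert len(records) == 1
        assert records[0].identity == pytest.approx(0.990, abs=1e-9)

    def test_degenerate_k_returns_empty(self):
        assert homology.anchor_align("ACGTACGTACGT", "ACGTACGTACGT", k=20) == []

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            homology.anchor_align("ACGT" * 100, "ACGT" * 100, k=9)

    def test_self_alignment_excludes_trivial_diagonal(self):
        seq = random_dna(20_000, 3)
        assert homology.anchor_align(seq, seq) == []


class TestPafIO:
    @staticmethod
    def record(**kw):
        base = dict(
            qname="q", qlen=5000, qstart=100, qend=1100, strand="+",
            tname="t", tlen=8000, tstart=2000, tend=3000,
            matches=990, block_len=1000,
        )
        base.update(kw)
        return homology.AlignmentRecord(**base)

    def test_identity_is_column_arithmetic(self):
        assert self.record().identity == pytest.approx(0.990)

    def test_round_trip_is_lossless(self, tmp_path):
        records = [
            self.record(),
            self.record(strand="-", qstart=0, qend=500, matches=450,
                        block_len=500, tstart=7000, tend=7500),
        ]
        path = tmp_path / "aln.paf"
        homology.write_paf(records, path)
        assert homology.read_paf(path) == records

    @given(
        qstart=st.integers(0, 1000),
        span=st.integers(100, 5000),
        matches_frac=st.floats(0.5, 1.0),
        strand=st.sampled_from("+-"),
    )
    def test_round_trip_property(self, tmp_path_factory, qstart, span,
                                 matches_frac, strand):
        rec = self.record(
            qstart=qstart, qend=qstart + span, strand=strand,
            tstart=0, tend=span, qlen=qstart + span + 10, tlen=span,
            matches=max(1, int(span * matches_frac)), block_len=span,
        )
        path = tmp_path_factory.mktemp("paf") / "one.paf"
        homology.write_paf([rec], path)
        assert homology.read_paf(path) == [rec]

    def test_malformed_row_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "aln.paf"
        homology.write_paf([self.record() for _ in range(10)], path)
        lines = path.read_text().splitlines()
        lines[4] = "garbage\trow"
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level("WARNING", logger="sdlocus.homology"):
            records = homology.read_paf(path)
        assert len(records) == 9
        assert any("skipped" in m for m in caplog.messages)


class TestMergeToBlocks:
    @staticmethod
    def rec(qs, qe, ts, te, strand="+", identity=0.99):
        span = qe - qs
        return homology.AlignmentRecord(
            qname="s", qlen=100_000, qstart=qs, qend=qe, strand=strand,
            tname="s", tlen=100_000, tstart=ts, tend=te,
            matches=int(span * identity), block_len=span,
        )

    def test_adjacent_records_merge_into_one_block(self):
        records = [self.rec(0, 2000, 50_000, 52_000),
                   self.rec(2100, 4000, 52_100, 54_000)]
        blocks = homology.merge_to_blocks(records, max_join_gap=200)
        assert len(blocks) == 1
        assert blocks[0].a.length() == 4000

    def test_distant_records_stay_separate(self):
        records = [self.rec(0, 2000, 50_000, 52_000),
                   self.rec(9000, 11_000, 59_000, 61_000)]
        assert len(homology.merge_to_blocks(records, max_join_gap=200)) == 2

    def test_orientations_never_merge(self):
        records = [self.rec(0, 2000, 50_000, 52_000, "+"),
                   self.rec(2100, 4000, 52_100, 54_000, "-")]
        blocks = homology.merge_to_blocks(records, max_join_gap=500)
        assert {b.orientation for b in blocks} == {"direct", "inverted"}

    def test_same_query_different_target_copies_not_merged(self):
        # one query repeat aligning to two separate target copies
        records = [self.rec(0, 2000, 50_000, 52_000),
                   self.rec(0, 2000, 80_000, 82_000)]
        assert len(homology.merge_to_blocks(records)) == 2

    def test_identity_and_length_filters(self):
        records = [self.rec(0, 2000, 50_000, 52_000, identity=0.85)]
        assert homology.merge_to_blocks(records, min_identity=0.9) == []
        records = [self.rec(0, 500, 50_000, 50_500)]
        assert homology.merge_to_blocks(records, min_len=1000) == []


class TestPlantedArchitectureRecovery:
    def test_every_planted_copy_recovered_once(self, human_arch):
        _, _, truth, _, blocks = human_arch
        for pair in truth.sd_pairs:
            block = match_planted_block(blocks, pair)
            assert block is not None, f"{pair.copy.label} not recovered"
            assert block.orientation == pair.orientation
            assert (
                abs(block.length - pair.copy.length())
                <= 0.05 * pair.copy.length()
            )
            assert abs(block.identity - pair.identity) <= 0.003

    def test_bp_pair_ranking_matches_architecture(self, human_arch):
        _, _, truth, _, blocks = human_arch
        comparisons = homology.compare_bps(truth.locus_map, blocks)
        top3 = {c.pair for c in comparisons[:3]}
        assert top3 == {("BP1", "BP3"), ("BP2", "BP3"), ("BP4", "BP5")}

    def test_totals_split_by_orientation(self, human_arch):
        _, _, truth, _, blocks = human_arch
        comparisons = homology.compare_bps(truth.locus_map, blocks)
        by_pair = {c.pair: c for c in comparisons}
        c13 = by_pair[("BP1", "BP3")]
        assert c13.direct_bp > c13.inverted_bp > 0
        assert c13.total_bp == c13.direct_bp + c13.inverted_bp

    def test_compare_bps_is_symmetric_in_block_sides(self, human_arch):
        _, _, truth, _, blocks = human_arch
        swapped = [
            homology.SDBlock(
                a=b.b, b=b.a, identity=b.identity,
                orientation=b.orientation, length=b.length,
            )
            for b in blocks
        ]
        totals = {
            c.pair: (c.direct_bp, c.inverted_bp)
            for c in homology.compare_bps(truth.locus_map, blocks)
        }
        swapped_totals = {
            c.pair: (c.direct_bp, c.inverted_bp)
            for c in homology.compare_bps(truth.locus_map, swapped)
        }
        assert totals == swapped_totals

    def test_no_blocks_no_comparisons(self, human_arch):
        _, _, truth, _, _ = human_arch
        assert homology.compare_bps(truth.locus_map, []) == []


class TestClassifyRegionOrientation:
    region = GenomicInterval("ref", 10_000, 20_000, label="R")

    @staticmethod
    def rec(ts, te, strand):
        span = te - ts
        return homology.AlignmentRecord(
            qname="sp", qlen=50_000, qstart=0, qend=span, strand=strand,
            tname="ref", tlen=50_000, tstart=ts, tend=te,
            matches=span, block_len=span,
        )

    def test_fully_covered_plus_region_is_direct(self):
        assert homology.classify_region_orientation(
            [self.rec(9000, 21_000, "+")], self.region
        ) == "direct"

    def test_even_strand_split_is_unresolved(self):
        records = [self.rec(10_000, 15_500, "+"), self.rec(15_500, 20_000, "-")]
        assert (
            homology.classify_region_orientation(records, self.region)
            == "unresolved"
        )

    def test_low_coverage_is_unresolved(self):
        assert homology.classify_region_orientation(
            [self.rec(10_000, 12_000, "+")], self.region
        ) == "unresolved"

    def test_inverted_species_region_classified_from_alignment(self):
        # an orangutan-like haplotype with one region physically inverted
        tree_seq = random_dna(60_000, 5)
        region = GenomicInterval("ref", 20_000, 40_000, label="R")
        codes = synth.encode_sequence(tree_seq)
        codes[region.start : region.end] = synth.revcomp_codes(
            codes[region.start : region.end]
        )
        species = synth.decode_sequence(codes)
        records = homology.anchor_align(
            species, tree_seq, qname="sp", tname="ref"
        )
        assert homology.classify_region_orientation(records, region) == "inverted"
        outside = GenomicInterval("ref", 0, 20_000)
        assert homology.classify_region_orientation(records, outside) == "direct"


class TestDuplicatedLength:
    def test_disjoint_blocks_sum_both_sides(self):
        blocks = [
            homology.SDBlock(
                a=GenomicInterval("s", 0, 10_000),
                b=GenomicInterval("s", 50_000, 60_000),
                identity=0.99, orientation="direct", length=10_000,
            ),
            homology.SDBlock(
                a=GenomicInterval("s", 20_000, 30_000),
                b=GenomicInterval("s", 70_000, 80_000),
                identity=0.99, orientation="direct", length=10_000,
            ),
        ]
        assert homology.duplicated_length(blocks) == 40_000

    def test_overlapping_sides_count_once(self):
        blocks = [
            homology.SDBlock(
                a=GenomicInterval("s", 0, 10_000),
                b=GenomicInterval("s", 5000, 15_000),
                identity=0.99, orientation="direct", length=10_000,
            )
        ]
        assert homology.duplicated_length(blocks) == 15_000

    def test_fold_change_guards_zero_denominator(self):
        assert homology.fold_change(30, 10) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            homology.fold_change(30, 0)
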