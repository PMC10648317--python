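"""The synthetic-data generator: planted divergence, inheritance,
strand-count simulation, probe-order simulation, determinism."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sdlocus.core import GenomicInterval, SpeciesTree
from sdlocus import synth


def two_segment_blueprint(identity, orientation, length=10_000, seed=0):
    return synth.LocusBlueprint(
        name="toy",
        segments=[
            synth.SegmentSpec("unique", "src", length, block="BP1"),
            synth.SegmentSpec("unique", "gap", 2000, region="BP1-BP2"),
            synth.SegmentSpec(
                "sd_copy", "cpy", source_id="src", identity=identity,
                orientation=orientation, block="BP2",
            ),
        ],
        scale=1,
        seed=seed,
    )


class TestBuildAncestralLocus:
    def test_copy_divergence_matches_binomial_expectation(self):
        # 10 kbp copy at 99%: mismatches ~ Binomial(10000, 0.01)
        seq, truth = synth.build_ancestral_locus(
            two_segment_blueprint(0.99, "direct")
        )
        src = truth.segments["src"]
        cpy = truth.segments["cpy"]
        mism = sum(
            1
            for a, b in zip(seq[src.start : src.end], seq[cpy.start : cpy.end])
            if a != b
        )
        sd = np.sqrt(10_000 * 0.01 * 0.99)
        assert abs(mism - 100) <= 3 * sd

    def test_identity_one_direct_copy_is_byte_identical(self):
        seq, truth = synth.build_ancestral_locus(
            two_segment_blueprint(1.0, "direct")
        )
        src, cpy = truth.segments["src"], truth.segments["cpy"]
        assert seq[src.start : src.end] == seq[cpy.start : cpy.end]

    def test_identity_one_inverted_copy_is_reverse_complement(self):
        seq, truth = synth.build_ancestral_locus(
            two_segment_blueprint(1.0, "inverted")
        )
        src, cpy = truth.segments["src"], truth.segments["cpy"]
        rc = synth.decode_sequence(
            synth.revcomp_codes(synth.encode_sequence(seq[cpy.start : cpy.end]))
        )
        assert rc == seq[src.start : src.end]

    @given(s=st.text(alphabet="ACGT", min_size=1, max_size=200))
    def test_reverse_complement_is_an_involution(self, s):
        codes = synth.encode_sequence(s)
        assert synth.decode_sequence(
            synth.revcomp_codes(synth.revcomp_codes(codes))
        ) == s

    def test_identity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            two_segment_blueprint(0.7, "direct")

    def test_dangling_source_rejected(self):
        with pytest.raises(ValueError):
            synth.LocusBlueprint(
                name="bad",
                segments=[
                    synth.SegmentSpec(
                        "sd_copy", "c", source_id="nowhere", identity=0.99
                    )
                ],
            )

    def test_seed_determinism(self):
        a, _ = synth.build_ancestral_locus(two_segment_blueprint(0.95, "direct"))
        b, _ = synth.build_ancestral_locus(two_segment_blueprint(0.95, "direct"))
        assert a == b


@pytest.fixture(scope="module")
def history():
    tree = SpeciesTree.default()
    blueprint = synth.inversion_history_blueprint(seed=3)
    ancestral, truth = synth.build_ancestral_locus(
        blueprint, np.random.default_rng(3)
    )
    return tree, blueprint, ancestral, truth


class TestEvolveHaplotypes:
    def test_event_inherited_by_descendants_only(self, history):
        tree, _, ancestral, truth = history
        events = [
            synth.EventSpec(
                "African great ape ancestor", "inversion", region="BP1-BP2"
            )
        ]
        haps, _ = synth.evolve_haplotypes(
            tree, ancestral, events, truth.locus_map, realize_sequence=False
        )
        for sp in ("HSA", "PTR", "GGO"):
            assert haps[sp][0].region_states["BP1-BP2"] == "inv"
        for sp in ("PPY", "MMU", "CJA"):
            assert haps[sp][0].region_states["BP1-BP2"] == "dir"

    def test_no_events_leaves_all_species_ancestral(self, history):
        tree, _, ancestral, truth = history
        haps, _ = synth.evolve_haplotypes(tree, ancestral, [], truth.locus_map)
        for sp in tree.leaf_labels:
            assert haps[sp][0].sequence == ancestral
            assert haps[sp][1].sequence == ancestral

    def test_double_inversion_restores_ancestral_orientation(self, history):
        tree, _, ancestral, truth = history
        events = [
            synth.EventSpec("Catarrhini ancestor", "inversion", region="BP2-BP3"),
            synth.EventSpec("MMU", "inversion", region="BP2-BP3"),
        ]
        haps, _ = synth.evolve_haplotypes(
            tree, ancestral, events, truth.locus_map
        )
        assert haps["MMU"][0].region_states["BP2-BP3"] == "dir"
        assert haps["MMU"][0].sequence == ancestral
        assert haps["PPY"][0].region_states["BP2-BP3"] == "inv"

    def test_het_event_applies_to_second_haplotype_only(self, history):
        tree, _, ancestral, truth = history
        events = [
            synth.EventSpec("GGO", "inversion", region="BP3-BP4",
                            zygosity="het", species="GGO")
        ]
        haps, _ = synth.evolve_haplotypes(
            tree, ancestral, events, truth.locus_map, realize_sequence=False
        )
        assert haps["GGO"][0].region_states["BP3-BP4"] == "dir"
        assert haps["GGO"][1].region_states["BP3-BP4"] == "inv"

    def test_unknown_branch_rejected(self, history):
        tree, _, ancestral, truth = history
        with pytest.raises(ValueError, match="unknown branch"):
            synth.evolve_haplotypes(
                tree, ancestral,
                [synth.EventSpec("Strepsirrhini", "inversion", region="BP1-BP2")],
                truth.locus_map,
            )


def plain_haplotype(hap_index, inversions=(), deletions=(), L=50_000):
    return synth.Haplotype(
        species="X", hap_index=hap_index, length=L, sequence=None,
        inversions=list(inversions), deletions=list(deletions),
        region_states={}, chrom="locus",
    )


class TestStrandSeqSimulation:
    def test_noise_free_cells_are_single_strand(self):
        rng = np.random.default_rng(0)
        pair = (plain_haplotype(0), plain_haplotype(1))
        matrix, templates = synth.simulate_strandseq_cells(
            pair, 20, 1000, 40.0, 0.0, rng
        )
        for idx, (t1, t2) in enumerate(templates):
            if t1 == t2 == "W":
                assert matrix.C[idx].sum() == 0
            if t1 == t2 == "C":
                assert matrix.W[idx].sum() == 0

    def test_homozygous_inversion_gives_complete_switch(self):
        rng = np.random.default_rng(1)
        inv = GenomicInterval("locus", 10_000, 20_000)
        pair = (
            plain_haplotype(0, inversions=[inv]),
            plain_haplotype(1, inversions=[inv]),
        )
        matrix, templates = synth.simulate_strandseq_cells(
            pair, 20, 1000, 40.0, 0.0, rng
        )
        inside = matrix.bin_mask(inv)
        ww = [i for i, (a, b) in enumerate(templates) if a == b == "W"]
        assert ww, "expected at least one WW cell"
        assert matrix.W[np.ix_(ww, np.flatnonzero(inside))].sum() == 0
        assert matrix.C[np.ix_(ww, np.flatnonzero(~inside))].sum() == 0

    def test_het_inversion_minority_fraction_near_half(self):
        rng = np.random.default_rng(2)
        inv = GenomicInterval("locus", 10_000, 30_000)
        pair = (plain_haplotype(0), plain_haplotype(1, inversions=[inv]))
        matrix, templates = synth.simulate_strandseq_cells(
            pair, 12, 1000, 100.0, 0.0, rng
        )
        inside = np.flatnonzero(matrix.bin_mask(inv))
        ww = [i for i, (a, b) in enumerate(templates) if a == b == "W"]
        assert ww
        c_in = matrix.C[np.ix_(ww, inside)].sum()
        n_in = (matrix.W + matrix.C)[np.ix_(ww, inside)].sum()
        se = np.sqrt(0.25 / n_in)
        assert abs(c_in / n_in - 0.5) <= 3 * se

    def test_strand_totals_conserve_reads_per_cell(self):
        rng = np.random.default_rng(3)
        pair = (plain_haplotype(0), plain_haplotype(1))
        matrix, _ = synth.simulate_strandseq_cells(pair, 5, 1000, 20.0, 0.1, rng)
        assert (matrix.total_reads() == (matrix.W + matrix.C).sum(axis=1)).all()
        assert (matrix.total_reads() > 0).all()

    def test_bin_size_larger_than_sequence_rejected(self):
        pair = (plain_haplotype(0, L=500), plain_haplotype(1, L=500))
        with pytest.raises(ValueError):
            synth.simulate_strandseq_cells(
                pair, 2, 1000, 10.0, 0.0, np.random.default_rng(0)
            )

    def test_count_matrix_round_trips_through_directory(self, tmp_path):
        from sdlocus.strand import CellCountMatrix

        rng = np.random.default_rng(4)
        pair = (plain_haplotype(0), plain_haplotype(1))
        matrix, _ = synth.simulate_strandseq_cells(pair, 4, 1000, 15.0, 0.05, rng)
        matrix.write_dir(tmp_path / "counts")
        back = CellCountMatrix.read_dir(tmp_path / "counts")
        assert (back.W == matrix.W).all() and (back.C == matrix.C).all()
        assert [b.start for b in back.bins] == [b.start for b in matrix.bins]


class TestFishSimulation:
    region = GenomicInterval("locus", 10_000, 40_000, label="R")
    probes = [("red", 12_000), ("green", 30_000), ("blue", 45_000)]

    def hap(self, state, deletions=()):
        return synth.Haplotype(
            species="X", hap_index=0, length=50_000, sequence=None,
            inversions=[], deletions=list(deletions),
            region_states={"R": state}, chrom="locus",
        )

    def test_direct_haplotype_reads_in_reference_order(self):
        obs = synth.simulate_fish_observations(
            (self.hap("dir"), self.hap("dir")), self.probes, self.region
        )
        assert obs == ["red-green-blue", "red-green-blue"]

    def test_inverted_haplotype_swaps_inner_pair(self):
        obs = synth.simulate_fish_observations(
            (self.hap("inv"), self.hap("dir")), self.probes, self.region
        )
        assert obs == ["green-red-blue", "red-green-blue"]

    def test_noise_free_observations_are_deterministic(self):
        runs = {
            tuple(
                synth.simulate_fish_observations(
                    (self.hap("dir"), self.hap("inv")), self.probes, self.region,
                    flip_noise=0.0, rng=np.random.default_rng(idx),
                )
            )
            for idx in range(100)
        }
        assert len(runs) == 1

    def test_deleted_probe_leaves_two_signals(self):
        deleted = self.hap("dir", deletions=[GenomicInterval("locus", 11_000, 13_000)])
        obs = synth.simulate_fish_observations(
            (deleted, self.hap("dir")), self.probes, self.region
        )
        assert obs[0] == "green-blue"
        assert obs[1] == "red-green-blue"

    def test_wrong_probe_count_rejected(self):
        with pytest.raises(ValueError):
            synth.simulate_fish_observations(
                (self.hap("dir"), self.hap("dir")),
                self.probes[:2], self.region,
            )


class TestDeterminism:
    def test_same_seed_gives_identical_fasta_and_counts(self, tmp_path):
        outputs = []
        for run in ("a", "b"):
            tree = SpeciesTree.default()
            blueprint = synth.inversion_history_blueprint(seed=11)
            rng = np.random.default_rng(11)
            ancestral, truth = synth.build_ancestral_locus(blueprint, rng)
            haps, truth = synth.evolve_haplotypes(
                tree, ancestral, synth.table1_history_events(), truth.locus_map,
                truth=truth,
            )
            path = tmp_path / f"{run}.fasta"
            synth.write_haplotypes_fasta(haps, path)
            matrix, _ = synth.simulate_strandseq_cells(
                haps["GGO"], 10, 1000, 20.0, 0.05, rng
            )
            outputs.append((path.read_bytes(), matrix.W.copy(), matrix.C.copy()))
        assert outputs[0][0] == outputs[1][0]
        assert (outputs[0][1] == outputs[1][1]).all()
        assert (outputs[0][2] == outputs[1][2]).all()
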