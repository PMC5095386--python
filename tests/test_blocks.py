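"""Block segmentation, extension, phasing and crossover calling."""

import numpy as np
import pytest

from coscape import blocks, markers, pipeline, simulate
from coscape.blocks import (
    HET,
    HOM,
    HOM_A,
    HOM_B,
    GenotypeSequence,
    ReferenceHaplotypeError,
    call_crossovers,
    extend_blocks,
    find_seeds,
    merge_seeds,
    segment,
)
from coscape.markers import GenotypeCall

from conftest import make_matrix


def seq_of(labels, pos=None, sample="s", chrom="c"):
    labels = np.asarray(labels, dtype=np.int8)
    if pos is None:
        pos = np.arange(len(labels)) * 1000 + 1  # 1 kbp spacing
    return GenotypeSequence(sample=sample, chrom=chrom, pos=np.asarray(pos), labels=labels)


class TestSeeds:
    def test_run_of_25_spanning_over_10kbp_is_a_seed(self):
        s = seq_of([HET] * 25, pos=np.linspace(0, 12_000, 25).astype(int))
        assert find_seeds(s) == [(0, 24, HET)]

    def test_span_not_over_10kbp_is_rejected(self):
        s = seq_of([HET] * 25, pos=np.linspace(0, 9_000, 25).astype(int))
        assert find_seeds(s) == []
        # boundary: span exactly 10 kbp fails the strict "over"
        s = seq_of([HET] * 25, pos=np.linspace(0, 10_000, 25).astype(int))
        assert find_seeds(s) == []

    def test_24_markers_insufficient(self):
        s = seq_of([HET] * 24, pos=np.linspace(0, 20_000, 24).astype(int))
        assert find_seeds(s, k=25) == []

    def test_alternating_labels_yield_no_seeds(self):
        s = seq_of([HET, HOM] * 30)
        assert find_seeds(s) == []

    def test_empty_sequence(self):
        assert find_seeds(seq_of([])) == []


class TestMergeExtend:
    def test_same_label_seeds_fuse_absorbing_noise(self):
        lab = [HET] * 25 + [HOM, HET, HOM] + [HET] * 25
        s = seq_of(lab)
        seeds = find_seeds(s, k=25, min_span=10_000)
        assert len(seeds) == 2
        merged = merge_seeds(seeds, s)
        assert len(merged) == 1
        assert merged[0].label == HET
        assert merged[0].n_mismatch == 2
        assert merged[0].n_markers == 53

    def test_opposing_seed_prevents_merge(self):
        lab = [HET] * 25 + [HOM] * 25 + [HET] * 25
        s = seq_of(lab)
        merged = merge_seeds(find_seeds(s), s)
        assert [b.label for b in merged] == [HET, HOM, HET]

    def test_single_seed_single_block(self):
        s = seq_of([HOM] * 30)
        merged = merge_seeds(find_seeds(s), s)
        assert len(merged) == 1 and merged[0].n_markers == 30

    @pytest.mark.parametrize("gap,expected_reach", [
        ([], 0),
        ([HOM, HOM], 0),                      # zero matching markers: no extension
        ([HET, HET, HET], 3),                 # all matching: extend to the furthest
        ([HET, HET, HET, HOM, HET, HET], 6),  # score recovers: furthest maximum
        ([HET, HOM, HOM, HET], 1),            # declining proportion stops extension
        ([HET, HOM, HET, HOM], 3),            # tie (score 1 after idx 1 and 3): furthest wins
    ])
    def test_extension_reach_against_prefix_oracle(self, gap, expected_reach):
        gap = np.asarray(gap, dtype=np.int8)
        j, _ = blocks._extension_reach(gap, HET)
        # brute-force oracle: furthest matching prefix with maximal score
        best, best_j = 0, 0
        score = 0
        for i, lab in enumerate(gap, start=1):
            score += 1 if lab == HET else -1
            if lab == HET and score >= best and score > 0:
                best, best_j = score, i
        assert j == best_j == expected_reach

    def test_adjacent_runs_leave_no_gap(self):
        # the two long runs absorb the leading gap markers into their own seeds
        lab = [HET] * 25 + [HET, HET, HOM, HOM, HOM] + [HOM] * 25
        s = seq_of(lab)
        out = segment(s, k=25, min_span=10_000)
        assert [b.label for b in out] == [HET, HOM]
        assert out[0].last == 26  # the two matching gap markers joined the run
        assert out[1].first == 27

    def test_contested_gap_split_maximizes_total_score(self):
        # gap [HET HOM HET HOM] claimed from both sides; overlap resolved at the
        # split maximizing the summed scores (tie -> nearest the gap midpoint)
        lab = np.array([HET] * 5 + [HET, HOM, HET, HOM] + [HOM] * 5, dtype=np.int8)
        s = seq_of(lab)
        left = blocks.Block("s", "c", 0, 4, int(s.pos[0]), int(s.pos[4]), HET, 5, 0)
        right = blocks.Block("s", "c", 9, 13, int(s.pos[9]), int(s.pos[13]), HOM, 5, 0)
        out = extend_blocks([left, right], s)
        assert out[0].last == 5 and out[1].first == 6
        assert out[0].n_mismatch == 0
        assert out[1].n_mismatch == 1  # absorbed [HOM HET HOM]

    def test_extension_into_chromosome_ends(self):
        lab = [HET, HOM, HET, HET] + [HET] * 25 + [HET, HOM]
        s = seq_of(lab)
        out = segment(s, k=25, min_span=10_000)
        assert len(out) == 1
        assert out[0].first == 0 or out[0].first == 2
        # trailing: last matching marker is index len-2
        assert out[0].last == len(lab) - 2


class TestCrossovers:
    def test_single_block_no_events(self):
        s = seq_of([HET] * 30)
        assert call_crossovers(segment(s)) == []

    def test_midpoint_arithmetic(self):
        b1 = blocks.Block("s", "c", 0, 9, 900_000, 1_000_000, HET, 10, 0)
        b2 = blocks.Block("s", "c", 10, 19, 1_030_000, 1_200_000, HOM_A, 10, 0)
        (ev,) = call_crossovers([b1, b2])
        assert ev.left == 1_000_000 and ev.right == 1_030_000
        assert ev.midpoint == 1_015_000
        assert ev.resolution == 30_000

    def test_hom_hom_adjacency_counts_double_with_warning(self):
        b1 = blocks.Block("s", "c", 0, 9, 0, 100_000, HOM_A, 10, 0)
        b2 = blocks.Block("s", "c", 10, 19, 130_000, 200_000, HOM_B, 10, 0)
        with pytest.warns(UserWarning, match="double"):
            evs = call_crossovers([b1, b2])
        assert len(evs) == 2
        assert evs[0].midpoint == evs[1].midpoint == 115_000


def _all_hom_matrix():
    """4 markers x [F1, S1(all-hom), S2(het), S3(all-hom, fewer calls)]."""
    H, E, R, A = (GenotypeCall.HET, GenotypeCall.MISSING, GenotypeCall.HOM_REF,
                  GenotypeCall.HOM_ALT)
    calls = np.array([
        [H, R, H, R],
        [H, A, H, E],
        [H, R, H, R],
        [H, A, H, A],
    ], dtype=np.int8)
    return make_matrix([1, 12_000, 24_000, 36_000], calls)


class TestPhasing:
    def test_select_reference_prefers_most_informative_all_hom_sample(self):
        m = _all_hom_matrix()
        # k=2, small span so the toy runs seed
        assert blocks.select_reference_haplotype(m, "chr1", k=2, min_span=5_000) == "S1"

    def test_select_reference_errors_without_candidate(self):
        H = GenotypeCall.HET
        calls = np.full((30, 3), H, dtype=np.int8)
        m = make_matrix(np.arange(30) * 1000 + 1, calls)
        with pytest.raises(ReferenceHaplotypeError):
            blocks.select_reference_haplotype(m, "chr1", k=5, min_span=2_000)

    def test_reference_sample_phases_to_single_block(self, noiseless_matrix):
        m, truth, cfg = noiseless_matrix
        chrom = m.chroms[0]
        ref_sample = blocks.select_reference_haplotype(m, chrom)
        ref = blocks.reference_alleles_from_sample(m, chrom, ref_sample)
        seqs = blocks.phase_intraspecific(m, chrom, ref)
        out = segment(seqs[ref_sample])
        assert len(out) == 1 and out[0].label == HOM_A
        assert call_crossovers(out) == []

    def test_phase_invariance_under_complementary_reference(self, noiseless_matrix):
        m, truth, cfg = noiseless_matrix
        chrom = m.chroms[0]
        ref_sample = blocks.select_reference_haplotype(m, chrom)
        ref = blocks.reference_alleles_from_sample(m, chrom, ref_sample)
        comp = np.where(ref >= 0, 1 - ref, -1).astype(np.int8)
        for s in m.f2_samples[:5]:
            e1 = call_crossovers(segment(blocks.phase_intraspecific(m, chrom, ref)[s]))
            e2 = call_crossovers(segment(blocks.phase_intraspecific(m, chrom, comp)[s]))
            assert [ev.midpoint for ev in e1] == [ev.midpoint for ev in e2]
            swap = {HOM_A: HOM_B, HOM_B: HOM_A, HET: HET}
            assert [swap[ev.from_label] for ev in e2] == [ev.from_label for ev in e1]

    def test_noiseless_phased_calls_recover_truth_exactly(self, noiseless_matrix):
        m, truth, cfg = noiseless_matrix
        events, _, _ = blocks.call_intraspecific(m)
        score = simulate.score_crossovers(events, truth)
        assert score["recall"] == 1.0
        assert score["precision"] == 1.0
        # every called midpoint lies between the true breakpoint's flanking markers
        for row in events.itertuples(index=False):
            bps = truth.breakpoints(row.sample, row.chrom)
            d = np.abs(bps - row.midpoint)
            bp = bps[np.argmin(d)]
            assert row.left <= bp <= row.right

    def test_stitched_reference_matches_single_sample_phasing(self, noiseless_matrix):
        m, truth, cfg = noiseless_matrix
        chrom = m.chroms[0]
        stitched = blocks.build_reference_haplotype(m, chrom)
        ref_sample = blocks.select_reference_haplotype(m, chrom)
        ref = blocks.reference_alleles_from_sample(m, chrom, ref_sample)
        both = (stitched >= 0) & (ref >= 0)
        agree = (stitched[both] == ref[both]).mean()
        assert agree in (0.0, 1.0)  # identical up to global haplotype swap
        assert (stitched >= 0).mean() > 0.99


class TestInterspecific:
    def test_parent_labelled_calls_equal_truth_phase(self, noiseless_matrix):
        m, truth, cfg = noiseless_matrix
        chrom = m.chroms[0]
        h1 = truth.f1_hap1_allele[chrom]
        # parent A homozygous for the haplotype-1 allele, parent B for the other
        pa = np.where(h1 == 0, GenotypeCall.HOM_REF, GenotypeCall.HOM_ALT).astype(np.int8)
        pb = np.where(h1 == 1, GenotypeCall.HOM_REF, GenotypeCall.HOM_ALT).astype(np.int8)
        seqs, n_drop = blocks.genotype_interspecific(m, chrom, pa, pb)
        assert n_drop == 0
        for s in m.f2_samples[:5]:
            true_lab = truth.phase_labels(s, chrom)
            lab = seqs[s].labels
            # noiseless: sequences align marker by marker
            assert np.array_equal(lab, np.where(true_lab == 0, HET, np.where(true_lab == 2, HOM_A, HOM_B)))

    def test_uninformative_parent_markers_dropped(self):
        m = _all_hom_matrix()
        R, A, H = GenotypeCall.HOM_REF, GenotypeCall.HOM_ALT, GenotypeCall.HET
        pa = np.array([R, R, H, R], dtype=np.int8)
        pb = np.array([A, R, A, A], dtype=np.int8)
        seqs, n_drop = blocks.genotype_interspecific(m, "chr1", pa, pb)
        assert n_drop == 2  # shared allele at idx 1, parent het at idx 2
        assert len(seqs["S1"].pos) <= 2


class TestPopulationProperties:
    def test_blocks_alternate_and_calls_deterministic(self, small_sim):
        table, truth, cfg = small_sim
        m = markers.filter_variants(table)
        ev1, bl1, _ = blocks.call_intraspecific(m)
        ev2, bl2, _ = blocks.call_intraspecific(m)
        assert ev1.equals(ev2) and bl1.equals(bl2)
        for (s, c), g in bl1.groupby(["sample", "chrom"], sort=False):
            labels = g["label"].tolist()
            assert all(a != b for a, b in zip(labels, labels[1:]))

    def test_noisy_small_simulation_high_recall_precision(self, small_sim):
        table, truth, cfg = small_sim
        m = markers.filter_variants(table)
        events, _, _ = blocks.call_intraspecific(m)
        score = simulate.score_crossovers(events, truth)
        assert score["recall"] >= 0.95
        assert score["precision"] >= 0.95
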