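import numpy as np
import pytest

from xciphase import SimConfig, simulate_matrix
from xciphase.classification import (
    GROUP0,
    GROUP1,
    UNASSIGNED,
    CellClassification,
    CellDivision,
    IterationConfig,
    NoInformativeSNPsError,
    classify_once,
    division_overlap,
    iterate_cutoffs,
    merge_fragments,
    score_against_truth,
    vote_cells,
)
from xciphase.core_matrix import BaseCountMatrix, build_allele_calls
from xciphase.linkage_phasing import Fragment
from tests.test_linkage_phasing import calls_matrix


def make_fragment(positions, sides, score=10):
    return Fragment(
        sites=np.array(positions, dtype=np.int64),
        hap1_base=[None] * len(positions),
        hap1_side=np.array(sides, dtype=np.int8),
        linkage_score=score,
    )


def division_from_labels(labels):
    labels = np.asarray(labels)
    v1 = (labels == GROUP0).astype(np.int64)
    v2 = (labels == GROUP1).astype(np.int64)
    return CellDivision(fragment_id=0, votes_h1=v1, votes_h2=v2)


class TestVoteCells:
    def test_majority_wins(self):
        rows = [[1, 1, 1, 2]]  # matches hap1 at 3 sites, hap2 at 1
        calls = calls_matrix(rows, [1, 2, 3, 4])
        frag = make_fragment([1, 2, 3, 4], [1, 1, 1, 1])
        d = vote_cells(frag, calls)
        assert (d.votes_h1[0], d.votes_h2[0]) == (3, 1)
        assert d.labels[0] == GROUP0

    def test_tie_is_unassigned(self):
        calls = calls_matrix([[1, 1, 2, 2]], [1, 2, 3, 4])
        frag = make_fragment([1, 2, 3, 4], [1, 1, 1, 1])
        assert vote_cells(frag, calls).labels[0] == UNASSIGNED

    def test_uncovered_cell_unassigned(self):
        calls = calls_matrix([[0, 0]], [1, 2])
        d = vote_cells(make_fragment([1, 2], [1, 1]), calls)
        assert (d.votes_h1[0], d.votes_h2[0]) == (0, 0)
        assert d.labels[0] == UNASSIGNED

    def test_side_two_counts_for_hap1(self):
        calls = calls_matrix([[2, 2]], [1, 2])
        d = vote_cells(make_fragment([1, 2], [2, 2]), calls)
        assert d.votes_h1[0] == 2 and d.labels[0] == GROUP0


class TestDivisionOverlap:
    def test_nine_of_ten_concordant(self):
        d1 = division_from_labels([GROUP0] * 5 + [GROUP1] * 5)
        d2 = division_from_labels([GROUP0] * 4 + [GROUP1] * 6)
        assert division_overlap(d1, d2) == pytest.approx(0.9)

    def test_identical_divisions(self):
        d = division_from_labels([GROUP0, GROUP1, GROUP0])
        assert division_overlap(d, d) == 1.0

    def test_orientation_free(self):
        d1 = division_from_labels([GROUP0] * 5 + [GROUP1] * 5)
        d2 = division_from_labels([GROUP1] * 5 + [GROUP0] * 5)
        assert division_overlap(d1, d2) == 1.0

    def test_disjoint_assigned_sets(self):
        d1 = division_from_labels([GROUP0, UNASSIGNED])
        d2 = division_from_labels([UNASSIGNED, GROUP1])
        assert division_overlap(d1, d2) == 0.0


class TestMergeFragments:
    def _two_fragment_calls(self):
        # 10 cells, 4 sites; fragment A = sites (1,2), fragment B = sites (3,4)
        # cells 0-4 express hap1 everywhere, cells 5-9 hap2, except cell 9
        # disagrees on fragment B's sites
        rows = []
        for i in range(5):
            rows.append([1, 1, 1, 1])
        for i in range(4):
            rows.append([2, 2, 2, 2])
        rows.append([2, 2, 1, 1])
        return calls_matrix(rows, [1, 2, 3, 4])

    def test_merge_concatenates_site_sets(self):
        calls = self._two_fragment_calls()
        frag_a = make_fragment([1, 2], [1, 1], score=20)
        frag_b = make_fragment([3, 4], [1, 1], score=10)
        merged, classification = merge_fragments([frag_a, frag_b], calls)
        assert list(merged.sites) == [1, 2, 3, 4]
        assert classification.labels[0] == classification.labels[4]
        assert classification.labels[5] != classification.labels[0]

    def test_flipped_second_fragment_is_oriented(self):
        calls = self._two_fragment_calls()
        frag_a = make_fragment([1, 2], [1, 1], score=20)
        frag_b = make_fragment([3, 4], [2, 2], score=10)  # opposite polarity
        merged, _ = merge_fragments([frag_a, frag_b], calls)
        assert list(merged.hap1_side) == [1, 1, 1, 1]

    def test_single_fragment_classification_is_its_division(self):
        calls = self._two_fragment_calls()
        frag = make_fragment([1, 2], [1, 1])
        _, classification = merge_fragments([frag], calls)
        d = vote_cells(frag, calls)
        assert np.array_equal(classification.labels, d.labels)

    def test_boundary_overlap_not_merged(self):
        # divisions agree on exactly half the jointly assigned cells
        rows = [[1, 1]] * 5 + [[1, 2]] * 5
        calls = calls_matrix(rows, [1, 2])
        frag_a = make_fragment([1], [1], score=20)
        frag_b = make_fragment([2], [1], score=10)
        merged, _ = merge_fragments([frag_a, frag_b], calls, overlap_threshold=0.5)
        assert len(merged.sites) == 1  # no merge happened

    def test_no_fragments_all_unassigned(self):
        calls = calls_matrix([[1], [2]], [1])
        merged, classification = merge_fragments([], calls)
        assert merged is None
        assert set(classification.labels) == {UNASSIGNED}


class TestIterateCutoffs:
    def test_single_cutoff_equals_one_run(self, clean_sim):
        m, _ = clean_sim
        single = iterate_cutoffs(m, iter_cfg=IterationConfig(n_cutoffs=1))
        direct = classify_once(m)
        assert np.array_equal(single.labels, direct.labels)
        assert "chosen_cutoff" in single.provenance

    def test_stable_runs_return_consensus_labeling(self, clean_sim):
        m, truth = clean_sim
        cls = iterate_cutoffs(m)
        assert score_against_truth(cls, truth) == 1.0

    def test_empty_matrix_raises(self):
        m = BaseCountMatrix(
            barcodes=[], positions=np.array([], dtype=np.int64),
            counts=np.zeros((0, 0, 4), dtype=np.int64),
        )
        with pytest.raises(NoInformativeSNPsError, match="no informative SNPs"):
            iterate_cutoffs(m)

    def test_fuller_consensus_run_preferred(self, clean_sim):
        """A cutoff discarding most sites assigns fewer cells and loses the
        selection to a fuller, consensus-concordant run."""
        m, truth = clean_sim
        coverage = m.site_coverage()
        harsh = float(np.quantile(coverage, 0.995))
        cls = iterate_cutoffs(m, iter_cfg=IterationConfig(cutoff_grid=[0.0, harsh]))
        assert cls.provenance["chosen_cutoff"] == 0.0
        assert score_against_truth(cls, truth) == 1.0


class TestScoreAgainstTruth:
    def _classification(self, labels):
        labels = np.asarray(labels, dtype=np.int8)
        zeros = np.zeros(len(labels), dtype=np.int64)
        return CellClassification(
            barcodes=[f"c{i}" for i in range(len(labels))],
            labels=labels, votes_h1=zeros, votes_h2=zeros,
        )

    def test_perfect_and_flipped_labels_score_one(self):
        truth = np.array([1, 1, 2, 2])
        perfect = self._classification([GROUP0, GROUP0, GROUP1, GROUP1])
        flipped = self._classification([GROUP1, GROUP1, GROUP0, GROUP0])
        assert score_against_truth(perfect, truth) == 1.0
        assert score_against_truth(flipped, truth) == 1.0

    def test_unassigned_counts_as_error(self):
        truth = np.array([1, 1, 2, 2])
        half = self._classification([GROUP0, UNASSIGNED, GROUP1, UNASSIGNED])
        assert score_against_truth(half, truth) == 0.5

    def test_random_labels_score_near_half(self):
        rng = np.random.default_rng(11)
        n = 10_000
        truth = rng.integers(1, 3, size=n)
        labels = rng.integers(0, 2, size=n).astype(np.int8)
        acc = score_against_truth(self._classification(labels), truth)
        # 3 binomial SD plus the small max-over-permutations inflation
        assert abs(acc - 0.5) < 3 * 0.5 / np.sqrt(n) + 0.01

    def test_label_permutation_invariance_end_to_end(self, clean_sim):
        m, truth = clean_sim
        calls, _ = build_allele_calls(m)
        from xciphase.linkage_phasing import PhasingConfig, build_fragments, find_linkages

        frags = build_fragments(find_linkages(calls), PhasingConfig())
        _, cls = merge_fragments(frags, calls)
        flipped_frags = [
            Fragment(
                sites=f.sites, hap1_base=f.hap1_base,
                hap1_side=(3 - f.hap1_side).astype(np.int8),
                linkage_score=f.linkage_score,
            )
            for f in frags
        ]
        _, cls_flipped = merge_fragments(flipped_frags, calls)
        assigned = cls.labels != UNASSIGNED
        assert np.array_equal(cls.labels[assigned], 1 - cls_flipped.labels[assigned])
        assert score_against_truth(cls, truth) == score_against_truth(cls_flipped, truth)
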