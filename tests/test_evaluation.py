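"""ROC/AUC, P_random, top-k coverage/accuracy, and LOOCV plumbing."""

import numpy as np
import pytest

from patchkernel.errors import DataError, EmptyInputError, PatchKernelError
from patchkernel.evaluation import (
    ScoredPatch,
    build_training_pairs,
    loocv_patch_classification,
    p_random,
    protein_patch_pair,
    rank_scored_patches,
    roc_from_scores,
    topk_coverage_accuracy,
)
from patchkernel.kernel import KernelParams
from patchkernel.patches import Patch


def _patch(nums, center=None, pid="p"):
    keys = tuple(("A", n, "") for n in nums)
    return Patch(protein_id=pid, residue_keys=keys,
                 center=("A", center, "") if center else None)


class TestRocFromScores:
    def test_constant_scores_give_half(self):
        _, auc = roc_from_scores([5] * 10, [True] * 4 + [False] * 6, total=10)
        assert auc == pytest.approx(0.5)

    def test_perfectly_ordered_scores_give_one(self):
        scores = [9, 8, 7, 2, 1, 0]
        labels = [True, True, True, False, False, False]
        _, auc = roc_from_scores(scores, labels, total=10)
        assert auc == pytest.approx(1.0)

    def test_reversed_scores_give_zero(self):
        scores = [0, 1, 2, 7, 8, 9]
        labels = [True, True, True, False, False, False]
        _, auc = roc_from_scores(scores, labels, total=10)
        assert auc == pytest.approx(0.0)

    def test_single_class_is_error(self):
        with pytest.raises(DataError):
            roc_from_scores([1, 2], [True, True], total=5)

    def test_one_point_per_threshold(self):
        points, _ = roc_from_scores([0, 3], [False, True], total=5)
        assert [p[0] for p in points] == [5, 4, 3, 2, 1, 0]

    def test_matches_rank_statistic_oracle(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            total = 15
            scores = rng.integers(0, total + 1, size=n)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            _, auc = roc_from_scores(scores, labels, total)
            assert auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-9)


class TestPRandom:
    def test_ratio_of_qualifying_patches(self):
        interface = {("A", n, "") for n in range(1, 7)}
        top1 = _patch(range(1, 7))  # 6 interface residues
        # 5 patches (incl. top1) contain >= 6 interface residues, 95 contain none
        qualifying = [_patch(range(1, 7), pid=f"q{i}") for i in range(4)]
        others = [_patch(range(100 + 10 * i, 100 + 10 * i + 6), pid=f"o{i}")
                  for i in range(95)]
        assert p_random([top1] + qualifying + others, top1, interface) == 0.05

    def test_top1_without_interface_residues_gives_one(self):
        interface = {("A", 50, "")}
        all_patches = [_patch(range(1, 4)), _patch(range(4, 7))]
        assert p_random(all_patches, all_patches[0], interface) == 1.0

    def test_strictly_best_top1_gives_one_over_n(self):
        interface = {("A", 1, ""), ("A", 2, "")}
        top1 = _patch([1, 2, 3])
        rest = [_patch([1, 10, 11]), _patch([20, 21, 22]), _patch([30, 31, 32])]
        assert p_random([top1] + rest, top1, interface) == 0.25

    def test_empty_patch_list_is_error(self):
        with pytest.raises(EmptyInputError):
            p_random([], _patch([1]), set())


class TestTopkCoverageAccuracy:
    def _ranked(self):
        return [
            ScoredPatch(_patch(range(1, 7), center=1), votes=10, total=10),
            ScoredPatch(_patch(range(5, 11), center=5), votes=8, total=10),
            ScoredPatch(_patch(range(40, 46), center=40), votes=2, total=10),
        ]

    def test_all_interface_top1(self):
        interface = {("A", n, "") for n in range(1, 27)}  # N_int = 26
        metrics = topk_coverage_accuracy(self._ranked(), 1, interface)
        assert metrics.tp == 6 and metrics.n_int == 26 and metrics.n_pr == 6
        assert metrics.coverage == pytest.approx(6 / 26)
        assert metrics.precision_accuracy == 1.0

    def test_union_semantics(self):
        interface = {("A", n, "") for n in range(1, 27)}
        metrics = topk_coverage_accuracy(self._ranked(), 2, interface)
        assert metrics.n_pr == 10  # overlap of patches 1 and 2 counted once
        assert metrics.tp == 10

    def test_full_coverage_when_union_covers_interface(self):
        interface = {("A", n, "") for n in range(1, 11)}
        metrics = topk_coverage_accuracy(self._ranked(), 3, interface)
        assert metrics.coverage == 1.0

    def test_coverage_non_decreasing_in_k(self):
        interface = {("A", n, "") for n in range(1, 27)}
        coverages = [topk_coverage_accuracy(self._ranked(), k, interface).coverage
                     for k in (1, 2, 3)]
        assert coverages == sorted(coverages)

    def test_empty_interface_is_error(self):
        with pytest.raises(DataError):
            topk_coverage_accuracy(self._ranked(), 1, set())

    def test_k_below_one_is_error(self):
        with pytest.raises(PatchKernelError):
            topk_coverage_accuracy(self._ranked(), 0, {("A", 1, "")})


def test_rank_scored_patches_tie_break_on_center():
    scored = [
        ScoredPatch(_patch([3], center=3), votes=5, total=9),
        ScoredPatch(_patch([1], center=1), votes=5, total=9),
        ScoredPatch(_patch([2], center=2), votes=7, total=9),
    ]
    ranked = rank_scored_patches(scored)
    assert [s.patch.center[1] for s in ranked] == [2, 1, 3]


class TestLoocv:
    def test_training_pairs_are_size_matched(self, small_dataset):
        pairs = build_training_pairs(small_dataset, seed=3)
        assert len(pairs) == len(small_dataset)
        for pair in pairs:
            assert pair.interface_graph.n_nodes == pair.noninterface_graph.n_nodes

    def test_patch_pair_is_deterministic(self, small_dataset):
        a = protein_patch_pair(small_dataset[0], seed=3)
        b = protein_patch_pair(small_dataset[0], seed=3)
        assert a[0].residue_keys == b[0].residue_keys
        assert a[1].residue_keys == b[1].residue_keys

    def test_invariant_to_protein_ordering(self, small_dataset):
        params = KernelParams()
        forward = loocv_patch_classification(small_dataset, params, seed=3)
        backward = loocv_patch_classification(small_dataset[::-1], params, seed=3)
        assert forward == backward

    def test_needs_at_least_three_proteins(self, small_dataset):
        with pytest.raises(PatchKernelError):
            loocv_patch_classification(small_dataset[:2], KernelParams(), seed=3)

    def test_perfect_separation_reaches_ceiling(self, small_dataset):
        metrics = loocv_patch_classification(small_dataset, KernelParams(), seed=3)
        assert metrics.accuracy == 1.0
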