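"""Evaluation protocol: leave-one-out cross-validation, ROC/AUC over vote
thresholds, P_random for the top-ranked patch, and top-k coverage/accuracy.

All cross-validation is at the protein level: when a protein's patches are
classified, no patch from that protein appears in the training set, and the
attribute normalizer is refit on the fold's training proteins only.

Per-protein randomness (the sampled non-interface patch) is seeded from a
stable hash of (run seed, protein id), so results do not depend on the order
proteins are listed in.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataError, EmptyInputError, PatchKernelError
from .features import Normalizer, Protein, ResKey, fit_normalizer
from .graphs import ShortestPathGraph, build_patch_graph, shortest_path_transform
from .kernel import KernelParams
from .patches import (
    INTERFACE,
    Patch,
    extract_interface_patch,
    centered_surface_patches,
    interface_residues,
    sample_noninterface_patch,
)
from .voting import TrainingPair, vote

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalMetrics:
    """Classification/prediction metrics.  ``coverage`` is TP/N_int (fraction
    of actual interface residues recovered) and ``precision_accuracy`` is
    TP/N_pr (fraction of predicted residues that are actually interface)."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    auc: float | None = None
    tp: int | None = None
    n_int: int | None = None
    n_pr: int | None = None
    coverage: float | None = None
    precision_accuracy: float | None = None


def pair_sampling_seed(seed: int, protein_id: str) -> int:
    """Order-independent per-protein seed (< 2^31) for non-interface sampling."""
    return zlib.crc32(f"{seed}:{protein_id}".encode()) & 0x7FFFFFFF


def protein_patch_pair(protein: Protein, seed: int) -> tuple[Patch, Patch]:
    """The protein's interface patch and a size-matched sampled non-interface
    patch (seeded deterministically from ``seed`` and the protein id)."""
    interface_patch = extract_interface_patch(protein)
    noninterface_patch = sample_noninterface_patch(
        protein, interface_patch.size, pair_sampling_seed(seed, protein.protein_id)
    )
    return interface_patch, noninterface_patch


def _patch_graph(patch: Patch, protein: Protein,
                 features: Sequence[int] | None) -> ShortestPathGraph:
    return shortest_path_transform(build_patch_graph(patch, protein,
                                                     features=features))


def build_training_pairs(proteins: Sequence[Protein], seed: int, *,
                         normalizer: Normalizer | None = None,
                         features: Sequence[int] | None = None,
                         ) -> list[TrainingPair]:
    """One size-matched :class:`TrainingPair` per training protein.

    When no normalizer is given, one is fitted on the pooled residues of
    ``proteins`` (the dataset-wide min-max convention).
    """
    if normalizer is None:
        normalizer = fit_normalizer(proteins)
    pairs = []
    for protein in proteins:
        int_patch, non_patch = protein_patch_pair(protein, seed)
        norm = normalizer.transform(protein)
        pairs.append(
            TrainingPair(
                protein_id=protein.protein_id,
                interface_graph=_patch_graph(int_patch, norm, features),
                noninterface_graph=_patch_graph(non_patch, norm, features),
            )
        )
    return pairs


def _check_dataset(proteins: Sequence[Protein], minimum: int) -> None:
    if len(proteins) < minimum:
        raise PatchKernelError(f"need at least {minimum} proteins, got {len(proteins)}")
    for protein in proteins:
        if not interface_residues(protein):
            raise DataError(f"{protein.protein_id}: no interface residues")


def loocv_patch_classification(proteins: Sequence[Protein],
                               params: KernelParams = KernelParams(),
                               seed: int = 0, *,
                               features: Sequence[int] | None = None,
                               ) -> EvalMetrics:
    """Leave-one-protein-out classification of interface vs non-interface
    patches: 2N patch classifications in total, each voted over the other
    N − 1 proteins' pairs."""
    _check_dataset(proteins, minimum=3)
    patch_pairs = {
        p.protein_id: protein_patch_pair(p, seed) for p in proteins
    }
    tp = tn = fp = fn = 0
    for held_out in proteins:
        train = [p for p in proteins if p.protein_id != held_out.protein_id]
        normalizer = fit_normalizer(train)
        train_pairs = build_training_pairs(train, seed, normalizer=normalizer,
                                           features=features)
        query = normalizer.transform(held_out)
        int_patch, non_patch = patch_pairs[held_out.protein_id]
        for patch, truly_interface in ((int_patch, True), (non_patch, False)):
            graph = _patch_graph(patch, query, features)
            result = vote(graph, train_pairs, params)
            predicted_interface = result.label == INTERFACE
            if truly_interface and predicted_interface:
                tp += 1
            elif truly_interface:
                fn += 1
            elif predicted_interface:
                fp += 1
            else:
                tn += 1
        logger.info("loocv fold %s: done", held_out.protein_id)
    total = tp + tn + fp + fn
    return EvalMetrics(
        accuracy=(tp + tn) / total,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
    )


@dataclass(frozen=True)
class ScoredPatch:
    patch: Patch
    votes: int
    total: int


def loocv_centered_patch_votes(proteins: Sequence[Protein],
                               params: KernelParams = KernelParams(),
                               seed: int = 0, k: int = 5, *,
                               features: Sequence[int] | None = None,
                               ) -> dict[str, list[ScoredPatch]]:
    """For every protein, vote all of its centered surface patches using the
    other proteins' pairs as training set (protein-level holdout)."""
    _check_dataset(proteins, minimum=2)
    out: dict[str, list[ScoredPatch]] = {}
    for held_out in proteins:
        train = [p for p in proteins if p.protein_id != held_out.protein_id]
        normalizer = fit_normalizer(train)
        train_pairs = build_training_pairs(train, seed, normalizer=normalizer,
                                           features=features)
        query = normalizer.transform(held_out)
        scored = []
        for patch in centered_surface_patches(held_out, k):
            graph = _patch_graph(patch, query, features)
            result = vote(graph, train_pairs, params)
            scored.append(ScoredPatch(patch=patch, votes=result.votes,
                                      total=result.total))
        out[held_out.protein_id] = scored
        logger.info("centered-patch fold %s: %d patches scored",
                    held_out.protein_id, len(scored))
    return out


def rank_scored_patches(scored: Sequence[ScoredPatch]) -> list[ScoredPatch]:
    """Descending by votes; ties break on the center residue key."""
    return sorted(scored, key=lambda s: (-s.votes,
                                         s.patch.center if s.patch.center
                                         is not None else (),
                                         s.patch.residue_keys))


# ---------------------------------------------------------------------------
# ROC over vote thresholds


def roc_from_scores(scores: Sequence[int], labels: Sequence[bool], total: int,
                    ) -> tuple[list[tuple[int, float, float]], float]:
    """ROC points (threshold, TPR, FPR) for integer thresholds total..0
    (predict interface iff votes > threshold) and the trapezoid AUC.

    The trapezoid is taken over the threshold curve closed at (1, 1), which
    makes the AUC identical to the Mann–Whitney rank statistic of the scores.
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC is undefined for single-class ground truth")
    points = []
    for threshold in range(total, -1, -1):
        predicted = scores > threshold
        tpr = float((predicted & labels).sum()) / n_pos
        fpr = float((predicted & ~labels).sum()) / n_neg
        points.append((threshold, tpr, fpr))
    fpr_curve = [0.0] + [p[2] for p in points] + [1.0]
    tpr_curve = [0.0] + [p[1] for p in points] + [1.0]
    auc = float(np.trapezoid(tpr_curve, fpr_curve))
    return points, auc


def residue_roc(proteins: Sequence[Protein],
                params: KernelParams = KernelParams(),
                seed: int = 0, k: int = 5, *,
                features: Sequence[int] | None = None,
                ) -> tuple[list[tuple[int, float, float]], float]:
    """Residue-level ROC: each surface residue is scored with the votes of the
    patch centered on it, its ground truth is its own interface status."""
    votes_by_protein = loocv_centered_patch_votes(proteins, params, seed, k,
                                                  features=features)
    scores: list[int] = []
    labels: list[bool] = []
    total = 0
    for protein in proteins:
        truth = interface_residues(protein)
        for scored in votes_by_protein[protein.protein_id]:
            scores.append(scored.votes)
            labels.append(scored.patch.center in truth)
            total = max(total, scored.total)
    return roc_from_scores(scores, labels, total)


# ---------------------------------------------------------------------------
# Patch-ranking statistics


def p_random(all_patches: Sequence[Patch], top1_patch: Patch,
             interface_set: frozenset[ResKey] | set[ResKey]) -> float:
    """Probability that a randomly picked patch has at least as many interface
    residues as the top-ranked patch (N / N_all, inclusive, so ≥ 1/N_all)."""
    if not all_patches:
        raise EmptyInputError("p_random needs a non-empty patch list")
    top_count = len(top1_patch.key_set & interface_set)
    n = sum(1 for p in all_patches
            if len(p.key_set & interface_set) >= top_count)
    return n / len(all_patches)


def topk_coverage_accuracy(ranked_patches: Sequence[ScoredPatch] | Sequence[tuple[Patch, int]],
                           k: int,
                           interface_set: frozenset[ResKey] | set[ResKey],
                           ) -> EvalMetrics:
    """Predict the union of the top-k patches' residues; report coverage
    (TP/N_int) and accuracy (TP/N_pr)."""
    if k < 1:
        raise PatchKernelError("k must be at least 1")
    if not interface_set:
        raise DataError("coverage is undefined for an empty interface set")
    predicted: set[ResKey] = set()
    for item in list(ranked_patches)[:k]:
        patch = item.patch if isinstance(item, ScoredPatch) else item[0]
        predicted |= patch.key_set
    tp = len(predicted & set(interface_set))
    n_int = len(interface_set)
    n_pr = len(predicted)
    return EvalMetrics(
        tp=tp, n_int=n_int, n_pr=n_pr,
        coverage=tp / n_int,
        precision_accuracy=tp / n_pr if n_pr else 0.0,
    )
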