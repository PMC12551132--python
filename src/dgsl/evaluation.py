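"""Experimental protocols: balanced 10-fold CV, noise and sparsity
robustness, degree-group analysis, and cold-start node hold-out.

All protocols share the same conventions: positive cells are split (or
perturbed) on the *training* side only, test folds pair each held-out
positive with an equal number of negatives sampled from cells that are
positive nowhere in the dataset, and every random draw comes from a named
substream of one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)

from ._rng import substream
from .encoder import EncoderConfig
from .graphs import AssociationMatrix, NeighborGraph
from .training import TrainConfig, TrainResult, train

__all__ = [
    "FoldPlan",
    "MetricReport",
    "ColdStartPlan",
    "make_fold_plan",
    "compute_metrics",
    "evaluate_fold",
    "cross_validate",
    "noise_experiment",
    "sparsity_experiment",
    "degree_group_report",
    "make_cold_start_plan",
    "cold_start_experiment",
]

METRIC_NAMES = ("auroc", "auprc", "accuracy", "precision", "recall", "f1", "mcc")


@dataclass
class FoldPlan:
    """Partition of the positive cells plus balanced per-fold negatives."""

    fold_of_positive: dict[tuple[int, int], int]
    test_negatives: list[list[tuple[int, int]]]
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.test_negatives)

    def positives_of_fold(self, fold: int) -> list[tuple[int, int]]:
        return [p for p, f in self.fold_of_positive.items() if f == fold]


@dataclass
class MetricReport:
    auroc: float
    auprc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    threshold: float = 0.5

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def relative_to(self, baseline: "MetricReport") -> dict[str, float]:
        base = baseline.as_dict()
        return {k: (v / base[k] if base[k] != 0 else np.nan) for k, v in self.as_dict().items()}


@dataclass
class ColdStartPlan:
    side: Literal["disease", "gene"]
    proportion: float
    held_out_entities: list[int]
    test_positives: list[tuple[int, int]]
    test_negatives: list[tuple[int, int]]


# ---------------------------------------------------------------------------
# splits


def make_fold_plan(assoc: AssociationMatrix, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Shuffle the positives, deal them round-robin into folds, and sample
    an equal number of test negatives per fold from cells that are positive
    nowhere in the dataset (so no test negative is a hidden positive)."""
    positives = assoc.positives()
    if len(positives) < n_folds:
        raise ValueError(f"need at least {n_folds} positives for {n_folds}-fold CV")
    m, n = assoc.shape
    if m * n - len(positives) < len(positives):
        raise ValueError("complement too small to sample balanced negatives")
    rng = substream(seed, "folds")
    order = rng.permutation(len(positives))
    fold_of = {positives[int(p)]: i % n_folds for i, p in enumerate(order)}

    pos_set = set(positives)
    neg_rng = substream(seed, "negatives")
    fold_sizes = [sum(1 for f in fold_of.values() if f == k) for k in range(n_folds)]
    negatives: list[list[tuple[int, int]]] = []
    for k in range(n_folds):
        chosen: set[tuple[int, int]] = set()
        while len(chosen) < fold_sizes[k]:
            flat = neg_rng.integers(0, m * n, size=2 * (fold_sizes[k] - len(chosen)))
            for v in flat:
                cell = (int(v) // n, int(v) % n)
                if cell not in pos_set and cell not in chosen:
                    chosen.add(cell)
                    if len(chosen) == fold_sizes[k]:
                        break
        negatives.append(sorted(chosen))
    return FoldPlan(fold_of, negatives, seed)


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5) -> MetricReport:
    """Seven-metric report on scored pairs.

    AUROC is rank-based; AUPRC is the step-interpolated average precision;
    the thresholded metrics binarize the scores at ``threshold`` (0.5, the
    natural operating point for balanced test sets).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUROC/AUPRC are undefined for single-class labels")
    pred = (scores >= threshold).astype(np.int64)
    return MetricReport(
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        accuracy=float(accuracy_score(labels, pred)),
        precision=float(precision_score(labels, pred, zero_division=0)),
        recall=float(recall_score(labels, pred, zero_division=0)),
        f1=float(f1_score(labels, pred, zero_division=0)),
        mcc=float(matthews_corrcoef(labels, pred)),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# fold evaluation


def _score_pairs(result: TrainResult, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    idx_i = np.array([i for i, _ in pairs])
    idx_j = np.array([j for _, j in pairs])
    return result.probabilities[idx_i, idx_j]


def evaluate_fold(
    assoc: AssociationMatrix,
    disease_graph: NeighborGraph | None,
    gene_graph: NeighborGraph | None,
    plan: FoldPlan,
    fold: int,
    enc: EncoderConfig | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[MetricReport, TrainResult, list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Train with the fold's positives masked out; score its test set.

    Returns (report, trained model, test pairs, scores, labels)."""
    test_pos = plan.positives_of_fold(fold)
    test_neg = plan.test_negatives[fold]
    train_assoc = assoc.masked(test_pos)
    result = train(train_assoc, disease_graph, gene_graph, enc, cfg)
    pairs = list(test_pos) + list(test_neg)
    labels = np.array([1] * len(test_pos) + [0] * len(test_neg))
    scores = _score_pairs(result, pairs)
    return compute_metrics(scores, labels), result, pairs, scores, labels


def cross_validate(
    assoc: AssociationMatrix,
    disease_graph: NeighborGraph | None,
    gene_graph: NeighborGraph | None,
    n_folds: int = 10,
    seed: int = 0,
    enc: EncoderConfig | None = None,
    cfg: TrainConfig | None = None,
    folds: Sequence[int] | None = None,
) -> list[MetricReport]:
    """Balanced k-fold CV; ``folds`` restricts to a subset of fold indices."""
    plan = make_fold_plan(assoc, n_folds, seed)
    reports = []
    for fold in folds if folds is not None else range(n_folds):
        report, *_ = evaluate_fold(assoc, disease_graph, gene_graph, plan, fold, enc, cfg)
        reports.append(report)
    return reports


# ---------------------------------------------------------------------------
# robustness experiments


def _sample_complement_cells(
    rng: np.random.Generator, forbidden: set[tuple[int, int]], shape: tuple[int, int], count: int
) -> list[tuple[int, int]]:
    m, n = shape
    if m * n - len(forbidden) < count:
        raise ValueError("complement too small to sample the requested cells")
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < count:
        flat = rng.integers(0, m * n, size=2 * (count - len(chosen)))
        for v in flat:
            cell = (int(v) // n, int(v) % n)
            if cell not in forbidden and cell not in chosen:
                chosen.add(cell)
                if len(chosen) == count:
                    break
    return sorted(chosen)


def noise_experiment(
    assoc: AssociationMatrix,
    disease_graph: NeighborGraph | None,
    gene_graph: NeighborGraph | None,
    ratios: Sequence[float] = (1, 2, 3, 4),
    seed: int = 0,
    fold: int = 0,
    n_folds: int = 10,
    enc: EncoderConfig | None = None,
    cfg: TrainConfig | None = None,
) -> dict[float, dict[str, float]]:
    """Pseudo-edge robustness: retrain with r x |train positives| inserted
    false edges and report each metric relative to the clean run (ratio 0).

    Pseudo-edges are sampled from cells that are neither true positives nor
    already-inserted pseudo-edges; the test fold is untouched.
    """
    plan = make_fold_plan(assoc, n_folds, seed)
    test_pos = plan.positives_of_fold(fold)
    test_neg = plan.test_negatives[fold]
    pairs = list(test_pos) + list(test_neg)
    labels = np.array([1] * len(test_pos) + [0] * len(test_neg))

    train_assoc = assoc.masked(test_pos)
    clean_result = train(train_assoc, disease_graph, gene_graph, enc, cfg)
    clean = compute_metrics(_score_pairs(clean_result, pairs), labels)

    n_train_pos = len(train_assoc.positives())
    forbidden = set(assoc.positives())
    rng = substream(seed, "noise")
    out: dict[float, dict[str, float]] = {0.0: {k: 1.0 for k in METRIC_NAMES}}
    for r in ratios:
        pseudo = _sample_complement_cells(rng, forbidden, assoc.shape, int(round(r * n_train_pos)))
        noisy_vals = train_assoc.values.copy()
        for i, j in pseudo:
            noisy_vals[i, j] = 1.0
        noisy = AssociationMatrix(noisy_vals, assoc.row_ids, assoc.col_ids, set(train_assoc.train_mask))
        result = train(noisy, disease_graph, gene_graph, enc, cfg)
        report = compute_metrics(_score_pairs(result, pairs), labels)
        out[float(r)] = report.relative_to(clean)
    return out


def sparsity_experiment(
    assoc: AssociationMatrix,
    disease_graph: NeighborGraph | None,
    gene_graph: NeighborGraph | None,
    drop_fracs: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    seed: int = 0,
    fold: int = 0,
    n_folds: int = 10,
    enc: EncoderConfig | None = None,
    cfg: TrainConfig | None = None,
) -> dict[float, dict[str, dict[str, float]]]:
    """Edge-drop robustness: remove a fraction of *training* edges, retrain,
    report absolute and clean-relative metrics per drop fraction."""
    plan = make_fold_plan(assoc, n_folds, seed)
    test_pos = plan.positives_of_fold(fold)
    test_neg = plan.test_negatives[fold]
    pairs = list(test_pos) + list(test_neg)
    labels = np.array([1] * len(test_pos) + [0] * len(test_neg))

    train_assoc = assoc.masked(test_pos)
    clean_result = train(train_assoc, disease_graph, gene_graph, enc, cfg)
    clean = compute_metrics(_score_pairs(clean_result, pairs), labels)

    train_pos = train_assoc.positives()
    rng = substream(seed, "drop")
    out: dict[float, dict[str, dict[str, float]]] = {
        0.0: {"absolute": clean.as_dict(), "relative": {k: 1.0 for k in METRIC_NAMES}}
    }
    for frac in drop_fracs:
        n_drop = int(round(frac * len(train_pos)))
        if n_drop >= len(train_pos):
            raise ValueError(f"dropping {frac:.0%} leaves no training positives")
        drop_idx = rng.choice(len(train_pos), size=n_drop, replace=False)
        dropped = [train_pos[int(i)] for i in drop_idx]
        sparse = train_assoc.masked(dropped)
        result = train(sparse, disease_graph, gene_graph, enc, cfg)
        report = compute_metrics(_score_pairs(result, pairs), labels)
        out[float(frac)] = {"absolute": report.as_dict(), "relative": report.relative_to(clean)}
    return out


def degree_group_report(
    pairs: Sequence[tuple[int, int]],
    scores: Sequence[float],
    labels: Sequence[int],
    assoc: AssociationMatrix,
    group_edges: Sequence[int],
    side: Literal["disease", "gene"] = "disease",
    threshold: float = 0.5,
) -> dict[int, MetricReport]:
    """Per-degree-group metrics over scored test pairs.

    Each pair is attributed to the group of its disease (or gene), grouped
    by the entity's association count in the full dataset. A degree exactly
    on a boundary belongs to the higher group. Groups with no test pairs
    (or a single class) are absent from the report, not zero.
    """
    edges = list(group_edges)
    if any(b >= a for a, b in zip(edges[1:], edges)):
        raise ValueError("group_edges must be strictly increasing")
    deg = assoc.values.sum(axis=1) if side == "disease" else assoc.values.sum(axis=0)
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    entity_of = np.array([i if side == "disease" else j for i, j in pairs])
    group_of = np.searchsorted(edges, deg[entity_of], side="right")
    out: dict[int, MetricReport] = {}
    for g in sorted(set(group_of.tolist())):
        sel = group_of == g
        if len(set(labels[sel].tolist())) < 2:
            continue
        out[int(g)] = compute_metrics(scores[sel], labels[sel], threshold)
    return out


# ---------------------------------------------------------------------------
# cold start


def make_cold_start_plan(
    assoc: AssociationMatrix,
    side: Literal["disease", "gene"],
    proportion: float,
    seed: int = 0,
) -> ColdStartPlan:
    """Hold out a proportion of entities on one side: all their associations
    become test positives; per held-out entity an equal number of negatives
    is sampled from its non-associated partners."""
    if not 0 < proportion < 1:
        raise ValueError("proportion must be in (0, 1)")
    m, n = assoc.shape
    n_side = m if side == "disease" else n
    deg = assoc.values.sum(axis=1) if side == "disease" else assoc.values.sum(axis=0)
    eligible = np.nonzero(deg >= 1)[0]
    n_hold = max(1, int(round(proportion * n_side)))
    if n_hold > eligible.size:
        raise ValueError("not enough entities with positives to hold out")
    rng = substream(seed, f"coldstart-{side}")
    held = sorted(rng.choice(eligible, size=n_hold, replace=False).tolist())

    test_pos: list[tuple[int, int]] = []
    test_neg: list[tuple[int, int]] = []
    for e in held:
        if side == "disease":
            partners = np.nonzero(assoc.values[e])[0]
            non_partners = np.nonzero(assoc.values[e] == 0)[0]
            test_pos.extend((e, int(j)) for j in partners)
            negs = rng.choice(non_partners, size=partners.size, replace=False)
            test_neg.extend((e, int(j)) for j in negs)
        else:
            partners = np.nonzero(assoc.values[:, e])[0]
            non_partners = np.nonzero(assoc.values[:, e] == 0)[0]
            test_pos.extend((int(i), e) for i in partners)
            negs = rng.choice(non_partners, size=partners.size, replace=False)
            test_neg.extend((int(i), e) for i in negs)
    return ColdStartPlan(side, proportion, held, test_pos, test_neg)


def cold_start_experiment(
    assoc: AssociationMatrix,
    disease_graph: NeighborGraph | None,
    gene_graph: NeighborGraph | None,
    side: Literal["disease", "gene"] = "disease",
    proportion: float = 0.1,
    seed: int = 0,
    enc: EncoderConfig | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[MetricReport, ColdStartPlan]:
    """Train with held-out entities' associations removed; evaluate on them.

    Every supervision cell of a held-out entity is masked (their rows carry
    no association signal at all), but their similarity-derived neighbor
    edges remain — the mechanism that makes cold-start prediction possible.
    """
    plan = make_cold_start_plan(assoc, side, proportion, seed)
    m, n = assoc.shape
    if side == "disease":
        masked_cells = [(e, j) for e in plan.held_out_entities for j in range(n)]
    else:
        masked_cells = [(i, e) for e in plan.held_out_entities for i in range(m)]
    train_assoc = assoc.masked(masked_cells)
    result = train(train_assoc, disease_graph, gene_graph, enc, cfg)
    pairs = plan.test_positives + plan.test_negatives
    labels = np.array([1] * len(plan.test_positives) + [0] * len(plan.test_negatives))
    report = compute_metrics(_score_pairs(result, pairs), labels)
    return report, plan
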