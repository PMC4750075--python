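"""Benchmark statistics for inferred networks against a gold standard.

The scoreable universe is every ordered (regulator, target) pair with
self-pairs excluded; pairs absent from the predicted edge list score 0.
ROC handles score ties by the mid-rank convention (simultaneous threshold
drop), so the AUROC equals the Mann-Whitney probability that a random true
edge outranks a random non-edge.  The precision-recall area uses step
integration.  The selector value is the normalized weight of the
highest-ranked edge that is a true positive.  The OverallScore summarizes a
method across data sets: the average of the geometric means of the
per-data-set AUROCs and AUPRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gmean
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .io import GoldStandard
from .network import Network

logger = logging.getLogger("fusegrn")

__all__ = [
    "EvalReport",
    "make_universe",
    "roc_pr",
    "selector_value",
    "overall_score",
    "type_fractions",
]


@dataclass
class EvalReport:
    """ROC/PR curves and scalar metrics for one network vs a gold standard."""

    fpr: np.ndarray
    tpr: np.ndarray
    recall: np.ndarray
    precision: np.ndarray
    auroc: float
    aupr: float
    tpr_at_fpr: float
    fpr_requested: float

    def as_dict(self) -> dict[str, float]:
        return {
            "AUROC": self.auroc,
            "AUPR": self.aupr,
            f"TPR@FPR={self.fpr_requested:g}": self.tpr_at_fpr,
        }


def make_universe(
    regulators: Sequence[str], targets: Sequence[str]
) -> list[tuple[str, str]]:
    """All ordered regulator -> target pairs, self-pairs excluded."""
    return [(r, t) for r in regulators for t in targets if r != t]


def _scores_and_labels(
    network: Network, gold: GoldStandard, universe: Iterable[tuple[str, str]]
) -> tuple[np.ndarray, np.ndarray]:
    universe = list(universe)
    if not universe:
        raise ValueError("empty scoreable universe")
    uset = set(universe)
    outside = [e for e in gold.edges if e not in uset]
    if outside:
        raise ValueError(f"gold edges outside the universe: {outside[:5]}")
    weights = network.edge_weights()
    scores = np.array([weights.get(pair, 0.0) for pair in universe])
    labels = np.array([1 if pair in gold.edges else 0 for pair in universe])
    return scores, labels


def _trapezoid_auc(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.trapezoid(y, x))


def roc_pr(
    network: Network,
    gold: GoldStandard,
    universe: Iterable[tuple[str, str]],
    fpr_target: float = 0.03,
) -> EvalReport:
    """ROC and PR analysis of a normalized network over a pair universe.

    ``tpr_at_fpr`` is read off the step ROC curve at the largest achieved
    FPR not exceeding ``fpr_target``.
    """
    if len(gold) == 0:
        raise ValueError("gold standard is empty")
    scores, labels = _scores_and_labels(network, gold, universe)
    if labels.sum() == len(labels):
        raise ValueError("gold standard covers the whole universe")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auroc = _trapezoid_auc(fpr, tpr)
    precision, recall, _ = precision_recall_curve(labels, scores)
    aupr = float(average_precision_score(labels, scores))
    achieved = fpr[fpr <= fpr_target + 1e-12]
    tpr_at = float(tpr[len(achieved) - 1]) if len(achieved) else 0.0
    return EvalReport(
        fpr=fpr,
        tpr=tpr,
        recall=recall[::-1],
        precision=precision[::-1],
        auroc=auroc,
        aupr=aupr,
        tpr_at_fpr=tpr_at,
        fpr_requested=fpr_target,
    )


def selector_value(network: Network, gold: GoldStandard) -> float:
    """Normalized weight of the highest-ranked true-positive edge (0 if none).

    Values near 1 mean true edges receive top scores; the network's edge
    table is already ranked by descending normalized weight.
    """
    if len(gold) == 0:
        raise ValueError("gold standard is empty")
    for _, row in network.edges.iterrows():
        if (row["regulator"], row["target"]) in gold.edges:
            return float(row["normalized_weight"])
    logger.warning("no true positive in the retained edge list; selector value 0")
    return 0.0


def overall_score(
    pairs: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """(AUROCscore, AUPRscore, OverallScore) from per-data-set (AUROC, AUPR).

    AUROCscore and AUPRscore are geometric means across data sets; the
    OverallScore is their average.
    """
    if not pairs:
        raise ValueError("need at least one (AUROC, AUPR) pair")
    aurocs = np.array([p[0] for p in pairs], dtype=float)
    auprs = np.array([p[1] for p in pairs], dtype=float)
    if (aurocs <= 0).any() or (auprs <= 0).any():
        raise ValueError("geometric mean undefined for non-positive inputs")
    auroc_score = float(gmean(aurocs))
    aupr_score = float(gmean(auprs))
    return auroc_score, aupr_score, (auroc_score + aupr_score) / 2.0


def type_fractions(
    network: Network,
    gold: GoldStandard,
    universe: Iterable[tuple[str, str]],
) -> tuple[float, float, float, float]:
    """Signed-prediction accuracy: (+fraction, -fraction, TP, TN).

    +fraction: of the gold activating edges, the fraction predicted with a
    positive sign (repressing analogous).  TP: fraction of gold edges
    predicted irrespective of sign; TN: fraction of non-gold pairs of the
    universe not predicted.
    """
    signed = gold.signed_edges
    if not signed:
        raise ValueError("gold standard carries no signed edges")
    pred_signs = network.edge_signs()
    activating = [e for e, s in signed.items() if s == 1]
    repressing = [e for e, s in signed.items() if s == -1]
    plus = (
        sum(1 for e in activating if pred_signs.get(e) == 1) / len(activating)
        if activating else float("nan")
    )
    minus = (
        sum(1 for e in repressing if pred_signs.get(e) == -1) / len(repressing)
        if repressing else float("nan")
    )
    tp = sum(1 for e in gold.edges if e in pred_signs) / len(gold.edges)
    non_gold = [pair for pair in universe if pair not in gold.edges]
    if not non_gold:
        raise ValueError("universe contains no non-gold pairs")
    tn = sum(1 for pair in non_gold if pair not in pred_signs) / len(non_gold)
    return plus, minus, tp, tn
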