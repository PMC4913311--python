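"""Weighted ROC evaluation of template detection at the fold level.

Each (query, template) pair carries a score, a same-fold label and a
weight.  Fold weights are reciprocal fold sizes, so every fold contributes
equally to the true/false positive rates regardless of how many members it
has; a pair's weight is the product of its query and template weights.
Ties in score collapse into a single threshold step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LabeledScore", "fold_weights", "weighted_roc", "tpr_at_fpr", "pair_weight"]


@dataclass
class LabeledScore:
    query_id: str
    template_id: str
    score: float
    same_fold: int  # 1 = same fold (true pair), 0 = different fold
    weight: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.weight) and self.weight > 0):
            raise ValueError("weight must be finite and positive")
        if self.same_fold not in (0, 1):
            raise ValueError("same_fold label must be 0 or 1")


def fold_weights(fold_assignment: dict[str, str]) -> dict[str, float]:
    """weight(id) = 1 / size(fold of id), so each fold contributes equally."""
    sizes: dict[str, int] = {}
    for fold in fold_assignment.values():
        sizes[fold] = sizes.get(fold, 0) + 1
    return {ident: 1.0 / sizes[fold] for ident, fold in fold_assignment.items()}


def pair_weight(query_id: str, template_id: str, weights: dict[str, float]) -> float:
    return weights[query_id] * weights[template_id]


def weighted_roc(items: list[LabeledScore]) -> tuple[list[tuple[float, float]], float]:
    """Weighted ROC curve and its trapezoidal area.

    Sweeps the score threshold from high to low; at each distinct score the
    TPR (FPR) is the weight fraction of positives (negatives) at or above
    the threshold.  Requires at least one positive and one negative item.
    """
    pos_total = sum(it.weight for it in items if it.same_fold == 1)
    neg_total = sum(it.weight for it in items if it.same_fold == 0)
    if pos_total == 0 or neg_total == 0:
        raise ValueError("need at least one positive and one negative item")
    ordered = sorted(items, key=lambda it: -it.score)
    curve = [(0.0, 0.0)]
    tp = fp = 0.0
    i = 0
    n = len(ordered)
    while i < n:
        j = i
        while j < n and ordered[j].score == ordered[i].score:  # tie group, one step
            if ordered[j].same_fold == 1:
                tp += ordered[j].weight
            else:
                fp += ordered[j].weight
            j += 1
        curve.append((fp / neg_total, tp / pos_total))
        i = j
    # the sweep ends with all weight accumulated; snap accumulation error
    last = curve[-1]
    if abs(last[0] - 1.0) < 1e-9 and abs(last[1] - 1.0) < 1e-9:
        curve[-1] = (1.0, 1.0)
    else:
        curve.append((1.0, 1.0))
    xs = np.array([p[0] for p in curve])
    ys = np.array([p[1] for p in curve])
    area = float(np.trapezoid(ys, xs))
    return curve, area


def tpr_at_fpr(curve: list[tuple[float, float]], fpr_level: float = 0.10) -> float:
    """TPR at the requested FPR, linearly interpolated along the curve."""
    xs = np.array([p[0] for p in curve])
    ys = np.array([p[1] for p in curve])
    if not 0.0 <= fpr_level <= 1.0:
        raise ValueError("FPR level must lie in [0, 1]")
    return float(np.interp(fpr_level, xs, ys))
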