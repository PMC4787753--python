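"""Statistical validation of predicted targets, binding sites and networks.

The target-shift test asks whether predicted targets of a TF move with the
TF's activity: per-gene expression deltas between two conditions (e.g.
wild-type versus knockout) are compared between targets and background
genes with a Wilcoxon rank-sum test. Binding-site predictions are scored
against observed ChIP peaks with a region-level ROC, and networks inferred
from synthetic data are scored against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve

from .intervals import PeakSet
from .motifs import MotifHit
from .network import RegulatoryEdge

EXACT_MAX_N = 20


def wilcoxon_rank_sum(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (rank sum of sample_a, p-value).

    Exact p by enumeration of rank assignments when n+m <= 20 with no
    ties; otherwise the normal approximation with midranks, tie correction
    and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    has_ties = len(np.unique(pooled)) < pooled.size
    if np.ptp(pooled) == 0:
        # every value identical: the statistic carries no information
        return w, 1.0
    method = "exact" if (a.size + b.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    return w, float(res.pvalue)


@dataclass
class TargetShiftResult:
    n_targets: int
    n_background: int
    rank_sum_statistic: float
    p_value: float
    direction: str  # "up" | "down" | "none"
    target_deltas: pd.Series
    background_deltas: pd.Series


def target_expression_shift(
    targets: set[str],
    expr_condition_a: pd.DataFrame,
    expr_condition_b: pd.DataFrame,
    background: set[str] | None = None,
    alpha: float = 0.05,
) -> TargetShiftResult:
    """Do predicted targets shift between two expression conditions?

    ``expr_condition_a``/``b`` are genes x samples log2 matrices over the
    same genes. Per-gene delta = mean(a) - mean(b); target deltas are
    compared with background deltas (default: all non-target measured
    genes) by a two-sided Wilcoxon rank-sum test. Direction is the sign of
    the median target-vs-background delta difference when p < alpha.
    """
    measured = set(expr_condition_a.index) & set(expr_condition_b.index)
    if not targets <= measured:
        raise ValueError("targets must be a subset of measured genes")
    if len(targets) < 3:
        raise ValueError("need >=3 targets for a meaningful test")
    if background is None:
        background = measured - targets
    else:
        if not background <= measured:
            raise ValueError("background must be a subset of measured genes")
        background = background - targets
    if not background:
        raise ValueError("background gene set is empty")

    delta = expr_condition_a.mean(axis=1) - expr_condition_b.mean(axis=1)
    tgt = delta.loc[sorted(targets)]
    bg = delta.loc[sorted(background)]
    w, p = wilcoxon_rank_sum(tgt.to_numpy(), bg.to_numpy())
    if p < alpha:
        direction = "up" if float(tgt.median() - bg.median()) > 0 else "down"
    else:
        direction = "none"
    return TargetShiftResult(len(tgt), len(bg), w, p, direction, tgt, bg)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_binding_prediction(
    predicted_sites: Sequence[MotifHit],
    evaluation_regions: PeakSet,
    truth_regions: PeakSet,
) -> ROCResult:
    """Region-level ROC of motif-score binding prediction.

    Each evaluation region is scored by the maximum log-odds of predicted
    sites overlapping it (-inf when none); positives are regions
    overlapping >=1 observed ChIP peak of the validated TF. AUC is the
    trapezoidal integral; NaN when all regions share one label.
    """
    if len(evaluation_regions) == 0:
        raise ValueError("evaluation region set is empty")
    scores = []
    labels = []
    for iv in evaluation_regions:
        best = -np.inf
        for h in predicted_sites:
            if h.interval.overlaps(iv):
                best = max(best, h.log_odds_score)
        scores.append(best)
        labels.append(int(truth_regions.any_overlap(iv.chrom, iv.start, iv.end)))
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        return ROCResult(np.array([]), np.array([]), np.array([]), float("nan"))
    finite = scores[np.isfinite(scores)]
    floor = (finite.min() - 1.0) if finite.size else -1.0
    scores = np.where(np.isfinite(scores), scores, floor)
    fpr, tpr, thr = roc_curve(labels, scores)
    return ROCResult(thr, tpr, fpr, float(sk_auc(fpr, tpr)))


@dataclass
class RecoveryMetrics:
    precision: float
    recall: float
    f1: float
    per_stage: dict[str, dict[str, float]]
    self_loop_precision: float
    self_loop_recall: float
    n_predicted: int
    n_truth: int


def _prf(pred: set, truth: set) -> tuple[float, float, float]:
    tp = len(pred & truth)
    prec = tp / len(pred) if pred else float("nan")
    rec = tp / len(truth) if truth else float("nan")
    f1 = (
        2 * prec * rec / (prec + rec)
        if pred and truth and (prec + rec) > 0
        else (0.0 if pred and truth else float("nan"))
    )
    return prec, rec, f1


def network_recovery_metrics(
    predicted: Sequence[RegulatoryEdge],
    truth_edges: Sequence[tuple[str, str, str]],
) -> RecoveryMetrics:
    """Set-based precision/recall/F1 of (source, target, state) edges.

    Literature edges are excluded from the prediction side; truth edges are
    plain triples. Self-loops are additionally scored separately. Empty
    prediction -> precision NaN, recall 0; empty truth -> recall NaN.
    """
    pred = {
        e.key for e in predicted if not e.evidence.get("literature", False)
    }
    truth = set(truth_edges)
    prec, rec, f1 = _prf(pred, truth)
    if not pred and truth:
        rec = 0.0
        f1 = 0.0

    stages = sorted({k[2] for k in pred | truth})
    per_stage = {}
    for s in stages:
        ps = {k for k in pred if k[2] == s}
        ts = {k for k in truth if k[2] == s}
        sp, sr, sf = _prf(ps, ts)
        if not ps and ts:
            sr, sf = 0.0, 0.0
        per_stage[s] = {"precision": sp, "recall": sr, "f1": sf}

    loops_p = {k for k in pred if k[0] == k[1]}
    loops_t = {k for k in truth if k[0] == k[1]}
    lp, lr, _ = _prf(loops_p, loops_t)
    if not loops_p and loops_t:
        lr = 0.0
    return RecoveryMetrics(
        prec, rec, f1, per_stage, lp, lr, len(pred), len(truth)
    )
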