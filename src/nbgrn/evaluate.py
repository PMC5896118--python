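"""Benchmark metrics for directed-network recovery.

Predictions are scored over all ordered gene pairs (parent != child) against
a gold-standard directed edge set: Matthews correlation of the binary calls,
area under the precision-recall curve (continuous Davis-Goadrich style
interpolation between operating points, the convention of the PRROC family
of tools), and partial area under the ROC curve restricted to the
high-specificity region and standardized (McClish) so that 0.5 is chance and
1 is perfect.  True edges are rare (< 10% of ordered pairs in realistic
structures), which is why AUC-PR is the headline metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EdgePredictionSet",
    "mcc",
    "auc_pr",
    "partial_auc_roc",
    "benchmark",
    "aggregate_reports",
]


@dataclass
class EdgePredictionSet:
    """Aligned truth labels, continuous scores, and binary calls per pair."""

    truth: np.ndarray
    score: np.ndarray
    call: np.ndarray

    def __post_init__(self):
        self.truth = np.asarray(self.truth, dtype=int)
        self.score = np.asarray(self.score, dtype=float)
        self.call = np.asarray(self.call, dtype=bool)
        if not (self.truth.shape == self.score.shape == self.call.shape):
            raise ValueError("truth, score, and call must have equal length")
        if self.truth.ndim != 1:
            raise ValueError("prediction lists must be 1-d")
        if not np.all(np.isin(self.truth, [0, 1])):
            raise ValueError("truth labels must be 0/1")

    @classmethod
    def from_networks(cls, true_network, inferred_network) -> "EdgePredictionSet":
        """Align two DirectedNetwork objects over all ordered pairs."""
        t_nodes, i_nodes = set(true_network.nodes), set(inferred_network.nodes)
        if t_nodes != i_nodes:
            raise ValueError(
                f"node sets differ; only in truth: {sorted(t_nodes - i_nodes, key=str)}, "
                f"only in inferred: {sorted(i_nodes - t_nodes, key=str)}"
            )
        truth_set = set(true_network.selected_edges())
        inf = inferred_network.edges.set_index(["parent", "child"])
        pairs = [(p, c) for p in true_network.nodes for c in true_network.nodes if p != c]
        truth = np.array([1 if pc in truth_set else 0 for pc in pairs])
        score = np.array([inf.loc[pc, "score"] for pc in pairs], dtype=float)
        call = np.array([bool(inf.loc[pc, "selected"]) for pc in pairs])
        return cls(truth=truth, score=score, call=call)


def mcc(predictions: EdgePredictionSet) -> float:
    """Matthews correlation coefficient of the binary calls.

    Returns 0 (with a warning) when any confusion-matrix marginal is zero.
    """
    t, c = predictions.truth.astype(bool), predictions.call
    tp = int(np.sum(t & c))
    tn = int(np.sum(~t & ~c))
    fp = int(np.sum(~t & c))
    fn = int(np.sum(t & ~c))
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        warnings.warn("degenerate confusion-matrix marginal; MCC set to 0", stacklevel=2)
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom2)


def _curve_points(truth: np.ndarray, score: np.ndarray):
    """Cumulative (TP, FP) at each descending unique score (ties merged)."""
    order = np.argsort(-score, kind="mergesort")
    t = truth[order]
    s = score[order]
    # indices where a tie group ends
    boundary = np.nonzero(np.diff(s))[0]
    ends = np.append(boundary, t.size - 1)
    cum_tp = np.cumsum(t)[ends]
    cum_fp = (np.arange(1, t.size + 1) - np.cumsum(t))[ends]
    tp = np.concatenate([[0], cum_tp]).astype(float)
    fp = np.concatenate([[0], cum_fp]).astype(float)
    return tp, fp


def auc_pr(predictions: EdgePredictionSet) -> float:
    """Area under the precision-recall curve, continuous interpolation.

    Between consecutive operating points the curve is interpolated in
    (TP, FP) space (false positives accrue linearly with true positives at
    the local skew), and precision is integrated over recall in closed form
    on every segment.  Tied scores collapse to a single threshold.
    """
    truth, score = predictions.truth, predictions.score
    P = int(truth.sum())
    if P == 0:
        raise ValueError("AUC-PR undefined without positive labels")
    tp, fp = _curve_points(truth, score)
    area = 0.0
    for a in range(len(tp) - 1):
        d_tp = tp[a + 1] - tp[a]
        if d_tp == 0:
            continue
        skew = (fp[a + 1] - fp[a]) / d_tp
        k = 1.0 + skew
        c = tp[a] + fp[a]
        if c == 0:
            # segment from the origin: precision constant at 1/k
            area += d_tp / k
        else:
            area += d_tp / k + (k * tp[a] - c) / k**2 * np.log((c + k * d_tp) / c)
    return float(area / P)


def _roc_points(truth: np.ndarray, score: np.ndarray):
    tp, fp = _curve_points(truth, score)
    P, N = tp[-1], fp[-1]
    if P == 0 or N == 0:
        raise ValueError("ROC undefined without both positive and negative labels")
    return fp / N, tp / P  # FPR, TPR


def _piecewise_area(x: np.ndarray, y: np.ndarray, x_hi: float) -> float:
    """Trapezoid area under the piecewise-linear curve on [0, x_hi]."""
    area = 0.0
    for a in range(len(x) - 1):
        x0, x1 = x[a], x[a + 1]
        y0, y1 = y[a], y[a + 1]
        if x0 >= x_hi:
            break
        if x1 <= x0:
            continue
        hi = min(x1, x_hi)
        y_hi = y0 + (y1 - y0) * (hi - x0) / (x1 - x0)
        area += 0.5 * (y0 + y_hi) * (hi - x0)
    return area


def partial_auc_roc(
    predictions: EdgePredictionSet, cutoff: float = 0.95, bound: str = "specificity"
) -> float:
    """Standardized partial AUC-ROC over the high-specificity region.

    With ``bound="specificity"`` the ROC is integrated over false-positive
    rate in [0, 1-cutoff] and McClish-standardized to [0, 1] (0.5 = chance,
    1 = perfect).  ``bound="sensitivity"`` restricts to true-positive rate
    >= cutoff instead.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    fpr, tpr = _roc_points(predictions.truth, predictions.score)
    c = 1.0 - cutoff
    if bound == "specificity":
        area = _piecewise_area(fpr, tpr, c)
        a_min, a_max = c**2 / 2.0, c
    elif bound == "sensitivity":
        # integrate (1 - FPR) over TPR in [cutoff, 1]; mirror then reuse
        x = 1.0 - tpr[::-1]
        y = 1.0 - fpr[::-1]
        area = _piecewise_area(x, y, c)
        a_min, a_max = c**2 / 2.0, c
    else:
        raise ValueError("bound must be 'specificity' or 'sensitivity'")
    if a_max == a_min:
        return 0.5
    return float(0.5 * (1.0 + (area - a_min) / (a_max - a_min)))


def benchmark(true_network, inferred_network) -> dict:
    """All three metrics plus confusion counts for one inferred network."""
    preds = EdgePredictionSet.from_networks(true_network, inferred_network)
    t, c = preds.truth.astype(bool), preds.call
    report = {
        "n_pairs": int(preds.truth.size),
        "n_true_edges": int(preds.truth.sum()),
        "tp": int(np.sum(t & c)),
        "fp": int(np.sum(~t & c)),
        "fn": int(np.sum(t & ~c)),
        "tn": int(np.sum(~t & ~c)),
        "mcc": float(mcc(preds)),
        "auc_pr": float(auc_pr(preds)),
        "partial_auc_roc": float(partial_auc_roc(preds)),
    }
    report["prevalence"] = report["n_true_edges"] / report["n_pairs"]
    return report


def aggregate_reports(reports: list[dict]) -> dict:
    """Per-metric medians over repeated simulations of the same network."""
    keys = ("mcc", "auc_pr", "partial_auc_roc", "prevalence")
    return {f"median_{k}": float(np.median([r[k] for r in reports])) for k in keys}
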