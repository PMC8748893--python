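"""Benchmark metrics for comparing optimizer settings and classifying
model predictions.

Rank-based comparison: paired multi-start experiments (same start points for
each optimizer setting) are compared by ranking, per start, the final
objective values across settings (lower is better, ties averaged) and
averaging the ranks over starts.

Convergence criteria: a *value-to-reach* threshold is derived from a
reference optimizer's ten best final values (mean + 1 SD); a start counts as
converged when its full-dataset objective first drops below the threshold.
Cost is accounted in condition simulations, a hardware-independent proxy.

Classification: steady-state readouts are labelled *responsive* when they
fall below 50% of the untreated reference (strictly), and model scores are
assessed by ROC analysis with the discrete slope-1 tangency threshold
(the point maximizing TPR - FPR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RankingTable",
    "ROCResult",
    "rank_settings",
    "value_to_reach",
    "convergence_metrics",
    "waterfall",
    "classify_responsive",
    "roc_and_threshold",
    "parameter_interval_coverage",
]


@dataclass
class RankingTable:
    """Per-start ranks of optimizer settings and their means."""

    setting_names: list[str]
    finals: np.ndarray        # (n_settings, n_starts)
    ranks: np.ndarray         # (n_settings, n_starts)
    mean_ranks: np.ndarray    # (n_settings,)

    def ordered(self) -> list[tuple[str, float]]:
        order = np.argsort(self.mean_ranks)
        return [(self.setting_names[i], float(self.mean_ranks[i])) for i in order]


def rank_settings(finals: np.ndarray, setting_names: list[str] | None = None) -> RankingTable:
    """Rank optimizer settings per start by final objective value.

    ``finals`` is a (settings x starts) matrix of final values from *paired*
    starts.  Per start, settings are ranked ascending (rank 1 = best), ties
    averaged.  Failed/missing finals (NaN/inf) rank worst, tied among
    themselves.  The per-setting mean over starts summarizes overall quality.
    """
    finals = np.asarray(finals, dtype=float)
    if finals.ndim != 2:
        raise ValueError("finals must be a (settings x starts) matrix")
    n_settings, n_starts = finals.shape
    if setting_names is None:
        setting_names = [f"setting_{i}" for i in range(n_settings)]
    if len(setting_names) != n_settings:
        raise ValueError("setting_names length mismatch")
    col = np.where(np.isfinite(finals), finals, np.inf)
    ranks = np.empty_like(finals)
    for s in range(n_starts):
        ranks[:, s] = stats.rankdata(col[:, s], method="average")
    return RankingTable(list(setting_names), finals, ranks, ranks.mean(axis=1))


def value_to_reach(reference_finals: np.ndarray) -> float:
    """Convergence threshold: mean + 1 sample SD of the ten best finals.

    With fewer than ten finite values, all of them are used (with a
    warning).  Sample SD uses ddof=1.
    """
    vals = np.asarray(reference_finals, dtype=float)
    vals = np.sort(vals[np.isfinite(vals)])
    if vals.size == 0:
        raise ValueError("no finite reference finals")
    if vals.size < 10:
        import warnings

        warnings.warn(f"only {vals.size} reference finals; value-to-reach uses all of them")
    best = vals[: min(10, vals.size)]
    sd = float(np.std(best, ddof=1)) if best.size > 1 else 0.0
    return float(np.mean(best)) + sd


def convergence_metrics(
    histories,
    threshold: float,
    objective_traces: list[np.ndarray] | None = None,
    cost_traces: list[np.ndarray] | None = None,
) -> dict:
    """Threshold-based convergence summary over a set of runs.

    By default each history's per-epoch full-dataset objective trace
    (``full_j_per_epoch``) and cumulative simulation counts are used; both
    can be overridden with explicit traces.  A run converges at the first
    index where its objective <= threshold; its cost at that index is the
    cumulative number of condition simulations.

    Returns ``n_converged``, ``time_to_first_convergence`` (in simulations;
    inf if none converged) and ``converged_starts_per_unit_cost``
    (n_converged divided by the total cost of all runs).
    """
    if objective_traces is None:
        objective_traces = [np.asarray(h.full_j_per_epoch, dtype=float) for h in histories]
    if cost_traces is None:
        cost_traces = []
        for h, tr in zip(histories, objective_traces):
            spe = max(h.steps_per_epoch, 1)
            sims = np.asarray(h.sim_count_trace, dtype=float)
            # cost at each epoch boundary = sims after that epoch's steps
            idx = np.minimum((np.arange(len(tr)) + 1) * spe - 1, len(sims) - 1)
            cost_traces.append(sims[idx] if len(sims) else np.zeros(len(tr)))

    n_converged = 0
    first_costs = []
    total_cost = 0.0
    for tr, cost in zip(objective_traces, cost_traces):
        tr = np.asarray(tr, dtype=float)
        cost = np.asarray(cost, dtype=float)
        total_cost += float(cost[-1]) if cost.size else 0.0
        below = np.flatnonzero(tr <= threshold)
        if below.size:
            n_converged += 1
            first_costs.append(float(cost[below[0]]))
    time_to_first = min(first_costs) if first_costs else np.inf
    per_cost = n_converged / total_cost if total_cost > 0 else 0.0
    return {
        "n_converged": n_converged,
        "time_to_first_convergence": time_to_first,
        "converged_starts_per_unit_cost": per_cost,
    }


def waterfall(finals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted final values with their start indices (stable for ties)."""
    finals = np.asarray(finals, dtype=float)
    order = np.argsort(finals, kind="stable")
    return finals[order], order


def classify_responsive(
    readouts: dict,
    untreated_reference: dict,
    groups: dict,
) -> dict:
    """Label conditions responsive iff readout < 0.5 x untreated reference.

    ``groups`` maps condition id -> group key (e.g. cell line);
    ``untreated_reference`` maps group key -> untreated readout.  The rule is
    strict: a readout of exactly half the reference is non-responsive.
    """
    labels = {}
    for cid, value in readouts.items():
        g = groups[cid]
        if g not in untreated_reference:
            raise KeyError(f"no untreated reference for group {g!r}")
        labels[cid] = bool(value < 0.5 * untreated_reference[g])
    return labels


@dataclass
class ROCResult:
    """ROC sweep with the slope-1 tangency threshold.

    Scores are read as "higher = non-responsive" is *not* assumed: the caller
    passes scores oriented so that larger values indicate the positive class.
    ``chosen_threshold`` maximizes TPR - FPR (ties broken toward smaller
    FPR); a score counts as positive when score >= threshold.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    chosen_threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float

    def classify(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) >= self.chosen_threshold


def roc_and_threshold(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve, trapezoidal AUC and the discrete slope-1 tangency point.

    The threshold sweep runs over the unique score values (plus a
    cut-nothing sentinel); the chosen threshold maximizes Youden's
    TPR - FPR, the discrete analogue of the point where the ROC is tangent
    to a 45-degree line.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    # descending unique thresholds; predict positive where score >= thr
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        pred = scores >= thr
        tpr[i] = np.sum(pred & labels) / n_pos
        fpr[i] = np.sum(pred & ~labels) / n_neg
    auc = float(np.trapezoid(tpr, fpr))

    youden = tpr - fpr
    best = np.flatnonzero(youden == youden.max())
    # ties toward smaller FPR (more specific threshold)
    chosen = best[np.argmin(fpr[best])]
    thr = float(thresholds[chosen])
    pred = scores >= thr
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    return ROCResult(thresholds, tpr, fpr, auc, thr, tp, fp, tn, fn,
                     (tp + tn) / scores.size)


def parameter_interval_coverage(
    thetas: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
) -> np.ndarray:
    """Per-parameter fraction of the bound interval spanned by a set of runs.

    ``thetas`` is (n_runs x n_theta) on the log10 scale; coverage_j =
    (max_j - min_j) / (upper_j - lower_j).
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim != 2 or thetas.shape[0] < 2:
        raise ValueError("need at least two runs")
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    width = upper - lower
    if np.any(width <= 0):
        raise ValueError("degenerate bounds")
    return (thetas.max(axis=0) - thetas.min(axis=0)) / width
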