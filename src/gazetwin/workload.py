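"""Clinical-workload analysis from fixation durations.

Total fixation duration per case is used as a proxy for the visual
attention a case demands: cases are ranked by predicted total duration
(rank 1 = longest = highest workload) and compared with the ground-truth
ranking via Pearson (on totals) and Spearman (on ranks) correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Scanpath


@dataclass
class WorkloadRecord:
    case_id: str
    total_true_duration: float
    total_pred_duration: float
    true_rank: float  # 1 = longest total duration; ties get average ranks
    pred_rank: float


def total_duration(path: Scanpath) -> float:
    """Sum of fixation durations in seconds."""
    return float(sum(f.t for f in path.fixations))


def build_records(pred: dict[str, Scanpath], gt: dict[str, Scanpath]) -> list[WorkloadRecord]:
    """Pair predicted and true totals and rank them (rank 1 = highest workload)."""
    if set(pred) != set(gt):
        raise ValueError(
            f"case-id mismatch: {sorted(set(pred) ^ set(gt))}")
    ids = sorted(pred)
    t_true = np.array([total_duration(gt[c]) for c in ids])
    t_pred = np.array([total_duration(pred[c]) for c in ids])
    r_true = stats.rankdata(-t_true, method="average")
    r_pred = stats.rankdata(-t_pred, method="average")
    return [WorkloadRecord(c, float(tt), float(tp), float(rt), float(rp))
            for c, tt, tp, rt, rp in zip(ids, t_true, t_pred, r_true, r_pred)]


def workload_correlations(records: list[WorkloadRecord]):
    """Pearson r on totals and Spearman rho on ranks, each with a p-value.

    Returns ``((r, p_r), (rho, p_rho))``; a constant vector makes the
    corresponding correlation undefined and it is reported as NaN.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 cases for correlations")
    t_true = np.array([r.total_true_duration for r in records])
    t_pred = np.array([r.total_pred_duration for r in records])
    nan = (float("nan"), float("nan"))
    if t_true.std() == 0 or t_pred.std() == 0:
        return nan, nan
    pearson = stats.pearsonr(t_true, t_pred)
    spearman = stats.spearmanr(t_true, t_pred)
    return ((float(pearson.statistic), float(pearson.pvalue)),
            (float(spearman.statistic), float(spearman.pvalue)))


def rank_extremes(records: list[WorkloadRecord], k: int) -> tuple[list[str], list[str]]:
    """Top-k (highest predicted workload) and bottom-k case ids.

    Ordering is deterministic: descending predicted total, ties broken by
    case_id lexicographic; the bottom list is reported lowest-first.
    Requires ``2 * k <= n`` so the two lists cannot overlap.
    """
    n = len(records)
    if k < 1 or 2 * k > n:
        raise ValueError(f"k must satisfy 1 <= k <= n/2 (n={n}, k={k})")
    ordered = sorted(records, key=lambda r: (-r.total_pred_duration, r.case_id))
    top = [r.case_id for r in ordered[:k]]
    bottom = [r.case_id for r in ordered[-k:]][::-1]
    return top, bottom


def records_frame(records: list[WorkloadRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def write_report(records: list[WorkloadRecord], csv_path) -> None:
    records_frame(records).to_csv(csv_path, index=False, float_format="%.9f")


def plot_workload(records: list[WorkloadRecord], png_path) -> None:
    """Two-panel scatter: true vs predicted totals, and true vs predicted ranks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    (r, _), (rho, _) = workload_correlations(records)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.2))
    t_true = [x.total_true_duration for x in records]
    t_pred = [x.total_pred_duration for x in records]
    axes[0].scatter(t_true, t_pred, s=12, alpha=0.6)
    axes[0].set_xlabel("true total fixation duration (s)")
    axes[0].set_ylabel("predicted total fixation duration (s)")
    axes[0].set_title(f"Pearson r = {r:.2f}")
    axes[1].scatter([x.true_rank for x in records], [x.pred_rank for x in records],
                    s=12, alpha=0.6, color="tab:orange")
    axes[1].set_xlabel("true workload rank")
    axes[1].set_ylabel("predicted workload rank")
    axes[1].set_title(f"Spearman rho = {rho:.2f}")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
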