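"""Threshold-free ranking metrics: AUROC, AUPRC and AP@50.

AUROC is the Mann-Whitney probability that a random positive outscores a
random negative (ties half credit); AUPRC is the area under the
precision-recall step curve (precision summed over recall increments);
AP@50 averages top-k precision, AP(k) = TP@k / k, over k = 1..50 of the
ranked prediction list. Per-side-effect reports give both micro (pooled)
and macro (group-averaged) summaries, since class imbalance makes the two
diverge substantially on this task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. a single-class group)."""


@dataclass(frozen=True)
class ScoredLabels:
    """Parallel score/label vectors, optionally tagged with a group id."""

    scores: np.ndarray
    labels: np.ndarray
    group: str | None = None
    group_name: str | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64).ravel()
        y = np.asarray(self.labels).ravel().astype(np.int8)
        if s.shape != y.shape:
            raise ValueError("scores and labels must have equal length")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "labels", y)

    def __len__(self) -> int:
        return len(self.scores)


def auroc(data: ScoredLabels) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties 1/2)."""
    if data.labels.min() == data.labels.max():
        raise UndefinedMetricError("AUROC undefined: only one class present")
    return float(roc_auc_score(data.labels, data.scores))


def auprc(data: ScoredLabels) -> float:
    """Area under the precision-recall step curve."""
    if data.labels.sum() == 0:
        raise UndefinedMetricError("AUPRC undefined: no positives")
    return float(average_precision_score(data.labels, data.scores))


def ap_at_50(data: ScoredLabels, k: int = 50) -> float:
    """Mean over k' = 1..k of precision within the top-k' ranked items.

    Items are sorted by descending score; ties keep input order (stable
    sort). If fewer than k items are scored, k truncates to n.
    """
    n = len(data)
    if n == 0:
        raise ValueError("AP@k undefined on empty input")
    k = min(k, n)
    order = np.argsort(-data.scores, kind="stable")
    ranked = data.labels[order][:k]
    cum_tp = np.cumsum(ranked)
    precisions = cum_tp / np.arange(1, k + 1)
    return float(precisions.mean())


@dataclass
class MetricsReport:
    """Global and per-group evaluation summary."""

    micro: dict[str, float]
    macro: dict[str, float]
    per_group: pd.DataFrame = field(default_factory=pd.DataFrame)
    excluded_groups: list[str] = field(default_factory=list)

    def best_worst(self, n: int = 10, by: str = "auprc") -> tuple[pd.DataFrame, pd.DataFrame]:
        """Top/bottom-n groups ordered by a metric (default AUPRC)."""
        g = self.per_group.sort_values(by, ascending=False)
        return g.head(n), g.tail(n).iloc[::-1]

    def to_markdown(self) -> str:
        lines = ["| metric | micro | macro |", "|---|---|---|"]
        for m in ("auroc", "auprc", "ap50"):
            lines.append(f"| {m} | {self.micro[m]:.4f} | {self.macro[m]:.4f} |")
        if len(self.per_group):
            best, worst = self.best_worst()
            lines += ["", "Best groups by AUPRC:", best.to_markdown(index=False)]
            lines += ["", "Worst groups by AUPRC:", worst.to_markdown(index=False)]
        return "\n".join(lines)


def per_side_effect_report(groups: list[ScoredLabels]) -> MetricsReport:
    """Evaluate each side effect's group and pool for micro summaries.

    Groups with a single label class have no defined AUROC/AUPRC; they are
    excluded from the macro averages and listed in ``excluded_groups``.
    """
    rows = []
    excluded = []
    for g in groups:
        gid = g.group if g.group is not None else str(len(rows))
        if g.labels.min() == g.labels.max():
            excluded.append(gid)
            continue
        rows.append(
            {
                "group": gid,
                "name": g.group_name or "",
                "auroc": auroc(g),
                "auprc": auprc(g),
                "ap50": ap_at_50(g),
                "n_positives": int(g.labels.sum()),
                "n": len(g),
            }
        )
    per_group = pd.DataFrame(rows)
    pooled = ScoredLabels(
        np.concatenate([g.scores for g in groups]),
        np.concatenate([g.labels for g in groups]),
    )
    micro = {"auroc": auroc(pooled), "auprc": auprc(pooled), "ap50": ap_at_50(pooled)}
    if len(per_group):
        macro = {
            "auroc": float(per_group["auroc"].mean()),
            "auprc": float(per_group["auprc"].mean()),
            "ap50": float(per_group["ap50"].mean()),
        }
    else:
        macro = {"auroc": float("nan"), "auprc": float("nan"), "ap50": float("nan")}
    return MetricsReport(micro=micro, macro=macro, per_group=per_group, excluded_groups=excluded)


def columnwise_report(
    probs: np.ndarray,
    targets: np.ndarray,
    group_ids: list[str] | None = None,
    group_names: list[str] | None = None,
) -> MetricsReport:
    """Per-side-effect report for a multi-label probability matrix.

    Each column (side effect) is one group evaluated over all rows (pairs).
    """
    n, m = probs.shape
    if targets.shape != (n, m):
        raise ValueError("probability and target matrices must share shape")
    groups = [
        ScoredLabels(
            probs[:, j],
            targets[:, j],
            group=group_ids[j] if group_ids else str(j),
            group_name=group_names[j] if group_names else None,
        )
        for j in range(m)
    ]
    return per_side_effect_report(groups)


def aggregate_runs(reports: list[dict[str, float]]) -> dict[str, tuple[float, float]]:
    """Mean and sample standard deviation of each metric across folds/runs."""
    keys = reports[0].keys()
    out = {}
    for key in keys:
        vals = np.array([r[key] for r in reports], dtype=np.float64)
        std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[key] = (float(vals.mean()), std)
    return out
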