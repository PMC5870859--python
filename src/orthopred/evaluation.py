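"""Time-series cross-validation and the virtual-screening metric suite.

Evaluation is chronological: with ``TimeSeriesSplit``-style folds every
test compound is strictly newer than all compounds a model trained on,
which mimics prospective prediction rather than random-split optimism.
Metrics per target are precision/recall/F1 at p(activity) > 0.5, the
area under the precision–recall curve, and BEDROC (α = 20), the
Boltzmann-enhanced early-recognition statistic of Truchon and Bayly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score
from sklearn.model_selection import TimeSeriesSplit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricConfig:
    """Evaluation settings: decision threshold, BEDROC α, fold count."""

    decision_threshold: float = 0.5
    bedroc_alpha: float = 20.0
    n_splits: int = 5

    def __post_init__(self):
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.bedroc_alpha <= 0:
            raise ValueError("bedroc_alpha must be positive")
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")


def time_series_folds(dates, n_splits: int = 5) -> list[tuple[np.ndarray, np.ndarray]]:
    """Expanding-window chronological folds over records with dates.

    Records are ordered by date (missing dates last, original order
    preserved among ties).  With t = ⌊n/(n_splits+1)⌋ the test blocks
    are the ``n_splits`` consecutive windows of size t ending at the
    newest record, and each fold trains on everything strictly older
    than its test block; the oldest ⌊n/(n_splits+1)⌋ + remainder records
    are never tested.

    Returns (train_indices, test_indices) pairs into the *original*
    record order.
    """
    dates = pd.to_datetime(pd.Series(list(dates)), errors="coerce")
    n = len(dates)
    if n <= n_splits:
        raise ValueError(f"need more than n_splits={n_splits} records, got {n}")
    order = dates.sort_values(na_position="last", kind="mergesort").index.to_numpy()
    folds = []
    for train_pos, test_pos in TimeSeriesSplit(n_splits=n_splits).split(order):
        folds.append((order[train_pos], order[test_pos]))
    return folds


def classification_metrics(
    p_values, labels, threshold: float = 0.5
) -> dict[str, float]:
    """Precision, recall and F1 of thresholded probabilities.

    Precision is NaN (undefined, not zero) when no compound is called
    positive; F1 is NaN whenever precision is undefined or precision
    and recall are both zero.
    """
    p = np.asarray(p_values, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(p) == 0:
        raise ValueError("empty input")
    calls = p > threshold
    tp = int(np.sum(calls & (y == 1)))
    fp = int(np.sum(calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))
    precision = tp / (tp + fp) if (tp + fp) > 0 else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        f1 = float("nan") if math.isnan(precision) or math.isnan(recall) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {"precision": precision, "recall": recall, "f1": f1}


def pr_auc(scores, labels) -> float:
    """Area under the precision–recall curve (step summation, no
    interpolation; tied scores grouped)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("pr_auc requires both classes")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def bedroc(scores, labels, alpha: float = 20.0) -> float:
    """Boltzmann-enhanced discrimination of ROC (Truchon–Bayly).

    With n actives among N compounds ranked by descending score (ranks
    r_i, 1-based, ties kept in input order with a warning),

        RIE    = Σ exp(−α·r_i/N) / [ (n/N)·(1−e^{−α}) / (e^{α/N}−1) ]
        BEDROC = RIE · Ra·sinh(α/2) / (cosh(α/2) − cosh(α/2 − α·Ra))
                 + 1 / (1 − e^{α(1−Ra)}),   Ra = n/N

    which maps early-recognition performance onto [0, 1].  The
    degenerate all-active input is defined as 1 (no ranking possible).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    N = len(s)
    n = int((y == 1).sum())
    if n == 0:
        raise ValueError("bedroc requires at least one active")
    if n == N:
        logger.warning("all compounds active: BEDROC degenerate, defined as 1")
        return 1.0
    if len(np.unique(s)) < N:
        logger.warning("tied scores in bedroc; ties broken by stable input order")
    order = np.argsort(-s, kind="stable")
    ranks = np.empty(N, dtype=float)
    ranks[order] = np.arange(1, N + 1)
    r_act = ranks[y == 1]
    ra = n / N
    rie_denom = ra * (1.0 - math.exp(-alpha)) / (math.exp(alpha / N) - 1.0)
    rie = float(np.sum(np.exp(-alpha * r_act / N))) / rie_denom
    factor = ra * math.sinh(alpha / 2.0) / (
        math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra)
    )
    constant = 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))
    return rie * factor + constant


def fold_metrics(
    p_values, labels, config: MetricConfig | None = None
) -> dict[str, float]:
    """All metrics for one evaluation block (one fold, or folds pooled)."""
    config = config or MetricConfig()
    out = classification_metrics(p_values, labels, config.decision_threshold)
    y = np.asarray(labels, dtype=int)
    if 0 < y.sum() < len(y):
        out["pr_auc"] = pr_auc(p_values, labels)
        out["bedroc"] = bedroc(p_values, labels, config.bedroc_alpha)
    else:
        out["pr_auc"] = float("nan")
        out["bedroc"] = float("nan")
    return out


@dataclass
class BenchmarkReport:
    """Paired before/after-orthologue comparison across targets."""

    per_target: pd.DataFrame  # target, <metric>_before, <metric>_after, f1_delta
    share_stable_or_improved: float  # % of targets with F1 after >= before
    medians: pd.DataFrame  # metric, arm, median, iqr

    def summary(self) -> str:
        lines = [
            f"targets compared: {len(self.per_target)}",
            f"stable or improved F1: {self.share_stable_or_improved:.1f}%",
        ]
        for _, row in self.medians.iterrows():
            lines.append(
                f"{row['metric']:>9} [{row['arm']}] median {row['median']:.3f} "
                f"(IQR {row['iqr']:.3f})"
            )
        return "\n".join(lines)


METRIC_NAMES = ("precision", "recall", "f1", "pr_auc", "bedroc")


def benchmark(
    per_target_before: pd.DataFrame, per_target_after: pd.DataFrame
) -> BenchmarkReport:
    """Pair per-target metric tables from two arms sharing folds.

    Both frames need a ``target`` column plus metric columns; the target
    lists must match exactly.
    """
    b = per_target_before.set_index("target").sort_index()
    a = per_target_after.set_index("target").sort_index()
    if list(b.index) != list(a.index):
        raise ValueError("before/after arms cover different target lists")
    metrics = [m for m in METRIC_NAMES if m in b.columns and m in a.columns]
    paired = pd.DataFrame(index=b.index)
    for m in metrics:
        paired[f"{m}_before"] = b[m]
        paired[f"{m}_after"] = a[m]
    paired["f1_delta"] = paired["f1_after"] - paired["f1_before"]
    ok = paired.dropna(subset=["f1_delta"])
    share = 100.0 * float((ok["f1_delta"] >= 0).mean()) if len(ok) else float("nan")

    rows = []
    for m in metrics:
        for arm, frame in (("before", b), ("after", a)):
            v = frame[m].dropna().to_numpy(dtype=float)
            rows.append({
                "metric": m, "arm": arm,
                "median": float(np.median(v)) if len(v) else float("nan"),
                "iqr": float(np.subtract(*np.percentile(v, [75, 25])))
                if len(v) else float("nan"),
            })
    return BenchmarkReport(paired.reset_index(), share, pd.DataFrame(rows))
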