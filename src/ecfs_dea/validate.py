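"""Quantitative and visual validation of a selected feature on held-out samples.

Provides the 2x2 confusion matrix, per-class and support-weighted
precision/recall/F1, the ROC staircase with trapezoidal AUC computed from
ensemble vote-fraction scores, and the projection-heatmap sample ordering
(k-means on the discrete classification results; for binary predictions this
reduces to grouping by predicted class, which is asserted in tests).

Two metric layers are exposed deliberately:

* :func:`precision_recall_f1` — full-precision closed-form metrics (weighted =
  support-weighted average); and
* :func:`rounded_metric_table` — the 3-decimal presentation layer, in which F1
  is computed from the already-rounded precision and recall and weighted rows
  are rounded means of the rounded per-class values. This sequential rounding
  is how such report tables are conventionally printed, and differs from
  rounding the exact values by one unit in the last place in some cells.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class ConfusionMatrix2x2:
    """counts[t][p] = number of samples with true class t predicted as p."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 2x2 with non-negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float


@dataclass
class ValidationReport:
    """Everything the feature-validation stage computes for one test set."""

    confusion: ConfusionMatrix2x2
    per_class: list[ClassMetrics]
    weighted: ClassMetrics
    roc_points: np.ndarray  # (k, 2) columns FPR, TPR
    auc: float
    heatmap_sample_order: np.ndarray
    heatmap_clusters: np.ndarray
    class_names: tuple[str, str] = ("0", "1")


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix2x2:
    """Count the 2x2 confusion matrix for labels in {0, 1}."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only labels 0 and 1")
    counts = np.zeros((2, 2), dtype=np.int64)
    for t in (0, 1):
        for p in (0, 1):
            counts[t, p] = int(np.sum((y_true == t) & (y_pred == p)))
    return ConfusionMatrix2x2(counts)


def precision_recall_f1(cm: ConfusionMatrix2x2) -> tuple[list[ClassMetrics], ClassMetrics]:
    """Full-precision per-class metrics and their support-weighted average.

    Precision of a class with an empty predicted column is defined as 0.
    A class with no true samples makes recall undefined and is an error.
    """
    c = cm.counts
    supports = c.sum(axis=1)
    if (supports == 0).any():
        raise ValueError("a class with no true samples has undefined recall")
    per_class = []
    for k in (0, 1):
        col = c[:, k].sum()
        precision = float(c[k, k] / col) if col > 0 else 0.0
        recall = float(c[k, k] / supports[k])
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        per_class.append(ClassMetrics(precision, recall, float(f1)))
    total = supports.sum()
    weighted = ClassMetrics(
        *(
            float(sum(supports[k] * getattr(per_class[k], m) for k in (0, 1)) / total)
            for m in ("precision", "recall", "f1")
        )
    )
    return per_class, weighted


def rounded_metric_table(
    cm: ConfusionMatrix2x2,
    class_names: tuple[str, str] = ("0", "1"),
    digits: int = 3,
) -> dict:
    """The printed-report layer: sequentially rounded precision/recall/F1.

    Precision and recall are rounded to ``digits`` decimals; each class's F1 is
    the harmonic mean of the ROUNDED precision and recall, rounded again; the
    weighted row is the support-weighted mean of the rounded per-class values,
    rounded once more.
    """
    c = cm.counts
    supports = c.sum(axis=1)
    if (supports == 0).any():
        raise ValueError("a class with no true samples has undefined recall")
    table: dict = {}
    rows = []
    for k in (0, 1):
        col = c[:, k].sum()
        p = round(float(c[k, k] / col) if col > 0 else 0.0, digits)
        r = round(float(c[k, k] / supports[k]), digits)
        f = round(2 * p * r / (p + r), digits) if p + r > 0 else 0.0
        rows.append((p, r, f))
        table[class_names[k]] = {"precision": p, "recall": r, "f1": f}
    weights = supports / supports.sum()
    table["weighted"] = {
        m: round(float(sum(weights[k] * rows[k][i] for k in (0, 1))), digits)
        for i, m in enumerate(("precision", "recall", "f1"))
    }
    return table


def roc_curve_points(scores: np.ndarray, y_true: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC staircase over all distinct score thresholds + trapezoidal AUC.

    Samples with tied scores move between the confusion cells together, so the
    trapezoid equals P(score+ > score-) + 0.5 P(score+ = score-).
    """
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.int64)
    if len(np.unique(y_true)) != 2:
        raise ValueError("ROC needs both classes present in y_true")
    fpr, tpr, _ = _sk_roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def heatmap_order(
    y_pred: np.ndarray, k: int = 2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample reordering for the projection heatmap.

    Runs k-means (10 restarts, seeded) on the 1-D discrete projection values —
    the hard classification results — and orders clusters by ascending centroid,
    samples within a cluster by original index. If k exceeds the number of
    distinct projection values the clustering collapses to grouping by value.
    Returns (ordered sample indices, cluster label per ordered sample), with
    cluster labels relabelled 0..k-1 in centroid order.
    """
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_pred.ndim != 1 or y_pred.size == 0:
        raise ValueError("y_pred must be a non-empty 1-D vector")
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct = np.unique(y_pred)
    if k >= distinct.size:
        assignments = np.searchsorted(distinct, y_pred)
        centroids = distinct
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        raw = km.fit_predict(y_pred.reshape(-1, 1))
        centroid_order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
        relabel = np.empty(k, dtype=np.int64)
        relabel[centroid_order] = np.arange(k)
        assignments = relabel[raw]
        centroids = km.cluster_centers_.ravel()[centroid_order]
    order = np.lexsort((np.arange(y_pred.size), assignments))
    return order, assignments[order]


def validation_report(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray,
    class_names: tuple[str, str] = ("0", "1"),
    *,
    k: int = 2,
    seed: int = 0,
) -> ValidationReport:
    """Assemble the full validation report from test-set predictions and scores."""
    cm = confusion(y_true, y_pred)
    per_class, weighted = precision_recall_f1(cm)
    roc_points, auc = roc_curve_points(scores, y_true)
    order, clusters = heatmap_order(np.asarray(y_pred), k=k, seed=seed)
    return ValidationReport(cm, per_class, weighted, roc_points, auc, order, clusters, class_names)


def report_to_dict(report: ValidationReport) -> dict:
    """JSON-ready dict: full-precision metrics plus the rounded presentation table."""
    names = report.class_names
    return {
        "class_names": list(names),
        "confusion": report.confusion.counts.tolist(),
        "accuracy": report.confusion.accuracy,
        "per_class": {
            names[k]: vars(report.per_class[k]) for k in (0, 1)
        },
        "weighted": vars(report.weighted),
        "rounded": rounded_metric_table(report.confusion, names),
        "auc": report.auc,
        "heatmap_sample_order": report.heatmap_sample_order.tolist(),
        "heatmap_clusters": report.heatmap_clusters.tolist(),
    }


def export_plots(
    report: ValidationReport,
    test_X_selected: np.ndarray,
    path_prefix,
    *,
    variable_names: list[str] | None = None,
    sample_ids: list[str] | None = None,
    y_true: np.ndarray | None = None,
    y_pred: np.ndarray | None = None,
    render: bool = False,
) -> list[str]:
    """Write plot-ready tables (and optionally PNGs) for one validation run.

    Always writes ``<prefix>.report.json``, ``<prefix>.confusion.tsv``,
    ``<prefix>.roc.tsv`` and ``<prefix>.heatmap.tsv`` (selected-variable
    expression over the reordered samples plus label/prediction/cluster rows).
    A scatter table is written for selections of 1-3 variables (1-D scatter
    uses the sample index as x); larger selections skip it with a warning.
    """
    from pathlib import Path

    test_X_selected = np.asarray(test_X_selected, dtype=np.float64)
    n, p = test_X_selected.shape
    prefix = str(path_prefix)
    Path(prefix).parent.mkdir(parents=True, exist_ok=True)
    if variable_names is None:
        variable_names = [f"var{j}" for j in range(p)]
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(n)]
    names = report.class_names
    if y_true is None:
        y_true = np.repeat([0, 1], report.confusion.counts.sum(axis=1))  # order-unknown fallback
    if y_pred is None:
        y_pred = np.zeros(n, dtype=np.int64)
    written: list[str] = []

    path = f"{prefix}.report.json"
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=1)
    written.append(path)

    path = f"{prefix}.confusion.tsv"
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(f"predicted_{c}" for c in names) + "\n")
        for t in (0, 1):
            fh.write(f"true_{names[t]}\t" + "\t".join(map(str, report.confusion.counts[t])) + "\n")
    written.append(path)

    path = f"{prefix}.roc.tsv"
    with open(path, "w") as fh:
        fh.write("fpr\ttpr\n")
        for fp, tp in report.roc_points:
            fh.write(f"{fp!r}\t{tp!r}\n")
    written.append(path)

    order = report.heatmap_sample_order
    path = f"{prefix}.heatmap.tsv"
    with open(path, "w") as fh:
        fh.write("row\t" + "\t".join(sample_ids[i] for i in order) + "\n")
        for j in range(p):
            cells = (repr(v) for v in test_X_selected[order, j].tolist())
            fh.write(variable_names[j] + "\t" + "\t".join(cells) + "\n")
        fh.write("prediction\t" + "\t".join(names[int(y_pred[i])] for i in order) + "\n")
        fh.write("true_label\t" + "\t".join(names[int(y_true[i])] for i in order) + "\n")
        fh.write("cluster\t" + "\t".join(map(str, report.heatmap_clusters)) + "\n")
    written.append(path)

    if 1 <= p <= 3:
        path = f"{prefix}.scatter.tsv"
        with open(path, "w") as fh:
            fh.write("sample_id\t" + "\t".join(variable_names[:p]) + "\tlabel\n")
            for i in range(n):
                cells = (repr(v) for v in test_X_selected[i].tolist())
                fh.write(sample_ids[i] + "\t" + "\t".join(cells) + f"\t{names[int(y_true[i])]}\n")
        written.append(path)
    else:
        warnings.warn(f"scatter export skipped: selection has {p} variables (supported: 1-3)")

    if render:
        written.extend(
            _render_pngs(report, test_X_selected, prefix, variable_names, y_true)
        )
    return written


def _render_pngs(report, X, prefix, variable_names, y_true) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    n, p = X.shape
    # ROC
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(report.roc_points[:, 0], report.roc_points[:, 1], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls=":", c="grey")
    ax.set(xlabel="FPR", ylabel="TPR", title=f"ROC (AUC = {report.auc:.3f})")
    fig.savefig(f"{prefix}.roc.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(f"{prefix}.roc.png")
    # scatter for 1-3 dims
    if 1 <= p <= 3:
        fig = plt.figure(figsize=(4.5, 4))
        colors = np.where(np.asarray(y_true) == 1, "tab:red", "tab:blue")
        if p == 1:
            ax = fig.add_subplot()
            ax.scatter(np.arange(n), X[:, 0], c=colors, s=8)
            ax.set(xlabel="sample index", ylabel=variable_names[0])
        elif p == 2:
            ax = fig.add_subplot()
            ax.scatter(X[:, 0], X[:, 1], c=colors, s=8)
            ax.set(xlabel=variable_names[0], ylabel=variable_names[1])
        else:
            ax = fig.add_subplot(projection="3d")
            ax.scatter(X[:, 0], X[:, 1], X[:, 2], c=colors, s=8)
        fig.savefig(f"{prefix}.scatter.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(f"{prefix}.scatter.png")
    # heatmap
    fig, ax = plt.subplots(figsize=(6, 2 + 0.3 * p))
    ax.imshow(X[report.heatmap_sample_order].T, aspect="auto", cmap="viridis")
    ax.set_yticks(range(p), variable_names)
    ax.set_xlabel("samples (k-means order)")
    fig.savefig(f"{prefix}.heatmap.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(f"{prefix}.heatmap.png")
    return written
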