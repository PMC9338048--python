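"""Classification metrics, ROC/AUC, fold aggregation and grid reports."""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix, roc_curve


@dataclass
class EvalReport:
    """Confusion matrix, scalar metrics and the ROC curve of one evaluation.

    ``auc`` (and the ROC arrays) are ``None`` when the label vector contains
    a single class, where the curve is undefined; the threshold metrics are
    still reported. F-measure is the F1 score (harmonic mean of precision
    and recall).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_fpr: np.ndarray | None
    roc_tpr: np.ndarray | None
    roc_thresholds: np.ndarray | None
    auc: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def confusion(self) -> np.ndarray:
        """2×2 matrix [[TN, FP], [FN, TP]] (rows: true class, cols: predicted)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc,
            }
        )


def evaluate(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Evaluate probability scores against binary labels.

    Hard predictions are ``score > threshold``; the ROC sweeps all distinct
    score thresholds and the AUC is the trapezoidal area under it (ties
    between a positive and a negative contribute one half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if scores.size and (scores.min() < 0 or scores.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    pred = (scores > threshold).astype(int)
    tn, fp, fn, tp = confusion_matrix(labels, pred, labels=[0, 1]).ravel()
    n = len(labels)
    accuracy = (tp + tn) / n if n else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    if len(np.unique(labels)) == 2:
        fpr, tpr, thresholds = roc_curve(labels, scores)
        auc_value = float(_trapezoid_auc(fpr, tpr))
    else:
        fpr = tpr = thresholds = None
        auc_value = None
    return EvalReport(
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
        accuracy=float(accuracy), precision=float(precision),
        recall=float(recall), f1=float(f1),
        roc_fpr=fpr, roc_tpr=tpr, roc_thresholds=thresholds, auc=auc_value,
    )


def aggregate_folds(reports: Sequence[EvalReport]) -> EvalReport:
    """Mean of the scalar metrics over folds; confusion matrices are summed.

    Per-fold ROC curves are not averaged (thresholds differ across folds);
    the aggregate's ROC fields are ``None`` unless a single report is given.
    """
    if not reports:
        raise ValueError("need at least one report to aggregate")
    if len(reports) == 1:
        return replace(reports[0])
    aucs = [r.auc for r in reports if r.auc is not None]
    return EvalReport(
        tp=sum(r.tp for r in reports),
        fp=sum(r.fp for r in reports),
        tn=sum(r.tn for r in reports),
        fn=sum(r.fn for r in reports),
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        roc_fpr=None, roc_tpr=None, roc_thresholds=None,
        auc=float(np.mean(aucs)) if aucs else None,
    )


def grid_report(
    results: Mapping[tuple[str, int, int], tuple[float, int]],
) -> dict[str, pd.DataFrame]:
    """Arrange per-(expert, window, chunks) results into summary tables.

    ``results`` maps (expert, window, chunks) to (mean test accuracy,
    total chunk count). Returns, per expert, an ``accuracy`` and a
    ``total_chunks`` table with window sizes as rows and requested chunk
    counts as columns.
    """
    tables: dict[str, pd.DataFrame] = {}
    experts = sorted({k[0] for k in results})
    for expert in experts:
        cells = {k: v for k, v in results.items() if k[0] == expert}
        windows = sorted({k[1] for k in cells})
        chunk_counts = sorted({k[2] for k in cells})
        acc = pd.DataFrame(index=windows, columns=chunk_counts, dtype=float)
        tot = pd.DataFrame(index=windows, columns=chunk_counts, dtype="Int64")
        for (_, w, c), (accuracy, total) in cells.items():
            acc.loc[w, c] = accuracy
            tot.loc[w, c] = total
        acc.index.name = tot.index.name = "window_s"
        acc.columns.name = tot.columns.name = "chunks"
        tables[f"{expert}_accuracy"] = acc
        tables[f"{expert}_total_chunks"] = tot
    return tables


def export_grid_report(
    results: Mapping[tuple[str, int, int], tuple[float, int]],
    directory: str | Path,
) -> list[Path]:
    """Write the grid tables as CSV files; header-only when the grid is empty."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    tables = grid_report(results)
    if not tables:
        path = directory / "grid_empty.csv"
        pd.DataFrame(columns=["window_s"]).to_csv(path, index=False)
        return [path]
    for name, table in tables.items():
        path = directory / f"grid_{name}.csv"
        table.to_csv(path)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# plots (optional helpers)


def plot_history(history, path: str | Path) -> Path:
    """Accuracy/loss learning curves (train vs validation) as an image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_acc, ax_loss) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    epochs = range(len(history.train_loss))
    ax_acc.plot(epochs, history.train_acc, label="training")
    ax_acc.plot(epochs, history.val_acc, label="validation")
    ax_acc.set_ylabel("accuracy")
    ax_acc.legend()
    ax_loss.plot(epochs, history.train_loss, label="training")
    ax_loss.plot(epochs, history.val_loss, label="validation")
    ax_loss.set_xlabel("epoch")
    ax_loss.set_ylabel("loss")
    ax_loss.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_roc(report: EvalReport, path: str | Path) -> Path:
    """ROC curve with its AUC as an image file."""
    if report.roc_fpr is None:
        raise ValueError("report has no ROC curve (single-class labels?)")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(report.roc_fpr, report.roc_tpr, label=f"AUC = {report.auc:.3f}")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
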