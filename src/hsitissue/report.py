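"""Report rendering: error maps, confusion heatmaps, ROC panels, metric tables.

The error map follows the surgical-visualization convention: black where the
prediction agrees with the annotation (or the pixel is unlabeled), otherwise the
display color of the *incorrectly predicted* class, so the map reads as "what
the model thought it was looking at".
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import AnnotationMask
from .evaluation import CVReport, compare_models


def error_map(mask: AnnotationMask, predicted: np.ndarray) -> np.ndarray:
    """RGB (H x W x 3, uint8) error visualization.

    Black = prediction matches the annotation, or the pixel is unlabeled.
    Colored = the display color of the class that was incorrectly predicted.
    """
    predicted = np.asarray(predicted)
    if predicted.shape != mask.shape:
        raise ValueError(f"mask {mask.shape} and prediction {predicted.shape} dims differ")
    out = np.zeros((*mask.shape, 3), dtype=np.uint8)
    wrong = (mask.labels > 0) & (predicted != mask.labels)
    for code in mask.class_set.codes:
        sel = wrong & (predicted == code)
        out[sel] = mask.class_set.color(code)
    return out


def metrics_table(reports: dict) -> pd.DataFrame:
    """Table-style summary: per model and metric, mean ± sd and ± se per class.

    Rows: (model, metric); columns: the 7 classes plus the macro average.
    """
    rows = []
    for name, report in reports.items():
        for metric in ("sensitivity", "specificity", "dsc"):
            summary = report.summary(metric)
            row = {"model": name, "metric": metric}
            for code in report.class_set.codes:
                s = summary[code]
                row[report.class_set.label(code)] = s["mean"]
                row[report.class_set.label(code) + "_sd"] = s["sd"]
                row[report.class_set.label(code) + "_se"] = s["se"]
            row["macro"] = report.macro(metric)
            rows.append(row)
    return pd.DataFrame(rows)


def _plot_confusions(reports: dict, path: Path) -> None:
    fig, axes = plt.subplots(1, len(reports), figsize=(4.2 * len(reports), 4))
    axes = np.atleast_1d(axes)
    for ax, (name, report) in zip(axes, reports.items()):
        norm = report.pooled_confusion.normalized
        labels = report.class_set.labels
        ax.imshow(norm, vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
        ax.set_yticks(range(len(labels)), labels, fontsize=7)
        ax.set_title(name, fontsize=9)
        for i in range(len(labels)):
            for j in range(len(labels)):
                if np.isfinite(norm[i, j]):
                    ax.text(j, i, f"{norm[i, j]:.2f}", ha="center", va="center",
                            fontsize=5, color="white" if norm[i, j] < 0.5 else "black")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_rocs(reports: dict, path: Path) -> None:
    fig, axes = plt.subplots(1, len(reports), figsize=(4.2 * len(reports), 4))
    axes = np.atleast_1d(axes)
    for ax, (name, report) in zip(axes, reports.items()):
        for code, roc in report.pooled_roc().items():
            ax.plot(roc.fpr, roc.tpr, lw=1,
                    label=f"{report.class_set.label(code)} (AUC {roc.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.5)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.set_title(name, fontsize=9)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_bars(reports: dict, comparisons: dict, path: Path) -> None:
    metrics = ("dsc", "sensitivity", "specificity")
    class_set = next(iter(reports.values())).class_set
    fig, axes = plt.subplots(len(metrics), 1, figsize=(10, 3.2 * len(metrics)))
    width = 0.8 / len(reports)
    x = np.arange(class_set.n_classes + 1)
    for ax, metric in zip(axes, metrics):
        for i, (name, report) in enumerate(reports.items()):
            summary = report.summary(metric)
            means = [summary[c]["mean"] for c in class_set.codes] + [report.macro(metric)]
            ses = [summary[c]["se"] for c in class_set.codes] + [0.0]
            ax.bar(x + i * width, means, width=width, yerr=ses, capsize=2, label=name)
        ax.set_xticks(x + 0.4 - width / 2, list(class_set.labels) + ["macro"], fontsize=8)
        ax.set_ylim(0, 1.1)
        ax.set_ylabel(metric)
        ax.legend(fontsize=7, ncol=len(reports))
        # significance stars from pairwise paired t-tests
        stars = []
        for (a, b), per_class in comparisons.get(metric, {}).items():
            for code, res in per_class.items():
                if res["stars"]:
                    stars.append(f"{a} vs {b}, {class_set.label(code)}: "
                                 f"p={res['p']:.4f} {res['stars']}")
        if stars:
            ax.set_title("; ".join(stars), fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def metrics_bundle(reports: dict, comparisons: dict) -> dict:
    """JSON-serializable bundle of every computed metric."""
    bundle = {"models": {}, "comparisons": {}}
    for name, report in reports.items():
        entry = {
            "pooled_confusion": report.pooled_confusion.counts.tolist(),
            "pooled_sensitivity": {
                report.class_set.label(c): v for c, v in report.pooled_sensitivity().items()
            },
            "roc_auc": {
                report.class_set.label(c): roc.auc for c, roc in report.pooled_roc().items()
            },
            "folds": [f.test_subject for f in report.folds],
        }
        for metric in ("sensitivity", "specificity", "dsc"):
            entry[metric] = {
                report.class_set.label(c): s for c, s in report.summary(metric).items()
            }
            entry[f"macro_{metric}"] = report.macro(metric)
        bundle["models"][name] = entry
    for metric, pairs in comparisons.items():
        bundle["comparisons"][metric] = {
            f"{a} vs {b}": {
                next(iter(reports.values())).class_set.label(code): {
                    "t": res["t"], "df": res["df"],
                    "p": round(res["p"], 4) if np.isfinite(res["p"]) else None,
                    "stars": res["stars"], "degenerate": res["degenerate"],
                }
                for code, res in per_class.items()
            }
            for (a, b), per_class in pairs.items()
        }
    return bundle


def render_report(reports: dict, out_dir) -> dict:
    """Write the full comparison bundle for a set of CVReports.

    Outputs: confusion heatmaps, ROC panels, grouped bar charts with standard
    error bars and significance markers, a CSV metric table, and a JSON metrics
    bundle. Returns the bundle.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comparisons = {
        metric: compare_models(reports, metric)
        for metric in ("dsc", "sensitivity", "specificity")
    }
    _plot_confusions(reports, out_dir / "confusion_matrices.png")
    _plot_rocs(reports, out_dir / "roc_curves.png")
    _plot_bars(reports, comparisons, out_dir / "metric_bars.png")
    metrics_table(reports).to_csv(out_dir / "metrics.csv", index=False)
    bundle = metrics_bundle(reports, comparisons)
    (out_dir / "metrics.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    return bundle
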