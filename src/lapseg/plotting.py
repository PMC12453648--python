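"""Figures: per-class metric bars and training curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

METRICS = ("precision", "recall", "f1", "iou")


def plot_class_metrics(table: pd.DataFrame, path=None, title="Per-class performance"):
    """Grouped bars of precision/recall/F1/IoU per class."""
    classes = table["class_name"].tolist()
    x = np.arange(len(classes))
    width = 0.2
    fig, ax = plt.subplots(figsize=(max(6, 1.2 * len(classes)), 4))
    for i, m in enumerate(METRICS):
        ax.bar(x + (i - 1.5) * width, table[m], width, label=m)
    ax.set_xticks(x)
    ax.set_xticklabels(classes, rotation=30, ha="right")
    ax.set_ylim(0, 1.05)
    ax.set_ylabel("score")
    ax.set_title(title)
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_history(history: pd.DataFrame, path=None):
    """Loss components, validation loss/IoU and learning rate per epoch."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for k in ("l_cls", "l_iou", "l_box", "l_obj", "l_total"):
        axes[0].plot(history["epoch"], history[k], label=k)
    axes[0].set_title("training loss")
    axes[0].legend(fontsize=7)
    axes[1].plot(history["epoch"], history["val_loss"], label="val loss")
    axes[1].plot(history["epoch"], history["val_macro_iou"], label="val macro IoU")
    axes[1].set_title("validation")
    axes[1].legend(fontsize=8)
    axes[2].semilogy(history["epoch"], history["lr"])
    axes[2].set_title("learning rate")
    for ax in axes:
        ax.set_xlabel("epoch")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
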