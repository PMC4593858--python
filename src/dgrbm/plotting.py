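"""Standard figures for an interference experiment.

Four panels per regime: proactive curves (during-training accuracy per
group), retroactive curves (post-training accuracy per group), accuracy vs
hidden-code overlap, and the distribution of post-training accuracies.
All functions accept the tidy frames produced by
:class:`~dgrbm.protocol.InterferenceResults` (or read back from CSV).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd

__all__ = [
    "plot_proactive",
    "plot_retroactive",
    "plot_accuracy_vs_overlap",
    "plot_accuracy_distribution",
    "save_report_figures",
]


def _curve(per_group: pd.DataFrame, column: str, ax, title: str):
    for variant, sub in per_group.groupby("variant", sort=False):
        curve = sub.groupby("group")[column].mean()
        ax.plot(curve.index + 1, curve.values, marker="o", label=variant)
    ax.set_xlabel("training group")
    ax.set_ylabel("reconstruction accuracy")
    ax.set_title(title)
    ax.legend(fontsize="small")
    return ax


def plot_proactive(per_group: pd.DataFrame, ax=None):
    """During-training accuracy per group (proactive interference)."""
    if ax is None:
        _, ax = plt.subplots()
    return _curve(per_group, "during_accuracy", ax, "During-training (proactive) accuracy")


def plot_retroactive(per_group: pd.DataFrame, ax=None):
    """Post-training accuracy per group (retroactive interference)."""
    if ax is None:
        _, ax = plt.subplots()
    return _curve(per_group, "post_accuracy", ax, "Post-training (retroactive) accuracy")


def plot_accuracy_vs_overlap(per_rep: pd.DataFrame, ax=None):
    """Post-training accuracy against hidden-code overlap, one point per repetition."""
    if ax is None:
        _, ax = plt.subplots()
    for variant, sub in per_rep.groupby("variant", sort=False):
        ax.scatter(sub["hidden_overlap"] * 100, sub["post_mean"], label=variant, alpha=0.7)
    ax.set_xlabel("hidden activation overlap (%)")
    ax.set_ylabel("post-training accuracy")
    ax.set_title("Accuracy vs pattern separation")
    ax.legend(fontsize="small")
    return ax


def plot_accuracy_distribution(per_group: pd.DataFrame, ax=None):
    """Distribution of post-training accuracies over groups and repetitions."""
    if ax is None:
        _, ax = plt.subplots()
    variants = list(per_group["variant"].unique())
    data = [per_group.loc[per_group["variant"] == v, "post_accuracy"] for v in variants]
    ax.boxplot(data, tick_labels=variants)
    ax.set_ylabel("post-training accuracy")
    ax.set_title("Post-training accuracy distribution")
    ax.tick_params(axis="x", rotation=20)
    return ax


def save_report_figures(per_group: pd.DataFrame, per_rep: pd.DataFrame, out_dir, prefix: str = "") -> list:
    """Render the four standard panels to PNG files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panels = [
        ("proactive", plot_proactive, per_group),
        ("retroactive", plot_retroactive, per_group),
        ("accuracy_vs_overlap", plot_accuracy_vs_overlap, per_rep),
        ("accuracy_distribution", plot_accuracy_distribution, per_group),
    ]
    paths = []
    for name, fn, frame in panels:
        fig, ax = plt.subplots(figsize=(6, 4))
        fn(frame, ax=ax)
        fig.tight_layout()
        path = out / f"{prefix}{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
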