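"""ROC / PR curve and score-distribution figures for evaluation reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_roc(report, path):
    """Overlay ROC curves of the baseline and each augmented method."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for method, (fpr, tpr) in report.curves.items():
        auc = report.per_repeat[method]["AUC"].mean()
        ax.plot(fpr, tpr, label=f"{method} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.set_title(f"{report.setting} ({report.scheme})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_score_distributions(report, path):
    """Positive vs negative out-of-fold score distributions per method."""
    df = report.score_distributions()
    methods = df["method"].unique()
    fig, axes = plt.subplots(1, len(methods), figsize=(3 * len(methods), 3), sharey=True)
    if len(methods) == 1:
        axes = [axes]
    for ax, method in zip(axes, methods):
        sub = df[df["method"] == method]
        for lab, color in ((1, "tab:red"), (0, "tab:blue")):
            vals = sub[sub["label"] == lab]["score"]
            ax.hist(vals, bins=20, alpha=0.5, density=True, color=color,
                    label="positive" if lab else "negative")
        ax.set_title(method, fontsize=9)
        ax.set_xlabel("score")
    axes[0].set_ylabel("density")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
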