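"""Minimal matplotlib helpers for the two standard displays."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .evaluate import KMEstimate, TimeAUCCurve

__all__ = ["plot_km", "plot_auc"]


def plot_km(estimates: dict[str, KMEstimate], path: str | Path, title: str = "") -> None:
    """Step-plot Kaplan-Meier curves, one line per group."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, km in estimates.items():
        ax.step(km.times, km.survival, where="post", label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_auc(curves: list[TimeAUCCurve], path: str | Path, title: str = "") -> None:
    """Time-dependent AUC with bootstrap bands, one curve per marker."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for c in curves:
        ax.plot(c.times, c.auc, marker="o", label=c.marker)
        if not all(map(lambda v: v != v, c.ci_low)):  # skip all-NaN bands
            ax.fill_between(c.times, c.ci_low, c.ci_high, alpha=0.15)
    ax.axhline(0.5, ls="--", c="grey", lw=0.8)
    ax.set_xlabel("time")
    ax.set_ylabel("AUC(t)")
    ax.set_ylim(0.3, 1.0)
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
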