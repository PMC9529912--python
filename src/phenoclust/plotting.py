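"""Scatter / scree / bar exports for fitted results.

Each plotting helper takes a fitted results or report object, writes an
optional PNG, and returns the underlying table so the same numbers can be
exported as CSV.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .experiments import AblationReport, BootstrapCurve
from .model import BehaviorClusterResults


def plot_pc_scatter(results: BehaviorClusterResults,
                    path: Optional[str | Path] = None) -> pd.DataFrame:
    """Animals in 2-PC space, colored by genotype, misclassified highlighted."""
    df = results.scores_frame()
    if path is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for geno, sub in df.groupby("genotype"):
            ax.scatter(sub["PC1"], sub["PC2"], s=18, label=str(geno), alpha=0.75)
        bad = df[df["misclassified"]]
        ax.scatter(bad["PC1"], bad["PC2"], s=60, facecolors="none",
                   edgecolors="tab:blue", linewidths=1.5, label="misclassified")
        ax.set_xlabel("PC1 (severity)")
        ax.set_ylabel("PC2")
        ax.legend(frameon=False, fontsize=8)
        ax.set_title(f"accuracy {results.accuracy:.1f}%")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return df


def plot_scree(results: BehaviorClusterResults,
               path: Optional[str | Path] = None) -> pd.DataFrame:
    df = results.scree_frame()
    if path is not None:
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(df["component"], 100 * df["variance_fraction"], "o-")
        ax.set_xlabel("principal component")
        ax.set_ylabel("variance explained (%)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return df


def plot_ablation(report: AblationReport,
                  path: Optional[str | Path] = None) -> pd.DataFrame:
    rows = [{
        "excluded": "+".join(c.excluded) or "(none)",
        "n_measures": c.n_measures,
        "n_animals": c.n_animals,
        "accuracy": c.accuracy,
        "fisher_p_vs_baseline": c.fisher_p_vs_baseline,
    } for c in report.conditions]
    df = pd.DataFrame(rows)
    if path is not None:
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.bar(range(len(df)), df["accuracy"], color="gray")
        ax.set_xticks(range(len(df)))
        ax.set_xticklabels(df["excluded"], rotation=60, ha="right", fontsize=7)
        ax.set_ylabel("accuracy (%)")
        ax.set_ylim(50, 100)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return df


def plot_bootstrap(curve: BootstrapCurve,
                   path: Optional[str | Path] = None) -> pd.DataFrame:
    df = pd.DataFrame({
        "n": curve.n_values,
        "mean_accuracy": curve.mean_accuracy,
        "sd": curve.sd_accuracy,
    })
    if path is not None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(df["n"], df["mean_accuracy"], "o-")
        ax.set_xlabel("animals per genotype")
        ax.set_ylabel("mean accuracy (%)")
        ax.set_ylim(50, 100)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return df
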