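"""Basic plots: per-cluster intake profiles and coefficient (forest) plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_cluster_profiles", "plot_coefficients"]


def plot_cluster_profiles(profile: pd.DataFrame, path=None):
    """Line plot of standardized mean intake per variable, one line per
    cluster (legend carries cluster sizes)."""
    fig, ax = plt.subplots(figsize=(max(6, profile["variable"].nunique() * 0.35), 4))
    for cluster, grp in profile.groupby("cluster"):
        ax.plot(grp["variable"], grp["mean_standardized"], marker="o", markersize=3,
                label=f"C{cluster} (n={grp['size'].iloc[0]})")
    ax.axhline(0, color="grey", lw=0.6)
    ax.set_ylabel("standardized mean intake")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_coefficients(results: pd.DataFrame, outcome: str, path=None):
    """Forest plot of per-cluster estimates with 95% CIs, by sex and model."""
    sub = results[results["outcome"] == outcome]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(sub))))
    ypos = range(len(sub))
    labels = [f"{r.sex[:1].upper()}/{r.model}/{r.factor.split('_')[0]}{r.cluster}"
              for r in sub.itertuples()]
    est = sub["estimate"] if (sub["scale"] == "identity").all() else sub["ratio"]
    ax.errorbar(est, list(ypos),
                xerr=[est - sub["ci_lo"], sub["ci_hi"] - est],
                fmt="o", markersize=3, lw=1, capsize=2)
    null = 0.0 if (sub["scale"] == "identity").all() else 1.0
    ax.axvline(null, color="grey", lw=0.6)
    ax.set_yticks(list(ypos))
    ax.set_yticklabels(labels, fontsize=6)
    ax.set_xlabel("mean difference" if null == 0.0 else "geometric mean ratio")
    ax.set_title(outcome)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
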