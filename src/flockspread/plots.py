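"""Basic summary plots of the main result surfaces.

Each function takes the CSV-shaped tables produced by :mod:`~flockspread.analysis`
and returns a matplotlib Figure; nothing is written to disk here.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .contagion import RULES
from .metrics import NODE_METRICS

__all__ = [
    "plot_acquisition_profiles",
    "plot_correlation_distributions",
    "plot_size_effects",
    "plot_prob_curves",
]


def _rules_in(df: pd.DataFrame) -> list:
    present = df["rule"].unique()
    return [r for r in RULES if r in present]


def plot_acquisition_profiles(profiles: pd.DataFrame):
    """Mean standardized metric per acquisition position (rules x metrics)."""
    rules = _rules_in(profiles)
    fig, axes = plt.subplots(
        len(rules), len(NODE_METRICS), figsize=(11, 2.6 * len(rules)),
        sharex=False, squeeze=False,
    )
    for i, rule in enumerate(rules):
        for j, metric in enumerate(NODE_METRICS):
            ax = axes[i][j]
            sub = profiles[(profiles["rule"] == rule)
                           & (profiles["metric_name"] == metric)]
            for size_bin, grp in sub.groupby("size_bin", observed=True):
                grp = grp.sort_values("position")
                ax.plot(grp["position"], grp["mean_value"], label=str(size_bin))
                ax.fill_between(grp["position"], grp["ci_low"], grp["ci_high"],
                                alpha=0.2)
            ax.axhline(0, color="grey", lw=0.5)
            if i == 0:
                ax.set_title(metric, fontsize=9)
            if j == 0:
                ax.set_ylabel(rule)
    axes[-1][1].set_xlabel("order of acquisition")
    axes[0][-1].legend(title="network size", fontsize=7)
    fig.tight_layout()
    return fig


def plot_correlation_distributions(records: pd.DataFrame):
    """Distribution of mean rho per rule, one panel per metric."""
    fig, axes = plt.subplots(1, len(NODE_METRICS), figsize=(11, 3.2), sharey=True)
    rules = _rules_in(records)
    for j, metric in enumerate(NODE_METRICS):
        ax = axes[j]
        data = [
            records[(records["rule"] == r) & (records["metric_name"] == metric)]
            ["mean_rho"].dropna()
            for r in rules
        ]
        ax.violinplot(data, showmeans=True)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_xticks(range(1, len(rules) + 1), rules, rotation=30, fontsize=8)
        ax.set_title(metric, fontsize=9)
    axes[0].set_ylabel("mean Spearman rho")
    fig.tight_layout()
    return fig


def plot_size_effects(records: pd.DataFrame, models: pd.DataFrame | None = None):
    """Mean rho against network size with fitted slopes (metrics x rules)."""
    rules = _rules_in(records)
    fig, axes = plt.subplots(
        len(NODE_METRICS), len(rules), figsize=(2.7 * len(rules), 8),
        sharex=True, squeeze=False,
    )
    for i, metric in enumerate(NODE_METRICS):
        for j, rule in enumerate(rules):
            ax = axes[i][j]
            sub = records[(records["rule"] == rule)
                          & (records["metric_name"] == metric)]
            ax.scatter(sub["network_size"], sub["mean_rho"], s=6, alpha=0.4)
            if models is not None:
                row = models[(models["rule"] == rule)
                             & (models["metric_name"] == metric)]
                if len(row):
                    row = row.iloc[0]
                    xs = sub["network_size"].sort_values()
                    ax.plot(xs, row["intercept"] + row["slope"] * xs, color="C3")
            ax.axhline(0, color="grey", lw=0.5)
            if i == 0:
                ax.set_title(rule, fontsize=9)
            if j == 0:
                ax.set_ylabel(metric, fontsize=8)
    axes[-1][0].set_xlabel("network size")
    fig.tight_layout()
    return fig


def plot_prob_curves(curves: pd.DataFrame):
    """Mean p_social vs number informed, one panel per rule."""
    rules = _rules_in(curves)
    fig, axes = plt.subplots(1, len(rules), figsize=(2.9 * len(rules), 3.2),
                             sharey=True, squeeze=False)
    for j, rule in enumerate(rules):
        ax = axes[0][j]
        sub = curves[curves["rule"] == rule]
        for size_bin, grp in sub.groupby("size_bin", observed=True):
            grp = grp.sort_values("n_informed")
            ax.plot(grp["n_informed"], grp["mean_p_social"], label=str(size_bin))
            ax.fill_between(grp["n_informed"], grp["ci_low"], grp["ci_high"],
                            alpha=0.2)
        ax.set_title(rule, fontsize=9)
        ax.set_xlabel("number informed")
        ax.set_ylim(-0.02, 1.02)
    axes[0][0].set_ylabel("P(social learning)")
    axes[0][-1].legend(title="network size", fontsize=7)
    fig.tight_layout()
    return fig
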