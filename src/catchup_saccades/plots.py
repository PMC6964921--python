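"""Plotting hooks: phase plots, proportion curves, trigger-time distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def phase_plot(metrics: pd.DataFrame, ax=None, condition: str | None = None):
    """Pre-saccadic (PE, RS) scatter; the low-density double cone is the smooth zone."""
    if ax is None:
        _, ax = plt.subplots()
    df = metrics.loc[~metrics["excluded"] & (metrics["klass"] != "smooth")]
    if condition:
        df = df[df["condition"] == condition]
    ax.scatter(df["pe_presacc"], df["rs_presacc"], s=4, alpha=0.4)
    for txe in (40.0, 180.0):  # smooth-zone boundary slopes RS = -PE/T_xe
        pe = np.linspace(-20, 20, 9)
        ax.plot(pe, -pe / (txe / 1000.0), "r--", lw=0.8)
    ax.set_xlabel("PE (deg)")
    ax.set_ylabel("RS (deg/s)")
    return ax


def proportion_curve_plot(curves: pd.DataFrame, ax=None):
    """Saccade-trial proportion vs binned PE_pred, one line per |VS| band."""
    if ax is None:
        _, ax = plt.subplots()
    for (cond, band), g in curves.groupby(["condition", "vs_band"]):
        g = g.sort_values("bin_center")
        ax.plot(g["bin_center"], g["prop_saccade"], marker="o", ms=3,
                label=f"{cond} VS {band}")
    ax.set_xlabel("PE_pred (deg)")
    ax.set_ylabel("saccade trial proportion")
    ax.legend(fontsize=7)
    return ax


def trigger_time_hist(metrics: pd.DataFrame, by: str = "klass", ax=None):
    """Trigger-time histograms (bimodality = early/late split at 175 ms)."""
    if ax is None:
        _, ax = plt.subplots()
    df = metrics.loc[~metrics["excluded"] & metrics["trigger_time"].notna()]
    for key, g in df.groupby(by, observed=True):
        ax.hist(g["trigger_time"], bins=np.arange(0, 600, 10), alpha=0.5, label=str(key))
    ax.set_xlabel("trigger time (ms)")
    ax.legend(fontsize=7)
    return ax


def pe_pred_txt_scatter(metrics: pd.DataFrame, ax=None):
    """Per-trial scatter of PE_pred vs T_xt colored by early/late/smooth class."""
    if ax is None:
        _, ax = plt.subplots()
    df = metrics.loc[~metrics["excluded"]]
    colors = {"early": "tab:red", "late": "tab:blue", "smooth": "tab:gray"}
    for k, g in df.groupby("klass", observed=True):
        ax.scatter(g["txt"], g["pe_pred_at_step"], s=4, alpha=0.4,
                   c=colors.get(k, "k"), label=k)
    ax.set_xlim(-1100, 1100)
    ax.set_xlabel("T_xt (ms)")
    ax.set_ylabel("PE_pred at step (deg)")
    ax.legend(fontsize=7)
    return ax
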