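#!/usr/bin/env python
"""Saccade-trial proportion curves and diagnostic figures.

Computes the proportion of saccade trials as a function of predicted
position error (2-deg bins) per |velocity-step| band and condition — the
low-proportion dip around zero is the smooth zone — and renders the phase
plot, trigger-time histograms and the PE_pred/T_xt scatter.

Reads scratch/model_metrics.csv (regenerates if missing); writes
results/proportion_curves.csv and scratch/fig_*.png.
"""

import argparse
from pathlib import Path

import matplotlib.pyplot as plt
import pandas as pd

from catchup_saccades.experiments import run_model_study
from catchup_saccades.group_stats import proportion_curves
from catchup_saccades.plots import (
    pe_pred_txt_scatter,
    phase_plot,
    proportion_curve_plot,
    trigger_time_hist,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cache = ROOT / "scratch" / "model_metrics.csv"
    metrics = pd.read_csv(cache) if cache.exists() else run_model_study(seed=args.seed)

    curves = proportion_curves(metrics)
    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "scratch").mkdir(exist_ok=True)
    curves.to_csv(ROOT / "results" / "proportion_curves.csv", index=False)

    dip = curves[(curves["n"] >= 20)].sort_values("prop_saccade").head(3)
    print("lowest-proportion cells (the smooth zone):")
    print(dip.to_string(index=False))

    for name, fn in (
        ("phase_plot", phase_plot),
        ("trigger_hist", trigger_time_hist),
        ("scatter", pe_pred_txt_scatter),
    ):
        fig, ax = plt.subplots(figsize=(5, 4))
        fn(metrics, ax=ax)
        fig.savefig(ROOT / "scratch" / f"fig_{name}.png", dpi=120)
        plt.close(fig)
    fig, ax = plt.subplots(figsize=(5, 4))
    proportion_curve_plot(curves, ax=ax)
    fig.savefig(ROOT / "scratch" / "fig_proportion_curves.png", dpi=120)
    plt.close(fig)
    print("figures written to scratch/")


if __name__ == "__main__":
    main()
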