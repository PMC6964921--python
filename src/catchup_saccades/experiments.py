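"""Canned study-scale runs shared by the analysis drivers and checks.

The full study is 75,000 trials; the runs here use a scaled-down design
(10 synthetic participants x 200 trials, alternating clear/blur sessions)
that keeps every qualitative contrast estimable in a few minutes on one
core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .group_stats import _iqr
from .synthesis import DatasetConfig, generate_dataset
from .trace_analysis import AnalysisConfig, analyze_dataset
from .trigger_model import ModelParams

#: the scaled study: 10 participants x 2 sessions (clear/blur) x 2 x 50 = 2000 trials
STUDY_CONFIG = DatasetConfig(
    n_participants=10, n_sessions=2, blocks_per_session=2, trials_per_block=50
)


def run_model_study(
    seed: int,
    config: DatasetConfig = STUDY_CONFIG,
    params: ModelParams | None = None,
    analysis: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Simulate the scaled study with the trigger model and analyze every trial."""
    rng = np.random.default_rng(seed)
    ds = generate_dataset(
        config, mode="model", rng=rng, model_params=params or ModelParams()
    )
    return analyze_dataset(ds.traces, analysis or AnalysisConfig())


def trigger_time_contrasts(metrics: pd.DataFrame) -> dict:
    """The headline directional contrasts of a metrics table, in ms.

    Returns pooled medians/IQRs for the small vs large |PE_pred| split, the
    three T_xt bins, the clear/blur shift, and the velocity-step signatures
    (smooth-zone narrowing and SDN timing at matched small |PE_pred|).
    """
    ok = metrics.loc[~metrics["excluded"]].copy()
    ok["vs2_abs"] = ok["vs2"].abs()
    sac = ok[ok["klass"] != "smooth"]
    small = sac["pe_pred_at_step"].abs() < 5

    txt_bin = pd.cut(sac["txt"], [-np.inf, 0, 400, np.inf], right=False,
                     labels=["neg", "mid", "high"])
    med_txt = sac.groupby(txt_bin, observed=True)["trigger_time"].median()
    iqr_txt = sac.groupby(txt_bin, observed=True)["trigger_time"].apply(
        lambda s: _iqr(s.dropna().to_numpy())
    )
    blur = sac["condition"] == "blur"

    zone = ok[(ok["txt"] >= 40) & (ok["txt"] < 180)]
    # SDN timing: compare low vs high |VS| halves within matched 2-deg
    # PE_pred bins (unmatched comparisons confound |VS| with step size)
    sac = sac.assign(_ppb=np.floor(sac["pe_pred_at_step"] / 2.0) * 2.0)
    lo_half = sac[sac["vs2_abs"] < 15]
    hi_half = sac[sac["vs2_abs"] >= 30]
    wins = total = 0
    for b in sorted(set(lo_half["_ppb"]) & set(hi_half["_ppb"])):
        l = lo_half.loc[lo_half["_ppb"] == b, "trigger_time"]
        h = hi_half.loc[hi_half["_ppb"] == b, "trigger_time"]
        if len(l) >= 8 and len(h) >= 8:
            total += 1
            wins += h.median() > l.median()
    return {
        "median_small_pe_pred": float(sac.loc[small, "trigger_time"].median()),
        "median_large_pe_pred": float(sac.loc[~small, "trigger_time"].median()),
        "iqr_small_pe_pred": _iqr(sac.loc[small, "trigger_time"].dropna().to_numpy()),
        "iqr_large_pe_pred": _iqr(sac.loc[~small, "trigger_time"].dropna().to_numpy()),
        "median_txt": {k: float(v) for k, v in med_txt.items()},
        "iqr_txt": {k: float(v) for k, v in iqr_txt.items()},
        "blur_median_shift": float(
            sac.loc[blur, "trigger_time"].median()
            - sac.loc[~blur, "trigger_time"].median()
        ),
        "blur_shift_small_pe_pred": float(
            sac.loc[small & blur, "trigger_time"].median()
            - sac.loc[small & ~blur, "trigger_time"].median()
        ),
        "blur_shift_large_pe_pred": float(
            sac.loc[~small & blur, "trigger_time"].median()
            - sac.loc[~small & ~blur, "trigger_time"].median()
        ),
        "zone_saccade_prop_low_vs": float(
            (zone.loc[zone["vs2_abs"] < 10, "klass"] != "smooth").mean()
        ),
        "zone_saccade_prop_high_vs": float(
            (zone.loc[zone["vs2_abs"] >= 40, "klass"] != "smooth").mean()
        ),
        "sdn_matched_bin_wins": int(wins),
        "sdn_matched_bins": int(total),
    }
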