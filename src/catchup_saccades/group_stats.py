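"""Binning, per-subject summaries, and the hypothesis-test chain.

Trials are binned by predicted position error (PE_pred), target-crossing
time (T_xt), eye-crossing time (T_xe) or absolute velocity step; per subject,
condition and bin we summarize the trigger-time median and IQR (linear
interpolation quartiles) and the early/late/smooth proportions, then compare
bins with repeated-measures ANOVA (partial eta squared reported), Bonferroni
paired post-hocs, and a BIC-approximated Bayes factor.

The four directional hypotheses the chain tests on simulated data:
H1 small |PE_pred| lengthens and disperses trigger times; H2 the 0-400 ms
T_xt bin (foveopetal, near-future re-crossing) has the longest and most
variable trigger times; H3 target blur raises trigger times most at small
|PE_pred|; H4 larger velocity steps narrow the smooth zone (more saccades at
re-crossing times inside it) while their signal-dependent noise lengthens
trigger times at matched |PE_pred|.
"""

from __future__ import annotations

import math

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
import statsmodels.formula.api as smf

INF = float("inf")


@dataclass(frozen=True)
class BinScheme:
    """Half-open [lo, hi) bins over one trial variable."""

    variable: str  # metrics column
    edges: tuple

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("edges must be strictly increasing with >= 2 entries")

    @property
    def labels(self) -> list[str]:
        def f(v):
            return "-inf" if v == -INF else ("inf" if v == INF else f"{v:g}")

        return [f"[{f(a)},{f(b)})" for a, b in zip(self.edges[:-1], self.edges[1:])]


# canonical schemes
PE_PRED_COARSE = BinScheme("pe_pred_at_step", (-INF, -5.0, 5.0, INF))
PE_PRED_FINE = BinScheme("pe_pred_presacc", tuple(np.arange(-20.0, 20.0 + 1e-9, 2.0)))
TXT_BINS = BinScheme("txt", (-INF, 0.0, 400.0, INF))
TXE_BINS = BinScheme("txe_presacc", tuple(np.arange(-400.0, 600.0 + 1e-9, 50.0)))
VS_ABS_FIVE = BinScheme("vs2_abs", (0.0, 10.0, 20.0, 30.0, 40.0, 50.0 + 1e-9))
VS_ABS_COARSE_BANDS = ((0.0, 10.0), (20.0, 30.0), (40.0, 50.0 + 1e-9))


def _iqr(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])  # linear-interpolation quartiles
    return float(q75 - q25)


def bin_trials(metrics: pd.DataFrame, scheme: BinScheme) -> pd.DataFrame:
    """Assign every non-excluded trial to exactly one half-open bin.

    Rows whose binning variable is undefined (NaN, e.g. T_xe with RS ~ 0)
    are dropped.  Adds a categorical ``bin`` column.
    """
    df = metrics.loc[~metrics["excluded"]].copy()
    if scheme.variable == "vs2_abs" and "vs2_abs" not in df:
        df["vs2_abs"] = df["vs2"].abs()
    vals = df[scheme.variable]
    df = df.loc[vals.notna()].copy()
    df["bin"] = pd.cut(
        df[scheme.variable], bins=list(scheme.edges), right=False,
        labels=scheme.labels, include_lowest=False,
    )
    df = df.loc[df["bin"].notna()]
    return df


def summarize_bins(
    grouped: pd.DataFrame, min_n: int = 5, by_condition: bool = True
) -> pd.DataFrame:
    """Per subject x condition x bin: trigger-time median/IQR and class proportions.

    Medians and IQRs use saccade trials only; proportions use all assigned
    trials.  Cells with fewer than ``min_n`` saccade trials report NaN
    median/IQR (missing, not zero).
    """
    keys = ["participant_id"] + (["condition"] if by_condition else []) + ["bin"]
    rows = []
    for key, g in grouped.groupby(keys, observed=True):
        key = key if isinstance(key, tuple) else (key,)
        sacc = g.loc[g["klass"] != "smooth", "trigger_time"].dropna().to_numpy()
        row = dict(zip(keys, key))
        row["n"] = len(g)
        row["n_saccade"] = sacc.size
        row["median_trigger"] = float(np.median(sacc)) if sacc.size >= min_n else np.nan
        row["iqr_trigger"] = _iqr(sacc) if sacc.size >= min_n else np.nan
        row["prop_saccade"] = float((g["klass"] != "smooth").mean())
        for k in ("early", "late", "smooth"):
            row[f"prop_{k}"] = float((g["klass"] == k).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def proportion_curves(
    metrics: pd.DataFrame,
    scheme: BinScheme = PE_PRED_FINE,
    vs_bands=VS_ABS_COARSE_BANDS,
    by_condition: bool = True,
) -> pd.DataFrame:
    """Saccade-trial proportion per fine bin and |VS| band (pooled over subjects).

    Saccade trials contribute their pre-saccadic sample; smooth trials their
    400-ms post-step average (both are already in the metrics table).
    """
    df = metrics.loc[~metrics["excluded"]].copy()
    df["vs2_abs"] = df["vs2"].abs()
    rows = []
    conds = df["condition"].unique() if by_condition else ["all"]
    for cond in conds:
        dc = df if cond == "all" else df[df["condition"] == cond]
        for lo, hi in vs_bands:
            band = dc[(dc["vs2_abs"] >= lo) & (dc["vs2_abs"] < hi)]
            binned = bin_trials(band.assign(excluded=False), scheme)
            for b, g in binned.groupby("bin", observed=True):
                rows.append(
                    {
                        "condition": cond,
                        "vs_band": f"{lo:g}-{min(hi, 50):g}",
                        "bin": b,
                        "bin_center": 0.5
                        * (scheme.edges[scheme.labels.index(b)]
                           + scheme.edges[scheme.labels.index(b) + 1]),
                        "n": len(g),
                        "prop_saccade": float((g["klass"] != "smooth").mean()),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inferential statistics


def rm_anova(
    summary: pd.DataFrame,
    dv: str = "median_trigger",
    within: str | list[str] = "bin",
    subject: str = "participant_id",
) -> dict:
    """One- or two-way repeated-measures ANOVA on per-subject bin summaries.

    Missing cells are dropped listwise (subjects lacking any cell are
    removed).  Returns F, dfs, partial eta squared and p of the (first
    listed / interaction) effect.
    """
    within_l = [within] if isinstance(within, str) else list(within)
    df = summary.dropna(subset=[dv]).copy()
    for w in within_l:
        df[w] = df[w].astype(str)
    # listwise completion: keep subjects with all cells
    cells = df.groupby(subject, observed=True)[within_l].nunique()
    full = (cells == df[within_l].nunique()).all(axis=1)
    keep = full[full].index
    df = df[df[subject].isin(keep)]
    if df[subject].nunique() < 2:
        raise ValueError("need at least 2 subjects with complete cells")
    aov = pg.rm_anova(
        data=df, dv=dv, within=within_l if len(within_l) > 1 else within_l[0],
        subject=subject, detailed=True, effsize="np2",
    )
    # row of interest: the interaction for two-way, the factor for one-way
    if len(within_l) > 1:
        row = aov.loc[aov["Source"].str.contains(r"\*")].iloc[0]
        df1, df2 = float(row["ddof1"]), float(row["ddof2"])
    else:
        row = aov.loc[aov["Source"] == within_l[0]].iloc[0]
        df1 = float(row["DF"])
        df2 = float(aov.loc[aov["Source"] == "Error", "DF"].iloc[0])
    # degenerate data (zero within-cell variation) yields no F column at all
    f_val = float(row["F"]) if "F" in row else float("nan")
    p_val = float(row["p_unc"]) if "p_unc" in row else float("nan")
    if math.isnan(f_val) and float(row["SS"]) == 0.0:
        f_val, p_val = 0.0, 1.0  # no between-cell variation at all
    np2 = float(row["np2"]) if "np2" in row else float("nan")
    return {
        "F": f_val,
        "df1": df1,
        "df2": df2,
        "partial_eta_sq": 0.0 if math.isnan(np2) else np2,
        "p": p_val,
        "table": aov,
    }


def posthoc_paired(
    summary: pd.DataFrame,
    dv: str = "median_trigger",
    within: str = "bin",
    subject: str = "participant_id",
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """All pairwise paired t tests across bins, Bonferroni-corrected.

    p values are multiplied by the number of comparisons and capped at 1.
    """
    df = summary.dropna(subset=[dv])
    wide = df.pivot_table(index=subject, columns=within, values=dv, observed=True).dropna()
    levels = list(wide.columns)
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        x, y = wide[a].to_numpy(), wide[b].to_numpy()
        if np.allclose(x, y):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(x, y)
        p_corr = min(float(p) * n_comp, 1.0) if correction == "bonferroni" else float(p)
        rows.append(
            {
                "A": a, "B": b, "mean_diff": float(np.mean(x - y)),
                "t": float(t), "p_unc": float(p), "p_corr": p_corr,
                "n_comparisons": n_comp,
            }
        )
    return pd.DataFrame(rows)


def bayes_factor_anova(
    summary: pd.DataFrame,
    dv: str = "median_trigger",
    within: str | list[str] = "bin",
    subject: str = "participant_id",
) -> float:
    """BF10 via the BIC approximation, BF10 = exp((BIC_null - BIC_alt)/2).

    Null model: dv ~ subject; alternative adds the within factor(s) (and
    their interaction for two factors).  This is an approximation to a full
    Bayesian ANOVA, adequate for order-of-magnitude evidence statements.
    """
    within_l = [within] if isinstance(within, str) else list(within)
    df = summary.dropna(subset=[dv]).copy()
    df = df.rename(columns={subject: "subj", dv: "y"})
    for i, w in enumerate(within_l):
        df[f"w{i}"] = df[w].astype(str)
    null = smf.ols("y ~ C(subj)", data=df).fit()
    terms = " * ".join(f"C(w{i})" for i in range(len(within_l)))
    alt = smf.ols(f"y ~ C(subj) + {terms}", data=df).fit()
    return float(np.exp((null.bic - alt.bic) / 2.0))


# ---------------------------------------------------------------------------
# extrapolation-horizon recovery


def recover_dt(
    metrics: pd.DataFrame,
    dts_ms=tuple(range(90, 291, 10)),
) -> tuple[float, pd.DataFrame]:
    """Recover the PE-extrapolation horizon from smooth-trial geometry.

    A trial stays smooth when its predicted error is held near zero, i.e.
    PE ~ -dt * RS (the smooth-zone equivalence: PE_pred = 0 exactly when
    T_xe = dt).  Scanning candidate horizons, the variance of
    PE + dt * RS across smooth trials is minimized at the generating dt
    (equivalently, the regression slope of PE on RS is -dt).  Returns
    (best dt in ms, scan table).
    """
    sm = metrics.loc[
        (~metrics["excluded"]) & (metrics["klass"] == "smooth")
    ].dropna(subset=["pe_presacc", "rs_presacc"])
    if len(sm) < 20:
        raise ValueError("too few smooth trials to recover the horizon")
    rows = []
    for dt in dts_ms:
        pp = sm["pe_presacc"] + dt / 1000.0 * sm["rs_presacc"]
        rows.append({"dt_ms": dt, "pe_pred_var": float(pp.var(ddof=1))})
    scan = pd.DataFrame(rows)
    best = float(scan.loc[scan["pe_pred_var"].idxmin(), "dt_ms"])
    return best, scan


# ---------------------------------------------------------------------------
# directional hypothesis checks (pass/fail report used by the CLI)


def hypothesis_report(metrics: pd.DataFrame) -> pd.DataFrame:
    """Directional checks of the four hypotheses on a metrics table.

    Each row gives the hypothesis, the quantities compared and a boolean
    pass.  These are direction-of-effect checks on pooled data, not the
    subject-level inferential tests (see rm_anova and friends for those).
    """
    df = metrics.loc[~metrics["excluded"]].copy()
    sacc = df[df["klass"] != "smooth"]
    rows = []

    # H1: small |PE_pred| -> longer and more variable trigger times
    small = sacc["pe_pred_at_step"].abs() < 5
    med_small, med_large = (
        sacc.loc[small, "trigger_time"].median(),
        sacc.loc[~small, "trigger_time"].median(),
    )
    iqr_small = _iqr(sacc.loc[small, "trigger_time"].dropna().to_numpy())
    iqr_large = _iqr(sacc.loc[~small, "trigger_time"].dropna().to_numpy())
    rows.append(
        {
            "hypothesis": "H1",
            "detail": f"median {med_small:.0f} vs {med_large:.0f} ms; "
                      f"IQR {iqr_small:.0f} vs {iqr_large:.0f} ms (small vs large |PE_pred|)",
            "passed": bool(med_small > med_large and iqr_small > iqr_large),
        }
    )

    # H2: 0 <= T_xt < 400 bin has the longest, most variable trigger times
    b = pd.cut(sacc["txt"], [-INF, 0, 400, INF], right=False,
               labels=["neg", "mid", "high"])
    med = sacc.groupby(b, observed=True)["trigger_time"].median()
    iqr = sacc.groupby(b, observed=True)["trigger_time"].apply(
        lambda s: _iqr(s.dropna().to_numpy())
    )
    rows.append(
        {
            "hypothesis": "H2",
            "detail": f"medians ms neg/mid/high: {med.get('neg', np.nan):.0f}/"
                      f"{med.get('mid', np.nan):.0f}/{med.get('high', np.nan):.0f}",
            "passed": bool(
                med.get("mid", -np.inf) >= med.max() - 1e-9
                and iqr.get("mid", -np.inf) >= iqr.max() - 1e-9
            ),
        }
    )

    # H3: blur raises medians, most at small |PE_pred|
    if set(df["condition"]) >= {"clear", "blur"}:
        small_mask = sacc["pe_pred_at_step"].abs() < 5
        med_cb = sacc.groupby("condition", observed=True)["trigger_time"].median()
        shift_small = (
            sacc.loc[small_mask & (sacc["condition"] == "blur"), "trigger_time"].median()
            - sacc.loc[small_mask & (sacc["condition"] == "clear"), "trigger_time"].median()
        )
        shift_large = (
            sacc.loc[~small_mask & (sacc["condition"] == "blur"), "trigger_time"].median()
            - sacc.loc[~small_mask & (sacc["condition"] == "clear"), "trigger_time"].median()
        )
        rows.append(
            {
                "hypothesis": "H3",
                "detail": f"blur-clear median shift {med_cb.get('blur', np.nan) - med_cb.get('clear', np.nan):.0f} ms; "
                          f"small-PE_pred shift {shift_small:.0f} vs large {shift_large:.0f} ms",
                "passed": bool(
                    med_cb.get("blur", -np.inf) > med_cb.get("clear", np.inf)
                    and shift_small > shift_large
                ),
            }
        )

    # H4, two velocity-step signatures:
    # (a) smooth-zone narrowing: within the zone (target re-crossing 40-180 ms
    #     ahead) larger |VS| accrues error faster, so the saccade proportion
    #     rises with the |VS| band;
    # (b) signal-dependent noise: at matched small |PE_pred| the extra slip
    #     uncertainty of a large |VS| slows the evidence rise, lengthening
    #     trigger times.
    df["vs2_abs"] = df["vs2"].abs()
    zone = df[(df["txt"] >= 40) & (df["txt"] < 180)]
    prop_lo = (zone.loc[zone["vs2_abs"] < 10, "klass"] != "smooth").mean()
    prop_hi = (zone.loc[zone["vs2_abs"] >= 40, "klass"] != "smooth").mean()
    sb = sacc.assign(
        _ppb=np.floor(sacc["pe_pred_at_step"] / 2.0) * 2.0,
        _vsab=sacc["vs2"].abs(),
    )
    lo_half, hi_half = sb[sb["_vsab"] < 15], sb[sb["_vsab"] >= 30]
    wins = total = 0
    for b_ in sorted(set(lo_half["_ppb"]) & set(hi_half["_ppb"])):
        l = lo_half.loc[lo_half["_ppb"] == b_, "trigger_time"]
        h = hi_half.loc[hi_half["_ppb"] == b_, "trigger_time"]
        if len(l) >= 8 and len(h) >= 8:
            total += 1
            wins += h.median() > l.median()
    rows.append(
        {
            "hypothesis": "H4",
            "detail": f"smooth-zone saccade proportion {prop_lo:.2f} (|VS|<10) vs "
                      f"{prop_hi:.2f} (|VS|>=40); high-|VS| median longer in "
                      f"{wins}/{total} matched PE_pred bins",
            "passed": bool(prop_hi > prop_lo and total > 0 and wins > 0.5 * total),
        }
    )
    return pd.DataFrame(rows)
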