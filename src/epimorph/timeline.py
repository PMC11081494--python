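"""Movie synchronisation, binning, and genotype comparison.

Movies are synchronised to the onset of germband extension in two stages:
each movie is first offset so that its mean AP-projected tissue strain rate
reaches a small positive threshold (0.01 pp/min, sustained) at a provisional
zero, then a single per-genotype shift places the zero crossing of the
genotype-average curve at t = 0. Genotype differences are tested per 30-s
time bin with a mixed-effects model (random intercept per embryo) at
p < 0.01, with no multiple-testing correction across bins; 3-bin smoothing
is applied to display copies only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SyncResult:
    """Per-movie time offsets (minutes to subtract from raw time) and flags."""

    offsets_min: dict
    genotype_shift_min: float
    unsynchronisable: list


def _sustained_crossing(times: np.ndarray, values: np.ndarray,
                        threshold: float, sustain_min: float) -> float | None:
    """First time the series reaches ``threshold`` and stays there for
    ``sustain_min`` minutes; None if never."""
    ok = np.isfinite(values)
    t, v = times[ok], values[ok]
    if len(t) < 2:
        return None
    dt = np.median(np.diff(t))
    need = max(1, int(round(sustain_min / dt)))
    above = v >= threshold
    for i in range(len(t)):
        j = min(len(t), i + need)
        if above[i:j].all() and (j - i) >= min(need, len(t) - i):
            return float(t[i])
    return None


def synchronise(
    series: dict,
    threshold: float = 0.01,
    sustain_min: float = 2.0,
) -> SyncResult:
    """Two-stage synchronisation of movies of one genotype.

    ``series`` maps movie id -> (times_min, mean AP tissue strain rate).
    Stage 1 offsets each movie so its series first reaches ``threshold``
    (sustained) at a provisional zero; stage 2 shifts the whole genotype so
    the genotype-average series crosses 0 pp/min at t = 0. Movies never
    reaching the threshold are flagged unsynchronisable and excluded.
    """
    offsets, flagged = {}, []
    for mid, (t, v) in series.items():
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        t_star = _sustained_crossing(t, v, threshold, sustain_min)
        if t_star is None:
            flagged.append(mid)
        else:
            offsets[mid] = t_star
    if not offsets:
        return SyncResult({}, 0.0, flagged)

    # stage 2: zero crossing of the genotype-average curve near the
    # provisional zero
    grids = []
    for mid, t0 in offsets.items():
        t, v = series[mid]
        grids.append((np.asarray(t, dtype=float) - t0, np.asarray(v, dtype=float)))
    lo = max(g[0].min() for g in grids)
    hi = min(g[0].max() for g in grids)
    dt = min(np.median(np.diff(g[0])) for g in grids)
    common = np.arange(lo, hi + dt / 2, dt)
    avg = np.mean([np.interp(common, t, v) for t, v in grids], axis=0)

    shift = 0.0
    below = np.nonzero((avg[:-1] <= 0) & (avg[1:] > 0) & (common[:-1] <= dt))[0]
    if len(below):
        i = below[-1]  # last upward crossing at or before the provisional zero
        if avg[i + 1] != avg[i]:
            shift = float(
                common[i] - avg[i] * (common[i + 1] - common[i]) / (avg[i + 1] - avg[i])
            )
    return SyncResult(
        {mid: t0 + shift for mid, t0 in offsets.items()}, shift, flagged
    )


def apply_offsets(df: pd.DataFrame, offsets: dict, movie_col: str = "movie",
                  time_col: str = "time_min") -> pd.DataFrame:
    out = df[df[movie_col].isin(offsets)].copy()
    out[time_col] = out[time_col] - out[movie_col].map(offsets)
    return out


# ---------------------------------------------------------------------------
# Binning and region selection
# ---------------------------------------------------------------------------

def spatiotemporal_bin(
    df: pd.DataFrame,
    value_col: str,
    time_col: str,
    space_col: str,
    time_edges: np.ndarray,
    space_edges: np.ndarray,
):
    """Mean of ``value_col`` on a (space x time) grid; returns (means, counts)
    DataFrames indexed by space-bin start, columns = time-bin start. Empty
    bins are NaN in the means and 0 in the counts."""
    time_edges = np.asarray(time_edges, dtype=float)
    space_edges = np.asarray(space_edges, dtype=float)
    sub = df[[value_col, time_col, space_col]].dropna()
    ti = np.digitize(sub[time_col], time_edges) - 1
    si = np.digitize(sub[space_col], space_edges) - 1
    ok = (ti >= 0) & (ti < len(time_edges) - 1) & (si >= 0) & (si < len(space_edges) - 1)
    sums = np.zeros((len(space_edges) - 1, len(time_edges) - 1))
    counts = np.zeros_like(sums)
    np.add.at(sums, (si[ok], ti[ok]), sub[value_col].to_numpy()[ok])
    np.add.at(counts, (si[ok], ti[ok]), 1.0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    idx = space_edges[:-1]
    cols = time_edges[:-1]
    return (pd.DataFrame(means, index=idx, columns=cols),
            pd.DataFrame(counts.astype(int), index=idx, columns=cols))


def central_region(df: pd.DataFrame, ap_col: str, anterior_bound_um: float,
                   width_um: float = 100.0) -> pd.DataFrame:
    """Rows with AP position inside [anterior_bound, anterior_bound + width].

    The central window controls for un-registered AP positioning between
    movies; an empty selection raises a warning but is returned as-is.
    """
    sel = df[(df[ap_col] >= anterior_bound_um)
             & (df[ap_col] <= anterior_bound_um + width_um)]
    if sel.empty:
        warnings.warn("central region selection is empty", stacklevel=2)
    return sel


# ---------------------------------------------------------------------------
# Genotype comparison
# ---------------------------------------------------------------------------

def _mixed_model_p(sub: pd.DataFrame) -> float:
    """Cell-level mixed model p-value: random intercept per embryo, Wald t
    on the genotype fixed effect.

    The reference distribution is t with df = n_embryos - 2 (the
    between-embryo degrees of freedom): the genotype contrast is estimated
    across embryos, so a normal reference would be anticonservative for
    cohorts of a few embryos per genotype.
    """
    import statsmodels.formula.api as smf

    n_emb = sub.embryo.nunique()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("value ~ C(genotype)", sub, groups=sub["embryo"])
        fit = md.fit(reml=True, method="bfgs")
        coef = fit.fe_params.iloc[1]
        se = fit.bse_fe.iloc[1]
    if not np.isfinite(se) or se == 0:
        # boundary fit (zero random-effect variance estimate): fall back to
        # the exact embryo-mean test
        return _embryo_mean_p(sub)
    return float(2 * stats.t.sf(abs(coef / se), df=max(n_emb - 2, 1)))


def _embryo_mean_p(sub: pd.DataFrame) -> float:
    """Pooled-variance t-test on embryo means (the balanced mixed-model
    test; exact under normality)."""
    means = sub.groupby(["genotype", "embryo"]).value.mean()
    groups = [means.xs(g).to_numpy() for g in means.index.get_level_values(0).unique()]
    if len(groups) != 2 or min(len(g) for g in groups) < 2:
        return np.nan
    if np.allclose(np.concatenate(groups), np.concatenate(groups)[0]):
        return np.nan  # zero variance: untestable
    res = stats.ttest_ind(groups[0], groups[1], equal_var=True)
    return float(res.pvalue)


def genotype_compare(
    df: pd.DataFrame,
    alpha: float = 0.01,
    method: str = "auto",
    value_col: str = "value",
    bin_col: str = "bin",
    embryo_col: str = "embryo",
    genotype_col: str = "genotype",
) -> pd.DataFrame:
    """Per-bin two-genotype comparison with embryo as the random unit.

    ``method='mixed'`` fits a cell-level random-intercept model per bin;
    ``method='embryo_mean'`` tests embryo means (pooled t); ``'auto'`` uses
    the mixed model when every embryo contributes > 1 observation and both
    genotypes have >= 3 embryos, else embryo means. Bins with < 2 embryos in
    a genotype are untestable (p = NaN, never flagged). No multiple-testing
    correction is applied across bins.
    """
    out = []
    work = df.rename(columns={value_col: "value", bin_col: "bin",
                              embryo_col: "embryo", genotype_col: "genotype"})
    for b, sub in work.groupby("bin"):
        sub = sub.dropna(subset=["value"])
        genos = sub.genotype.unique()
        emb_per = sub.groupby("genotype").embryo.nunique()
        if len(genos) != 2 or (emb_per < 2).any():
            out.append(dict(bin=b, p=np.nan, significant=False, testable=False))
            continue
        obs_per_embryo = sub.groupby("embryo").size()
        use_mixed = method == "mixed" or (
            method == "auto"
            and (emb_per >= 3).all()
            and (obs_per_embryo > 1).all()
        )
        if sub.groupby("genotype").value.std(ddof=0).max() == 0 and (
            sub.groupby("genotype").value.mean().nunique() == 1
        ):
            p = np.nan  # identical constant data: untestable
        elif use_mixed:
            try:
                p = _mixed_model_p(sub)
            except Exception:
                p = _embryo_mean_p(sub)
        else:
            p = _embryo_mean_p(sub)
        out.append(dict(bin=b, p=p,
                        significant=bool(np.isfinite(p) and p < alpha),
                        testable=bool(np.isfinite(p))))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Ribbon summaries
# ---------------------------------------------------------------------------

def smooth3(values: np.ndarray) -> np.ndarray:
    """Centred 3-bin moving average (edges use the nearest value), for
    presentation only."""
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(np.asarray(values, dtype=float), size=3,
                            mode="nearest")


def ribbon_summary(per_embryo: pd.DataFrame, value_col: str = "value",
                   bin_col: str = "bin", embryo_col: str = "embryo") -> pd.DataFrame:
    """Cross-embryo mean, SE, and a 3-bin smoothed display series per bin.

    Significance testing always runs on unsmoothed values; the smoothed
    columns exist only for plotting.
    """
    g = per_embryo.groupby(bin_col)[value_col]
    out = g.agg(["mean", "sem"]).reset_index()
    out = out.rename(columns={"mean": "mean_value", "sem": "se",
                              bin_col: "bin"})
    out["smoothed"] = smooth3(out["mean_value"].to_numpy())
    out["se_smoothed"] = smooth3(out["se"].to_numpy())
    return out


def plot_ribbon(summaries: dict, ax=None, significance: pd.DataFrame = None,
                ylabel: str = "", colors=("magenta", "green")):
    """Ribbon plot: per-genotype smoothed mean +/- SE over time, with
    significant bins shaded grey. ``summaries`` maps genotype ->
    `ribbon_summary` output. Returns the axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    if significance is not None:
        for row in significance.itertuples():
            if row.significant:
                ax.axvspan(row.bin, row.bin + 0.5, color="0.85", zorder=0)
    for (name, summ), color in zip(summaries.items(), colors):
        ax.plot(summ["bin"], summ.smoothed, color=color, label=name)
        ax.fill_between(summ["bin"], summ.smoothed - summ.se_smoothed,
                        summ.smoothed + summ.se_smoothed, color=color,
                        alpha=0.25, linewidth=0)
    ax.axhline(0.0, color="k", linewidth=0.5)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False)
    return ax


def bin_series(df: pd.DataFrame, value_col: str, time_col: str,
               bin_width_min: float = 0.5, t_min: float | None = None,
               t_max: float | None = None,
               extra_group_cols: tuple = ("movie",)) -> pd.DataFrame:
    """Per-movie (embryo) means of a per-cell value in 30-s time bins."""
    sub = df.dropna(subset=[value_col]).copy()
    lo = sub[time_col].min() if t_min is None else t_min
    hi = sub[time_col].max() if t_max is None else t_max
    edges = np.arange(np.floor(lo / bin_width_min) * bin_width_min,
                      hi + bin_width_min, bin_width_min)
    sub["bin"] = edges[np.clip(np.digitize(sub[time_col], edges) - 1, 0,
                               len(edges) - 2)]
    keep = (sub[time_col] >= edges[0]) & (sub[time_col] < edges[-1])
    grouped = (
        sub[keep].groupby([*extra_group_cols, "bin"])[value_col]
        .mean().reset_index()
    )
    return grouped.rename(columns={value_col: "value"})
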