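"""Statistics for phase-triggered stimulation effects on kinematics.

Pre/post joint-angle contrasts, movement latencies from stimulation
onset, Welch and paired t tests, Hedges' g with the small-sample
correction J = 1 - 3/(4 df - 1), timepoint-wise condition contrasts with
Benjamini-Hochberg correction, and one-way ANOVA with Tukey HSD.  The
statistical unit for cross-condition tests is the animal-level mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .kinematics import JointAngleSeries
from .records import StimEpoch

DEFAULT_PRE_MS = 100.0
DEFAULT_POST_MS = 100.0


@dataclass
class EffectSizeResult:
    t: float
    df: float
    p: float
    g: float | None
    n1: int
    n2: int


@dataclass
class LatencyResult:
    onset_latency_ms: float | None
    max_latency_ms: float | None
    threshold: float
    flagged: bool = False


def prepost_angles(
    angles: JointAngleSeries,
    relative_time_ms: np.ndarray,
    epoch: StimEpoch,
    pre_ms: float = DEFAULT_PRE_MS,
    post_ms: float = DEFAULT_POST_MS,
) -> tuple[float, float]:
    """Mean angle over [onset - pre, onset) and [offset, offset + post)."""
    t = np.asarray(relative_time_ms, dtype=float)
    a = angles.angle_deg
    if pre_ms <= 0 or post_ms <= 0:
        raise ValueError("pre_ms and post_ms must be positive")
    pre_lo, pre_hi = epoch.onset_ms - pre_ms, epoch.onset_ms
    post_lo, post_hi = epoch.offset_ms, epoch.offset_ms + post_ms
    if pre_hi > post_lo:
        raise ValueError("pre and post windows overlap")
    if pre_lo < t[0] or post_hi > t[-1] + (t[1] - t[0]):
        raise ValueError("pre/post windows outside recording")
    pre_m = (t >= pre_lo) & (t < pre_hi)
    post_m = (t >= post_lo) & (t < post_hi)
    return float(np.nanmean(a[pre_m])), float(np.nanmean(a[post_m]))


def paired_t(pre: np.ndarray, post: np.ndarray) -> EffectSizeResult:
    """Classical paired t on animal-level means, df = n - 1."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size or pre.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0):
        if np.allclose(diff, 0):
            return EffectSizeResult(t=0.0, df=pre.size - 1, p=1.0, g=None,
                                    n1=pre.size, n2=pre.size)
        raise ZeroDivisionError("zero variance of nonzero differences")
    res = stats.ttest_rel(post, pre)
    return EffectSizeResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        g=None, n1=pre.size, n2=post.size,
    )


def welch_t(x: np.ndarray, y: np.ndarray) -> EffectSizeResult:
    """Two-sided Welch's t with Welch-Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return EffectSizeResult(t=0.0, df=float(x.size + y.size - 2),
                                    p=1.0, g=None, n1=x.size, n2=y.size)
        raise ZeroDivisionError("both variances zero with unequal means")
    res = stats.ttest_ind(x, y, equal_var=False)
    return EffectSizeResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        g=hedges_g(x, y), n1=x.size, n2=y.size,
    )


def hedges_j(df: int | float) -> float:
    """Small-sample correction J = 1 - 3/(4 df - 1)."""
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g(x: np.ndarray, y: np.ndarray) -> float:
    """Hedges' g: J * (mean x - mean y) / pooled SD (df = n1 + n2 - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 + n2 < 3:
        raise ValueError("need n1 + n2 >= 3")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if pooled_var == 0:
        raise ZeroDivisionError("zero pooled variance; g undefined")
    return hedges_j(df) * (x.mean() - y.mean()) / np.sqrt(pooled_var)


def movement_latency(
    series: np.ndarray,
    relative_time_ms: np.ndarray,
    epoch: StimEpoch,
    baseline_ms: float = 100.0,
    c: float = 3.0,
    m: int = 3,
    search_ms: float = 200.0,
) -> LatencyResult:
    """Latency from stimulation onset to movement initiation and maximum.

    Onset latency: first time >= epoch onset at which |series - baseline
    mean| exceeds ``c`` baseline SDs for at least ``m`` consecutive
    frames.  Max latency: time of the extremal excursion from baseline
    within [onset, onset + search_ms].  The baseline SD is floored at a
    tiny fraction of the baseline mean so noiseless traces are handled.
    """
    t = np.asarray(relative_time_ms, dtype=float)
    x = np.asarray(series, dtype=float)
    base_m = (t >= epoch.onset_ms - baseline_ms) & (t < epoch.onset_ms)
    if not base_m.any():
        raise ValueError("baseline window precedes the recording")
    mu = float(np.nanmean(x[base_m]))
    sd = float(np.nanstd(x[base_m]))
    sd = max(sd, 1e-9 * max(abs(mu), 1.0))
    thresh = c * sd

    search = (t >= epoch.onset_ms) & (t <= epoch.onset_ms + search_ms)
    idx = np.flatnonzero(search)
    dev = np.abs(x[idx] - mu)
    above = dev > thresh
    onset_latency = None
    if above.size >= m:
        ok = np.convolve(above.astype(int), np.ones(m, int), "valid") == m
        hits = np.flatnonzero(ok)
        if hits.size:
            onset_latency = float(t[idx[hits[0]]] - epoch.onset_ms)
    max_latency = None
    if onset_latency is not None:
        max_latency = float(t[idx[int(np.argmax(dev))]] - epoch.onset_ms)
        max_latency = max(max_latency, onset_latency)
    return LatencyResult(
        onset_latency_ms=onset_latency,
        max_latency_ms=max_latency,
        threshold=thresh,
        flagged=onset_latency is None,
    )


def timepoint_contrast(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    time_bins_ms: np.ndarray,
    correction: str = "BH",
) -> pd.DataFrame:
    """Welch t per time bin on animal-level means, optional BH adjustment.

    ``cond_a``/``cond_b`` are (n_animals, n_bins) arrays; underpopulated
    bins (< 2 finite values in either condition) are skipped.
    """
    if correction not in ("none", "BH"):
        raise ValueError("correction must be 'none' or 'BH'")
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    rows = []
    for j, tb in enumerate(np.asarray(time_bins_ms, dtype=float)):
        xa = a[:, j][np.isfinite(a[:, j])]
        xb = b[:, j][np.isfinite(b[:, j])]
        if xa.size < 2 or xb.size < 2:
            continue
        if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
            t_stat, p = (0.0, 1.0) if xa.mean() == xb.mean() else (np.inf, 0.0)
        else:
            res = stats.ttest_ind(xa, xb, equal_var=False)
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"time_ms": tb, "t": t_stat, "p": p})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no bins with >= 2 animals per condition")
    if correction == "BH":
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adj"] = df["p"]
    return df


def oneway_anova_tukey(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA across groups plus Tukey HSD pairwise comparisons."""
    names = list(groups)
    arrs = [np.asarray(groups[g], dtype=float) for g in names]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(a.var(ddof=1) == 0 for a in arrs):
        if len({a.mean() for a in arrs}) == 1:
            n = sum(a.size for a in arrs)
            return {
                "F": 0.0, "df1": len(arrs) - 1, "df2": n - len(arrs),
                "p": 1.0, "tukey": {},
            }
        raise ZeroDivisionError("zero within-group variance everywhere")
    f_res = stats.f_oneway(*arrs)
    tk = stats.tukey_hsd(*arrs)
    pairwise = {
        (names[i], names[j]): float(tk.pvalue[i, j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    n = sum(a.size for a in arrs)
    return {
        "F": float(f_res.statistic),
        "df1": len(arrs) - 1,
        "df2": n - len(arrs),
        "p": float(f_res.pvalue),
        "tukey": pairwise,
    }
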