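"""Genome-wide comparisons between hotspot strength tables.

Covers the comparative stage of the pipeline: correlation of hotspot
strengths (NormHpM) between genotypes, per-hotspot log2 fold changes,
along-chromosome loess-style smoothing of fold changes, 50 kb
centromere-centred binning for heatmaps, preparation of a
pro-DSB-factor association-time track (confidence filter, per-chromosome
loess with span 80/N, 50 kb bins), and rank correlation of binned fold
change against association time.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "hotspot_correlation", "log2_ratio_per_hotspot", "smooth_ratio",
    "bin_ratios_50kb", "prepare_timing_track", "correlate_fc_with_timing",
    "loess_smooth", "BIN_SIZE",
]

BIN_SIZE = 50_000


def _paired_norm(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    for t in (table_a, table_b):
        if "NormHpM" not in t.columns:
            raise ValueError("tables need a NormHpM column (see hotspot_strengths)")
    a = table_a.set_index(["chrom", "start", "end"])["NormHpM"]
    b = table_b.set_index(["chrom", "start", "end"])["NormHpM"]
    pair = pd.DataFrame({"a": a, "b": b}).dropna()
    return pair.reset_index()


def hotspot_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame,
                        method: str = "pearson") -> dict:
    """Correlation of NormHpM strengths over the shared hotspot template.

    Hotspots flagged zero on either side are excluded and counted.
    Returns {r, p, n, n_excluded}.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    pair = _paired_norm(table_a, table_b)
    ok = (pair["a"] > 0) & (pair["b"] > 0)
    kept = pair[ok]
    if len(kept) < 3:
        raise ValueError("need at least 3 paired hotspots")
    f = stats.pearsonr if method == "pearson" else stats.spearmanr
    r, p = f(kept["a"], kept["b"])
    return {"r": float(r), "p": float(p), "n": int(len(kept)),
            "n_excluded": int((~ok).sum())}


def log2_ratio_per_hotspot(table_a: pd.DataFrame, table_b: pd.DataFrame
                           ) -> pd.DataFrame:
    """Per-hotspot log2(NormHpM_A / NormHpM_B) over the shared template.

    No pseudocount: a zero on either side yields NaN with the ``excluded``
    flag set.  Swapping A and B negates every defined value.
    """
    pair = _paired_norm(table_a, table_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(pair["a"].to_numpy() / pair["b"].to_numpy())
    out = pair.copy()
    out["midpoint"] = (out["start"] + out["end"]) // 2
    out["log2fc"] = np.where(np.isfinite(ratio), ratio, np.nan)
    out["excluded"] = ~np.isfinite(ratio)
    return out


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float,
                 eval_x: np.ndarray | None = None) -> np.ndarray:
    """Degree-1 local regression with tricube weights (loess, it=0).

    For each evaluation point the nearest ``ceil(span * n)`` data points
    (ties broken by data order) form the neighbourhood; tricube weights
    ``(1 - (d/dmax)^3)^3`` feed a weighted straight-line fit evaluated at
    the point.  Degenerate neighbourhoods (zero spread or fewer than two
    distinct x) fall back to the weighted mean.  Deterministic.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if eval_x is None:
        eval_x = x
    n = len(x)
    k = max(2, int(math.ceil(span * n)))
    k = min(k, n)
    out = np.empty(len(eval_x))
    for i, x0 in enumerate(eval_x):
        d = np.abs(x - x0)
        order = np.argsort(d, kind="stable")[:k]
        dmax = d[order].max()
        if dmax == 0.0:
            out[i] = y[order].mean()
            continue
        w = (1.0 - (d[order] / dmax) ** 3) ** 3
        w = np.maximum(w, 0.0)
        if w.sum() <= 0 or np.unique(x[order][w > 0]).size < 2:
            wm = w if w.sum() > 0 else np.ones_like(w)
            out[i] = float(np.average(y[order], weights=wm))
            continue
        xs, ys = x[order], y[order]
        sw = w.sum()
        xbar = np.dot(w, xs) / sw
        ybar = np.dot(w, ys) / sw
        sxx = np.dot(w, (xs - xbar) ** 2)
        if sxx <= 0:
            out[i] = ybar
            continue
        slope = np.dot(w, (xs - xbar) * (ys - ybar)) / sxx
        out[i] = ybar + slope * (x0 - xbar)
    return out


def smooth_ratio(ratios: pd.DataFrame, span: float = 0.1,
                 min_points: int = 5) -> pd.DataFrame:
    """Smooth per-hotspot log2 fold changes along each chromosome.

    Operates on the output of :func:`log2_ratio_per_hotspot` (columns
    chrom, midpoint, log2fc); excluded hotspots are dropped.  Chromosomes
    with fewer than ``min_points`` defined values pass through unsmoothed
    with ``smoothed_flag = False``.  Unweighted in hotspot strength.
    """
    frames = []
    for chrom, sub in ratios.dropna(subset=["log2fc"]).groupby("chrom"):
        sub = sub.sort_values("midpoint").copy()
        if len(sub) < min_points:
            sub["smoothed"] = sub["log2fc"]
            sub["smoothed_flag"] = False
        else:
            sub["smoothed"] = loess_smooth(sub["midpoint"].to_numpy(float),
                                           sub["log2fc"].to_numpy(float), span)
            sub["smoothed_flag"] = True
        frames.append(sub)
    return (pd.concat(frames, ignore_index=True) if frames
            else ratios.iloc[0:0].assign(smoothed=[], smoothed_flag=[]))


def _cen_bins(length: int, cen: int, bin_size: int) -> list[tuple[int, int, int]]:
    """Centromere-anchored bins (k, start, end), 1-based inclusive, clipped.

    Bin k covers [cen + k*bin_size, cen + (k+1)*bin_size); terminal partial
    bins are retained.
    """
    k_min = -math.ceil((cen - 1) / bin_size)
    k_max = math.ceil((length - cen + 1) / bin_size) - 1
    out = []
    for k in range(k_min, k_max + 1):
        s = max(1, cen + k * bin_size)
        e = min(length, cen + (k + 1) * bin_size - 1)
        if s <= e:
            out.append((k, s, e))
    return out


def bin_ratios_50kb(table_a: pd.DataFrame, table_b: pd.DataFrame,
                    centromeres: dict[str, int],
                    chrom_lengths: dict[str, int],
                    bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Centromere-centred binned log2 fold change between two tables.

    Hotspots are assigned to bins by midpoint; the bin value is
    ``log2(sum NormHpM_A / sum NormHpM_B)`` over its hotspots.  Bins where
    either side sums to zero (or holds no hotspot) are flagged undefined.
    The output carries per-side binned mass so totals can be audited, and
    a chromosome size rank (1 = largest) for heatmap row ordering.
    """
    pair = _paired_norm(table_a, table_b)
    pair["midpoint"] = (pair["start"] + pair["end"]) // 2
    rows = []
    for chrom, cen in centromeres.items():
        length = chrom_lengths[chrom]
        if not 0 < cen < length:
            raise ValueError(f"{chrom}: centromere outside chromosome")
        sub = pair[pair["chrom"] == chrom]
        for k, s, e in _cen_bins(length, cen, bin_size):
            inbin = sub[(sub["midpoint"] >= s) & (sub["midpoint"] <= e)]
            sa, sb = inbin["a"].sum(), inbin["b"].sum()
            defined = sa > 0 and sb > 0
            rows.append({
                "chrom": chrom, "bin": k, "start": s, "end": e,
                "sum_a": sa, "sum_b": sb,
                "log2fc": math.log2(sa / sb) if defined else math.nan,
                "n_hotspots": len(inbin), "defined": defined,
            })
    out = pd.DataFrame(rows)
    sizes = pd.Series(chrom_lengths)
    rank = sizes.rank(ascending=False, method="first").astype(int)
    out["size_rank"] = out["chrom"].map(rank)
    return out


def prepare_timing_track(track: pd.DataFrame, loess_numerator: float = 80.0,
                         bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Filter, smooth and bin an association-time track.

    Rows with a falsy ``confidence`` flag are dropped; each chromosome is
    smoothed by local regression with span ``loess_numerator / N`` (N =
    points on that chromosome; clamped to (0, 1]); smoothed values are
    averaged in ``bin_size`` bins anchored at position 0.  Returns one row
    per (chrom, bin) with the mean smoothed time.
    """
    if "confidence" in track.columns:
        track = track[track["confidence"].astype(bool)]
    if track.empty:
        raise ValueError("timing track empty after confidence filtering")
    rows = []
    for chrom, sub in track.groupby("chrom"):
        sub = sub.sort_values("position")
        n = len(sub)
        span = min(1.0, loess_numerator / n) if n else 1.0
        x = sub["position"].to_numpy(float)
        y = sub["time"].to_numpy(float)
        sm = loess_smooth(x, y, span) if n >= 2 else y.copy()
        b = ((x - 1) // bin_size).astype(int)
        for k in np.unique(b):
            sel = b == k
            rows.append({"chrom": chrom, "bin": int(k),
                         "start": int(k) * bin_size + 1,
                         "end": (int(k) + 1) * bin_size,
                         "time": float(sm[sel].mean()),
                         "n_points": int(sel.sum())})
    return pd.DataFrame(rows)


def _reanchor_timing(timing: pd.DataFrame, binned: pd.DataFrame) -> pd.DataFrame:
    """Average the 0-anchored timing bins onto the centromere-anchored grid.

    Overlap-weighted mean of timing-bin values over each ratio bin's
    interval, so (time, fold-change) pairs align on the same grid.
    """
    rows = []
    for _, r in binned.iterrows():
        sub = timing[timing["chrom"] == r["chrom"]]
        if sub.empty:
            continue
        ov_lo = np.maximum(sub["start"].to_numpy(), r["start"])
        ov_hi = np.minimum(sub["end"].to_numpy(), r["end"])
        w = np.maximum(0, ov_hi - ov_lo + 1).astype(float)
        if w.sum() <= 0:
            continue
        rows.append({"chrom": r["chrom"], "bin": r["bin"],
                     "time": float(np.average(sub["time"].to_numpy(), weights=w))})
    return pd.DataFrame(rows)


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for small n (full enumeration)."""
    n = len(xr)
    count, total = 0, 0
    for perm in itertools.permutations(range(n)):
        r = stats.spearmanr(xr, yr[list(perm)]).statistic
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def correlate_fc_with_timing(binned_ratios: pd.DataFrame,
                             binned_timing: pd.DataFrame) -> dict:
    """Spearman rank correlation of binned log2 fold change vs time.

    Timing bins are re-anchored onto the ratio bins' centromere grid by
    overlap-weighted averaging; undefined ratio bins are dropped.  The
    p-value uses the large-sample t approximation, or exact permutation
    when n < 10.  The raw sign convention (positive = fold change grows
    with later association time) is reported alongside the coefficient.
    Returns {r, p, n, sign_convention, pairs}.
    """
    defined = binned_ratios[binned_ratios["defined"]]
    timing = _reanchor_timing(binned_timing, defined)
    pairs = defined.merge(timing, on=["chrom", "bin"])
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired bins")
    r = float(stats.spearmanr(pairs["time"], pairs["log2fc"]).statistic)
    if len(pairs) < 10:
        xr = stats.rankdata(pairs["time"])
        yr = stats.rankdata(pairs["log2fc"])
        p = _spearman_exact_p(xr, yr, r)
    else:
        p = float(stats.spearmanr(pairs["time"], pairs["log2fc"]).pvalue)
    return {"r": r, "p": p, "n": int(len(pairs)),
            "sign_convention": "positive r means log2FC increases with "
                               "later association time",
            "pairs": pairs[["chrom", "bin", "time", "log2fc"]]}
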