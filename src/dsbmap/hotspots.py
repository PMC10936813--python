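"""CC-seq hotspot identification, background calibration and NormHpM.

The calling recipe operates on strand-combined per-base HpM signal:

1. smooth with a 201 bp Hann window (weights normalised to sum 1,
   chromosome ends zero-padded);
2. threshold the smoothed profile at 0.193 HpM (candidate intervals are
   maximal supra-cutoff runs);
3. merge candidates separated by < 200 bp;
4. keep intervals of length >= 25 bp carrying >= 25 reads of raw mass.

Hotspots are called per library and combined into a single template by
interval union.  Background is calibrated as the mean HpM per bp inside
the 47 longest ORFs (> 5.5 kb) -- regions of presumed Spo11 inactivity --
and hotspot strength is the background-corrected HpM sum expressed per
million of the total corrected signal in all hotspots (NormHpM, which sums
to 1e6 per library by construction).

All coordinates are 1-based inclusive; gaps between intervals are
``next.start - prev.end - 1`` bp.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .maps import FullMap

__all__ = [
    "hann_smooth", "smooth_fullmap", "call_hotspots", "combine_templates",
    "estimate_background", "exclude_region", "hotspot_strengths",
    "overlap_templates", "merge_intervals",
]

DEFAULT_HANN_WINDOW = 201
DEFAULT_CUTOFF_HPM = 0.193
LOWERED_CUTOFF_HPM = 0.125      # used for the catalytically dead control
DEFAULT_MIN_LEN = 25
DEFAULT_MIN_READS = 25
DEFAULT_MERGE_GAP = 200
DEFAULT_MIN_ORF_LEN = 5500
DEFAULT_N_ORFS = 47

TEMPLATE_COLUMNS = ["chrom", "start", "end"]


def hann_window(window: int) -> np.ndarray:
    """Hann weights w_k = 0.5*(1 - cos(2*pi*k/(window-1))), normalised to 1.

    The raw window sums to (window-1)/2, so a unit impulse smoothed with a
    201 bp window peaks at 1/100 of its mass.
    """
    if window % 2 == 0:
        raise ValueError("Hann window must be odd")
    if window < 3:
        raise ValueError("Hann window must be >= 3")
    k = np.arange(window)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (window - 1)))
    return w / w.sum()


def hann_smooth(signal: np.ndarray, window: int = DEFAULT_HANN_WINDOW,
                full: bool = False) -> np.ndarray:
    """Smooth a dense per-bp signal with a normalised Hann window.

    The chromosome is implicitly zero-padded: with ``full=True`` the
    returned array covers the padded domain (length n + window - 1) on
    which total signal is conserved exactly; with ``full=False`` (default)
    the central slice aligned with the input positions is returned.
    """
    w = hann_window(window)
    out = np.convolve(np.asarray(signal, dtype=float), w, mode="full")
    if full:
        return out
    half = (window - 1) // 2
    return out[half:half + len(signal)]


def smooth_fullmap(fullmap: FullMap, window: int = DEFAULT_HANN_WINDOW
                   ) -> dict[str, np.ndarray]:
    """Per-chromosome smoothed HpM profiles (Watson + Crick combined)."""
    return {c: hann_smooth(fullmap.dense_hpm(c), window)
            for c in fullmap.chromosomes}


def _runs_above(x: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Maximal runs with x >= cutoff, as 1-based inclusive (start, end)."""
    above = x >= cutoff
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0]
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(x) - 1]
    return [(int(s) + 1, int(e) + 1) for s, e in zip(starts, ends)]


def _merge_close(intervals: list[tuple[int, int]], merge_gap: int
                 ) -> list[tuple[int, int]]:
    """Merge sorted intervals whose gap (next.start - prev.end - 1) < merge_gap."""
    if not intervals:
        return []
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def call_hotspots(smoothed: dict[str, np.ndarray], raw: FullMap,
                  cutoff: float = DEFAULT_CUTOFF_HPM,
                  min_len: int = DEFAULT_MIN_LEN,
                  min_reads: float = DEFAULT_MIN_READS,
                  merge_gap: int = DEFAULT_MERGE_GAP) -> pd.DataFrame:
    """Call hotspot intervals from a smoothed profile plus the raw map.

    Rule order: threshold -> merge (< merge_gap bp) -> length and read-mass
    filters, so merged composites are eligible as single hotspots.  The
    read-mass filter sums the raw strand-combined counts inside the
    interval (for an HpM-normalised pooled map this is HpM mass).
    Deterministic; returns a sorted template frame (chrom, start, end).
    """
    if cutoff < 0 or min_len < 0 or min_reads < 0 or merge_gap < 0:
        raise ValueError("thresholds must be non-negative")
    rows = []
    for chrom in sorted(smoothed):
        prof = smoothed[chrom]
        counts = raw.dense_counts(chrom)
        if len(counts) < len(prof):
            counts = np.r_[counts, np.zeros(len(prof) - len(counts))]
        cand = _runs_above(prof, cutoff)
        for s, e in _merge_close(cand, merge_gap):
            if e - s + 1 < min_len:
                continue
            if counts[s - 1:e].sum() < min_reads:
                continue
            rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=TEMPLATE_COLUMNS)


def merge_intervals(template: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: overlapping or abutting intervals merged."""
    rows = []
    for chrom, sub in template.sort_values(["chrom", "start"]).groupby("chrom"):
        cur = None
        for _, r in sub.iterrows():
            s, e = int(r["start"]), int(r["end"])
            if cur is None:
                cur = [s, e]
            elif s <= cur[1] + 1:
                cur[1] = max(cur[1], e)
            else:
                rows.append((chrom, cur[0], cur[1]))
                cur = [s, e]
        if cur is not None:
            rows.append((chrom, cur[0], cur[1]))
    return pd.DataFrame(rows, columns=TEMPLATE_COLUMNS)


def combine_templates(templates: list[pd.DataFrame],
                      names: list[str] | None = None) -> pd.DataFrame:
    """Combine per-library templates into one (union, merged).

    Per-source presence flags (``in_<name>`` boolean columns) record which
    library called each combined hotspot (any bp overlap).
    """
    if not templates:
        raise ValueError("need at least one template")
    names = names or [f"lib{i + 1}" for i in range(len(templates))]
    merged = merge_intervals(pd.concat(templates, ignore_index=True)
                             if len(templates) > 1 else templates[0])
    for name, t in zip(names, templates):
        flags = []
        for _, r in merged.iterrows():
            sub = t[t["chrom"] == r["chrom"]]
            flags.append(bool(((sub["start"] <= r["end"])
                               & (sub["end"] >= r["start"])).any()))
        merged[f"in_{name}"] = flags
    return merged


def estimate_background(fullmap: FullMap, orfs: pd.DataFrame,
                        min_orf_len: int = DEFAULT_MIN_ORF_LEN,
                        n_orfs: int = DEFAULT_N_ORFS) -> float:
    """Background HpM per bp from the longest ORFs.

    Selects the ``n_orfs`` longest ORFs exceeding ``min_orf_len`` and
    returns total HpM inside them divided by their total length.  If fewer
    than ``n_orfs`` qualify, all qualifying ORFs are used with a warning.
    """
    orfs = orfs.copy()
    orfs["length"] = orfs["end"] - orfs["start"] + 1
    qual = orfs[orfs["length"] > min_orf_len].sort_values(
        "length", ascending=False)
    if qual.empty:
        raise ValueError(f"no ORFs longer than {min_orf_len} bp")
    if len(qual) < n_orfs:
        warnings.warn(f"only {len(qual)} ORFs exceed {min_orf_len} bp; "
                      f"using all of them (requested {n_orfs})")
    sel = qual.head(n_orfs)
    total_hpm, total_bp = 0.0, 0
    for chrom, sub in sel.groupby("chrom"):
        dense = fullmap.dense_hpm(chrom)
        for _, r in sub.iterrows():
            s, e = int(r["start"]), int(r["end"])
            total_hpm += dense[s - 1:min(e, len(dense))].sum()
            total_bp += e - s + 1
    return total_hpm / total_bp


def exclude_region(template: pd.DataFrame, region: tuple[str, int, int]
                   ) -> tuple[pd.DataFrame, int]:
    """Drop hotspots overlapping a region (e.g. the rDNA array).

    Returns (filtered template, number removed).
    """
    chrom, start, end = region
    if start > end:
        raise ValueError("malformed region: start > end")
    hit = ((template["chrom"] == chrom)
           & (template["start"] <= end) & (template["end"] >= start))
    return template[~hit].reset_index(drop=True), int(hit.sum())


def hotspot_strengths(fullmap: FullMap, template: pd.DataFrame,
                      background: float = 0.0) -> pd.DataFrame:
    """Per-hotspot HpM, background-corrected signal, and NormHpM.

    corrected = max(0, HpM sum - background * length); NormHpM scales the
    corrected signal to parts-per-million of the total corrected signal
    over all hotspots (sums to 1e6 per library).  Negative corrected
    values are floored to 0 and flagged.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    if template.empty:
        raise ValueError("empty hotspot template")
    out = template.reset_index(drop=True).copy()
    hpm_sums = np.zeros(len(out))
    for chrom, sub in out.groupby("chrom"):
        dense = fullmap.dense_hpm(chrom)
        for i, r in sub.iterrows():
            s, e = int(r["start"]), int(r["end"])
            hpm_sums[i] = dense[s - 1:min(e, len(dense))].sum()
    lengths = (out["end"] - out["start"] + 1).to_numpy(float)
    raw_corrected = hpm_sums - background * lengths
    out["HpM"] = hpm_sums
    out["corrected"] = np.maximum(raw_corrected, 0.0)
    out["floored"] = raw_corrected < 0
    total = out["corrected"].sum()
    if total <= 0:
        raise ValueError("all corrected hotspot signals are zero")
    out["NormHpM"] = out["corrected"] / total * 1e6
    if "id" not in out.columns:
        out.insert(0, "id", [f"{c}:{s}-{e}" for c, s, e in
                             zip(out["chrom"], out["start"], out["end"])])
    return out


def overlap_templates(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Venn-style overlap summary between two templates.

    "Shared" means any bp overlap.  Returns counts plus the NormHpM (or
    HpM, if present) strength values split by class for each input.
    """
    def flags(t: pd.DataFrame, other: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(t), dtype=bool)
        for i, (_, r) in enumerate(t.iterrows()):
            sub = other[other["chrom"] == r["chrom"]]
            out[i] = bool(((sub["start"] <= r["end"])
                           & (sub["end"] >= r["start"])).any())
        return out

    a = a.reset_index(drop=True)
    b = b.reset_index(drop=True)
    a_shared = flags(a, b)
    b_shared = flags(b, a)

    def strengths(t: pd.DataFrame, mask: np.ndarray) -> np.ndarray:
        col = "NormHpM" if "NormHpM" in t.columns else (
            "HpM" if "HpM" in t.columns else None)
        return t.loc[mask, col].to_numpy() if col else np.array([])

    return {
        "a_total": len(a), "b_total": len(b),
        "a_only": int((~a_shared).sum()), "b_only": int((~b_shared).sum()),
        "shared_a": int(a_shared.sum()), "shared_b": int(b_shared.sum()),
        "a_only_strengths": strengths(a, ~a_shared),
        "a_shared_strengths": strengths(a, a_shared),
        "b_only_strengths": strengths(b, ~b_shared),
        "b_shared_strengths": strengths(b, b_shared),
    }
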