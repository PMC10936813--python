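"""DSB-interference statistics from single- and double-cut frequencies.

For a pair of hotspots assayed in a population, the expected double-cut
(DC) frequency under independence is the product of the two single-DSB
frequencies.  The coefficient of coincidence is

    CoC = observed DC / expected DC

and interference is expressed as ``-log2(CoC)``: positive values mean
fewer coincident cuts than chance (classical interference), values near
zero independence, negative values concerted cutting (clustering).
Interference is computed per biological repeat -- on frequencies averaged
over the 6 and 8 h timepoints to damp technical variation -- then averaged
across repeats; genotypes are compared with an equal-variance two-tailed
t-test on the per-repeat values.

Because the ratio is unstable when both frequencies are tiny, repeats
where either side falls below an exclusion threshold ``epsilon`` are
flagged and left out rather than reported as +/-infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "correct_multicopy", "correct_distal_single", "average_timepoints",
    "expected_dc", "interference", "aggregate", "aggregate_and_compare",
    "interference_per_repeat", "InterferenceResult", "DEFAULT_EPSILON",
]

DEFAULT_EPSILON = 1e-4   # fraction units; near-zero exclusion threshold


def correct_multicopy(raw: float, copies: int) -> tuple[float, bool]:
    """Multi-copy probe correction: raw frequency times copy number.

    When a probe hybridises to ``copies`` loci but only one is assayed,
    the detected fraction under-reports the locus by that factor (the x3
    correction for the three LEU2 copies).  Returns (frequency, overflow):
    values exceeding 1 are capped at 1 with the overflow flag set.
    """
    if copies < 1:
        raise ValueError("copy number must be >= 1")
    if not 0.0 <= raw <= 1.0:
        raise ValueError("raw frequency must be in [0, 1]")
    value = raw * copies
    if value > 1.0:
        return 1.0, True
    return value, False


def correct_distal_single(proximal_fragment: float, dc: float) -> float:
    """Occlusion correction for a distal hotspot measured past a proximal one.

    A probe-side cut at the proximal hotspot hides the distal cut, so the
    distal single-cut frequency is recovered by adding back the double-cut
    frequency measured between the pair.
    """
    for v in (proximal_fragment, dc):
        if not 0.0 <= v <= 1.0:
            raise ValueError("frequencies must be in [0, 1]")
    return proximal_fragment + dc


def average_timepoints(table: pd.DataFrame,
                       timepoints: list[float] = (6.0, 8.0)) -> pd.DataFrame:
    """Unweighted mean frequency over the listed timepoints, per repeat x assay.

    Repeats missing any requested timepoint for an assay are kept but
    flagged (``complete = False``), never silently dropped.
    """
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("empty timepoint list")
    sub = table[table["timepoint_h"].isin(timepoints)]
    rows = []
    for (rep, assay), grp in sub.groupby(["repeat", "assay"], sort=True):
        present = set(grp["timepoint_h"])
        rows.append({
            "repeat": rep, "assay": assay,
            "kind": grp["kind"].iloc[0],
            "frequency": grp["frequency"].mean(),
            "complete": all(t in present for t in timepoints),
        })
    return pd.DataFrame(rows)


def expected_dc(f1: float, f2: float) -> float:
    """Expected double-cut frequency under independence: f1 * f2."""
    for v in (f1, f2):
        if not 0.0 <= v <= 1.0:
            raise ValueError("single-cut frequencies must be in [0, 1]")
    return f1 * f2


def interference(observed: float, expected: float,
                 epsilon: float = DEFAULT_EPSILON) -> float | None:
    """-log2(observed/expected), or None when either side is near zero.

    Returns the per-repeat interference value; ``None`` marks an excluded
    (unstable) measurement and is never +/-infinity.
    """
    if observed < 0 or expected < 0:
        raise ValueError("frequencies must be non-negative")
    if observed <= epsilon or expected <= epsilon:
        return None
    return -math.log2(observed / expected)


@dataclass
class InterferenceResult:
    """Per-repeat interference values with aggregate and comparison stats."""

    values: list[float]
    excluded: int = 0
    mean: float = math.nan
    sd: float = math.nan
    n: int = 0
    t_stat: float | None = None
    p_value: float | None = None
    degenerate_test: bool = False
    per_repeat: pd.DataFrame | None = field(default=None, repr=False)


def aggregate(values: list[float | None]) -> InterferenceResult:
    """Mean/SD/n over non-excluded per-repeat values."""
    kept = [v for v in values if v is not None]
    res = InterferenceResult(values=kept, excluded=len(values) - len(kept))
    if kept:
        arr = np.asarray(kept, float)
        res.mean = float(arr.mean())
        res.sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        res.n = len(arr)
    return res


def aggregate_and_compare(values_a: list[float | None],
                          values_b: list[float | None]
                          ) -> tuple[InterferenceResult, InterferenceResult]:
    """Aggregate two genotypes and run the equal-variance two-tailed t-test.

    The pooled-variance two-sample test is run when both groups retain at
    least two repeats.  With zero pooled variance the p-value degenerates:
    1.0 for equal means, 0.0 otherwise, with ``degenerate_test`` flagged.
    The test statistics are stored on both results.
    """
    res_a, res_b = aggregate(values_a), aggregate(values_b)
    if res_a.n == 0 or res_b.n == 0:
        raise ValueError("empty group after exclusions")
    if res_a.n >= 2 and res_b.n >= 2:
        a = np.asarray(res_a.values)
        b = np.asarray(res_b.values)
        pooled = ((a.var(ddof=1) * (len(a) - 1) + b.var(ddof=1) * (len(b) - 1))
                  / (len(a) + len(b) - 2))
        if pooled == 0.0:
            t = 0.0 if res_a.mean == res_b.mean else math.inf
            p = 1.0 if res_a.mean == res_b.mean else 0.0
            res_a.degenerate_test = res_b.degenerate_test = True
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
            t, p = float(t), float(p)
        res_a.t_stat = res_b.t_stat = t
        res_a.p_value = res_b.p_value = p
    return res_a, res_b


def interference_per_repeat(table: pd.DataFrame, dc_assay: str,
                            single1: str, single2: str,
                            timepoints: list[float] = (6.0, 8.0),
                            epsilon: float = DEFAULT_EPSILON,
                            dc_copies: int = 1,
                            distal_correction: str | None = None
                            ) -> pd.DataFrame:
    """Full per-repeat pipeline on a tidy CutFrequencyTable.

    Averages the requested timepoints, applies the multi-copy correction to
    the DC assay and (optionally) the occlusion correction that adds the DC
    frequency onto the ``distal_correction`` single assay, forms expected =
    single1 * single2, CoC and -log2(CoC) per repeat.  Returns one row per
    repeat with an ``excluded`` flag.
    """
    avg = average_timepoints(table, timepoints)
    piv = avg.pivot_table(index="repeat", columns="assay",
                          values="frequency", aggfunc="first")
    rows = []
    for rep, r in piv.iterrows():
        if any(pd.isna(r.get(a)) for a in (dc_assay, single1, single2)):
            rows.append({"repeat": rep, "observed": math.nan,
                         "expected": math.nan, "coc": math.nan,
                         "interference": math.nan, "excluded": True,
                         "overflow": False})
            continue
        obs, overflow = correct_multicopy(float(r[dc_assay]), dc_copies)
        f1, f2 = float(r[single1]), float(r[single2])
        if distal_correction == single1:
            f1 = correct_distal_single(f1, obs)
        elif distal_correction == single2:
            f2 = correct_distal_single(f2, obs)
        exp = expected_dc(f1, f2)
        val = interference(obs, exp, epsilon)
        rows.append({"repeat": rep, "observed": obs, "expected": exp,
                     "coc": obs / exp if exp > 0 else math.nan,
                     "interference": math.nan if val is None else val,
                     "excluded": val is None, "overflow": overflow})
    return pd.DataFrame(rows)
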