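"""Synthetic genome layouts for the per-cell Spo11-DSB simulator.

A :class:`GenomeLayout` is the simulator's world model: chromosomes with
centromeres, DSB hotspots with intrinsic per-hour firing rates, and "priming
domains" -- contiguous groups of adjacent hotspots (end-to-end span bounded,
by default < 15 kb) that mature to a DSB-competent state together at a mean
priming time tau_d.  The priming time follows a configurable spatial
gradient, by default increasing with distance from the centromere, emulating
the early pericentromeric association of pro-DSB factors such as Rec114.

Layouts are deterministic for a fixed seed.  Default parameters are
calibrated so that the expected number of DSBs per cell (four chromatids,
no suppression, evaluated at the mean prophase-exit time) falls in the
100-200 range characteristic of budding-yeast meiosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = ["LayoutConfig", "GenomeLayout", "build_layout"]

# Chromosome lengths (kb) and centromere positions (kb) loosely modelled on
# the 16 S. cerevisiae chromosomes; synthetic, not a genome build.
_DEFAULT_CHROM_KB = [
    (230, 151), (813, 238), (316, 114), (1532, 450), (577, 152), (270, 149),
    (1091, 497), (563, 106), (440, 356), (746, 436), (667, 440), (1078, 151),
    (924, 268), (784, 629), (1091, 327), (948, 556),
]


@dataclass
class LayoutConfig:
    """Parameters of the synthetic genome.

    chromosomes: list of (id, length_bp, centromere_bp). Defaults to a
        16-chromosome, ~12 Mb genome.
    hotspot_spacing: mean distance between hotspot midpoints (bp).
    hotspot_width: hotspot width (bp); cuts land within +/- width/2 of the
        midpoint.
    rate_log_sd: SD of the log-normal intrinsic-rate heterogeneity across
        hotspots (natural-log units).
    calibrate_breaks: if not None, rescale all rates so the expected number
        of breaks per cell, sum over hotspots of 4*(1 - exp(-w*T)) at
        T = calibrate_window_h, equals this target.
    max_domain_span: maximal end-to-end midpoint span of a priming domain (bp).
    tau_cen / tau_range: priming-time gradient in hours: tau at the
        centromere and the additional delay at the most centromere-distal
        point of each chromosome (linear in distance from the centromere).
    rec114_offset: constant offset (h) between a domain's priming time and
        its emulated Rec114 association time.
    n_cold_orfs / cold_orf_len: per-chromosome count and length (bp) of
        hotspot-free "long ORF" intervals reserved for background
        calibration.
    rdna: optional excluded interval as (chrom_id, start, end), 1-based
        inclusive, emulating the rDNA array.
    """

    chromosomes: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            (f"chr{i + 1}", kb * 1000, cen * 1000)
            for i, (kb, cen) in enumerate(_DEFAULT_CHROM_KB)
        ]
    )
    hotspot_spacing: int = 3000
    hotspot_width: int = 200
    rate_log_sd: float = 1.0
    calibrate_breaks: float | None = 150.0
    calibrate_window_h: float = 7.0
    max_domain_span: int = 15000
    tau_cen: float = 2.0
    tau_range: float = 4.0
    rec114_offset: float = 0.0
    n_cold_orfs: int = 3
    cold_orf_len: int = 7000
    rdna: tuple[str, int, int] | None = ("chr12", 451640, 467844)

    def validate(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        for cid, length, cen in self.chromosomes:
            if length <= 0:
                raise ValueError(f"{cid}: non-positive chromosome length {length}")
            if not (0 < cen < length):
                raise ValueError(f"{cid}: centromere {cen} outside chromosome (1..{length})")
        if self.hotspot_spacing <= 0 or self.hotspot_width <= 0:
            raise ValueError("hotspot spacing and width must be positive")
        if self.max_domain_span <= 0:
            raise ValueError("max_domain_span must be positive")
        if self.tau_cen < 0 or self.tau_range < 0:
            raise ValueError("priming-time gradient must be non-negative")


@dataclass
class GenomeLayout:
    """World model: chromosomes, hotspots, priming domains, cold ORFs.

    hotspots columns: id, chrom, midpoint, width, rate, domain.
    domains columns: domain, chrom, start, end (midpoint span, bp), tau,
    rec114_time.
    """

    chromosomes: pd.DataFrame        # columns: chrom, length, cen
    hotspots: pd.DataFrame
    domains: pd.DataFrame
    orfs: pd.DataFrame               # columns: chrom, start, end (1-based incl.)
    rdna: tuple[str, int, int] | None
    config: LayoutConfig
    seed: int

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(zip(self.chromosomes["chrom"], self.chromosomes["length"]))

    @property
    def centromeres(self) -> dict[str, int]:
        return dict(zip(self.chromosomes["chrom"], self.chromosomes["cen"]))

    def expected_breaks_per_cell(self, window_h: float) -> float:
        """Expected DSBs per cell with no suppression: sum 4*(1-exp(-w*T))."""
        w = self.hotspots["rate"].to_numpy()
        return float(np.sum(4.0 * (1.0 - np.exp(-w * window_h))))

    def hotspot_interval(self, hotspot_id: str) -> tuple[str, int, int]:
        row = self.hotspots.set_index("id").loc[hotspot_id]
        half = int(row["width"]) // 2
        return str(row["chrom"]), int(row["midpoint"]) - half, int(row["midpoint"]) + half


def _partition_domains(midpoints: np.ndarray, max_span: int) -> np.ndarray:
    """Greedy maximal runs of adjacent hotspots with end-to-end span <= max_span.

    Returns a domain index per hotspot (0-based, per call).
    """
    idx = np.zeros(len(midpoints), dtype=int)
    if len(midpoints) == 0:
        return idx
    dom, start = 0, midpoints[0]
    for i in range(1, len(midpoints)):
        if midpoints[i] - start > max_span:
            dom += 1
            start = midpoints[i]
        idx[i] = dom
    return idx


def build_layout(config: LayoutConfig | None = None, seed: int = 0) -> GenomeLayout:
    """Build a deterministic synthetic genome layout.

    Hotspot midpoints are placed on a regular grid of ``hotspot_spacing``
    with a seeded uniform jitter of +/- spacing/4, skipping reserved cold-ORF
    intervals.  Intrinsic rates are log-normal, optionally rescaled so the
    expected breaks per cell hits ``calibrate_breaks``.  Adjacent hotspots
    are grouped into priming domains by maximal runs with end-to-end span
    <= ``max_domain_span``; each domain's priming time follows the
    centromere-anchored linear gradient.
    """
    config = config or LayoutConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD5B]))

    chroms = pd.DataFrame(config.chromosomes, columns=["chrom", "length", "cen"])

    # Reserve cold (hotspot-free) long-ORF intervals on each chromosome arm.
    orf_rows = []
    for cid, length, cen in config.chromosomes:
        n = config.n_cold_orfs
        if length < (n + 2) * (config.cold_orf_len + 2 * config.hotspot_spacing):
            n = max(0, length // (2 * config.cold_orf_len) - 1)
        # deterministic, evenly spread anchor points avoiding the centromere
        anchors = np.linspace(0.15, 0.85, max(n, 1)) * length
        placed = 0
        for a in anchors:
            if placed >= n:
                break
            start = int(a)
            end = start + config.cold_orf_len - 1
            if end >= length:
                continue
            if start <= cen <= end:
                start += config.cold_orf_len
                end += config.cold_orf_len
                if end >= length:
                    continue
            orf_rows.append((cid, start + 1, end + 1))
            placed += 1
    orfs = pd.DataFrame(orf_rows, columns=["chrom", "start", "end"])

    hs_rows = []
    half_w = config.hotspot_width // 2
    for cid, length, cen in config.chromosomes:
        grid = np.arange(config.hotspot_spacing // 2, length - half_w, config.hotspot_spacing)
        jitter = rng.integers(-config.hotspot_spacing // 4,
                              config.hotspot_spacing // 4 + 1, size=grid.size)
        mids = np.clip(grid + jitter, half_w + 1, length - half_w)
        corfs = orfs[orfs["chrom"] == cid]
        if len(corfs):
            keep = np.ones(mids.size, dtype=bool)
            for _, o in corfs.iterrows():
                keep &= ~((mids - half_w <= o["end"]) & (mids + half_w >= o["start"]))
            mids = mids[keep]
        mids = np.unique(mids)
        for m in mids:
            hs_rows.append((cid, int(m)))
    hs = pd.DataFrame(hs_rows, columns=["chrom", "midpoint"])
    hs["width"] = config.hotspot_width

    # Log-normal intrinsic rates, optionally calibrated to a target
    # expected breaks-per-cell at the reference window.
    raw = rng.lognormal(mean=0.0, sigma=config.rate_log_sd, size=len(hs))
    if config.calibrate_breaks is not None:
        target, T = float(config.calibrate_breaks), float(config.calibrate_window_h)

        def excess(c: float) -> float:
            return float(np.sum(4.0 * (1.0 - np.exp(-c * raw * T)))) - target

        c = brentq(excess, 1e-12, 10.0 / (raw.mean() * T))
        rates = c * raw
    else:
        rates = 1e-3 * raw
    hs["rate"] = rates

    # Priming domains: per-chromosome maximal runs of adjacent hotspots.
    dom_rows = []
    dom_index = np.zeros(len(hs), dtype=int)
    offset = 0
    for cid, _, cen in config.chromosomes:
        mask = (hs["chrom"] == cid).to_numpy()
        mids = hs.loc[mask, "midpoint"].to_numpy()
        local = _partition_domains(mids, config.max_domain_span)
        dom_index[mask] = local + offset
        length = int(chroms.set_index("chrom").loc[cid, "length"])
        dmax = max(cen - 1, length - cen)
        for d in range(local.max() + 1 if local.size else 0):
            span = mids[local == d]
            mid = 0.5 * (span[0] + span[-1])
            dist = abs(mid - cen)
            tau = config.tau_cen + config.tau_range * (dist / dmax if dmax > 0 else 0.0)
            dom_rows.append((offset + d, cid, int(span[0]), int(span[-1]),
                             float(tau), float(tau + config.rec114_offset)))
        offset += local.max() + 1 if local.size else 0
    hs["domain"] = dom_index
    hs["id"] = [f"{c}_h{i}" for i, c in enumerate(hs["chrom"])]
    hs = hs[["id", "chrom", "midpoint", "width", "rate", "domain"]]
    domains = pd.DataFrame(
        dom_rows, columns=["domain", "chrom", "start", "end", "tau", "rec114_time"]
    )

    return GenomeLayout(chromosomes=chroms, hotspots=hs, domains=domains,
                        orfs=orfs, rdna=config.rdna, config=config, seed=int(seed))


def layout_from_tables(chromosomes: pd.DataFrame, hotspots: pd.DataFrame,
                       taus: dict[int, float] | None = None,
                       max_domain_span: int = 15000,
                       orfs: pd.DataFrame | None = None,
                       rdna: tuple[str, int, int] | None = None) -> GenomeLayout:
    """Assemble a layout from explicit tables (mainly for tests and fixtures).

    ``hotspots`` needs columns id, chrom, midpoint, width, rate; domains are
    derived by the maximal-run rule and given priming times from ``taus``
    (domain index -> hours, default 0.0).
    """
    chroms = chromosomes.copy()
    for _, r in chroms.iterrows():
        if r["length"] <= 0:
            raise ValueError(f"{r['chrom']}: non-positive chromosome length")
        if not (0 < r["cen"] < r["length"]):
            raise ValueError(f"{r['chrom']}: centromere outside chromosome")
    hs = hotspots.copy().sort_values(["chrom", "midpoint"]).reset_index(drop=True)
    bad = hs.merge(chroms, on="chrom")
    if ((bad["midpoint"] - bad["width"] // 2 < 1)
            | (bad["midpoint"] + bad["width"] // 2 > bad["length"])).any():
        raise ValueError("hotspot positions must lie strictly inside their chromosome")
    dom_index = np.zeros(len(hs), dtype=int)
    offset = 0
    dom_rows = []
    for cid in chroms["chrom"]:
        mask = (hs["chrom"] == cid).to_numpy()
        mids = hs.loc[mask, "midpoint"].to_numpy()
        local = _partition_domains(mids, max_domain_span)
        dom_index[mask] = local + offset
        cen = int(chroms.set_index("chrom").loc[cid, "cen"])
        for d in range(local.max() + 1 if local.size else 0):
            span = mids[local == d]
            tau = (taus or {}).get(offset + d, 0.0)
            dom_rows.append((offset + d, cid, int(span[0]), int(span[-1]),
                             float(tau), float(tau)))
        offset += local.max() + 1 if local.size else 0
    hs["domain"] = dom_index
    domains = pd.DataFrame(
        dom_rows, columns=["domain", "chrom", "start", "end", "tau", "rec114_time"]
    )
    cfg = LayoutConfig(chromosomes=[(r["chrom"], int(r["length"]), int(r["cen"]))
                                    for _, r in chroms.iterrows()],
                       max_domain_span=max_domain_span, rdna=rdna)
    return GenomeLayout(chromosomes=chroms, hotspots=hs, domains=domains,
                        orfs=orfs if orfs is not None else pd.DataFrame(
                            columns=["chrom", "start", "end"]),
                        rdna=rdna, config=cfg, seed=0)
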