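"""Per-cell stochastic simulation of meiotic Spo11-DSB formation.

The model, per cell:

1. The cell draws a prophase-exit time ``T``.  With Ndt80 present, ``T`` is
   truncated-normal on ``[0, t_max]`` with a genotype-dependent mean (Tel1
   loss accelerates exit); without Ndt80 the cell arrests, ``T = t_max``.
2. Each priming domain draws a priming time ``t_d = max(0, tau_d + jitter)``.
   Hotspots in a domain are DSB-competent only during ``[t_d, T)`` -- the
   "primed domain" picture: in a heterogeneous population only the fraction
   of cells with ``t_d < T`` can break the region at all.
3. Four chromatids are simulated independently.  In discrete time steps of
   ``dt`` each uncut, primed hotspot-chromatid fires with probability
   ``w * dt * sigma``, where ``w`` is the hotspot's intrinsic hourly rate
   and ``sigma`` is the Tel1 DSB-interference factor: the product over
   previously committed cuts at midpoint distance ``d`` of
   ``(1 - s * exp(-d / lam))``, floored at zero.  By default suppression
   acts in cis (same chromatid) only; a switch extends it in trans.

The discrete-hazard process is sampled exactly by geometric waiting times
(memoryless between suppression-changing cut events), so runtime scales with
the number of cuts rather than the number of time steps.  Randomness uses
one root seed with per-cell substreams ``SeedSequence([seed, cell_index])``,
so enlarging ``n_cells`` never reshuffles earlier cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .layout import GenomeLayout
from .maps import FullMap

__all__ = [
    "SimParams", "PopulationBreaks", "simulate_population", "primed_fraction",
    "breaks_to_fullmap", "breaks_to_assay", "SingleCutAssay", "DoubleCutAssay",
]


@dataclass
class SimParams:
    """Simulation parameters (one genotype, one run).

    tel1: Tel1 present.  When False, suppression strength ``s`` must be 0.
    ndt80: Ndt80 present.  When False the cell arrests in prophase and the
        DSB-permissive window runs to ``t_max`` in every cell.
    exit_mean / exit_sd: prophase-exit distribution (h), truncated to
        ``[0, t_max]``.  Defaults encode the accelerated exit of tel1-delta
        cells relative to TEL1+ (configurable, not claimed as measured).
    jitter_sd: SD (h) of the per-cell, per-domain priming-time jitter.
    s / lam: Tel1 suppression strength (dimensionless, in [0, 1]) and decay
        length (bp).  Illustrative defaults; the strength and reach of DSB
        interference are not quantitatively known.
    trans_suppression: if True, prior cuts on any chromatid of the cell
        suppress (same chromosome); default cis-only.
    dt: hazard time step (h).  Discretisation bias is O(w*dt).
    beta: uniform background read rate in HpM per bp added to FullMaps.
    library_reads: declared total mapped reads for a background-only map.
    census_times: optional assay timepoints (h); a cut is visible at census
        ``t`` if it happened by ``min(t, T)``.  Default: single census at
        ``t_max``.
    """

    tel1: bool = True
    ndt80: bool = True
    exit_mean: float = 7.0
    exit_sd: float = 0.5
    t_max: float = 10.0
    jitter_sd: float = 0.5
    s: float = 0.8
    lam: float = 10_000.0
    trans_suppression: bool = False
    dt: float = 0.1
    beta: float = 0.0
    library_reads: float = 1_000_000.0
    census_times: list[float] | None = None
    n_cells: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not self.tel1 and self.s != 0.0:
            raise ValueError("tel1 flag off requires suppression strength s = 0")
        if self.s < 0 or self.lam <= 0:
            raise ValueError("suppression parameters must satisfy s >= 0, lam > 0")
        if self.dt <= 0:
            raise ValueError("time step dt must be positive")
        if min(self.exit_mean, self.exit_sd, self.t_max, self.jitter_sd, self.beta) < 0:
            raise ValueError("rates, times and SDs must be non-negative")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")

    def exit_window_label(self) -> float:
        return self.t_max if self.census_times is None else max(self.census_times)


@dataclass
class PopulationBreaks:
    """Realised cuts for a simulated population.

    cuts columns: cell, chromatid (0-3), chrom, hotspot (row index into
    layout.hotspots), position (1-based bp), time (h).  Each hotspot-
    chromatid is cut at most once.
    """

    cuts: pd.DataFrame
    exit_times: np.ndarray          # (n_cells,)
    priming_times: np.ndarray       # (n_cells, n_domains)
    primed_fraction: pd.Series      # realised f_d per domain index
    layout: GenomeLayout
    params: SimParams

    @property
    def n_cells(self) -> int:
        return self.params.n_cells

    @property
    def n_chromatids(self) -> int:
        return 4 * self.params.n_cells


def _truncnorm_ppf(u: float, mu: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0.0:
        return min(max(mu, lo), hi)
    a, b = ndtr((lo - mu) / sd), ndtr((hi - mu) / sd)
    return mu + sd * float(ndtri(a + u * (b - a)))


def _geometric_steps(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    """First-success trial index (>= 1) for per-element probabilities p.

    Elements with p <= 0 never fire (np.inf); p = 1 fires on trial 1.
    """
    u = rng.random(p.shape)
    out = np.full(p.shape, np.inf)
    pos = p > 0
    full = p >= 1.0
    with np.errstate(divide="ignore"):
        out[pos] = np.ceil(np.log1p(-u[pos]) / np.log1p(-np.minimum(p[pos], 1 - 1e-15)))
    out[full] = 1.0
    return out


def simulate_population(layout: GenomeLayout, params: SimParams) -> PopulationBreaks:
    """Simulate ``params.n_cells`` cells under the primed-domain model.

    Exact event-driven sampling of the discrete-time hazard: each
    hotspot-chromatid draws a geometric waiting time at its current hazard
    ``w*dt*sigma``; committed cuts update ``sigma`` for (cis or trans)
    neighbours, whose waiting times are redrawn from the current step --
    valid by memorylessness of the geometric distribution.  Bit-identical
    for a fixed seed and parameter set.
    """
    params.validate()
    hs = layout.hotspots
    w = hs["rate"].to_numpy(float)
    if np.max(w, initial=0.0) * params.dt > 1.0:
        raise ValueError(
            "dt too large: w*dt exceeds 1 for at least one hotspot "
            f"(max w = {w.max():.3g}/h, dt = {params.dt} h)")

    n_hot = len(hs)
    mids = hs["midpoint"].to_numpy(float)
    widths = hs["width"].to_numpy(int)
    dom_of_hot = hs["domain"].to_numpy(int)
    chrom_codes, chrom_names = pd.factorize(hs["chrom"])
    n_dom = len(layout.domains)
    taus = layout.domains.sort_values("domain")["tau"].to_numpy(float)

    dt = params.dt
    p_base = w * dt
    # joint (chromatid, hotspot) arrays, chromatid-major
    j_chromatid = np.repeat(np.arange(4), n_hot)
    j_hot = np.tile(np.arange(n_hot), 4)
    j_p = np.tile(p_base, 4)
    j_chrom = np.tile(chrom_codes, 4)
    j_mid = np.tile(mids, 4)

    exit_times = np.empty(params.n_cells)
    priming = np.empty((params.n_cells, n_dom))
    rec_cell, rec_chromatid, rec_hot, rec_step = [], [], [], []
    rec_pos = []

    for cell in range(params.n_cells):
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, cell]))
        # 1) prophase exit
        if params.ndt80:
            T = _truncnorm_ppf(rng.random(), params.exit_mean, params.exit_sd,
                               0.0, params.t_max)
        else:
            T = params.t_max
        exit_times[cell] = T
        # 2) domain priming
        t_d = np.maximum(0.0, taus + params.jitter_sd * rng.standard_normal(n_dom))
        priming[cell] = t_d
        k1 = int(np.floor(T / dt + 1e-9))
        k0_dom = np.ceil(t_d / dt - 1e-9).astype(int)
        j_k0 = k0_dom[dom_of_hot][j_hot]

        # 3) initial geometric schedules at sigma = 1
        g = _geometric_steps(rng, j_p)
        sched = np.where(np.isfinite(g), j_k0 + g - 1, np.inf)
        sched[j_k0 >= k1] = np.inf

        if params.s == 0.0:
            fired = sched < k1
            idx = np.nonzero(fired)[0]
            order = np.lexsort((j_hot[idx], j_chromatid[idx], sched[idx]))
            idx = idx[order]
            steps = sched[idx].astype(int)
        else:
            cut = np.zeros(4 * n_hot, dtype=bool)
            sigma_tab = np.ones(4 * n_hot)   # accumulated suppression per site
            idx_list: list[int] = []
            step_list: list[int] = []
            while True:
                m = sched.min()
                if m >= k1:
                    break
                # ties within a step commit one at a time in (chromatid,
                # hotspot) order; a committed cut immediately suppresses
                # pending same-step fires (redrawn below), so total
                # suppression fully abolishes coincident cutting
                tied = np.nonzero(sched == m)[0]
                f = tied[np.lexsort((j_hot[tied], j_chromatid[tied]))][0]
                cut[f] = True
                sched[f] = np.inf
                idx_list.append(int(f))
                step_list.append(int(m))
                same_chrom = (j_chrom == j_chrom[f]) & ~cut
                if not params.trans_suppression:
                    same_chrom &= j_chromatid == j_chromatid[f]
                neigh = np.nonzero(same_chrom)[0]
                if neigh.size:
                    factor = 1.0 - params.s * np.exp(
                        -np.abs(j_mid[neigh] - j_mid[f]) / params.lam)
                    sigma_tab[neigh] *= np.maximum(factor, 0.0)
                    p_new = j_p[neigh] * sigma_tab[neigh]
                    # base m-1 keeps a fire at the current step possible
                    # under the updated hazard
                    base = np.maximum(m - 1, j_k0[neigh] - 1)
                    g = _geometric_steps(rng, p_new)
                    new_sched = np.where(np.isfinite(g), base + g, np.inf)
                    new_sched[j_k0[neigh] >= k1] = np.inf
                    sched[neigh] = np.where(new_sched < k1, new_sched, np.inf)
            idx = np.asarray(idx_list, dtype=int)
            steps = np.asarray(step_list, dtype=int)

        # 4) cut positions: midpoint +/- uniform jitter within the hotspot
        if idx.size:
            h = j_hot[idx]
            half = widths[h] // 2
            jit = rng.integers(-half, half + 1)
            pos = mids[h].astype(int) + jit
            rec_cell.append(np.full(idx.size, cell))
            rec_chromatid.append(j_chromatid[idx])
            rec_hot.append(h)
            rec_step.append(steps)
            rec_pos.append(pos)

    if rec_cell:
        cuts = pd.DataFrame({
            "cell": np.concatenate(rec_cell),
            "chromatid": np.concatenate(rec_chromatid),
            "hotspot": np.concatenate(rec_hot),
            "position": np.concatenate(rec_pos),
            "time": (np.concatenate(rec_step) + 1) * dt,
        })
        cuts["chrom"] = chrom_names[chrom_codes[cuts["hotspot"]]]
    else:
        cuts = pd.DataFrame(columns=["cell", "chromatid", "hotspot",
                                     "position", "time", "chrom"])
    cuts = cuts[["cell", "chromatid", "chrom", "hotspot", "position", "time"]]

    f_d = pd.Series(
        (priming < exit_times[:, None]).mean(axis=0),
        index=layout.domains.sort_values("domain")["domain"].to_numpy(),
        name="primed_fraction",
    )
    return PopulationBreaks(cuts=cuts, exit_times=exit_times,
                            priming_times=priming, primed_fraction=f_d,
                            layout=layout, params=params)


def primed_fraction(layout: GenomeLayout, params: SimParams, domain: int) -> float:
    """Closed-form P(t_d < T): the analytic oracle for the realised f_d.

    Uses untruncated normal tails for exit time and jitter, so it is exact
    when the exit distribution mass lies inside [0, t_max] and
    ``tau_d`` is well above 0 relative to the jitter SD; ties (zero-variance
    boundary cases) resolve by the strict inequality, i.e. to 0.0.
    """
    doms = layout.domains.set_index("domain")
    if domain not in doms.index:
        raise KeyError(f"unknown domain {domain!r}")
    tau = float(doms.loc[domain, "tau"])
    if params.ndt80:
        mu_T, sd_T = params.exit_mean, params.exit_sd
    else:
        mu_T, sd_T = params.t_max, 0.0
    spread = float(np.hypot(sd_T, params.jitter_sd))
    if spread == 0.0:
        return 1.0 if tau < mu_T else 0.0
    return float(ndtr((mu_T - tau) / spread))


def breaks_to_fullmap(pop: PopulationBreaks, params: SimParams | None = None,
                      name: str = "sim", seed: int | None = None) -> FullMap:
    """Collapse a population into a CC-seq-style per-base break map.

    Each cut contributes one Watson read at its position and one Crick read
    at position + 1 (the two covalently Spo11-bound ends of the break).
    Uniform background reads are added at ``beta`` HpM per bp: the declared
    library total is solved so the expected background density in HpM units
    equals ``beta``, then background read counts are Poisson.
    """
    params = params or pop.params
    chrom_lengths = pop.layout.chrom_lengths
    L = float(sum(chrom_lengths.values()))
    n_cuts = len(pop.cuts)
    signal_reads = 2.0 * n_cuts

    watson = pop.cuts.groupby(["chrom", "position"]).size()
    crick_pos = pop.cuts.assign(position=pop.cuts["position"] + 1)
    crick = crick_pos.groupby(["chrom", "position"]).size()

    # background-only maps keep a declared library size; an empty map with
    # no background has zero mapped reads
    total = signal_reads if signal_reads > 0 else (
        float(params.library_reads) if params.beta > 0 else 0.0)
    if params.beta > 0:
        bg_frac = params.beta * L / 1e6
        if bg_frac >= 1.0:
            raise ValueError("background rate beta implies >= 100% of the library")
        if signal_reads > 0:
            total = signal_reads / (1.0 - bg_frac)
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed if seed is None else seed, 0xB6]))
        lam_bg = params.beta * (total / 1e6) * L
        n_bg = int(rng.poisson(lam_bg))
        chroms = list(chrom_lengths)
        lens = np.array([chrom_lengths[c] for c in chroms], dtype=float)
        which = rng.choice(len(chroms), size=n_bg, p=lens / lens.sum())
        pos = rng.integers(1, lens[which].astype(int) + 1)
        strand = rng.integers(0, 2, size=n_bg)
        bg = pd.DataFrame({"chrom": np.array(chroms, dtype=object)[which],
                           "position": pos, "strand": strand})
        bgw = bg[bg["strand"] == 0].groupby(["chrom", "position"]).size()
        bgc = bg[bg["strand"] == 1].groupby(["chrom", "position"]).size()
        watson = watson.add(bgw, fill_value=0)
        crick = crick.add(bgc, fill_value=0)
        # the declared library total stays the solved value, under which the
        # expected background density equals beta HpM per bp exactly

    df = pd.DataFrame({"Watson": watson, "Crick": crick}).fillna(0).astype(int)
    if df.empty:
        df = pd.DataFrame({"Chr": pd.Series(dtype=object),
                           "Pos": pd.Series(dtype=np.int64),
                           "Watson": pd.Series(dtype=np.int64),
                           "Crick": pd.Series(dtype=np.int64)})
    else:
        df.index.names = ["Chr", "Pos"]
        df = df.reset_index().sort_values(["Chr", "Pos"]).reset_index(drop=True)
    return FullMap(df=df, total_reads=float(total) if total > 0 else 0.0,
                   name=name, chrom_lengths=dict(chrom_lengths))


@dataclass
class SingleCutAssay:
    """Southern-blot-style single-DSB assay: probe on one side of a hotspot."""
    id: str
    hotspot: str
    side: str = "left"            # probe side: 'left' or 'right'
    window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("probe side must be 'left' or 'right'")


@dataclass
class DoubleCutAssay:
    """Double-cut assay between an ordered pair of hotspots."""
    id: str
    hotspot1: str
    hotspot2: str


def breaks_to_assay(pop: PopulationBreaks,
                    assays: list[SingleCutAssay | DoubleCutAssay],
                    mode: str = "ideal",
                    repeat: str = "r1") -> pd.DataFrame:
    """Quantify a simulated population the way a blot lane would.

    Frequencies are fractions of chromatids (the fraction-of-lane-signal
    analogue).  ``ideal`` mode counts every cut; ``blot`` mode reproduces
    the technique's occlusion: a single-DSB probe only sees the *nearest*
    cut on its side, and a double-cut band requires no intervening cut.
    Returns a tidy CutFrequencyTable frame (one row per assay x census
    timepoint).
    """
    if mode not in ("ideal", "blot"):
        raise ValueError("mode must be 'ideal' or 'blot'")
    hs = pop.layout.hotspots.reset_index(drop=True)
    id_to_idx = {hid: i for i, hid in enumerate(hs["id"])}
    for a in assays:
        wanted = [a.hotspot] if isinstance(a, SingleCutAssay) else [a.hotspot1, a.hotspot2]
        for hid in wanted:
            if hid not in id_to_idx:
                raise KeyError(f"assay {a.id!r} references unknown hotspot {hid!r}")

    census = pop.params.census_times or [pop.params.t_max]
    n_molecules = 4 * pop.n_cells
    cuts = pop.cuts
    rows = []
    for t in census:
        vis = cuts[cuts["time"] <= t + 1e-12]
        for a in assays:
            if isinstance(a, SingleCutAssay):
                h = id_to_idx[a.hotspot]
                target_chrom = hs.loc[h, "chrom"]
                on_chrom = vis[vis["chrom"] == target_chrom]
                if a.window is not None:
                    lo, hi = a.window
                    on_chrom = on_chrom[(on_chrom["position"] >= lo)
                                        & (on_chrom["position"] <= hi)]
                if mode == "ideal":
                    n = int((on_chrom["hotspot"] == h).sum())
                else:
                    if len(on_chrom):
                        grp = on_chrom.sort_values("position").groupby(
                            ["cell", "chromatid"], sort=False)
                        nearest = grp.first() if a.side == "left" else grp.last()
                        n = int((nearest["hotspot"] == h).sum())
                    else:
                        n = 0
                rows.append((repeat, t, a.id, "single", n / n_molecules,
                             a.hotspot, a.side, "", ""))
            else:
                h1, h2 = id_to_idx[a.hotspot1], id_to_idx[a.hotspot2]
                c1 = vis[vis["hotspot"] == h1][["cell", "chromatid", "position"]]
                c2 = vis[vis["hotspot"] == h2][["cell", "chromatid", "position"]]
                both = c1.merge(c2, on=["cell", "chromatid"],
                                suffixes=("_1", "_2"))
                if mode == "ideal" or both.empty:
                    n = len(both)
                else:
                    chrom = hs.loc[h1, "chrom"]
                    mid = vis[(vis["chrom"] == chrom)
                              & (vis["hotspot"] != h1) & (vis["hotspot"] != h2)]
                    m = both.merge(mid[["cell", "chromatid", "position"]],
                                   on=["cell", "chromatid"], how="left")
                    lo = np.minimum(m["position_1"], m["position_2"])
                    hi = np.maximum(m["position_1"], m["position_2"])
                    blocked = (m["position"] > lo) & (m["position"] < hi)
                    bad = m.loc[blocked.fillna(False), ["cell", "chromatid"]]
                    n = len(both) - both.merge(
                        bad.drop_duplicates(), on=["cell", "chromatid"]).shape[0]
                rows.append((repeat, t, a.id, "dc", n / n_molecules,
                             "", "", a.hotspot1, a.hotspot2))
    return pd.DataFrame(rows, columns=[
        "repeat", "timepoint_h", "assay", "kind", "frequency",
        "hotspot", "side", "hotspot1", "hotspot2"])
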