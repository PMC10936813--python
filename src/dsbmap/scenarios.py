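"""Canonical simulation scenarios for the primed-domain model.

These encode the study conditions the analyses are run under:

* a two-hotspot domain for the coincidence-law and genotype-contrast
  analyses (all-or-none priming realises an exact primed fraction f);
* the four-genotype contrast (Tel1 +/-, prophase arrest +/-) whose
  interference signs mirror the short-range blot comparisons;
* a genome-scale centromere-early priming gradient contrasting a short
  prophase against ndt80-arrest, for the map-ratio / association-time
  analyses;
* background-only and background-plus-hotspot maps for calibration of the
  hotspot caller and the ORF background estimator.

Priming note: with ``tau_d = mean exit time`` and a priming-jitter SD much
larger than the prophase window, priming is effectively all-or-none --
exactly half the cells prime (at time ~0, enjoying the full window) and
half never do.  This makes the primed fraction f = 0.5 exact and the
per-chromatid cut probability essentially constant among primed cells,
the regime in which population frequencies factorise as f*p.
"""

from __future__ import annotations

import pandas as pd

from .interference import expected_dc, interference
from .layout import GenomeLayout, LayoutConfig, build_layout, layout_from_tables
from .maps import FullMap
from .simulate import (DoubleCutAssay, PopulationBreaks, SimParams,
                       SingleCutAssay, breaks_to_assay, breaks_to_fullmap,
                       simulate_population)

__all__ = [
    "two_hotspot_layout", "coc_law_params", "run_coc_law",
    "four_genotype_params", "run_four_genotypes",
    "gradient_layout", "gradient_params", "background_only_map",
]

T_MAX = 8.0
RATE = 0.25          # per-chromatid hourly firing rate; w*T_max = 2
ALL_OR_NONE_JITTER = 200.0


def two_hotspot_layout(spacing: int = 5000, rate: float = RATE,
                       tau: float = 0.0) -> GenomeLayout:
    """One 100 kb chromosome with two hotspots in a single priming domain."""
    chroms = pd.DataFrame({"chrom": ["chrI"], "length": [100_000],
                           "cen": [20_000]})
    hs = pd.DataFrame({
        "id": ["H1", "H2"],
        "chrom": ["chrI", "chrI"],
        "midpoint": [60_000, 60_000 + spacing],
        "width": [200, 200],
        "rate": [rate, rate],
    })
    return layout_from_tables(chroms, hs, taus={0: tau})


def coc_law_params(primed: float, n_cells: int, seed: int) -> tuple[GenomeLayout, SimParams]:
    """Layout + parameters realising an exact primed fraction under arrest.

    primed = 1.0: tau = 0, no jitter -- every cell primes for the whole
    window.  primed = 0.5: tau = t_max with a huge jitter SD -- all-or-none
    priming, P(primed) = P(jitter < 0) = 1/2 exactly.  No Tel1 suppression.
    """
    if primed not in (0.5, 1.0):
        raise ValueError("supported primed fractions: 0.5, 1.0")
    tau = T_MAX if primed == 0.5 else 0.0
    jitter = ALL_OR_NONE_JITTER if primed == 0.5 else 0.0
    layout = two_hotspot_layout(tau=tau)
    params = SimParams(tel1=False, s=0.0, ndt80=False, t_max=T_MAX,
                       jitter_sd=jitter, dt=0.1, n_cells=n_cells, seed=seed)
    return layout, params


def _assay_interference(pop: PopulationBreaks, mode: str = "ideal"
                        ) -> dict[str, float]:
    """Run the single/DC assays and the CoC pipeline on one population."""
    assays = [SingleCutAssay("s1", "H1", side="left"),
              SingleCutAssay("s2", "H2", side="left"),
              DoubleCutAssay("dc", "H1", "H2")]
    table = breaks_to_assay(pop, assays, mode=mode)
    f = table.set_index("assay")["frequency"]
    exp = expected_dc(float(f["s1"]), float(f["s2"]))
    val = interference(float(f["dc"]), exp)
    return {"single1": float(f["s1"]), "single2": float(f["s2"]),
            "observed_dc": float(f["dc"]), "expected_dc": exp,
            "interference": float("nan") if val is None else val}


def run_coc_law(primed: float, n_cells: int = 20_000, seed: int = 1) -> dict:
    """Simulate the coincidence-law scenario and return the statistics.

    With no suppression the coefficient of coincidence converges to 1/f,
    so interference converges to log2(f): -1 at f = 0.5, 0 at f = 1.
    """
    layout, params = coc_law_params(primed, n_cells, seed)
    pop = simulate_population(layout, params)
    out = _assay_interference(pop)
    out["primed_fraction_realised"] = float(pop.primed_fraction.iloc[0])
    out["primed_fraction_requested"] = primed
    return out


def four_genotype_params(n_cells: int, seed: int) -> dict[str, tuple[GenomeLayout, SimParams]]:
    """The four-genotype contrast at a two-hotspot domain.

    TEL1+ scenarios use suppression s = 0.9 with a 20 kb decay; tel1-delta
    sets s = 0 and an accelerated mean prophase exit.  Arrest scenarios fix
    the window at t_max with every cell primed; NDT80+ scenarios draw a
    finite exit and prime all-or-none (f ~ 0.5).  The firing rate keeps the
    per-chromatid cut probability near 0.5 (a strong natural hotspot) so
    suppression is not masked by hazard saturation.
    """
    base = dict(t_max=T_MAX, dt=0.1, n_cells=n_cells, lam=20_000.0)
    mk = lambda tau: two_hotspot_layout(rate=0.1, tau=tau)
    out = {}
    out["tel1_arrest"] = (mk(0.0), SimParams(
        tel1=True, s=0.9, ndt80=False, jitter_sd=0.0, seed=seed, **base))
    out["tel1_short"] = (mk(7.0), SimParams(
        tel1=True, s=0.9, ndt80=True, exit_mean=7.0, exit_sd=0.5,
        jitter_sd=ALL_OR_NONE_JITTER, seed=seed + 1, **base))
    out["tel1d_arrest"] = (mk(0.0), SimParams(
        tel1=False, s=0.0, ndt80=False, jitter_sd=0.0, seed=seed + 2, **base))
    out["tel1d_short"] = (mk(5.5), SimParams(
        tel1=False, s=0.0, ndt80=True, exit_mean=5.5, exit_sd=0.5,
        jitter_sd=ALL_OR_NONE_JITTER, seed=seed + 3, **base))
    return out


def run_four_genotypes(n_cells: int = 5000, seed: int = 1) -> pd.DataFrame:
    """Interference for the four genotype scenarios (one row each)."""
    rows = []
    for label, (layout, params) in four_genotype_params(n_cells, seed).items():
        pop = simulate_population(layout, params)
        stats = _assay_interference(pop)
        stats["scenario"] = label
        stats["primed_fraction_realised"] = float(pop.primed_fraction.iloc[0])
        rows.append(stats)
    return pd.DataFrame(rows).set_index("scenario")


def gradient_layout(seed: int = 0, n_chromosomes: int = 4,
                    chrom_length: int = 600_000, cen: int = 150_000,
                    spacing: int = 3000) -> GenomeLayout:
    """Genome-scale layout with a centromere-early priming gradient.

    Priming time runs from 2 h at the centromere to 8 h at the most distal
    point of each chromosome; rates are calibrated to ~150 expected breaks
    per cell at a 7 h window.
    """
    config = LayoutConfig(
        chromosomes=[(f"chr{i + 1}", chrom_length, cen)
                     for i in range(n_chromosomes)],
        hotspot_spacing=spacing, hotspot_width=200, rate_log_sd=0.5,
        calibrate_breaks=150.0, calibrate_window_h=7.0,
        max_domain_span=15_000, tau_cen=2.0, tau_range=6.0,
        n_cold_orfs=2, cold_orf_len=7000, rdna=None)
    return build_layout(config, seed=seed)


def gradient_params(genotype: str, n_cells: int, seed: int,
                    beta: float = 0.01) -> SimParams:
    """Tel1-free populations contrasting a short prophase with arrest.

    ``short``: Ndt80 present, mean exit 5 h (SD 0.5) -- only early-priming
    (pericentromeric) domains are primed in most cells.  ``arrest``:
    ndt80-delta, window to t_max = 10 h -- essentially every domain primes.
    """
    if genotype == "short":
        return SimParams(tel1=False, s=0.0, ndt80=True, exit_mean=5.0,
                         exit_sd=0.5, t_max=10.0, jitter_sd=1.0, dt=0.1,
                         beta=beta, n_cells=n_cells, seed=seed)
    if genotype == "arrest":
        return SimParams(tel1=False, s=0.0, ndt80=False, t_max=10.0,
                         jitter_sd=1.0, dt=0.1, beta=beta,
                         n_cells=n_cells, seed=seed)
    raise ValueError("genotype must be 'short' or 'arrest'")


def background_only_map(beta: float, chrom_length: int = 500_000,
                        library_reads: float = 3e7, seed: int = 0,
                        name: str = "null") -> FullMap:
    """Pure-background FullMap (no hotspots): the catalytic-dead analogue."""
    chroms = pd.DataFrame({"chrom": ["chrI"], "length": [chrom_length],
                           "cen": [chrom_length // 2]})
    hs = pd.DataFrame(columns=["id", "chrom", "midpoint", "width", "rate"])
    layout = layout_from_tables(chroms, hs)
    params = SimParams(tel1=False, s=0.0, ndt80=False, beta=beta,
                       library_reads=library_reads, n_cells=1, seed=seed)
    pop = simulate_population(layout, params)
    return breaks_to_fullmap(pop, params, name=name, seed=seed)
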