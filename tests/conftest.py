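"""Shared fixtures: small layouts, populations and maps built in-process."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dsbmap.maps import FullMap
from dsbmap.simulate import PopulationBreaks, SimParams, simulate_population

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_fullmap(records, total_reads, name="test", chrom_lengths=None):
    """records: iterable of (chrom, pos, watson, crick)."""
    df = pd.DataFrame(records, columns=["Chr", "Pos", "Watson", "Crick"])
    return FullMap(df=df, total_reads=float(total_reads), name=name,
                   chrom_lengths=chrom_lengths or {})


def uniform_fullmap(chrom="chrI", length=50_000, count_per_bp=2,
                    total_reads=1_000_000):
    """Every position carries the same count: HpM density is flat."""
    pos = np.arange(1, length + 1)
    df = pd.DataFrame({"Chr": chrom, "Pos": pos,
                       "Watson": count_per_bp, "Crick": 0})
    return FullMap(df=df, total_reads=float(total_reads), name="uniform",
                   chrom_lengths={chrom: length})


@pytest.fixture(scope="session")
def two_hotspot_pop():
    """20k-cell population on a two-hotspot domain, fully primed, no Tel1."""
    from dsbmap.scenarios import two_hotspot_layout
    layout = two_hotspot_layout(rate=0.15, tau=0.0)
    params = SimParams(tel1=False, s=0.0, ndt80=False, t_max=8.0,
                       jitter_sd=0.0, dt=0.1, n_cells=4000, seed=42)
    return simulate_population(layout, params)


def manual_population(cut_rows, n_cells=1, layout=None, params=None):
    """Hand-built PopulationBreaks for bookkeeping tests.

    cut_rows: iterable of (cell, chromatid, chrom, hotspot_index, position,
    time).
    """
    from dsbmap.scenarios import two_hotspot_layout
    layout = layout or two_hotspot_layout()
    params = params or SimParams(tel1=False, s=0.0, n_cells=n_cells,
                                 t_max=8.0)
    params = params if params.n_cells == n_cells else SimParams(
        **{**params.__dict__, "n_cells": n_cells})
    cuts = pd.DataFrame(cut_rows, columns=["cell", "chromatid", "chrom",
                                           "hotspot", "position", "time"])
    n_dom = len(layout.domains)
    return PopulationBreaks(
        cuts=cuts, exit_times=np.full(n_cells, params.t_max),
        priming_times=np.zeros((n_cells, n_dom)),
        primed_fraction=pd.Series(np.ones(n_dom),
                                  index=layout.domains["domain"]),
        layout=layout, params=params)
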