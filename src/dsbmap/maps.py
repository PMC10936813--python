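"""FullMap: per-base, strand-resolved break-count maps.

A FullMap is the CC-seq processing surface: sparse records of
(chromosome, 1-based position, Watson count, Crick count) plus the
library's total mapped reads.  HpM (hits per million mapped reads) at a
position is ``(Watson + Crick) * 1e6 / total_reads`` and is recomputable
from the stored fields at any time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FullMap", "pool_fullmaps"]

FULLMAP_COLUMNS = ["Chr", "Pos", "Watson", "Crick"]


@dataclass
class FullMap:
    """Sparse per-base break-count map for one library (or a pooled one)."""

    df: pd.DataFrame
    total_reads: float
    name: str = "library"
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.df.columns) != FULLMAP_COLUMNS:
            self.df = self.df[FULLMAP_COLUMNS]
        if len(self.df):
            if (self.df[["Watson", "Crick"]].to_numpy() < 0).any():
                raise ValueError("negative counts in FullMap")
            if self.df.duplicated(["Chr", "Pos"]).any():
                raise ValueError("duplicate (Chr, Pos) rows in FullMap")
        if self.total_reads < 0:
            raise ValueError("total mapped reads must be non-negative")

    @property
    def chromosomes(self) -> list[str]:
        seen = dict.fromkeys(self.df["Chr"])
        for c in self.chrom_lengths:
            seen.setdefault(c)
        return list(seen)

    def total_counts(self) -> float:
        return float(self.df[["Watson", "Crick"]].to_numpy().sum())

    def hpm(self) -> pd.DataFrame:
        """Per-position HpM (Watson + Crick combined)."""
        if self.total_reads <= 0:
            raise ValueError("total mapped reads is zero; HpM undefined")
        out = self.df[["Chr", "Pos"]].copy()
        out["HpM"] = ((self.df["Watson"] + self.df["Crick"])
                      * 1e6 / self.total_reads)
        return out

    def length_of(self, chrom: str) -> int:
        if chrom in self.chrom_lengths:
            return int(self.chrom_lengths[chrom])
        sub = self.df[self.df["Chr"] == chrom]
        return int(sub["Pos"].max()) if len(sub) else 0

    def dense_hpm(self, chrom: str) -> np.ndarray:
        """Dense strand-combined HpM for one chromosome, index 0 = bp 1."""
        length = self.length_of(chrom)
        arr = np.zeros(length)
        sub = self.df[self.df["Chr"] == chrom]
        if len(sub) and self.total_reads > 0:
            pos = sub["Pos"].to_numpy(int)
            keep = (pos >= 1) & (pos <= length)
            np.add.at(arr, pos[keep] - 1,
                      (sub["Watson"] + sub["Crick"]).to_numpy(float)[keep]
                      * 1e6 / self.total_reads)
        return arr

    def dense_counts(self, chrom: str) -> np.ndarray:
        """Dense strand-combined raw counts for one chromosome."""
        length = self.length_of(chrom)
        arr = np.zeros(length)
        sub = self.df[self.df["Chr"] == chrom]
        if len(sub):
            pos = sub["Pos"].to_numpy(int)
            keep = (pos >= 1) & (pos <= length)
            np.add.at(arr, pos[keep] - 1,
                      (sub["Watson"] + sub["Crick"]).to_numpy(float)[keep])
        return arr

    def as_hpm_map(self, name: str | None = None) -> "FullMap":
        """Rescale counts to HpM with a declared total of 1e6.

        After rescaling, stored 'counts' equal HpM values directly.
        """
        if self.total_reads <= 0:
            raise ValueError("total mapped reads is zero; HpM undefined")
        scale = 1e6 / self.total_reads
        df = self.df.copy()
        df["Watson"] = df["Watson"] * scale
        df["Crick"] = df["Crick"] * scale
        return FullMap(df=df, total_reads=1e6,
                       name=name or self.name,
                       chrom_lengths=dict(self.chrom_lengths))


def pool_fullmaps(maps: list[FullMap], name: str = "pooled") -> FullMap:
    """Equal-weight pooling of libraries.

    Each library is first normalised to HpM, then the per-position
    unweighted mean across libraries is taken; the pooled total is set to
    1e6 so stored counts equal HpM.  Pooling a single map returns its own
    HpM profile; pooling is idempotent.
    """
    if not maps:
        raise ValueError("need at least one FullMap to pool")
    declared = [set(m.chrom_lengths) for m in maps if m.chrom_lengths]
    if declared and any(d != declared[0] for d in declared[1:]):
        raise ValueError("chromosome name mismatch between libraries")
    if declared:
        stray = set().union(*(set(m.df["Chr"].unique()) for m in maps)) - declared[0]
        if stray:
            raise ValueError(f"chromosome name mismatch: unknown {sorted(stray)}")
    frames = []
    for m in maps:
        h = m.as_hpm_map().df
        frames.append(h.set_index(["Chr", "Pos"]))
    summed = frames[0]
    for f in frames[1:]:
        summed = summed.add(f, fill_value=0.0)
    mean = (summed / len(maps)).reset_index().sort_values(["Chr", "Pos"])
    lengths: dict[str, int] = {}
    for m in maps:
        for c, L in m.chrom_lengths.items():
            lengths[c] = max(L, lengths.get(c, 0))
    return FullMap(df=mean.reset_index(drop=True), total_reads=1e6,
                   name=name, chrom_lengths=lengths)
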