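"""Readers and writers for the pipeline's plain-text formats.

Formats (all TSV with explicit headers, 1-based coordinates internally):

* FullMap: ``Chr  Pos  Watson  Crick``; library name and total mapped
  reads live in a JSON sidecar manifest ``<path>.manifest.json``.
* Hotspot tables / templates: one row per hotspot with interval and any
  strength columns.
* Cut-frequency tables: tidy repeat x timepoint x assay records.
* BED6 export converts 1-based inclusive [s, e] to 0-based half-open
  [s-1, e); bedGraph likewise for per-bp profiles.
* Run configuration: flat YAML with nested sections, round-trippable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .maps import FULLMAP_COLUMNS, FullMap

__all__ = [
    "read_fullmap", "write_fullmap", "read_hotspot_table",
    "write_hotspot_table", "export_bed", "read_bed", "write_bedgraph",
    "read_cut_frequency_table", "write_cut_frequency_table",
    "read_config", "write_config",
]


class FullMapFormatError(ValueError):
    """Malformed FullMap input; message carries the offending line number."""


def write_fullmap(fullmap: FullMap, path: str | Path) -> None:
    path = Path(path)
    df = fullmap.df.copy()
    counts = df[["Watson", "Crick"]].to_numpy()
    if np.allclose(counts, np.round(counts)):
        df["Watson"] = df["Watson"].round().astype(np.int64)
        df["Crick"] = df["Crick"].round().astype(np.int64)
    df.to_csv(path, sep="\t", index=False)
    manifest = {
        "name": fullmap.name,
        "total_reads": fullmap.total_reads,
        "chrom_lengths": {k: int(v) for k, v in fullmap.chrom_lengths.items()},
    }
    Path(str(path) + ".manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def read_fullmap(path: str | Path,
                 known_chromosomes: list[str] | None = None) -> FullMap:
    """Read a FullMap TSV (+ sidecar manifest when present).

    Rejects malformed rows and duplicate (Chr, Pos) records with the line
    number; unknown chromosomes relative to ``known_chromosomes`` raise a
    warning, not an error.  Without a manifest the total is the sum of
    counts.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != FULLMAP_COLUMNS:
            raise FullMapFormatError(
                f"{path}:1: expected header {FULLMAP_COLUMNS}, got {header}")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FullMapFormatError(f"{path}:{lineno}: expected 4 fields")
            try:
                rows.append((parts[0], int(parts[1]),
                             float(parts[2]), float(parts[3])))
            except ValueError as err:
                raise FullMapFormatError(f"{path}:{lineno}: {err}") from None
    df = pd.DataFrame(rows, columns=FULLMAP_COLUMNS)
    if len(df):
        dup = df.duplicated(["Chr", "Pos"])
        if dup.any():
            first = int(np.nonzero(dup.to_numpy())[0][0]) + 2
            raise FullMapFormatError(f"{path}:{first}: duplicate (Chr, Pos) row")
        if (df["Pos"] < 1).any():
            bad = int(np.nonzero((df["Pos"] < 1).to_numpy())[0][0]) + 2
            raise FullMapFormatError(f"{path}:{bad}: positions are 1-based")
    counts = df[["Watson", "Crick"]].to_numpy(float)
    if counts.size == 0 or np.allclose(counts, np.round(counts)):
        df["Watson"] = df["Watson"].astype(float).round().astype(np.int64)
        df["Crick"] = df["Crick"].astype(float).round().astype(np.int64)
    name, total, lengths = path.stem, None, {}
    man_path = Path(str(path) + ".manifest.json")
    if man_path.exists():
        man = json.loads(man_path.read_text())
        name = man.get("name", name)
        total = man.get("total_reads")
        lengths = {k: int(v) for k, v in man.get("chrom_lengths", {}).items()}
    if total is None:
        total = float(df[["Watson", "Crick"]].to_numpy().sum())
    if known_chromosomes is not None:
        unknown = set(df["Chr"].unique()) - set(known_chromosomes)
        if unknown:
            import warnings
            warnings.warn(f"{path}: unknown chromosomes {sorted(unknown)}")
    return FullMap(df=df, total_reads=float(total), name=name,
                   chrom_lengths=lengths)


def write_hotspot_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_hotspot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


def export_bed(template: pd.DataFrame, path: str | Path,
               score_col: str | None = None) -> None:
    """Write a template/table as BED6 (0-based half-open).

    A 1-based inclusive interval [s, e] becomes the BED line ``s-1  e``.
    The score column (default NormHpM when present) is scaled into the
    conventional 0-1000 range.
    """
    t = template.reset_index(drop=True)
    for chrom, sub in t.groupby("chrom", sort=False):
        if not sub["start"].is_monotonic_increasing:
            raise ValueError("template must be sorted within chromosomes")
    if score_col is None and "NormHpM" in t.columns:
        score_col = "NormHpM"
    if score_col is not None and len(t):
        vals = t[score_col].to_numpy(float)
        top = vals.max() if vals.max() > 0 else 1.0
        scores = np.round(vals / top * 1000).astype(int)
    else:
        scores = np.zeros(len(t), dtype=int)
    names = (t["id"] if "id" in t.columns
             else pd.Series([f"hs{i}" for i in range(len(t))]))
    with open(path, "w") as fh:
        fh.write('track name="hotspots"\n')
        for i, r in t.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}"
                     f"\t{names.iloc[i]}\t{scores[i]}\t.\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED back into the internal 1-based inclusive convention."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            rec = {"chrom": parts[0], "start": int(parts[1]) + 1,
                   "end": int(parts[2])}
            if len(parts) > 3:
                rec["id"] = parts[3]
            rows.append(rec)
    return pd.DataFrame(rows)


def write_bedgraph(profiles: dict[str, np.ndarray], path: str | Path,
                   min_value: float = 0.0) -> None:
    """Write dense per-bp profiles as bedGraph, run-length compressed.

    Values <= ``min_value`` are omitted (sparse output).
    """
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="profile"\n')
        for chrom in sorted(profiles):
            vals = np.asarray(profiles[chrom], float)
            if not len(vals):
                continue
            change = np.r_[True, np.diff(vals) != 0]
            starts = np.nonzero(change)[0]
            ends = np.r_[starts[1:], len(vals)]
            for s, e in zip(starts, ends):
                if vals[s] > min_value:
                    fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]:.6g}\n")


FREQ_COLUMNS = ["repeat", "timepoint_h", "assay", "kind", "frequency",
                "hotspot", "side", "hotspot1", "hotspot2"]


def write_cut_frequency_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    for col in FREQ_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out[FREQ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cut_frequency_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"repeat": str, "assay": str, "kind": str})
    df["timepoint_h"] = df["timepoint_h"].astype(float)
    df["frequency"] = df["frequency"].astype(float)
    return df


def write_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
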