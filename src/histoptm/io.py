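"""Readers and writers for the interchange formats.

One TSV dialect everywhere: tab-separated, UTF-8, ``#`` comment lines.
Tables (areas, ratios, profiles, results) are plain TSV with the row key in
the first column.  Genomic intervals use 3-6 column BED (0-based half-open);
coverage uses bedGraph over fixed-size bins.  Centroid spectra are TSV
triplets (rt, mz, intensity).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chipseq import CoverageTrack, GenomicInterval

__all__ = [
    "read_table",
    "write_table",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "read_spectra",
    "write_spectra",
    "read_config",
]


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a keyed TSV table (first column = row key, '#' comments)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_table(df: pd.DataFrame, path: str | Path, key_name: str = "key") -> None:
    df = df.copy()
    df.index.name = key_name
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>size`` file."""
    sizes: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, size = line.split("\t")[:2]
        sizes[chrom] = int(size)
    return sizes


def read_bed(
    path: str | Path, chrom_sizes: dict[str, int] | None = None
) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into validated intervals.

    Rows failing validation (start >= end, unknown chromosome, out of
    bounds) raise ValueError naming the 1-based line number.
    """
    intervals: list[GenomicInterval] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else "."
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
        if start >= end:
            raise ValueError(f"{path}: line {lineno}: start {start} >= end {end}")
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}: line {lineno}: unknown chromosome {chrom}")
            if end > chrom_sizes[chrom]:
                raise ValueError(f"{path}: line {lineno}: interval beyond chromosome end")
        intervals.append(GenomicInterval(chrom, start, end, name, score))
    return intervals


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED; name/score columns only when informative."""
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name != "." or iv.score is not None:
                fields.append(iv.name)
            if iv.score is not None:
                s = iv.score
                fields.append(f"{s:.6g}" if not math.isnan(s) else ".")
            fh.write("\t".join(fields) + "\n")


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a binned coverage track as bedGraph (one line per bin)."""
    with open(path, "w") as fh:
        fh.write(f"# bin_size={track.bin_size}\ttotal_mapped_reads={track.total_mapped_reads:.10g}\n")
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            for i, v in enumerate(arr):
                fh.write(
                    f"{chrom}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{v:.10g}\n"
                )


def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a bedGraph written by :func:`write_bedgraph` (fixed-size bins)."""
    bin_size = None
    total = None
    data: dict[str, list[float]] = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            for tok in line[1:].split("\t"):
                k, _, v = tok.strip().partition("=")
                if k == "bin_size":
                    bin_size = int(v)
                elif k == "total_mapped_reads":
                    total = float(v)
            continue
        if not line.strip() or line.startswith(("track", "browser")):
            continue
        chrom, start, end, value = line.split("\t")
        start, end = int(start), int(end)
        if bin_size is None:
            bin_size = end - start
        idx = start // bin_size
        arr = data.setdefault(chrom, [])
        while len(arr) <= idx:
            arr.append(0.0)
        arr[idx] = float(value)
    if bin_size is None:
        raise ValueError(f"{path}: empty bedGraph")
    arrays = {c: np.asarray(a, dtype=float) for c, a in data.items()}
    if total is None:
        total = float(sum(a.sum() for a in arrays.values()))
    return CoverageTrack(arrays, bin_size, total)


def read_spectra(path: str | Path) -> pd.DataFrame:
    """Read centroid spectra TSV (columns rt, mz, intensity)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"rt", "mz", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing spectra columns {sorted(missing)}")
    return df.sort_values(["rt", "mz"], kind="stable").reset_index(drop=True)


def write_spectra(spectra: pd.DataFrame, path: str | Path) -> None:
    spectra.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_config(path: str | Path, known_keys: set[str] | None = None) -> dict:
    """Read a flat key-value (YAML) run configuration.

    With ``known_keys`` given, unknown keys are rejected.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if known_keys is not None:
        unknown = set(cfg) - known_keys
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg
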