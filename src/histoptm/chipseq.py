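"""Differential ChIP-seq peak classification between two cell populations.

Downstream of peak calling: coverage tracks are normalized to reads per
million mapped reads (RPM, times a configurable global scale), each called
peak is scanned with a 200 bp sliding window, and a peak is *specific* to a
population if any window shows more than a 4-fold enrichment of one
population over the other; peaks without such a window are *constitutive*.
Also provides replicate peak merging (coalesced interval union) and
TF-binding-site overlap fractions within a maximum edge-to-edge distance.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "PeakClassification",
    "rpm_normalize",
    "classify_peaks",
    "merge_replicate_peaks",
    "overlap_fraction",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, with an optional score."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Binned read coverage per chromosome.

    ``data`` maps chromosome name to an array of per-bin values (raw counts
    or normalized density); bin i covers [i*bin_size, (i+1)*bin_size).
    """

    data: dict[str, np.ndarray]
    bin_size: int
    total_mapped_reads: float

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, arr in self.data.items():
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"negative coverage on {chrom}")

    def chrom_sizes(self) -> dict[str, int]:
        """Upper bound on chromosome sizes implied by the binned arrays."""
        return {c: len(a) * self.bin_size for c, a in self.data.items()}


@dataclass(frozen=True)
class PeakClassification:
    """Label for one peak: specific_A, specific_B, or constitutive."""

    interval: GenomicInterval
    label: str
    max_window_fold: float
    window: GenomicInterval


def rpm_normalize(t: CoverageTrack, scale: float = 10.0) -> CoverageTrack:
    """Normalize a count track to reads per million mapped reads.

    Each bin becomes ``count * scale * 1e6 / total_mapped_reads``.  The
    global ``scale`` (default 10) reproduces the convention of normalizing
    to 10 reads per million; set scale=1 for plain RPM.
    """
    if t.total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    factor = scale * 1e6 / t.total_mapped_reads
    return CoverageTrack(
        data={c: np.asarray(a, dtype=float) * factor for c, a in t.data.items()},
        bin_size=t.bin_size,
        total_mapped_reads=t.total_mapped_reads,
    )


def _peak_bins(peak: GenomicInterval, bin_size: int) -> tuple[int, int]:
    """Bin index range [first, last) covering the peak."""
    return peak.start // bin_size, math.ceil(peak.end / bin_size)


def classify_peaks(
    peaks: list[GenomicInterval],
    a: CoverageTrack,
    b: CoverageTrack,
    window: int = 200,
    fold: float = 4.0,
    pseudocount: float = 0.1,
) -> list[PeakClassification]:
    """Classify peaks as population-specific or constitutive.

    A ``window`` bp window slides across each peak in steps of one bin; per
    window, fold = (mean_a + pseudocount) / (mean_b + pseudocount) on the
    normalized tracks.  A peak is ``specific_A`` if any window fold exceeds
    ``fold``, ``specific_B`` if any inverse fold does, else ``constitutive``.
    If both directions exceed the threshold in different windows the larger
    maximum wins.  Peaks shorter than one window (or one bin) are evaluated
    as a single window over the peak itself.
    """
    if a.bin_size != b.bin_size:
        raise ValueError("tracks must share bin size")
    bin_size = a.bin_size
    out: list[PeakClassification] = []
    win_bins = max(1, window // bin_size)
    for peak in peaks:
        if peak.chrom not in a.data or peak.chrom in a.data and peak.chrom not in b.data:
            raise ValueError(f"chromosome {peak.chrom} missing from track")
        arr_a, arr_b = a.data[peak.chrom], b.data[peak.chrom]
        lo, hi = _peak_bins(peak, bin_size)
        hi = min(hi, len(arr_a))
        n_bins = hi - lo
        w = min(win_bins, n_bins)
        best_fold = 1.0
        best_dir = 0  # +1 A over B, -1 B over A
        best_win = (lo, lo + w)
        for i in range(lo, hi - w + 1):
            ma = float(arr_a[i : i + w].mean())
            mb = float(arr_b[i : i + w].mean())
            f_ab = (ma + pseudocount) / (mb + pseudocount)
            f_ba = 1.0 / f_ab
            if f_ab > best_fold:
                best_fold, best_dir, best_win = f_ab, 1, (i, i + w)
            if f_ba > best_fold:
                best_fold, best_dir, best_win = f_ba, -1, (i, i + w)
        if best_fold > fold:
            label = "specific_A" if best_dir > 0 else "specific_B"
        else:
            label = "constitutive"
        win_iv = GenomicInterval(
            peak.chrom, best_win[0] * bin_size, best_win[1] * bin_size
        )
        out.append(PeakClassification(peak, label, best_fold, win_iv))
    return out


def merge_replicate_peaks(
    rep1: list[GenomicInterval],
    rep2: list[GenomicInterval],
    mode: str = "union",
) -> list[GenomicInterval]:
    """Combine two replicate peak sets into a single peak set.

    ``union`` (default) coalesces overlapping or book-ended intervals from
    both replicates; ``intersection`` keeps only the base-pair intersection.
    Output is sorted and non-overlapping.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "intersection":
        out: list[GenomicInterval] = []
        merged1 = merge_replicate_peaks(rep1, [], mode="union")
        merged2 = merge_replicate_peaks(rep2, [], mode="union")
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in merged2:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for iv in merged1:
            for other in by_chrom.get(iv.chrom, ()):
                s, e = max(iv.start, other.start), min(iv.end, other.end)
                if s < e:
                    out.append(GenomicInterval(iv.chrom, s, e))
        return sorted(out)
    ivs = sorted(list(rep1) + list(rep2))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and iv.chrom == merged[-1].chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end, name=".")
        else:
            merged.append(replace(iv, name=".", score=None))
    return merged


def _edge_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Edge-to-edge distance; 0 when the intervals overlap or touch."""
    if a.chrom != b.chrom:
        return math.inf
    return max(a.start - b.end, b.start - a.end, 0)


def overlap_fraction(
    tf_sites: list[GenomicInterval],
    peaks: list[GenomicInterval],
    max_dist: int = 1000,
) -> float:
    """Fraction of TF sites within ``max_dist`` bp of any peak.

    Distance is edge-to-edge; an overlapping site counts as distance 0.
    Raises on an empty site list (the fraction is undefined).
    """
    if not tf_sites:
        raise ValueError("overlap fraction undefined for empty TF site list")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for lst in by_chrom.values():
        lst.sort()
    hits = 0
    for site in tf_sites:
        cands = by_chrom.get(site.chrom, ())
        if any(_edge_distance(site, p) <= max_dist for p in cands):
            hits += 1
    return hits / len(tf_sites)
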