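"""Label-free peptidoform quantification from centroided spectra.

The quantification strategy is targeted extracted-ion chromatography: for
each peptidoform in the library an EIC is pulled from the centroid stream at
a ppm mass tolerance (default 10 ppm, boundary inclusive), integrated over
its retention-time window by the trapezoidal rule, and — where several forms
are isobaric and co-elute — the shared area is apportioned linearly by
unique fragment-ion intensity.  Peak areas are then converted to relative
ratios within each peptide family (all forms sharing a backbone sequence and
span): ratio = area / family total, so defined ratios sum to 1 per family
and sample.

Spectra are represented as a pandas DataFrame with columns ``rt`` (minutes),
``mz`` (Th) and ``intensity``, sorted by retention time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peptidoforms import Peptidoform, compute_mz

__all__ = [
    "Chromatogram",
    "extract_ion_chromatogram",
    "integrate_area",
    "apportion_isobaric",
    "relative_ratios",
    "isobaric_groups",
    "quantify_sample",
]

logger = logging.getLogger(__name__)

SPECTRA_COLUMNS = ("rt", "mz", "intensity")


@dataclass
class Chromatogram:
    """An extracted ion chromatogram: summed intensity vs retention time."""

    target_mz: float
    ppm_tol: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.size and np.any(np.diff(self.rt) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


def extract_ion_chromatogram(
    spectra: pd.DataFrame, target_mz: float, ppm_tol: float = 10.0
) -> Chromatogram:
    """Extract an ion chromatogram at ``target_mz`` within ``ppm_tol`` ppm.

    Per spectrum (unique retention time), intensities of all centroids with
    ``|mz - target_mz| / target_mz * 1e6 <= ppm_tol`` are summed; the ppm
    boundary is inclusive.  Spectra with no matching centroid contribute
    intensity 0, so the trace covers every acquired scan.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm_tol must be positive")
    if spectra.empty:
        raise ValueError("empty spectra series")
    half_width = target_mz * ppm_tol * 1e-6
    mz = spectra["mz"].to_numpy()
    inside = np.abs(mz - target_mz) <= half_width
    rts = np.unique(spectra["rt"].to_numpy())
    matched = spectra.loc[inside].groupby("rt")["intensity"].sum()
    trace = matched.reindex(rts, fill_value=0.0)
    return Chromatogram(target_mz, ppm_tol, rts, trace.to_numpy())


def integrate_area(c: Chromatogram, rt_window: tuple[float, float]) -> float:
    """Trapezoidal integral of the trace within [start, end] (intensity*min).

    Returns 0 when fewer than two points fall inside the window.
    """
    start, end = rt_window
    if start >= end:
        raise ValueError("rt window start must precede end")
    mask = (c.rt >= start) & (c.rt <= end)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(c.intensity[mask], c.rt[mask]))


def apportion_isobaric(
    shared_area: float, forms: list[str], unique_fragment_intensity: dict[str, float]
) -> dict[str, float]:
    """Split a shared isobaric peak area proportionally to fragment evidence.

    ``area_i = shared_area * intensity_i / sum(intensities)``; outputs sum to
    the shared area.  All-zero fragment intensities leave the split
    undefined: the area is divided equally and a warning is logged.
    """
    if shared_area < 0:
        raise ValueError("shared_area must be non-negative")
    intens = np.array(
        [float(unique_fragment_intensity.get(f, 0.0)) for f in forms], dtype=float
    )
    if np.any(intens < 0):
        raise ValueError("fragment intensities must be non-negative")
    total = intens.sum()
    if total == 0:
        logger.warning(
            "all-zero fragment intensities for isobaric group %s; equal split",
            forms,
        )
        weights = np.full(len(forms), 1.0 / len(forms))
    else:
        weights = intens / total
    return {f: shared_area * w for f, w in zip(forms, weights)}


def relative_ratios(a: pd.DataFrame) -> pd.DataFrame:
    """Convert an area table to per-family relative abundances.

    Rows are peptidoform keys ``histone:start-end:modstring``; the family is
    the ``histone:start-end`` prefix.  Per (family, sample column), each
    area is divided by the family total.  Missing areas are treated as 0; a
    family whose total is 0 in a sample yields undefined (NaN) ratios there,
    and the number of such cells is logged.
    """
    if a.index.duplicated().any():
        dups = a.index[a.index.duplicated()].tolist()
        raise ValueError(f"duplicate peptidoform keys: {dups}")
    filled = a.fillna(0.0)
    if (filled.to_numpy() < 0).any():
        raise ValueError("negative peak areas")
    families = [":".join(k.split(":")[:2]) for k in filled.index]
    totals = filled.groupby(families, sort=False).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = filled / totals
    ratios = ratios.where(totals > 0)
    n_undef = int(ratios.isna().sum().sum())
    if n_undef:
        logger.info("relative_ratios: %d undefined cells (family total zero)", n_undef)
    return ratios


def isobaric_groups(
    library: list[Peptidoform], charge: int = 2, ppm_tol: float = 10.0
) -> list[list[Peptidoform]]:
    """Group library forms whose m/z are indistinguishable at ``ppm_tol``.

    Forms are clustered by single-linkage over sorted m/z: consecutive forms
    within the tolerance join the same group (positional isomers, e.g. H4
    K5ac vs K8ac, have identical mass and always co-cluster).
    """
    forms = sorted(library, key=lambda p: compute_mz(p, charge))
    groups: list[list[Peptidoform]] = []
    for p in forms:
        mz = compute_mz(p, charge)
        if groups:
            prev = compute_mz(groups[-1][-1], charge)
            if (mz - prev) / prev * 1e6 <= ppm_tol:
                groups[-1].append(p)
                continue
        groups.append([p])
    return groups


def quantify_sample(
    spectra: pd.DataFrame,
    library: list[Peptidoform],
    rt_windows: dict[str, tuple[float, float]],
    fragment_intensities: dict[str, float] | None = None,
    ppm_tol: float = 10.0,
    charge: int = 2,
) -> pd.Series:
    """Quantify every library form in one sample's centroid spectra.

    Non-isobaric forms get the trapezoidal integral of their own EIC over
    their retention-time window.  Isobaric groups share one EIC integrated
    over the union of member windows, then split by ``apportion_isobaric``
    using the provided unique-fragment intensities.

    Returns a Series of peak areas indexed by peptidoform key.
    """
    areas: dict[str, float] = {}
    for group in isobaric_groups(library, charge=charge, ppm_tol=ppm_tol):
        mzs = [compute_mz(p, charge) for p in group]
        target = float(np.mean(mzs))
        eic = extract_ion_chromatogram(spectra, target, ppm_tol)
        starts, ends = zip(*(rt_windows[p.key] for p in group))
        shared = integrate_area(eic, (min(starts), max(ends)))
        if len(group) == 1:
            areas[group[0].key] = shared
        else:
            frag = fragment_intensities or {}
            split = apportion_isobaric(shared, [p.key for p in group], frag)
            areas.update(split)
    return pd.Series(areas, name="area")
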