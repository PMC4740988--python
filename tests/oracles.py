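"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles against the documented
contracts — plain Python loops, atomic-composition mass sums, base-level
interval masks — and deliberately shares no code with the package.
"""

from __future__ import annotations

import numpy as np

# --- peptide mass from atomic composition ---------------------------------

_ATOM = {"C": 12.0, "H": 1.00782503, "N": 14.00307401, "O": 15.99491462,
         "S": 31.97207069}

# residue formulas (amino acid minus water), counts of C,H,N,O,S
_RESIDUE_FORMULA = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}

# modification deltas as formulas: methyl CH2, acetyl C2H2O, propionyl C3H4O
_MOD_FORMULA = {
    "un": (0, 0, 0, 0, 0),
    "me1": (1, 2, 0, 0, 0),
    "me2": (2, 4, 0, 0, 0),
    "me3": (3, 6, 0, 0, 0),
    "ac": (2, 2, 0, 1, 0),
    "pr": (3, 4, 0, 1, 0),
}


def _formula_mass(counts) -> float:
    c, h, n, o, s = counts
    return (c * _ATOM["C"] + h * _ATOM["H"] + n * _ATOM["N"]
            + o * _ATOM["O"] + s * _ATOM["S"])


def peptide_mass_oracle(sequence: str, start_res: int,
                        mods: dict[int, str]) -> float:
    """Neutral monoisotopic mass of a propionyl-derivatized peptidoform."""
    mass = sum(_formula_mass(_RESIDUE_FORMULA[aa]) for aa in sequence)
    mass += _formula_mass((0, 2, 0, 1, 0))  # water
    mass += _formula_mass(_MOD_FORMULA["pr"])  # N-terminal propionyl
    for i, aa in enumerate(sequence):
        if aa != "K":
            continue
        code = mods.get(start_res + i, "un")
        mass += _formula_mass(_MOD_FORMULA[code])
        if code in ("un", "me1"):
            mass += _formula_mass(_MOD_FORMULA["pr"])
    return mass


# --- EIC matching ----------------------------------------------------------

def eic_oracle(spectra_rows, target_mz: float, ppm_tol: float):
    """Exhaustive per-centroid EIC: dict rt -> summed matched intensity.

    ``spectra_rows`` is an iterable of (rt, mz, intensity) triplets.
    """
    trace: dict[float, float] = {}
    for rt, mz, inten in spectra_rows:
        trace.setdefault(rt, 0.0)
        if abs(mz - target_mz) / target_mz * 1e6 <= ppm_tol:
            trace[rt] += inten
    return trace


# --- trapezoid integration -------------------------------------------------

def trapezoid_oracle(rt, intensity, start: float, end: float) -> float:
    """Sum of trapezoids over consecutive in-window points."""
    pts = [(t, y) for t, y in zip(rt, intensity) if start <= t <= end]
    total = 0.0
    for (t0, y0), (t1, y1) in zip(pts, pts[1:]):
        total += 0.5 * (y0 + y1) * (t1 - t0)
    return total


# --- sliding-window peak classification ------------------------------------

def classify_oracle(peak_start: int, peak_end: int, arr_a, arr_b,
                    bin_size: int, window: int, fold: float,
                    pseudocount: float) -> str:
    """Exhaustive window scan at every bin-aligned offset inside the peak."""
    lo = peak_start // bin_size
    hi = min(-(-peak_end // bin_size), len(arr_a))
    w = max(1, window // bin_size)
    w = min(w, hi - lo)
    best = 1.0
    direction = 0
    for i in range(lo, hi - w + 1):
        ma = sum(arr_a[i:i + w]) / w
        mb = sum(arr_b[i:i + w]) / w
        f = (ma + pseudocount) / (mb + pseudocount)
        for val, d in ((f, 1), (1.0 / f, -1)):
            if val > best:
                best, direction = val, d
    if best > fold:
        return "specific_A" if direction > 0 else "specific_B"
    return "constitutive"


# --- interval merge via base mask ------------------------------------------

def merge_oracle(intervals, chrom_len: int):
    """Mark covered bases on one chromosome, then re-segment."""
    mask = np.zeros(chrom_len, dtype=bool)
    for s, e in intervals:
        mask[s:e] = True
    out = []
    in_run = False
    for i, m in enumerate(mask):
        if m and not in_run:
            start, in_run = i, True
        elif not m and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, chrom_len))
    return out


# --- TF-site overlap via intervaltree --------------------------------------

def overlap_oracle(sites, peaks, max_dist: int) -> float:
    """Fraction of sites within an inclusive edge distance of any peak.

    Each site is expanded by max_dist + 1 on both sides; with intervaltree's
    half-open overlap semantics this matches integer edge-to-edge distance
    <= max_dist (overlap = 0).
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in peaks:
        trees.setdefault(chrom, IntervalTree()).addi(s, e)
    hits = 0
    for chrom, s, e in sites:
        tree = trees.get(chrom)
        if tree is not None and tree.overlap(s - max_dist - 1, e + max_dist + 1):
            hits += 1
    return hits / len(sites)


# --- one-way ANOVA from sums of squares ------------------------------------

def anova_oracle(groups):
    """Textbook between/within sum-of-squares F statistic and p-value."""
    from scipy.stats import f as fdist

    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    F = (ss_between / df_b) / (ss_within / df_w)
    return F, float(fdist.sf(F, df_b, df_w))
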