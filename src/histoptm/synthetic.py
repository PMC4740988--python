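"""Ground-truthed synthetic data with the statistical structure of a
differentiating-ESC histone PTM study.

The generator emulates a five-time-point embryonic stem cell differentiation
course (ESC, embryoid body, retinoic-acid treatment, day 4 and day 7 plated
cells) measured with two biological replicates and three technical
replicates each.  Peptidoform peak areas are positive and right-skewed, so
technical and biological variation are modelled as multiplicative lognormal
noise with unit mean; within each peptide family the *true* composition at
each time point is a baseline profile reshaped by configurable
time-trajectory effects and renormalized to sum to 1.

Default trajectories reproduce the hallmark trends of ESC differentiation:
H3K4me1 declining from 17.1% to 13.0% of total H3 K4 peptide, H3K27me3
collapsing from 25.9% to 7.1%, H3K36me2 rising toward 44.4% at the embryoid
body stage, H3K9me2 gain / H3K9me1 loss, a five-fold monotone loss of
tetra-acetylated H4 aa 4-17 accompanied by loss of the other multiply
acetylated states, and an H4K16ac gain.

Also generates centroided spectra (Gaussian elution profiles on a regular
retention-time grid, isobaric forms co-eluting by construction) and toy
ChIP coverage tracks with population-specific and constitutive peaks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chipseq import CoverageTrack, GenomicInterval
from .peptidoforms import Peptidoform, compute_mz

__all__ = [
    "SampleDesign",
    "EffectSpec",
    "ElutionSchedule",
    "factor_for_marginal",
    "default_timecourse_effects",
    "default_baseline_weights",
    "simulate_area_table",
    "simulate_centroid_spectra",
    "simulate_chip_data",
    "default_elution_schedule",
]

DEFAULT_TIME_POINTS = ("ESC", "EB", "RA", "RA4d", "RA7d")
H4_ACETYL_FAMILY = "H4:4-17"


@dataclass(frozen=True)
class SampleDesign:
    """Time points x biological x technical replicate layout.

    Sample IDs are ``<time>.<bio>.<tech>``, e.g. ``ESC.A.1``.
    """

    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS
    n_bio: int = 2
    n_tech: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("n_bio and n_tech must be >= 1")
        if len(self.time_points) < 1:
            raise ValueError("need at least one time point")

    @property
    def bio_labels(self) -> tuple[str, ...]:
        return tuple(chr(ord("A") + i) for i in range(self.n_bio))

    def sample_ids(self) -> list[str]:
        return [
            f"{tp}.{b}.{t}"
            for tp in self.time_points
            for b in self.bio_labels
            for t in range(1, self.n_tech + 1)
        ]

    @staticmethod
    def parse_sample_id(sample_id: str) -> tuple[str, str, str]:
        """Split ``time.bio.tech`` into its three components."""
        parts = sample_id.rsplit(".", 2)
        if len(parts) != 3:
            raise ValueError(f"malformed sample id {sample_id!r}")
        return parts[0], parts[1], parts[2]


@dataclass(frozen=True)
class EffectSpec:
    """A multiplicative time-course effect on a set of peptidoforms.

    Exactly one selector is set: ``mark`` (all forms carrying that single
    PTM, e.g. "H3K4me1"), ``acetyl_count`` together with ``family`` (forms
    of that family with exactly that many acetyl groups), or ``form_key``
    (one exact form).  ``trajectory`` gives one multiplicative factor per
    time point applied to the true abundance before renormalization.
    """

    trajectory: tuple[float, ...]
    mark: str | None = None
    family: str | None = None
    acetyl_count: int | None = None
    form_key: str | None = None

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.trajectory):
            raise ValueError("trajectory factors must be positive")
        selectors = [
            self.mark is not None,
            self.acetyl_count is not None,
            self.form_key is not None,
        ]
        if sum(selectors) != 1:
            raise ValueError("set exactly one of mark / acetyl_count / form_key")
        if self.acetyl_count is not None and self.family is None:
            raise ValueError("acetyl_count selector requires a family")

    def selects(self, p: Peptidoform) -> bool:
        if self.mark is not None:
            return self.mark in p.marks
        if self.form_key is not None:
            return p.key == self.form_key
        return p.family == self.family and p.acetyl_count() == self.acetyl_count


def factor_for_marginal(baseline: float, target: float) -> float:
    """Multiplicative factor turning a marginal ratio ``baseline`` into
    ``target`` after family renormalization.

    If the forms carrying a mark hold fraction m0 of the family and are all
    scaled by f, the renormalized marginal is m0*f / (m0*f + 1 - m0);
    solving for f gives ``target*(1-baseline) / (baseline*(1-target))``.
    """
    if not (0 < baseline < 1 and 0 < target < 1):
        raise ValueError("marginals must lie strictly inside (0, 1)")
    return target * (1 - baseline) / (baseline * (1 - target))


def _geometric_trajectory(final_factor: float, n: int) -> tuple[float, ...]:
    """Monotone trajectory interpolating 1 -> final_factor geometrically."""
    if n == 1:
        return (1.0,)
    return tuple(final_factor ** (i / (n - 1)) for i in range(n))


# ESC-stage per-site modification frequencies used to build baseline family
# compositions (assuming independence between sites on the same peptide).
_SITE_BASELINES: dict[str, dict[str, float]] = {
    "H3:3-8:4": {"un": 0.600, "me1": 0.171, "me2": 0.150, "me3": 0.079},
    "H3:9-17:9": {"un": 0.250, "me1": 0.300, "me2": 0.300, "me3": 0.100, "ac": 0.050},
    "H3:9-17:14": {"un": 0.800, "ac": 0.200},
    "H3:18-26:18": {"un": 0.850, "ac": 0.150},
    "H3:18-26:23": {"un": 0.700, "ac": 0.300},
    "H3:27-40:27": {"un": 0.250, "me1": 0.250, "me2": 0.200, "me3": 0.259, "ac": 0.041},
    "H3:27-40:36": {"un": 0.450, "me1": 0.150, "me2": 0.308, "me3": 0.092},
    "H4:4-17:5": {"un": 0.880, "ac": 0.120},
    "H4:4-17:8": {"un": 0.900, "ac": 0.100},
    "H4:4-17:12": {"un": 0.900, "ac": 0.100},
    "H4:4-17:16": {"un": 0.700, "ac": 0.300},
    "H4:20-23:20": {"un": 0.150, "me1": 0.250, "me2": 0.550, "me3": 0.050},
}


def default_baseline_weights(library: list[Peptidoform]) -> pd.Series:
    """ESC-stage true family compositions for the default library.

    Each form's weight is the product of its per-site modification
    frequencies; weights are normalized within each family.  Forms from
    peptides without declared site frequencies get uniform weights.
    """
    weights: dict[str, float] = {}
    for p in library:
        w = 1.0
        mods = p.mod_dict
        for i, aa in enumerate(p.sequence):
            res = p.start_res + i
            site = f"{p.family}:{res}"
            if site in _SITE_BASELINES:
                w *= _SITE_BASELINES[site].get(mods.get(res, "un"), 0.0)
        weights[p.key] = w
    s = pd.Series(weights)
    fams = [":".join(k.split(":")[:2]) for k in s.index]
    sums = s.groupby(fams).transform("sum")
    s = s.where(sums > 0, 1.0)
    sums = s.groupby(fams).transform("sum")
    return s / sums


def default_timecourse_effects(
    time_points: tuple[str, ...] = DEFAULT_TIME_POINTS,
) -> list[EffectSpec]:
    """The differentiation-course effect set the generator applies by default."""
    n = len(time_points)

    def shift(mark: str, start: float, end: float) -> EffectSpec:
        return EffectSpec(
            trajectory=_geometric_trajectory(factor_for_marginal(start, end), n),
            mark=mark,
        )

    effects = [
        # H3K4me1 17.1% -> 13.0% of the K4 peptide across the course
        shift("H3K4me1", 0.171, 0.130),
        # H3K27me3 25.9% -> 7.1%
        shift("H3K27me3", 0.259, 0.071),
        # H3K9me2 gain, H3K9me1 loss upon differentiation
        shift("H3K9me2", 0.300, 0.450),
        shift("H3K9me1", 0.300, 0.180),
        # H3K36me2 30.8% -> 44.4% peaking at the embryoid-body stage
        EffectSpec(
            trajectory=(1.0,)
            + (factor_for_marginal(0.308, 0.444),) * (n - 1),
            mark="H3K36me2",
        ),
        # five-fold monotone loss of tetra-acetylated H4 aa 4-17
        EffectSpec(
            trajectory=_geometric_trajectory(0.2, n),
            family=H4_ACETYL_FAMILY,
            acetyl_count=4,
        ),
        # other multiply acetylated states decline too, less steeply
        EffectSpec(
            trajectory=_geometric_trajectory(0.4, n),
            family=H4_ACETYL_FAMILY,
            acetyl_count=3,
        ),
        EffectSpec(
            trajectory=_geometric_trajectory(0.6, n),
            family=H4_ACETYL_FAMILY,
            acetyl_count=2,
        ),
        # H4K16ac increases upon differentiation
        shift("H4K16ac", 0.300, 0.380),
    ]
    return effects


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Lognormal draws with mean 1 and coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    mu = -sigma2 / 2
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def true_ratio_table(
    library: list[Peptidoform],
    time_points: tuple[str, ...],
    effects: list[EffectSpec],
    baseline: pd.Series | None = None,
) -> pd.DataFrame:
    """Ground-truth per-family relative ratios, forms x time points."""
    if not library:
        raise ValueError("empty peptidoform library")
    if baseline is None:
        baseline = default_baseline_weights(library)
    keys = [p.key for p in library]
    for e in effects:
        if not any(e.selects(p) for p in library):
            raise ValueError(f"effect {e} selects no library form")
        if len(e.trajectory) != len(time_points):
            raise ValueError("trajectory length must equal number of time points")
    weights = np.tile(baseline.loc[keys].to_numpy()[:, None], (1, len(time_points)))
    for e in effects:
        sel = np.array([e.selects(p) for p in library])
        weights[sel] *= np.asarray(e.trajectory)[None, :]
    df = pd.DataFrame(weights, index=keys, columns=list(time_points))
    fams = [p.family for p in library]
    totals = df.groupby(fams, sort=False).transform("sum")
    return df / totals


def simulate_area_table(
    library: list[Peptidoform],
    design: SampleDesign,
    effects: list[EffectSpec] | None = None,
    baseline: pd.Series | None = None,
    tech_cv: float = 0.05,
    bio_cv: float = 0.15,
    family_scale: float = 1e7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an area table and return it with its ground truth.

    Observed area = family_scale * true_ratio * lognormal(bio) *
    lognormal(tech), with unit-mean lognormal noise so the expectation
    equals the scaled true ratio.  Biological noise is drawn per (form,
    time point, biological replicate); technical noise per sample.

    Returns
    -------
    (areas, truth)
        ``areas``: forms x samples peak areas.  ``truth``: forms x samples
        ground-truth relative ratios (identical across replicates of a time
        point).  Identical ``design.seed`` gives identical output.
    """
    if not library:
        raise ValueError("empty peptidoform library")
    if family_scale <= 0:
        raise ValueError("family_scale must be positive")
    if tech_cv < 0 or bio_cv < 0:
        raise ValueError("noise CVs must be non-negative")
    if effects is None:
        effects = default_timecourse_effects(design.time_points)
    rng = np.random.default_rng(design.seed)
    truth_tp = true_ratio_table(library, design.time_points, effects, baseline)
    n_forms = len(library)
    samples = design.sample_ids()
    truth = pd.DataFrame(index=truth_tp.index, columns=samples, dtype=float)
    areas = pd.DataFrame(index=truth_tp.index, columns=samples, dtype=float)
    bio_noise = {
        (tp, b): _lognormal_unit_mean(rng, bio_cv, n_forms)
        for tp in design.time_points
        for b in design.bio_labels
    }
    for tp in design.time_points:
        col_truth = truth_tp[tp].to_numpy()
        for b in design.bio_labels:
            bn = bio_noise[(tp, b)]
            for t in range(1, design.n_tech + 1):
                sid = f"{tp}.{b}.{t}"
                tn = _lognormal_unit_mean(rng, tech_cv, n_forms)
                areas[sid] = family_scale * col_truth * bn * tn
                truth[sid] = col_truth
    return areas, truth


@dataclass(frozen=True)
class ElutionSchedule:
    """Per-form elution parameters: retention-time mean and Gaussian width."""

    rt_means: dict[str, float] = field(default_factory=dict)
    width: float = 0.2  # minutes (Gaussian sigma)

    def window(self, key: str, n_sigma: float = 3.0) -> tuple[float, float]:
        m = self.rt_means[key]
        return (m - n_sigma * self.width, m + n_sigma * self.width)


def default_elution_schedule(
    library: list[Peptidoform],
    rt_start: float = 10.0,
    rt_end: float = 50.0,
    width: float = 0.2,
    charge: int = 2,
) -> ElutionSchedule:
    """Deterministic targeted elution schedule over a toy gradient.

    Forms are spaced evenly over [rt_start, rt_end] in mass order, except
    that isobaric forms (identical m/z within 1 ppm) share one retention
    time so that they genuinely co-elute.
    """
    from .ms_quant import isobaric_groups

    groups = isobaric_groups(library, charge=charge, ppm_tol=1.0)
    n = len(groups)
    rts: dict[str, float] = {}
    for i, group in enumerate(groups):
        rt = rt_start if n == 1 else rt_start + (rt_end - rt_start) * i / (n - 1)
        for p in group:
            rts[p.key] = rt
    return ElutionSchedule(rt_means=rts, width=width)


def simulate_centroid_spectra(
    areas: pd.Series,
    library: list[Peptidoform],
    elution: ElutionSchedule,
    rt_step: float = 0.05,
    mz_jitter_ppm: float = 0.0,
    seed: int = 0,
    charge: int = 2,
) -> pd.DataFrame:
    """Emit centroid spectra for one sample's peak areas.

    Each form with positive area contributes a Gaussian elution profile
    sampled on a regular retention-time grid: the centroid intensity at grid
    point t is ``area * N(t; rt_mean, width)``, so the trapezoidal integral
    of its EIC recovers the area to within quadrature error.  Isobaric
    co-eluting forms each emit their own centroids (at essentially the same
    m/z), summing in the shared EIC.  Zero-area forms emit nothing.

    Returns a DataFrame with columns (rt, mz, intensity) sorted by rt.
    """
    if elution.width <= 0:
        raise ValueError("elution width must be positive")
    if rt_step <= 0:
        raise ValueError("rt_step must be positive")
    rng = np.random.default_rng(seed)
    by_key = {p.key: p for p in library}
    rows: list[pd.DataFrame] = []
    rt_min = min(elution.rt_means.values()) - 4 * elution.width
    rt_max = max(elution.rt_means.values()) + 4 * elution.width
    grid = np.arange(rt_min, rt_max + rt_step / 2, rt_step)
    sig = elution.width
    for key, area in areas.items():
        if area <= 0 or key not in by_key:
            continue
        p = by_key[key]
        mu = elution.rt_means[key]
        mask = np.abs(grid - mu) <= 4 * sig
        rt = grid[mask]
        dens = np.exp(-0.5 * ((rt - mu) / sig) ** 2) / (sig * math.sqrt(2 * math.pi))
        inten = float(area) * dens
        mz = compute_mz(p, charge)
        if mz_jitter_ppm > 0:
            mz_arr = mz * (1 + rng.normal(0, mz_jitter_ppm * 1e-6, size=rt.size))
        else:
            mz_arr = np.full(rt.size, mz)
        rows.append(pd.DataFrame({"rt": rt, "mz": mz_arr, "intensity": inten}))
    if not rows:
        return pd.DataFrame(columns=["rt", "mz", "intensity"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["rt", "mz"], kind="stable").reset_index(drop=True)


def fragment_intensity_summary(
    areas: pd.Series, fragment_cv: float = 0.0, seed: int = 0
) -> dict[str, float]:
    """Unique-fragment ion intensity summary for isobaric apportionment.

    Modelled as proportional to the form's true area with optional
    multiplicative lognormal noise — a stand-in for MS/MS fragment evidence.
    """
    rng = np.random.default_rng(seed)
    noise = _lognormal_unit_mean(rng, fragment_cv, len(areas))
    return dict(zip(areas.index, np.maximum(areas.to_numpy(), 0.0) * noise))


def simulate_chip_data(
    chrom_sizes: dict[str, int],
    true_peaks: list[tuple[GenomicInterval, float, float]],
    background_rate: float = 50.0,
    bin_size: int = 50,
    seed: int = 0,
    fold_threshold: float = 4.0,
) -> tuple[CoverageTrack, CoverageTrack, list[GenomicInterval], list[str]]:
    """Simulate binned ChIP coverage for two populations with known labels.

    Per bin, counts are Poisson at ``background_rate`` outside peaks and
    ``background_rate * factor`` inside, where each true peak carries an
    enrichment factor per population.  Truth labels follow the generating
    factors: ratio > ``fold_threshold`` in either direction -> specific to
    the enriched population, else constitutive.

    Returns (track_A, track_B, peaks, labels).
    """
    rng = np.random.default_rng(seed)
    lam_a = {c: np.full(math.ceil(s / bin_size), background_rate, dtype=float)
             for c, s in chrom_sizes.items()}
    lam_b = {c: arr.copy() for c, arr in lam_a.items()}
    peaks: list[GenomicInterval] = []
    labels: list[str] = []
    for iv, fa, fb in true_peaks:
        if fa <= 0 or fb <= 0:
            raise ValueError("enrichment factors must be positive")
        if iv.chrom not in chrom_sizes or iv.end > chrom_sizes[iv.chrom]:
            raise ValueError(f"peak {iv} outside chromosome bounds")
        lo, hi = iv.start // bin_size, math.ceil(iv.end / bin_size)
        lam_a[iv.chrom][lo:hi] = background_rate * fa
        lam_b[iv.chrom][lo:hi] = background_rate * fb
        peaks.append(iv)
        if fa / fb > fold_threshold:
            labels.append("specific_A")
        elif fb / fa > fold_threshold:
            labels.append("specific_B")
        else:
            labels.append("constitutive")
    data_a = {c: rng.poisson(lam).astype(float) for c, lam in lam_a.items()}
    data_b = {c: rng.poisson(lam).astype(float) for c, lam in lam_b.items()}
    track_a = CoverageTrack(data_a, bin_size, float(sum(a.sum() for a in data_a.values())))
    track_b = CoverageTrack(data_b, bin_size, float(sum(a.sum() for a in data_b.values())))
    return track_a, track_b, peaks, labels
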