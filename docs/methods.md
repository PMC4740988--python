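# Methods

## Peptidoforms and masses

A peptidoform is one combinatorial modification state of a tryptic histone
peptide. The chemistry modelled is the standard propionylation workflow:
propionic anhydride derivatizes the peptide N-terminus and every lysine
side chain that is still reactive — unmodified or monomethylated — while
acetylated, di- and trimethylated lysines are blocked. Neutral monoisotopic
masses are the sum of residue masses, water, the modification deltas
(me1 +14.015650, me2 +28.031300, me3 +42.046950, ac +42.010565,
pr +56.026215 Da) and the implied propionyl groups; m/z at charge z is
(M + z·1.007276)/z. The residue and modification masses are embedded as a
single table in `histoptm.masses`; the test suite cross-checks them against
an independent atomic-composition computation.

The default library (`default_histone_library`) expands six H3/H4 tryptic
peptides into 58 forms, including the H4 aa 4-17 peptide GKGGKGLGKGGAKR
with its four acetylatable lysines (2⁴ = 16 forms) and the H3 K27/K36
peptide with 5 × 4 = 20 methyl/acetyl combinations. Trimethyl and acetyl
lysine differ by 0.0364 Da — resolvable at 10 ppm for these peptides —
whereas positional acetyl isomers (K5ac vs K8ac) are exactly isobaric and
are the reason for the fragment-based apportionment step.

## Synthetic data model

The generator emulates a five-stage differentiation course (ESC, embryoid
body, retinoic acid, day 4, day 7) with 2 biological × 3 technical
replicates per stage — the layout of the study design it mimics; all three
axes are configurable.

*True composition.* Within each peptide family a baseline weight per form is
built as the product of per-site modification frequencies (ESC-stage values;
independence between sites on one peptide). Time-course effects are
multiplicative factors per time point applied to selected forms (by single
mark, by acetyl count within a family, or by exact form), after which
weights are renormalized to family ratios. Because the baseline is
product-form, scaling all carriers of one site level by
`factor_for_marginal(m₀, m₁) = m₁(1−m₀)/(m₀(1−m₁))` moves that site's
marginal exactly from m₀ to m₁ — this is how the default course pins
H3K4me1 at 17.1% → 13.0% and H3K27me3 at 25.9% → 7.1%, alongside a
five-fold monotone loss of tetra-acetylated H4, loss of the other multiply
acetylated states, an H3K36me2 rise to 44.4% at the EB stage, H3K9me2
gain/H3K9me1 loss and an H4K16ac gain. Where two effects touch the same
family level (e.g. K9me1 and K9me2) the endpoint marginals are approximate;
directions are always exact.

*Noise.* Observed area = family scale (10⁷) × true ratio × LN(bio) ×
LN(tech), with unit-mean lognormal noise: multiplicative, positive and
right-skewed, as peak areas are. Biological noise is drawn per (form, time
point, biological replicate); technical noise per sample. Defaults tech
CV 5% and bio CV 15% are stated placeholders of realistic magnitude for
label-free histone MS, not inferred from any dataset.

*Spectra.* Each form with positive area emits centroids on a regular
retention-time grid (0.05 min) following a Gaussian elution profile
(σ = 0.2 min) whose sampled density is scaled by the area, so the
trapezoidal EIC integral recovers the area to quadrature accuracy
(measured systematic error < 0.01%). Forms are spaced over a 10-50 min toy
gradient in mass order; exactly isobaric forms share one retention time so
that they genuinely co-elute. Optional ppm jitter perturbs centroid m/z.
A unique-fragment intensity summary (proportional to the true areas,
optionally noisy) stands in for MS/MS evidence. Isotope envelopes, charge
state distributions and retention-time drift are not modelled — passing
tests therefore say nothing about deconvolution or alignment on real data.

*ChIP.* Per-bin Poisson counts at a background rate (default 50 reads per
50 bp bin) times a per-population enrichment factor inside true peaks.
Truth labels follow the generating factors (ratio > 4 → specific).

## Quantification

EICs sum centroid intensities within ±10 ppm of the target m/z, boundary
inclusive; scans without a match contribute zero so every trace covers all
scans. Integration is trapezoidal over the form's elution window (±3 σ;
fewer than two in-window points integrate to zero). Library forms whose m/z
agree within the tolerance are clustered by single-linkage over sorted m/z
and share one EIC integrated over the union of their windows; the shared
area is split as `areaᵢ = shared × fragᵢ / Σ frag`. All-zero fragment
evidence makes the split undefined: it is logged and divided equally rather
than propagated as NaN. Relative ratios divide each area by its family
total; missing areas count as zero (form not observed), while a family
total of zero leaves that family's ratios undefined (NaN) and logged —
two deliberately distinct conditions.

## Profiles and statistics

Technical replicates are averaged arithmetically per (time point,
biological replicate) on the *ratio* scale, before display statistics;
undefined cells are excluded from means, never imputed. Marginalization is
linear, so it commutes with averaging (tested to 1e-12). Row z-scores use
the sample standard deviation (n−1); constant rows are set to zero with a
warning. Z-scoring is applied after technical averaging; the reverse order
is a documented alternative that would rescale but not reorder profiles.

ANOVA is the classical one-way fixed-effects F-test; the treatment contrast
is the pooled-variance two-tailed t-test with log₂ fold change of
arithmetic mean ratios (undefined, not pseudocounted, when a mean is
non-positive). Significance is −log₂ p > 4.32 ⇔ p < 0.05 (strict); raw
p-values carry the flags and BH q-values are reported alongside as an
extension. Degenerate inputs: all values identical → p = 1; zero
within-group variance with unequal means → the p → 0 limit.

The observation unit for the paper-matching time-course ANOVA is the
biological-replicate mean (2 per time point) — the displayed unit of the
replicate structure; replicate-level observations (6 per time point) are
available by passing unaveraged columns. The distinction matters: at the
default noise levels the configured 5-fold tetra-acetyl decline reaches
p < 0.01 in ~81% of runs with biological means (df 4,5) and in ~100% with
replicate-level observations (df 4,25). The recovery benchmark in the test
suite and acceptance script uses replicate-level observations and verifies
the trajectory's sign in expectation over runs; the measured joint recovery
rate is ~95%.

## ChIP-seq classification

Coverage is normalized per bin to reads per million mapped reads times a
global scale of 10 (the "10 RPM" convention; set scale = 1 for plain RPM —
the fold ratio is scale-invariant either way). Windows of 200 bp slide
across each peak in steps of one bin; per window the fold is
(mean_A + c)/(mean_B + c) with pseudocount c = 0.1 RPM guarding empty
denominators. Any window fold > 4 makes the peak specific to the enriched
population (the larger maximum wins if both directions exceed the threshold
in different windows); peaks shorter than a window are evaluated as a
single window. Replicate merging is coalesced union of intervals
(book-ended intervals join), with base-pair intersection behind a flag.
TF-site overlap uses inclusive edge-to-edge distance, overlap counting as
zero. All coordinates are 0-based half-open (BED).

## Numerical and design choices

| Parameter | Default | Rationale |
|---|---|---|
| EIC tolerance | 10 ppm | high-resolution Orbitrap-class matching window |
| RT grid / elution σ | 0.05 / 0.2 min | quadrature error ≪ 1% of peak area |
| ppm boundary | inclusive | a centroid exactly on the window edge is evidence |
| tech / bio CV | 5% / 15% | realistic placeholders, not fitted values |
| classification window / fold | 200 bp / 4 | the specific-peak definition being implemented |
| pseudocount | 0.1 RPM | stabilizes folds over zero-coverage bins |
| TF distance | ≤ 1000 bp edge-to-edge | overlap = 0 by convention |
| significance | −log₂ p > 4.32 | exactly p < 0.05, strict inequality |
| z-score sd | sample (n−1) | matches heatmap-tool convention |

Problem sizes in the shipped tests and acceptance script — 58-form library,
5 × 2 × 3 design, 100 recovery runs, 1,000 null simulations, 200 simulated
peaks on a 2 Mb toy chromosome — were chosen so the complete pipeline
re-runs from scratch in well under a minute while keeping Monte-Carlo error
a small fraction of every tolerance tested.

## Limitations

The generator's ground truth is the package's own compositional model;
agreement demonstrates internal consistency of quantification, statistics
and classification, not instrument-level validity. Isobaric apportionment
is linear in fragment intensity — a simplification of fragment-ratio
deconvolution as performed by dedicated tools. No multiple-testing
correction feeds the significance flags (raw p-values with a fixed 0.05
rule); the hierarchical tech-within-bio structure is handled by averaging,
not mixed models. Peak calling, read alignment and GO enrichment are
upstream/downstream of this package and are treated as inputs or out of
scope.
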