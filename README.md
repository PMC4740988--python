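# histoptm

Quantitative analysis of histone post-translational modifications (PTMs)
during embryonic stem cell differentiation, as measured by bottom-up mass
spectrometry of propionylated histone peptides — together with the
downstream epigenomic readout: classification of ChIP-seq peaks into
population-specific and constitutive sets.

The package is aimed at proteomics/epigenetics analysts who have (or want to
simulate) peptidoform-level peak areas over a multi-time-point, multi-replicate
design and need the standard derived quantities: relative abundances,
single-mark profiles, acetylation-state distributions, time-course and
treatment statistics, and differential peak calls.

## What it computes

**Peptidoform quantification.** Histones are chemically propionylated
(N-termini and unmodified/monomethyl lysines) and digested with trypsin,
producing Arg-C-like peptides such as GKGGKGLGKGGAKR (H4 aa 4-17, carrying
K5/K8/K12/K16). Each combinatorial modification state (peptidoform) is
quantified by extracted ion chromatography: centroids within ±10 ppm of the
form's m/z are summed per scan and the trace is integrated over the elution
window (trapezoidal rule). Isobaric co-eluting forms (e.g. positional acetyl
isomers) share one chromatogram; the area is apportioned linearly by unique
fragment-ion intensity.

**Relative abundance.** For a peptide *family* (all forms sharing one
backbone and span) the relative ratio of form *i* in sample *s* is

    r_is = A_is / Σ_j A_js

so ratios sum to 1 per family and sample. Single-mark abundances (e.g.
H3K9me2) are marginal sums over every family member carrying the mark; the
H4 acetyl-state profile sums forms with exactly k = 0…4 acetyl groups.

**Statistics.** Technical replicates are averaged per biological replicate;
time-course effects are tested per feature with one-way ANOVA, treatment
contrasts with homoscedastic two-tailed t-tests. A feature is significant
when −log₂ p > 4.32, i.e. exactly p < 0.05; log₂ fold changes and
Benjamini–Hochberg q-values (reported as an extension) accompany each test.
PCA of the mark profiles and the Pearson concordance of fold changes between
two inhibitor doses summarize global structure.

**ChIP-seq classification.** Binned coverage is normalized to reads per
million mapped reads (×10 by convention). A peak is *specific* to one
population if any 200 bp window inside it shows a more-than-4-fold
enrichment over the other population (0.1 RPM pseudocount), otherwise
*constitutive*. Replicate peak sets are merged by coalesced union, and TF
binding-site proximity is scored as the fraction of sites within 1 kb
(edge-to-edge) of a peak.

All stages run on ground-truthed synthetic data from `histoptm.synthetic`:
log-normally noisy peak areas over a 5 time-point × 2 biological × 3
technical design, Gaussian-elution centroid spectra, and Poisson ChIP
coverage with known peak labels — so every result can be checked against
its generating truth.

## Worked example

```python
from histoptm import (default_histone_library, SampleDesign,
                      simulate_area_table, relative_ratios,
                      single_mark_abundance, average_technical_replicates)

library = default_histone_library()          # 58 H3/H4 peptidoforms
design = SampleDesign(seed=1)                # ESC→EB→RA→RA4d→RA7d, 2×3 reps
areas, truth = simulate_area_table(library, design, tech_cv=0, bio_cv=0)
marks = average_technical_replicates(single_mark_abundance(relative_ratios(areas)))
print(marks.loc["H3K4me1", ["ESC.A", "RA7d.A"]].round(3).to_dict())
print(marks.loc["H3K27me3", ["ESC.A", "RA7d.A"]].round(3).to_dict())
```

prints

```
{'ESC.A': 0.171, 'RA7d.A': 0.13}
{'ESC.A': 0.259, 'RA7d.A': 0.071}
```

— the noise-free differentiation course configured in the generator:
H3K4me1 falls from 17.1% to 13.0% of the H3 K4 peptide and H3K27me3 from
25.9% to 7.1%. The same pipeline, run end-to-end from simulated spectra with
realistic noise, is available as one command:

```bash
histoptm demo --seed 1 --out-dir demo_out
```

which writes the intermediate tables (areas, ratios, mark and acetyl-state
profiles, ANOVA and volcano tables, classified peaks) and prints a JSON
report, e.g. `"chip_label_accuracy": 1.0` on 60 simulated peaks and
`"jq1_dose_concordance_r": 0.87` between the two inhibitor doses.

Other subcommands: `simulate`, `quantify`, `profile`, `diff`, `anova`,
`classify-peaks`, `overlap` (see `histoptm --help`).

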