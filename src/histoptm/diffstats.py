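"""Differential statistics for time-course and treatment PTM profiles.

* one-way fixed-effects ANOVA across time points per feature;
* homoscedastic (pooled-variance) two-tailed two-sample t-tests with
  log2 fold changes, significance flagged at -log2(p) > 4.32 — i.e.
  exactly p < 0.05;
* Pearson concordance of log2 fold changes between two treatments;
* PCA of sample x feature abundance profiles.

Raw p-values carry the significance flags; Benjamini-Hochberg q-values are
reported alongside as an extension and never feed the flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiffResult",
    "NEGLOG2_ALPHA",
    "anova_timecourse",
    "ttest_fold_change",
    "ttest_table",
    "dose_concordance",
    "pca_profiles",
]

ALPHA = 0.05
#: -log2(0.05) = 4.3219...; the conventional "> 4.32" volcano cutoff.
NEGLOG2_ALPHA = -math.log2(ALPHA)


@dataclass(frozen=True)
class DiffResult:
    """One feature's differential test result."""

    feature: str
    log2_fc: float
    p_value: float
    neglog2_p: float
    significant: bool


def _neglog2(p: float) -> float:
    if p <= 0:
        return math.inf
    return -math.log2(p)


def anova_timecourse(groups: dict[str, np.ndarray]) -> float:
    """One-way fixed-effects ANOVA p-value across time-point groups.

    Groups are time points; observations are replicate-level relative
    abundances.  Degenerate cases: zero within-group variance with unequal
    means gives the p -> 0 limit (0.0); all values identical gives p = 1
    (nothing to detect).
    """
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        return 1.0
    within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if within == 0:
        return 0.0
    return float(stats.f_oneway(*arrays).pvalue)


def anova_table(
    values: pd.DataFrame, group_of: dict[str, str]
) -> pd.DataFrame:
    """Per-feature ANOVA over a features x samples table.

    ``group_of`` maps sample column to group label (time point).  Returns a
    DataFrame with p_value and BH q_value per feature.
    """
    labels = [group_of[c] for c in values.columns]
    out = {}
    for feat, row in values.iterrows():
        groups: dict[str, list[float]] = {}
        for g, v in zip(labels, row.to_numpy()):
            if np.isfinite(v):
                groups.setdefault(g, []).append(v)
        out[feat] = anova_timecourse({g: np.asarray(v) for g, v in groups.items()})
    df = pd.DataFrame({"p_value": pd.Series(out)})
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df


def ttest_fold_change(
    control: np.ndarray, treated: np.ndarray, feature: str = ""
) -> DiffResult:
    """Pooled-variance two-tailed t-test with log2 fold change.

    ``log2_fc = log2(mean(treated) / mean(control))``; undefined (NaN) when
    either mean is non-positive, though the p-value is still reported.
    Significant iff -log2(p) > 4.32, equivalently p < 0.05 (strict).
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.size < 2 or treated.size < 2:
        raise ValueError("each arm needs >= 2 observations")
    if np.ptp(np.concatenate([control, treated])) == 0:
        p = 1.0
    elif control.var(ddof=1) == 0 and treated.var(ddof=1) == 0:
        p = 0.0  # zero within-arm variance, unequal means: p -> 0 limit
    else:
        p = float(stats.ttest_ind(treated, control, equal_var=True).pvalue)
    mc, mt = control.mean(), treated.mean()
    lfc = math.log2(mt / mc) if (mc > 0 and mt > 0) else math.nan
    nlp = _neglog2(p)
    return DiffResult(feature, lfc, p, nlp, p < ALPHA)


def ttest_table(
    values: pd.DataFrame, control_cols: list[str], treated_cols: list[str]
) -> pd.DataFrame:
    """Per-feature t-test/fold-change over a features x samples table.

    Returns a volcano-ready DataFrame (log2_fc, p_value, neglog2_p,
    significant, q_value) indexed by feature.
    """
    rows = []
    for feat, row in values.iterrows():
        r = ttest_fold_change(
            row[control_cols].to_numpy(), row[treated_cols].to_numpy(), str(feat)
        )
        rows.append((r.feature, r.log2_fc, r.p_value, r.neglog2_p, r.significant))
    df = pd.DataFrame(
        rows, columns=["feature", "log2_fc", "p_value", "neglog2_p", "significant"]
    ).set_index("feature")
    df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df


def dose_concordance(
    diff_a: pd.DataFrame, diff_b: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Pair fold changes of two treatments and compute their correlation.

    Inner-joins the two result tables on feature and returns the paired
    log2 fold changes plus their Pearson correlation.  Fewer than 3 shared
    finite pairs leaves the correlation undefined (NaN).
    """
    paired = pd.DataFrame(
        {"log2_fc_a": diff_a["log2_fc"], "log2_fc_b": diff_b["log2_fc"]}
    ).dropna()
    if len(paired) < 3:
        return paired, math.nan
    r = float(stats.pearsonr(paired["log2_fc_a"], paired["log2_fc_b"]).statistic)
    return paired, r


def pca_profiles(
    m: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of a samples x features matrix (features centered).

    Returns (scores, loadings, explained_variance_ratio); the ratios over
    the full decomposition sum to 1.
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 samples and >= 2 features")
    X = m.to_numpy(dtype=float)
    if np.allclose(X - X.mean(axis=0), 0):
        raise ValueError("matrix has rank 0 after centering")
    k = n_components or min(m.shape[0] - 1, m.shape[1])
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    pcs = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return (
        pd.DataFrame(scores, index=m.index, columns=pcs),
        pd.DataFrame(pca.components_.T, index=m.columns, columns=pcs),
        pca.explained_variance_ratio_,
    )
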