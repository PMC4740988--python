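"""PTM abundance profiles derived from peptidoform relative ratios.

Three summaries of a relative-abundance table:

* **single-mark marginals** — for each individual PTM (e.g. H3K9me2,
  H4K16ac), the summed relative abundance of every peptidoform in the
  mark's family that carries it;
* **acetyl-state profile** — for the H4 aa 4-17 peptide, the summed
  abundance of forms with exactly 0..4 acetylated lysines (an exact
  partition of the family, so columns sum to 1);
* **row z-scores** — heatmap-style per-row standardization.

Technical replicates are averaged per (time point, biological replicate)
before display or testing; undefined (NaN) cells are excluded from means,
never imputed.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .peptidoforms import parse_form_key
from .synthetic import SampleDesign

__all__ = [
    "average_technical_replicates",
    "single_mark_abundance",
    "acetyl_state_profile",
    "zscore_rows",
    "to_long_format",
]

logger = logging.getLogger(__name__)


def average_technical_replicates(t: pd.DataFrame) -> pd.DataFrame:
    """Average table columns over technical replicates.

    Columns named ``time.bio.tech`` collapse to ``time.bio`` by arithmetic
    mean; NaN cells are excluded from the mean (all-NaN stays NaN).  Column
    order follows first appearance.  Unequal replicate counts across groups
    are logged but tolerated.
    """
    groups = [".".join(SampleDesign.parse_sample_id(c)[:2]) for c in t.columns]
    counts = pd.Series(groups).value_counts()
    if counts.nunique() > 1:
        logger.warning(
            "unequal technical replicate counts: %s", dict(counts)
        )
    out = t.T.groupby(groups, sort=False).mean().T
    return out


_MARK_RE = re.compile(r"^(H\d+[A-Za-z]*)K(\d+)(me1|me2|me3|ac)$")


def single_mark_abundance(r: pd.DataFrame) -> pd.DataFrame:
    """Marginal relative abundance of every single PTM present in the table.

    A mark's marginal in a sample is the sum of relative ratios of all
    peptidoforms in its family carrying that mark.  Marks are labelled
    ``<histone>K<residue><code>``; rows are sorted by histone, residue and
    code.
    """
    mark_rows: dict[str, list[str]] = {}
    for key in r.index:
        histone, _, _, mods = parse_form_key(key)
        for res, code in mods.items():
            mark_rows.setdefault(f"{histone}K{res}{code}", []).append(key)
    if not mark_rows:
        return pd.DataFrame(columns=r.columns)
    rows = {mark: r.loc[keys].sum(axis=0, min_count=1) for mark, keys in mark_rows.items()}
    out = pd.DataFrame(rows).T

    def sort_key(mark: str):
        m = _MARK_RE.match(mark)
        return (m.group(1), int(m.group(2)), m.group(3))

    return out.loc[sorted(out.index, key=sort_key)]


def acetyl_state_profile(r: pd.DataFrame, family: str = "H4:4-17") -> pd.DataFrame:
    """Summed abundance per acetylation state (0..max) of one peptide family.

    cell(k, sample) = sum of relative ratios of forms of ``family`` with
    exactly k acetylated lysines.  Columns partition the family, so they
    sum to 1 wherever the family is defined.
    """
    fam_keys = [k for k in r.index if k.startswith(family + ":")]
    if not fam_keys:
        raise ValueError(f"family {family!r} absent from table")
    ac_counts = [
        sum(1 for c in parse_form_key(k)[3].values() if c == "ac") for k in fam_keys
    ]
    sub = r.loc[fam_keys]
    out = sub.groupby(ac_counts, sort=True).sum(min_count=1)
    out.index = [f"{family}:{k}ac" for k in out.index]
    return out


def zscore_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row: (x - row mean) / row sample sd (ddof=1).

    Rows with zero spread (constant) become all zeros with a warning; NaN
    cells are ignored in the statistics and stay NaN.
    """
    mean = m.mean(axis=1)
    sd = m.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "zscore_rows: %d constant row(s) set to zero: %s",
            int(constant.sum()),
            list(m.index[constant])[:5],
        )
    sd = sd.replace(0, np.nan)
    z = m.sub(mean, axis=0).div(sd, axis=0)
    z.loc[constant] = z.loc[constant].where(m.loc[constant].isna(), 0.0)
    return z


def to_long_format(m: pd.DataFrame, value_name: str = "value") -> pd.DataFrame:
    """Heatmap-ready long format: one (row, sample, value) record per cell."""
    long = m.reset_index(names="row").melt(
        id_vars="row", var_name="sample", value_name=value_name
    )
    return long
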