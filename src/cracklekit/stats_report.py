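"""Group-comparison report: per-group means +/- SD and two-sample t-tests.

Produces the standard cohort-description table for crackle features: one
row per feature per breath phase with each group's mean and SD and the
p-value of an unpaired two-sample t-test against the reference group
(default IPF).  Welch's unequal-variance variant is the default since group
SDs generally differ; the pooled-variance classic form is available.  No
multiple-testing correction is applied — rows are flagged at raw p < .05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparisonRow", "compare_groups", "comparison_table"]

ALPHA = 0.05


@dataclass
class GroupComparisonRow:
    feature: str
    phase: str
    group_mean: dict[str, float]
    group_sd: dict[str, float]
    group_n: dict[str, int]
    p_values: dict[str, float]          # keyed by comparison group
    significant: dict[str, bool]
    degenerate: dict[str, bool]         # zero-variance comparison


def _welch_or_pooled(a: np.ndarray, b: np.ndarray, welch: bool
                     ) -> tuple[float, bool]:
    """Two-sample t-test p-value; degenerate (zero total variance) pairs
    report p = 1 with a flag rather than NaN."""
    if np.var(a, ddof=1) + np.var(b, ddof=1) <= 0:
        return (1.0, True) if np.mean(a) == np.mean(b) else (0.0, True)
    p = float(sps.ttest_ind(a, b, equal_var=not welch).pvalue)
    if np.isnan(p):
        return 1.0, True
    return p, False


def compare_groups(
    summaries: pd.DataFrame,
    features: list[str] | None = None,
    group_col: str = "group",
    phase_col: str = "phase",
    reference: str = "IPF",
    welch: bool = True,
) -> list[GroupComparisonRow]:
    """Compare per-patient feature summaries between groups.

    Parameters
    ----------
    summaries
        One row per patient (or per patient x phase when ``phase_col``
        exists) with a group label and numeric feature columns.
    features
        Columns to compare; defaults to every numeric column except
        bookkeeping ones.
    reference
        Each other group is tested against this one.

    Every group needs at least 2 patients.  Rows with p < .05 are flagged
    significant.
    """
    if group_col not in summaries.columns:
        raise ValueError(f"missing group column {group_col!r}")
    groups = list(pd.unique(summaries[group_col]))
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not present in data")
    counts = summaries.groupby(group_col).size()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups need >= 2 patients; too small: {small}")
    others = [g for g in groups if g != reference]
    phases = (list(pd.unique(summaries[phase_col]))
              if phase_col in summaries.columns else [None])
    if features is None:
        skip = {group_col, phase_col, "patient", "n_crackles", "missing"}
        features = [c for c in summaries.columns
                    if c not in skip
                    and pd.api.types.is_numeric_dtype(summaries[c])]

    rows = []
    for phase in phases:
        sub = summaries if phase is None else summaries[summaries[phase_col] == phase]
        for feat in features:
            vals = {g: sub.loc[sub[group_col] == g, feat].dropna().to_numpy(float)
                    for g in groups}
            mean = {g: float(np.mean(v)) if v.size else float("nan")
                    for g, v in vals.items()}
            sd = {g: float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
                  for g, v in vals.items()}
            n = {g: int(v.size) for g, v in vals.items()}
            pvals, sig, degen = {}, {}, {}
            for g in others:
                a, b = vals[reference], vals[g]
                if a.size < 2 or b.size < 2:
                    pvals[g], degen[g] = 1.0, True
                else:
                    pvals[g], degen[g] = _welch_or_pooled(a, b, welch)
                sig[g] = (pvals[g] < ALPHA) and not degen[g]
            rows.append(GroupComparisonRow(
                feature=feat, phase=phase if phase is not None else "all",
                group_mean=mean, group_sd=sd, group_n=n,
                p_values=pvals, significant=sig, degenerate=degen,
            ))
    return rows


def comparison_table(rows: list[GroupComparisonRow]) -> pd.DataFrame:
    """Flatten comparison rows into a table (one row per feature x phase)."""
    out = []
    for r in rows:
        rec = {"feature": r.feature, "phase": r.phase}
        for g, m in r.group_mean.items():
            rec[f"mean_{g}"] = m
            rec[f"sd_{g}"] = r.group_sd[g]
            rec[f"n_{g}"] = r.group_n[g]
        for g, p in r.p_values.items():
            rec[f"p_vs_{g}"] = p
            rec[f"sig_vs_{g}"] = r.significant[g]
        out.append(rec)
    return pd.DataFrame(out)
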