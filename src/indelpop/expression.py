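"""Relative expression by the Livak 2^-ddCT method and group comparison.

Per sample: dCT = CT(target) - CT(reference); ddCT = dCT - mean dCT of the
calibrator group; relative expression = 2^-ddCT.  By construction the
calibrator group's *mean dCT* maps to fold change 1.

Group comparisons are two-sided Welch t-tests on the fold-change scale (a
log2 option is available), with significance stars at 0.05 and 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidationError

logger = logging.getLogger("indelpop")

__all__ = ["ddct", "group_compare", "GroupComparison"]


def ddct(records: pd.DataFrame, calibrator: str) -> pd.DataFrame:
    """Compute per-sample relative expression against a calibrator group.

    Parameters
    ----------
    records : DataFrame
        CT table with columns sample_id, group, tissue, ct_target,
        ct_reference.  Rows with a missing CT are dropped with a warning.
    calibrator : str
        Group whose mean dCT anchors the ddCT scale (its mean fold change on
        the log scale is 1 by construction).

    Returns
    -------
    DataFrame with columns sample_id, group, tissue, delta_ct,
    delta_delta_ct, rel_expr.
    """
    df = records.copy()
    bad = df["ct_target"].isna() | df["ct_reference"].isna()
    if bad.any():
        logger.warning("dropping %d sample(s) with missing CT values", int(bad.sum()))
        df = df[~bad]
    if not (df["group"] == calibrator).any():
        raise ValidationError(f"calibrator group {calibrator!r} is empty")
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    calibrator_mean = df.loc[df["group"] == calibrator, "delta_ct"].mean()
    df["delta_delta_ct"] = df["delta_ct"] - calibrator_mean
    df["rel_expr"] = np.exp2(-df["delta_delta_ct"])
    return df[["sample_id", "group", "tissue", "delta_ct", "delta_delta_ct",
               "rel_expr"]].reset_index(drop=True)


@dataclass(frozen=True)
class GroupComparison:
    """Welch t-test comparison of relative expression between two groups."""

    group1: str
    group2: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sem1: float
    sem2: float
    p: float
    stars: str

    @property
    def fold_ratio(self) -> float:
        """Mean fold change of group1 relative to group2."""
        return self.mean1 / self.mean2


def _stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_compare(exprs: pd.DataFrame, g1: str, g2: str,
                  log_scale: bool = False) -> GroupComparison:
    """Compare mean relative expression of two groups (Welch two-sample t).

    ``log_scale=True`` performs the test on log2 fold change instead of the
    fold-change scale; means and SEMs are always reported on the fold scale.
    Each group needs at least two samples.
    """
    x1 = exprs.loc[exprs["group"] == g1, "rel_expr"].to_numpy(dtype=float)
    x2 = exprs.loc[exprs["group"] == g2, "rel_expr"].to_numpy(dtype=float)
    if len(x1) < 2 or len(x2) < 2:
        raise ValidationError(
            f"groups must have >= 2 samples (got {len(x1)} and {len(x2)})"
        )
    if log_scale:
        t1, t2 = np.log2(x1), np.log2(x2)
    else:
        t1, t2 = x1, x2
    if np.allclose(t1.var(ddof=1) + t2.var(ddof=1), 0) and np.isclose(t1.mean(), t2.mean()):
        p = 1.0  # identical constant groups: no evidence of difference
    else:
        p = float(stats.ttest_ind(t1, t2, equal_var=False).pvalue)
    return GroupComparison(
        group1=g1, group2=g2, n1=len(x1), n2=len(x2),
        mean1=float(x1.mean()), mean2=float(x2.mean()),
        sem1=float(x1.std(ddof=1) / np.sqrt(len(x1))),
        sem2=float(x2.std(ddof=1) / np.sqrt(len(x2))),
        p=p, stars=_stars(p),
    )
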