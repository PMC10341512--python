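"""Pairwise differential-abundance screening.

Fold changes are ratios of group means on the TSS scale (first-named group
over second); two-sample t-tests run on the log10 scale; Benjamini–Hochberg
adjustment is applied per comparison over all metabolites tested. A
metabolite is significant when the adjusted p falls below alpha AND the
fold change is at least the threshold in either direction
(FC >= thr or FC <= 1/thr) — the threshold is symmetric because depletion
is as informative as accumulation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable

logger = logging.getLogger("metamark")

__all__ = ["fold_change", "ttest_pair", "bh_adjust", "significance_filter",
           "univariate_screen"]


def _split(table: FeatureTable, comparison: tuple[str, str]):
    g1, g2 = comparison
    table.require_groups(g1, g2)
    labels = table.group_labels
    a = table.intensities.loc[(labels == g1).to_numpy()]
    b = table.intensities.loc[(labels == g2).to_numpy()]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"comparison {g1} vs {g2} needs >= 2 samples per group")
    return a, b


def fold_change(table: FeatureTable, comparison: tuple[str, str]) -> pd.Series:
    """Per-metabolite ratio of group means, first-named over second.

    Computed on the TSS scale, where the reported study-style fold changes
    are ratio-scaled.
    """
    if table.scale_state != "tss":
        raise ValueError("fold_change expects a tss-scale table")
    a, b = _split(table, comparison)
    denom = b.mean(axis=0)
    if (denom == 0).any():
        bad = list(denom.index[denom == 0])
        raise ZeroDivisionError(f"zero denominator group mean for {bad}")
    fc = a.mean(axis=0) / denom
    fc.name = "fold_change"
    return fc


def ttest_pair(table: FeatureTable, comparison: tuple[str, str],
               *, equal_var: bool = True) -> pd.Series:
    """Two-sided two-sample t-test p-value per metabolite on tss_log10 data.

    Pooled variance by default; Welch via ``equal_var=False``. Degenerate
    columns (zero variance in both groups, equal means) get p = 1 by
    convention and are logged.
    """
    if table.scale_state != "tss_log10":
        raise ValueError("ttest_pair expects a tss_log10-scale table")
    a, b = _split(table, comparison)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a.to_numpy(), b.to_numpy(), axis=0,
                              equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        names = [m for m, d in zip(a.columns, degenerate) if d]
        logger.info("zero-variance metabolites, p set to 1 by convention: %s",
                    names)
        p[degenerate] = 1.0
    out = pd.Series(p, index=a.columns, name="p_raw")
    return out


def bh_adjust(p_raw: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini–Hochberg step-up adjusted p-values (monotonicity enforced).

    The family is the full vector passed in — all metabolites of one
    pairwise comparison.
    """
    arr = np.asarray(p_raw, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    index = p_raw.index if isinstance(p_raw, pd.Series) else None
    return pd.Series(adj, index=index, name="p_adjusted")


def significance_filter(result: pd.DataFrame, *, alpha: float = 0.05,
                        fc_threshold: float = 1.5) -> pd.DataFrame:
    """Apply the joint FDR + fold-change rule to a univariate result table.

    Requires columns ``fold_change`` and ``p_adjusted``; returns the input
    with a boolean ``significant`` column added (adjusted p < alpha and FC
    outside (1/thr, thr)).
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    fc = result["fold_change"].to_numpy(dtype=float)
    padj = result["p_adjusted"].to_numpy(dtype=float)
    flag = (padj < alpha) & ((fc >= fc_threshold) | (fc <= 1.0 / fc_threshold))
    out = result.copy()
    out["significant"] = flag
    return out


def univariate_screen(tss: FeatureTable, tss_log10: FeatureTable,
                      comparison: tuple[str, str], *, alpha: float = 0.05,
                      fc_threshold: float = 1.5,
                      equal_var: bool = True) -> pd.DataFrame:
    """Full per-comparison univariate table: FC, raw p, BH-adjusted p, flag."""
    fc = fold_change(tss, comparison)
    p = ttest_pair(tss_log10, comparison, equal_var=equal_var)
    res = pd.DataFrame({"fold_change": fc, "p_raw": p,
                        "p_adjusted": bh_adjust(p)})
    res.index.name = "metabolite"
    return significance_filter(res, alpha=alpha, fc_threshold=fc_threshold)
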