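"""Metabolite–phenotype association screening.

Pearson product-moment correlation of each metabolite's log10 TSS
intensity against a per-sample behavioral phenotype (forced-swim-test
immobility seconds), with the two-sided p-value from the t-distributed
transform of r. The screening rule keeps |r| above a threshold (default
0.4) with p below alpha; no multiplicity adjustment is applied — the rule
is a plain threshold screen.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable

logger = logging.getLogger("metamark")

__all__ = ["pearson_by_metabolite", "correlation_filter"]


def pearson_by_metabolite(table: FeatureTable, phenotype: pd.Series) -> pd.DataFrame:
    """Per-metabolite Pearson r and two-sided p against the phenotype.

    ``phenotype`` must cover exactly the table's samples (aligned by index
    when indexed, by position otherwise). Constant metabolites have no
    defined correlation; they are reported as r = 0, p = 1 with
    ``degenerate=True`` and logged.
    """
    if table.scale_state != "tss_log10":
        raise ValueError("pearson_by_metabolite expects a tss_log10 table")
    y = pd.Series(phenotype)
    if isinstance(phenotype, pd.Series) and not y.index.equals(
            table.intensities.index):
        y = y.reindex(table.intensities.index)
        if y.isna().any():
            raise ValueError("phenotype index does not cover the table samples")
    if len(y) != table.n_samples:
        raise ValueError(f"phenotype length {len(y)} != n_samples "
                         f"{table.n_samples}")
    yv = y.to_numpy(dtype=float)
    if np.std(yv) == 0:
        raise ValueError("phenotype has zero variance")

    rows = []
    for metab in table.metabolite_ids:
        x = table.intensities[metab].to_numpy(dtype=float)
        if np.std(x) == 0:
            logger.info("constant metabolite %s: correlation undefined, "
                        "reported as r=0, p=1", metab)
            rows.append((metab, 0.0, 1.0, True))
            continue
        r, p = stats.pearsonr(x, yv)
        rows.append((metab, float(r), float(p), False))
    out = pd.DataFrame(rows, columns=["metabolite", "r", "p", "degenerate"])
    return out.set_index("metabolite")


def correlation_filter(result: pd.DataFrame, *, r_threshold: float = 0.4,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Keep metabolites with |r| > r_threshold and p < alpha, sorted by r."""
    if r_threshold <= 0:
        raise ValueError("r_threshold must be positive")
    keep = (result["r"].abs() > r_threshold) & (result["p"] < alpha)
    return result.loc[keep].sort_values("r")
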