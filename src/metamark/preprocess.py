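"""Missing-value handling and the normalization chain.

Order of operations: half-minimum imputation on the raw table (so TSS row
totals include the imputed mass), then total sum scaling (each sample's
intensities divided by their row total), then a base-10 log transform.
Fold changes downstream are computed on the ``tss`` scale; t-tests on
``tss_log10``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .io import FeatureTable

logger = logging.getLogger("metamark")

__all__ = ["impute_half_min", "tss_normalize", "log10_transform", "normalize_chain"]


def impute_half_min(table: FeatureTable) -> FeatureTable:
    """Replace each missing or zero cell by half the metabolite's minimum
    positive observed value.

    Zeros are treated as LC–MS non-detects. Metabolites with no positive
    observation carry no usable signal and are dropped with a warning.
    """
    if table.scale_state != "raw":
        raise ValueError("impute_half_min expects a raw-scale table")
    vals = table.intensities.to_numpy(copy=True)
    vals[vals <= 0] = np.nan
    col_min = np.nanmin(np.where(np.isnan(vals), np.inf, vals), axis=0)
    dead = ~np.isfinite(col_min)
    if dead.any():
        dropped = [m for m, d in zip(table.metabolite_ids, dead) if d]
        msg = f"dropping {len(dropped)} all-missing metabolite(s): {dropped}"
        warnings.warn(msg, stacklevel=2)
        logger.warning(msg)
    fill = np.broadcast_to(col_min / 2.0, vals.shape)
    vals = np.where(np.isnan(vals), fill, vals)
    out = table.intensities.copy()
    out.loc[:, :] = vals
    out = out.loc[:, ~dead]
    ann = table.annotations.loc[out.columns] if table.annotations is not None else None
    return table.replace(intensities=out, annotations=ann)


def tss_normalize(table: FeatureTable) -> FeatureTable:
    """Total sum scaling: divide each cell by its sample's row total.

    Requires a raw-scale table with strictly positive values (impute first);
    refuses to renormalize an already-normalized table.
    """
    if table.scale_state != "raw":
        raise ValueError(f"tss_normalize expects scale_state='raw', got "
                         f"{table.scale_state!r}; renormalizing is not allowed")
    vals = table.intensities.to_numpy()
    if np.isnan(vals).any() or (vals <= 0).any():
        raise ValueError("tss_normalize requires strictly positive values; "
                         "run impute_half_min first")
    totals = vals.sum(axis=1, keepdims=True)
    out = table.intensities / totals.ravel()[:, None]
    return table.replace(intensities=out, scale_state="tss")


def log10_transform(table: FeatureTable) -> FeatureTable:
    """Elementwise base-10 logarithm of a TSS-normalized table."""
    if table.scale_state != "tss":
        raise ValueError(f"log10_transform expects scale_state='tss', got "
                         f"{table.scale_state!r}")
    vals = table.intensities.to_numpy()
    if (vals <= 0).any():
        raise ValueError("non-positive value reached log10_transform; "
                         "the imputation/TSS chain should prevent this")
    return table.replace(intensities=np.log10(table.intensities),
                         scale_state="tss_log10")


def normalize_chain(table: FeatureTable) -> tuple[FeatureTable, FeatureTable]:
    """Run impute → TSS → log10; returns the (tss, tss_log10) pair used by
    the downstream stages."""
    tss = tss_normalize(impute_half_min(table))
    return tss, log10_transform(tss)
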