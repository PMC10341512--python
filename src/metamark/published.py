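"""Reported summary statistics from the motivating rat study.

The pipeline's defaults emulate an untargeted LC–HRMS metabolomics study of
the prefrontal cortex in chronically socially isolated (CSIS) rats with and
without fluoxetine (Flx) treatment: 117 identified metabolites over four
groups (Control, Control+Flx, CSIS, CSIS+Flx) of 6–8 animals. The study's
published per-metabolite summaries — fold changes with FDR-adjusted
p-values, per-metabolite ROC AUC values, and metabolite–immobility Pearson
correlations — are reproduced here as plain data. They serve two purposes:

* worked examples: the screening rules (`significance_filter`,
  `marker_screen` retention, `correlation_filter`) applied to these printed
  values must reproduce the study's reported counts (6 univariate hits for
  Flx efficacy, 4 CSIS markers, 10 Flx-efficacy markers);
* realistic defaults: the synthetic generator spikes its ground-truth
  metabolites at these fold-change magnitudes.

Each univariate record: (metabolite, fold change, raw p, adjusted p).
Fold change is the ratio of group means, first-named group over second.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "UNIVARIATE_REPORTED",
    "MARKER_AUC_REPORTED",
    "CORRELATION_REPORTED",
    "PLSDA_REPORTED",
    "univariate_reported",
    "marker_auc_reported",
    "correlation_reported",
]

GROUPS = ("Control", "Control+Flx", "CSIS", "CSIS+Flx")

COMPARISONS = (
    ("Control+Flx", "Control"),
    ("CSIS", "Control"),
    ("CSIS+Flx", "CSIS"),
)

# significantly changed metabolites per pairwise comparison:
# metabolite -> (FC, p_raw, p_adjusted)
UNIVARIATE_REPORTED: dict[tuple[str, str], dict[str, tuple[float, float, float]]] = {
    ("Control+Flx", "Control"): {
        "N-acetyl-L-arginine": (0.27, 1.00e-5, 1.20e-3),
        "Xanthine": (0.61, 1.95e-3, 3.80e-2),
        "N1-methylnicotinamide": (0.65, 7.26e-4, 2.12e-2),
        "Sedoheptulose-7-phosphate": (2.24, 1.09e-4, 2.56e-2),
        "2-hydroxyglutaric acid": (2.28, 6.84e-4, 2.12e-2),
        "Indoxylsulfate": (2.57, 2.49e-3, 4.16e-2),
        "Stachydrine": (5.08, 3.10e-5, 1.80e-3),
    },
    ("CSIS", "Control"): {
        "Myo-inositol": (1.56, 2.69e-4, 3.15e-2),
    },
    ("CSIS+Flx", "CSIS"): {
        "Sedoheptulose-7-phosphate": (2.40, 6.89e-4, 2.02e-2),
        "Hexanoylcarnitine": (0.45, 2.60e-4, 2.02e-2),
        "Xanthosine": (0.62, 6.83e-4, 2.02e-2),
        "Riboflavin": (0.64, 9.14e-4, 2.14e-2),
        "Hypotaurine": (1.62, 1.16e-3, 2.25e-2),
        "Acetyl-L-carnitine": (3.31, 5.24e-4, 2.02e-2),
    },
}

# best per-metabolite marker candidates: metabolite -> (AUC, p_raw, FC)
MARKER_AUC_REPORTED: dict[tuple[str, str], dict[str, tuple[float, float, float]]] = {
    ("CSIS", "Control"): {
        "Myo-inositol": (1.000, 2.69e-4, 1.56),
        "Methylnicotinamide": (0.95238, 2.40e-3, 0.75),
        "cAMP": (0.92857, 1.13e-2, 1.66),
        "NAD": (0.90476, 2.03e-2, 1.76),
    },
    ("CSIS+Flx", "CSIS"): {
        "Sedoheptulose-7-phosphate": (1.0, 6.89e-4, 2.40),
        "Hypotaurine": (0.98214, 1.16e-3, 1.62),
        "Riboflavin": (0.98214, 1.29e-3, 0.64),
        "Acetyl-L-carnitine": (0.96429, 5.24e-4, 3.31),
        "Hexanoylcarnitine": (0.96429, 2.60e-4, 0.45),
        "Xanthosine": (0.94643, 6.83e-4, 0.62),
        "Aconitate": (0.92857, 4.69e-3, 0.71),
        "Cytosine5": (0.91071, 2.98e-3, 1.39),
        "5-Methylcytosine": (0.91071, 5.77e-3, 0.76),
        "Myo-inositol": (0.91071, 3.57e-3, 0.76),
    },
}

# metabolite–immobility Pearson correlations: metabolite -> (r, p)
CORRELATION_REPORTED: dict[str, tuple[float, float]] = {
    "Sedoheptulose-7-phosphate": (-0.5698, 3.70e-3),
    "Indoxylsulfate": (-0.4942, 1.41e-2),
    "Cytosine": (-0.4642, 2.24e-2),
    "C6H13O9P": (-0.4622, 2.30e-2),
    "Urocanic acid": (-0.4517, 2.70e-2),
    "Saccharopine": (0.4093, 4.71e-2),
    "Adenosine diphosphoribose": (0.4121, 4.54e-2),
    "Acetylcholine": (0.4362, 3.31e-2),
    "Adenine": (0.4585, 2.43e-2),
    "Guanosine": (0.4667, 2.15e-2),
    "Acetylarginine": (0.4669, 2.15e-2),
    "NAD": (0.5001, 1.28e-2),
    "Riboflavin": (0.5359, 7.00e-3),
    "cAMP": (0.5521, 5.20e-3),
    "Myo-inositol": (0.5932, 2.30e-3),
}

# PLS-DA classifier performances per comparison: (n_components, R2, Q2, accuracy)
PLSDA_REPORTED: dict[tuple[str, str], tuple[int, float, float, float]] = {
    ("Control+Flx", "Control"): (5, 0.99953, 0.92444, 1.0),
    ("CSIS", "Control"): (5, 0.99587, 0.29245, 0.84615),
    ("CSIS+Flx", "CSIS"): (5, 0.99636, 0.86544, 1.0),
}


def univariate_reported(comparison: tuple[str, str]) -> pd.DataFrame:
    """Published (FC, p_raw, p_adjusted) rows for one comparison."""
    recs = UNIVARIATE_REPORTED[tuple(comparison)]
    return pd.DataFrame(
        [(m, fc, p, padj) for m, (fc, p, padj) in recs.items()],
        columns=["metabolite", "fold_change", "p_raw", "p_adjusted"],
    ).set_index("metabolite")


def marker_auc_reported(comparison: tuple[str, str]) -> pd.DataFrame:
    """Published per-metabolite marker AUC rows for one comparison."""
    recs = MARKER_AUC_REPORTED[tuple(comparison)]
    return pd.DataFrame(
        [(m, a, p, fc) for m, (a, p, fc) in recs.items()],
        columns=["metabolite", "auc", "p_raw", "fold_change"],
    ).set_index("metabolite")


def correlation_reported() -> pd.DataFrame:
    """Published metabolite–immobility Pearson correlations."""
    return pd.DataFrame(
        [(m, r, p) for m, (r, p) in CORRELATION_REPORTED.items()],
        columns=["metabolite", "r", "p"],
    ).set_index("metabolite")
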