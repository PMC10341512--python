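"""Per-metabolite classical ROC marker screening.

Each metabolite is scored alone as a binary classifier between the two
groups of a comparison. The raw AUC is the Mann–Whitney probability that a
random positive-class sample exceeds a random negative-class sample (ties
counted half); the oriented AUC max(A, 1−A) records which direction
discriminates, because a depleted metabolite is as good a marker as an
accumulated one. The optimal cutoff is the threshold closest to the
perfect-classification corner (0, 1) of the ROC plane, and the AUC
confidence interval is a stratified percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .io import FeatureTable

__all__ = ["RocMarkerResult", "auc", "roc_points", "optimal_cutoff",
           "auc_ci_bootstrap", "marker_screen", "marker_table"]


def auc(values, labels) -> float:
    """Raw AUC: P(random positive > random negative), ties counted 1/2.

    Computed through the rank-sum (Mann–Whitney) identity; ``labels`` are
    boolean with True = positive class.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    ranks = stats.rankdata(values)
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_points(values, labels) -> pd.DataFrame:
    """ROC curve points (1−specificity, sensitivity) plus thresholds.

    Starts at (0, 0) and ends at (1, 1); both coordinates non-decreasing.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    fpr, tpr, thr = roc_curve(labels, values, drop_intermediate=False)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def optimal_cutoff(curve: pd.DataFrame) -> tuple[float, float, float]:
    """Threshold minimizing the distance to the (0, 1) ROC corner.

    Returns (threshold, sensitivity, specificity); ties broken toward the
    higher specificity (lower false-positive rate). The endpoint pseudo-
    threshold at (0, 0) is excluded: classifying everything negative is not
    a usable cutoff.
    """
    if len(curve) < 2:
        raise ValueError("degenerate single-point ROC curve")
    fpr = curve["fpr"].to_numpy(dtype=float)
    tpr = curve["tpr"].to_numpy(dtype=float)
    thr = curve["threshold"].to_numpy(dtype=float)
    dist = np.sqrt((1.0 - tpr) ** 2 + fpr ** 2)
    order = np.lexsort((fpr, dist))          # min distance, then min fpr
    best = order[0]
    return float(thr[best]), float(tpr[best]), float(1.0 - fpr[best])


def auc_ci_bootstrap(values, labels, n_boot: int = 500,
                     seed: int = 0) -> tuple[float, float]:
    """95% percentile bootstrap interval for the raw AUC.

    Samples are resampled with replacement within each class (stratified),
    so every replicate keeps both classes populated. The upper bound is
    clipped at 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = values[labels], values[~labels]
    if len(pos) < 3 or len(neg) < 3:
        raise ValueError("bootstrap needs >= 3 samples per class")
    rng = np.random.default_rng(seed)
    n_pos, n_neg = len(pos), len(neg)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        p = pos[rng.integers(0, n_pos, n_pos)]
        n = neg[rng.integers(0, n_neg, n_neg)]
        # vectorized pair count: mean over all pos x neg pairs, ties half
        diff = p[:, None] - n[None, :]
        boots[b] = (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (n_pos * n_neg)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(lo), float(min(hi, 1.0))


@dataclass
class RocMarkerResult:
    """Single-metabolite marker assessment for one comparison."""

    metabolite: str
    auc_oriented: float
    auc_raw: float
    direction: str            # which group runs higher: "case-high"/"control-high"
    curve: pd.DataFrame
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    ci95: tuple[float, float]


def marker_screen(table: FeatureTable, comparison: tuple[str, str],
                  *, auc_threshold: float = 0.9, n_boot: int = 500,
                  seed: int = 0) -> list[RocMarkerResult]:
    """Screen every metabolite as a single marker; rank by oriented AUC.

    The positive class is the first-named group. For metabolites running
    higher in the second group the value axis is flipped before the curve
    and cutoff are computed, so the oriented AUC is max(A, 1−A) and
    direction records the flip. Retained markers are those with oriented
    AUC strictly above ``auc_threshold``; the returned list holds all
    metabolites sorted by descending oriented AUC (ties alphabetical).
    """
    if table.scale_state != "tss_log10":
        raise ValueError("marker_screen expects a tss_log10-scale table")
    g1, g2 = comparison
    sub = table.subset_groups(g1, g2)
    labels = (sub.group_labels == g1).to_numpy()
    results: list[RocMarkerResult] = []
    rng = np.random.default_rng(seed)
    for metab in sub.metabolite_ids:
        values = sub.intensities[metab].to_numpy(dtype=float)
        a_raw = auc(values, labels)
        flip = a_raw < 0.5
        oriented_vals = -values if flip else values
        curve = roc_points(oriented_vals, labels)
        thr, sens, spec = optimal_cutoff(curve)
        if flip:
            thr = -thr
        ci = auc_ci_bootstrap(oriented_vals, labels, n_boot=n_boot,
                              seed=int(rng.integers(0, 2**31 - 1)))
        results.append(RocMarkerResult(
            metabolite=metab,
            auc_oriented=max(a_raw, 1.0 - a_raw),
            auc_raw=a_raw,
            direction="control-high" if flip else "case-high",
            curve=curve,
            cutoff=thr,
            sens_at_cutoff=sens,
            spec_at_cutoff=spec,
            ci95=ci))
    results.sort(key=lambda r: (-r.auc_oriented, r.metabolite))
    return results


def marker_table(results: list[RocMarkerResult],
                 univariate: pd.DataFrame | None = None,
                 *, auc_threshold: float = 0.9) -> pd.DataFrame:
    """Flat summary of a marker screen, optionally joined with the
    univariate fold change and raw p for the same comparison."""
    rows = []
    for r in results:
        rows.append({"metabolite": r.metabolite, "auc": r.auc_oriented,
                     "auc_raw": r.auc_raw, "direction": r.direction,
                     "cutoff": r.cutoff, "sensitivity": r.sens_at_cutoff,
                     "specificity": r.spec_at_cutoff,
                     "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                     "retained": r.auc_oriented > auc_threshold})
    out = pd.DataFrame(rows).set_index("metabolite")
    if univariate is not None:
        out = out.join(univariate[["fold_change", "p_raw"]])
    return out
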