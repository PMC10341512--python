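"""Synthetic feature tables and behavioral phenotypes with known ground truth.

The generator emulates the statistical structure of a four-group rodent
chronic-stress metabolomics experiment: 117 metabolites over groups
Control, Control+Flx, CSIS, CSIS+Flx with 6–8 animals each. Peak areas are
log-normal around a per-metabolite baseline, multiplied by a per-group fold
change (the ground-truth effect), a per-sample total-intensity drift factor
(which total sum scaling removes exactly), and within-group log-normal
noise. A fraction of cells is blanked uniformly at random to mimic
non-detects. The forced-swim-test immobility phenotype is a group-level
baseline plus a residual coupled to chosen metabolites' standardized log
intensities so that its population correlation with each coupled metabolite
equals a chosen target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable
from .published import GROUPS, UNIVARIATE_REPORTED

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "default_effects",
    "default_spec",
    "simulate_feature_table",
    "simulate_phenotype",
    "classify_responders",
]


def default_effects() -> dict[str, dict[str, float]]:
    """Ground-truth fold changes emulating the motivating study.

    Multipliers are expressed per group relative to the Control baseline;
    a metabolite reported changed in CSIS+Flx vs CSIS gets multiplier
    FC × (its CSIS multiplier).
    """
    effects: dict[str, dict[str, float]] = {}
    for (g1, g2), recs in UNIVARIATE_REPORTED.items():
        for metab, (fc, _p, _padj) in recs.items():
            per_group = effects.setdefault(metab, {})
            base = per_group.get(g2, 1.0) if g2 != "Control" else 1.0
            per_group[g1] = fc * base
    return effects


@dataclass
class SimulationSpec:
    """Ground-truth description of one synthetic experiment.

    ``effects`` maps metabolite → group → multiplicative fold change on the
    raw scale (relative to the Control baseline). ``couplings`` maps
    metabolite → target Pearson r with the immobility phenotype.
    ``baseline_log_mean_range`` and the log-sd parameters are in natural-log
    units; immobility is in seconds.
    """

    n_per_group: int = 7
    groups: tuple[str, ...] = GROUPS
    n_metabolites: int = 117
    baseline_log_mean_range: tuple[float, float] = (10.0, 16.0)
    within_log_sd: float = 0.25
    sample_size_factor_sd: float = 0.15
    missing_rate: float = 0.02
    effects: dict = field(default_factory=dict)
    metabolite_names: tuple[str, ...] | None = None
    phenotype_base: float = 150.0
    group_shift: dict = field(default_factory=dict)
    phenotype_sd: float = 30.0
    couplings: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3: smaller groups make "
                             "downstream cross-validation infeasible")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        for metab, per_group in self.effects.items():
            for g, fc in per_group.items():
                if fc <= 0:
                    raise ValueError(f"fold change for {metab}/{g} must be > 0")
                if g not in self.groups:
                    raise ValueError(f"effect group {g!r} not in {self.groups}")
        r2 = sum(r * r for r in self.couplings.values())
        if any(abs(r) >= 1 for r in self.couplings.values()) or r2 >= 1:
            raise ValueError("coupling targets must satisfy |r| < 1 and "
                             "sum(r^2) < 1")

    def metabolites(self) -> list[str]:
        if self.metabolite_names is not None:
            names = list(self.metabolite_names)
            if len(names) != self.n_metabolites:
                raise ValueError("metabolite_names length mismatch")
            return names
        named = list(dict.fromkeys(list(self.effects) + list(self.couplings)))
        if len(named) > self.n_metabolites:
            raise ValueError("more named effect metabolites than n_metabolites")
        fillers = [f"metabolite_{i:03d}" for i in range(1, self.n_metabolites + 1)]
        taken = set(named)
        out = named + [f for f in fillers if f not in taken]
        return out[: self.n_metabolites]


@dataclass
class GroundTruth:
    """Deterministic truth underlying one simulated experiment."""

    effects: dict                      # metabolite -> group -> multiplier
    true_fold_change: dict             # comparison -> metabolite -> FC
    coupled: dict                      # metabolite -> target r
    baseline_log_mean: pd.Series
    sample_factors: pd.Series

    def differential_set(self, comparison: tuple[str, str]) -> set[str]:
        """Metabolites with a non-unit injected fold change in a comparison."""
        fcs = self.true_fold_change[tuple(comparison)]
        return {m for m, fc in fcs.items() if fc != 1.0}


def default_spec(seed: int = 0, **overrides) -> SimulationSpec:
    """Study-like defaults: published effect sizes, immobility elevated under
    chronic isolation and partially rescued by treatment, myo-inositol
    coupled to immobility at r = 0.59."""
    kw = dict(
        effects=default_effects(),
        group_shift={"Control": 0.0, "Control+Flx": 0.0,
                     "CSIS": 60.0, "CSIS+Flx": 15.0},
        couplings={"Myo-inositol": 0.59},
        seed=seed,
    )
    kw.update(overrides)
    return SimulationSpec(**kw)


def _effect_matrix(spec: SimulationSpec, metabolites: list[str]) -> np.ndarray:
    groups = list(spec.groups)
    eff = np.ones((len(groups), len(metabolites)))
    col = {m: j for j, m in enumerate(metabolites)}
    for metab, per_group in spec.effects.items():
        if metab not in col:
            raise ValueError(f"effect metabolite {metab!r} not in table")
        for g, fc in per_group.items():
            eff[groups.index(g), col[metab]] = fc
    return eff


def simulate_feature_table(spec: SimulationSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw one synthetic raw-scale feature table plus its ground truth.

    intensity(i, j) = exp(mu_j) * effect(group_i, j) * drift_i * lognormal
    noise, with ``missing_rate`` of cells blanked to NaN. Identical specs
    (including seed) give identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    metabolites = spec.metabolites()
    groups = list(spec.groups)
    n = spec.n_per_group * len(groups)
    m = spec.n_metabolites

    lo, hi = spec.baseline_log_mean_range
    mu = rng.uniform(lo, hi, size=m)
    drift = np.exp(rng.normal(0.0, spec.sample_size_factor_sd, size=n))
    noise = np.exp(rng.normal(0.0, spec.within_log_sd, size=(n, m)))

    labels = np.repeat(groups, spec.n_per_group)
    sample_ids = [f"{g}_{k + 1:02d}" for g in groups
                  for k in range(spec.n_per_group)]
    eff = _effect_matrix(spec, metabolites)
    group_idx = np.repeat(np.arange(len(groups)), spec.n_per_group)
    values = np.exp(mu)[None, :] * eff[group_idx] * drift[:, None] * noise

    if spec.missing_rate > 0:
        mask = rng.uniform(size=(n, m)) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    annotations = pd.DataFrame(
        {"retention_time_min": rng.uniform(1.0, 18.0, size=m),
         "mz": rng.uniform(80.0, 900.0, size=m)},
        index=metabolites)
    table = FeatureTable(
        pd.DataFrame(values, index=sample_ids, columns=metabolites),
        pd.Series(labels, index=sample_ids),
        scale_state="raw",
        annotations=annotations)

    col = {mname: j for j, mname in enumerate(metabolites)}
    true_fc: dict[tuple[str, str], dict[str, float]] = {}
    for i, g1 in enumerate(groups):
        for j, g2 in enumerate(groups):
            if i == j:
                continue
            gi, gj = groups.index(g1), groups.index(g2)
            true_fc[(g1, g2)] = {mname: eff[gi, col[mname]] / eff[gj, col[mname]]
                                 for mname in metabolites}
    truth = GroundTruth(
        effects={mname: dict(per) for mname, per in spec.effects.items()},
        true_fold_change=true_fc,
        coupled=dict(spec.couplings),
        baseline_log_mean=pd.Series(mu, index=metabolites),
        sample_factors=pd.Series(drift, index=sample_ids))
    return table, truth


def simulate_phenotype(table: FeatureTable, spec: SimulationSpec) -> pd.Series:
    """Immobility seconds per sample, coupled to chosen metabolites.

    y_i = base + shift(group_i) + sd * (sum_m r_m z_m,i + sqrt(1 - sum r^2) e_i)

    where z_m is the metabolite's standardized log intensity across the
    table's samples, computed on the total-sum-scaled values so the
    per-sample drift factor (an artifact of injection amount, removed by
    normalization before any correlation is measured) does not dilute the
    coupling. For independent coupled metabolites each population
    correlation corr(y_residual, z_m) equals r_m; with a single coupled
    metabolite this is the classic construction y ∝ r z + sqrt(1-r^2) e.
    """
    missing = [m for m in spec.couplings if m not in table.intensities.columns]
    if missing:
        raise KeyError(f"coupled metabolite(s) absent from table: {missing}")
    rng = np.random.default_rng([spec.seed, 202])
    n = table.n_samples
    shift = table.group_labels.map(lambda g: spec.group_shift.get(g, 0.0))
    vals = table.intensities.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        vals = np.where(np.isnan(vals) | (vals <= 0), np.nan, vals)
    row_totals = np.nansum(vals, axis=1)
    resid = np.zeros(n)
    r2 = 0.0
    for metab, r in spec.couplings.items():
        x = vals[:, table.metabolite_ids.index(metab)] / row_totals
        logx = np.log(x)
        mu, sd = np.nanmean(logx), np.nanstd(logx)
        z = np.where(np.isnan(logx), 0.0, (logx - mu) / (sd if sd > 0 else 1.0))
        resid += r * z
        r2 += r * r
    eps = rng.normal(size=n)
    resid = resid + np.sqrt(1.0 - r2) * eps
    y = spec.phenotype_base + shift.to_numpy(dtype=float) + spec.phenotype_sd * resid
    return pd.Series(y, index=table.intensities.index, name="immobility_s")


def classify_responders(immobility: pd.DataFrame, design: pd.Series,
                        *, reference_week: int = 6,
                        csis_reference: float | None = None,
                        threshold: float = 0.20,
                        stressed_group: str = "CSIS",
                        treated_group: str = "CSIS+Flx") -> pd.Series:
    """Designate each animal from its week-0/3/6 immobility trajectory.

    A vehicle-treated stressed animal is designated ``CSIS`` when immobility
    at BOTH week 3 and week 6 exceeds its baseline by more than the
    threshold (default 20%); otherwise it is ``CSIS-resilient``. A treated
    stressed animal is a ``Flx-responder`` when its week-6 immobility lies
    more than the threshold below the stressed-group reference (mean
    immobility of the CSIS-designated animals at ``reference_week``, 3 or
    6); otherwise ``Flx-resilient``. Control animals keep their group label.
    """
    cols = {0: None, 3: None, 6: None}
    for wk in cols:
        for cand in (wk, f"week{wk}", f"week_{wk}", str(wk)):
            if cand in immobility.columns:
                cols[wk] = cand
                break
        if cols[wk] is None:
            raise ValueError(f"immobility table lacks a week-{wk} column")
    if immobility[list(cols.values())].isna().any().any():
        raise ValueError("missing immobility time point")
    if reference_week not in (3, 6):
        raise ValueError("reference_week must be 3 or 6")
    w0 = immobility[cols[0]]
    w3 = immobility[cols[3]]
    w6 = immobility[cols[6]]
    design = pd.Series(design, index=immobility.index)

    out = design.astype(object).copy()
    stressed = design == stressed_group
    up = (w3 > (1 + threshold) * w0) & (w6 > (1 + threshold) * w0)
    out[stressed & up] = stressed_group
    out[stressed & ~up] = f"{stressed_group}-resilient"

    treated = design == treated_group
    if csis_reference is None and treated.any():
        designated = stressed & up
        if not designated.any():
            raise ValueError("no CSIS-designated animals to define the "
                             "responder reference; pass csis_reference")
        ref_col = w3 if reference_week == 3 else w6
        csis_reference = float(ref_col[designated].mean())
    elif csis_reference is None:
        csis_reference = np.inf   # unused: no treated animals present
    down = w6 < (1 - threshold) * csis_reference
    out[treated & down] = "Flx-responder"
    out[treated & ~down] = "Flx-resilient"
    return out
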