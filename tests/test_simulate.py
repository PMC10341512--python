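"""Synthetic-data generator: determinism, effect injection, phenotype
coupling and responder designation."""

import numpy as np
import pandas as pd
import pytest

from metamark import (SimulationSpec, classify_responders, normalize_chain,
                      pearson_by_metabolite, simulate_feature_table,
                      simulate_phenotype)


class TestFeatureTableGenerator:
    def test_identical_seeds_identical_tables(self):
        spec = SimulationSpec(seed=11)
        t1, g1 = simulate_feature_table(spec)
        t2, g2 = simulate_feature_table(SimulationSpec(seed=11))
        pd.testing.assert_frame_equal(t1.intensities, t2.intensities)
        pd.testing.assert_series_equal(g1.baseline_log_mean,
                                       g2.baseline_log_mean)

    def test_null_model_log_ratios_center_at_zero(self):
        spec = SimulationSpec(n_per_group=40, groups=("A", "B"),
                              n_metabolites=60, missing_rate=0.0,
                              sample_size_factor_sd=0.0, seed=5)
        table, _ = simulate_feature_table(spec)
        a = table.intensities[(table.group_labels == "A").to_numpy()]
        b = table.intensities[(table.group_labels == "B").to_numpy()]
        log_fc = np.log(a.mean(axis=0) / b.mean(axis=0))
        # sd of a null log ratio at n=40 is ~0.25*sqrt(2/40) ~ 0.056
        assert abs(log_fc.mean()) < 0.03
        assert np.abs(log_fc).mean() < 0.1

    def test_spiked_fold_change_recovered_on_raw_scale(self):
        ratios = []
        for seed in range(100):
            spec = SimulationSpec(
                seed=seed, missing_rate=0.0,
                effects={"hit": {"CSIS+Flx": 2.4}})
            table, _ = simulate_feature_table(spec)
            g = table.group_labels
            a = table.intensities.loc[(g == "CSIS+Flx").to_numpy(), "hit"]
            b = table.intensities.loc[(g == "CSIS").to_numpy(), "hit"]
            ratios.append(a.mean() / b.mean())
        assert 1.8 < np.mean(ratios) < 3.2

    def test_ground_truth_differential_sets(self):
        spec = SimulationSpec(effects={"up": {"B": 2.0}, "dn": {"B": 0.5}},
                              groups=("A", "B"), seed=0)
        _, truth = simulate_feature_table(spec)
        assert truth.differential_set(("B", "A")) == {"up", "dn"}
        assert truth.true_fold_change[("B", "A")]["up"] == 2.0
        assert truth.true_fold_change[("A", "B")]["dn"] == 2.0

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="cross-validation"):
            SimulationSpec(n_per_group=2)

    def test_missing_rate_injected(self):
        spec = SimulationSpec(missing_rate=0.1, seed=2)
        table, _ = simulate_feature_table(spec)
        frac = np.isnan(table.intensities.to_numpy()).mean()
        assert 0.05 < frac < 0.15


class TestPhenotype:
    def test_zero_coupling_gives_null_correlation(self):
        rs = []
        for seed in range(100):
            spec = SimulationSpec(seed=seed, groups=("A", "B"),
                                  n_metabolites=5, missing_rate=0.0,
                                  couplings={"m": 0.0})
            table, _ = simulate_feature_table(spec)
            y = simulate_phenotype(table, spec)
            x = np.log(table.intensities["m"].to_numpy())
            rs.append(np.corrcoef(x, y)[0, 1])
        assert abs(np.mean(rs)) < 2 / np.sqrt(14)

    def test_target_correlation_recovered(self):
        """Coupling at r=0.59, n=24: sampling mean of empirical r."""
        rs = []
        for seed in range(200):
            spec = SimulationSpec(seed=seed, n_per_group=12,
                                  groups=("Control", "CSIS"),
                                  n_metabolites=30, missing_rate=0.0,
                                  couplings={"Myo-inositol": 0.59})
            table, _ = simulate_feature_table(spec)
            y = simulate_phenotype(table, spec)
            _, tlog = normalize_chain(table)
            r = pearson_by_metabolite(tlog, y).loc["Myo-inositol", "r"]
            rs.append(r)
        assert 0.45 < np.mean(rs) < 0.70

    def test_near_degenerate_coupling_approaches_unity(self):
        spec = SimulationSpec(seed=4, groups=("A", "B"), n_metabolites=5,
                              missing_rate=0.0, couplings={"m": 0.9999})
        table, _ = simulate_feature_table(spec)
        y = simulate_phenotype(table, spec)
        _, tlog = normalize_chain(table)
        assert pearson_by_metabolite(tlog, y).loc["m", "r"] > 0.99

    def test_coupled_metabolite_must_exist(self):
        spec = SimulationSpec(seed=0, couplings={"absent_one": 0.5},
                              metabolite_names=tuple(
                                  f"m{i}" for i in range(117)))
        table, _ = simulate_feature_table(
            SimulationSpec(seed=0, metabolite_names=tuple(
                f"m{i}" for i in range(117))))
        with pytest.raises(KeyError, match="absent_one"):
            simulate_phenotype(table, spec)

    def test_coupling_budget_validated(self):
        with pytest.raises(ValueError, match="r"):
            SimulationSpec(couplings={"a": 0.8, "b": 0.7})


class TestResponderDesignation:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["week0", "week3", "week6"])

    def test_sustained_increase_designates_csis(self):
        imm = self._frame([[100.0, 125.0, 130.0]])
        out = classify_responders(imm, pd.Series(["CSIS"]))
        assert list(out) == ["CSIS"]

    def test_insufficient_increase_is_resilient(self):
        imm = self._frame([[100.0, 115.0, 130.0]])
        out = classify_responders(imm, pd.Series(["CSIS"]))
        assert list(out) == ["CSIS-resilient"]

    def test_decline_below_reference_is_responder(self):
        imm = self._frame([[100.0, 140.0, 150.0]])
        out = classify_responders(imm, pd.Series(["CSIS+Flx"]),
                                  csis_reference=200.0)
        assert list(out) == ["Flx-responder"]
        out = classify_responders(self._frame([[100.0, 140.0, 170.0]]),
                                  pd.Series(["CSIS+Flx"]),
                                  csis_reference=200.0)
        assert list(out) == ["Flx-resilient"]

    def test_reference_defaults_to_designated_csis_mean(self):
        imm = self._frame([
            [100.0, 130.0, 200.0],   # designated CSIS
            [100.0, 125.0, 130.0],   # designated CSIS
            [100.0, 140.0, 120.0],   # treated: 120 < 0.8*165 -> responder
        ])
        design = pd.Series(["CSIS", "CSIS", "CSIS+Flx"])
        out = classify_responders(imm, design)
        assert list(out) == ["CSIS", "CSIS", "Flx-responder"]
        # week-3 reference: mean(130, 125)=127.5; 120 > 0.8*127.5=102 -> resilient
        out3 = classify_responders(imm, design, reference_week=3)
        assert list(out3) == ["CSIS", "CSIS", "Flx-resilient"]

    def test_missing_time_point_rejected(self):
        imm = self._frame([[100.0, np.nan, 130.0]])
        with pytest.raises(ValueError, match="missing"):
            classify_responders(imm, pd.Series(["CSIS"]))
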