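"""Sweeps, treatment summaries, ANOVA + Tukey letters, density maps."""

import numpy as np
import pandas as pd
import pytest

from polyestab.config import SimulationConfig
from polyestab.environment import LayerSpec, SyntheticEnvSpec
from polyestab.experiments import (
    ExperimentDesign,
    ExperimentError,
    anova_f,
    compare_treatments,
    config_for_level,
    establishment_efficiency,
    replicate_seed,
    run_experiment,
    spe_density_map,
    summarize_treatments,
    treatment_report,
)
from polyestab.reproduction import MatingConfig


def _tiny_config() -> SimulationConfig:
    """A miniature landscape + short clock, for shape/contract tests."""
    cfg = SimulationConfig()
    layers = list(cfg.env.layers)
    layers[3] = LayerSpec(22.0, 5.0, 6.0, 40.0, 20.0)
    layers[4] = LayerSpec(9.0, 3.0, 6.0, 24.0, 20.0)
    cfg.env = SyntheticEnvSpec(width=40, height=40, layers=tuple(layers))
    cfg.mating = MatingConfig(onset_generation=20)
    cfg.horizon_after_onset = 30
    return cfg


class TestDesignAndLevels:
    def test_unknown_family_rejected(self):
        with pytest.raises(ExperimentError):
            ExperimentDesign(family="hexaploidy")

    def test_invalid_level_rejected(self):
        with pytest.raises(ExperimentError):
            ExperimentDesign(family="selfing", levels=(1.5,), replicates=2)
        with pytest.raises(ExperimentError):
            config_for_level("unreduced", -0.1, SimulationConfig())
        with pytest.raises(ExperimentError):
            config_for_level("tolerance", 0.0, SimulationConfig())

    def test_level_application(self):
        base = SimulationConfig()
        cfg = config_for_level("unreduced", 0.2, base)
        assert cfg.mating.unreduced_rate_2x == 0.2
        cfg = config_for_level("selfing", 0.75, base)
        assert cfg.mating.selfing_rate[4] == 0.75
        assert cfg.mating.selfing_rate[2] == 0.0  # diploids stay self-sterile
        cfg = config_for_level("mixed", 0.25, base)
        assert cfg.mating.apomixis_rate[4] == 0.25
        assert cfg.mating.selfing_rate[4] == 0.75  # remainder selfing, no outcrossing
        cfg = config_for_level("tolerance", 1.5, base)
        assert cfg.tolerance.limit_multiplier_4x == 1.5
        assert all(v == 0.0 for v in cfg.mating.selfing_rate.values())
        cfg = config_for_level("shifted_optimum", 20.0, base)
        assert cfg.shift_distance == 20.0
        assert base.shift_distance is None  # base untouched

    def test_seed_policy_reproducible_and_distinct(self):
        s1 = replicate_seed(0, "unreduced", 0.2, 3)
        assert s1 == replicate_seed(0, "unreduced", 0.2, 3)
        assert s1 != replicate_seed(0, "unreduced", 0.2, 4)
        assert s1 != replicate_seed(0, "selfing", 0.2, 3)
        assert 0 <= s1 < 2**31

    def test_sweep_table_shape(self):
        design = ExperimentDesign(
            family="unreduced", levels=(0.006, 0.2), replicates=2,
            base_config=_tiny_config(), root_seed=1,
        )
        table = run_experiment(design)
        assert len(table) == 4
        assert set(table["level"]) == {0.006, 0.2}
        for col in ("spe", "upe", "bilateral", "unilateral", "final_4x", "stop_reason"):
            assert col in table.columns
        # replays identically
        assert table.equals(run_experiment(design))


class TestSummaries:
    def _toy_table(self):
        rows = []
        for level, values in [(1.0, (1, 2, 3)), (2.0, (4, 4, 4))]:
            for rep, v in enumerate(values):
                rows.append(
                    dict(family="unreduced", level=level, replicate=rep, spe=v,
                         upe=2 * v, bilateral=v, unilateral=v, final_4x=0.5,
                         gpip=np.nan, guf=np.nan)
                )
        return pd.DataFrame(rows)

    def test_mean_and_sd_closed_form(self):
        summary = summarize_treatments(self._toy_table())
        row = summary[summary["level"] == 1.0].iloc[0]
        assert row["spe_mean"] == pytest.approx(2.0)
        assert row["spe_sd"] == pytest.approx(1.0)
        row2 = summary[summary["level"] == 2.0].iloc[0]
        assert row2["spe_sd"] == 0.0

    def test_undefined_guf_reported_as_na(self):
        summary = summarize_treatments(self._toy_table())
        assert summary["guf_mean"].isna().all()

    def test_empty_table_rejected(self):
        with pytest.raises(ExperimentError):
            summarize_treatments(pd.DataFrame())


class TestTreatmentComparison:
    def test_anova_f_hand_computed(self):
        # groups (1,2,3), (2,3,4), (7,8,9): SSB = 62, SSW = 6, F = (62/2)/(6/6) = 31
        f, p = anova_f([np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([7.0, 8, 9])])
        assert f == pytest.approx(31.0, abs=1e-6)
        assert p < 0.01

    def _table(self, groups: dict) -> pd.DataFrame:
        rows = []
        for level, values in groups.items():
            for rep, v in enumerate(values):
                rows.append(dict(level=level, replicate=rep, spe=v))
        return pd.DataFrame(rows)

    def test_identical_distributions_share_a_letter(self):
        t = self._table({1.0: [5, 6, 7, 5, 6, 7], 2.0: [5, 6, 7, 5, 6, 7]})
        letters = compare_treatments(t, "spe")
        assert letters[1.0] == letters[2.0]

    def test_forced_separation_gets_distinct_letters(self):
        rng = np.random.default_rng(0)
        t = self._table(
            {1.0: 0.0 + 0.01 * rng.random(6), 2.0: 10.0 + 0.01 * rng.random(6)}
        )
        letters = compare_treatments(t, "spe")
        assert letters[1.0] != letters[2.0]

    def test_zero_variance_equal_means_one_letter(self):
        t = self._table({1.0: [3, 3, 3], 2.0: [3, 3, 3]})
        letters = compare_treatments(t, "spe")
        assert letters[1.0] == letters[2.0]

    def test_letters_deterministic(self):
        rng = np.random.default_rng(1)
        groups = {lv: lv * 3 + rng.random(5) for lv in (1.0, 2.0, 3.0)}
        t = self._table(groups)
        assert compare_treatments(t, "spe") == compare_treatments(t, "spe")

    def test_middle_group_can_share_both_letters(self):
        rng = np.random.default_rng(2)
        t = self._table(
            {1.0: rng.normal(0, 1, 8), 2.0: rng.normal(1.6, 1, 8), 3.0: rng.normal(3.2, 1, 8)}
        )
        letters = compare_treatments(t, "spe", alpha=0.01)
        # extremes differ; all letters non-empty
        assert set(letters[1.0]).isdisjoint(set(letters[3.0]))
        assert all(letters.values())

    def test_report_merges_letters(self):
        t = self._table({1.0: [0, 0, 1], 2.0: [8, 9, 10]})
        t[["upe", "bilateral", "unilateral", "final_4x"]] = 0.0
        t[["gpip", "guf"]] = np.nan
        t["family"] = "unreduced"
        rep = treatment_report(t, responses=("spe",))
        assert "spe_letters" in rep.columns


class TestMapsAndEfficiency:
    def test_density_map_conserves_mass(self):
        locs = [(1, 2), (1, 2), (3, 4)]
        grid = spe_density_map(locs, (10, 10))
        assert grid.sum() == 3
        assert grid[2, 1] == 2 and grid[4, 3] == 1

    def test_density_map_empty(self):
        table = pd.DataFrame({"first_spe_x": [np.nan], "first_spe_y": [np.nan]})
        grid = spe_density_map(table, (10, 10))
        assert grid.sum() == 0

    def test_efficiency_ratio_and_undefined(self):
        summary = pd.DataFrame(
            {"level": [0.5, 1.0], "final_4x_mean": [0.92, 0.5], "spe_mean": [1.49, 0.0]}
        )
        eff = establishment_efficiency(summary)
        assert eff.loc[0.5] == pytest.approx(0.92 / 1.49)  # ~0.617
        assert np.isnan(eff.loc[1.0])
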