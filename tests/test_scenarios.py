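"""Preset registry, sweep driver, and external-pH fluctuations."""

import numpy as np
import pandas as pd
import pytest

from ventcell.config import build_runspec
from ventcell.scenarios import (
    SCENARIOS,
    FluctuationSpec,
    Scenario,
    SweepAxis,
    acid_adaptation_sweep,
    fluctuating_run,
    list_scenarios,
    resolve_scenario,
    run_scenario,
    run_sweep,
)

FIGURE_PANELS = [
    "fig3a", "fig3b", "fig3c", "fig3d",
    "fig4a", "fig4b", "fig4cd",
    "fig5a", "fig5b", "fig5c",
    "fig6a", "fig6b", "fig6c", "fig6d",
    "figS1", "figS2", "figS3", "figS4", "figS5",
    "open_system",
]

FAST = {"sim": {"t_end_s": 0.5, "record_interval_s": 0.1}}


class TestRegistry:
    def test_registry_covers_every_figure_panel(self):
        assert set(FIGURE_PANELS) <= set(list_scenarios())

    def test_unknown_scenario_lists_alternatives(self):
        with pytest.raises(KeyError, match="fig3a"):
            resolve_scenario("fig9z")

    def test_every_preset_resolves_to_a_complete_config(self):
        for name in list_scenarios():
            scenario, config = resolve_scenario(name)
            for axis in scenario.axes:
                axis.apply(config, axis.values[0])
            spec = build_runspec(config)  # raises if anything is missing
            assert spec.sim.t_end > 0

    @pytest.mark.parametrize("name", FIGURE_PANELS)
    def test_every_preset_runs_end_to_end(self, name):
        scenario = SCENARIOS[name]
        if scenario.reference_only:
            spec = build_runspec(scenario.resolve())
            assert spec.cell().open_system_reference().minus_dg_reported > 0
            return
        result = run_scenario(name, FAST)
        assert result.summary["t_final"] == pytest.approx(0.5)

    def test_resolved_presets_match_their_captions(self):
        _, fig5 = resolve_scenario("fig5b")
        assert fig5["proteins"]["atpase"]["surface_fraction"] == 0.01
        assert fig5["membrane"]["permeability_h_cm_s"] == 1e-3
        spap_axis = [a for a in SCENARIOS["fig5b"].axes if "spap" in a.name]
        assert spap_axis[0].values == (0.0, 0.01, 0.05, 0.10)

        _, fig3b = resolve_scenario("fig3b")
        assert fig3b["membrane"]["permeability_h_cm_s"] == 1e-6

        _, fig4cd = resolve_scenario("fig4cd")
        assert fig4cd["environment"]["ph_acid"] == fig4cd["environment"]["ph_alk"]

    def test_user_overrides_win(self):
        _, config = resolve_scenario("fig3a", {"environment": {"ph_acid": 6.0}})
        assert config["environment"]["ph_acid"] == 6.0


class TestSweep:
    def test_degenerate_single_cell_sweep_equals_plain_run(self):
        scenario = Scenario(
            name="tiny",
            description="one-cell sweep",
            overrides={"proteins": {"atpase": {"surface_fraction": 0.01}}},
            axes=(SweepAxis("membrane.permeability_h_cm_s", (1e-3,)),),
        )
        table = run_sweep(scenario, FAST)
        assert len(table) == 1
        config = scenario.resolve(FAST)
        scenario.axes[0].apply(config, 1e-3)
        spec = build_runspec(config)
        single = spec.cell().run(spec.sim)
        assert table.loc[0, "minus_dg_reported"] == pytest.approx(
            single.summary["minus_dg_reported"]
        )

    def test_cartesian_grid_order_and_columns(self):
        table = run_sweep("fig5b", {"sim": {"t_end_s": 0.2}})
        assert len(table) == 3 * 4  # gradients x SPAP fractions
        assert list(table["gradient"][:4]) == ["5.0/8.0"] * 4
        for column in ("minus_dg_h", "minus_dg_na", "minus_dg_reported",
                       "dpsi", "ph_internal", "stop_reason", "error"):
            assert column in table.columns
        assert (table["error"] == "").all()

    def test_failed_cell_recorded_in_row(self):
        scenario = Scenario(
            name="broken",
            description="one bad cell",
            overrides={},
            axes=(SweepAxis("proteins.atpase.surface_fraction", (0.01, 7.0)),),
        )
        table = run_sweep(scenario, FAST)
        assert table.loc[0, "error"] == ""
        assert "surface_fraction" in table.loc[1, "error"]

    def test_acid_adaptation_grid_shape(self):
        table = acid_adaptation_sweep({"sim": {"t_end_s": 0.2}})
        assert len(table) == 3 * 5  # gradients x permeability grid
        assert (table["error"] == "").all()


class TestFluctuations:
    BASE = {
        "proteins": {"atpase": {"surface_fraction": 0.01}},
        "sim": {"t_end_s": 10.0, "record_interval_s": 0.5},
    }

    def test_zero_amplitude_matches_static_run(self):
        fluct = FluctuationSpec(side="acid", amplitude=0.0, seed=1)
        traj, _ = fluctuating_run(self.BASE, fluct)
        spec = build_runspec(self.BASE)
        static = spec.cell().run(spec.sim).timeseries
        traj = traj.assign(t=traj["t"].round(6))
        static = static.assign(t=static["t"].round(6))
        merged = traj.merge(static, on="t", suffixes=("_f", "_s"))
        assert len(merged) > 5
        np.testing.assert_allclose(
            merged["minus_dg_reported_f"], merged["minus_dg_reported_s"], rtol=1e-9
        )

    def test_identical_seeds_identical_trajectories(self):
        fluct = FluctuationSpec(side="acid", amplitude=0.3, seed=11)
        a, _ = fluctuating_run(self.BASE, fluct)
        b, _ = fluctuating_run(self.BASE, fluct)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a, _ = fluctuating_run(self.BASE, FluctuationSpec(amplitude=0.3, seed=1))
        b, _ = fluctuating_run(self.BASE, FluctuationSpec(amplitude=0.3, seed=2))
        assert not a["ph_external"].equals(b["ph_external"])

    def test_bounds_are_respected(self):
        fluct = FluctuationSpec(amplitude=1.0, seed=3, ph_min=6.0, ph_max=8.0)
        trace = fluct.trace(7.0, 500)
        assert trace.min() >= 6.0 and trace.max() <= 8.0

    def test_histogram_summary_shape(self):
        fluct = FluctuationSpec(amplitude=0.2, seed=5)
        _, summary = fluctuating_run(self.BASE, fluct)
        assert len(summary["hist_counts"]) == 30
        assert len(summary["hist_edges"]) == 31
        assert summary["min_minus_dg"] <= summary["mean_minus_dg"] <= summary["max_minus_dg"]

    def test_sinusoid_is_deterministic_without_seed_dependence(self):
        fluct = FluctuationSpec(process="sinusoid", amplitude=0.5, seed=1)
        other = FluctuationSpec(process="sinusoid", amplitude=0.5, seed=99)
        np.testing.assert_allclose(fluct.trace(7.0, 100), other.trace(7.0, 100))
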