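"""Time stepping: fixed points, bookkeeping, water coupling, references."""

import math

import pytest

import ventcell as vc
from ventcell.constants import MOL_PER_L_TO_MOL_PER_M3 as TO_SI
from ventcell.simulator import ION_ORDER


def make_cell(perm_cm_s=1e-3, proteins=(), env=None, **kwargs) -> vc.Protocell:
    return vc.Protocell(
        env or vc.Environment(),
        vc.MembraneGeometry(),
        list(proteins),
        perm_cm_s * 1e-2,
        **kwargs,
    )


class TestEnvironment:
    def test_face_compositions_charge_balance(self, vent_env):
        for side in ("acid", "alk"):
            c = vent_env.face_concentrations(side, 1e-14)
            assert c["Na"] + c["K"] + c["H"] == pytest.approx(c["Cl"] + c["OH"])

    def test_ph_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            vc.Environment(ph_acid=-1.0)

    def test_initial_state_matches_alkaline_fluid(self):
        cell = make_cell()
        state = cell.initial_state()
        alk = cell.env.face_concentrations("alk", 1e-14)
        for name in ION_ORDER:
            assert state.concentrations[name] == pytest.approx(alk[name] * TO_SI)


class TestFixedPoint:
    def test_no_gradient_no_proteins_is_stationary(self):
        env = vc.Environment(ph_acid=7.0, ph_alk=7.0)
        cell = make_cell(env=env)
        state = cell.initial_state()
        totals, _ = cell.fluxes(state)
        for name, flux in totals.items():
            assert flux == pytest.approx(0.0, abs=1e-25)
        stepped = vc.step(cell, state, 1e-3)
        for name in ION_ORDER:
            assert stepped.concentrations[name] == pytest.approx(
                state.concentrations[name], rel=1e-12
            )

    def test_free_energy_zero_without_gradient_or_potential(self):
        env = vc.Environment(ph_acid=7.0, ph_alk=7.0)
        cell = make_cell(env=env)
        fe = cell.free_energy(cell.initial_state())
        assert fe.minus_dg_h == pytest.approx(0.0, abs=1e-9)
        assert fe.minus_dg_na == pytest.approx(0.0, abs=1e-9)
        assert fe.minus_dg_reported == pytest.approx(0.0, abs=1e-9)


class TestStepBookkeeping:
    def test_single_step_updates_salt_by_flux_dt_over_volume(self):
        cell = make_cell()
        state = cell.initial_state()
        totals, _ = cell.fluxes(state)
        dt = 1e-4
        new_state, dt_used, _ = cell.step(state, dt)
        assert dt_used == dt
        expected = state.concentrations["Na"] + totals["Na"] * dt / cell.geometry.volume
        assert new_state.concentrations["Na"] == pytest.approx(expected, rel=1e-12)

    def test_water_product_restored_every_step(self):
        cell = make_cell(proteins=[vc.ProteinSpec.of("atpase", 0.01)])
        state = cell.initial_state()
        for _ in range(50):
            state, _, residual = cell.step(state, 1e-3)
            product = state.concentrations["H"] * state.concentrations["OH"]
            assert product == pytest.approx(cell.kw_si, rel=1e-9)
            assert residual <= 1e-9

    def test_step_conserves_charge_difference_through_equilibration(self):
        cell = make_cell(proteins=[vc.ProteinSpec.of("atpase", 0.01)])
        state = cell.initial_state()
        totals, _ = cell.fluxes(state)
        dt = 1e-4
        vol = cell.geometry.volume
        new_state, dt_used, _ = cell.step(state, dt)
        before = state.concentrations["H"] - state.concentrations["OH"]
        injected = (totals["H"] - totals["OH"]) * dt_used / vol
        after = new_state.concentrations["H"] - new_state.concentrations["OH"]
        assert after == pytest.approx(before + injected, rel=1e-9)

    def test_run_and_step_agree(self):
        """The unrolled fast loop must reproduce the reference step() path."""
        cell = make_cell(proteins=[vc.ProteinSpec.of("atpase", 0.01)])
        sim = vc.SimConfig(dt=1e-3, t_end=0.05, record_interval=0.05, steady_tol=0.0)
        fast = cell.run(sim).final_state
        slow = cell.initial_state()
        while slow.t < 0.05 - 1e-12:
            slow, _, _ = cell.step(slow, min(1e-3, 0.05 - slow.t))
        for name in ION_ORDER:
            assert fast.concentrations[name] == pytest.approx(
                slow.concentrations[name], rel=1e-9
            )
        assert fast.dpsi == pytest.approx(slow.dpsi, rel=1e-9)


class TestRun:
    def test_timeseries_is_well_formed(self):
        cell = make_cell(proteins=[vc.ProteinSpec.of("atpase", 0.01)])
        result = cell.run(vc.SimConfig(t_end=5.0, record_interval=0.5, steady_tol=0.0))
        frame = result.timeseries
        assert list(frame["t"]) == sorted(frame["t"])
        assert frame["t"].is_unique
        assert not frame.isna().any().any()
        assert result.summary["stop_reason"] == "t_end"

    def test_bitwise_reproducible(self):
        cell = make_cell(proteins=[vc.ProteinSpec.of("atpase", 0.01)])
        sim = vc.SimConfig(t_end=2.0, steady_tol=0.0)
        a = cell.run(sim).timeseries
        b = make_cell(proteins=[vc.ProteinSpec.of("atpase", 0.01)]).run(sim).timeseries
        assert a.equals(b)

    def test_audit_mode_reports_small_residual(self):
        cell = make_cell(proteins=[vc.ProteinSpec.of("atpase", 0.01)])
        result = cell.run(vc.SimConfig(t_end=2.0, audit=True, steady_tol=0.0))
        assert result.summary["max_conservation_residual"] <= 1e-9

    def test_steady_detection_stops_early(self):
        # no proteins, no gradient: flat from the start
        env = vc.Environment(ph_acid=7.0, ph_alk=7.0)
        cell = make_cell(env=env)
        result = cell.run(vc.SimConfig(t_end=300.0, steady_window=5.0))
        assert result.summary["stop_reason"] == "steady"
        assert result.summary["t_final"] < 300.0


class TestOpenSystemReference:
    def test_no_gradient_reference_is_zero(self):
        env = vc.Environment(ph_acid=7.0, ph_alk=7.0)
        fe = make_cell(env=env).open_system_reference()
        assert fe.minus_dg_reported == pytest.approx(0.0, abs=1e-9)

    def test_chemical_term_of_three_unit_gradient(self):
        fe = make_cell().open_system_reference()
        # chemical part of the H+ term is RT ln(10^3) = 17.11 kJ/mol
        assert -fe.dg_chemical["H"] == pytest.approx(17.11, abs=0.02)

    def test_reference_interior_is_alkaline_fluid(self):
        cell = make_cell()
        fe = cell.open_system_reference()
        state = cell.initial_state()
        assert fe.minus_dg_h == pytest.approx(cell.free_energy(state).minus_dg_h)


class TestValidation:
    def test_free_energy_rejects_zero_concentration(self):
        cell = make_cell()
        state = cell.initial_state()
        state.concentrations["H"] = 0.0
        with pytest.raises(ValueError):
            cell.free_energy(state)

    def test_pump_for_unknown_ion_rejected_at_construction(self):
        spec = vc.ProteinSpec.of("pump", 0.01)
        object.__setattr__(spec, "pumped_ion", "Mg")
        with pytest.raises(ValueError):
            make_cell(proteins=[spec])
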