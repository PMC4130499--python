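"""Protein flux operators: counts, saturation, promiscuity, antiport, pump."""

import numpy as np
import pytest

import ventcell as vc
from ventcell.constants import AVOGADRO
from ventcell.proteins import (
    DrivingForces,
    ProteinKind,
    ProteinSpec,
    SaturationModel,
    atpase_flux,
    atpase_lipid_flux_density_ratio,
    ech_flux,
    pump_flux,
    saturation_factor,
    spap_flux,
    unit_count,
)


def forces(dg_h=0.0, dg_na=0.0, chem_h=None, chem_na=None) -> DrivingForces:
    return DrivingForces(
        total={"H": dg_h, "Na": dg_na},
        chemical={"H": dg_h if chem_h is None else chem_h,
                  "Na": dg_na if chem_na is None else chem_na},
    )


class TestUnitCount:
    def test_zero_fraction(self, geometry):
        spec = ProteinSpec.of("atpase", 0.0)
        assert unit_count(spec, geometry) == 0.0

    def test_default_atpase_density(self, geometry):
        # 1% of the 6.283e-12 m2 acid face at 64 nm2 per unit -> ~982 units
        spec = ProteinSpec.of("atpase", 0.01)
        assert unit_count(spec, geometry) == pytest.approx(981.7, rel=1e-3)

    def test_linear_in_fraction(self, geometry):
        one = unit_count(ProteinSpec.of("atpase", 0.01), geometry)
        two = unit_count(ProteinSpec.of("atpase", 0.02), geometry)
        assert two == pytest.approx(2.0 * one, rel=1e-12)

    def test_zero_footprint_rejected(self):
        with pytest.raises(ValueError):
            ProteinSpec.of("atpase", 0.01, unit_footprint=0.0)


class TestSaturation:
    def test_zero_drive_zero_flux(self):
        assert saturation_factor(0.0) == 0.0

    def test_hyperbolic_value_at_20(self):
        assert saturation_factor(20.0, SaturationModel(2.0)) == pytest.approx(20 / 22)

    def test_monotone_and_bounded(self):
        grid = np.linspace(0.0, 100.0, 400)
        values = [saturation_factor(g) for g in grid]
        assert all(0.0 <= v < 1.0 for v in values)
        assert all(b > a for a, b in zip(values, values[1:]))
        assert saturation_factor(20.0) >= 0.9  # saturation just beyond 20 kJ/mol


class TestPromiscuousProteins:
    def test_no_driving_force_no_flux(self, geometry):
        spec = ProteinSpec.of("atpase", 0.01)
        assert atpase_flux(spec, geometry, forces(0.0, 0.0)) == {"H": 0.0, "Na": 0.0}

    def test_partition_excludes_unfavorable_ion(self, geometry):
        spec = ProteinSpec.of("atpase", 0.01)
        out = atpase_flux(spec, geometry, forces(dg_h=-15.0, dg_na=+3.0))
        assert out["Na"] == 0.0
        assert out["H"] > 0.0
        total_bound = (
            unit_count(spec, geometry)
            * spec.max_turnover
            * spec.efficiency_scale
            * spec.ions_per_cycle
            / AVOGADRO
        )
        assert out["H"] == pytest.approx(total_bound * saturation_factor(15.0))

    def test_flux_never_exceeds_turnover_bound(self, geometry):
        rng = np.random.default_rng(7)
        spec = ProteinSpec.of("atpase", 0.05)
        bound = (
            unit_count(spec, geometry)
            * spec.max_turnover
            * spec.efficiency_scale
            * spec.ions_per_cycle
            / AVOGADRO
        )
        for _ in range(10_000):
            dg_h, dg_na = rng.uniform(-60, 60, 2)
            out = atpase_flux(spec, geometry, forces(dg_h, dg_na))
            assert 0.0 <= out["H"] + out["Na"] < bound

    def test_ech_matches_its_kinetic_defaults(self, geometry):
        f = forces(dg_h=-20.0, dg_na=-10.0)
        atp = atpase_flux(ProteinSpec.of("atpase", 0.02), geometry, f)
        ech = ech_flux(ProteinSpec.of("ech", 0.02), geometry, f)
        # same fraction: per-area ion rate is 2x with the footprint correction
        expected_ratio = (2000.0 / 1000.0) * (64.0 / 50.0)
        assert sum(ech.values()) == pytest.approx(
            sum(atp.values()) * expected_ratio, rel=1e-9
        )

    def test_kind_mismatch_rejected(self, geometry):
        with pytest.raises(ValueError):
            atpase_flux(ProteinSpec.of("ech", 0.01), geometry, forces())


class TestSpap:
    def test_equal_gradients_idle(self, geometry):
        spec = ProteinSpec.of("spap", 0.05)
        assert spap_flux(spec, geometry, forces(-5.0, -5.0)) == {"H": 0.0, "Na": 0.0}

    def test_strict_one_to_one_antiport(self, geometry):
        spec = ProteinSpec.of("spap", 0.05)
        out = spap_flux(spec, geometry, forces(dg_h=-12.0, dg_na=-2.0))
        assert out["H"] > 0.0  # H+ gradient dominant: H+ in, Na+ out
        assert out["H"] + out["Na"] == 0.0  # zero net charge, exactly

    def test_direction_reverses_with_dominant_na_gradient(self, geometry):
        spec = ProteinSpec.of("spap", 0.05)
        fwd = spap_flux(spec, geometry, forces(dg_h=-12.0, dg_na=-2.0))
        rev = spap_flux(spec, geometry, forces(dg_h=-2.0, dg_na=-12.0))
        assert rev["H"] == -fwd["H"] and rev["Na"] == -fwd["Na"]

    def test_uses_chemical_terms_only(self, geometry):
        spec = ProteinSpec.of("spap", 0.05)
        # identical chemical gradients with different electrical offsets
        a = spap_flux(spec, geometry, forces(-12.0, -2.0, chem_h=-8.0, chem_na=-1.0))
        b = spap_flux(spec, geometry, forces(-20.0, -10.0, chem_h=-8.0, chem_na=-1.0))
        assert a == b


class TestPump:
    def test_no_h2_no_pumping(self, geometry):
        spec = ProteinSpec.of("pump", 0.05)
        assert pump_flux(spec, geometry, forces(), h2=0.0) == {"H": 0.0, "Na": 0.0}

    def test_opposing_gradient_throttles(self, geometry):
        spec = ProteinSpec.of("pump", 0.05)
        easy = pump_flux(spec, geometry, forces(dg_h=-5.0), h2=1e-3)
        hard = pump_flux(spec, geometry, forces(dg_h=-20.0), h2=1e-3)
        assert abs(hard["H"]) < abs(easy["H"])

    def test_saturating_h2_and_no_opposition_reaches_ceiling(self, geometry):
        spec = ProteinSpec.of("pump", 0.05)
        out = pump_flux(spec, geometry, forces(dg_h=+4.0), h2=1.0)
        ceiling = (
            unit_count(spec, geometry)
            * spec.max_turnover
            * spec.efficiency_scale
            / AVOGADRO
        )
        assert out["H"] < 0.0  # outward
        assert abs(out["H"]) == pytest.approx(ceiling, rel=0.01)

    def test_unknown_pumped_ion_rejected(self):
        with pytest.raises(ValueError):
            ProteinSpec.of("pump", 0.05, pumped_ion="K")


def test_atpase_to_lipid_flux_density_ratio_is_thousands():
    # 270 ATP/s * 3.3 ions through 64 nm2, against P*[H+] at 1e-2 cm/s, pH 7:
    # ~3.4 orders of magnitude per unit membrane area
    spec = ProteinSpec.of("atpase", 0.01)
    ratio = atpase_lipid_flux_density_ratio(spec, permeability=1e-4, c_acid=1e-4)
    assert np.log10(ratio) == pytest.approx(3.36, abs=0.01)
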