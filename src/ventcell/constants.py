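"""Physical constants and the calibrated protein kinetic defaults.

Every number that parameterizes the model lives here, in one place, so a run
manifest can record exactly which values were resolved.  The protein kinetics
are a one-time calibration against the published flux-ratio, open-system and
antiporter-gain anchors; they are not free per-run tuning knobs.

Units: internal computation is SI throughout the package (m, s, mol, V, J),
with concentrations in mol/m3.  Configuration files use the field's customary
units (cm/s, mol/L, nm2, kJ/mol) and are converted once at ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Avogadro constant, 1/mol (ion counts <-> moles).
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants used by the flux, voltage and free-energy laws.

    faraday            C/mol
    gas_constant       J/(mol K)
    water_ion_product  (mol/L)^2, fixed at its 25 degC value
    standard_temperature  K
    """

    faraday: float = 96485.0
    gas_constant: float = 8.314
    water_ion_product: float = 1e-14
    standard_temperature: float = 298.0

    def __post_init__(self) -> None:
        for name in (
            "faraday",
            "gas_constant",
            "water_ion_product",
            "standard_temperature",
        ):
            value = getattr(self, name)
            if not (value > 0.0):
                raise ValueError(f"PhysicalConstants.{name} must be > 0, got {value!r}")

    @property
    def rt(self) -> float:
        """R*T in J/mol at the standard temperature."""
        return self.gas_constant * self.standard_temperature


CONSTANTS = PhysicalConstants()

# ---------------------------------------------------------------------------
# Unit conversions (ingestion boundary; see UnitPolicy in docs/methods.md)
# ---------------------------------------------------------------------------

CM_PER_S_TO_M_PER_S = 1e-2
MOL_PER_L_TO_MOL_PER_M3 = 1e3
NM2_TO_M2 = 1e-18
KJ_PER_MOL_TO_J_PER_MOL = 1e3


def cm_per_s(value: float) -> float:
    """Permeability quoted in cm/s -> m/s."""
    return value * CM_PER_S_TO_M_PER_S


def mol_per_litre(value: float) -> float:
    """Concentration quoted in mol/L -> mol/m3."""
    return value * MOL_PER_L_TO_MOL_PER_M3


def nm2(value: float) -> float:
    """Protein footprint quoted in nm2 -> m2."""
    return value * NM2_TO_M2


def kj_per_mol(value: float) -> float:
    """Energy quoted in kJ/mol -> J/mol."""
    return value * KJ_PER_MOL_TO_J_PER_MOL


# ---------------------------------------------------------------------------
# Membrane and environment defaults
# ---------------------------------------------------------------------------

#: Default protocell radius, m (1 um sphere, half in each fluid).
DEFAULT_RADIUS = 1e-6

#: Na+ : H+ lipid permeability ratio.  Fatty-acid flip-flop gives H+ a
#: permeability ~6 orders of magnitude above that of Na+; K+ defaults to
#: the Na+ value and OH- to the H+ value of the same run.
NA_TO_H_PERMEABILITY_RATIO = 1e-6

#: Cl- lipid permeability, cm/s.  Anion permeation does not go through the
#: protonation/flip-flop pathway, so it is an absolute value at the
#: fatty-acid-vesicle scale rather than a ratio to the H+ permeability;
#: the dominant counter-ion path that closes the circuit for protein-borne
#: H+/Na+ currents.
DEFAULT_CL_PERMEABILITY_CM_S = 1e-7

#: Ocean-like external composition, mol/L.
DEFAULT_OCEAN_NA = 0.4
DEFAULT_OCEAN_K = 0.01

#: Dissolved H2 available to the pump, mol/L, and its half-saturation.
DEFAULT_H2 = 1e-3
K_H2 = 1e-4

# ---------------------------------------------------------------------------
# Protein kinetic defaults (the calibrated constants file)
# ---------------------------------------------------------------------------
# Calibration notes:
#  * ATPase: maximum turnover 270 ATP/s per unit (the measured E. coli
#    F1F0 maximum), F_O footprint 64 nm2, 3.3 ions per ATP.  Per unit area
#    of protein the maximal ion throughput is ~1.4e19 ions m-2 s-1, between
#    3 and 4 orders of magnitude above the passive H+ flux density through
#    lipid at 1e-2 cm/s and pH 7.
#  * Ech: per-unit ion rate double the ATPase's, slightly smaller footprint.
#  * SPAP: turnover of the fastest measured Na+/H+ antiporters (NhaA,
#    ~1e5 exchanges/s); footprint of a small 12-TM carrier.
#  * Pump: generic H2-driven extruder at the Ech scale.
#  * efficiency_scale 0.1: primordial enzymes taken at 10% of modern rates.

#: Fraction of the modern turnover assumed for primordial proteins.
DEFAULT_EFFICIENCY_SCALE = 0.1

#: Half-saturation of the hyperbolic driving-force response, kJ/mol.
#: |dG|/(|dG|+2) reaches ~0.91 at 20 kJ/mol, i.e. saturation "slightly
#: beyond" the 20 kJ/mol (~200 mV) scale of modern membranes.
SATURATION_HALF_KJ = 2.0

#: Opposing-gradient half-scale of the pump, kJ/mol.
K_PUMP_KJ = 10.0

PROTEIN_DEFAULTS: dict[str, dict[str, float]] = {
    "atpase": {
        "max_turnover": 270.0,    # ATP/s per unit, modern maximum
        "unit_footprint_nm2": 64.0,
        "ions_per_cycle": 3.3,
    },
    "ech": {
        "max_turnover": 540.0,    # cycles/s per unit (2x ATPase ion rate)
        "unit_footprint_nm2": 50.0,
        "ions_per_cycle": 3.3,
    },
    "spap": {
        "max_turnover": 1e5,      # exchanges/s per unit (NhaA scale)
        "unit_footprint_nm2": 25.0,
        "ions_per_cycle": 1.0,
    },
    "pump": {
        "max_turnover": 540.0,    # ions/s per unit (Ech running in reverse)
        "unit_footprint_nm2": 25.0,
        "ions_per_cycle": 1.0,
    },
}
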