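"""Mechanistic flux operators for the four membrane proteins.

All proteins sit on the acid face only (the proton gradient is inverted on
the alkaline face, so a gradient-harvesting protein is only useful on the
acidic side).  Each operator returns molar fluxes with the package-wide
inward-positive convention.

Common structure
----------------
A protein population is ``unit_count = surface_fraction * acid_face_area /
unit_footprint`` units (continuum-valued).  Each unit moves at most
``max_turnover * ions_per_cycle`` ions per second, scaled by
``efficiency_scale`` (primordial enzymes at a fraction of modern rates) and
by a hyperbolic response ``|dG| / (|dG| + K)`` to its driving force, which
saturates slightly beyond 20 kJ/mol with the default ``K = 2 kJ/mol``.

* **ATPase** and **Ech** are fully promiscuous for H+ and Na+: the total
  flux is partitioned between the two ions in proportion to their favorable
  inward driving forces, an ion with an unfavorable gradient receiving none.
* **SPAP** performs strict 1:1 electroneutral Na+/H+ exchange; the direction
  follows the larger of the two chemical gradients (the membrane potential
  cancels for a non-electrogenic 1:1 swap).
* **Pump** extrudes H+ or Na+ at the expense of H2, throttled by the H2
  supply and by the opposing electrochemical gradient.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

from .constants import (
    AVOGADRO,
    DEFAULT_EFFICIENCY_SCALE,
    K_H2,
    K_PUMP_KJ,
    PROTEIN_DEFAULTS,
    SATURATION_HALF_KJ,
    nm2,
)
from .membrane import MembraneGeometry

__all__ = [
    "ProteinKind",
    "ProteinSpec",
    "SaturationModel",
    "DrivingForces",
    "unit_count",
    "saturation_factor",
    "atpase_flux",
    "ech_flux",
    "spap_flux",
    "pump_flux",
    "atpase_lipid_flux_density_ratio",
]

#: The coupling ions the promiscuous proteins can carry.
COUPLING_IONS = ("H", "Na")


class ProteinKind(str, enum.Enum):
    ATPASE = "atpase"
    ECH = "ech"
    SPAP = "spap"
    PUMP = "pump"


@dataclass(frozen=True)
class SaturationModel:
    """Hyperbolic driving-force response, ``|dG| / (|dG| + K)`` in [0, 1)."""

    half_saturation: float = SATURATION_HALF_KJ  # kJ/mol

    def __post_init__(self) -> None:
        if self.half_saturation <= 0.0:
            raise ValueError("half_saturation must be > 0")

    def __call__(self, dg_drive: float) -> float:
        return saturation_factor(dg_drive, self)


def saturation_factor(
    dg_drive: float, model: SaturationModel | None = None
) -> float:
    """Fraction of the maximum turnover mobilized by a driving force (kJ/mol)."""
    k = SATURATION_HALF_KJ if model is None else model.half_saturation
    mag = abs(float(dg_drive))
    return mag / (mag + k)


@dataclass(frozen=True)
class ProteinSpec:
    """A membrane protein population.

    ``surface_fraction`` is the share of the acid-face area covered (0.01 for
    "1%"); ``unit_footprint`` in m2; ``max_turnover`` in cycles/s per unit at
    modern rates; ``ions_per_cycle`` ions moved per cycle (3.3 for the
    ATPase); ``pumped_ion`` names the extruded ion for the pump only.
    """

    kind: ProteinKind
    surface_fraction: float
    unit_footprint: float  # m2
    max_turnover: float  # cycles/s, modern value
    ions_per_cycle: float = 1.0
    efficiency_scale: float = DEFAULT_EFFICIENCY_SCALE
    pumped_ion: str | None = None
    saturation: SaturationModel = field(default_factory=SaturationModel)

    def __post_init__(self) -> None:
        if not 0.0 <= self.surface_fraction <= 1.0:
            raise ValueError(
                f"surface_fraction must be in [0, 1], got {self.surface_fraction}"
            )
        if self.unit_footprint <= 0.0:
            raise ValueError("unit_footprint must be > 0")
        if self.max_turnover <= 0.0:
            raise ValueError("max_turnover must be > 0")
        if self.ions_per_cycle <= 0.0:
            raise ValueError("ions_per_cycle must be > 0")
        if not 0.0 < self.efficiency_scale <= 1.0:
            raise ValueError("efficiency_scale must be in (0, 1]")
        if self.kind is ProteinKind.PUMP:
            if self.pumped_ion not in COUPLING_IONS:
                raise ValueError(
                    f"pump must extrude one of {COUPLING_IONS}, got {self.pumped_ion!r}"
                )
        elif self.pumped_ion is not None:
            raise ValueError("pumped_ion is only meaningful for the pump")

    @classmethod
    def of(cls, kind: ProteinKind | str, surface_fraction: float, **overrides) -> "ProteinSpec":
        """Build a spec from the calibrated defaults for its kind."""
        kind = ProteinKind(kind)
        defaults = PROTEIN_DEFAULTS[kind.value]
        spec = cls(
            kind=kind,
            surface_fraction=surface_fraction,
            unit_footprint=nm2(defaults["unit_footprint_nm2"]),
            max_turnover=defaults["max_turnover"],
            ions_per_cycle=defaults["ions_per_cycle"],
            pumped_ion="H" if kind is ProteinKind.PUMP else None,
        )
        return replace(spec, **overrides) if overrides else spec


@dataclass(frozen=True)
class DrivingForces:
    """Per-ion free energies of inward transfer across the acid face, kJ/mol.

    ``total`` is the full electrochemical term ``zF.dpsi + RT ln(c_in/c_acid)``;
    ``chemical`` omits the electrical term (used by the electroneutral SPAP).
    Negative values mean inward transfer is downhill.
    """

    total: dict[str, float]
    chemical: dict[str, float]


def unit_count(spec: ProteinSpec, geometry: MembraneGeometry) -> float:
    """Number of protein units on the acid face (continuum-valued)."""
    return spec.surface_fraction * geometry.area_acid_face / spec.unit_footprint


def _max_flux(spec: ProteinSpec, geometry: MembraneGeometry) -> float:
    """Turnover-derived ceiling on total ion flux, mol/s."""
    return (
        unit_count(spec, geometry)
        * spec.max_turnover
        * spec.efficiency_scale
        * spec.ions_per_cycle
        / AVOGADRO
    )


def _promiscuous_partition(forces: DrivingForces) -> tuple[dict[str, float], float]:
    """Partition weights over favorable coupling ions and the effective drive.

    Weights are proportional to each ion's favorable inward driving force
    ``max(-dG, 0)`` and sum to 1 (all zero when nothing is favorable); the
    effective driving force is the partition-weighted mean, kJ/mol.
    """
    favorable = {ion: max(-forces.total[ion], 0.0) for ion in COUPLING_IONS}
    total = sum(favorable.values())
    if total <= 0.0:
        return {ion: 0.0 for ion in COUPLING_IONS}, 0.0
    weights = {ion: f / total for ion, f in favorable.items()}
    dg_eff = sum(weights[ion] * favorable[ion] for ion in COUPLING_IONS)
    return weights, dg_eff


def _synthase_like_flux(
    spec: ProteinSpec, geometry: MembraneGeometry, forces: DrivingForces
) -> dict[str, float]:
    weights, dg_eff = _promiscuous_partition(forces)
    total = _max_flux(spec, geometry) * saturation_factor(dg_eff, spec.saturation)
    return {ion: total * weights[ion] for ion in COUPLING_IONS}


def atpase_flux(
    spec: ProteinSpec, geometry: MembraneGeometry, forces: DrivingForces
) -> dict[str, float]:
    """Inward H+ and Na+ flux (mol/s) through the ATP synthase.

    Synthesis direction only; reversal into a pump is not modelled.
    """
    if spec.kind is not ProteinKind.ATPASE:
        raise ValueError(f"expected an ATPase spec, got kind={spec.kind}")
    return _synthase_like_flux(spec, geometry, forces)


def ech_flux(
    spec: ProteinSpec, geometry: MembraneGeometry, forces: DrivingForces
) -> dict[str, float]:
    """Inward H+ and Na+ flux (mol/s) through the energy-converting hydrogenase."""
    if spec.kind is not ProteinKind.ECH:
        raise ValueError(f"expected an Ech spec, got kind={spec.kind}")
    return _synthase_like_flux(spec, geometry, forces)


def spap_flux(
    spec: ProteinSpec, geometry: MembraneGeometry, forces: DrivingForces
) -> dict[str, float]:
    """Coupled H+/Na+ flows (mol/s) of the 1:1 antiporter; equal and opposite.

    The net exchange driving force is ``dG_net = dG_H - dG_Na`` over the
    chemical terms only; its sign sets the direction, its magnitude the speed.
    """
    if spec.kind is not ProteinKind.SPAP:
        raise ValueError(f"expected a SPAP spec, got kind={spec.kind}")
    dg_net = forces.chemical["H"] - forces.chemical["Na"]
    if dg_net == 0.0:
        return {"H": 0.0, "Na": 0.0}
    magnitude = _max_flux(spec, geometry) * saturation_factor(dg_net, spec.saturation)
    if dg_net < 0.0:  # H+ inward transfer the more favorable
        return {"H": magnitude, "Na": -magnitude}
    return {"H": -magnitude, "Na": magnitude}


def pump_flux(
    spec: ProteinSpec,
    geometry: MembraneGeometry,
    forces: DrivingForces,
    h2: float,
    k_h2: float = K_H2,
    k_pump_kj: float = K_PUMP_KJ,
) -> dict[str, float]:
    """Flux (mol/s, inward-positive, hence <= 0) of the H2-driven ion pump.

    Extrusion rate = ceiling * f_H2 * g_opp with ``f_H2 = [H2]/([H2]+K_H2)``
    and ``g_opp = 1/(1 + dG_opp/K_pump)`` against the opposing (outward)
    electrochemical gradient, so pumping into an acidic exterior is harder
    than into an alkaline one.  Strictly zero without H2.
    """
    if spec.kind is not ProteinKind.PUMP:
        raise ValueError(f"expected a pump spec, got kind={spec.kind}")
    if h2 < 0.0 or math.isnan(h2):
        raise ValueError(f"H2 concentration must be >= 0, got {h2!r}")
    flux = {ion: 0.0 for ion in COUPLING_IONS}
    if h2 == 0.0:
        return flux
    ion = spec.pumped_ion
    assert ion is not None
    # Outward transfer free energy is minus the inward one; positive opposes.
    dg_opp = max(-forces.total[ion], 0.0)
    f_h2 = h2 / (h2 + k_h2)
    g_opp = 1.0 / (1.0 + dg_opp / k_pump_kj)
    flux[ion] = -_max_flux(spec, geometry) * f_h2 * g_opp
    return flux


def atpase_lipid_flux_density_ratio(
    spec: ProteinSpec,
    permeability: float,
    c_acid: float,
) -> float:
    """Ratio of maximal ATPase H+ flux density to the passive lipid density.

    Compares ion throughput per unit membrane area: a fully driven ATPase
    unit passes ``max_turnover * ions_per_cycle`` ions/s (modern kinetics,
    no efficiency discount) through its ``unit_footprint``, against the
    passive flux density ``P * [H+]_acid`` through bare lipid.
    ``permeability`` in m/s, ``c_acid`` in mol/m3; the ratio is dimensionless.
    """
    if permeability <= 0.0 or c_acid <= 0.0:
        raise ValueError("permeability and c_acid must be > 0")
    protein_density = (
        spec.max_turnover * spec.ions_per_cycle / AVOGADRO / spec.unit_footprint
    )
    lipid_density = permeability * c_acid
    return protein_density / lipid_density
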