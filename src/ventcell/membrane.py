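"""Passive transmembrane transport and the membrane potential.

Flux laws
---------
Neutral species cross by simple diffusion, ``J = P A (c_out - c_in)``.
Charged species follow the Goldman-Hodgkin-Katz (GHK) constant-field flux
equation; the resting potential is the GHK voltage over every permeant ion.

Conventions, fixed package-wide:

* flux is **inward-positive** (mol/s into the cell);
* the membrane potential is ``dpsi = psi_in - psi_out``, so a permeant
  cation in external excess polarizes the interior positive.

With ``u = z F dpsi / (R T)`` the inward GHK flux is

    J = P A u (c_out e^{-u} - c_in) / (1 - e^{-u})

which reduces to ``P A (c_out - c_in)`` as ``dpsi -> 0`` and vanishes exactly
at the Nernst potential ``(RT/zF) ln(c_out/c_in)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .chemistry import effective_external
from .constants import CONSTANTS, PhysicalConstants

__all__ = [
    "IonSpec",
    "MembraneGeometry",
    "passive_flux_neutral",
    "ghk_flux",
    "ghk_voltage",
]

#: Switch to the series expansion of the GHK flux below this |u|; the
#: truncation error there is ~u^2/12 < 1e-16 relative.
_GHK_SERIES_SWITCH = 1e-8


def _check_finite(value: float, name: str) -> float:
    value = float(value)
    if math.isnan(value):
        raise ValueError(f"{name} is NaN")
    return value


@dataclass
class IonSpec:
    """One ion: charge, lipid permeability and its fixed external pools.

    Concentrations are stored in mol/m3 (SI); builders that ingest mol/L
    convert at the boundary.  ``conc_acid_face``/``conc_alk_face`` are the
    clamped external concentrations on the two faces; ``initial_internal``
    seeds the cell state.
    """

    name: str
    valence: int
    permeability: float  # m/s
    conc_acid_face: float  # mol/m3
    conc_alk_face: float  # mol/m3
    initial_internal: float  # mol/m3

    def __post_init__(self) -> None:
        if self.valence not in (-1, 1):
            raise ValueError(f"ion {self.name}: valence must be +/-1, got {self.valence}")
        if self.permeability < 0.0:
            raise ValueError(f"ion {self.name}: permeability must be >= 0")
        for attr in ("conc_acid_face", "conc_alk_face", "initial_internal"):
            if getattr(self, attr) < 0.0:
                raise ValueError(f"ion {self.name}: {attr} must be >= 0")

    def effective_external_conc(self, geometry: "MembraneGeometry") -> float:
        """Face-area-weighted mean external concentration (mol/m3)."""
        return effective_external(
            self.conc_acid_face,
            self.conc_alk_face,
            geometry.area_acid_face,
            geometry.area_alk_face,
        )


@dataclass
class MembraneGeometry:
    """Spherical protocell half-embedded in each fluid.

    By default each face is half of the sphere surface; the split can be
    overridden for sensitivity runs.
    """

    radius: float = 1e-6  # m
    acid_face_fraction: float = 0.5
    area_acid_face: float = field(init=False)
    area_alk_face: float = field(init=False)
    volume: float = field(init=False)  # m3

    def __post_init__(self) -> None:
        if self.radius <= 0.0:
            raise ValueError("radius must be > 0")
        if not 0.0 < self.acid_face_fraction < 1.0:
            raise ValueError("acid_face_fraction must be in (0, 1)")
        surface = 4.0 * math.pi * self.radius**2
        self.area_acid_face = surface * self.acid_face_fraction
        self.area_alk_face = surface * (1.0 - self.acid_face_fraction)
        self.volume = (4.0 / 3.0) * math.pi * self.radius**3


def passive_flux_neutral(
    permeability: float, area: float, c_ext: float, c_int: float
) -> float:
    """Inward diffusive flux of a neutral species, mol/s."""
    for name, value in (
        ("permeability", permeability),
        ("area", area),
        ("c_ext", c_ext),
        ("c_int", c_int),
    ):
        _check_finite(value, name)
    if permeability < 0.0 or area < 0.0:
        raise ValueError("permeability and area must be >= 0")
    return permeability * area * (c_ext - c_int)


def ghk_flux(
    permeability: float,
    valence: int,
    area: float,
    c_in: float,
    c_out: float,
    dpsi: float,
    temperature: float = CONSTANTS.standard_temperature,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Inward GHK flux of a charged species, mol/s.

    ``c_in``/``c_out`` in mol/m3, ``dpsi = psi_in - psi_out`` in volts.
    """
    for name, value in (
        ("permeability", permeability),
        ("area", area),
        ("c_in", c_in),
        ("c_out", c_out),
        ("dpsi", dpsi),
    ):
        _check_finite(value, name)
    if permeability < 0.0 or area < 0.0:
        raise ValueError("permeability and area must be >= 0")
    if temperature <= 0.0:
        raise ValueError("temperature must be > 0")
    if c_in == 0.0 and c_out == 0.0:
        return 0.0
    u = valence * constants.faraday * dpsi / (constants.gas_constant * temperature)
    pa = permeability * area
    if abs(u) < _GHK_SERIES_SWITCH:
        # First-order expansion keeps the function continuous through u = 0.
        return pa * ((c_out - c_in) - 0.5 * u * (c_out + c_in))
    if u > 0.0:
        emu = math.exp(-u)
        return pa * u * (c_out * emu - c_in) / (1.0 - emu)
    # For u < 0 rescale by e^{u} to avoid overflow at large |u|.
    eu = math.exp(u)
    return pa * u * (c_out - c_in * eu) / (eu - 1.0)


def ghk_voltage(
    ions: list[IonSpec],
    internal: dict[str, float],
    geometry: MembraneGeometry,
    temperature: float = CONSTANTS.standard_temperature,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """GHK resting potential ``psi_in - psi_out`` in volts.

    ``internal`` maps ion name -> internal concentration (mol/m3); external
    concentrations are the pooled face-area-weighted means.  Cation external
    and anion internal concentrations enter the numerator, so a permeant
    cation in external excess yields a positive potential.
    """
    if temperature <= 0.0:
        raise ValueError("temperature must be > 0")
    numerator = 0.0
    denominator = 0.0
    for ion in ions:
        if ion.permeability == 0.0:
            continue
        c_out = ion.effective_external_conc(geometry)
        c_in = internal[ion.name]
        if ion.valence > 0:
            numerator += ion.permeability * c_out
            denominator += ion.permeability * c_in
        else:
            numerator += ion.permeability * c_in
            denominator += ion.permeability * c_out
    if numerator <= 0.0 or denominator <= 0.0:
        side = []
        if numerator <= 0.0:
            side.append("numerator (external cations + internal anions)")
        if denominator <= 0.0:
            side.append("denominator (internal cations + external anions)")
        raise ValueError(
            "GHK voltage undefined: zero permeability-weighted concentration in "
            + " and ".join(side)
        )
    rt_over_f = constants.gas_constant * temperature / constants.faraday
    return rt_over_f * math.log(numerator / denominator)
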