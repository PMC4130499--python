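"""Electrochemical free-energy bookkeeping (the chemiosmotic ledger).

The free energy of moving one mole of an ion from the acid-face fluid into
the cell is

    dG = z F dpsi + R T ln(c_in / c_acid)        [J/mol]

the classic proton-motive-force expression; the analogous term is used for
Na+.  ``-dG`` (reported in kJ/mol) is the driving force the membrane
proteins can harvest.

A promiscuous H+/Na+ machine can draw on both gradients.  The package
reports a single headline ``-dG`` as the **sum of the favorable per-ion
components** — the total electrochemical free energy available per coupling
site — while always emitting the per-ion components alongside.  A
partition-weighted mean (bounded by the largest single component) is
available via ``combine="mean"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import CONSTANTS, PhysicalConstants

__all__ = [
    "FreeEnergies",
    "ion_delta_g",
    "combine_minus_dg",
    "delta_g_to_voltage",
    "voltage_to_delta_g",
    "atp_adp_displacement_orders",
]


def ion_delta_g(
    c_in: float,
    c_acid: float,
    valence: int,
    dpsi: float,
    temperature: float = CONSTANTS.standard_temperature,
    constants: PhysicalConstants = CONSTANTS,
) -> tuple[float, float]:
    """(total, chemical-only) free energy of inward transfer, kJ/mol.

    ``c_in``/``c_acid`` may be in any common unit; only their ratio enters.
    """
    if c_in <= 0.0 or c_acid <= 0.0:
        raise ValueError(
            f"free energy undefined for non-positive concentration "
            f"(c_in={c_in!r}, c_acid={c_acid!r})"
        )
    chemical = constants.gas_constant * temperature * math.log(c_in / c_acid)
    total = valence * constants.faraday * dpsi + chemical
    return total / 1e3, chemical / 1e3


@dataclass(frozen=True)
class FreeEnergies:
    """Per-ion and combined driving forces at one instant, kJ/mol."""

    minus_dg_h: float
    minus_dg_na: float
    minus_dg_reported: float
    dg_total: dict[str, float]  # inward dG per ion (sign not flipped)
    dg_chemical: dict[str, float]


def combine_minus_dg(minus_dgs: dict[str, float], mode: str = "sum") -> float:
    """Collapse per-ion ``-dG`` values into the reported headline number.

    ``"sum"``: total favorable free energy over the coupling ions (default).
    ``"mean"``: partition-weighted mean, weights proportional to each ion's
    favorable driving force (all weight on one ion when only it is favorable).
    Ions with unfavorable gradients contribute zero either way.
    """
    favorable = {ion: max(v, 0.0) for ion, v in minus_dgs.items()}
    total = sum(favorable.values())
    if total <= 0.0:
        return 0.0
    if mode == "sum":
        return total
    if mode == "mean":
        return sum(v * v for v in favorable.values()) / total
    raise ValueError(f"unknown combination mode {mode!r}; use 'sum' or 'mean'")


def delta_g_to_voltage(
    minus_dg_kj: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Membrane potential (V) equivalent to a purely electrical dG (kJ/mol).

    20 kJ/mol on a monovalent ion corresponds to ~207 mV.
    """
    return minus_dg_kj * 1e3 / constants.faraday


def voltage_to_delta_g(
    dpsi: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Inverse of :func:`delta_g_to_voltage`: volts -> kJ/mol on |z| = 1."""
    return dpsi * constants.faraday / 1e3


def atp_adp_displacement_orders(
    minus_dg_kj: float,
    ions_per_atp: float = 3.3,
    temperature: float = CONSTANTS.standard_temperature,
    constants: PhysicalConstants = CONSTANTS,
) -> float:
    """Orders of magnitude the ATP/ADP ratio can be displaced from equilibrium.

    ``ions_per_atp`` translocations each worth ``minus_dg_kj`` kJ/mol can
    hold the mass-action ratio ``10**orders`` away from equilibrium:
    ``orders = n * dG / (R T ln 10)``.
    """
    return (
        ions_per_atp
        * minus_dg_kj
        * 1e3
        / (constants.gas_constant * temperature * math.log(10.0))
    )
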