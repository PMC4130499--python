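"""pH arithmetic and the water self-ionization equilibrium.

All functions here are unit-agnostic where they can be (``equilibrate_water``
works in any concentration unit as long as ``kw`` matches) and otherwise use
mol/L, the unit in which pH is defined.
"""

from __future__ import annotations

import math

from .constants import CONSTANTS

__all__ = [
    "ph_to_concentration",
    "concentration_to_ph",
    "equilibrate_water",
    "effective_external",
]


def _require_finite(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


def ph_to_concentration(ph: float) -> float:
    """H+ concentration (mol/L) of a fluid at the given pH."""
    ph = _require_finite(ph, "pH")
    return 10.0 ** (-ph)


def concentration_to_ph(concentration: float) -> float:
    """pH of a fluid with the given H+ concentration (mol/L)."""
    concentration = _require_finite(concentration, "concentration")
    if concentration <= 0.0:
        raise ValueError(
            f"concentration must be > 0 to have a pH, got {concentration!r}"
        )
    return -math.log10(concentration)


def equilibrate_water(
    total_h: float,
    total_oh: float,
    kw: float = CONSTANTS.water_ion_product,
) -> tuple[float, float]:
    """Neutralize and re-equilibrate an H+/OH- pair against water.

    Given gross amounts of H+ and OH- (e.g. after a transport step has added
    ions of both kinds), returns the pair ``(h, oh)`` that (i) conserves the
    charge difference exactly, ``h - oh == total_h - total_oh``, and (ii)
    satisfies the ion product ``h * oh == kw``.  Solved in closed form from
    the quadratic ``h * (h - d) = kw`` with ``d = total_h - total_oh``:

        h = (d + sqrt(d^2 + 4 kw)) / 2

    The subtraction-free root is used so the result is accurate even when
    ``|d| >> sqrt(kw)``.
    """
    total_h = _require_finite(total_h, "total_h")
    total_oh = _require_finite(total_oh, "total_oh")
    if total_h < 0.0 or total_oh < 0.0:
        raise ValueError(
            f"ion totals must be >= 0, got total_h={total_h!r} total_oh={total_oh!r}"
        )
    if kw <= 0.0:
        raise ValueError(f"kw must be > 0, got {kw!r}")
    d = total_h - total_oh
    root = math.sqrt(d * d + 4.0 * kw)
    # Pick the algebraically equivalent root form that avoids cancellation,
    # then recover the partner so the difference is conserved exactly.
    if d > 0.0:
        h = 0.5 * (d + root)
        oh = kw / h
        h = oh + d
    else:
        h = 2.0 * kw / (root - d)
        oh = h - d
    return h, oh


def equilibrate_from_difference(
    d: float, kw: float = CONSTANTS.water_ion_product
) -> tuple[float, float]:
    """Water-equilibrated (H, OH) pair with charge difference ``d = H - OH``.

    Unlike :func:`equilibrate_water` this accepts any real ``d``: the water
    pool regenerates whichever species a flux imbalance has consumed, so the
    equilibrated state exists for net-acid and net-alkaline interiors alike.
    """
    d = _require_finite(d, "charge difference")
    if kw <= 0.0:
        raise ValueError(f"kw must be > 0, got {kw!r}")
    root = math.sqrt(d * d + 4.0 * kw)
    if d > 0.0:
        h = 0.5 * (d + root)
        oh = kw / h
        return oh + d, oh
    h = 2.0 * kw / (root - d)
    return h, h - d


def effective_external(
    conc_acid_face: float,
    conc_alk_face: float,
    area_acid_face: float,
    area_alk_face: float,
) -> float:
    """Pool the two external fluids into one effective concentration.

    The membrane-potential equation sees a single exterior; the two fluids
    are combined as the face-area-weighted mean, which degenerates to the
    common value whenever the two fluids are identical.
    """
    for name, value in (
        ("conc_acid_face", conc_acid_face),
        ("conc_alk_face", conc_alk_face),
        ("area_acid_face", area_acid_face),
        ("area_alk_face", area_alk_face),
    ):
        _require_finite(value, name)
    total = area_acid_face + area_alk_face
    if total <= 0.0:
        raise ValueError("membrane faces must have positive total area")
    return (conc_acid_face * area_acid_face + conc_alk_face * area_alk_face) / total
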