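"""Oxygen-tension unit conversions and culture-vessel geometry.

Oxygen in culture work is reported interchangeably as a gas-phase fraction
(% O2), a partial pressure (mmHg), or a dissolved concentration (µM).  The
package pivots everything through % O2 — the unit incubators and optical
sensors report — using two linear constants:

* ``mmhg_per_percent``: 7.7 mmHg per % O2 at sea level, so room air in a
  humidified 37 °C incubator (18.6 % O2) is ~143 mmHg.
* ``solubility_um_per_mmhg``: Henry-law solubility of O2 in culture medium
  at 37 °C, default 1.27 µM/mmHg, so 1 % O2 dissolves ~9.78 µM O2.

Dissolved-molar units only matter where a Michaelis constant (given in µM)
meets the simulated field (kept in % O2); both constants are configurable.

The vessel registry maps common labware names to growth areas so that a
(vessel, medium volume) pair determines the media-column height ``L`` of the
1-D transport model: ``L = volume / growth_area``, with ``x = 0`` the vessel
bottom (the cell layer) and ``x = L`` the gas–media interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "TensionConstants",
    "VesselGeometry",
    "MediaColumn",
    "UNITS",
    "convert_tension",
    "media_height",
    "builtin_vessels",
    "get_vessel",
]

UNITS = ("percent", "mmHg", "micromolar")

_UNIT_ALIASES = {
    "percent": "percent",
    "%": "percent",
    "pct": "percent",
    "mmhg": "mmHg",
    "torr": "mmHg",
    "micromolar": "micromolar",
    "um": "micromolar",
    "µm": "micromolar",
}


@dataclass(frozen=True)
class TensionConstants:
    """Linear constants linking % O2, partial pressure and dissolved O2.

    Attributes
    ----------
    mmhg_per_percent : float
        Partial pressure per gas-phase percent, mmHg / % O2.
    solubility_um_per_mmhg : float
        Dissolved O2 per unit partial pressure at 37 °C, µM / mmHg.
    """

    mmhg_per_percent: float = 7.7
    solubility_um_per_mmhg: float = 1.27

    def __post_init__(self) -> None:
        if self.mmhg_per_percent <= 0:
            raise ValueError("mmhg_per_percent must be positive")
        if self.solubility_um_per_mmhg <= 0:
            raise ValueError("solubility_um_per_mmhg must be positive")

    @property
    def um_per_percent(self) -> float:
        """Dissolved µM per % O2 (product of the two base constants)."""
        return self.mmhg_per_percent * self.solubility_um_per_mmhg

    def percent_from_micromolar(self, um: float) -> float:
        return um / self.um_per_percent

    def mol_per_cm3_per_percent(self) -> float:
        """Dissolved mol·cm⁻³ per % O2 (1 µM = 1e-9 mol/cm³)."""
        return self.um_per_percent * 1e-9


DEFAULT_CONSTANTS = TensionConstants()


def _canonical_unit(unit: str) -> str:
    try:
        return _UNIT_ALIASES[unit.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown O2 unit {unit!r}; supported: {', '.join(UNITS)}"
        ) from None


def convert_tension(
    value: float,
    from_unit: str,
    to_unit: str,
    constants: TensionConstants = DEFAULT_CONSTANTS,
) -> float:
    """Convert an O2 amount between % O2, mmHg and µM.

    Conversion is linear through the % O2 pivot; round-trips are identities
    to floating precision.  Negative values are rejected (an O2 tension is
    non-negative by definition).
    """
    if value < 0:
        raise ValueError(f"O2 tension must be non-negative, got {value}")
    src = _canonical_unit(from_unit)
    dst = _canonical_unit(to_unit)
    # to percent
    if src == "percent":
        pct = value
    elif src == "mmHg":
        pct = value / constants.mmhg_per_percent
    else:
        pct = value / constants.um_per_percent
    # from percent
    if dst == "percent":
        return pct
    if dst == "mmHg":
        return pct * constants.mmhg_per_percent
    return pct * constants.um_per_percent


@dataclass(frozen=True)
class VesselGeometry:
    """A named piece of labware reduced to its growth area."""

    name: str
    growth_area_cm2: float

    def __post_init__(self) -> None:
        if not self.growth_area_cm2 > 0:
            raise ValueError(
                f"growth area must be positive, got {self.growth_area_cm2}"
            )


#: Manufacturer-standard growth areas (cm²).  These are configurable
#: defaults; actual areas vary a few percent between suppliers.
_BUILTIN_AREAS = {
    "96-well": 0.32,
    "24-well": 1.9,
    "12-well": 3.8,
    "6-well": 9.6,
    "60mm-dish": 21.5,
    "T25": 25.0,
    "T75": 75.0,
}


def builtin_vessels() -> dict[str, VesselGeometry]:
    """Registry of common culture vessels keyed by name."""
    return {name: VesselGeometry(name, a) for name, a in _BUILTIN_AREAS.items()}


def get_vessel(name: str) -> VesselGeometry:
    """Look up a built-in vessel; raises ``KeyError`` with the known names."""
    reg = builtin_vessels()
    if name not in reg:
        raise KeyError(
            f"unknown vessel {name!r}; built-in vessels: {', '.join(reg)}"
        )
    return reg[name]


def media_height(volume_ml: float, geometry: VesselGeometry) -> float:
    """Media-column height (cm) for a volume (mL) in a vessel (1 mL = 1 cm³)."""
    if not volume_ml > 0:
        raise ValueError(f"volume must be positive, got {volume_ml}")
    return volume_ml / geometry.growth_area_cm2


@dataclass(frozen=True)
class MediaColumn:
    """The 1-D spatial domain: a media column of height L over the cells.

    ``x = 0`` is the vessel bottom (pericellular position) and ``x = L`` the
    gas–media interface.
    """

    geometry: VesselGeometry
    volume_ml: float

    def __post_init__(self) -> None:
        if not self.volume_ml > 0:
            raise ValueError(f"volume must be positive, got {self.volume_ml}")

    @property
    def height_cm(self) -> float:
        return media_height(self.volume_ml, self.geometry)

    @classmethod
    def from_vessel(cls, name: str, volume_ml: float) -> "MediaColumn":
        return cls(get_vessel(name), volume_ml)
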