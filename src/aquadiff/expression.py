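"""From membrane permeability to channel expression level.

A membrane water permeability P (um/ms) is converted to a per-cell
volumetric water flow P*A (um^3/ms, with A the cell surface area), to a
channel count via the single-channel osmotic water conductance, and to a
cellular concentration via Avogadro's number and the cell volume.  A
dose-response ratio allows extrapolating a concentration measured at high
induction to a lower induction level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .units import AVOGADRO, um3_to_litre

__all__ = [
    "ExpressionEstimate",
    "permeability_to_concentration",
    "cell_volume_from_area",
    "extrapolate_low_dose_concentration",
]

#: Average CHO cell surface area, um^2.
DEFAULT_SURFACE_AREA = 380.0
#: Single water channel osmotic conductance, um^3/ms.
DEFAULT_UNIT_CONDUCTANCE = 6e-5


def cell_volume_from_area(surface_area_um2: float) -> float:
    """Volume of the sphere with the given surface area (um^3).

    380 um^2 corresponds to r = 5.50 um and V = 697 um^3.
    """
    if surface_area_um2 <= 0:
        raise ConfigurationError("surface area must be positive")
    r = math.sqrt(surface_area_um2 / (4.0 * math.pi))
    return 4.0 / 3.0 * math.pi * r**3


@dataclass
class ExpressionEstimate:
    """Channel expression implied by a membrane permeability."""

    permeability: float  # um/ms
    volumetric_flow: float  # um^3/ms
    channels_per_cell: float
    concentration_uM: float
    assumptions: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "permeability_um_per_ms": self.permeability,
                "volumetric_flow_um3_per_ms": self.volumetric_flow,
                "channels_per_cell": self.channels_per_cell,
                "concentration_uM": self.concentration_uM,
                "assumptions": self.assumptions,
            }
        )


def permeability_to_concentration(
    P_um_per_ms: float,
    surface_area_um2: float = DEFAULT_SURFACE_AREA,
    unit_conductance_um3_per_ms: float = DEFAULT_UNIT_CONDUCTANCE,
    cell_volume_um3: float | None = None,
    multimer_factor: float = 1.0,
) -> ExpressionEstimate:
    """Convert a membrane permeability to a channel concentration.

    flow = P * A; channels = flow / unit conductance; concentration =
    channels / (multimer_factor * N_A * V).  By default the cell volume is
    that of the sphere matching the surface area; pass ``cell_volume_um3``
    to use e.g. the pellet-model mean-radius sphere instead.  The
    ``multimer_factor`` counts conducting units per counted protomer (1 =
    conductance interpreted per monomer).
    """
    if P_um_per_ms < 0:
        raise ConfigurationError("permeability must be >= 0")
    if surface_area_um2 <= 0 or unit_conductance_um3_per_ms <= 0:
        raise ConfigurationError("surface area and unit conductance must be positive")
    if multimer_factor <= 0:
        raise ConfigurationError("multimer_factor must be positive")
    if cell_volume_um3 is None:
        cell_volume_um3 = cell_volume_from_area(surface_area_um2)
    if cell_volume_um3 <= 0:
        raise ConfigurationError("cell volume must be positive")
    flow = P_um_per_ms * surface_area_um2
    channels = flow / unit_conductance_um3_per_ms
    moles_per_litre = channels / (multimer_factor * AVOGADRO * um3_to_litre(cell_volume_um3))
    return ExpressionEstimate(
        permeability=float(P_um_per_ms),
        volumetric_flow=float(flow),
        channels_per_cell=float(channels),
        concentration_uM=float(moles_per_litre * 1e6),
        assumptions={
            "surface_area_um2": surface_area_um2,
            "unit_conductance_um3_per_ms": unit_conductance_um3_per_ms,
            "cell_volume_um3": cell_volume_um3,
            "multimer_factor": multimer_factor,
        },
    )


def extrapolate_low_dose_concentration(
    high_dose_concentration: float, response_ratio: float
) -> float:
    """Scale a concentration measured at full induction by a dose-response
    ratio (e.g. from a co-transcribed fluorescent reporter): 2.54 uM at full
    induction times a ratio of 0.18 gives 0.4572 uM (457.2 nM)."""
    if high_dose_concentration < 0 or response_ratio < 0:
        raise ConfigurationError("inputs must be non-negative")
    return high_dose_concentration * response_ratio
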