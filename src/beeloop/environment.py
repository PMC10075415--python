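"""Flower fields and visual-perception geometry.

A bumblebee resolves an object once it subtends about 3 degrees on the
retina, so the perception distance of a flower of diameter ``D`` is
``D / (2 tan(threshold / 2))`` — about 3.8 m for a 20 cm flower and 13 m
for a 70 cm one.  Fields are squares of uniformly, independently placed
flowers of a common diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.random import Generator, default_rng

__all__ = ["FlowerField", "perception_distance", "generate_field"]

ANGULAR_THRESHOLD = math.radians(3.0)  # rad, visual detection threshold


def perception_distance(object_diameter: float,
                        angular_threshold: float = ANGULAR_THRESHOLD) -> float:
    """Distance at which an object subtends the angular threshold, m.

    Exact formula ``D / (2 tan(threshold/2))``; at 3 degrees this differs
    from the small-angle approximation ``D / threshold`` by ~ 0.02 %.
    """
    if object_diameter < 0:
        raise ValueError("diameter must be >= 0")
    if not 0 < angular_threshold < math.pi:
        raise ValueError("angular threshold must lie in (0, pi)")
    return object_diameter / (2.0 * math.tan(angular_threshold / 2.0))


@dataclass
class FlowerField:
    """Uniform random flowers of a common diameter on a square field.

    The square has half-width ``extent`` (m) centred on the nest; the
    flower count is the deterministic ``round(density * area)``, matching
    an *average* density while keeping tests reproducible in N.
    """

    positions: np.ndarray      # (n, 2), m
    flower_diameter: float     # m
    density: float             # flowers / m^2
    extent: float              # field half-width, m
    angular_threshold: float = ANGULAR_THRESHOLD

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)

    @property
    def perception_distance(self) -> float:
        return perception_distance(self.flower_diameter, self.angular_threshold)

    @property
    def n_flowers(self) -> int:
        return len(self.positions)


def generate_field(density: float, diameter: float, extent: float = 1000.0,
                   rng: Generator | None = None) -> FlowerField:
    """Draw a uniform random field of ``round(density * (2 extent)^2)`` flowers."""
    if density < 0:
        raise ValueError("density must be >= 0")
    if not extent > 0:
        raise ValueError("extent must be > 0")
    rng = default_rng() if rng is None else rng
    n = int(round(density * (2.0 * extent) ** 2))
    positions = rng.uniform(-extent, extent, size=(n, 2))
    return FlowerField(positions=positions, flower_diameter=diameter,
                       density=density, extent=extent)
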