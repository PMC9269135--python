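"""Cylindrical EIT domain and multi-layer ring electrode array.

The sensing hardware this package models is a circle of vertical sticks
inserted in a soil or water column, each stick carrying several electrodes at
fixed vertical spacing. For the complete electrode model the electrodes are
idealized as patches on the lateral wall of the cylindrical finite-element
domain whose diameter equals the stick ring diameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import inches

__all__ = ["CylDomain", "ElectrodeArray", "build_electrode_array", "GeometryError"]


class GeometryError(ValueError):
    """Raised for inconsistent or non-physical geometry."""


@dataclass(frozen=True)
class CylDomain:
    """Cylindrical imaging domain.

    Parameters
    ----------
    height : float
        Cylinder height in meters.
    diameter : float
        Cylinder diameter in meters.
    background_sigma : float
        Homogeneous background conductivity in S/m.
    """

    height: float
    diameter: float
    background_sigma: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.diameter <= 0:
            raise GeometryError("domain height and diameter must be positive")
        if self.background_sigma <= 0:
            raise GeometryError("background conductivity must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        return np.pi * self.radius**2 * self.height


@dataclass(frozen=True)
class ElectrodePosition:
    """Placement of one electrode: stick/layer indices plus cylinder coordinates."""

    stick: int
    layer: int
    angle: float  # rad, stick azimuth, CCW from +x
    z_offset: float  # m, axial offset from the array's vertical center


@dataclass(frozen=True)
class ElectrodeArray:
    """Ring array of ``n_sticks`` sticks with ``layers`` electrodes each.

    Electrodes are numbered sequentially layer by layer (top layer first),
    counter-clockwise within a layer starting from the stick at azimuth 0.
    ``contact_impedance`` is the per-electrode contact impedance in Ω·m².
    ``contact_height`` is the axial extent of the idealized wall patch; the
    effective contact area on the domain boundary is a modeling parameter,
    not a measured quantity.
    """

    n_sticks: int
    layers: int
    ring_diameter: float
    layer_spacing: float
    electrode_length: float
    electrode_diameter: float
    contact_impedance: float = 0.01
    contact_height: float | None = None
    positions: tuple[ElectrodePosition, ...] = field(default=())

    @property
    def n_electrodes(self) -> int:
        return self.n_sticks * self.layers

    @property
    def ring_radius(self) -> float:
        return self.ring_diameter / 2.0

    def effective_contact_height(self) -> float:
        """Axial patch extent used on the idealized boundary.

        Defaults to the physical electrode length, capped at 80% of the layer
        spacing so that same-stick patches never overlap.
        """
        if self.contact_height is not None:
            return self.contact_height
        if self.layers > 1:
            return min(self.electrode_length, 0.8 * self.layer_spacing)
        return self.electrode_length

    def vertical_span(self) -> float:
        """Distance from top-layer patch top to bottom-layer patch bottom."""
        return (self.layers - 1) * self.layer_spacing + self.effective_contact_height()

    def layer_z_offsets(self) -> np.ndarray:
        """Axial layer-center offsets from the array center, top layer first."""
        half = (self.layers - 1) / 2.0
        return np.array([(half - i) * self.layer_spacing for i in range(self.layers)])


def build_electrode_array(
    n_sticks: int = 8,
    layers: int = 3,
    ring_diameter: float = inches(6.0),
    layer_spacing: float = inches(1.0),
    electrode_length: float = inches(2.0),
    electrode_diameter: float = inches(0.0625),
    contact_impedance: float = 0.01,
    contact_height: float | None = None,
    domain: CylDomain | None = None,
) -> ElectrodeArray:
    """Build a planar-aligned multi-layer ring electrode array.

    Sticks are equally spaced in angle; each stick's electrodes share one
    vertical line (planar alignment). If ``domain`` is given, the array is
    checked to fit inside it.
    """
    if n_sticks < 3:
        raise GeometryError("need at least 3 sticks for a ring array")
    if layers < 1:
        raise GeometryError("need at least one electrode layer")
    for name, v in [
        ("ring_diameter", ring_diameter),
        ("layer_spacing", layer_spacing),
        ("electrode_length", electrode_length),
        ("electrode_diameter", electrode_diameter),
        ("contact_impedance", contact_impedance),
    ]:
        if v <= 0:
            raise GeometryError(f"{name} must be positive, got {v}")

    arr = ElectrodeArray(
        n_sticks=n_sticks,
        layers=layers,
        ring_diameter=ring_diameter,
        layer_spacing=layer_spacing,
        electrode_length=electrode_length,
        electrode_diameter=electrode_diameter,
        contact_impedance=contact_impedance,
        contact_height=contact_height,
    )
    z_off = arr.layer_z_offsets()
    positions = tuple(
        ElectrodePosition(
            stick=s,
            layer=l,
            angle=2.0 * np.pi * s / n_sticks,
            z_offset=float(z_off[l]),
        )
        for l in range(layers)
        for s in range(n_sticks)
    )
    arr = ElectrodeArray(
        n_sticks=n_sticks,
        layers=layers,
        ring_diameter=ring_diameter,
        layer_spacing=layer_spacing,
        electrode_length=electrode_length,
        electrode_diameter=electrode_diameter,
        contact_impedance=contact_impedance,
        contact_height=contact_height,
        positions=positions,
    )

    if domain is not None:
        if ring_diameter > domain.diameter * (1 + 1e-12):
            raise GeometryError(
                f"electrode ring diameter {ring_diameter:.4f} m exceeds domain "
                f"diameter {domain.diameter:.4f} m"
            )
        if arr.vertical_span() > domain.height:
            raise GeometryError(
                f"electrode stack spans {arr.vertical_span():.4f} m, taller than "
                f"the domain height {domain.height:.4f} m"
            )
    return arr
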