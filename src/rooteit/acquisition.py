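"""Impedance-converter (AD5933-style) acquisition model.

The instrument excites the sample with a programmable-frequency sine, runs an
on-chip DFT, and reports real/imaginary outputs R and X. Impedance magnitude
follows from a gain factor calibrated against a known resistor:

    Z = 1 / (gain × √(R² + X²)),   gain = 1 / (R_cal × |DFT|_cal)

so re-measuring the calibration magnitude returns R_cal exactly. The sweep
frequency is quantized through a 29-bit code: f = f_clk × code / 2²⁹.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forward import CEMSystem
from .geometry import ElectrodeArray

__all__ = [
    "AcquisitionConfig",
    "DftReading",
    "ImpedanceTable",
    "TwoElectrodeModel",
    "gain_factor",
    "dft_to_impedance",
    "frequency_code",
    "physical_frequency",
    "reactance",
    "capacitance",
    "reactance_from_phase",
    "impedance_to_boundary_voltage",
    "two_pole_matrix",
]

F_CLK_DEFAULT = 16.776e6  # Hz, converter master clock
CODE_BITS = 29


@dataclass(frozen=True)
class AcquisitionConfig:
    f_clk: float = F_CLK_DEFAULT
    excitation: float = 2.0  # Vpp
    calibration_resistance: float = 7500.0  # Ω
    stimulation_current: float = 1e-3  # A

    def __post_init__(self) -> None:
        if not (0.2 <= self.excitation <= 2.0):
            raise ValueError("excitation must lie in [0.2, 2] Vpp")
        for name in ("f_clk", "calibration_resistance", "stimulation_current"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class DftReading:
    real: float
    imag: float
    frequency: float

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.real, self.imag))


@dataclass(frozen=True)
class TwoElectrodeModel:
    """Parallel-plate style two-electrode sample model (spacing d, area A)."""

    spacing: float  # m
    area: float  # m²
    medium_constant: float  # F/m
    capacitance: float = field(init=False)
    phase: float = 0.0  # rad

    def __post_init__(self) -> None:
        if min(self.spacing, self.area, self.medium_constant) <= 0:
            raise ValueError("spacing, area and medium constant must be positive")
        object.__setattr__(self, "capacitance", capacitance(self.medium_constant, self.area, self.spacing))


def gain_factor(calibration_resistance: float, dft_magnitude: float) -> float:
    """Gain calibrated so the conversion formula returns the reference resistor."""
    if calibration_resistance <= 0 or dft_magnitude <= 0:
        raise ValueError("calibration resistance and DFT magnitude must be positive")
    return 1.0 / (calibration_resistance * dft_magnitude)


def dft_to_impedance(reading: DftReading, gain: float) -> float:
    """Impedance magnitude Z = 1 / (gain × √(R² + X²))."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    mag = reading.magnitude
    if mag == 0:
        raise ValueError("zero DFT magnitude")
    return 1.0 / (gain * mag)


def frequency_code(f: float, f_clk: float = F_CLK_DEFAULT) -> int:
    """Integer frequency code: f = f_clk × code / 2²⁹."""
    if not (0 < f <= f_clk):
        raise ValueError(f"frequency {f} Hz outside (0, f_clk]")
    return int(round(f * 2**CODE_BITS / f_clk))


def physical_frequency(code: int, f_clk: float = F_CLK_DEFAULT) -> float:
    """Inverse of :func:`frequency_code`."""
    return f_clk * code / 2**CODE_BITS


def reactance(f: float, C: float) -> float:
    """Capacitive reactance X_c = 1/(2πfC)."""
    if f <= 0 or C <= 0:
        raise ValueError("frequency and capacitance must be positive")
    return 1.0 / (2.0 * np.pi * f * C)


def capacitance(eps: float, area: float, d: float) -> float:
    """Sample capacitance C = εA/d."""
    if min(eps, area, d) <= 0:
        raise ValueError("ε, A, d must be positive")
    return eps * area / d


def reactance_from_phase(Z: float, theta: float) -> float:
    """X_c = Z sin θ."""
    if Z <= 0:
        raise ValueError("impedance magnitude must be positive")
    return Z * np.sin(theta)


def impedance_to_boundary_voltage(Z: float, current: float) -> float:
    """Boundary voltage V = Z × I for a given stimulation current."""
    if Z <= 0 or current <= 0:
        raise ValueError("impedance and current must be positive")
    return Z * current


# ---------------------------------------------------------------------------
# Two-pole electrode-pair impedance tables
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "electrode_a",
    "electrode_b",
    "layer",
    "frequency_hz",
    "impedance_ohm",
    "condition",
    "sample_id",
    "replicate",
]


@dataclass
class ImpedanceTable:
    """Electrode-pair × frequency impedance magnitudes, as a tidy DataFrame."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TABLE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"impedance table missing columns: {sorted(missing)}")
        if np.any(self.data["impedance_ohm"] <= 0):
            raise ValueError("impedance magnitudes must be positive")

    def layer_slice(self, layer: int, frequency: float) -> pd.DataFrame:
        d = self.data
        return d[(d["layer"] == layer) & (np.isclose(d["frequency_hz"], frequency))]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ImpedanceTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_records(cls, recs) -> "ImpedanceTable":
        return cls(pd.DataFrame.from_records(recs, columns=TABLE_COLUMNS))


def two_pole_matrix(
    system: CEMSystem,
    layer: int,
    frequency: float,
    condition: str = "homogeneous",
    sample_id: str = "sim",
    replicate: int = 0,
) -> ImpedanceTable:
    """Simulated 8×8 (n×n per layer) two-pole impedance slice.

    Off-diagonal entries are transfer impedances through the drive pair
    itself, Z(a,b) = (U_a − U_b)/I, which include both contact impedances.
    The self-pair entry Z(a,a) is modeled as the pure contact path: twice the
    electrode's contact impedance divided by its patch area.
    """
    array: ElectrodeArray = system.array
    if not (0 <= layer < array.layers):
        raise ValueError(f"layer {layer} out of range")
    n = array.n_sticks
    offset = layer * n
    electrodes = list(range(offset, offset + n))

    pairs = [(a, b) for a in electrodes for b in electrodes if a < b]
    currents = np.zeros((len(pairs), system.n_electrodes))
    for i, (a, b) in enumerate(pairs):
        currents[i, a] = 1.0
        currents[i, b] = -1.0
    sols = np.atleast_2d(system.solve_currents(currents))
    U = system.electrode_potentials(sols)

    z = {}
    for i, (a, b) in enumerate(pairs):
        z[(a, b)] = z[(b, a)] = float(U[i, a] - U[i, b])
    for e in electrodes:
        z[(e, e)] = 2.0 * array.contact_impedance / system.mesh.electrode_area(e)

    recs = [
        (a - offset + 1, b - offset + 1, layer, frequency, z[(a, b)], condition, sample_id, replicate)
        for a in electrodes
        for b in electrodes
    ]
    return ImpedanceTable.from_records(recs)
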