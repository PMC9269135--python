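"""Synthetic phantoms and datasets standing in for hardware measurements.

Two generators are provided. The imaging generator plants a tapered,
root-like conductive inclusion in a homogeneous cylinder and simulates
boundary-voltage frame pairs through the CEM forward solver. The regression
generator emits per-layer two-pole impedance tables whose layer means follow
the log-linear law ln Z = a_f − b_f·W observed for tap roots: impedance
decreases with both frequency and fresh biomass weight.

All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acquisition import TABLE_COLUMNS, ImpedanceTable
from .forward import (
    ConductivityImage,
    MeasurementFrame,
    assemble_cem,
    forward_solve_fields,
)
from .geometry import CylDomain, ElectrodeArray, GeometryError
from .mesh import Mesh
from .protocol import Protocol
from .units import inches

__all__ = [
    "DispersionParams",
    "RootPhantom",
    "NoiseModel",
    "dispersion",
    "make_root_phantom",
    "simulate_measurement_pair",
    "BiomassRelation",
    "synth_biomass_dataset",
    "layer_mean_log_sd",
    "SOIL_SIGMA",
    "WATER_SIGMA",
    "ROOT_SIGMA_LOW",
]

# Background/root conductivity defaults (S/m). These are modeling choices for
# a moist growth substrate and a fresh tap root, exposed in configuration.
SOIL_SIGMA = 0.05
WATER_SIGMA = 0.02
ROOT_SIGMA_LOW = 0.1


@dataclass(frozen=True)
class DispersionParams:
    """Single-dispersion conductivity rise with frequency (β-type relaxation)."""

    sigma_high: float = 0.3  # S/m, high-frequency plateau
    f_c: float = 50e3  # Hz, characteristic frequency
    p: float = 1.0  # slope exponent

    def __post_init__(self) -> None:
        if min(self.sigma_high, self.f_c, self.p) <= 0:
            raise ValueError("dispersion parameters must be positive")


def dispersion(sigma_low: float, f: float, params: DispersionParams) -> float:
    """σ(f) = σ_low + (σ_high − σ_low)·(f/f_c)^p / (1 + (f/f_c)^p).

    Strictly increasing in f (tissue conducts better at higher frequency, so
    impedance falls as frequency rises).
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    if sigma_low <= 0:
        raise ValueError("sigma_low must be positive")
    x = (f / params.f_c) ** params.p
    return sigma_low + (params.sigma_high - sigma_low) * x / (1.0 + x)


@dataclass(frozen=True)
class RootPhantom:
    """Tapered-frustum root inclusion.

    Fresh weight (g) maps to inclusion volume through ``density`` (g/cm³);
    ``taper_ratio`` is the tip/top radius ratio of the frustum, which hangs
    from the top of the domain along a vertical axis at ``axis_position``.
    """

    length: float  # m
    fresh_weight: float  # g
    taper_ratio: float = 0.25
    axis_position: tuple[float, float] = (0.0, 0.0)
    density: float = 1.03  # g/cm³
    sigma_low: float = ROOT_SIGMA_LOW
    dispersion_params: DispersionParams = field(default_factory=DispersionParams)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.fresh_weight < 0:
            raise ValueError("length must be positive and weight non-negative")
        if not (0 < self.taper_ratio <= 1):
            raise ValueError("taper_ratio must lie in (0, 1]")
        if self.density <= 0:
            raise ValueError("density must be positive")

    @property
    def volume(self) -> float:
        """Inclusion volume in m³ from fresh weight and density."""
        return self.fresh_weight / self.density * 1e-6

    def top_radius(self) -> float:
        """Frustum top radius consistent with volume, length and taper."""
        t = self.taper_ratio
        return float(np.sqrt(3.0 * self.volume / (np.pi * self.length * (1 + t + t * t))))

    def sigma_root(self, frequency: float) -> float:
        return dispersion(self.sigma_low, frequency, self.dispersion_params)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise, seed-deterministic."""

    relative_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_root_phantom(
    phantom: RootPhantom,
    mesh: Mesh,
    background: CylDomain,
    frequency: float,
) -> ConductivityImage:
    """Paint the phantom into a per-element absolute conductivity image.

    Elements are ranked by their normalized distance to the frustum axis
    (radial distance over the local taper profile) and included from the
    inside out until the inclusion volume matches weight/density; the achieved
    volume therefore differs from the target by at most one element volume.
    """
    sig_root = phantom.sigma_root(frequency)
    if sig_root <= background.background_sigma:
        raise GeometryError(
            "root phantom must be more conductive than the background "
            f"(σ_root={sig_root:.3g}, σ_bg={background.background_sigma:.3g} S/m)"
        )
    values = np.full(mesh.n_elements, background.background_sigma)
    target = phantom.volume
    if target <= 0:
        return ConductivityImage(mesh, values, kind="absolute")

    H = background.height
    L = phantom.length
    if L > H * (1 + 1e-12):
        raise GeometryError(f"phantom length {L:.4f} m exceeds domain height {H:.4f} m")
    r_top = phantom.top_radius()
    ax, ay = phantom.axis_position
    if r_top + np.hypot(ax, ay) > background.radius:
        raise GeometryError("phantom does not fit inside the domain radius")

    c = mesh.element_centroids()
    z = c[:, 2]
    in_z = z >= H - L
    # normalized taper profile: 1 at the top of the domain, taper_ratio at the tip
    prof = phantom.taper_ratio + (1 - phantom.taper_ratio) * (z - (H - L)) / L
    radial = np.hypot(c[:, 0] - ax, c[:, 1] - ay)
    score = np.where(in_z & (prof > 0), radial / np.maximum(prof, 1e-30), np.inf)

    order = np.argsort(score, kind="stable")
    cum = np.cumsum(mesh.element_volumes[order])
    n_in = int(np.searchsorted(cum, target) + 1)
    n_in = min(n_in, int(np.isfinite(score).sum()))
    if n_in > 0 and cum[n_in - 1] - target > target - (cum[n_in - 2] if n_in > 1 else 0.0):
        n_in -= 1  # closer to target without the last element
    values[order[:n_in]] = sig_root
    return ConductivityImage(mesh, values, kind="absolute")


def simulate_measurement_pair(
    phantom: RootPhantom,
    mesh: Mesh,
    array: ElectrodeArray,
    protocol: Protocol,
    frequencies: list[float],
    noise: NoiseModel,
    background: CylDomain,
) -> tuple[list[MeasurementFrame], list[MeasurementFrame], dict]:
    """Simulate homogeneous/inhomogeneous frame pairs at each frequency.

    Returns (homogeneous frames, inhomogeneous frames, extras); extras carries
    the homogeneous CEM system, drive fields and phantom images for reuse in
    reconstruction (the Jacobian is evaluated at the background conductivity).
    """
    rng = noise.rng()
    h_frames: list[MeasurementFrame] = []
    i_frames: list[MeasurementFrame] = []
    extras: dict = {"systems": {}, "fields": {}, "images": {}}
    sigma_h = ConductivityImage.homogeneous(mesh, background.background_sigma)
    sys_h = assemble_cem(mesh, sigma_h, array)
    extras["background_system"] = sys_h
    for f in frequencies:
        frame_h, fields = forward_solve_fields(sys_h, protocol, frequency=f, condition="homogeneous")
        extras["fields"][f] = fields
        img = make_root_phantom(phantom, mesh, background, f)
        extras["images"][f] = img
        if np.any(img.values != background.background_sigma):
            sys_i = assemble_cem(mesh, img, array)
            frame_i, _ = forward_solve_fields(sys_i, protocol, frequency=f, condition="inhomogeneous")
        else:
            frame_i = MeasurementFrame(
                protocol=protocol, frequency=f, condition="inhomogeneous",
                voltages=frame_h.voltages.copy(),
            )
        if noise.relative_sd > 0:
            frame_h.voltages = frame_h.voltages * (
                1.0 + noise.relative_sd * rng.standard_normal(len(protocol))
            )
            frame_i.voltages = frame_i.voltages * (
                1.0 + noise.relative_sd * rng.standard_normal(len(protocol))
            )
        h_frames.append(frame_h)
        i_frames.append(frame_i)
    return h_frames, i_frames, extras


# ---------------------------------------------------------------------------
# Regression-ready impedance/biomass datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiomassRelation:
    """Log-linear impedance–biomass law: ln Z̄(f, W) = a_f − b_f·W.

    a_f = ln_z0 − freq_decay·ln(f/f_ref) (impedance falls with frequency),
    b_f = b0·(1 + b_growth·ln(f/f_ref)) (correlation strengthens with
    frequency, as observed at 100 kHz). Layer multipliers and a deterministic
    sinusoidal electrode-pair pattern reproduce the within-layer structure of
    ring measurements; their arithmetic mean is exactly 1, so layer means obey
    the law exactly at zero noise.
    """

    ln_z0: float = float(np.log(5000.0))  # ln Ω at f_ref for W = 0
    freq_decay: float = 0.25
    b0: float = 0.004  # 1/g at f_ref
    b_growth: float = 0.15
    f_ref: float = 5000.0  # Hz
    layer_multipliers: tuple[float, ...] = (1.05, 1.0, 0.95)
    pair_amplitude: float = 0.1

    def a(self, f: float) -> float:
        return self.ln_z0 - self.freq_decay * np.log(f / self.f_ref)

    def b(self, f: float) -> float:
        b = self.b0 * (1.0 + self.b_growth * np.log(f / self.f_ref))
        if b <= 0:
            raise ValueError(f"weight slope non-positive at {f} Hz; adjust b_growth")
        return b

    def layer_mean(self, f: float, weight: float) -> float:
        return float(np.exp(self.a(f) - self.b(f) * weight))


def layer_mean_log_sd(noise: NoiseModel, n_entries: int = 64) -> float:
    """Standard deviation of ln(layer-mean impedance) under the generator.

    Three noise components enter a layer mean: the per-sweep drift (sd), a
    per-layer term (sd/2), and per-entry noise averaged over ``n_entries``
    electrode pairs (sd/√n)."""
    sd = noise.relative_sd
    return float(np.sqrt(sd**2 + (0.5 * sd) ** 2 + sd**2 / n_entries))


def synth_biomass_dataset(
    n_samples: int = 9,
    weight_range: tuple[float, float] = (62.0, 115.0),
    frequencies: tuple[float, ...] = (5e3, 15e3, 25e3, 40e3, 60e3, 80e3, 100e3),
    relation: BiomassRelation | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    n_electrodes_per_layer: int = 8,
) -> tuple[ImpedanceTable, pd.DataFrame]:
    """Generate a regression-ready two-pole impedance table plus biomass table.

    Weights are evenly spread over ``weight_range`` (then jittered), lengths
    co-generated with positive correlation (length ∝ weight^⅓), and the
    sample-level noise ε is applied on the log-impedance scale so the fitted
    biomass RMSE at the default 2% log-noise lands near the few-gram scale of
    careful EIS replicate averaging.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    lo, hi = weight_range
    if not (0 < lo < hi):
        raise ValueError("degenerate weight_range")
    relation = relation or BiomassRelation()
    noise = noise or NoiseModel(relative_sd=0.02, seed=seed)
    rng = np.random.default_rng(seed)

    weights = np.linspace(lo, hi, n_samples)
    weights = weights + rng.uniform(-0.02, 0.02, n_samples) * (hi - lo) / n_samples
    weights = np.clip(weights, lo, hi)
    lengths = inches(6.75) * (weights / 62.0) ** (1.0 / 3.0)

    n = n_electrodes_per_layer
    aa, bb = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    # symmetric sinusoidal ring pattern; sums to zero over a full period, so
    # the arithmetic mean over the n×n grid is exactly 1
    pair_pattern = (
        1.0
        + relation.pair_amplitude
        * 0.5
        * (np.sin(2.0 * np.pi * aa / n) + np.sin(2.0 * np.pi * bb / n))
    ).ravel()

    noise_rng = noise.rng()
    sd = noise.relative_sd
    recs = []
    for s in range(n_samples):
        for f in frequencies:
            eps = sd * noise_rng.standard_normal()  # shared EIS drift per sweep
            base = np.exp(relation.a(f) - relation.b(f) * weights[s] + eps)
            for layer, mult in enumerate(relation.layer_multipliers):
                eps_layer = 0.5 * sd * noise_rng.standard_normal()
                entry_noise = 1.0 + sd * noise_rng.standard_normal(n * n)
                zmat = base * mult * np.exp(eps_layer) * pair_pattern * entry_noise
                idx = 0
                for a in range(1, n + 1):
                    for b in range(1, n + 1):
                        recs.append(
                            (a, b, layer, f, zmat[idx], "difference", f"sample{s + 1}", 0)
                        )
                        idx += 1
    table = ImpedanceTable(pd.DataFrame.from_records(recs, columns=TABLE_COLUMNS))
    biomass = pd.DataFrame(
        {
            "sample_id": [f"sample{s + 1}" for s in range(n_samples)],
            "weight_g": weights,
            "length_m": lengths,
        }
    )
    return table, biomass
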