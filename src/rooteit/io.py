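"""Run configuration, validation, and manifests.

A run is described by a YAML config with four blocks — geometry, acquisition,
inverse, phantom — plus a mesh block. Every stochastic step takes its seed
from the config so a run can be replayed exactly; each command writes a
manifest listing inputs, seed, package version and output checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .geometry import CylDomain, ElectrodeArray, build_electrode_array
from .inverse import DEFAULT_LAMBDA, InverseConfig
from .phantom import SOIL_SIGMA, DispersionParams, NoiseModel, RootPhantom
from .units import inches

__all__ = ["RunConfig", "load_config", "ConfigError", "write_manifest", "sha256_file"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Configuration problem, reported with a path to the offending field."""


def _get(block: dict, key: str, default=None, required=False, path=""):
    if key in block:
        return block[key]
    if required:
        raise ConfigError(f"missing required config field: {path}{key}")
    return default


@dataclass
class RunConfig:
    domain: CylDomain
    array: ElectrodeArray
    target_edge: float
    frequencies: list[float]
    current: float
    scheme: str
    inverse: InverseConfig
    phantom: RootPhantom | None
    noise: NoiseModel
    seed: int
    raw: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if cfg.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {cfg.get('schema_version')}")

    g = cfg.get("geometry", {})
    dom = g.get("domain", {})
    domain = CylDomain(
        height=float(_get(dom, "height_m", inches(8.0), path="geometry.domain.")),
        diameter=float(_get(dom, "diameter_m", inches(6.0), path="geometry.domain.")),
        background_sigma=float(_get(dom, "background_sigma", SOIL_SIGMA)),
    )
    a = g.get("array", {})
    array = build_electrode_array(
        n_sticks=int(_get(a, "n_sticks", 8)),
        layers=int(_get(a, "layers", 3)),
        ring_diameter=float(_get(a, "ring_diameter_m", domain.diameter)),
        layer_spacing=float(_get(a, "layer_spacing_m", inches(1.0))),
        electrode_length=float(_get(a, "electrode_length_m", inches(2.0))),
        electrode_diameter=float(_get(a, "electrode_diameter_m", inches(0.0625))),
        contact_impedance=float(_get(a, "contact_impedance", 0.01)),
        contact_height=a.get("contact_height_m"),
        domain=domain,
    )
    target_edge = float(_get(g, "target_edge_m", 0.02))

    acq = cfg.get("acquisition", {})
    freqs = [float(f) for f in _get(acq, "frequencies_hz", [5e3, 100e3])]
    if any(f <= 0 for f in freqs):
        raise ConfigError("acquisition.frequencies_hz must be positive")
    current = float(_get(acq, "current_a", 1e-3))
    scheme = str(_get(acq, "scheme", "adjacent"))

    inv = cfg.get("inverse", {})
    inverse = InverseConfig(
        lam=float(_get(inv, "lambda", DEFAULT_LAMBDA)),
        prior=str(_get(inv, "prior", "noser")),
        noser_exponent=float(_get(inv, "noser_exponent", 1.0)),
        normalization=str(_get(inv, "normalization", "normalized_difference")),
    )

    ph = cfg.get("phantom", {})
    seed = cfg.get("seed", ph.get("seed"))
    if seed is None:
        raise ConfigError("missing required config field: seed (stochastic steps need one)")
    seed = int(seed)
    noise = NoiseModel(relative_sd=float(_get(ph, "noise_relative_sd", 0.01)), seed=seed)
    phantom = None
    if "weight_g" in ph:
        disp = ph.get("dispersion", {})
        phantom = RootPhantom(
            length=float(_get(ph, "length_m", inches(6.75), path="phantom.")),
            fresh_weight=float(ph["weight_g"]),
            taper_ratio=float(_get(ph, "taper_ratio", 0.25)),
            axis_position=tuple(_get(ph, "axis_position_m", (0.0, 0.0))),
            density=float(_get(ph, "density_g_cm3", 1.03)),
            sigma_low=float(_get(ph, "sigma_low", 0.1)),
            dispersion_params=DispersionParams(
                sigma_high=float(_get(disp, "sigma_high", 0.3)),
                f_c=float(_get(disp, "f_c_hz", 50e3)),
                p=float(_get(disp, "p", 1.0)),
            ),
        )

    return RunConfig(
        domain=domain,
        array=array,
        target_edge=target_edge,
        frequencies=freqs,
        current=current,
        scheme=scheme,
        inverse=inverse,
        phantom=phantom,
        noise=noise,
        seed=seed,
        raw=cfg,
    )


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, config_path, outputs: list, seed: int) -> Path:
    """Write a replay manifest next to a command's outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "config": str(config_path) if config_path else None,
        "config_sha256": sha256_file(config_path) if config_path else None,
        "seed": seed,
        "package": "rooteit",
        "version": __version__,
        "outputs": {str(Path(p).name): sha256_file(p) for p in outputs},
    }
    path = out_dir / f"{command}_manifest.json"
    with open(path, "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return path
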