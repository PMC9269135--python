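"""One-step Gauss–Newton difference imaging.

The conductivity change between two measurement frames is obtained from the
single linearized, regularized least-squares update

    Δσ = (JᵀWJ + λ²R)⁻¹ JᵀW ΔV

with J the sensitivity matrix, W the measurement weighting (identity unless a
measurement covariance is known), and R either the identity (Tikhonov) or the
NOSER diagonal diag(JᵀWJ)^p. The hyperparameter λ trades resolution against
noise amplification; the default 2.17 is the value this sensor geometry was
tuned with.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .forward import ConductivityImage, MeasurementFrame
from .mesh import Mesh

__all__ = [
    "InverseConfig",
    "voltage_difference",
    "build_prior",
    "reconstruct_one_step",
    "time_difference_series",
    "scale_jacobian_normalized",
    "IllConditionedWarning",
    "DEFAULT_LAMBDA",
]

DEFAULT_LAMBDA = 2.17


class IllConditionedWarning(UserWarning):
    pass


@dataclass(frozen=True)
class InverseConfig:
    """Configuration of the one-step Gauss–Newton reconstruction."""

    lam: float = DEFAULT_LAMBDA
    prior: str = "noser"  # "noser" | "tikhonov"
    noser_exponent: float = 1.0
    weight: np.ndarray | str = "identity"
    normalization: str = "normalized_difference"  # | "raw_difference"
    condition_warn: float = 1e12

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("hyperparameter λ must be positive")
        if not (0 < self.noser_exponent <= 1):
            raise ValueError("NOSER exponent must lie in (0, 1]")
        if self.prior not in ("noser", "tikhonov"):
            raise ValueError(f"unknown prior '{self.prior}'")
        if self.normalization not in ("normalized_difference", "raw_difference"):
            raise ValueError(f"unknown normalization '{self.normalization}'")

    def weight_matrix(self, n_meas: int) -> np.ndarray:
        if isinstance(self.weight, str):
            if self.weight != "identity":
                raise ValueError(f"unknown weight spec '{self.weight}'")
            return np.eye(n_meas)
        W = np.asarray(self.weight, dtype=float)
        if W.shape != (n_meas, n_meas):
            raise ValueError("weight matrix shape mismatch")
        return W


def _check_pair(v_h: MeasurementFrame, v_i: MeasurementFrame) -> None:
    if v_h.protocol is not v_i.protocol and v_h.protocol.rows != v_i.protocol.rows:
        raise ValueError("frames must share the same protocol")
    if v_h.frequency != v_i.frequency:
        raise ValueError("frames must share the same frequency")


def voltage_difference(
    v_h: MeasurementFrame, v_i: MeasurementFrame, normalization: str = "normalized_difference"
) -> np.ndarray:
    """ΔV between inhomogeneous and homogeneous frames.

    raw_difference        : ΔV = V_i − V_h
    normalized_difference : ΔV = (V_i − V_h) / V_h  (elementwise)
    """
    _check_pair(v_h, v_i)
    if v_h.condition != "homogeneous" or v_i.condition != "inhomogeneous":
        raise ValueError(
            "expected (homogeneous, inhomogeneous) frames, got "
            f"({v_h.condition}, {v_i.condition})"
        )
    diff = v_i.voltages - v_h.voltages
    if normalization == "raw_difference":
        return diff
    if normalization == "normalized_difference":
        if np.any(v_h.voltages == 0):
            raise ValueError("zero homogeneous voltage; cannot normalize")
        return diff / v_h.voltages
    raise ValueError(f"unknown normalization '{normalization}'")


def scale_jacobian_normalized(J: np.ndarray, v_h: MeasurementFrame) -> np.ndarray:
    """Row-scale J by 1/V_h so it is consistent with normalized differences."""
    if np.any(v_h.voltages == 0):
        raise ValueError("zero homogeneous voltage; cannot normalize Jacobian")
    return J / v_h.voltages[:, None]


def build_prior(J: np.ndarray | None, config: InverseConfig, n_elements: int | None = None) -> np.ndarray:
    """Regularization matrix R: identity (tikhonov) or NOSER diagonal.

    NOSER entries are diag(JᵀWJ)**exponent; zero (insensitive-element) entries
    are floored at a small ε with a warning.
    """
    if config.prior == "tikhonov":
        if n_elements is None:
            if J is None:
                raise ValueError("need J or n_elements to size the prior")
            n_elements = J.shape[1]
        return np.eye(n_elements)
    if J is None:
        raise ValueError("NOSER prior requires the Jacobian")
    d = _prior_diagonal(J, config)
    return np.diag(d)


def _prior_diagonal(J: np.ndarray, config: InverseConfig) -> np.ndarray:
    """Diagonal of the regularization matrix (both priors are diagonal)."""
    if config.prior == "tikhonov":
        return np.ones(J.shape[1])
    if isinstance(config.weight, str):  # identity fast path
        d = np.einsum("me,me->e", J, J)
    else:
        W = config.weight_matrix(J.shape[0])
        d = np.einsum("me,mn,ne->e", J, W, J)
    if np.any(d <= 0):
        eps = max(d.max(), 1.0) * 1e-12
        warnings.warn(
            f"{int((d <= 0).sum())} insensitive elements; flooring NOSER diagonal at {eps:.3e}",
            IllConditionedWarning,
        )
        d = np.maximum(d, eps)
    return d**config.noser_exponent


def reconstruct_one_step(
    J: np.ndarray,
    delta_v: np.ndarray,
    config: InverseConfig,
    mesh: Mesh | None = None,
) -> ConductivityImage | np.ndarray:
    """One-step Gauss–Newton update Δσ = (JᵀWJ + λ²R)⁻¹ JᵀW ΔV.

    Returns a difference ConductivityImage if ``mesh`` is given, else the raw
    Δσ vector. Values are in normalized (dimensionless) units when ΔV is a
    normalized difference.
    """
    J = np.asarray(J, dtype=float)
    delta_v = np.asarray(delta_v, dtype=float)
    if J.shape[0] != delta_v.shape[0]:
        raise ValueError(f"J has {J.shape[0]} rows but ΔV has {delta_v.shape[0]}")
    m, n_el = J.shape
    identity_w = isinstance(config.weight, str)
    r_diag = _prior_diagonal(J, config)

    if n_el > m:
        # Both priors are diagonal, so the normal equations are solved in
        # measurement space via the Woodbury identity:
        #   (λ²R + JᵀWJ)⁻¹JᵀW = R⁻¹Jᵀ (λ²W⁻¹ + J R⁻¹ Jᵀ)⁻¹
        Jr = J / r_diag[None, :]
        M = J @ Jr.T
        if identity_w:
            M[np.diag_indices_from(M)] += config.lam**2
        else:
            W = config.weight_matrix(m)
            M += config.lam**2 * np.linalg.inv(W)
        cond = np.linalg.cond(M)
        if cond > config.condition_warn:
            warnings.warn(
                f"regularized system is ill-conditioned (cond ≈ {cond:.3e})",
                IllConditionedWarning,
            )
        dsigma = Jr.T @ sla.solve(M, delta_v, assume_a="pos")
    else:
        W = np.eye(m) if identity_w else config.weight_matrix(m)
        A = J.T @ W @ J + config.lam**2 * np.diag(r_diag)
        cond = np.linalg.cond(A)
        if cond > config.condition_warn:
            warnings.warn(
                f"regularized normal equations are ill-conditioned (cond ≈ {cond:.3e})",
                IllConditionedWarning,
            )
        cho = sla.cho_factor(A)
        dsigma = sla.cho_solve(cho, J.T @ (W @ delta_v))
    if mesh is not None:
        return ConductivityImage(mesh, dsigma, kind="difference")
    return dsigma


def time_difference_series(
    frames: list[MeasurementFrame],
    reference_index: int,
    J: np.ndarray,
    config: InverseConfig,
    mesh: Mesh | None = None,
) -> list[ConductivityImage | np.ndarray]:
    """Reconstruct each frame against a reference frame (time-difference EIT)."""
    if not frames:
        raise ValueError("empty frame list")
    ref = frames[reference_index]
    for fr in frames:
        if fr.protocol.rows != ref.protocol.rows:
            raise ValueError("all frames must share the reference protocol")
    out = []
    for fr in frames:
        diff = fr.voltages - ref.voltages
        if config.normalization == "normalized_difference":
            if np.any(ref.voltages == 0):
                raise ValueError("zero reference voltage; cannot normalize")
            diff = diff / ref.voltages
        out.append(reconstruct_one_step(J, diff, config, mesh=mesh))
    return out


def layer_summary(image: ConductivityImage, n_bands: int = 3) -> "pd.DataFrame":
    """Max/min Δσ per horizontal band of the mesh (top band first)."""
    import pandas as pd

    z = image.mesh.element_centroids()[:, 2]
    zmin, zmax = z.min(), z.max()
    edges = np.linspace(zmin, zmax, n_bands + 1)
    recs = []
    for b in range(n_bands):
        lo, hi = edges[n_bands - 1 - b], edges[n_bands - b]
        m = (z >= lo) & (z <= hi)
        vals = image.values[m]
        recs.append((b + 1, float(vals.max()), float(vals.min())))
    return pd.DataFrame(recs, columns=["band", "max_dsigma", "min_dsigma"])
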