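"""Complete-electrode-model (CEM) finite element forward solver.

Solves ∇·σ∇V = 0 in the cylinder with CEM boundary conditions: finite
electrode patches with contact impedance z_l, prescribed net current per
electrode, zero flux elsewhere, and the gauge fixed by constraining the
electrode potentials to sum to zero (Lagrange multiplier). First-order
(P1) tetrahedral elements; piecewise-constant conductivity per element.

The sensitivity (Jacobian) of measured voltages to per-element conductivity
is computed with the adjoint method:

    ∂V_m/∂σ_e = −(1/I_meas) ∫_e ∇u_drive(m) · ∇u_sense(m) dV

where u_sense is the field obtained by driving unit current through row m's
measurement pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ElectrodeArray
from .mesh import Mesh
from .protocol import Protocol

__all__ = [
    "ConductivityImage",
    "MeasurementFrame",
    "CEMSystem",
    "assemble_cem",
    "forward_solve",
    "compute_jacobian",
    "frames_to_csv",
    "frames_from_csv",
    "ForwardError",
]


class ForwardError(RuntimeError):
    pass


@dataclass
class ConductivityImage:
    """Per-element conductivity (absolute, S/m) or conductivity change.

    ``kind`` is "absolute" (strictly positive values) or "difference"
    (normalized, signed changes)."""

    mesh: Mesh
    values: np.ndarray
    kind: str = "absolute"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != self.mesh.n_elements:
            raise ValueError(
                f"{self.values.shape[0]} values for {self.mesh.n_elements} elements"
            )
        if self.kind not in ("absolute", "difference"):
            raise ValueError(f"unknown image kind '{self.kind}'")
        if self.kind == "absolute" and np.any(self.values <= 0):
            raise ValueError("absolute conductivity images must be strictly positive")

    @classmethod
    def homogeneous(cls, mesh: Mesh, sigma: float) -> "ConductivityImage":
        return cls(mesh, np.full(mesh.n_elements, float(sigma)), kind="absolute")


@dataclass
class MeasurementFrame:
    """Boundary voltages for one protocol at one frequency and condition."""

    protocol: Protocol
    frequency: float
    condition: str  # "homogeneous" | "inhomogeneous"
    voltages: np.ndarray

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.shape[0] != len(self.protocol):
            raise ValueError("voltage count must equal protocol row count")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


def _element_gradients(mesh: Mesh) -> np.ndarray:
    """(E, 4, 3) gradients of the four P1 basis functions per tetrahedron."""
    p = mesh.nodes[mesh.elements]  # (E,4,3)
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    e3 = p[:, 3] - p[:, 0]
    J = np.stack([e1, e2, e3], axis=2)  # (E,3,3) columns are edges
    Jinv = np.linalg.inv(J)  # rows of Jinv are gradients of λ1..λ3
    g = np.empty((mesh.n_elements, 4, 3))
    g[:, 1:] = Jinv
    g[:, 0] = -Jinv.sum(axis=1)
    return g


@dataclass
class CEMSystem:
    """Assembled CEM system ready for factorization and repeated solves."""

    mesh: Mesh
    array: ElectrodeArray
    sigma: ConductivityImage
    matrix: sp.csc_matrix
    grads: np.ndarray  # (E,4,3) P1 basis gradients
    _lu: spla.SuperLU | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes

    @property
    def n_electrodes(self) -> int:
        return self.array.n_electrodes

    def factorize(self) -> spla.SuperLU:
        if self._lu is None:
            try:
                self._lu = spla.splu(self.matrix)
            except RuntimeError as err:  # pragma: no cover - singular systems
                raise ForwardError(f"CEM system factorization failed: {err}") from err
        return self._lu

    def solve_currents(self, currents: np.ndarray) -> np.ndarray:
        """Solve for one or more electrode current patterns.

        ``currents``: (L,) or (n_rhs, L) net current per electrode (A).
        Returns solution vectors of length N + L + 1 (nodal potentials,
        electrode potentials, gauge multiplier), shaped like the input.
        """
        currents = np.atleast_2d(np.asarray(currents, dtype=float))
        if currents.shape[1] != self.n_electrodes:
            raise ForwardError("current pattern length must equal electrode count")
        n = self.n_nodes + self.n_electrodes + 1
        rhs = np.zeros((currents.shape[0], n))
        rhs[:, self.n_nodes : self.n_nodes + self.n_electrodes] = currents
        lu = self.factorize()
        sol = lu.solve(rhs.T)
        if not np.all(np.isfinite(sol)):
            raise ForwardError("CEM solve produced non-finite values")
        out = sol.T
        return out[0] if out.shape[0] == 1 else out

    def electrode_potentials(self, solution: np.ndarray) -> np.ndarray:
        return solution[..., self.n_nodes : self.n_nodes + self.n_electrodes]


def assemble_cem(mesh: Mesh, sigma: ConductivityImage, array: ElectrodeArray) -> CEMSystem:
    """Assemble the symmetric CEM system matrix.

    Block structure (u = nodal potentials, U = electrode potentials,
    γ = gauge multiplier)::

        [ K + S   B    0 ] [u]   [0]
        [ Bᵀ      D    1 ] [U] = [I]
        [ 0       1ᵀ   0 ] [γ]   [0]

    with K the σ-weighted stiffness matrix, S/B/D the contact-impedance
    surface couplings, and the last row enforcing ΣU_l = 0.
    """
    if sigma.kind != "absolute":
        raise ForwardError("forward assembly needs an absolute conductivity image")
    if sigma.mesh is not mesh and sigma.values.shape[0] != mesh.n_elements:
        raise ForwardError("conductivity image does not match the mesh")
    if np.any(sigma.values <= 0):
        raise ForwardError("conductivity must be strictly positive everywhere")

    N = mesh.n_nodes
    L = array.n_electrodes
    grads = _element_gradients(mesh)
    vols = mesh.element_volumes
    sig = sigma.values

    # volume stiffness: K_ij = Σ_e σ_e vol_e ∇φ_i·∇φ_j
    gg = np.einsum("eid,ejd->eij", grads, grads)  # (E,4,4)
    ke = gg * (sig * vols)[:, None, None]
    ii = np.repeat(mesh.elements, 4, axis=1).reshape(-1)
    jj = np.tile(mesh.elements, (1, 4)).reshape(-1)
    K = sp.coo_matrix((ke.reshape(-1), (ii, jj)), shape=(N, N))

    # electrode surface terms
    zc = array.contact_impedance
    tri_mass = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    s_rows, s_cols, s_vals = [], [], []
    b_rows, b_cols, b_vals = [], [], []
    D = np.zeros(L)
    for el, face_idx in mesh.electrode_faces.items():
        faces = mesh.boundary_faces[face_idx]
        areas = mesh.face_areas(faces)
        D[el] = areas.sum() / zc
        for f, a in zip(faces, areas):
            m = tri_mass * a / zc
            for p in range(3):
                b_rows.append(f[p])
                b_cols.append(el)
                b_vals.append(-a / (3.0 * zc))
                for q in range(3):
                    s_rows.append(f[p])
                    s_cols.append(f[q])
                    s_vals.append(m[p, q])
    S = sp.coo_matrix((s_vals, (s_rows, s_cols)), shape=(N, N))
    B = sp.coo_matrix((b_vals, (b_rows, b_cols)), shape=(N, L))

    ones = sp.coo_matrix((np.ones(L), (np.arange(L), np.zeros(L, dtype=int))), shape=(L, 1))
    zero_N1 = sp.coo_matrix((N, 1))
    A = sp.bmat(
        [
            [K + S, B, zero_N1],
            [B.T, sp.diags(D), ones],
            [zero_N1.T, ones.T, None],
        ],
        format="csc",
    )
    return CEMSystem(mesh=mesh, array=array, sigma=sigma, matrix=A, grads=grads)


def _pair_currents(system: CEMSystem, pairs: list[tuple[int, int]], amp: float) -> np.ndarray:
    cur = np.zeros((len(pairs), system.n_electrodes))
    for i, (p, n) in enumerate(pairs):
        cur[i, p] += amp
        cur[i, n] -= amp
    return cur


def forward_solve(system: CEMSystem, protocol: Protocol) -> MeasurementFrame:
    """Compute one boundary voltage per protocol row (frequency left at 1 Hz).

    Voltages are reported as (sense+ − sense−) electrode potentials with
    positive current injected at drive+.
    """
    frame, _ = forward_solve_fields(system, protocol)
    return frame


def forward_solve_fields(
    system: CEMSystem, protocol: Protocol, frequency: float = 1.0, condition: str = "homogeneous"
) -> tuple[MeasurementFrame, dict[tuple[int, int], np.ndarray]]:
    """Forward solve returning the frame plus the field per unique drive pair."""
    if protocol.n_electrodes != system.n_electrodes:
        raise ForwardError(
            f"protocol is for {protocol.n_electrodes} electrodes, system has "
            f"{system.n_electrodes}"
        )
    pairs = protocol.drive_pairs()
    sols = np.atleast_2d(
        system.solve_currents(_pair_currents(system, pairs, protocol.current_amplitude))
    )
    fields = {p: sols[i] for i, p in enumerate(pairs)}
    U = system.electrode_potentials(sols)
    by_pair = {p: U[i] for i, p in enumerate(pairs)}
    volts = np.array(
        [by_pair[(r.drive_pos, r.drive_neg)][r.sense_pos] - by_pair[(r.drive_pos, r.drive_neg)][r.sense_neg] for r in protocol.rows]
    )
    return (
        MeasurementFrame(protocol=protocol, frequency=frequency, condition=condition, voltages=volts),
        fields,
    )


def compute_jacobian(
    system: CEMSystem,
    protocol: Protocol,
    fields: dict[tuple[int, int], np.ndarray] | None = None,
) -> np.ndarray:
    """Adjoint sensitivity matrix J (rows = protocol rows, cols = elements).

    J[m, e] = ∂(voltage of row m)/∂(σ of element e). If ``fields`` from
    :func:`forward_solve_fields` is supplied, the drive solves are reused.
    """
    if protocol.n_electrodes != system.n_electrodes:
        raise ForwardError("protocol/system electrode count mismatch")
    drive_pairs = protocol.drive_pairs()
    if fields is None:
        sols = np.atleast_2d(
            system.solve_currents(
                _pair_currents(system, drive_pairs, protocol.current_amplitude)
            )
        )
        fields = {p: sols[i] for i, p in enumerate(drive_pairs)}
    sense_pairs = protocol.sense_pairs()
    adj = np.atleast_2d(system.solve_currents(_pair_currents(system, sense_pairs, 1.0)))
    adj_fields = {p: adj[i] for i, p in enumerate(sense_pairs)}

    N = system.n_nodes
    elems = system.mesh.elements
    vols = system.mesh.element_volumes

    def elem_grad(sol: np.ndarray) -> np.ndarray:
        # (E,3) constant gradient of the P1 field on each element
        return np.einsum("eid,ei->ed", system.grads, sol[:N][elems])

    gdrive = {p: elem_grad(f) for p, f in fields.items()}
    gsense = {p: elem_grad(f) for p, f in adj_fields.items()}

    J = np.empty((len(protocol), system.mesh.n_elements))
    for m, r in enumerate(protocol.rows):
        gd = gdrive[(r.drive_pos, r.drive_neg)]
        gs = gsense[(r.sense_pos, r.sense_neg)]
        J[m] = -vols * np.einsum("ed,ed->e", gd, gs)
    return J


# ---------------------------------------------------------------------------
# CSV serialization of measurement frames
# ---------------------------------------------------------------------------

FRAME_COLUMNS = [
    "row_id",
    "drive_pos",
    "drive_neg",
    "sense_pos",
    "sense_neg",
    "frequency_hz",
    "condition",
    "voltage_v",
]


def frames_to_csv(frames: list[MeasurementFrame], path) -> None:
    recs = []
    for fr in frames:
        for i, (row, v) in enumerate(zip(fr.protocol.rows, fr.voltages)):
            recs.append(
                (i, row.drive_pos, row.drive_neg, row.sense_pos, row.sense_neg,
                 fr.frequency, fr.condition, v)
            )
    pd.DataFrame.from_records(recs, columns=FRAME_COLUMNS).to_csv(path, index=False)


def frames_from_csv(path, protocol: Protocol) -> list[MeasurementFrame]:
    df = pd.read_csv(path)
    frames = []
    for (freq, cond), grp in df.groupby(["frequency_hz", "condition"], sort=True):
        grp = grp.sort_values("row_id")
        if len(grp) != len(protocol):
            raise ValueError(
                f"frame at {freq} Hz/{cond} has {len(grp)} rows, protocol expects "
                f"{len(protocol)}"
            )
        frames.append(
            MeasurementFrame(
                protocol=protocol,
                frequency=float(freq),
                condition=str(cond),
                voltages=grp["voltage_v"].to_numpy(),
            )
        )
    return frames
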