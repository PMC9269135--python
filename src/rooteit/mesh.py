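"""Structured tetrahedral meshing of the cylindrical EIT domain.

The mesh is built deterministically: a polar triangulation of the disk
cross-section (a center vertex plus ``nr`` concentric rings of ``na`` nodes)
is extruded through a sorted list of z-levels, and every resulting prism is
split into three tetrahedra with the classic minimum-vertex-index rule so the
decomposition is conforming across shared quad faces. Identical inputs give
identical node orderings.

The angular resolution is always a multiple of the stick count so that every
stick azimuth coincides with a mesh node line, and extra z-levels are inserted
at electrode patch edges so patches are tiled exactly by boundary faces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CylDomain, ElectrodeArray, GeometryError

__all__ = ["Mesh", "build_cylinder_mesh", "write_vtk", "read_vtk", "MeshError"]


class MeshError(RuntimeError):
    """Raised when mesh generation produces an invalid mesh."""


@dataclass
class Mesh:
    """Tetrahedral mesh with electrode boundary patches.

    Attributes
    ----------
    nodes : (N, 3) float array, meters
    elements : (E, 4) int array of node indices (positive orientation)
    boundary_faces : (B, 3) int array of node indices
    electrode_faces : dict mapping electrode index -> array of boundary-face rows
    element_volumes : (E,) float array, m³
    """

    nodes: np.ndarray
    elements: np.ndarray
    boundary_faces: np.ndarray
    electrode_faces: dict[int, np.ndarray]
    element_volumes: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def face_areas(self, faces: np.ndarray) -> np.ndarray:
        p = self.nodes[faces]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def electrode_area(self, electrode: int) -> float:
        return float(self.face_areas(self.boundary_faces[self.electrode_faces[electrode]]).sum())


def _tet_volumes(nodes: np.ndarray, elements: np.ndarray) -> np.ndarray:
    p = nodes[elements]
    return (
        np.einsum(
            "ij,ij->i",
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
            p[:, 3] - p[:, 0],
        )
        / 6.0
    )


def _split_prism(b0, b1, b2, t0, t1, t2):
    """Split a prism into 3 tets using the minimum-vertex-index rule.

    Bottom (b0,b1,b2) and top (t0,t1,t2) with ti vertically above bi. The
    diagonal of every quad face passes through the face's smallest global
    vertex index, which makes splits of adjacent prisms agree.
    """
    verts = [b0, b1, b2, t0, t1, t2]
    k = int(np.argmin(verts))
    if k >= 3:
        # flip: 180° symmetry that exchanges bottom and top
        b0, b1, b2, t0, t1, t2 = t0, t2, t1, b0, b2, b1
        k -= 3
        if k == 1:
            k = 2
        elif k == 2:
            k = 1
    # rotate so smallest vertex is b0
    for _ in range(k):
        b0, b1, b2, t0, t1, t2 = b1, b2, b0, t1, t2, t0
    if min(b1, t2) < min(b2, t1):
        return [(b0, b1, b2, t2), (b0, b1, t2, t1), (b0, t1, t2, t0)]
    return [(b0, b1, b2, t1), (b0, t1, b2, t2), (b0, t1, t2, t0)]


def _disk_triangulation(radius: float, na: int, nr: int):
    """Polar triangulation: center node + nr rings of na nodes each."""
    pts = [(0.0, 0.0)]
    for k in range(1, nr + 1):
        r = radius * k / nr
        for j in range(na):
            th = 2.0 * np.pi * j / na
            pts.append((r * np.cos(th), r * np.sin(th)))
    pts = np.asarray(pts)

    def ring(k: int, j: int) -> int:  # 1-based ring index
        return 1 + (k - 1) * na + (j % na)

    tris = []
    for j in range(na):
        tris.append((0, ring(1, j), ring(1, j + 1)))
    for k in range(1, nr):
        for j in range(na):
            a0, a1 = ring(k, j), ring(k, j + 1)
            b0, b1 = ring(k + 1, j), ring(k + 1, j + 1)
            tris.append((a0, b0, b1))
            tris.append((a0, b1, a1))
    return pts, np.asarray(tris, dtype=np.int64)


def _z_levels(height: float, target_edge: float, array: ElectrodeArray) -> np.ndarray:
    nz = max(2, int(np.ceil(height / target_edge)))
    levels = list(np.linspace(0.0, height, nz + 1))
    h = array.effective_contact_height()
    for pos in array.positions:
        zc = height / 2.0 + pos.z_offset
        for edge in (zc - h / 2.0, zc + h / 2.0):
            if 0.0 < edge < height:
                levels.append(edge)
    levels = np.array(sorted(levels))
    # merge levels closer than 1% of target_edge to avoid sliver layers
    keep = [levels[0]]
    for z in levels[1:]:
        if z - keep[-1] > 0.01 * target_edge:
            keep.append(z)
    keep[-1] = height
    return np.asarray(keep)


def build_cylinder_mesh(
    domain: CylDomain, array: ElectrodeArray, target_edge: float
) -> Mesh:
    """Mesh the cylinder and attach electrode wall patches.

    ``target_edge`` (m) sets the nominal element edge length; it must be
    positive and smaller than the electrode length so each patch is resolved
    by several faces.
    """
    if target_edge <= 0:
        raise MeshError("target_edge must be positive")
    if target_edge >= array.electrode_length:
        raise MeshError(
            f"target_edge {target_edge} must be smaller than the electrode "
            f"length {array.electrode_length}"
        )
    if abs(array.ring_diameter - domain.diameter) > 1e-9 * domain.diameter:
        raise GeometryError(
            "electrode ring diameter must equal the FEM domain diameter "
            f"(got ring {array.ring_diameter}, domain {domain.diameter}); "
            "the complete electrode model places electrodes on the boundary"
        )
    if array.vertical_span() > domain.height:
        raise GeometryError("electrode stack is taller than the domain")

    R = domain.radius
    circumference = 2.0 * np.pi * R
    na = int(np.ceil(circumference / target_edge))
    na = max(array.n_sticks, int(np.ceil(na / array.n_sticks)) * array.n_sticks)
    nr = max(2, int(np.ceil(R / target_edge)))
    zs = _z_levels(domain.height, target_edge, array)

    disk_pts, tris = _disk_triangulation(R, na, nr)
    npd = disk_pts.shape[0]
    nlev = zs.shape[0]

    nodes = np.empty((npd * nlev, 3))
    for i, z in enumerate(zs):
        nodes[i * npd : (i + 1) * npd, 0:2] = disk_pts
        nodes[i * npd : (i + 1) * npd, 2] = z

    elements = []
    for i in range(nlev - 1):
        lo, hi = i * npd, (i + 1) * npd
        for (a, b, c) in tris:
            elements.extend(_split_prism(lo + a, lo + b, lo + c, hi + a, hi + b, hi + c))
    elements = np.asarray(elements, dtype=np.int64)

    vols = _tet_volumes(nodes, elements)
    neg = vols < 0
    if np.any(neg):  # canonicalize orientation
        elements[neg] = elements[neg][:, [0, 1, 3, 2]]
        vols = np.abs(vols)
    if np.any(vols <= 1e-18):
        raise MeshError("degenerate (zero-volume) tetrahedra produced")

    boundary = _boundary_faces(elements)
    mesh = Mesh(
        nodes=nodes,
        elements=elements,
        boundary_faces=boundary,
        electrode_faces={},
        element_volumes=vols,
    )
    mesh.electrode_faces = _assign_electrode_faces(mesh, domain, array, na)
    return mesh


def _boundary_faces(elements: np.ndarray) -> np.ndarray:
    faces = elements[:, [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]]].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


def _assign_electrode_faces(
    mesh: Mesh, domain: CylDomain, array: ElectrodeArray, na: int
) -> dict[int, np.ndarray]:
    R = domain.radius
    pts = mesh.nodes[mesh.boundary_faces]
    cent = pts.mean(axis=1)
    rad = np.linalg.norm(mesh.nodes[mesh.boundary_faces][:, :, :2], axis=2)
    on_wall = np.all(rad > R * (1 - 1e-9), axis=1)
    theta = np.arctan2(cent[:, 1], cent[:, 0])
    h = array.effective_contact_height()
    dtheta = 2.0 * np.pi / na  # one angular face column on each side of the stick

    out: dict[int, np.ndarray] = {}
    claimed = np.zeros(mesh.boundary_faces.shape[0], dtype=bool)
    for e, pos in enumerate(array.positions):
        zc = domain.height / 2.0 + pos.z_offset
        dang = np.abs((theta - pos.angle + np.pi) % (2.0 * np.pi) - np.pi)
        in_col = on_wall & (dang < dtheta * (1 - 1e-9))
        in_win = in_col & (np.abs(cent[:, 2] - zc) < h / 2.0 + 1e-12)
        idx = np.flatnonzero(in_win & ~claimed)
        if idx.size == 0:
            # coarse axial grid: fall back to the nearest unclaimed wall faces
            cand = np.flatnonzero(in_col & ~claimed)
            if cand.size == 0:
                raise MeshError(f"electrode {e} received no boundary faces")
            dz = np.abs(cent[cand, 2] - zc)
            idx = cand[dz <= dz.min() + 1e-12]
        claimed[idx] = True
        out[e] = idx
    return out


# ---------------------------------------------------------------------------
# Legacy-ASCII VTK unstructured-grid I/O
# ---------------------------------------------------------------------------


def write_vtk(
    path,
    mesh: Mesh,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "rooteit mesh",
) -> None:
    """Write the mesh (and optional per-element scalars) as legacy ASCII VTK."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title}\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for p in mesh.nodes:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        f.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}\n")
        for el in mesh.elements:
            f.write(f"4 {el[0]} {el[1]} {el[2]} {el[3]}\n")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        f.write("\n".join(["10"] * mesh.n_elements) + "\n")
        if cell_data:
            f.write(f"CELL_DATA {mesh.n_elements}\n")
            for name, vals in cell_data.items():
                vals = np.asarray(vals, dtype=float)
                if vals.shape[0] != mesh.n_elements:
                    raise ValueError(f"cell data '{name}' length mismatch")
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{v:.12g}" for v in vals) + "\n")


def read_vtk(path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read points, tetrahedra, and per-cell scalars from a legacy ASCII VTK file."""
    with open(path) as f:
        tokens = f.read().split()

    def find(word: str, start: int) -> int:
        for j in range(start, len(tokens)):
            if tokens[j].upper() == word:
                return j
        raise ValueError(f"VTK file missing {word}")

    i = find("POINTS", 0)
    n_pts = int(tokens[i + 1])
    pts = np.array(tokens[i + 3 : i + 3 + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    i = find("CELLS", i)
    n_cells = int(tokens[i + 1])
    raw = np.array(tokens[i + 3 : i + 3 + 5 * n_cells], dtype=np.int64).reshape(n_cells, 5)
    if not np.all(raw[:, 0] == 4):
        raise ValueError("only tetrahedral cells supported")
    cells = raw[:, 1:]
    data: dict[str, np.ndarray] = {}
    j = i
    while True:
        try:
            j = find("SCALARS", j + 1)
        except ValueError:
            break
        name = tokens[j + 1]
        vals = np.array(tokens[j + 6 : j + 6 + n_cells], dtype=float)
        data[name] = vals
    return pts, cells, data
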