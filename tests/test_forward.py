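"""CEM forward solver: assembly oracle, reciprocity, scaling, Jacobian."""

import numpy as np
import pytest

import rooteit as rt
from rooteit.forward import ForwardError, _element_gradients, frames_from_csv, frames_to_csv
from rooteit.mesh import Mesh


def _two_tet_mesh() -> Mesh:
    """Two tetrahedra sharing a face; electrode patches on two outer faces."""
    nodes = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [1.0, 1.0, 1.0],
        ]
    )
    elements = np.array([[0, 1, 2, 3], [1, 2, 3, 4]])
    vols = np.abs(
        np.einsum(
            "ij,ij->i",
            np.cross(
                nodes[elements][:, 1] - nodes[elements][:, 0],
                nodes[elements][:, 2] - nodes[elements][:, 0],
            ),
            nodes[elements][:, 3] - nodes[elements][:, 0],
        )
        / 6.0
    )
    boundary = np.array(
        [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 4], [1, 3, 4], [2, 3, 4]]
    )
    return Mesh(
        nodes=nodes,
        elements=elements,
        boundary_faces=boundary,
        electrode_faces={0: np.array([0]), 1: np.array([5])},
        element_volumes=vols,
    )


def test_stiffness_matches_hand_assembly():
    """The σ-weighted stiffness block equals an independent per-element assembly."""
    mesh = _two_tet_mesh()
    # a bare 2-electrode array: assembly only uses counts and contact impedance
    arr = rt.ElectrodeArray(
        n_sticks=2, layers=1, ring_diameter=1.0, layer_spacing=0.1,
        electrode_length=0.1, electrode_diameter=0.01, contact_impedance=1.0,
    )
    sigma = rt.ConductivityImage(mesh, np.array([2.0, 3.0]))
    system = rt.assemble_cem(mesh, sigma, arr)
    N = mesh.n_nodes

    # oracle: K_ij = σ_e V_e ∇φ_i·∇φ_j with gradients from explicit inversion
    K = np.zeros((N, N))
    for e in range(2):
        idx = mesh.elements[e]
        p = mesh.nodes[idx]
        M = np.hstack([np.ones((4, 1)), p])  # barycentric coefficient system
        C = np.linalg.inv(M)
        grads = C[1:, :].T  # (4,3) gradient of each basis function
        K[np.ix_(idx, idx)] += sigma.values[e] * mesh.element_volumes[e] * grads @ grads.T

    A = system.matrix.toarray()[:N, :N]
    # subtract the electrode surface mass term to isolate the stiffness block
    for el, faces in mesh.electrode_faces.items():
        tri = mesh.boundary_faces[faces[0]]
        a = mesh.face_areas(mesh.boundary_faces[faces])[0]
        m = (a / (12.0 * arr.contact_impedance)) * (np.ones((3, 3)) + np.eye(3))
        A[np.ix_(tri, tri)] -= m
    assert np.allclose(A, K, atol=1e-12)


def test_element_gradients_reproduce_linear_fields(small_setup):
    _, _, mesh = small_setup
    g = _element_gradients(mesh)
    coeff = np.array([0.3, -1.2, 0.7])
    field = mesh.nodes @ coeff
    grad = np.einsum("eid,ei->ed", g, field[mesh.elements])
    assert np.allclose(grad, coeff[None, :], atol=1e-9)


def test_reciprocity(small_system):
    prot = rt.make_protocol(8, "adjacent", 1e-3)
    frame = rt.forward_solve(small_system, prot)
    v = {
        (r.drive_pos, r.drive_neg, r.sense_pos, r.sense_neg): frame.voltages[i]
        for i, r in enumerate(prot.rows)
    }
    checked = 0
    for (dp, dn, sp, sn), val in v.items():
        swapped = (sp, sn, dp, dn)
        if swapped in v:
            assert v[swapped] == pytest.approx(val, rel=1e-9)
            checked += 1
    assert checked > 0


def test_voltages_linear_in_current(small_system):
    p1 = rt.make_protocol(8, "adjacent", 1e-3)
    p2 = rt.make_protocol(8, "adjacent", 3e-3)
    f1 = rt.forward_solve(small_system, p1)
    f2 = rt.forward_solve(small_system, p2)
    assert np.allclose(f2.voltages, 3.0 * f1.voltages, rtol=1e-10)


def test_joint_sigma_contact_scaling_is_exact(small_setup):
    """σ → cσ with z → z/c scales all voltages by exactly 1/c (CEM homogeneity)."""
    dom, arr, mesh = small_setup
    prot = rt.make_protocol(8, "adjacent", 1e-3)
    c = 2.0
    s1 = rt.assemble_cem(mesh, rt.ConductivityImage.homogeneous(mesh, 0.05), arr)
    arr2 = rt.build_electrode_array(
        n_sticks=8, layers=1, contact_impedance=arr.contact_impedance / c
    )
    s2 = rt.assemble_cem(mesh, rt.ConductivityImage.homogeneous(mesh, 0.05 * c), arr2)
    f1 = rt.forward_solve(s1, prot)
    f2 = rt.forward_solve(s2, prot)
    assert np.allclose(f2.voltages, f1.voltages / c, rtol=1e-9)


def test_sigma_only_scaling_approximately_inverse(small_setup):
    """At fixed contact impedance, σ-doubling halves voltages to within a few %."""
    dom, arr, mesh = small_setup
    prot = rt.make_protocol(8, "adjacent", 1e-3)
    s1 = rt.assemble_cem(mesh, rt.ConductivityImage.homogeneous(mesh, 0.05), arr)
    s2 = rt.assemble_cem(mesh, rt.ConductivityImage.homogeneous(mesh, 0.10), arr)
    f1 = rt.forward_solve(s1, prot)
    f2 = rt.forward_solve(s2, prot)
    assert np.max(np.abs(2 * f2.voltages - f1.voltages) / np.abs(f1.voltages)) < 0.05


def test_rotational_symmetry_to_discretization_accuracy(small_system):
    """Rows related by one-stick rotation agree to ≲1% (mesh split asymmetry)."""
    prot = rt.make_protocol(8, "adjacent", 1e-3)
    frame = rt.forward_solve(small_system, prot)
    v = np.empty((8, 5))
    for r, val in zip(prot.rows, frame.voltages):
        v[r.drive_pos, (r.sense_pos - r.drive_pos) % 8 - 2] = val
    spread = np.abs(v - v.mean(axis=0)) / np.abs(v.mean(axis=0))
    assert spread.max() < 0.01


def test_jacobian_matches_central_finite_differences(small_setup, small_system):
    dom, arr, mesh = small_setup
    prot = rt.make_protocol(8, "adjacent", 1e-3)
    frame, fields = rt.forward_solve_fields(small_system, prot)
    J = rt.compute_jacobian(small_system, prot, fields=fields)
    rng = np.random.default_rng(7)
    sigma0 = small_system.sigma.values
    d = 0.01 * 0.05  # 1% perturbation
    for e in rng.choice(mesh.n_elements, 4, replace=False):
        up, dn = sigma0.copy(), sigma0.copy()
        up[e] += d
        dn[e] -= d
        fp = rt.forward_solve(rt.assemble_cem(mesh, rt.ConductivityImage(mesh, up), arr), prot)
        fm = rt.forward_solve(rt.assemble_cem(mesh, rt.ConductivityImage(mesh, dn), arr), prot)
        fd = (fp.voltages - fm.voltages) / (2 * d)
        scale = np.abs(fd).max()
        assert np.abs(fd - J[:, e]).max() / scale < 0.01


def test_jacobian_row_dot_sigma_predicts_scaling_derivative(small_system):
    """Σ_e J[m,e] σ_e ≈ −V_m (directional derivative along uniform σ scaling)."""
    prot = rt.make_protocol(8, "adjacent", 1e-3)
    frame, fields = rt.forward_solve_fields(small_system, prot)
    J = rt.compute_jacobian(small_system, prot, fields=fields)
    pred = J @ small_system.sigma.values
    assert np.allclose(pred, -frame.voltages, rtol=0.05)


def test_forward_errors():
    mesh = _two_tet_mesh()
    with pytest.raises(ValueError):
        rt.ConductivityImage(mesh, np.array([1.0, -1.0]))  # non-positive absolute σ
    with pytest.raises(ValueError):
        rt.ConductivityImage(mesh, np.ones(3))  # wrong length


def test_protocol_system_mismatch(small_system):
    with pytest.raises(ForwardError):
        rt.forward_solve(small_system, rt.make_protocol(24, "adjacent"))


def test_frame_csv_round_trip(tmp_path, small_system):
    prot = rt.make_protocol(8, "adjacent", 1e-3)
    f1, _ = rt.forward_solve_fields(small_system, prot, frequency=5e3)
    f2 = rt.MeasurementFrame(prot, 5e3, "inhomogeneous", f1.voltages * 1.1)
    path = tmp_path / "frames.csv"
    frames_to_csv([f1, f2], path)
    back = frames_from_csv(path, prot)
    assert len(back) == 2
    by_cond = {f.condition: f for f in back}
    assert np.allclose(by_cond["homogeneous"].voltages, f1.voltages)
    assert np.allclose(by_cond["inhomogeneous"].voltages, f2.voltages)
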