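"""Shared fixtures: small meshes and assembled CEM systems.

Everything is generated programmatically; the "small" single-layer ring is
used for fast solver checks, the full three-layer 24-electrode setup for
end-to-end imaging tests.
"""

import pytest

import rooteit as rt
from rooteit.phantom import SOIL_SIGMA


@pytest.fixture(scope="session")
def small_setup():
    """Coarse single-layer 8-electrode ring for fast forward/Jacobian checks."""
    dom = rt.CylDomain(height=rt.inches(4), diameter=rt.inches(6), background_sigma=0.05)
    arr = rt.build_electrode_array(n_sticks=8, layers=1, domain=dom)
    mesh = rt.build_cylinder_mesh(dom, arr, 0.025)
    return dom, arr, mesh


@pytest.fixture(scope="session")
def small_system(small_setup):
    dom, arr, mesh = small_setup
    sigma = rt.ConductivityImage.homogeneous(mesh, dom.background_sigma)
    return rt.assemble_cem(mesh, sigma, arr)


@pytest.fixture(scope="session")
def full_setup():
    """Three-layer 24-electrode soil cylinder at imaging resolution."""
    dom = rt.CylDomain(
        height=rt.inches(8), diameter=rt.inches(6), background_sigma=SOIL_SIGMA
    )
    arr = rt.build_electrode_array(domain=dom)
    mesh = rt.build_cylinder_mesh(dom, arr, 0.018)
    return dom, arr, mesh


@pytest.fixture(scope="session")
def full_system(full_setup):
    dom, arr, mesh = full_setup
    sigma = rt.ConductivityImage.homogeneous(mesh, dom.background_sigma)
    return rt.assemble_cem(mesh, sigma, arr)


@pytest.fixture(scope="session")
def full_jacobian(full_setup, full_system):
    """Homogeneous-background fields, frame and normalized Jacobian (24 el)."""
    _, _, mesh = full_setup
    prot = rt.make_protocol(24, "adjacent", 1e-3)
    frame, fields = rt.forward_solve_fields(full_system, prot)
    J = rt.compute_jacobian(full_system, prot, fields=fields)
    Jn = rt.scale_jacobian_normalized(J, frame)
    return prot, frame, J, Jn
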