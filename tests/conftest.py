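import numpy as np
import pytest

from lvmech.geometry import LVGeometrySpec, build_lv_mesh, build_cube_mesh
from lvmech.fibers import FiberField, assign_fiber_field
from lvmech.materials import ActiveParams, PassiveParams
from lvmech.fem import FemProblem, basal_boundary_condition


@pytest.fixture(scope="session")
def default_mesh():
    return build_lv_mesh(LVGeometrySpec(), seed=1)


@pytest.fixture(scope="session")
def fiber_field(default_mesh):
    return assign_fiber_field(default_mesh)


@pytest.fixture(scope="session")
def lv_problem(default_mesh, fiber_field):
    return FemProblem(mesh=default_mesh, fibers=fiber_field,
                      passive=PassiveParams(), active=ActiveParams(),
                      bc=basal_boundary_condition(default_mesh))


def make_cube_problem(n=1, passive=None, active=None, lr=1.85):
    """Small cube with axis-aligned fibers; pressure tag on the whole boundary."""
    mesh = build_cube_mesh(n=n, L=1.0)
    mesh.transmural_coord = np.zeros(mesh.n_nodes)
    E = mesh.n_elements
    fib = FiberField(f0=np.tile([1.0, 0, 0], (E, 1)),
                     s0=np.tile([0, 1.0, 0], (E, 1)),
                     n0=np.tile([0, 0, 1.0], (E, 1)),
                     lr=np.full(E, lr))
    return FemProblem(mesh=mesh, fibers=fib,
                      passive=passive or PassiveParams(),
                      active=active or ActiveParams(),
                      bc={0: 0.0}, pressure_tag="boundary")


@pytest.fixture()
def cube_problem():
    return make_cube_problem()


@pytest.fixture(scope="session")
def hemisphere_spec():
    return LVGeometrySpec(endo_long_radius=25.0, endo_short_radius=25.0,
                          wall_thickness_base=10.0, wall_thickness_apex=10.0,
                          truncation_height=1e-9, target_edv=None,
                          mesh_edge_length=6.0)


@pytest.fixture(scope="session")
def hemisphere_mesh(hemisphere_spec):
    return build_lv_mesh(hemisphere_spec, seed=0)
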