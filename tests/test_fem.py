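import numpy as np
import pytest
import scipy.sparse as sp

from lvmech.geometry import GeometryError, LVGeometrySpec, build_lv_mesh
from lvmech.fibers import assign_fiber_field
from lvmech.materials import PassiveParams, ActiveParams, passive_stress
import lvmech.fem as fem
from lvmech.fem import (FemProblem, FemSolution, basal_boundary_condition,
                        cavity_volume, cavity_volume_gradient,
                        fiber_stress_strain_field, solve_static,
                        solve_volume_constrained)

from conftest import make_cube_problem
from _oracles import sphere_inflation_radius


# --------------------------------------------------------------------------
# assembly correctness (tangents vs finite differences)
# --------------------------------------------------------------------------

def test_stiffness_consistent_with_residual(cube_problem):
    c = cube_problem._setup()
    rng = np.random.default_rng(1)
    u = 0.05 * rng.standard_normal(c["ndof"])
    t, a = 0.15, 1.0
    _, Ke, _ = fem._internal_force(cube_problem, c, u, t, a, need_K=True)
    K = sp.coo_matrix((Ke.ravel(), (c["rows"], c["cols"])),
                      shape=(c["ndof"],) * 2).tocsr()
    h = 1e-6
    for _ in range(3):
        d = rng.standard_normal(c["ndof"])
        fp, _, _ = fem._internal_force(cube_problem, c, u + h * d, t, a, False)
        fm, _, _ = fem._internal_force(cube_problem, c, u - h * d, t, a, False)
        fd = (fp - fm) / (2 * h)
        assert np.linalg.norm(K @ d - fd) / np.linalg.norm(fd) < 1e-6


def test_follower_load_tangent(cube_problem):
    c = cube_problem._setup()
    rng = np.random.default_rng(2)
    u = 0.05 * rng.standard_normal(c["ndof"])
    _, Kf, fdofs = fem._pressure_force(cube_problem, c, u, 2.0, need_K=True)
    rows = np.repeat(fdofs, 18, axis=1).ravel()
    cols = np.tile(fdofs, (1, 18)).ravel()
    KF = sp.coo_matrix((Kf.ravel(), (rows, cols)), shape=(c["ndof"],) * 2).tocsr()
    h = 1e-6
    for _ in range(3):
        d = rng.standard_normal(c["ndof"])
        fp, _, _ = fem._pressure_force(cube_problem, c, u + h * d, 2.0, False)
        fm, _, _ = fem._pressure_force(cube_problem, c, u - h * d, 2.0, False)
        fd = (fp - fm) / (2 * h)
        assert np.linalg.norm(KF @ d - fd) / np.linalg.norm(fd) < 1e-6


def test_cavity_volume_gradient(default_mesh):
    rng = np.random.default_rng(3)
    u = 0.1 * rng.standard_normal((default_mesh.n_nodes, 3))
    g = cavity_volume_gradient(default_mesh, u)
    h = 1e-6
    for _ in range(3):
        d = rng.standard_normal(3 * default_mesh.n_nodes)
        vp = cavity_volume(default_mesh, (u.ravel() + h * d).reshape(-1, 3))
        vm = cavity_volume(default_mesh, (u.ravel() - h * d).reshape(-1, 3))
        fd = (vp - vm) / (2 * h)
        assert np.isclose(g @ d, fd, rtol=1e-6)


# --------------------------------------------------------------------------
# cavity volume
# --------------------------------------------------------------------------

def test_cavity_volume_translation_invariant(default_mesh):
    v0 = cavity_volume(default_mesh, np.zeros((default_mesh.n_nodes, 3)))
    shift = np.tile([3.0, -2.0, 5.0], (default_mesh.n_nodes, 1))
    v1 = cavity_volume(default_mesh, shift)
    assert abs(v1 - v0) / v0 < 1e-10


def test_cavity_volume_cubic_scaling(default_mesh):
    v0 = cavity_volume(default_mesh, np.zeros((default_mesh.n_nodes, 3)))
    u = 0.1 * default_mesh.nodes        # x -> 1.1 x
    v1 = cavity_volume(default_mesh, u)
    assert abs(v1 - 1.1 ** 3 * v0) / v0 < 1e-8


def test_cavity_volume_open_surface_raises(default_mesh):
    import copy
    m = copy.copy(default_mesh)
    m.endo_basal_ring = np.array([], dtype=int)
    with pytest.raises(GeometryError):
        cavity_volume(m, np.zeros((m.n_nodes, 3)))


# --------------------------------------------------------------------------
# static solver
# --------------------------------------------------------------------------

def test_zero_load_reference_equilibrium(lv_problem):
    sol = solve_static(lv_problem, 0.0, 0.0)
    assert sol.converged
    assert sol.newton_iterations <= 1
    assert np.abs(sol.displacement).max() == 0.0


def test_patch_homogeneous_deformation():
    """Affine boundary displacement reproduces constant stress to 1e-8."""
    prob = make_cube_problem(n=2)
    mesh = prob.mesh
    A = np.array([[0.02, 0.01, 0.0], [0.0, -0.015, 0.005], [0.0, 0.0, 0.01]])
    boundary = np.unique(mesh.surface_tags["boundary"][:, :6].ravel())
    u_affine = mesh.nodes @ A.T
    bc = {}
    for n in boundary:
        for i in range(3):
            bc[3 * int(n) + i] = float(u_affine[n, i])
    prob.bc = bc
    prob._cache.clear()
    prob.__post_init__()
    sol = solve_static(prob, 0.0, 0.0, rtol=1e-12)
    assert sol.converged
    F = np.eye(3) + A
    sig_exact = passive_stress(F, prob.fibers.f0[0], prob.fibers.s0[0],
                               prob.passive)
    stress, strain, vols = fiber_stress_strain_field(prob, sol)
    f_def = F @ prob.fibers.f0[0]
    f_def /= np.linalg.norm(f_def)
    expected = f_def @ sig_exact @ f_def
    assert np.abs(stress - expected).max() < 1e-8
    # interior displacement is the affine field
    assert np.abs(sol.displacement - u_affine).max() < 1e-8


def test_small_load_linearity(lv_problem):
    """Doubling a small pressure doubles the displacement norm within 5%."""
    s1 = solve_static(lv_problem, 0.025, 0.0)
    s2 = solve_static(lv_problem, 0.05, 0.0, warm_start=s1)
    r = np.linalg.norm(s2.displacement) / np.linalg.norm(s1.displacement)
    assert abs(r - 2.0) < 0.1


def test_sphere_inflation_matches_shell_oracle(hemisphere_mesh):
    """Isotropic incompressible thick sphere: FEM inner-radius expansion vs
    the classical shell inflation integral, within 2%."""
    passive = PassiveParams(af=0.0, bulk_modulus=2000.0)
    fibers = assign_fiber_field(hemisphere_mesh)
    prob = FemProblem(mesh=hemisphere_mesh, fibers=fibers, passive=passive,
                      active=ActiveParams(),
                      bc=basal_boundary_condition(hemisphere_mesh))
    p = 1.0   # kPa
    sol = solve_static(prob, p, 0.0)
    endo = np.unique(hemisphere_mesh.surface_tags["endocardium"].ravel())
    x = hemisphere_mesh.nodes[endo] + sol.displacement[endo]
    a_fem = np.linalg.norm(x, axis=1).mean()
    a_oracle = sphere_inflation_radius(p, 25.0, 35.0, passive.a, passive.b)
    assert abs(a_fem - a_oracle) / (a_oracle - 25.0) < 0.02 or \
        abs(a_fem - a_oracle) / a_oracle < 0.02


def test_incompressibility_of_converged_state(lv_problem):
    """J stays within [0.97, 1.03] at the quadrature points under load."""
    sol = solve_static(lv_problem, 1.0, 0.0)
    c = lv_problem._setup()
    ue = sol.displacement[c["elems"]]
    F = np.einsum("eqaJ,eai->eqiJ", c["G"], ue)
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    F[..., 2, 2] += 1.0
    J = np.linalg.det(F)
    assert J.min() > 0.97 and J.max() < 1.03


# --------------------------------------------------------------------------
# derived fields
# --------------------------------------------------------------------------

def test_fields_zero_at_rest(lv_problem):
    sol = FemSolution(displacement=np.zeros((lv_problem.mesh.n_nodes, 3)),
                      cavity_pressure=0.0, t=0.0, converged=True,
                      newton_iterations=0, residual_norm=0.0, active_scale=0.0)
    stress, strain, _ = fiber_stress_strain_field(lv_problem, sol)
    assert np.abs(stress).max() < 1e-12
    assert np.abs(strain).max() < 1e-12


def test_homogeneous_stretch_uniform_stress(cube_problem):
    lam = 1.05
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    u = cube_problem.mesh.nodes @ (F.T - np.eye(3))
    sol = FemSolution(displacement=u, cavity_pressure=0.0, t=0.0,
                      converged=True, newton_iterations=0, residual_norm=0.0,
                      active_scale=0.0)
    stress, strain, _ = fiber_stress_strain_field(cube_problem, sol)
    assert stress.std() < 1e-10
    assert np.allclose(strain, (lam ** 2 - 1) / 2)


def test_inflation_gives_tensile_fiber_stress(lv_problem):
    sol = solve_static(lv_problem, 0.4, 0.0)
    stress, strain, vols = fiber_stress_strain_field(lv_problem, sol)
    assert np.average(stress, weights=vols) > 0.0
    assert np.average(strain, weights=vols) > 0.0


# --------------------------------------------------------------------------
# volume-constrained solver
# --------------------------------------------------------------------------

def test_volume_constraint_is_met(lv_problem):
    target = 195.0
    sol = solve_volume_constrained(lv_problem, target, 0.0)
    v = cavity_volume(lv_problem.mesh, sol.displacement)
    assert abs(v - target) / target < 1e-7
    assert sol.cavity_pressure > 0.0


def test_mesh_refinement_stability():
    """Mean fiber stress of an activated state changes < 5% under refinement."""
    results = []
    for L in (12.0, 9.0):
        mesh = build_lv_mesh(LVGeometrySpec(mesh_edge_length=L), seed=0)
        prob = FemProblem(mesh=mesh, fibers=assign_fiber_field(mesh),
                          passive=PassiveParams(), active=ActiveParams(),
                          bc=basal_boundary_condition(mesh), active_scale=0.3)
        sol = None
        for t in (0.0, 0.08, 0.16, 0.25):
            sol = solve_volume_constrained(prob, 170.0, t, warm_start=sol)
        stress, _, vols = fiber_stress_strain_field(prob, sol)
        results.append(np.average(stress, weights=vols))
    assert abs(results[1] - results[0]) / abs(results[1]) < 0.05
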