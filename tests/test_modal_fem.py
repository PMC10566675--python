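import numpy as np
import pytest

from tpcvibe import modal_fem as mf
from tpcvibe.geometry import MaterialCard, MaterialSweep, TetMesh, scale_mesh, surface_extract, to_quadratic
from tpcvibe.synthetic_data import make_beam_mesh

RHO, E, NU = 2400.0, 25e9, 0.3


# ---------------------------------------------------------------------------
# independent dense element oracle: Duffy-mapped tensor Gauss quadrature
# (exact for polynomial integrands) with the Voigt B-matrix formulation
# ---------------------------------------------------------------------------

_EDGES = [(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3)]


def _duffy_rule(n=6):
    u, w = np.polynomial.legendre.leggauss(n)
    u, w = 0.5 * (u + 1), 0.5 * w
    pts, wts = [], []
    for a, wa in zip(u, w):
        for b, wb in zip(u, w):
            for c, wc in zip(u, w):
                y = b * (1 - a)
                z = c * (1 - a - y)
                pts.append((a, y, z))
                wts.append(wa * wb * wc * (1 - a) * (1 - a - y))
    return np.array(pts), np.array(wts)


def _shapes(order, p):
    x, y, z = p
    lam = np.array([1 - x - y - z, x, y, z])
    dlam = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    if order == 4:
        return lam, dlam
    n = np.concatenate([lam * (2 * lam - 1), [4 * lam[a] * lam[b] for a, b in _EDGES]])
    dn = np.zeros((10, 3))
    for i in range(4):
        dn[i] = (4 * lam[i] - 1) * dlam[i]
    for k, (a, b) in enumerate(_EDGES):
        dn[4 + k] = 4 * (lam[b] * dlam[a] + lam[a] * dlam[b])
    return n, dn


def element_oracle(corners, order, card):
    """Dense element stiffness/mass by brute-force exact integration."""
    lam_, mu_ = card.lame
    d = np.zeros((6, 6))
    d[:3, :3] = lam_
    d[np.arange(3), np.arange(3)] += 2 * mu_
    d[np.arange(3, 6), np.arange(3, 6)] = mu_
    jac = (corners[1:] - corners[0]).T
    detj = np.linalg.det(jac)
    jinv = np.linalg.inv(jac)
    npe = order
    pts, wts = _duffy_rule()
    k = np.zeros((3 * npe, 3 * npe))
    m = np.zeros((3 * npe, 3 * npe))
    for p, w in zip(pts, wts):
        nvec, dn = _shapes(order, p)
        g = dn @ jinv
        bmat = np.zeros((6, 3 * npe))
        for a in range(npe):
            gx, gy, gz = g[a]
            bmat[:, 3 * a : 3 * a + 3] = [
                [gx, 0, 0], [0, gy, 0], [0, 0, gz],
                [gy, gx, 0], [0, gz, gy], [gz, 0, gx],
            ]
        nmat = np.zeros((3, 3 * npe))
        for a in range(npe):
            nmat[:, 3 * a : 3 * a + 3] = nvec[a] * np.eye(3)
        k += w * detj * bmat.T @ d @ bmat
        m += w * detj * card.density * nmat.T @ nmat
    return k, m


@pytest.mark.parametrize("order", [4, 10])
def test_element_matrices_match_dense_oracle(order):
    corners = np.array([[0.1, 0.0, 0.0], [1.1, 0.2, 0.1], [0.3, 0.9, -0.1], [0.2, 0.1, 1.2]])
    card = MaterialCard(RHO, E, NU)
    k_ref, m_ref = element_oracle(corners, order, card)
    nodes = corners
    if order == 10:
        nodes = np.vstack([corners, [(corners[a] + corners[b]) / 2 for a, b in _EDGES]])
    mesh = TetMesh(
        nodes,
        np.arange(order)[None, :],
        np.array(["x"], dtype=object),
        np.array(["stiff_bone"], dtype=object),
    )
    k, m = mf.assemble_full(mesh, {"stiff_bone": card})
    assert np.abs(k.toarray() - k_ref).max() <= 1e-10 * np.abs(k_ref).max()
    assert np.abs(m.toarray() - m_ref).max() <= 1e-10 * np.abs(m_ref).max()


# ---------------------------------------------------------------------------
# assembly-level properties
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("order", [4, 10])
def test_rigid_body_null_space(order, stiff_card):
    mesh = make_beam_mesh(0.3, 0.1, 0.1, (3, 1, 1), order=order)
    k, _ = mf.assemble_full(mesh, {"stiff_bone": stiff_card})
    kmax = abs(k).max()
    for axis in range(3):
        u = np.zeros(3 * mesh.n_nodes)
        u[axis::3] = 1.0
        assert np.abs(k @ u).max() <= 1e-9 * kmax
    rot = np.cross([0.3, -1.2, 0.7], mesh.nodes)
    assert np.abs(k @ rot.ravel()).max() <= 1e-9 * kmax


@pytest.mark.parametrize("order", [4, 10])
def test_translational_mass_equals_rho_v(order, stiff_card):
    mesh = make_beam_mesh(0.3, 0.1, 0.1, (3, 1, 1), order=order)
    _, m = mf.assemble_full(mesh, {"stiff_bone": stiff_card})
    expect = stiff_card.density * 0.3 * 0.1 * 0.1
    for axis in range(3):
        u = np.zeros(3 * mesh.n_nodes)
        u[axis::3] = 1.0
        assert u @ (m @ u) == pytest.approx(expect, rel=1e-9)


def test_missing_material_card(toy):
    mesh, _ = toy
    with pytest.raises(ValueError, match="missing material"):
        mf.assemble_full(mesh, {"stiff_bone": MaterialCard(RHO, E, NU)})


def test_system_symmetry_and_dof_map(toy_system):
    ek, em = toy_system.symmetry_error()
    assert ek <= 1e-10 and em <= 1e-10
    n_fixed_dofs = len(np.flatnonzero(toy_system.dof_map < 0))
    assert toy_system.n_free == 3 * toy_system.n_nodes - n_fixed_dofs
    # dof map inverts free_dofs
    np.testing.assert_array_equal(
        toy_system.dof_map[toy_system.free_dofs], np.arange(toy_system.n_free)
    )


# ---------------------------------------------------------------------------
# eigen solves
# ---------------------------------------------------------------------------


def test_free_free_six_rigid_modes(small_beam):
    mesh, mats, _ = small_beam
    system = mf.assemble_system(mesh, mats, None)
    sol = mf.solve_modes(system, 8)
    om2 = (2 * np.pi * sol.frequencies_hz) ** 2
    assert np.all(om2[:6] / om2.max() < 1e-8)
    assert om2[6] / om2.max() > 1e-4


def test_cantilever_matches_euler_bernoulli(slender_beam_solution):
    s = slender_beam_solution
    length, width, card = s["length"], s["width"], s["card"]
    area = width * width
    inertia = width**4 / 12
    base = np.sqrt(card.young_modulus * inertia / (card.density * area * length**4))

    def eb(bl):
        return bl**2 / (2 * np.pi) * base

    freqs = s["solution"].frequencies_hz
    # bending modes come in near-degenerate y/z pairs: compare pair means
    assert freqs[0] == pytest.approx(eb(1.8751), rel=0.03)
    assert freqs[2] == pytest.approx(eb(4.6941), rel=0.03)


def test_solution_invariants(toy_solution):
    sol = toy_solution
    assert np.all(np.diff(sol.frequencies_hz) >= 0)
    assert np.all(sol.frequencies_hz >= 0)
    assert sol.mass_orth_error <= 1e-8
    assert sol.residuals.max() <= 1e-6


def test_solve_deterministic(toy_system):
    a = mf.solve_modes(toy_system, 6)
    b = mf.solve_modes(toy_system, 6)
    np.testing.assert_array_equal(a.frequencies_hz, b.frequencies_hz)
    np.testing.assert_array_equal(a.shapes, b.shapes)


def test_k_out_of_range(toy_system):
    with pytest.raises(ValueError, match="k="):
        mf.solve_modes(toy_system, 0)
    with pytest.raises(ValueError, match="k="):
        mf.solve_modes(toy_system, toy_system.n_free)


def test_scaling_law(toy, toy_materials, toy_solution):
    mesh, truth = toy
    scaled = scale_mesh(mesh, 1.2)
    system = mf.assemble_system(scaled, toy_materials, truth["base_nodes"])
    sol = mf.solve_modes(system, toy_solution.k)
    np.testing.assert_allclose(
        sol.frequencies_hz, toy_solution.frequencies_hz / 1.2, rtol=1e-9
    )


def test_stiffness_and_density_scaling(small_beam):
    mesh, mats, fixed = small_beam
    base = mf.solve_modes(mf.assemble_system(mesh, mats, fixed), 4)
    card = mats["stiff_bone"]
    stiffer = {"stiff_bone": MaterialCard(card.density, 4 * card.young_modulus, card.poisson_ratio)}
    denser = {"stiff_bone": MaterialCard(4 * card.density, card.young_modulus, card.poisson_ratio)}
    f_stiff = mf.solve_modes(mf.assemble_system(mesh, stiffer, fixed), 4).frequencies_hz
    f_dense = mf.solve_modes(mf.assemble_system(mesh, denser, fixed), 4).frequencies_hz
    np.testing.assert_allclose(f_stiff, 2 * base.frequencies_hz, rtol=1e-9)
    np.testing.assert_allclose(f_dense, base.frequencies_hz / 2, rtol=1e-9)


def test_mode_shapes_invariant_under_scaling(toy, toy_materials, toy_solution, toy_system):
    mesh, truth = toy
    scaled = scale_mesh(mesh, 1.2)
    system = mf.assemble_system(scaled, toy_materials, truth["base_nodes"])
    sol = mf.solve_modes(system, 12)
    track = mf.track_modes(toy_solution, sol, toy_system, threshold=0.7)
    matched = {a: m for a, _, m in track.pairs}
    assert all(matched[i] >= 0.999 for i in range(12))


# ---------------------------------------------------------------------------
# normal displacement
# ---------------------------------------------------------------------------


def _planted_solution(mesh, shapes):
    shapes = np.asarray(shapes, float)
    return mf.ModalSolution(
        frequencies_hz=np.arange(1.0, len(shapes) + 1),
        shapes=shapes,
        provenance={"mesh_hash": mesh.mesh_hash()},
    )


def test_normal_displacement_translation_on_cube():
    mesh = make_beam_mesh(1.0, 1.0, 1.0, (2, 2, 2), order=4)
    surf = surface_extract(mesh)
    shape = np.zeros((1, mesh.n_nodes, 3))
    shape[0, :, 0] = 1.0  # +x translation
    field = mf.normal_displacement(_planted_solution(mesh, shape), surf)
    verts = surf.vertices
    on_x = (np.abs(verts[:, 0]) < 1e-12) | (np.abs(verts[:, 0] - 1) < 1e-12)
    on_y = (np.abs(verts[:, 1]) < 1e-12) | (np.abs(verts[:, 1] - 1) < 1e-12)
    on_z = (np.abs(verts[:, 2]) < 1e-12) | (np.abs(verts[:, 2] - 1) < 1e-12)
    interior_x = on_x & ~on_y & ~on_z  # face interiors: unambiguous normals
    interior_yz = (on_y ^ on_z) & ~on_x
    assert np.all(np.abs(field.values[0, interior_x] - 1) < 1e-12)
    assert np.all(np.abs(field.values[0, interior_yz]) < 1e-12)


def test_normal_displacement_brute_force(toy, toy_solution):
    mesh, _ = toy
    surf = surface_extract(mesh)
    field = mf.normal_displacement(toy_solution, surf)
    vn = surf.vertex_normals()
    for k in (0, 5, 11):
        expect = np.abs(
            np.sum(toy_solution.shapes[k][surf.vertex_to_volume] * vn, axis=1)
        )
        np.testing.assert_allclose(field.values[k], expect, atol=1e-15)


def test_normal_displacement_hash_mismatch(toy, toy_solution):
    mesh, _ = toy
    other = surface_extract(scale_mesh(mesh, 2.0))
    with pytest.raises(ValueError, match="hash"):
        mf.normal_displacement(toy_solution, other)


# ---------------------------------------------------------------------------
# sweeps and tracking
# ---------------------------------------------------------------------------


def test_sweep_single_combination_equals_direct(small_beam):
    mesh, mats, fixed = small_beam
    sweep = MaterialSweep({"stiff_bone": [mats["stiff_bone"]]})
    sols = mf.sweep_materials(mesh, sweep, fixed, 4)
    direct = mf.solve_modes(mf.assemble_system(mesh, mats, fixed), 4)
    assert len(sols) == 1
    np.testing.assert_array_equal(sols[0].frequencies_hz, direct.frequencies_hz)
    assert "materials" in sols[0].provenance


def test_sweep_limit(small_beam):
    mesh, mats, fixed = small_beam
    sweep = MaterialSweep({"stiff_bone": [mats["stiff_bone"]] * 5})
    with pytest.raises(ValueError, match="limit"):
        mf.sweep_materials(mesh, sweep, fixed, 2, max_combinations=4)


def test_track_self_identity(toy_solution, toy_system):
    track = mf.track_modes(toy_solution, toy_solution, toy_system)
    assert [(a, b) for a, b, _ in track.pairs] == [(i, i) for i in range(toy_solution.k)]
    assert all(abs(m - 1) < 1e-10 for _, _, m in track.pairs)
    assert track.unmatched_a == [] and track.unmatched_b == []


def test_track_two_dof_crossing():
    """Eigenvalue crossing in a 2-dof system: tracking follows shapes.

    K = [[k1, -c], [-c, k2]], M = I.  In closed form the eigenpairs rotate
    from (e1, e2) to (e2, e1) as k1 sweeps through k2; with small coupling
    the shapes barely mix away from the crossing, so MAC tracking must
    report the index swap.
    """

    def closed_form(k1, k2, c):
        tr, det = k1 + k2, k1 * k2 - c * c
        disc = np.sqrt(tr * tr / 4 - det)
        lo, hi = tr / 2 - disc, tr / 2 + disc
        vecs = []
        for lam in (lo, hi):
            v = np.array([c, k1 - lam]) if abs(k1 - lam) > abs(k2 - lam) else np.array(
                [k2 - lam, c]
            )
            vecs.append(v / np.linalg.norm(v))
        return np.array([lo, hi]), np.stack(vecs)

    c = 0.01
    vals_a, vecs_a = closed_form(1.0, 2.0, c)
    vals_b, vecs_b = closed_form(3.0, 2.0, c)
    # sanity: oracle matches numpy's dense eigensolver
    for (k1, vals, vecs) in ((1.0, vals_a, vecs_a), (3.0, vals_b, vecs_b)):
        w, v = np.linalg.eigh(np.array([[k1, -c], [-c, 2.0]]))
        np.testing.assert_allclose(w, vals, rtol=1e-12)
        assert np.abs(np.abs(np.sum(v.T * vecs, axis=1)) - 1).max() < 1e-9

    mac = mf.mac_matrix(vecs_a, vecs_b)
    track = mf.greedy_match(mac, np.sqrt(vals_a), np.sqrt(vals_b), threshold=0.7)
    assert {(a, b) for a, b, _ in track.pairs} == {(0, 1), (1, 0)}
    assert all(m >= 0.9 for _, _, m in track.pairs)


def test_track_toy_corner_materials(toy, toy_system):
    """The two bone-stiffness corner cases pair off with MAC >= 0.7."""
    mesh, truth = toy
    lig = MaterialCard(1200, 1e6, 0.3)
    mats_a = {
        "stiff_bone": MaterialCard(2400, 25e9, 0.3),
        "flexible_bone": MaterialCard(2000, 5e9, 0.3),
        "stiff_ligament": lig,
    }
    mats_b = {
        "stiff_bone": MaterialCard(2400, 10e9, 0.3),
        "flexible_bone": MaterialCard(2000, 9e9, 0.3),
        "stiff_ligament": lig,
    }
    sol_a = mf.solve_modes(mf.assemble_system(mesh, mats_a, truth["base_nodes"]), 10)
    sol_b = mf.solve_modes(mf.assemble_system(mesh, mats_b, truth["base_nodes"]), 10)
    track = mf.track_modes(sol_a, sol_b, toy_system)
    assert len(track.pairs) >= 8
    assert all(m >= 0.7 for _, _, m in track.pairs)
    # partial injection: no index reused
    a_idx = [a for a, _, _ in track.pairs]
    b_idx = [b for _, b, _ in track.pairs]
    assert len(set(a_idx)) == len(a_idx) and len(set(b_idx)) == len(b_idx)


def test_track_dof_mismatch(toy_solution, small_beam):
    mesh, mats, fixed = small_beam
    system = mf.assemble_system(mesh, mats, fixed)
    other = mf.solve_modes(system, 4)
    with pytest.raises(ValueError, match="dof"):
        mf.track_modes(toy_solution, other, system)


def test_strain_energy_fractions_partition(toy, toy_materials, toy_solution):
    mesh, _ = toy
    total = np.zeros(toy_solution.k)
    for comp in mesh.components():
        total += mf.strain_energy_fractions(mesh, toy_materials, toy_solution, [comp])
    np.testing.assert_allclose(total, 1.0, rtol=1e-9)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def test_save_load_round_trip(tmp_path, toy_solution):
    path = tmp_path / "sol.h5"
    mf.save_solution(path, toy_solution)
    back = mf.load_solution(path)
    np.testing.assert_array_equal(back.frequencies_hz, toy_solution.frequencies_hz)
    np.testing.assert_array_equal(back.shapes, toy_solution.shapes)
    assert back.provenance == toy_solution.provenance


def test_frequencies_csv(tmp_path, toy_solution):
    path = tmp_path / "f.csv"
    mf.frequencies_csv(path, [toy_solution])
    import pandas as pd

    df = pd.read_csv(path)
    assert len(df) == toy_solution.k
    np.testing.assert_allclose(
        df.frequency_hz.to_numpy(), toy_solution.frequencies_hz, rtol=1e-8
    )
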