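"""Small-strain isotropic elasticity on labeled tet meshes: assembly and modes.

Element matrices are exact for straight-sided (affine) tetrahedra: the
consistent mass matrix is integrated in closed form over barycentric
monomials, and the stiffness uses a degree-2 quadrature rule that is exact
because the strain interpolation of an affine T10 element is linear.
Constraints are imposed by dof elimination.  The generalized eigenproblem
``K phi = omega^2 M phi`` is solved by shift-invert Lanczos with a seeded
start vector so repeated runs are bit-stable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import factorial
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from tpcvibe.geometry import (
    TET10_EDGES,
    MaterialCard,
    MaterialSweep,
    SurfaceMesh,
    TetMesh,
)

__all__ = [
    "SystemMatrices",
    "ModalSolution",
    "ModeTrack",
    "NormalDisplacementField",
    "assemble_full",
    "assemble_system",
    "solve_modes",
    "normal_displacement",
    "sweep_materials",
    "track_modes",
    "mac_matrix",
    "greedy_match",
    "strain_energy_fractions",
    "save_solution",
    "load_solution",
    "frequencies_csv",
]


# ---------------------------------------------------------------------------
# reference-element machinery
# ---------------------------------------------------------------------------

# barycentric exponent tuples per shape function: N = sum c * prod(lam^e)
_T4_SHAPE = [{tuple(int(j == i) for j in range(4)): 1.0} for i in range(4)]

_T10_SHAPE: list[dict[tuple[int, int, int, int], float]] = []
for i in range(4):
    e1 = tuple(2 * int(j == i) for j in range(4))
    e2 = tuple(int(j == i) for j in range(4))
    _T10_SHAPE.append({e1: 2.0, e2: -1.0})
for a, b in TET10_EDGES:
    e = tuple(int(j == a) + int(j == b) for j in range(4))
    _T10_SHAPE.append({e: 4.0})


def _bary_integral(exps: Sequence[int]) -> float:
    """Exact integral of ``prod(lam_i^e_i)`` over the unit reference tet."""
    num = 1.0
    for e in exps:
        num *= factorial(e)
    return num / factorial(sum(exps) + 3)


def _reference_mass(shape) -> np.ndarray:
    n = len(shape)
    q = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            s = 0.0
            for ea, ca in shape[a].items():
                for eb, cb in shape[b].items():
                    s += ca * cb * _bary_integral(tuple(x + y for x, y in zip(ea, eb)))
            q[a, b] = q[b, a] = s
    return q


#: integral of N N^T over the reference tet (volume 1/6), exact.
_QREF = {4: _reference_mass(_T4_SHAPE), 10: _reference_mass(_T10_SHAPE)}

# dlam/dxi for lam = (1-x1-x2-x3, x1, x2, x3)
_DLAM = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])

# degree-2 quadrature on the reference tet (4 points, exact for quadratics)
_QP_A = 0.5854101966249684544614
_QP_B = 0.1381966011250105151795
_T10_QPOINTS = np.array(
    [
        [_QP_A, _QP_B, _QP_B, _QP_B],
        [_QP_B, _QP_A, _QP_B, _QP_B],
        [_QP_B, _QP_B, _QP_A, _QP_B],
        [_QP_B, _QP_B, _QP_B, _QP_A],
    ]
)
_T10_QWEIGHT = 1.0 / 24.0  # per point, in reference (xi) measure


def _t10_grad_ref(lam: np.ndarray) -> np.ndarray:
    """(10, 3) gradients of T10 shape functions w.r.t. xi at barycentric lam."""
    g = np.zeros((10, 3))
    for i in range(4):
        g[i] = (4 * lam[i] - 1) * _DLAM[i]
    for k, (a, b) in enumerate(TET10_EDGES):
        g[4 + k] = 4 * (lam[b] * _DLAM[a] + lam[a] * _DLAM[b])
    return g


_T10_GRADS = np.stack([_t10_grad_ref(lam) for lam in _T10_QPOINTS])  # (4, 10, 3)
_T4_GRADS = _DLAM[None, :, :]  # (1, 4, 3); constant-strain element


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SystemMatrices:
    """Stiffness and consistent mass over free displacement dofs.

    ``free_dofs`` indexes into the full dof vector (dof of node ``n`` along
    axis ``ax`` is ``3 n + ax``); ``dof_map`` sends full dof ids to rows of
    the reduced matrices (-1 for constrained dofs).
    """

    stiffness: sp.csr_matrix
    mass: sp.csr_matrix
    free_dofs: np.ndarray
    dof_map: np.ndarray
    n_nodes: int
    mesh_hash: str
    free_free: bool = False

    @property
    def n_free(self) -> int:
        return len(self.free_dofs)

    def symmetry_error(self) -> tuple[float, float]:
        ek = abs(self.stiffness - self.stiffness.T).max() / max(
            abs(self.stiffness).max(), 1e-300
        )
        em = abs(self.mass - self.mass.T).max() / max(abs(self.mass).max(), 1e-300)
        return float(ek), float(em)


def _element_matrices(mesh: TetMesh, lam: np.ndarray, mu: np.ndarray, rho: np.ndarray):
    """Vectorized exact element stiffness and mass for all elements.

    Returns ``(ke, me)`` with shapes ``(m, 3*npe, 3*npe)``.
    """
    npe = mesh.order
    corner = mesh.nodes[mesh.elements[:, :4]]  # (m, 4, 3)
    jac = np.transpose(corner[:, 1:] - corner[:, :1], (0, 2, 1))  # (m, 3, 3)
    detj = np.linalg.det(jac)
    if np.any(detj <= 0):
        raise ValueError("singular or inverted element Jacobian")
    jinv = np.linalg.inv(jac)
    grads = _T10_GRADS if npe == 10 else _T4_GRADS
    m = mesh.n_elements

    ke = np.zeros((m, npe, 3, npe, 3))
    eye = np.eye(3)
    wq = _T10_QWEIGHT if npe == 10 else 1.0 / 6.0  # reference-measure weight
    for gq in grads:  # quadrature loop (1 point for T4, 4 for T10)
        g = np.einsum("ai,mij->maj", gq, jinv)  # (m, npe, 3) physical gradients
        dots = np.einsum("mak,mbk->mab", g, g)
        outer = np.einsum("mai,mbj->maibj", g, g)
        contrib = (
            lam[:, None, None, None, None] * outer
            + mu[:, None, None, None, None] * np.transpose(outer, (0, 3, 2, 1, 4))
            + mu[:, None, None, None, None] * np.einsum("mab,ij->maibj", dots, eye)
        )
        ke += contrib * (wq * detj)[:, None, None, None, None]

    qref = _QREF[npe]
    me = np.einsum("m,ab,ij->maibj", rho * detj, qref, eye)
    return ke.reshape(m, 3 * npe, 3 * npe), me.reshape(m, 3 * npe, 3 * npe)


def _materials_per_element(mesh: TetMesh, materials: Mapping[str, MaterialCard]):
    for r in mesh.regions():
        if r not in materials:
            raise ValueError(f"missing material card for region {r!r}")
    lam = np.empty(mesh.n_elements)
    mu = np.empty(mesh.n_elements)
    rho = np.empty(mesh.n_elements)
    for r in mesh.regions():
        mask = np.asarray(mesh.region, dtype=str) == r
        l, m_ = materials[r].lame
        lam[mask] = l
        mu[mask] = m_
        rho[mask] = materials[r].density
    return lam, mu, rho


def assemble_full(
    mesh: TetMesh,
    materials: Mapping[str, MaterialCard],
    element_ids: np.ndarray | None = None,
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Unconstrained stiffness and mass over all ``3 * n_nodes`` dofs.

    ``element_ids`` restricts assembly to a subset of elements (used for
    per-component strain energies); matrices keep the full dof dimension.
    """
    lam, mu, rho = _materials_per_element(mesh, materials)
    if element_ids is not None:
        sub = TetMesh(
            nodes=mesh.nodes,
            elements=mesh.elements[element_ids],
            component=mesh.component[element_ids],
            region=mesh.region[element_ids],
        )
        lam, mu, rho = lam[element_ids], mu[element_ids], rho[element_ids]
        mesh = sub
    ke, me = _element_matrices(mesh, lam, mu, rho)
    npe = mesh.order
    dofs = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(
        mesh.n_elements, 3 * npe
    )
    rows = np.repeat(dofs, 3 * npe, axis=1).ravel()
    cols = np.tile(dofs, (1, 3 * npe)).ravel()
    n = 3 * mesh.n_nodes
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    m = sp.coo_matrix((me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return k, m


def assemble_system(
    mesh: TetMesh,
    materials: Mapping[str, MaterialCard],
    fixed: Iterable[int] | None,
) -> SystemMatrices:
    """Assemble reduced stiffness/mass with fixed-node dofs eliminated.

    ``fixed=None`` (or empty) produces a free-free diagnostic system that
    retains the six rigid-body modes.
    """
    k, m = assemble_full(mesh, materials)
    n = 3 * mesh.n_nodes
    fixed = np.asarray(sorted(set(fixed))) if fixed is not None else np.array([], int)
    if len(fixed):
        if fixed.min() < 0 or fixed.max() >= mesh.n_nodes:
            raise ValueError("fixed node id out of range")
    fixed_dofs = (3 * fixed[:, None] + np.arange(3)).ravel() if len(fixed) else []
    mask = np.ones(n, dtype=bool)
    mask[fixed_dofs] = False
    free = np.flatnonzero(mask)
    dof_map = np.full(n, -1, dtype=np.int64)
    dof_map[free] = np.arange(len(free))
    return SystemMatrices(
        stiffness=k[np.ix_(free, free)].tocsr(),
        mass=m[np.ix_(free, free)].tocsr(),
        free_dofs=free,
        dof_map=dof_map,
        n_nodes=mesh.n_nodes,
        mesh_hash=mesh.mesh_hash(),
        free_free=len(fixed) == 0,
    )


# ---------------------------------------------------------------------------
# eigen solve
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModalSolution:
    """Ascending natural frequencies with mass-normalized mode shapes.

    ``shapes`` has shape ``(k, n_nodes, 3)`` with zeros at constrained
    nodes; ``residuals`` are the per-mode relative eigen-residuals and
    ``mass_orth_error`` the max deviation of ``Phi^T M Phi`` from identity.
    """

    frequencies_hz: np.ndarray
    shapes: np.ndarray
    provenance: dict = field(default_factory=dict)
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    mass_orth_error: float = 0.0

    @property
    def k(self) -> int:
        return len(self.frequencies_hz)

    def flat_shapes(self) -> np.ndarray:
        """Mode shapes as ``(k, 3 * n_nodes)`` row vectors."""
        return self.shapes.reshape(self.k, -1)


def solve_modes(
    system: SystemMatrices,
    k: int,
    seed: int = 0,
    sigma: float | None = None,
) -> ModalSolution:
    """Lowest ``k`` eigenpairs of ``K phi = omega^2 M phi``.

    Shift-invert Lanczos about ``sigma`` (default 0 for constrained systems;
    a small negative shift is chosen automatically in free-free mode so the
    six rigid modes are recovered).  The start vector is seeded, so repeated
    calls are deterministic.
    """
    nfree = system.n_free
    if not 1 <= k < nfree:
        raise ValueError(f"k={k} must satisfy 1 <= k < {nfree} free dofs")
    kk, mm = system.stiffness, system.mass
    if sigma is None:
        if system.free_free:
            scale = kk.diagonal().mean() / mm.diagonal().mean()
            sigma = -1e-3 * scale
        else:
            sigma = 0.0
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(nfree)
    try:
        vals, vecs = spla.eigsh(kk, k=k, M=mm, sigma=sigma, which="LM", v0=v0)
    except spla.ArpackNoConvergence as err:  # pragma: no cover - rare
        raise RuntimeError(
            f"eigensolver failed to converge: {len(err.eigenvalues)}/{k} modes, "
            f"residual info: {err}"
        ) from err
    order = np.argsort(vals)
    vals, vecs = vals[order], vecs[:, order]

    # symmetric re-orthonormalization in the mass inner product
    g = vecs.T @ (mm @ vecs)
    w, u = np.linalg.eigh(g)
    vecs = vecs @ (u / np.sqrt(w)) @ u.T
    g = vecs.T @ (mm @ vecs)
    mass_err = float(np.abs(g - np.eye(k)).max())

    vals = np.where(vals < 0, np.where(vals > -1e-6 * max(vals.max(), 1), 0.0, vals), vals)
    if np.any(vals < 0):
        raise RuntimeError(f"negative eigenvalue encountered: {vals.min()}")
    freqs = np.sqrt(vals) / (2 * np.pi)

    kv = kk @ vecs
    mv = mm @ vecs
    resid = np.linalg.norm(kv - mv * vals, axis=0)
    denom = np.maximum(np.linalg.norm(kv, axis=0), 1e-300)
    residuals = resid / denom

    shapes = np.zeros((k, 3 * system.n_nodes))
    shapes[:, system.free_dofs] = vecs.T
    return ModalSolution(
        frequencies_hz=freqs,
        shapes=shapes.reshape(k, system.n_nodes, 3),
        provenance={"mesh_hash": system.mesh_hash, "seed": seed},
        residuals=residuals,
        mass_orth_error=mass_err,
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalDisplacementField:
    """Per-mode |u . n| at each surface vertex (zero at constrained nodes)."""

    values: np.ndarray  # (k, n_surface_vertices)
    vertex_to_volume: np.ndarray
    frequencies_hz: np.ndarray


def normal_displacement(
    solution: ModalSolution, surface: SurfaceMesh
) -> NormalDisplacementField:
    """Magnitude of the surface-normal displacement component per mode."""
    if surface.mesh_hash and solution.provenance.get("mesh_hash") not in (
        None,
        surface.mesh_hash,
    ):
        raise ValueError("surface was extracted from a different mesh (hash mismatch)")
    vn = surface.vertex_normals()
    u = solution.shapes[:, surface.vertex_to_volume, :]  # (k, v, 3)
    vals = np.abs(np.einsum("kvi,vi->kv", u, vn))
    return NormalDisplacementField(
        values=vals,
        vertex_to_volume=surface.vertex_to_volume,
        frequencies_hz=solution.frequencies_hz,
    )


def sweep_materials(
    mesh: TetMesh,
    sweep: MaterialSweep,
    fixed: Iterable[int],
    k: int,
    seed: int = 0,
    max_combinations: int = 256,
) -> list[ModalSolution]:
    """One modal solution per factorial material combination, tagged with cards."""
    sweep.validate_for(mesh)
    combos = sweep.combinations()
    if len(combos) > max_combinations:
        raise ValueError(
            f"sweep has {len(combos)} combinations, limit {max_combinations}"
        )
    out = []
    fixed = list(fixed)
    for combo in combos:
        system = assemble_system(mesh, combo, fixed)
        try:
            sol = solve_modes(system, k, seed=seed)
        except RuntimeError as err:
            raise RuntimeError(f"solve failed for combination {combo}: {err}") from err
        sol.provenance["materials"] = {
            r: {
                "density": c.density,
                "young_modulus": c.young_modulus,
                "poisson_ratio": c.poisson_ratio,
            }
            for r, c in combo.items()
        }
        out.append(sol)
    return out


# ---------------------------------------------------------------------------
# mode tracking (modal assurance criterion)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModeTrack:
    """Partial injection between mode indices of two solutions with MAC scores."""

    pairs: list[tuple[int, int, float]]  # (index_a, index_b, mac)
    unmatched_a: list[int]
    unmatched_b: list[int]
    threshold: float

    def permutation(self) -> dict[int, int]:
        return {a: b for a, b, _ in self.pairs}


def mac_matrix(
    a: np.ndarray, b: np.ndarray, weight: sp.spmatrix | np.ndarray | None = None
) -> np.ndarray:
    """MAC(i, j) = (a_i^T W b_j)^2 / ((a_i^T W a_i)(b_j^T W b_j))."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if weight is None:
        wb = b.T
        wa = a.T
    else:
        wb = weight @ b.T
        wa = weight @ a.T
    cross = a @ wb
    na = np.einsum("ij,ji->i", a, wa)
    nb = np.einsum("ij,ji->i", b, wb)
    return cross**2 / np.outer(na, nb)


def greedy_match(
    mac: np.ndarray,
    freqs_a: np.ndarray | None = None,
    freqs_b: np.ndarray | None = None,
    threshold: float = 0.7,
) -> ModeTrack:
    """Greedy descending-MAC assignment, each index used once.

    Ties are broken by the smaller frequency gap when frequencies are given.
    """
    ka, kb = mac.shape
    cells = list(itertools.product(range(ka), range(kb)))
    if freqs_a is not None and freqs_b is not None:
        gap = {(i, j): abs(freqs_a[i] - freqs_b[j]) for i, j in cells}
    else:
        gap = {c: 0.0 for c in cells}
    cells.sort(key=lambda c: (-mac[c], gap[c], c))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for i, j in cells:
        if mac[i, j] < threshold:
            break
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j, float(mac[i, j])))
        used_a.add(i)
        used_b.add(j)
    pairs.sort()
    return ModeTrack(
        pairs=pairs,
        unmatched_a=sorted(set(range(ka)) - used_a),
        unmatched_b=sorted(set(range(kb)) - used_b),
        threshold=threshold,
    )


def track_modes(
    a: ModalSolution,
    b: ModalSolution,
    mass: SystemMatrices,
    threshold: float = 0.7,
) -> ModeTrack:
    """Match modes of two solutions on the same mesh by mass-weighted MAC."""
    if a.shapes.shape[1] != mass.n_nodes or b.shapes.shape[1] != mass.n_nodes:
        raise ValueError("solutions and mass matrix live on different dof maps")
    fa = a.flat_shapes()[:, mass.free_dofs]
    fb = b.flat_shapes()[:, mass.free_dofs]
    mac = mac_matrix(fa, fb, weight=mass.mass)
    return greedy_match(mac, a.frequencies_hz, b.frequencies_hz, threshold)


def strain_energy_fractions(
    mesh: TetMesh,
    materials: Mapping[str, MaterialCard],
    solution: ModalSolution,
    components: Iterable[str],
) -> np.ndarray:
    """Per-mode fraction of modal strain energy carried by the named components."""
    eids = mesh.element_ids(components)
    if len(eids) == 0:
        raise ValueError("no elements in the named components")
    k_sub, _ = assemble_full(mesh, materials, element_ids=eids)
    k_all, _ = assemble_full(mesh, materials)
    phi = solution.flat_shapes()
    e_sub = np.einsum("ki,ki->k", phi, (k_sub @ phi.T).T)
    e_all = np.einsum("ki,ki->k", phi, (k_all @ phi.T).T)
    return e_sub / np.maximum(e_all, 1e-300)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_solution(path: str | Path, solution: ModalSolution) -> None:
    """Persist a modal solution to HDF5 (frequencies, shapes, provenance attrs)."""
    import json

    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("frequencies_hz", data=solution.frequencies_hz)
        fh.create_dataset("shapes", data=solution.shapes)
        fh.create_dataset("residuals", data=solution.residuals)
        fh.attrs["mass_orth_error"] = solution.mass_orth_error
        fh.attrs["provenance"] = json.dumps(solution.provenance)


def load_solution(path: str | Path) -> ModalSolution:
    import json

    import h5py

    with h5py.File(path, "r") as fh:
        return ModalSolution(
            frequencies_hz=fh["frequencies_hz"][...],
            shapes=fh["shapes"][...],
            provenance=json.loads(fh.attrs["provenance"]),
            residuals=fh["residuals"][...],
            mass_orth_error=float(fh.attrs["mass_orth_error"]),
        )


def frequencies_csv(path: str | Path, solutions: Sequence[ModalSolution]) -> None:
    """Frequencies-only table: mode_index, frequency_hz, material tags, scale."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["solution", "mode_index", "frequency_hz", "materials", "scale"])
        for s, sol in enumerate(solutions):
            mats = sol.provenance.get("materials", "")
            scale = sol.provenance.get("scale", 1.0)
            for i, f in enumerate(sol.frequencies_hz):
                w.writerow([s, i + 1, f"{f:.9g}", mats, scale])
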