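"""Labeled tetrahedral volume meshes: types, IO, transforms and surface extraction.

Coordinates are stored in meters.  Elements are 4-node (linear) or 10-node
(quadratic) tetrahedra; midside nodes follow the VTK edge ordering
(0,1), (1,2), (0,2), (0,3), (1,3), (2,3).  Every element carries one
component label (free vocabulary: ``periotic``, ``bulla``, ``malleus`` ...)
and one material-region label drawn from :data:`REGIONS`.
"""

from __future__ import annotations

import csv
import hashlib
import io
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "REGIONS",
    "TetMesh",
    "MaterialCard",
    "MaterialSweep",
    "SurfaceMesh",
    "MeshError",
    "read_mesh",
    "write_mesh",
    "scale_mesh",
    "remove_components",
    "fixed_node_set",
    "surface_extract",
    "to_quadratic",
]

#: Controlled vocabulary of material regions.
REGIONS = ("stiff_bone", "flexible_bone", "stiff_ligament", "flexible_ligament")

#: Midside-node edge ordering for 10-node tetrahedra (VTK convention).
TET10_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))

#: Corner faces of a tetrahedron, oriented outward for a positively
#: oriented element.
TET_FACES = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))


class MeshError(ValueError):
    """Raised for invalid meshes, unknown labels, or malformed mesh files."""


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TetMesh:
    """Labeled tetrahedral volume mesh.

    Parameters
    ----------
    nodes : (n, 3) float array
        Node coordinates in meters.
    elements : (m, 4) or (m, 10) int array
        Node indices per tetrahedron.  The first four columns are corner
        nodes; columns 4-9 (if present) are midside nodes in the order of
        :data:`TET10_EDGES`.
    component : (m,) str array
        Per-element component label.
    region : (m,) str array
        Per-element material-region label (one of :data:`REGIONS`).
    """

    nodes: np.ndarray
    elements: np.ndarray
    component: np.ndarray
    region: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=np.float64))
        object.__setattr__(self, "elements", np.asarray(self.elements, dtype=np.int64))
        object.__setattr__(self, "component", np.asarray(self.component, dtype=object))
        object.__setattr__(self, "region", np.asarray(self.region, dtype=object))
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be an (n, 3) array")
        if self.elements.ndim != 2 or self.elements.shape[1] not in (4, 10):
            raise MeshError("elements must be (m, 4) or (m, 10)")
        if len(self.elements) == 0:
            raise MeshError("mesh has no elements")
        if len(self.component) != len(self.elements) or len(self.region) != len(
            self.elements
        ):
            raise MeshError("one component and one region label required per element")
        if self.elements.min() < 0 or self.elements.max() >= len(self.nodes):
            raise MeshError("element node index out of range")
        bad = np.flatnonzero(~np.isin(np.asarray(self.region, dtype=str), REGIONS))
        if len(bad):
            raise MeshError(
                f"unknown region label {self.region[bad[0]]!r} on element {bad[0]}"
            )
        vols = self.volumes()
        bad = np.flatnonzero(vols <= 0)
        if len(bad):
            raise MeshError(
                f"non-positive signed volume on element(s) {bad[:10].tolist()}"
            )

    # -- basic queries ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def order(self) -> int:
        """Nodes per element: 4 (linear) or 10 (quadratic)."""
        return self.elements.shape[1]

    def volumes(self) -> np.ndarray:
        """Signed corner-tet volume per element (positive for valid meshes)."""
        p = self.nodes[self.elements[:, :4]]
        d = p[:, 1:] - p[:, :1]
        return np.linalg.det(d) / 6.0

    def components(self) -> list[str]:
        return sorted(set(self.component.tolist()))

    def regions(self) -> list[str]:
        return sorted(set(self.region.tolist()))

    def element_ids(self, components: Iterable[str]) -> np.ndarray:
        names = set(components)
        mask = np.array([c in names for c in self.component])
        return np.flatnonzero(mask)

    def component_nodes(self, name: str) -> np.ndarray:
        """Sorted unique node ids touched by elements of the named component."""
        eids = self.element_ids([name])
        if len(eids) == 0:
            raise MeshError(f"unknown component {name!r}")
        return np.unique(self.elements[eids])

    def mesh_hash(self) -> str:
        """Stable content hash of coordinates, connectivity and labels."""
        h = hashlib.sha256()
        h.update(np.round(self.nodes, 12).tobytes())
        h.update(self.elements.tobytes())
        h.update("|".join(map(str, self.component)).encode())
        h.update("|".join(map(str, self.region)).encode())
        return h.hexdigest()


@dataclass(frozen=True)
class MaterialCard:
    """Isotropic linear-elastic material: density, Young's modulus, Poisson ratio."""

    density: float  # kg/m^3
    young_modulus: float  # Pa
    poisson_ratio: float  # dimensionless

    def __post_init__(self):
        if not self.density > 0:
            raise ValueError("density must be positive")
        if not self.young_modulus > 0:
            raise ValueError("young_modulus must be positive")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        """Lame parameters (lambda, mu) in Pa."""
        e, nu = self.young_modulus, self.poisson_ratio
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        return lam, mu


@dataclass(frozen=True)
class MaterialSweep:
    """Per-region lists of material cards combined factorially."""

    cards: Mapping[str, Sequence[MaterialCard]]

    def validate_for(self, mesh: TetMesh) -> None:
        for r in mesh.regions():
            if r not in self.cards or len(self.cards[r]) == 0:
                raise ValueError(f"sweep missing cards for region {r!r}")

    def combinations(self) -> list[dict[str, MaterialCard]]:
        keys = sorted(self.cards)
        out = []
        for combo in itertools.product(*(self.cards[k] for k in keys)):
            out.append(dict(zip(keys, combo)))
        return out

    def __len__(self) -> int:
        n = 1
        for v in self.cards.values():
            n *= len(v)
        return n


@dataclass(frozen=True)
class SurfaceMesh:
    """Boundary triangles of a tet mesh with outward unit normals.

    ``triangles`` index into ``vertex_to_volume``; surface vertex ``i`` sits
    at volume node ``vertex_to_volume[i]``.  ``element_of`` records the
    single tetrahedron owning each boundary face.
    """

    vertices: np.ndarray  # (v, 3) coordinates
    triangles: np.ndarray  # (t, 3) surface-vertex indices
    normals: np.ndarray  # (t, 3) outward unit normals
    areas: np.ndarray  # (t,)
    vertex_to_volume: np.ndarray  # (v,) volume node ids
    element_of: np.ndarray  # (t,) owning element ids
    mesh_hash: str = ""

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted average of incident triangle normals, unit length."""
        vn = np.zeros_like(self.vertices)
        w = (self.normals.T * self.areas).T
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], w)
        norms = np.linalg.norm(vn, axis=1)
        norms[norms == 0] = 1.0
        return vn / norms[:, None]


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def scale_mesh(mesh: TetMesh, s: float) -> TetMesh:
    """Uniformly scale all node coordinates about the origin by ``s > 0``."""
    if not s > 0:
        raise ValueError(f"scale factor must be positive, got {s}")
    return replace(mesh, nodes=mesh.nodes * float(s))


def remove_components(
    mesh: TetMesh, names: Iterable[str]
) -> tuple[TetMesh, np.ndarray]:
    """Delete elements of the named components and prune orphaned nodes.

    Returns the reduced mesh and a length-``n_nodes`` renumbering map
    (old node id -> new node id, or -1 for deleted nodes).
    """
    names = set(names)
    if not names:
        return mesh, np.arange(mesh.n_nodes)
    present = set(mesh.component.tolist())
    unknown = names - present
    if unknown:
        raise MeshError(f"unknown component label(s): {sorted(unknown)}")
    keep = np.array([c not in names for c in mesh.component])
    if not keep.any():
        raise MeshError("removal would produce an empty mesh")
    elements = mesh.elements[keep]
    used = np.unique(elements)
    renum = np.full(mesh.n_nodes, -1, dtype=np.int64)
    renum[used] = np.arange(len(used))
    out = TetMesh(
        nodes=mesh.nodes[used],
        elements=renum[elements],
        component=mesh.component[keep],
        region=mesh.region[keep],
    )
    return out, renum


def to_quadratic(mesh: TetMesh) -> TetMesh:
    """Promote a 4-node mesh to 10 nodes by inserting shared edge midpoints."""
    if mesh.order == 10:
        return mesh
    elems = mesh.elements
    edges = np.concatenate(
        [np.sort(elems[:, list(e)], axis=1) for e in TET10_EDGES], axis=0
    )
    uniq, inv = np.unique(edges, axis=0, return_inverse=True)
    mid = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    mid_ids = mesh.n_nodes + inv.reshape(len(TET10_EDGES), -1).T
    return TetMesh(
        nodes=np.vstack([mesh.nodes, mid]),
        elements=np.hstack([elems, mid_ids]),
        component=mesh.component,
        region=mesh.region,
    )


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------


def fixed_node_set(
    mesh: TetMesh,
    component: str = "periotic",
    predicate: Callable[[np.ndarray], np.ndarray] | None = None,
    delta: float | None = None,
    outward: np.ndarray | None = None,
) -> np.ndarray:
    """Node ids whose displacement dofs will be constrained to zero.

    With no ``predicate``, selects nodes of ``component`` within ``delta`` of
    the component's base plane: the least-squares plane through the nodes at
    the extreme of the outward direction (component centroid minus centroid
    of the rest of the mesh, overridable via ``outward``).  ``delta``
    defaults to 5% of the component's bounding-box diagonal.

    Raises :class:`MeshError` if fewer than 3 non-collinear nodes match.
    """
    node_ids = mesh.component_nodes(component)
    coords = mesh.nodes[node_ids]
    if predicate is not None:
        mask = np.asarray(predicate(coords), dtype=bool)
        sel = node_ids[mask]
    else:
        bbox = coords.max(axis=0) - coords.min(axis=0)
        if delta is None:
            delta = 0.05 * float(np.linalg.norm(bbox))
        if outward is None:
            rest = np.setdiff1d(np.arange(mesh.n_nodes), node_ids)
            ref = mesh.nodes[rest].mean(axis=0) if len(rest) else mesh.nodes.mean(axis=0)
            outward = coords.mean(axis=0) - ref
        d = np.asarray(outward, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise MeshError("outward direction for base-plane fit is degenerate")
        d = d / nrm
        t = coords @ d
        seed = coords[t >= t.max() - delta]
        # least-squares plane through the extreme slab
        centroid = seed.mean(axis=0)
        _, _, vt = np.linalg.svd(seed - centroid)
        normal = vt[-1]
        if normal @ d < 0:
            normal = -normal
        dist = np.abs((coords - centroid) @ normal)
        sel = node_ids[dist <= delta]
    if len(sel) < 3:
        raise MeshError(
            f"fixed-node selection matched only {len(sel)} node(s); need >= 3"
        )
    p = mesh.nodes[sel]
    if np.linalg.matrix_rank(p - p.mean(axis=0), tol=1e-12) < 2:
        raise MeshError("fixed-node selection is collinear (rank-deficient)")
    return np.sort(sel)


# ---------------------------------------------------------------------------
# surface extraction
# ---------------------------------------------------------------------------


def surface_extract(mesh: TetMesh) -> SurfaceMesh:
    """Boundary triangles (faces owned by exactly one tet) with outward normals."""
    corner = mesh.elements[:, :4]
    m = len(corner)
    faces = np.concatenate([corner[:, list(f)] for f in TET_FACES], axis=0)
    owner = np.tile(np.arange(m), 4)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = counts[inv] == 1
    faces = faces[boundary]
    owner = owner[boundary]

    used = np.unique(faces)
    renum = np.full(mesh.n_nodes, -1, dtype=np.int64)
    renum[used] = np.arange(len(used))
    tris = renum[faces]
    verts = mesh.nodes[used]

    a = verts[tris[:, 1]] - verts[tris[:, 0]]
    b = verts[tris[:, 2]] - verts[tris[:, 0]]
    cross = np.cross(a, b)
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    if np.any(areas == 0):
        raise MeshError("degenerate boundary triangle")
    normals = cross / (2 * areas)[:, None]

    # orientation check: normals must point away from the owning element centroid
    cent_el = mesh.nodes[corner[owner]].mean(axis=1)
    cent_tri = verts[tris].mean(axis=1)
    flip = np.einsum("ij,ij->i", normals, cent_tri - cent_el) < 0
    normals[flip] *= -1
    tris[flip] = tris[flip][:, ::-1]

    return SurfaceMesh(
        vertices=verts,
        triangles=tris,
        normals=normals,
        areas=areas,
        vertex_to_volume=used,
        element_of=owner,
        mesh_hash=mesh.mesh_hash(),
    )


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3}


def _read_sidecar(path: Path, n_elements: int) -> tuple[np.ndarray, np.ndarray]:
    comp = np.empty(n_elements, dtype=object)
    reg = np.empty(n_elements, dtype=object)
    seen = np.zeros(n_elements, dtype=bool)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        need = {"element_id", "component", "region"}
        if reader.fieldnames is None or not need <= set(reader.fieldnames):
            raise MeshError(f"label sidecar {path} must have columns {sorted(need)}")
        for row in reader:
            i = int(row["element_id"])
            if not 0 <= i < n_elements:
                raise MeshError(f"sidecar element_id {i} out of range")
            comp[i] = row["component"]
            reg[i] = row["region"]
            seen[i] = True
    if not seen.all():
        raise MeshError(
            f"sidecar leaves element(s) unlabeled: {np.flatnonzero(~seen)[:10].tolist()}"
        )
    return comp, reg


def _write_sidecar(path: Path, mesh: TetMesh) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["element_id", "component", "region"])
        for i in range(mesh.n_elements):
            w.writerow([i, mesh.component[i], mesh.region[i]])


# gmsh stores tet10 midside nodes with edges (2,3) and (1,3) swapped vs VTK
_GMSH_TET10_PERM = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]


def read_mesh(
    path: str | Path,
    format: str | None = None,
    labels: str | Path | None = None,
    unit: str = "m",
) -> TetMesh:
    """Read a labeled tet mesh from Gmsh MSH 4.1 ASCII or legacy VTK ASCII.

    Labels come from MSH physical names of the form ``component:region`` or
    from a CSV sidecar (``element_id,component,region``); the sidecar wins
    if both are supplied.  ``unit`` may be ``"m"`` or ``"mm"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "msh" if path.suffix == ".msh" else "vtk"
    if unit not in _UNIT_SCALE:
        raise MeshError(f"unsupported unit {unit!r}")
    if format == "msh":
        nodes, elements, comp, reg = _read_msh(path)
    elif format == "vtk":
        nodes, elements, comp, reg = _read_vtk(path)
    else:
        raise MeshError(f"unsupported mesh format {format!r}")
    nodes = nodes * _UNIT_SCALE[unit]
    if labels is not None:
        comp, reg = _read_sidecar(Path(labels), len(elements))
    if comp is None or any(c is None for c in comp):
        raise MeshError(
            "mesh carries no element labels; supply MSH physical names "
            "'component:region' or a CSV sidecar"
        )
    return TetMesh(nodes=nodes, elements=elements, component=comp, region=reg)


def write_mesh(
    path: str | Path,
    mesh: TetMesh,
    format: str | None = None,
    labels: str | Path | None = None,
) -> None:
    """Write a mesh as Gmsh MSH 4.1 ASCII or legacy VTK ASCII (meters).

    MSH files embed labels as physical names ``component:region``; for both
    formats a CSV sidecar is written when ``labels`` is given.  Element
    order is preserved.
    """
    path = Path(path)
    if format is None:
        format = "msh" if path.suffix == ".msh" else "vtk"
    if format == "msh":
        _write_msh(path, mesh)
    elif format == "vtk":
        _write_vtk(path, mesh)
    else:
        raise MeshError(f"unsupported mesh format {format!r}")
    if labels is not None:
        _write_sidecar(Path(labels), mesh)


# -- MSH 4.1 ASCII ----------------------------------------------------------


def _read_msh(path: Path):
    text = path.read_text()

    def section(name):
        start = text.find(f"${name}\n")
        if start < 0:
            return None
        start += len(name) + 2
        end = text.find(f"$End{name}")
        return text[start:end].strip("\n").split("\n")

    fmt = section("MeshFormat")
    if fmt is None or not fmt[0].startswith("4.1"):
        raise MeshError(f"{path}: expected MSH format 4.1 ASCII")

    phys_names: dict[int, str] = {}
    pn = section("PhysicalNames")
    if pn is not None:
        for line in pn[1:]:
            parts = line.split(maxsplit=2)
            if len(parts) == 3:
                phys_names[int(parts[1])] = parts[2].strip('"')

    # entity (dim=3) -> physical tag
    ent_phys: dict[int, int] = {}
    ent = section("Entities")
    if ent is not None:
        counts = list(map(int, ent[0].split()))
        idx = 1 + counts[0]
        for dim, n in ((1, counts[1]), (2, counts[2]), (3, counts[3])):
            for _ in range(n):
                vals = ent[idx].split()
                idx += 1
                if dim == 3:
                    nphys = int(vals[7])
                    if nphys >= 1:
                        ent_phys[int(vals[0])] = int(vals[8])

    nsec = section("Nodes")
    if nsec is None:
        raise MeshError(f"{path}: missing $Nodes")
    nblocks, ntotal = int(nsec[0].split()[0]), int(nsec[0].split()[1])
    coords = np.zeros((ntotal, 3))
    tag_to_idx: dict[int, int] = {}
    pos, filled = 1, 0
    for _ in range(nblocks):
        _, _, _, nb = map(int, nsec[pos].split())
        pos += 1
        tags = [int(nsec[pos + i]) for i in range(nb)]
        pos += nb
        for i, t in enumerate(tags):
            tag_to_idx[t] = filled + i
            coords[filled + i] = list(map(float, nsec[pos + i].split()[:3]))
        pos += nb
        filled += nb

    esec = section("Elements")
    if esec is None:
        raise MeshError(f"{path}: missing $Elements")
    eblocks = int(esec[0].split()[0])
    pos = 1
    elem_rows: list[list[int]] = []
    comp_rows: list[str | None] = []
    reg_rows: list[str | None] = []
    order = None
    for _ in range(eblocks):
        _, etag, etype, nb = map(int, esec[pos].split())
        pos += 1
        if etype not in (4, 11):  # tet4, tet10
            pos += nb
            continue
        npe = 4 if etype == 4 else 10
        if order is None:
            order = npe
        elif order != npe:
            raise MeshError(f"{path}: mixed tet4/tet10 element blocks")
        comp = reg = None
        ptag = ent_phys.get(etag)
        if ptag is not None and ptag in phys_names and ":" in phys_names[ptag]:
            comp, reg = phys_names[ptag].split(":", 1)
        for i in range(nb):
            vals = list(map(int, esec[pos + i].split()))
            conn = [tag_to_idx[t] for t in vals[1 : 1 + npe]]
            if npe == 10:
                conn = [conn[j] for j in _GMSH_TET10_PERM]
            elem_rows.append(conn)
            comp_rows.append(comp)
            reg_rows.append(reg)
        pos += nb
    if not elem_rows:
        raise MeshError(f"{path}: no tetrahedral elements found")
    return (
        coords,
        np.array(elem_rows, dtype=np.int64),
        np.array(comp_rows, dtype=object),
        np.array(reg_rows, dtype=object),
    )


def _write_msh(path: Path, mesh: TetMesh) -> None:
    # one entity block per contiguous run of identical labels: preserves the
    # input element order exactly while still encoding labels as physical names
    labels = [(str(c), str(r)) for c, r in zip(mesh.component, mesh.region)]
    phys: dict[tuple[str, str], int] = {}
    runs: list[tuple[tuple[str, str], int, int]] = []  # (label, start, stop)
    start = 0
    for i in range(1, mesh.n_elements + 1):
        if i == mesh.n_elements or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            phys.setdefault(labels[start], len(phys) + 1)
            start = i
    etype = 4 if mesh.order == 4 else 11

    buf = io.StringIO()
    buf.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
    buf.write(f"$PhysicalNames\n{len(phys)}\n")
    for (comp, reg), k in phys.items():
        buf.write(f'3 {k} "{comp}:{reg}"\n')
    buf.write("$EndPhysicalNames\n")
    buf.write(f"$Entities\n0 0 0 {len(runs)}\n")
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    for k, (label, _, _) in enumerate(runs, start=1):
        buf.write(
            f"{k} {lo[0]:.17g} {lo[1]:.17g} {lo[2]:.17g} "
            f"{hi[0]:.17g} {hi[1]:.17g} {hi[2]:.17g} 1 {phys[label]} 0\n"
        )
    buf.write("$EndEntities\n")
    n = mesh.n_nodes
    buf.write(f"$Nodes\n1 {n} 1 {n}\n3 1 0 {n}\n")
    for i in range(n):
        buf.write(f"{i + 1}\n")
    for p in mesh.nodes:
        buf.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    buf.write("$EndNodes\n")
    total = mesh.n_elements
    buf.write(f"$Elements\n{len(runs)} {total} 1 {total}\n")
    perm = _GMSH_TET10_PERM if mesh.order == 10 else list(range(4))
    eid = 1
    for k, (_, a, b) in enumerate(runs, start=1):
        buf.write(f"3 {k} {etype} {b - a}\n")
        for i in range(a, b):
            conn = mesh.elements[i][perm] + 1
            buf.write(f"{eid} " + " ".join(map(str, conn)) + "\n")
            eid += 1
    buf.write("$EndElements\n")
    path.write_text(buf.getvalue())


# -- legacy VTK ASCII -------------------------------------------------------


def _read_vtk(path: Path):
    lines = [ln for ln in path.read_text().splitlines()]
    i = 0

    def next_tokens():
        nonlocal i
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines):
            raise MeshError(f"{path}: unexpected end of VTK file")
        toks = lines[i].split()
        i += 1
        return toks

    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise MeshError(f"{path}: not a legacy VTK file")
    i = 2  # skip header + title
    if next_tokens()[0].upper() != "ASCII":
        raise MeshError(f"{path}: only ASCII VTK supported")
    toks = next_tokens()
    if toks[1].upper() != "UNSTRUCTURED_GRID":
        raise MeshError(f"{path}: expected UNSTRUCTURED_GRID")
    toks = next_tokens()
    assert toks[0].upper() == "POINTS"
    npts = int(toks[1])
    vals: list[float] = []
    while len(vals) < 3 * npts:
        vals.extend(map(float, next_tokens()))
    nodes = np.array(vals).reshape(npts, 3)
    toks = next_tokens()
    assert toks[0].upper() == "CELLS"
    ncells = int(toks[1])
    conn: list[list[int]] = []
    for _ in range(ncells):
        row = list(map(int, next_tokens()))
        if row[0] not in (4, 10):
            raise MeshError(f"{path}: only tetrahedral cells supported")
        conn.append(row[1:])
    toks = next_tokens()
    assert toks[0].upper() == "CELL_TYPES"
    types = [int(next_tokens()[0]) for _ in range(ncells)]
    if any(t not in (10, 24) for t in types):
        raise MeshError(f"{path}: only VTK cell types 10 (tet4) / 24 (tet10)")
    orders = {len(c) for c in conn}
    if len(orders) != 1:
        raise MeshError(f"{path}: mixed tet4/tet10 cells")
    elements = np.array(conn, dtype=np.int64)
    none = np.array([None] * ncells, dtype=object)
    return nodes, elements, none.copy(), none.copy()


def _write_vtk(path: Path, mesh: TetMesh) -> None:
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n")
    buf.write("tpcvibe mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
    buf.write(f"POINTS {mesh.n_nodes} double\n")
    for p in mesh.nodes:
        buf.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    npe = mesh.order
    buf.write(f"CELLS {mesh.n_elements} {mesh.n_elements * (npe + 1)}\n")
    for conn in mesh.elements:
        buf.write(f"{npe} " + " ".join(map(str, conn)) + "\n")
    buf.write(f"CELL_TYPES {mesh.n_elements}\n")
    ctype = 10 if npe == 4 else 24
    for _ in range(mesh.n_elements):
        buf.write(f"{ctype}\n")
    path.write_text(buf.getvalue())
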