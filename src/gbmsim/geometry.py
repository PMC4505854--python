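"""Simulation domains: structured tetrahedral meshes and mesh file I/O.

The whole-brain meshing pipeline (segmentation, surface extraction,
tetrahedralization) is external software territory; this package provides
(a) structured box generators — each hexahedral cell split into six
tetrahedra by the Kuhn/Freudenthal rule, which is conforming and symmetric
under coordinate permutation — with local red refinement plus green
conformity closure near the tumor seed, and (b) readers/writers for
externally prepared labeled tetrahedral meshes in Gmsh MSH v2.2 ASCII and
legacy VTK unstructured-grid format.  Coordinates are millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np

__all__ = ["Mesh", "box_mesh", "refine_region", "read_mesh", "write_mesh"]

logger = logging.getLogger("gbmsim")

#: Tissue label convention for labeled meshes.
TISSUE_LABELS = {0: "background", 1: "CSF", 2: "grey", 3: "white"}


@dataclass
class Mesh:
    """Tetrahedral simulation domain.

    vertices : (N, 3) float array, mm
    cells : (M, 4) int array of vertex indices, positively oriented
    labels : optional (M,) int array of per-cell tissue labels
    """

    vertices: np.ndarray
    cells: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if self.cells.ndim != 2 or self.cells.shape[1] != 4:
            raise ValueError("cells must be an (M, 4) array of tetrahedra")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.cells),):
                raise ValueError("labels must cover all cells")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_volumes(self) -> np.ndarray:
        v = self.vertices[self.cells]
        e = v[:, 1:] - v[:, :1]
        return np.linalg.det(e) / 6.0

    def barycenters(self) -> np.ndarray:
        return self.vertices[self.cells].mean(axis=1)

    def volume(self) -> float:
        return float(self.cell_volumes().sum())

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def edge_lengths(self) -> np.ndarray:
        v = self.vertices[self.cells]
        pairs = list(combinations(range(4), 2))
        return np.stack([np.linalg.norm(v[:, i] - v[:, j], axis=1)
                         for i, j in pairs], axis=1)

    def facets(self) -> tuple[np.ndarray, np.ndarray]:
        """All facets (sorted vertex triples) with their occurrence counts."""
        faces = self.cells[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]]
        faces = np.sort(faces.reshape(-1, 3), axis=1)
        uniq, counts = np.unique(faces, axis=0, return_counts=True)
        return uniq, counts

    def boundary_facets(self) -> np.ndarray:
        """Facets belonging to exactly one cell (the domain surface)."""
        uniq, counts = self.facets()
        if counts.max(initial=1) > 2:
            raise ValueError("non-manifold mesh: a facet is shared by more "
                             "than two cells")
        return uniq[counts == 1]

    def boundary_vertices(self) -> np.ndarray:
        """Indices of vertices lying on the boundary surface."""
        return np.unique(self.boundary_facets())

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if self.cells.min(initial=0) < 0 or self.cells.max(initial=-1) >= self.n_vertices:
            raise ValueError("cell vertex index out of range")
        vols = self.cell_volumes()
        degenerate = np.flatnonzero(vols <= 0.0)
        if len(degenerate):
            raise ValueError(f"degenerate (non-positive volume) cells at "
                             f"indices {degenerate[:10].tolist()}")
        self.boundary_facets()  # raises on non-manifold connectivity

    def oriented(self) -> "Mesh":
        """Copy with all cells reordered to positive orientation."""
        cells = self.cells.copy()
        neg = self.cell_volumes() < 0.0
        cells[neg] = cells[neg][:, [0, 2, 1, 3]]
        return Mesh(self.vertices.copy(), cells,
                    None if self.labels is None else self.labels.copy())


# The six tetrahedra of the Kuhn subdivision of a unit cube: one per
# permutation of the axes, every tet sharing the main diagonal (0,0,0)-(1,1,1).
_KUHN_PATHS = [np.array(p) for p in permutations(range(3))]


def box_mesh(extents, resolution, origin=None) -> Mesh:
    """Axis-aligned box tessellated into tetrahedra (6 per hex cell).

    Parameters
    ----------
    extents : three floats, mm — box side lengths.
    resolution : three ints — hexahedral cells per axis.
    origin : three floats, mm — minimum corner (default 0, 0, 0).
    """
    extents = np.asarray(extents, dtype=float).reshape(3)
    res = np.asarray(resolution, dtype=int).reshape(3)
    if np.any(extents <= 0.0):
        raise ValueError(f"extents must be positive, got {extents.tolist()}")
    if np.any(res < 1):
        raise ValueError(f"resolution must be >= 1 per axis, got {res.tolist()}")
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float).reshape(3)

    nx, ny, nz = res
    axes = [origin[a] + extents[a] / res[a] * np.arange(res[a] + 1) for a in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    vertices = grid.reshape(-1, 3)

    def vid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    base = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    cells = []
    for path in _KUHN_PATHS:
        corner = base.copy()
        tet = [vid(*corner.T)]
        for axis in path:
            corner = corner.copy()
            corner[:, axis] += 1
            tet.append(vid(*corner.T))
        cells.append(np.stack(tet, axis=1))
    cells = np.concatenate(cells, axis=0)
    return Mesh(vertices, cells).oriented()


# ---------------------------------------------------------------------------
# Local red refinement with green conformity closure
# ---------------------------------------------------------------------------

def _edge_key(a: int, b: int) -> tuple[int, int]:
    return (a, b) if a < b else (b, a)


_TET_EDGES = list(combinations(range(4), 2))
_TET_FACES = [(1, 2, 3), (0, 2, 3), (0, 1, 3), (0, 1, 2)]


def _red_children(tet, mid, vertices):
    """Bey-style 1:8 red subdivision; octahedron split along its shortest
    diagonal (global-index tie-break)."""
    v = list(tet)
    m = {e: mid[_edge_key(v[e[0]], v[e[1]])] for e in _TET_EDGES}
    corners = [
        (v[0], m[(0, 1)], m[(0, 2)], m[(0, 3)]),
        (m[(0, 1)], v[1], m[(1, 2)], m[(1, 3)]),
        (m[(0, 2)], m[(1, 2)], v[2], m[(2, 3)]),
        (m[(0, 3)], m[(1, 3)], m[(2, 3)], v[3]),
    ]
    # Octahedron vertices keyed by the local edge they bisect; opposite pairs
    # are the ones with disjoint local edges.
    diag_pairs = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
    lengths = [np.linalg.norm(vertices[m[a]] - vertices[m[b]]) for a, b in diag_pairs]
    a, b = diag_pairs[int(np.argmin(lengths))]
    others = [e for e in _TET_EDGES if e not in (a, b)]
    # Order the remaining four into a cycle where consecutive members share
    # a local vertex index (octahedron adjacency).
    cycle = [others.pop(0)]
    while others:
        last = cycle[-1]
        nxt = next(e for e in others if set(e) & set(last))
        others.remove(nxt)
        cycle.append(nxt)
    octa = [(m[a], m[b], m[cycle[i]], m[cycle[(i + 1) % 4]]) for i in range(4)]
    return corners + octa


def _split_face_quad(mA, vB, vC, mAC):
    """Canonical triangulation of the quad (mAB, B, C, mAC); the diagonal
    choice depends only on global vertex indices so both cells sharing the
    face agree."""
    if min(mA, vC) <= min(vB, mAC):
        return [(mA, vB, vC), (mA, vC, mAC)]
    return [(mA, vB, mAC), (vB, vC, mAC)]


def _green_children(tet, split, mid):
    """Children of a non-red tet whose split edges form a green template:
    one edge, two edges on a common face, or a fully split face.
    Returns None if the configuration is not a template (promote to red)."""
    v = list(tet)
    local_split = [e for e in _TET_EDGES
                   if _edge_key(v[e[0]], v[e[1]]) in split]
    k = len(local_split)
    if k == 0:
        return [tuple(v)]
    if k == 1:
        (i, j) = local_split[0]
        m = mid[_edge_key(v[i], v[j])]
        child1, child2 = list(v), list(v)
        child1[j] = m
        child2[i] = m
        return [tuple(child1), tuple(child2)]
    # All split edges must lie on one face for the face templates.
    for fi, face in enumerate(_TET_FACES):
        fset = set(face)
        if all(set(e) <= fset for e in local_split):
            apex = v[[i for i in range(4) if i not in fset][0]]
            face_edges = [tuple(sorted(e)) for e in combinations(face, 2)]
            split_here = [e for e in face_edges if e in
                          [tuple(sorted(le)) for le in local_split]]
            fv = [v[i] for i in face]
            if k == 3:
                mm = {e: mid[_edge_key(v[e[0]], v[e[1]])] for e in face_edges}
                e01, e02, e12 = face_edges[0], face_edges[1], face_edges[2]
                tris = [(fv[0], mm[e01], mm[e02]),
                        (mm[e01], fv[1], mm[e12]),
                        (mm[e02], mm[e12], fv[2]),
                        (mm[e01], mm[e12], mm[e02])]
            elif k == 2:
                common = set(split_here[0]) & set(split_here[1])
                if not common:
                    return None
                a_local = common.pop()
                others = [(set(e) - {a_local}).pop() for e in split_here]
                b_local, c_local = others
                A, B, C = v[a_local], v[b_local], v[c_local]
                mAB = mid[_edge_key(A, B)]
                mAC = mid[_edge_key(A, C)]
                tris = [(A, mAB, mAC)] + _split_face_quad(mAB, B, C, mAC)
            else:
                return None
            return [tri + (apex,) for tri in tris]
    return None


def refine_region(mesh: Mesh, center, radius: float, levels: int = 1) -> Mesh:
    """Red-refine cells near a point, with green closure for conformity.

    Cells whose barycenter lies within ``radius`` of ``center`` are
    subdivided 1:8; neighbors acquiring hanging nodes are closed with green
    templates (or promoted to red when no template applies), so the
    resulting mesh stays conforming for P1 elements.  Total volume is
    preserved exactly (children partition parents).  A center outside the
    mesh bounding box is a warning and a no-op.
    """
    if radius <= 0.0:
        raise ValueError(f"radius must be positive, got {radius!r}")
    if levels < 0:
        raise ValueError(f"levels must be >= 0, got {levels!r}")
    center = np.asarray(center, dtype=float).reshape(3)
    lo, hi = mesh.bounding_box()
    if np.any(center < lo) or np.any(center > hi):
        logger.warning("refine_region: center %s outside mesh bounding box; "
                       "no refinement performed", center.tolist())
        return Mesh(mesh.vertices.copy(), mesh.cells.copy(),
                    None if mesh.labels is None else mesh.labels.copy())
    out = mesh
    for _ in range(levels):
        marked = np.flatnonzero(
            np.linalg.norm(out.barycenters() - center[None, :], axis=1) <= radius)
        out = _refine_once(out, set(marked.tolist()))
    return out


def _refine_once(mesh: Mesh, red: set[int]) -> Mesh:
    if not red:
        return Mesh(mesh.vertices.copy(), mesh.cells.copy(),
                    None if mesh.labels is None else mesh.labels.copy())
    cells = mesh.cells

    # Closure: promote non-template configurations to red until stable.
    while True:
        split = set()
        for c in red:
            tet = cells[c]
            for i, j in _TET_EDGES:
                split.add(_edge_key(tet[i], tet[j]))
        promoted = False
        for c in range(len(cells)):
            if c in red:
                continue
            tet = cells[c]
            probe = _green_children(tet, split, _FakeMid())
            if probe is None:
                red.add(c)
                promoted = True
        if not promoted:
            break

    # Allocate midpoint vertices.
    mid: dict[tuple[int, int], int] = {}
    new_vertices = [mesh.vertices]
    next_id = mesh.n_vertices
    extra = []
    for a, b in sorted(split):
        mid[(a, b)] = next_id
        extra.append(0.5 * (mesh.vertices[a] + mesh.vertices[b]))
        next_id += 1
    if extra:
        new_vertices.append(np.asarray(extra))
    vertices = np.concatenate(new_vertices, axis=0)

    new_cells = []
    new_labels = [] if mesh.labels is not None else None
    for c in range(len(cells)):
        tet = cells[c]
        if c in red:
            children = _red_children(tet, mid, vertices)
        else:
            children = _green_children(tet, split, mid)
        new_cells.extend(children)
        if new_labels is not None:
            new_labels.extend([mesh.labels[c]] * len(children))
    refined = Mesh(vertices, np.asarray(new_cells, dtype=np.int64),
                   None if new_labels is None else np.asarray(new_labels))
    return refined.oriented()


class _FakeMid(dict):
    """Midpoint stand-in used when only classifying a split configuration."""

    def __getitem__(self, key):
        return -1


# ---------------------------------------------------------------------------
# Mesh file I/O (Gmsh MSH v2.2 ASCII, legacy VTK unstructured grid)
# ---------------------------------------------------------------------------

def read_mesh(path) -> Mesh:
    """Read a tetrahedral mesh from Gmsh MSH v2.2 ASCII or legacy VTK.

    The format is chosen by extension (.msh / .vtk).  Lower-dimensional
    elements in MSH files (points, lines, surface triangles) are skipped;
    any other volume element (pyramids, prisms, hexahedra) is an error.
    An integer cell-data field, if present, is read as the tissue label.
    Cells with inverted orientation are reordered; near-degenerate cells
    are an error.  Units are assumed to be mm.
    """
    path = str(path)
    if path.endswith(".msh"):
        mesh = _read_msh(path)
    elif path.endswith(".vtk"):
        mesh = _read_vtk(path)
    else:
        raise ValueError(f"unsupported mesh format for {path!r} "
                         "(expected .msh or .vtk)")
    mesh = mesh.oriented()
    mesh.validate()
    return mesh


def write_mesh(mesh: Mesh, path) -> None:
    """Write a mesh (with labels, if any) to .msh (v2.2) or legacy .vtk."""
    path = str(path)
    if path.endswith(".msh"):
        _write_msh(mesh, path)
    elif path.endswith(".vtk"):
        _write_vtk(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format for {path!r} "
                         "(expected .msh or .vtk)")


_MSH_TET = 4
_MSH_SKIP = {15: 1, 1: 2, 2: 3, 8: 3, 9: 6}  # points, lines, triangles (+2nd order)


def _read_msh(path: str) -> Mesh:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    try:
        i_nodes = lines.index("$Nodes")
        i_elems = lines.index("$Elements")
    except ValueError as exc:
        raise ValueError(f"{path}: not a Gmsh MSH ASCII file") from exc

    n_nodes = int(lines[i_nodes + 1])
    id_map = {}
    coords = np.empty((n_nodes, 3), dtype=float)
    for k in range(n_nodes):
        parts = lines[i_nodes + 2 + k].split()
        id_map[int(parts[0])] = k
        coords[k] = [float(x) for x in parts[1:4]]

    n_elems = int(lines[i_elems + 1])
    cells, labels = [], []
    any_tags = False
    for k in range(n_elems):
        parts = lines[i_elems + 2 + k].split()
        etype = int(parts[1])
        n_tags = int(parts[2])
        conn = parts[3 + n_tags:]
        if etype == _MSH_TET:
            if len(conn) != 4:
                raise ValueError(f"{path}: malformed tetrahedron on element "
                                 f"line {k}")
            cells.append([id_map[int(c)] for c in conn])
            if n_tags >= 1:
                labels.append(int(parts[3]))
                any_tags = True
            else:
                labels.append(0)
        elif etype in _MSH_SKIP:
            continue
        else:
            raise ValueError(f"{path}: non-tetrahedral volume element "
                             f"(gmsh type {etype}) is not supported")
    if not cells:
        raise ValueError(f"{path}: no tetrahedral cells found")
    return Mesh(coords, np.asarray(cells, dtype=np.int64),
                np.asarray(labels, dtype=np.int64) if any_tags else None)


def _write_msh(mesh: Mesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_vertices}\n")
        for i, (x, y, z) in enumerate(mesh.vertices, start=1):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_cells}\n")
        labels = mesh.labels if mesh.labels is not None else np.zeros(mesh.n_cells, dtype=int)
        for i, (tet, lab) in enumerate(zip(mesh.cells, labels), start=1):
            a, b, c, d = (tet + 1).tolist()
            fh.write(f"{i} 4 2 {int(lab)} {int(lab)} {a} {b} {c} {d}\n")
        fh.write("$EndElements\n")


def _read_vtk(path: str) -> Mesh:
    with open(path) as fh:
        tokens_lines = fh.read().splitlines()
    # Tokenize lazily: legacy VTK is whitespace/keyword structured.
    idx = 0

    def next_line():
        nonlocal idx
        while idx < len(tokens_lines):
            ln = tokens_lines[idx].strip()
            idx += 1
            if ln:
                return ln
        return None

    header = next_line()
    if header is None or not header.startswith("# vtk DataFile"):
        raise ValueError(f"{path}: not a legacy VTK file")
    next_line()  # title
    fmt = next_line()
    if fmt is None or fmt.upper() != "ASCII":
        raise ValueError(f"{path}: only ASCII legacy VTK is supported")
    dataset = next_line()
    if dataset is None or "UNSTRUCTURED_GRID" not in dataset.upper():
        raise ValueError(f"{path}: expected DATASET UNSTRUCTURED_GRID")

    vertices = cells = labels = None
    n_read_cells = 0
    while True:
        ln = next_line()
        if ln is None:
            break
        key = ln.split()[0].upper()
        if key == "POINTS":
            n = int(ln.split()[1])
            vals = []
            while len(vals) < 3 * n:
                vals.extend(next_line().split())
            vertices = np.array(vals[:3 * n], dtype=float).reshape(n, 3)
        elif key == "CELLS":
            n_read_cells = int(ln.split()[1])
            total = int(ln.split()[2])
            vals = []
            while len(vals) < total:
                vals.extend(next_line().split())
            vals = np.array(vals, dtype=np.int64)
            cells_list, pos = [], 0
            for _ in range(n_read_cells):
                cnt = int(vals[pos])
                cells_list.append(vals[pos + 1: pos + 1 + cnt])
                pos += 1 + cnt
            cells = cells_list
        elif key == "CELL_TYPES":
            n = int(ln.split()[1])
            vals = []
            while len(vals) < n:
                vals.extend(next_line().split())
            types = np.array(vals, dtype=int)
            if np.any(types != 10):
                bad = np.flatnonzero(types != 10)
                raise ValueError(f"{path}: non-tetrahedral cells (VTK types "
                                 f"{sorted(set(types[bad].tolist()))}) at "
                                 f"indices {bad[:10].tolist()}")
        elif key == "CELL_DATA":
            ln2 = next_line()
            if ln2 is not None and ln2.upper().startswith("SCALARS"):
                next_line()  # LOOKUP_TABLE
                vals = []
                while len(vals) < n_read_cells:
                    vals.extend(next_line().split())
                labels = np.array(vals[:n_read_cells], dtype=float).astype(np.int64)
    if vertices is None or cells is None:
        raise ValueError(f"{path}: missing POINTS or CELLS section")
    for i, c in enumerate(cells):
        if len(c) != 4:
            raise ValueError(f"{path}: cell {i} has {len(c)} vertices; only "
                             "tetrahedra are supported")
    return Mesh(vertices, np.asarray(cells, dtype=np.int64), labels)


def _write_vtk(mesh: Mesh, path: str, point_data: dict | None = None,
               cell_data: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ngbmsim mesh\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for x, y, z in mesh.vertices:
            fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
        fh.write(f"CELLS {mesh.n_cells} {5 * mesh.n_cells}\n")
        for tet in mesh.cells:
            fh.write("4 " + " ".join(str(int(v)) for v in tet) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_cells}\n")
        fh.write("\n".join(["10"] * mesh.n_cells) + "\n")

        cell_fields = dict(cell_data or {})
        if mesh.labels is not None and "tissue_label" not in cell_fields:
            cell_fields["tissue_label"] = mesh.labels
        if cell_fields:
            fh.write(f"CELL_DATA {mesh.n_cells}\n")
            for name, values in cell_fields.items():
                values = np.asarray(values)
                if values.dtype.kind in "iu":
                    fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(str(int(v)) for v in values) + "\n")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{float(v):.17g}" for v in values) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, values in point_data.items():
                values = np.asarray(values, dtype=float)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.17g}" for v in values) + "\n")


def write_fields_vtk(mesh: Mesh, path, point_data: dict | None = None,
                     cell_data: dict | None = None) -> None:
    """Write a mesh with point/cell data fields as legacy VTK (ASCII)."""
    _write_vtk(mesh, str(path), point_data=point_data, cell_data=cell_data)
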