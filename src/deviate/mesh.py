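"""Triangulated surface meshes and per-vertex scalar maps.

This module is the geometric substrate for the whole pipeline: cortical
thickness, residuals, statistics and masks are all scalars attached to the
vertices of one shared triangle mesh. Vertex indexing is 0-based everywhere,
including in the on-disk ASCII formats.

Two mesh dialects are supported:

* ``obj-ascii`` — a Wavefront-style text format with ``v x y z`` and
  ``f i j k`` records, except that face records are 0-based. Writing then
  reading is bit-exact.
* ``gifti`` — a GIFTI surface container (via nibabel); values round-trip to
  float32 precision (~1e-7 relative).

Scalar maps are stored either as one-value-per-line ASCII with a one-line
header naming the kind tag, or as GIFTI functional files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import FormatError, IntegrityError

MAP_KINDS = ("thickness", "residual", "statistic", "p_value", "mask")

_DEGENERATE_AREA = 1e-12


class TriangleMesh:
    """A triangulated surface: vertex coordinates (mm) and triangle indices.

    Parameters
    ----------
    vertices : (V, 3) array_like of float
        Vertex positions in millimetres.
    faces : (F, 3) array_like of int
        Triples of 0-based vertex indices.

    Raises
    ------
    IntegrityError
        If a face references an out-of-range vertex or repeats a vertex.
    """

    def __init__(self, vertices, faces):
        vertices = np.asarray(vertices, dtype=np.float64)
        faces = np.asarray(faces, dtype=np.int64)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise IntegrityError(f"vertices must be (V, 3), got {vertices.shape}")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise IntegrityError(f"faces must be (F, 3), got {faces.shape}")
        if faces.size and (faces.min() < 0 or faces.max() >= len(vertices)):
            bad = int(faces.max() if faces.max() >= len(vertices) else faces.min())
            raise IntegrityError(
                f"face references vertex index {bad} outside [0, {len(vertices) - 1}]"
            )
        if faces.size and (
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        ).any():
            raise IntegrityError("a triangle repeats a vertex")
        self.vertices = vertices
        self.faces = faces
        self._cache: dict = {}

    # ------------------------------------------------------------------ basic
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def _cached(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (E, 2) int array."""

        def build():
            pairs = np.concatenate(
                [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]]
            )
            pairs = np.sort(pairs, axis=1)
            return np.unique(pairs, axis=0)

        return self._cached("edges", build)

    def edge_lengths(self) -> np.ndarray:
        def build():
            e = self.edges()
            return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

        return self._cached("edge_lengths", build)

    def mean_edge_length(self) -> float:
        return float(self.edge_lengths().mean())

    def triangle_areas(self) -> np.ndarray:
        def build():
            a = self.vertices[self.faces[:, 0]]
            b = self.vertices[self.faces[:, 1]]
            c = self.vertices[self.faces[:, 2]]
            return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

        return self._cached("triangle_areas", build)

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def adjacency_matrix(self) -> sp.csr_matrix:
        """Symmetric boolean vertex adjacency (edge graph) in CSR form."""

        def build():
            e = self.edges()
            i = np.concatenate([e[:, 0], e[:, 1]])
            j = np.concatenate([e[:, 1], e[:, 0]])
            data = np.ones(len(i), dtype=np.int8)
            return sp.csr_matrix((data, (i, j)), shape=(self.n_vertices, self.n_vertices))

        return self._cached("adjacency", build)

    def n_components(self) -> int:
        n, _ = connected_components(self.adjacency_matrix(), directed=False)
        return int(n)

    def validate(self, require_connected: bool = True) -> None:
        """Check the full set of mesh invariants.

        Raises
        ------
        IntegrityError
            On degenerate (zero-area) triangles, or — when
            ``require_connected`` — on a multi-component edge graph.
        """
        areas = self.triangle_areas()
        if (areas <= _DEGENERATE_AREA).any():
            bad = int(np.argmax(areas <= _DEGENERATE_AREA))
            raise IntegrityError(f"triangle {bad} is degenerate (area {areas[bad]:g})")
        if require_connected:
            n = self.n_components()
            if n != 1:
                raise IntegrityError(
                    f"mesh has {n} connected components; pass keep_largest=True "
                    "to analyse the largest one"
                )

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.edges()) + self.n_faces


@dataclass
class VertexMap:
    """One scalar per mesh vertex, tagged with what the scalar means.

    ``kind`` is one of ``thickness`` (mm, strictly positive), ``residual``,
    ``statistic``, ``p_value`` (in [0, 1]) or ``mask`` (0/1).
    """

    values: np.ndarray
    kind: str = "statistic"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.kind not in MAP_KINDS:
            raise IntegrityError(f"unknown map kind {self.kind!r}; expected one of {MAP_KINDS}")

    def __len__(self):
        return len(self.values)

    def validate(self, mesh: TriangleMesh | None = None) -> None:
        if mesh is not None and len(self.values) != mesh.n_vertices:
            raise IntegrityError(
                f"map has {len(self.values)} values but mesh has {mesh.n_vertices} vertices"
            )
        if not np.isfinite(self.values).all():
            raise IntegrityError(f"{self.kind} map contains non-finite values")
        if self.kind == "thickness" and (self.values <= 0).any():
            raise IntegrityError("thickness map must be strictly positive")
        if self.kind == "p_value" and ((self.values < 0) | (self.values > 1)).any():
            raise IntegrityError("p_value map must lie in [0, 1]")
        if self.kind == "mask" and not np.isin(self.values, (0.0, 1.0)).all():
            raise IntegrityError("mask map must be 0/1")


# --------------------------------------------------------------------- ops
def vertex_areas(mesh: TriangleMesh) -> VertexMap:
    """Barycentric vertex areas: one third of each incident triangle.

    The areas sum exactly to the total mesh surface area, which is what the
    resel computation downstream relies on.
    """
    areas = mesh.triangle_areas()
    if (areas <= _DEGENERATE_AREA).any():
        bad = int(np.argmax(areas <= _DEGENERATE_AREA))
        raise IntegrityError(f"triangle {bad} is degenerate (area {areas[bad]:g})")
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.faces.ravel(), np.repeat(areas / 3.0, 3))
    return VertexMap(out, kind="statistic")


def vertex_adjacency(mesh: TriangleMesh) -> list[np.ndarray]:
    """Per-vertex sorted neighbour lists: u lists v iff they share a triangle."""
    adj = mesh.adjacency_matrix()
    return [adj.indices[adj.indptr[v] : adj.indptr[v + 1]].copy() for v in range(mesh.n_vertices)]


def largest_component(mesh: TriangleMesh) -> TriangleMesh:
    """Extract the largest connected component as a re-indexed mesh."""
    n, labels = connected_components(mesh.adjacency_matrix(), directed=False)
    if n == 1:
        return mesh
    keep = labels == np.bincount(labels).argmax()
    new_index = -np.ones(mesh.n_vertices, dtype=np.int64)
    new_index[keep] = np.arange(keep.sum())
    face_keep = keep[mesh.faces].all(axis=1)
    return TriangleMesh(mesh.vertices[keep], new_index[mesh.faces[face_keep]])


def region_topology(mesh: TriangleMesh, include: np.ndarray) -> tuple[int, float, float]:
    """Topology of the submesh induced by a boolean vertex mask.

    Returns
    -------
    (chi, boundary_length, area)
        Euler characteristic V - E + F of the induced submesh, total length
        (mm) of its boundary edges (edges belonging to exactly one included
        triangle), and its surface area (mm^2, triangles fully included).
    """
    include = np.asarray(include, dtype=bool)
    face_in = include[mesh.faces].all(axis=1)
    faces = mesh.faces[face_in]
    n_v = int(include.sum())
    edges = mesh.edges()
    edge_in = include[edges].all(axis=1)
    n_e = int(edge_in.sum())
    n_f = int(face_in.sum())
    chi = n_v - n_e + n_f
    area = float(mesh.triangle_areas()[face_in].sum())
    # boundary edges: included edges used by exactly one included triangle
    if n_f:
        pairs = np.sort(
            np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]]), axis=1
        )
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        b = uniq[counts == 1]
        boundary = float(
            np.linalg.norm(mesh.vertices[b[:, 0]] - mesh.vertices[b[:, 1]], axis=1).sum()
        )
    else:
        boundary = 0.0
    return chi, boundary, area


# ---------------------------------------------------------------------- I/O
def _format_from_path(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".obj":
        return "obj-ascii"
    if ext == ".gii":
        return "gifti"
    raise FormatError(f"cannot infer mesh format from extension {ext!r}")


def load_mesh(path, fmt: str | None = None, keep_largest: bool = False) -> TriangleMesh:
    """Read a mesh from disk and validate it.

    Parameters
    ----------
    path : str or Path
    fmt : {"obj-ascii", "gifti"}, optional
        Inferred from the extension (.obj / .gii) when omitted.
    keep_largest : bool
        If the edge graph has several components, analyse the largest
        instead of raising.
    """
    path = os.fspath(path)
    fmt = fmt or _format_from_path(path)
    if fmt == "obj-ascii":
        mesh = _load_obj(path)
    elif fmt == "gifti":
        mesh = _load_gifti_mesh(path)
    else:
        raise FormatError(f"unknown mesh format {fmt!r}")
    try:
        mesh.validate(require_connected=True)
    except IntegrityError:
        if keep_largest and mesh.n_components() > 1:
            mesh = largest_component(mesh)
            mesh.validate(require_connected=True)
        else:
            raise
    return mesh


def save_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    path = os.fspath(path)
    fmt = fmt or _format_from_path(path)
    if fmt == "obj-ascii":
        _save_obj(mesh, path)
    elif fmt == "gifti":
        _save_gifti_mesh(mesh, path)
    else:
        raise FormatError(f"unknown mesh format {fmt!r}")


def _load_obj(path) -> TriangleMesh:
    verts: list[tuple[float, float, float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "v":
                if len(parts) != 4:
                    raise FormatError(f"{path}:{lineno}: malformed vertex record {line!r}")
                try:
                    verts.append((float(parts[1]), float(parts[2]), float(parts[3])))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad coordinate in {line!r}") from exc
            elif parts[0] == "f":
                if len(parts) != 4:
                    raise FormatError(f"{path}:{lineno}: malformed face record {line!r}")
                try:
                    faces.append((int(parts[1]), int(parts[2]), int(parts[3])))
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad index in {line!r}") from exc
            else:
                raise FormatError(f"{path}:{lineno}: unknown record type {parts[0]!r}")
    if not verts:
        raise FormatError(f"{path}: no vertex records found")
    return TriangleMesh(np.array(verts), np.array(faces, dtype=np.int64).reshape(-1, 3))


def _save_obj(mesh: TriangleMesh, path) -> None:
    # repr() of a Python float is the shortest round-tripping decimal, which
    # makes write -> read -> write bit-stable.
    with open(path, "w") as fh:
        fh.write("# deviate triangle mesh; 0-based f records\n")
        for x, y, z in mesh.vertices:
            fh.write(f"v {float(x)!r} {float(y)!r} {float(z)!r}\n")
        for a, b, c in mesh.faces:
            fh.write(f"f {a} {b} {c}\n")


def _load_gifti_mesh(path) -> TriangleMesh:
    import nibabel as nib

    img = nib.load(path)
    pts = tris = None
    for da in img.darrays:
        intent = nib.nifti1.intent_codes.label[da.intent]
        if intent == "pointset":
            pts = da.data
        elif intent == "triangle":
            tris = da.data
    if pts is None or tris is None:
        raise FormatError(f"{path}: GIFTI file lacks pointset/triangle arrays")
    return TriangleMesh(np.asarray(pts, dtype=np.float64), np.asarray(tris, dtype=np.int64))


def _save_gifti_mesh(mesh: TriangleMesh, path) -> None:
    import nibabel as nib
    from nibabel.gifti import GiftiDataArray, GiftiImage

    img = GiftiImage(
        darrays=[
            GiftiDataArray(mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"),
            GiftiDataArray(mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"),
        ]
    )
    nib.save(img, os.fspath(path))


def load_map(path, fmt: str | None = None) -> VertexMap:
    """Read a per-vertex scalar map (ASCII ``.txt``/``.map`` or GIFTI ``.gii``)."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    fmt = fmt or ("gifti" if ext == ".gii" else "ascii")
    if fmt == "gifti":
        import nibabel as nib

        img = nib.load(path)
        kind = dict(img.meta).get("kind", "statistic")
        return VertexMap(np.asarray(img.darrays[0].data, dtype=np.float64), kind=kind)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# kind:"):
            raise FormatError(f"{path}:1: expected '# kind: <tag>' header, got {header!r}")
        kind = header.split(":", 1)[1].strip()
        try:
            values = np.array([float(line) for line in fh if line.strip()])
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric map value") from exc
    return VertexMap(values, kind=kind)


def save_map(vmap: VertexMap, path, fmt: str | None = None) -> None:
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    fmt = fmt or ("gifti" if ext == ".gii" else "ascii")
    if fmt == "gifti":
        import nibabel as nib
        from nibabel.gifti import GiftiDataArray, GiftiImage, GiftiMetaData

        img = GiftiImage(
            meta=GiftiMetaData(kind=vmap.kind),
            darrays=[GiftiDataArray(vmap.values.astype(np.float32), intent="NIFTI_INTENT_NONE")],
        )
        nib.save(img, path)
        return
    with open(path, "w") as fh:
        fh.write(f"# kind: {vmap.kind}\n")
        for v in vmap.values:
            fh.write(f"{float(v)!r}\n")
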