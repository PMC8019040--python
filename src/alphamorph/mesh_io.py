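"""Reading, validating and writing closed triangulated surface meshes.

A :class:`SurfaceMesh` is the anchor of the whole pipeline: the alpha-shape
refinement search is calibrated against the *exact* enclosed volume of the
input surface, so meshes that are not watertight are rejected rather than
repaired (silent hole-filling would bias the complexity score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import MeshFormatError, MeshValidationError

__all__ = [
    "SurfaceMesh",
    "read_mesh",
    "write_mesh",
    "mesh_volume",
    "validate_mesh",
    "write_heatmap_mesh",
    "read_heatmap_sidecar",
]


@dataclass
class SurfaceMesh:
    """A closed, consistently wound triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates in ``units``.
    faces : (m, 3) int array
        Triangles as ordered vertex-index triples, wound so the signed
        volume is positive (outward normals).
    units : str
        Opaque length-unit tag carried through for provenance; all
        downstream complexity quantities are dimensionless.
    name : str, optional
        Specimen identifier used in outputs.
    """

    vertices: np.ndarray
    faces: np.ndarray
    units: str = "mm"
    name: str | None = None
    _validated: bool = field(default=False, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Sum of signed tetrahedron volumes (origin, v1, v2, v3) over faces."""
    a = vertices[faces[:, 0]]
    b = vertices[faces[:, 1]]
    c = vertices[faces[:, 2]]
    return float(np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0)


def _edge_codes(faces: np.ndarray, n_vertices: int) -> tuple[np.ndarray, np.ndarray]:
    """Directed and undirected integer codes for the 3 edges of every face."""
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    directed = e[:, 0].astype(np.int64) * n_vertices + e[:, 1]
    lo = np.minimum(e[:, 0], e[:, 1]).astype(np.int64)
    hi = np.maximum(e[:, 0], e[:, 1]).astype(np.int64)
    undirected = lo * n_vertices + hi
    return directed, undirected


def validate_mesh(
    vertices: np.ndarray,
    faces: np.ndarray,
    units: str = "mm",
    name: str | None = None,
) -> SurfaceMesh:
    """Validate structure and return an orientation-normalized SurfaceMesh.

    Checks, in order: index validity, absence of degenerate (zero-area)
    faces, watertightness (every undirected edge shared by exactly two
    faces), consistent winding (every directed edge used exactly once).
    If the signed volume is negative all faces are flipped, so the result
    always encloses a non-negative volume.

    Raises
    ------
    MeshValidationError
        Naming the offending faces or (for open meshes) boundary edges.
    """
    vertices = np.ascontiguousarray(vertices, dtype=np.float64)
    faces = np.ascontiguousarray(faces, dtype=np.int64)
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise MeshValidationError(f"vertices must be (n, 3), got {vertices.shape}")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshValidationError(f"faces must be (m, 3), got {faces.shape}")
    n = vertices.shape[0]
    if faces.size and (faces.min() < 0 or faces.max() >= n):
        raise MeshValidationError("face indices out of range")
    if faces.shape[0] < 4:
        raise MeshValidationError("a closed surface needs at least 4 faces")

    # degenerate faces: repeated indices or (numerically) zero area
    same = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area2 = np.linalg.norm(cross, axis=1)
    scale = float(np.ptp(vertices, axis=0).max()) or 1.0
    degen = same | (area2 < 1e-14 * scale * scale)
    if degen.any():
        bad = np.flatnonzero(degen)[:10].tolist()
        raise MeshValidationError(f"degenerate (zero-area) faces at indices {bad}")

    directed, undirected = _edge_codes(faces, n)
    uniq, counts = np.unique(undirected, return_counts=True)
    if (counts != 2).any():
        bad_codes = uniq[counts != 2][:20]
        edges = [(int(c // n), int(c % n)) for c in bad_codes]
        raise MeshValidationError(
            f"mesh is not watertight: {int((counts != 2).sum())} boundary/"
            f"non-manifold edges, e.g. {edges[:8]}"
        )
    if np.unique(directed).size != directed.size:
        raise MeshValidationError(
            "inconsistent winding: some directed edge is used more than once"
        )

    if _signed_volume(vertices, faces) < 0.0:
        faces = faces[:, ::-1].copy()
    return SurfaceMesh(vertices, faces, units=units, name=name, _validated=True)


def read_mesh(path: str | Path, format: str = "auto", units: str = "mm") -> SurfaceMesh:
    """Read a PLY/OBJ/STL surface mesh and validate it.

    Parameters
    ----------
    path : path to the mesh file.
    format : "ply", "obj", "stl" or "auto" (infer from the extension).

    Raises
    ------
    MeshFormatError if the file cannot be parsed, MeshValidationError if
    the surface is open or inconsistently wound.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    file_type = None if format == "auto" else format
    try:
        m = trimesh.load(str(path), file_type=file_type, force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise MeshFormatError(f"could not read {path}: {exc}") from exc
    if not isinstance(m, trimesh.Trimesh) or len(m.faces) == 0:
        raise MeshFormatError(f"{path} did not contain a triangulated surface")
    # collapse duplicated vertices emitted by some exporters (STL is
    # vertex-soup by definition) without touching geometry
    m.merge_vertices()
    return validate_mesh(np.asarray(m.vertices), np.asarray(m.faces), units=units, name=path.stem)


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> Path:
    """Write a mesh to PLY/OBJ/STL (format from the extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.to_trimesh().export(str(path))
    return path


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Exact enclosed volume by the divergence theorem.

    Invariant to rigid motion; requires a watertight, consistently wound
    surface (validated meshes satisfy this by construction).
    """
    if not mesh._validated:
        mesh = validate_mesh(mesh.vertices, mesh.faces, mesh.units, mesh.name)
    return abs(_signed_volume(mesh.vertices, mesh.faces))


# ---------------------------------------------------------------------------
# heatmap export
# ---------------------------------------------------------------------------


def _heatmap_colors(vertex_k: np.ndarray, k_min: float, k_max: float) -> np.ndarray:
    """RGBA colors: warm at low k (fine-scale complexity), cool at high k.

    Applied to log10(k) because the refinement grid is logarithmic. The
    red-to-blue ramp is built so warmth (R - B) decreases strictly
    monotonically in k — off-the-shelf diverging maps darken at their
    extremes and break that. Points never seen on any boundary (NaN
    sentinel) render mid-gray.
    """
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "warm_cool", [(0.85, 0.10, 0.10), (0.93, 0.93, 0.82), (0.10, 0.20, 0.85)]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (np.log10(vertex_k) - np.log10(k_min)) / (np.log10(k_max) - np.log10(k_min))
    rgba = np.empty((len(vertex_k), 4), dtype=np.uint8)
    ok = np.isfinite(t)
    rgba[ok] = (np.asarray(cmap(np.clip(t[ok], 0.0, 1.0))) * 255).astype(np.uint8)
    rgba[~ok] = (128, 128, 128, 255)
    return rgba


def write_heatmap_mesh(hm, path: str | Path) -> tuple[Path, Path]:
    """Write a complexity heatmap as colored PLY plus a scalar sidecar CSV.

    The PLY carries per-vertex RGB from the warm-low-k / cool-high-k
    colormap; the sidecar (``<stem>_k.csv``) stores the raw per-vertex and
    per-face refinement coefficients with full precision so a re-read is
    bit-exact.
    """
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    base = hm.base
    rgba = _heatmap_colors(hm.vertex_k, hm.k_min, hm.k_max)
    tm = trimesh.Trimesh(base.vertices.copy(), base.faces.copy(), process=False)
    tm.visual.vertex_colors = rgba
    tm.export(str(path), encoding="ascii" if path.suffix == ".ply" else None)

    sidecar = path.with_name(path.stem + "_k.csv")
    rows = pd.DataFrame(
        {
            "kind": ["vertex"] * len(hm.vertex_k) + ["face"] * len(hm.face_k),
            "index": np.r_[np.arange(len(hm.vertex_k)), np.arange(len(hm.face_k))],
            "k": np.r_[hm.vertex_k, hm.face_k],
        }
    )
    # %.17g + round_trip parsing makes the scalar sidecar bit-exact
    rows.to_csv(sidecar, index=False, float_format="%.17g")
    return path, sidecar


def read_heatmap_sidecar(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back (vertex_k, face_k) written by :func:`write_heatmap_mesh`."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    vertex_k = df.loc[df["kind"] == "vertex", "k"].to_numpy()
    face_k = df.loc[df["kind"] == "face", "k"].to_numpy()
    return vertex_k, face_k
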