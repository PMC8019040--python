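"""Per-vertex complexity heatmaps on the optimal-refinement alpha shape.

Every cloud point is assigned the *coarsest* (largest) grid refinement
coefficient at which it still sits on the boundary of the alpha-shape fit:
convex-hull vertices persist to k_max, while points deep inside folds are
exposed only by tight fits and carry small values. Restricted to the
boundary of the optimal fit, these values localize which anatomical
regions drive a specimen's overall complexity score: low-k (warm) regions
are the complex ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alpha_engine import AlphaEngine, AlphaShapeFit, _engine, grid_alphas
from .errors import StateError
from .mesh_io import SurfaceMesh
from .point_cloud import InteriorPointCloud

__all__ = ["HeatmapMesh", "coarsest_contribution", "build_heatmap"]


@dataclass
class HeatmapMesh:
    """Boundary mesh of the optimal fit with per-vertex/per-face k values.

    ``vertex_k`` entries are members of the refinement grid; NaN marks
    points that never appeared on any grid fit's boundary. ``face_k`` is
    the mean of a face's non-NaN vertex values.
    """

    base: SurfaceMesh
    vertex_k: np.ndarray
    face_k: np.ndarray
    k_min: float
    k_max: float


def coarsest_contribution(
    cloud: InteriorPointCloud,
    k_grid: np.ndarray,
    boundary_flags: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Per-point coarsest contributing refinement coefficient.

    For each cloud point, the maximum grid k at which the point is a
    vertex of at least one boundary facet of the alpha shape at that k.
    Boundary membership is not monotone in k, so the grid is scanned from
    the coarsest end down and each point keeps the first (largest) k seen.
    Points never on any boundary receive NaN.

    ``boundary_flags`` may supply precomputed per-k boolean boundary
    membership arrays (aligned with ``k_grid``); otherwise they are
    computed from the cloud's cached alpha engine.
    """
    k_grid = np.asarray(k_grid, dtype=np.float64)
    if k_grid.size == 0:
        raise StateError("empty refinement grid")
    if cloud.l_ref is None and boundary_flags is None:
        raise StateError("cloud has no l_ref; compute reference_length first")
    n = cloud.n_points
    coarsest = np.full(n, np.nan)
    eng: AlphaEngine | None = None if boundary_flags is not None else _engine(cloud)
    alphas = grid_alphas(k_grid, cloud.l_ref) if boundary_flags is None else None
    any_fit = False
    for j in range(len(k_grid) - 1, -1, -1):
        if boundary_flags is not None:
            flags = boundary_flags[j]
        else:
            flags = eng.boundary_vertex_flags(alphas[j])
        if flags.any():
            any_fit = True
        newly = flags & np.isnan(coarsest)
        coarsest[newly] = k_grid[j]
    if not any_fit:
        raise StateError("no alpha fit in the grid has a non-empty boundary")
    return coarsest


def build_heatmap(
    opt_fit: AlphaShapeFit,
    coarsest: np.ndarray,
    cloud: InteriorPointCloud,
    k_grid: np.ndarray,
) -> HeatmapMesh:
    """Restrict coarsest-k values to the optimal fit's boundary mesh.

    Faces average their vertices' values; NaN (never-boundary) vertices
    are excluded from the mean and an all-NaN face inherits the mean of
    its edge-neighbors (iteratively, then the global mean as a last
    resort).
    """
    facets = opt_fit.boundary_facets
    if facets.shape[0] == 0:
        raise StateError("optimal fit has an empty boundary")
    used = np.unique(facets)
    vertex_k_full = np.asarray(coarsest, dtype=np.float64)
    if not np.isfinite(vertex_k_full[used]).any():
        raise StateError("no boundary vertex carries a coarsest-k value")
    remap = np.full(cloud.n_points, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    base = SurfaceMesh(
        vertices=cloud.points[used].copy(),
        faces=remap[facets],
        units="",
        name=cloud.source_mesh_id,
    )
    vertex_k = vertex_k_full[used]
    with np.errstate(invalid="ignore"):
        face_k = np.nanmean(vertex_k[base.faces], axis=1)
    face_k = _fill_nan_faces(base.faces, face_k)
    return HeatmapMesh(
        base=base,
        vertex_k=vertex_k,
        face_k=face_k,
        k_min=float(np.min(k_grid)),
        k_max=float(np.max(k_grid)),
    )


def _fill_nan_faces(faces: np.ndarray, face_k: np.ndarray) -> np.ndarray:
    """Propagate edge-neighbor means into all-NaN faces."""
    if not np.isnan(face_k).any():
        return face_k
    n_v = faces.max() + 1
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    lo = np.minimum(e[:, 0], e[:, 1]).astype(np.int64)
    hi = np.maximum(e[:, 0], e[:, 1]).astype(np.int64)
    codes = lo * n_v + hi
    face_of_edge = np.tile(np.arange(len(faces)), 3)
    order = np.argsort(codes, kind="stable")
    codes_s, faces_s = codes[order], face_of_edge[order]
    # manifold boundary: each edge appears exactly twice -> pair adjacency
    pair_start = np.flatnonzero(np.r_[True, codes_s[1:] != codes_s[:-1]])
    adj_a, adj_b = [], []
    for s in pair_start:
        group = faces_s[s : s + 2] if s + 1 < len(codes_s) and codes_s[s] == codes_s[s + 1] else None
        if group is not None and len(group) == 2:
            adj_a.append(group[0])
            adj_b.append(group[1])
    adj_a = np.asarray(adj_a, dtype=np.int64)
    adj_b = np.asarray(adj_b, dtype=np.int64)
    out = face_k.copy()
    for _ in range(32):
        nan = np.isnan(out)
        if not nan.any():
            break
        sums = np.zeros(len(out))
        cnts = np.zeros(len(out))
        ok_b = ~np.isnan(out[adj_b])
        np.add.at(sums, adj_a[ok_b], out[adj_b[ok_b]])
        np.add.at(cnts, adj_a[ok_b], 1.0)
        ok_a = ~np.isnan(out[adj_a])
        np.add.at(sums, adj_b[ok_a], out[adj_a[ok_a]])
        np.add.at(cnts, adj_b[ok_a], 1.0)
        fill = nan & (cnts > 0)
        if not fill.any():
            break
        out[fill] = sums[fill] / cnts[fill]
    still = np.isnan(out)
    if still.any():
        out[still] = np.nanmean(out) if np.isfinite(np.nanmean(out)) else 0.0
    return out
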