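"""Interior point clouds: rejection filling, down-sampling and l_ref.

The complexity metric is made scale-free by expressing the alpha radius in
units of a cloud-specific reference length l_ref: the mean distance from
each point of the down-sampled cloud to its 100 nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._raycast import ZRayCaster
from .errors import GeometryError, SizeError
from .mesh_io import SurfaceMesh, mesh_volume

__all__ = [
    "InteriorPointCloud",
    "in_polyhedron",
    "fill_interior",
    "downsample",
    "reference_length",
]

DEFAULT_FILL_MIN = 250_000
DEFAULT_DOWNSAMPLE = 100_000
DEFAULT_NEIGHBORS = 100


@dataclass
class InteriorPointCloud:
    """Random points strictly inside a source mesh, with seed provenance."""

    points: np.ndarray
    source_mesh_id: str | None = None
    seed: int | None = None
    n_raw: int | None = None
    n_down: int | None = None
    l_ref: float | None = None
    _engine: object = field(default=None, repr=False, compare=False)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


def in_polyhedron(mesh: SurfaceMesh, points, seed: int | None = None):
    """Containment test: odd number of +z ray crossings means inside.

    Accepts a single (3,) point (returns bool) or an (n, 3) array
    (returns a boolean array). Degenerate ray/edge grazings are re-cast
    from a jittered position.
    """
    caster = ZRayCaster(mesh.vertices, mesh.faces)
    pts = np.asarray(points, dtype=np.float64)
    single = pts.ndim == 1
    rng = np.random.default_rng(seed if seed is not None else 0x5EED)
    res = caster.contains(np.atleast_2d(pts), rng=rng)
    return bool(res[0]) if single else res


def fill_interior(
    mesh: SurfaceMesh,
    n_min: int = DEFAULT_FILL_MIN,
    seed: int = 0,
) -> InteriorPointCloud:
    """Fill a watertight mesh with >= n_min uniform interior points.

    Uniform candidates are drawn in the axis-aligned bounding box and kept
    iff they pass the ray-parity containment test, so accepted points are
    exactly uniform in the enclosed volume. Deterministic given ``seed``.

    Raises
    ------
    GeometryError
        If the acceptance rate falls below 1e-4 (pathologically thin mesh).
    """
    if n_min < 1:
        raise SizeError("n_min must be positive")
    vol = mesh_volume(mesh)
    if vol <= 0:
        raise GeometryError("mesh encloses no volume")
    lo, hi = mesh.bounds
    box = float(np.prod(hi - lo))
    rate_est = max(vol / box, 1e-6)
    caster = ZRayCaster(mesh.vertices, mesh.faces)
    rng = np.random.default_rng(seed)

    accepted: list[np.ndarray] = []
    n_acc = 0
    n_prop = 0
    while n_acc < n_min:
        need = n_min - n_acc
        batch = min(int(need / rate_est * 1.15) + 256, 2_000_000)
        u = rng.random((batch, 3))
        pts = lo + u * (hi - lo)
        keep = caster.contains(pts, rng=rng)
        n_prop += batch
        got = pts[keep]
        if len(got):
            accepted.append(got)
            n_acc += len(got)
        if n_prop >= max(1_000_000, 20 * n_min) and n_acc / n_prop < 1e-4:
            raise GeometryError(
                f"interior fill aborted: acceptance rate {n_acc / n_prop:.2e} "
                f"after {n_prop} proposals (thin or degenerate mesh?)"
            )
        rate_est = max(n_acc / n_prop, 1e-6)
    points = np.concatenate(accepted)
    return InteriorPointCloud(
        points=points,
        source_mesh_id=mesh.name,
        seed=seed,
        n_raw=len(points),
    )


def downsample(
    cloud: InteriorPointCloud,
    n_target: int = DEFAULT_DOWNSAMPLE,
    seed: int = 0,
) -> InteriorPointCloud:
    """Uniform random subset without replacement of size ``n_target``."""
    n = cloud.n_points
    if n_target < 1:
        raise SizeError("n_target must be positive")
    if n_target > n:
        raise SizeError(f"cannot down-sample {n} points to {n_target}")
    if n_target == n:
        pts = cloud.points.copy()
    else:
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=n_target, replace=False)
        idx.sort()
        pts = cloud.points[idx]
    return InteriorPointCloud(
        points=pts,
        source_mesh_id=cloud.source_mesh_id,
        seed=cloud.seed,
        n_raw=cloud.n_raw,
        n_down=n_target,
    )


def reference_length(
    cloud: InteriorPointCloud,
    n_neighbors: int = DEFAULT_NEIGHBORS,
) -> float:
    """Mean distance of every point to its ``n_neighbors`` nearest neighbors.

    Computed per point (excluding the point itself) and averaged over the
    cloud; with a fixed neighbor count this mean-of-means equals the pooled
    mean. The result is cached on the cloud as ``l_ref``.
    """
    n = cloud.n_points
    if n <= n_neighbors:
        raise SizeError(f"need more than {n_neighbors} points, have {n}")
    tree = cKDTree(cloud.points)
    dist, _ = tree.query(cloud.points, k=n_neighbors + 1, workers=-1)
    l_ref = float(dist[:, 1:].mean())
    cloud.l_ref = l_ref
    return l_ref
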