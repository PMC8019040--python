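"""Alpha-shape families, characteristic curves and the alpha-complexity score.

The alpha shape at radius alpha is the union of Delaunay tetrahedra whose
circumradius is at most alpha (circumradius-filtered alpha complex). As
alpha grows the kept set only grows, so the alpha-shape volume is exactly
non-decreasing and reaches the convex hull in the limit. The refinement
coefficient k expresses alpha in units of the cloud reference length,
alpha = k * l_ref, making the whole analysis dimensionless.

The complexity score of a specimen is 1 / k_opt, where k_opt is the
refinement at which the alpha-shape volume equals the enclosed volume of
the source surface mesh: complex, deeply invaginated shapes need a tight
(small-k) fit to shed the false volume a coarse fit spans across their
concavities, so they score high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay

from .errors import DomainError, GeometryError, StateError
from .mesh_io import SurfaceMesh, mesh_volume
from .point_cloud import InteriorPointCloud, reference_length

__all__ = [
    "AlphaShapeFit",
    "CharacteristicCurve",
    "ComplexityResult",
    "AlphaEngine",
    "alpha_radius",
    "fit_alpha_shape",
    "characteristic_curve",
    "optimal_refinement",
    "default_k_grid",
    "grid_alphas",
]

K_MIN = 0.1
K_MAX = 10_000.0
K_STEPS = 200


def grid_alphas(k_grid: np.ndarray, l_ref: float) -> np.ndarray:
    """Alpha radii for a refinement grid, with the coarsest endpoint mapped
    to infinity.

    The alpha-shape family is defined to span highly refined fits all the
    way to the convex hull, so its coarsest member IS the hull. Boundary
    tetrahedra with near-cocircular vertices can carry circumradii far
    above k_max * l_ref while holding real volume, so a finite cutoff at
    the top of the grid would undershoot the hull; pinning the endpoint at
    infinity makes the coarse limit exact.
    """
    alphas = np.asarray(k_grid, dtype=np.float64) * l_ref
    alphas[-1] = np.inf
    return alphas


def default_k_grid(k_min: float = K_MIN, k_max: float = K_MAX, n: int = K_STEPS) -> np.ndarray:
    """The standard refinement grid: n values log-spaced on [k_min, k_max]."""
    if not (0 < k_min < k_max) or n < 2:
        raise DomainError("need 0 < k_min < k_max and at least 2 grid points")
    return np.logspace(np.log10(k_min), np.log10(k_max), n)


def alpha_radius(k: float, l_ref: float) -> float:
    """Alpha radius for refinement coefficient k: alpha = k * l_ref."""
    if k <= 0 or l_ref <= 0:
        raise DomainError("k and l_ref must be positive")
    return k * l_ref


@dataclass
class AlphaShapeFit:
    """A single alpha shape: kept tetrahedra, boundary and volume."""

    alpha: float
    k: float | None
    kept_tetrahedra: np.ndarray  # indices into the Delaunay simplices
    boundary_facets: np.ndarray  # (b, 3) point-index triples
    volume: float
    volume_fraction: float | None = None  # percent of source-mesh volume

    @property
    def boundary_vertices(self) -> np.ndarray:
        return np.unique(self.boundary_facets)


@dataclass
class CharacteristicCurve:
    """Alpha-shape volume (% of mesh volume) as a function of k."""

    k_grid: np.ndarray
    volume_fractions: np.ndarray
    l_ref: float
    mesh_volume: float
    specimen_id: str | None = None

    def __post_init__(self):
        if len(self.k_grid) != len(self.volume_fractions):
            raise DomainError("k_grid and volume_fractions must align")
        if not np.all(np.diff(self.k_grid) > 0):
            raise DomainError("k_grid must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"k": self.k_grid, "volume_fraction": self.volume_fractions})


@dataclass
class ComplexityResult:
    """Optimal refinement and the alpha-complexity score 1/k_opt."""

    optimal_k: float
    alpha_complexity: float
    in_range: bool
    diagnostics: dict = field(default_factory=dict)


class AlphaEngine:
    """Per-cloud cache: one Delaunay, circumradii and tet volumes, reused
    across every alpha query (a fit is then a single threshold pass)."""

    def __init__(self, cloud: InteriorPointCloud):
        pts = np.asarray(cloud.points, dtype=np.float64)
        if len(pts) < 4:
            raise GeometryError("need at least 4 points")
        try:
            self.delaunay = Delaunay(pts)
        except Exception as exc:  # qhull failure on degenerate input
            raise GeometryError(f"Delaunay triangulation failed: {exc}") from exc
        if self.delaunay.simplices.shape[0] == 0:
            raise GeometryError("degenerate (coplanar) point cloud")
        self.points = pts
        self.simplices = self.delaunay.simplices.astype(np.int64)
        self.radii, self.volumes = _circumradii_and_volumes(pts, self.simplices)
        if not np.any(np.isfinite(self.radii)):
            raise GeometryError("degenerate (coplanar) point cloud")
        order = np.argsort(self.radii)
        self._order = order
        self._r_sorted = self.radii[order]
        self._cumvol = np.cumsum(self.volumes[order])

    # -- volume-only queries (used by curves and bisection) ----------------
    def volume_at(self, alpha) -> np.ndarray | float:
        """Alpha-shape volume at one or many alpha radii (inclusive cutoff;
        alpha = inf keeps every non-degenerate tetrahedron = convex hull)."""
        a = np.asarray(alpha, dtype=np.float64)
        idx = np.searchsorted(self._r_sorted, a, side="right")
        vol = np.where(idx > 0, self._cumvol[np.maximum(idx - 1, 0)], 0.0)
        return float(vol) if np.isscalar(alpha) else vol

    # -- full fit with boundary extraction ---------------------------------
    def fit(self, alpha: float, k: float | None = None) -> AlphaShapeFit:
        keep = np.flatnonzero((self.radii <= alpha) & np.isfinite(self.radii))
        if keep.size == 0:
            return AlphaShapeFit(alpha, k, keep, np.empty((0, 3), np.int64), 0.0)
        codes = _face_codes(self.simplices[keep], len(self.points))
        uniq, counts = np.unique(codes, return_counts=True)
        boundary = _decode_faces(uniq[counts == 1], len(self.points))
        return AlphaShapeFit(
            alpha=alpha,
            k=k,
            kept_tetrahedra=keep,
            boundary_facets=boundary,
            volume=float(self.volumes[keep].sum()),
        )

    def boundary_vertex_flags(self, alpha: float) -> np.ndarray:
        """Boolean flag per cloud point: on the boundary of the fit at alpha."""
        flags = np.zeros(len(self.points), dtype=bool)
        keep = (self.radii <= alpha) & np.isfinite(self.radii)
        if not keep.any():
            return flags
        codes = _face_codes(self.simplices[keep], len(self.points))
        uniq, counts = np.unique(codes, return_counts=True)
        verts = _decode_faces(uniq[counts == 1], len(self.points)).ravel()
        flags[np.unique(verts)] = True
        return flags


def _circumradii_and_volumes(points: np.ndarray, simplices: np.ndarray):
    """Circumradius and volume of every tetrahedron, vectorized.

    The circumcenter c satisfies (v_i - a) . (c - a) = |v_i - a|^2 / 2 for
    the three edges from vertex a; near-flat tetrahedra (tiny determinant)
    get an infinite radius so they are never kept — their volume is
    numerically negligible by the same token.
    """
    a = points[simplices[:, 0]]
    m = np.stack(
        [points[simplices[:, i]] - a for i in (1, 2, 3)], axis=1
    )  # (n, 3, 3) rows are edge vectors
    det = np.linalg.det(m)
    volumes = np.abs(det) / 6.0
    edge = np.abs(m).max(axis=(1, 2))
    degenerate = np.abs(det) < 1e-14 * np.maximum(edge, 1e-300) ** 3
    rhs = 0.5 * np.einsum("nij,nij->ni", m, m)
    radii = np.full(len(simplices), np.inf)
    good = ~degenerate
    if good.any():
        sol = np.linalg.solve(m[good], rhs[good][..., None])[..., 0]
        r = np.linalg.norm(sol, axis=1)
        r[~np.isfinite(r)] = np.inf
        radii[good] = r
    volumes[degenerate] = 0.0  # excluded from every fit by construction
    return radii, volumes


def _face_codes(simplices: np.ndarray, n_points: int) -> np.ndarray:
    """Encode the 4 faces of each tetrahedron as sorted int64 triples."""
    faces = simplices[:, [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]].reshape(-1, 3)
    faces = np.sort(faces, axis=1)
    return (faces[:, 0] * n_points + faces[:, 1]) * n_points + faces[:, 2]


def _decode_faces(codes: np.ndarray, n_points: int) -> np.ndarray:
    c = codes[:, None] // np.array([n_points * n_points, n_points, 1], dtype=np.int64)
    return (c % n_points).astype(np.int64)


def _engine(cloud: InteriorPointCloud) -> AlphaEngine:
    if cloud._engine is None:
        cloud._engine = AlphaEngine(cloud)
    return cloud._engine


def fit_alpha_shape(cloud: InteriorPointCloud, alpha: float) -> AlphaShapeFit:
    """Alpha shape of the cloud at radius alpha (Delaunay cached on the cloud)."""
    if alpha <= 0:
        raise DomainError("alpha must be positive")
    return _engine(cloud).fit(float(alpha))


def characteristic_curve(
    cloud: InteriorPointCloud,
    mesh: SurfaceMesh,
    k_grid: np.ndarray | None = None,
) -> CharacteristicCurve:
    """Volume fraction (percent of mesh volume) across the refinement grid.

    A single Delaunay is shared across all grid values. Fractions above
    100% at coarse k are expected for concave shapes (the near-hull fit
    spans their concavities).
    """
    if k_grid is None:
        k_grid = default_k_grid()
    k_grid = np.asarray(k_grid, dtype=np.float64)
    l_ref = cloud.l_ref if cloud.l_ref is not None else reference_length(cloud)
    vol = mesh_volume(mesh)
    eng = _engine(cloud)
    fractions = 100.0 * eng.volume_at(grid_alphas(k_grid, l_ref)) / vol
    return CharacteristicCurve(
        k_grid=k_grid,
        volume_fractions=fractions,
        l_ref=l_ref,
        mesh_volume=vol,
        specimen_id=cloud.source_mesh_id,
    )


def optimal_refinement(
    curve: CharacteristicCurve,
    cloud: InteriorPointCloud,
    mesh: SurfaceMesh | None = None,
    tol: float = 1e-3,
) -> ComplexityResult:
    """Solve for the k at which the alpha-shape volume equals the mesh volume.

    The volume fraction is monotone in k, so the smallest grid k reaching
    100% brackets the crossing with its left neighbor and bisection in
    log10(k) refines it (deterministic, derivative-free, cannot stall on
    the flat zero-volume region). Stops when the fraction is within
    ``100 * tol`` of 100% or the bracket is narrower than 1e-3 in log10(k).

    If even the coarsest fit stays below 100*(1 - tol) percent there is no
    crossing inside the grid: the result is flagged out-of-range and
    reported at the k_max boundary (convex bodies typically land here
    because the hull of interior samples slightly undershoots the mesh).
    """
    vol = curve.mesh_volume if mesh is None else mesh_volume(mesh)
    l_ref = curve.l_ref
    eng = _engine(cloud)
    frac = np.asarray(curve.volume_fractions)
    k_grid = np.asarray(curve.k_grid)
    n_eval = 0

    def frac_at(k: float) -> float:
        nonlocal n_eval
        n_eval += 1
        return 100.0 * eng.volume_at(k * l_ref) / vol

    reached = np.flatnonzero(frac >= 100.0)
    if reached.size == 0:
        top = float(frac[-1])
        k_opt = float(k_grid[-1])
        in_range = top >= 100.0 * (1.0 - tol)
        if not in_range:
            warnings.warn(
                f"no 100% crossing within k grid (top fraction {top:.2f}%); "
                "complexity reported at the k_max boundary",
                stacklevel=2,
            )
        return ComplexityResult(
            optimal_k=k_opt,
            alpha_complexity=1.0 / k_opt,
            in_range=in_range,
            diagnostics={"fraction": top, "n_eval": n_eval, "bracket": None},
        )
    i = int(reached[0])
    if i == 0:
        warnings.warn("volume already exceeds the mesh at k_min", stacklevel=2)
        k_opt = float(k_grid[0])
        return ComplexityResult(
            optimal_k=k_opt,
            alpha_complexity=1.0 / k_opt,
            in_range=False,
            diagnostics={"fraction": float(frac[0]), "n_eval": n_eval, "bracket": None},
        )
    lo, hi = np.log10(k_grid[i - 1]), np.log10(k_grid[i])
    f_mid = float(frac[i])
    k_mid = float(k_grid[i])
    while hi - lo > 1e-3:
        mid = 0.5 * (lo + hi)
        k_mid = 10.0**mid
        f_mid = frac_at(k_mid)
        if abs(f_mid - 100.0) <= 100.0 * tol:
            break
        if f_mid >= 100.0:
            hi = mid
        else:
            lo = mid
    else:
        k_mid = 10.0**hi
        f_mid = frac_at(k_mid)
    return ComplexityResult(
        optimal_k=float(k_mid),
        alpha_complexity=1.0 / float(k_mid),
        in_range=True,
        diagnostics={
            "fraction": f_mid,
            "n_eval": n_eval,
            "bracket": (float(10.0**lo), float(10.0**hi)),
        },
    )
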