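"""Independent oracles used by the test suite.

Each oracle recomputes a quantity from first principles along a different
algorithmic route than the implementation: winding numbers instead of ray
parity, exhaustive pairwise distances instead of kd-trees, sphere fitting
by least squares instead of the linear circumcenter solve, per-column
surface integration instead of the divergence theorem.
"""

from __future__ import annotations

import numpy as np


def winding_number_inside(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Containment via the generalized winding number (sum of signed solid
    angles of every triangle as seen from the query point; ~4*pi inside)."""
    tri = vertices[faces]
    out = np.empty(len(points), dtype=bool)
    for i, p in enumerate(points):
        a = tri[:, 0] - p
        b = tri[:, 1] - p
        c = tri[:, 2] - p
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        lc = np.linalg.norm(c, axis=1)
        num = np.einsum("ij,ij->i", a, np.cross(b, c))
        den = (
            la * lb * lc
            + np.einsum("ij,ij->i", a, b) * lc
            + np.einsum("ij,ij->i", b, c) * la
            + np.einsum("ij,ij->i", a, c) * lb
        )
        omega = 2.0 * np.arctan2(num, den)
        out[i] = abs(omega.sum()) > 2.0 * np.pi  # 4*pi inside, 0 outside
    return out


def brute_force_l_ref(points: np.ndarray, n_neighbors: int) -> float:
    """Exhaustive O(n^2) mean distance to the n nearest neighbors."""
    from scipy.spatial.distance import cdist

    d = cdist(points, points)
    d.sort(axis=1)
    return float(d[:, 1 : n_neighbors + 1].mean())


def circumradius_sphere_fit(tet: np.ndarray) -> float:
    """Circumradius of 4 points by least-squares sphere fitting:
    |x - c|^2 = R^2 linearized as 2 x.c - (R^2 - |c|^2) = |x|^2."""
    A = np.c_[2.0 * tet, np.ones(4)]
    b = (tet**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 < 0 or np.linalg.matrix_rank(A, tol=1e-10) < 4:
        return np.inf
    return float(np.sqrt(r2))


def column_parity_volume(vertices: np.ndarray, faces: np.ndarray, n: int = 128) -> float:
    """Volume by exact z-integration over an n x n column grid.

    For each xy grid cell center, all surface crossings along z are found
    by brute force over every triangle (2D edge-function inclusion test),
    and the inside length of the column is summed. Independent of both the
    divergence-theorem volume and the bucketed ray caster.
    """
    tri = vertices[faces]
    lo = vertices.min(axis=0)
    hi = vertices.max(axis=0)
    xs = lo[0] + (np.arange(n) + 0.5) / n * (hi[0] - lo[0])
    ys = lo[1] + (np.arange(n) + 0.5) / n * (hi[1] - lo[1])
    cell_area = (hi[0] - lo[0]) * (hi[1] - lo[1]) / (n * n)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    P = np.column_stack([X.ravel(), Y.ravel()])  # (q, 2)

    a = tri[:, 0, :2]
    v0 = tri[:, 1, :2] - a
    v1 = tri[:, 2, :2] - a
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    ok = np.abs(det) > 1e-14
    a, v0, v1, det = a[ok], v0[ok], v1[ok], det[ok]
    az = tri[ok, 0, 2]
    bz = tri[ok, 1, 2] - az
    cz = tri[ok, 2, 2] - az

    total = 0.0
    chunk = 2048
    for s in range(0, len(P), chunk):
        p = P[s : s + chunk]
        w = p[:, None, :] - a[None, :, :]
        ss = (w[:, :, 0] * v1[:, 1] - w[:, :, 1] * v1[:, 0]) / det
        tt = (v0[:, 0] * w[:, :, 1] - v0[:, 1] * w[:, :, 0]) / det
        inside = (ss >= 0) & (tt >= 0) & (ss + tt <= 1)
        z = az[None, :] + ss * bz[None, :] + tt * cz[None, :]
        z = np.where(inside, z, np.nan)
        z.sort(axis=1)
        for row in z:
            zz = row[~np.isnan(row)]
            if len(zz) >= 2:
                # pair consecutive crossings (entry/exit)
                total += (zz[1::2][: len(zz) // 2] - zz[0::2][: len(zz) // 2]).sum()
    return float(total * cell_area)


def rerooted_ancestral_state(tree, node, trait) -> float:
    """GLS mean of the tree re-rooted at ``node`` (re-rooting route to the
    ML Brownian ancestral state)."""
    import dendropy

    from alphamorph.phylo_comparative import Phylogeny

    t = tree.clone(depth=1)
    # find the matching node by its descendant leaf set
    target = frozenset(lf.taxon.label for lf in node.leaf_iter())
    match = None
    for nd in t.preorder_node_iter():
        if frozenset(lf.taxon.label for lf in nd.leaf_iter()) == target:
            match = nd
            break
    if match.parent_node is not None:
        t.reroot_at_node(match, update_bipartitions=False)
    phy = Phylogeny(t)
    labels, C = phy.covariance()
    x = np.asarray([trait[lab] for lab in labels])
    Cinv = np.linalg.inv(C + 1e-12 * np.eye(len(C)))
    one = np.ones(len(x))
    return float(one @ Cinv @ x / (one @ Cinv @ one))
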