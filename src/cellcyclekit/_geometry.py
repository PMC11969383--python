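"""Convex-hull voxel counting and caliper distances on voxel centers.

All geometry in this package uses the "unit cube" convention: a voxel (or
pixel) is represented by its integer center coordinate, the convex hull is
the hull of those centers, and hull area/volume is reported as the number
of lattice points whose centers lie inside the hull. This makes solidity
and convex area/volume exactly reproducible by a brute-force half-space
membership test, which the test suite exploits.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError


def _lattice_candidates(points: np.ndarray) -> np.ndarray:
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grid], axis=1)


def convex_voxel_count(mask: np.ndarray | None = None,
                       points: np.ndarray | None = None) -> int:
    """Number of lattice points inside the convex hull of voxel centers.

    Degenerate inputs (collinear / coplanar point sets) are handled by
    working inside the points' affine span.
    """
    if points is None:
        if mask is None:
            raise ValueError("give either mask or points")
        points = np.argwhere(mask)
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if n == 0:
        return 0
    if n == 1:
        return 1
    mean = pts.mean(axis=0)
    centered = pts - mean
    # affine rank via SVD; degenerate sets are measured within their span
    # (full_matrices=False: only the d x d right singular basis is needed)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > 1e-8).sum())
    cand = _lattice_candidates(points) - mean
    if rank == 0:
        return 1
    if rank < pts.shape[1]:
        off = np.abs(cand @ vt[rank:].T)
        on_span = (off < 1e-6).all(axis=1)
        cand = cand[on_span]
    proj_pts = centered @ vt[:rank].T
    proj_cand = cand @ vt[:rank].T
    if rank == 1:
        lo, hi = proj_pts.min(), proj_pts.max()
        return int(((proj_cand[:, 0] >= lo - 1e-9) & (proj_cand[:, 0] <= hi + 1e-9)).sum())
    # triangulate only the hull vertices: a filled voxel lattice is a
    # pathologically degenerate input for a full Delaunay triangulation
    try:
        hull = ConvexHull(proj_pts)
        verts = proj_pts[hull.vertices]
        tri = Delaunay(verts)
    except QhullError:
        tri = Delaunay(proj_pts, qhull_options="QJ")
    return int((tri.find_simplex(proj_cand, tol=1e-9) >= 0).sum())


def solidity(mask: np.ndarray) -> float:
    """Object voxels / convex-hull voxels, in (0, 1]."""
    v = int(np.count_nonzero(mask))
    if v == 0:
        raise ValueError("empty mask has no solidity")
    return v / convex_voxel_count(mask=mask)


def feret_max(points: np.ndarray) -> float:
    """Maximum caliper distance between hull-vertex centers (2D or 3D)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        return 0.0
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:  # degenerate (collinear) sets: all points are candidates
        verts = pts
    diff = verts[:, None, :] - verts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).max())


__all__ = ["convex_voxel_count", "solidity", "feret_max"]
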