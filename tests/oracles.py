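"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: AUROC by explicit
pair counting, convex voxel counts by half-space membership against qhull
facet equations, and 90-degree rotation by index permutation.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull


def auroc_paircount(labels, scores) -> float:
    """P(score_pos > score_neg) with ties counted 1/2, by explicit pairs."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes")
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (pos.size * neg.size)


def halfspace_convex_count(mask: np.ndarray) -> int:
    """Lattice points inside the hull of voxel centers, via facet
    inequalities A x + b <= 0 evaluated point by point."""
    pts = np.argwhere(mask).astype(float)
    hull = ConvexHull(pts)
    lo = pts.min(axis=0).astype(int)
    hi = pts.max(axis=0).astype(int)
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, mask.ndim)
    count = 0
    A, b = hull.equations[:, :-1], hull.equations[:, -1]
    for point in grid:
        if np.all(A @ point + b <= 1e-9):
            count += 1
    return count


def rot90_volume(volume: np.ndarray, k: int = 1) -> np.ndarray:
    """Exact 90-degree in-plane rotation of a (Z, Y, X) volume by index
    permutation, oriented to match the package's interpolating rotation."""
    return np.rot90(volume, k=k, axes=(1, 2))
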