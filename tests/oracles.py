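"""Independent brute-force oracles used by the test suite.

Each oracle is a deliberately naive re-derivation of a quantity the package
computes by an optimized route: exhaustive digital-segment closure for the
convex hull, exhaustive empty-circumcircle checking for the Delaunay
triangulation, and a direct O(N^2) discrete Fourier transform for boundary
descriptors.
"""

from __future__ import annotations

import numpy as np
from skimage.draw import line as _line


def canonical_line(p, q):
    """Bresenham segment drawn from the lexicographically smaller endpoint."""
    (px, py), (qx, qy) = p, q
    if (py, px) > (qy, qx):
        (px, py), (qx, qy) = (qx, qy), (px, py)
    return _line(py, px, qy, qx)


def closure_hull(patch: np.ndarray) -> np.ndarray:
    """Exhaustive all-pairs digital-segment closure, iterated to a fixpoint."""
    out = np.asarray(patch, dtype=bool).copy()
    while True:
        ys, xs = np.nonzero(out)
        pts = list(zip(xs.tolist(), ys.tolist()))
        added = False
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                rr, cc = canonical_line(pts[i], pts[j])
                if not out[rr, cc].all():
                    out[rr, cc] = True
                    added = True
        if not added:
            return out


def circumcircle(a, b, c):
    """Center and squared radius of the circle through three points."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    r2 = (ax - ux) ** 2 + (ay - uy) ** 2
    return (ux, uy), r2


def delaunay_violations(points: np.ndarray, simplices: np.ndarray,
                        tol: float = 1e-9) -> int:
    """Count triangles whose circumcircle strictly contains another vertex."""
    points = np.asarray(points, dtype=float)
    bad = 0
    for tri in simplices:
        cc = circumcircle(points[tri[0]], points[tri[1]], points[tri[2]])
        if cc is None:
            bad += 1
            continue
        (ux, uy), r2 = cc
        d2 = (points[:, 0] - ux) ** 2 + (points[:, 1] - uy) ** 2
        inside = d2 < r2 - tol * max(r2, 1.0)
        inside[list(tri)] = False
        if inside.any():
            bad += 1
    return bad


def dft_truncate_reconstruct(boundary: np.ndarray, terms: int) -> np.ndarray:
    """Direct-sum DFT, symmetric truncation, direct-sum inverse."""
    n = len(boundary)
    z = boundary[:, 0].astype(float) + 1j * boundary[:, 1].astype(float)
    ks = np.arange(n)
    fwd = np.array([np.sum(z * np.exp(-2j * np.pi * k * ks / n)) for k in ks])
    signed = np.where(ks <= n // 2, ks, ks - n)
    order = sorted(range(n), key=lambda i: (abs(signed[i]), signed[i] < 0))
    keep = np.zeros(n, dtype=bool)
    keep[order[:terms]] = True
    fwd[~keep] = 0
    inv = np.array([np.sum(fwd * np.exp(2j * np.pi * k * ks / n)) for k in ks]) / n
    return np.column_stack([inv.real, inv.imag])


def random_blob(rng: np.random.Generator, max_pixels: int = 200) -> np.ndarray:
    """Small random connected-ish component for hull/boundary tests."""
    import skimage.morphology as mo

    h, w = rng.integers(8, 24, 2)
    patch = np.zeros((h, w), dtype=bool)
    npts = int(rng.integers(3, 16))
    patch[rng.integers(0, h, npts), rng.integers(0, w, npts)] = True
    if rng.random() < 0.5:
        patch = mo.dilation(patch, mo.disk(1))
    while patch.sum() > max_pixels:
        patch = patch[::2, ::2]
    return patch
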