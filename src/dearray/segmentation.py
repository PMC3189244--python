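"""TMA core segmentation from slide thumbnails.

The stage chain is: contrast enhancement (CLAHE + sharpening with the negative
of a Laplacian kernel), Otsu thresholding and morphological closing; per-object
convex hulling with a speck filter; fragment detection via a quartile
area/distance rule over Delaunay neighbours and fragment joining; boundary
smoothing with a truncated pair of forward/inverse Fourier descriptors; and a
final minimum-area filter.

Masks are plain boolean numpy arrays (True = candidate tissue).  Coordinates
are 0-based, ``x`` rightward / ``y`` downward; bounding boxes are half-open
``(x_min, y_min, width, height)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError
from skimage import exposure, measure, morphology
from skimage.draw import line as _draw_line
from skimage.draw import polygon as _draw_polygon
from skimage.filters import threshold_otsu

__all__ = [
    "SegmentationParams",
    "CoreCandidate",
    "FragmentPair",
    "to_grayscale",
    "enhance_and_threshold",
    "extract_candidates",
    "hull_components",
    "detect_fragments",
    "join_fragments",
    "smooth_boundaries",
    "finalize_candidates",
    "trace_boundary",
    "fourier_smooth_boundary",
    "segment",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds of the segmentation stage."""

    clahe_clip: float = 0.01
    clahe_tiles: int = 8
    laplacian_alpha: float = 0.2
    close_radius: int = 2
    min_speck_area: int = 10
    min_core_area: int = 200
    fourier_terms: int = 8
    fragment_area_k: float = 1.5
    fragment_dist_k: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.clahe_clip <= 1:
            raise ValueError("clahe_clip must be in (0, 1]")
        if self.min_speck_area < 0 or self.min_core_area < 0:
            raise ValueError("area thresholds must be >= 0")
        if self.fourier_terms < 2:
            raise ValueError("fourier_terms must be >= 2")
        if self.fragment_area_k <= 0 or self.fragment_dist_k <= 0:
            raise ValueError("quartile multipliers must be > 0")


@dataclass
class CoreCandidate:
    """One segmented object: a potential TMA core."""

    label: int
    area: int
    centroid: tuple[float, float]  # (x, y)
    bbox: tuple[int, int, int, int]  # (x_min, y_min, width, height)
    boundary: np.ndarray | None = None  # (N, 2) ordered (x, y) pixel sequence


@dataclass(frozen=True)
class FragmentPair:
    """Two candidates flagged as fragments of a single broken core."""

    label_a: int
    label_b: int
    distance: float

    def __post_init__(self) -> None:
        if self.label_a == self.label_b:
            raise ValueError("a fragment pair needs two distinct labels")
        if self.distance <= 0:
            raise ValueError("fragment distance must be > 0")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an image to float grayscale in [0, 1] (Rec. 601 luminance)."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    img = img.astype(float)
    if img.size and img.max() > 1.0:
        img = img / 255.0
    return np.clip(img, 0.0, 1.0)


def _laplacian_kernel(alpha: float) -> np.ndarray:
    """3x3 Laplacian blending 4- and 8-neighbour stencils via ``alpha``."""
    a = alpha
    k = np.array(
        [
            [a / 4, (1 - a) / 4, a / 4],
            [(1 - a) / 4, -1.0, (1 - a) / 4],
            [a / 4, (1 - a) / 4, a / 4],
        ]
    )
    return 4.0 / (a + 1.0) * k


def enhance_and_threshold(
    image: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Enhance a thumbnail and binarize it; dark tissue becomes foreground.

    CLAHE boosts local contrast, subtracting the Laplacian response sharpens
    core rims, Otsu picks the global threshold, and a disk closing bridges
    sub-radius gaps.  A constant-intensity image (Otsu undefined) yields an
    all-background mask with a warning.
    """
    params = params or SegmentationParams()
    img = to_grayscale(image)
    if img.size == 0:
        raise ValueError("zero-sized image")
    if min(img.shape[:2]) < 32:
        raise ValueError("image too small: need min(width, height) >= 32")
    if np.ptp(img) == 0:
        warnings.warn("constant-intensity image; returning empty mask")
        return np.zeros(img.shape, dtype=bool)

    tiles = max(1, params.clahe_tiles)
    kernel = (max(1, img.shape[0] // tiles), max(1, img.shape[1] // tiles))
    enhanced = exposure.equalize_adapthist(img, kernel_size=kernel,
                                           clip_limit=params.clahe_clip)
    lap = ndimage.convolve(enhanced, _laplacian_kernel(params.laplacian_alpha),
                           mode="nearest")
    sharpened = np.clip(enhanced - lap, 0.0, 1.0)
    thresh = threshold_otsu(sharpened)
    mask = sharpened < thresh  # tissue is dark
    if params.close_radius > 0:
        mask = morphology.closing(mask, morphology.disk(params.close_radius))
    return mask


def _label(mask: np.ndarray) -> np.ndarray:
    return measure.label(mask, connectivity=2)


def _candidate_from_region(rp) -> CoreCandidate:
    y0, x0, y1, x1 = rp.bbox
    cy, cx = rp.centroid
    return CoreCandidate(
        label=int(rp.label),
        area=int(rp.area),
        centroid=(float(cx), float(cy)),
        bbox=(int(x0), int(y0), int(x1 - x0), int(y1 - y0)),
    )


def extract_candidates(
    mask: np.ndarray, params: SegmentationParams | None = None
) -> list[CoreCandidate]:
    """Replace each connected component by its filled convex hull.

    Hulls with area below ``min_speck_area`` are dropped.  The returned
    candidates carry the hulled geometry; :func:`compose_mask` rebuilds the
    full hulled mask from them.
    """
    params = params or SegmentationParams()
    hulled = hull_components(mask)
    out = []
    for rp in measure.regionprops(_label(hulled)):
        if rp.area < params.min_speck_area:
            continue
        out.append(_candidate_from_region(rp))
    return out


def hull_components(mask: np.ndarray) -> np.ndarray:
    """Per-component convex hull of a boolean mask."""
    lbl = _label(mask)
    out = np.zeros_like(mask, dtype=bool)
    for rp in measure.regionprops(lbl):
        y0, x0, y1, x1 = rp.bbox
        out[y0:y1, x0:x1] |= convex_hull_pixels(rp.image)
    return out


def digital_segment(p: tuple[int, int], q: tuple[int, int]):
    """Canonical Bresenham segment between two pixels, as ``(rows, cols)``.

    Bresenham lines are not symmetric in their endpoints on rounding ties, so
    the segment is always drawn from the lexicographically smaller endpoint
    (by ``(y, x)``) to make the closure well defined.
    """
    (px, py), (qx, qy) = p, q
    if (py, px) > (qy, qx):
        (px, py), (qx, qy) = (qx, qy), (px, py)
    return _draw_line(py, px, qy, qx)


def convex_hull_pixels(patch: np.ndarray) -> np.ndarray:
    """Digital convex hull of a boolean patch.

    Foreground is closed under digital line segments: every pixel on an
    8-connected Bresenham line between two foreground pixels becomes
    foreground, iterated to a fixpoint.  The fixpoint is computed efficiently
    by first drawing lines between all planar hull vertices (valid closure
    pairs) and then iterating over boundary-pixel pairs, which is equivalent
    to the exhaustive all-pairs closure (checked against a brute-force oracle
    in the test suite).
    """
    patch = np.asarray(patch, dtype=bool)
    out = patch.copy()
    ys, xs = np.nonzero(patch)
    n = len(ys)
    if n <= 2:
        if n == 2:
            rr, cc = digital_segment((xs[0], ys[0]), (xs[1], ys[1]))
            out[rr, cc] = True
        return out
    pts = np.column_stack([xs, ys])
    try:
        from scipy.spatial import ConvexHull

        verts = pts[ConvexHull(pts.astype(float)).vertices]
    except QhullError:
        verts = pts  # collinear component: every pixel is extremal
    i, j = np.triu_indices(len(verts), k=1)
    rr, cc = _batch_segments(verts[i], verts[j])
    out[rr, cc] = True
    # iterate boundary-pair closure to the fixpoint; after the first sweep
    # only pairs touching newly added pixels can contribute
    structure = np.ones((3, 3), bool)
    fresh: np.ndarray | None = None
    while True:
        interior = ndimage.binary_erosion(out, structure=structure)
        by, bx = np.nonzero(out & ~interior)
        boundary = np.column_stack([bx, by])
        if fresh is None:
            i, j = np.triu_indices(len(boundary), k=1)
            p0, p1 = boundary[i], boundary[j]
        else:
            i = np.repeat(np.arange(len(fresh)), len(boundary))
            j = np.tile(np.arange(len(boundary)), len(fresh))
            p0, p1 = fresh[i], boundary[j]
            same = (p0 == p1).all(axis=1)
            p0, p1 = p0[~same], p1[~same]
        if len(p0) == 0:
            return out
        rr, cc = _batch_segments(p0, p1)
        miss = ~out[rr, cc]
        if not miss.any():
            return out
        out[rr, cc] = True
        fresh = np.unique(np.column_stack([cc[miss], rr[miss]]), axis=0)


def _batch_segments(p0: np.ndarray, p1: np.ndarray):
    """Pixels of many canonical Bresenham segments at once.

    ``p0``/``p1`` are (M, 2) integer arrays of ``(x, y)`` endpoints.  Each
    segment is drawn from its lexicographically smaller endpoint (by
    ``(y, x)``), reproducing ``skimage.draw.line`` pixel for pixel (asserted
    against it in the test suite).  Returns concatenated ``(rows, cols)``.
    """
    p0 = np.asarray(p0, dtype=np.int64)
    p1 = np.asarray(p1, dtype=np.int64)
    flip = (p0[:, 1] > p1[:, 1]) | ((p0[:, 1] == p1[:, 1]) & (p0[:, 0] > p1[:, 0]))
    a = np.where(flip[:, None], p1, p0)
    b = np.where(flip[:, None], p0, p1)
    dx = b[:, 0] - a[:, 0]
    dy = b[:, 1] - a[:, 1]
    adx, ady = np.abs(dx), np.abs(dy)
    sx, sy = np.sign(dx), np.sign(dy)
    major = np.maximum(adx, ady)
    minor = np.minimum(adx, ady)
    steep = ady > adx
    t = np.arange(int(major.max()) + 1)[None, :]
    valid = t <= major[:, None]
    maj_safe = np.maximum(major, 1)[:, None]
    minor_off = (2 * t * minor[:, None] + maj_safe) // (2 * maj_safe)
    along = t
    xs = np.where(steep[:, None],
                  a[:, 0:1] + sx[:, None] * minor_off,
                  a[:, 0:1] + sx[:, None] * along)
    ys = np.where(steep[:, None],
                  a[:, 1:2] + sy[:, None] * along,
                  a[:, 1:2] + sy[:, None] * minor_off)
    return ys[valid], xs[valid]


def detect_fragments(
    candidates: list[CoreCandidate], params: SegmentationParams | None = None
) -> list[FragmentPair]:
    """Flag Delaunay-neighbour pairs that look like one broken core.

    Both members must have area below the lower Tukey fence
    ``Q1 - k * IQR`` of all candidate areas, and their separation must fall
    below the analogous lower fence of all Delaunay edge lengths.
    """
    params = params or SegmentationParams()
    if len(candidates) < 4:
        return []
    pts = np.array([c.centroid for c in candidates])
    areas = np.array([c.area for c in candidates], dtype=float)

    q1a, q3a = np.percentile(areas, [25, 75])
    area_bound = q1a - params.fragment_area_k * (q3a - q1a)

    edges = _delaunay_edges(pts)
    if not edges:
        return []
    dists = np.array([np.hypot(*(pts[a] - pts[b])) for a, b in edges])
    q1d, q3d = np.percentile(dists, [25, 75])
    dist_bound = q1d - params.fragment_dist_k * (q3d - q1d)

    pairs = []
    for (a, b), d in zip(edges, dists):
        if d <= 0:
            continue
        if areas[a] < area_bound and areas[b] < area_bound and d < dist_bound:
            pairs.append(FragmentPair(candidates[a].label, candidates[b].label,
                                      float(d)))
    return pairs


def _delaunay_edges(pts: np.ndarray) -> list[tuple[int, int]]:
    """Undirected Delaunay edges; collinear sets fall back to all pairs."""
    try:
        tri = Delaunay(pts)
    except QhullError:
        n = len(pts)
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((simplex[i], simplex[(i + 1) % 3]))
            edges.add((int(a), int(b)))
    return sorted(edges)


def join_fragments(
    mask: np.ndarray,
    pairs: list[FragmentPair],
    candidates: list[CoreCandidate],
) -> np.ndarray:
    """Join flagged fragments: draw centroid-to-centroid lines, then re-hull.

    Pairs referencing labels absent from ``candidates`` are skipped with a
    warning.  An empty pair list returns the mask unchanged.
    """
    if not pairs:
        return mask
    by_label = {c.label: c for c in candidates}
    out = mask.copy()
    for pair in pairs:
        if pair.label_a not in by_label or pair.label_b not in by_label:
            warnings.warn(f"fragment pair {pair.label_a}-{pair.label_b} "
                          "references a removed label; skipped")
            continue
        ax, ay = by_label[pair.label_a].centroid
        bx, by = by_label[pair.label_b].centroid
        rr, cc = _draw_line(int(round(ay)), int(round(ax)),
                            int(round(by)), int(round(bx)))
        out[rr, cc] = True
    return hull_components(out)


# ---------------------------------------------------------------------------
# Boundary tracing and Fourier-descriptor smoothing
# ---------------------------------------------------------------------------

# Moore neighbourhood in clockwise order on screen (y down), as (dx, dy)
_MOORE = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
_MOORE_INDEX = {d: i for i, d in enumerate(_MOORE)}


def trace_boundary(patch: np.ndarray) -> np.ndarray:
    """Moore-neighbour boundary trace of the first component in ``patch``.

    Returns an ordered, closed (start not repeated) clockwise sequence of
    boundary pixel coordinates ``(x, y)``.
    """
    patch = np.asarray(patch, dtype=bool)
    padded = np.pad(patch, 1)
    ys, xs = np.nonzero(padded)
    if len(ys) == 0:
        return np.empty((0, 2), dtype=int)
    # raster-order start: topmost row, leftmost pixel
    order = np.lexsort((xs, ys))
    sy, sx = int(ys[order[0]]), int(xs[order[0]])
    if len(ys) == 1:
        return np.array([[sx - 1, sy - 1]])

    boundary = [(sx, sy)]
    start = (sx, sy)
    start_back = (sx - 1, sy)  # backtrack left of start: background by raster order
    cur = start
    back = start_back
    limit = 4 * len(ys) + 8
    while True:
        dx, dy = back[0] - cur[0], back[1] - cur[1]
        k = _MOORE_INDEX[(dx, dy)]
        nxt = None
        for step in range(1, 9):
            d = _MOORE[(k + step) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if padded[cand[1], cand[0]]:
                nxt = cand
                break
        if nxt is None:  # isolated pixel
            break
        # the neighbour examined just before the hit becomes the new backtrack
        if step > 1:
            prev = (k + step - 1) % 8
            new_back = (cur[0] + _MOORE[prev][0], cur[1] + _MOORE[prev][1])
        else:
            new_back = back
        if nxt == start and new_back == start_back:
            break
        boundary.append(nxt)
        cur, back = nxt, new_back
        if len(boundary) > limit:
            break
    return np.array(boundary) - 1  # undo padding offset


def fourier_smooth_boundary(boundary: np.ndarray, terms: int) -> np.ndarray | None:
    """Truncated Fourier-descriptor reconstruction of a closed boundary.

    The boundary is treated as a complex sequence ``x + iy``; only the
    ``terms`` lowest-frequency descriptors (symmetric about zero frequency)
    are kept before inverting.  Returns the reconstructed (float) vertex
    sequence, or None when the boundary is shorter than ``terms``.
    """
    n = len(boundary)
    if n < terms:
        return None
    z = boundary[:, 0].astype(float) + 1j * boundary[:, 1].astype(float)
    zf = np.fft.fft(z)
    k = np.fft.fftfreq(n, d=1.0 / n).round().astype(int)  # signed indices
    # retain the `terms` frequencies closest to zero, preferring positive on ties
    order = np.lexsort((k < 0, np.abs(k)))
    keep = np.zeros(n, dtype=bool)
    keep[order[:terms]] = True
    zf[~keep] = 0
    z2 = np.fft.ifft(zf)
    return np.column_stack([z2.real, z2.imag])


def _rasterize_closed(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a closed float polygon: interior + rounded boundary, holes filled."""
    out = np.zeros(shape, dtype=bool)
    if len(vertices) == 0:
        return out
    vx = vertices[:, 0]
    vy = vertices[:, 1]
    rr, cc = _draw_polygon(vy, vx, shape=shape)
    out[rr, cc] = True
    rx = np.clip(np.round(vx).astype(int), 0, shape[1] - 1)
    ry = np.clip(np.round(vy).astype(int), 0, shape[0] - 1)
    for i in range(len(vertices)):
        j = (i + 1) % len(vertices)
        rr, cc = _draw_line(ry[i], rx[i], ry[j], rx[j])
        out[rr, cc] = True
    return ndimage.binary_fill_holes(out)


def smooth_boundaries(mask: np.ndarray, terms: int) -> np.ndarray:
    """Smooth every component with the ``terms``-term Fourier reconstruction.

    Components whose boundary is shorter than ``terms`` are kept unchanged
    (with a warning).
    """
    lbl = _label(mask)
    out = np.zeros_like(mask, dtype=bool)
    for rp in measure.regionprops(lbl):
        y0, x0, y1, x1 = rp.bbox
        patch = rp.image
        bd = trace_boundary(patch)
        smoothed = fourier_smooth_boundary(bd, terms) if len(bd) else None
        if smoothed is None:
            warnings.warn(f"component {rp.label}: boundary shorter than "
                          f"{terms} terms; left unchanged")
            out[y0:y1, x0:x1] |= patch
            continue
        filled = _rasterize_closed(smoothed, patch.shape)
        out[y0:y1, x0:x1] |= filled
    return out


def finalize_candidates(
    mask: np.ndarray, params: SegmentationParams | None = None
) -> list[CoreCandidate]:
    """Final size filter: keep objects with area >= ``min_core_area``."""
    params = params or SegmentationParams()
    out = []
    for rp in measure.regionprops(_label(mask)):
        if rp.area < params.min_core_area:
            continue
        cand = _candidate_from_region(rp)
        cand.boundary = trace_boundary(rp.image) + np.array(
            [cand.bbox[0], cand.bbox[1]]
        )
        out.append(cand)
    return out


@dataclass
class SegmentationResult:
    """Output of the full segmentation chain plus per-stage bookkeeping."""

    candidates: list[CoreCandidate]
    mask: np.ndarray
    n_initial: int
    n_hulled: int
    fragments_joined: int
    warnings: list[str]


def segment(
    image: np.ndarray, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Run the whole segmentation chain on a thumbnail.

    Boolean input images (e.g. pseudo slides) skip enhancement/thresholding
    and enter the chain at the hulling stage.
    """
    params = params or SegmentationParams()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        if np.asarray(image).dtype == bool:
            mask = np.asarray(image)
        else:
            mask = enhance_and_threshold(image, params)
        n_initial = int(_label(mask).max())

        hulled = hull_components(mask)
        hulled = _filter_area(hulled, params.min_speck_area)
        # components are already convex: build candidates without re-hulling
        candidates = [_candidate_from_region(rp)
                      for rp in measure.regionprops(_label(hulled))]

        pairs = detect_fragments(candidates, params)
        if pairs:
            hulled = join_fragments(hulled, pairs, candidates)
        smoothed = smooth_boundaries(hulled, params.fourier_terms)
        final_mask = _filter_area(smoothed, params.min_core_area)
        final = finalize_candidates(smoothed, params)
    return SegmentationResult(
        candidates=final,
        mask=final_mask,
        n_initial=n_initial,
        n_hulled=len(candidates),
        fragments_joined=len(pairs),
        warnings=[str(w.message) for w in caught],
    )


def _filter_area(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove components with area < ``min_area``."""
    lbl = _label(mask)
    areas = np.bincount(lbl.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[lbl]
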