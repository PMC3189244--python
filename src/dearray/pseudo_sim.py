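"""Pseudo TMA slide simulator.

Generates binary slide thumbnails of near-circular tissue cores on a regular
lattice, together with a ground-truth table (core id -> logical row/column and
centroid).  Irregularities seen on real slides can be layered on top of the
regular template: randomly missing cores, rigid rotation of the whole layout,
and non-linear stretching modelled by a difference-of-cosines displacement
profile.  A full five-set evaluation suite (missing / rotation / horizontal
stretch / vertical stretch / mixed, 113 slides) is produced by
:func:`generate_suite`.

Coordinates are image coordinates: ``x`` rightward, ``y`` downward, 0-based.
Positive rotation angles are clockwise on screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist
from skimage.draw import polygon as _draw_polygon

__all__ = [
    "PseudoSpec",
    "PseudoCore",
    "PseudoSlide",
    "make_template",
    "apply_missing",
    "apply_rotation",
    "apply_stretch",
    "generate_suite",
    "SUITE_SET_SIZES",
]

#: number of vertices used to rasterize one core outline
_SHAPE_VERTICES = 64

#: per-set slide counts of the evaluation suite
SUITE_SET_SIZES = {
    "missing": 26,
    "rotation": 31,
    "stretch_h": 13,
    "stretch_v": 16,
    "mixed": 27,
}


@dataclass(frozen=True)
class PseudoSpec:
    """Parameters of the regular pseudo-slide template."""

    n_rows: int = 9
    n_cols: int = 14
    pitch: float = 50.0
    core_diameter: float = 30.0
    radius_jitter: float = 0.10
    boundary_noise: float = 0.03
    margin_factor: float = 2.0
    stretch_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice must contain at least one core")
        if self.pitch <= self.core_diameter:
            raise ValueError("pitch must exceed the core diameter")
        if self.core_diameter <= 0:
            raise ValueError("core diameter must be positive")

    @property
    def margin(self) -> float:
        return self.margin_factor * self.pitch


@dataclass
class PseudoCore:
    """One simulated core: logical index, centroid and outline shape."""

    core_id: int
    row: int
    col: int
    x: float
    y: float
    #: (V, 2) outline vertex offsets relative to the centroid, (dx, dy)
    shape: np.ndarray


@dataclass
class PseudoSlide:
    """A simulated binary thumbnail plus its ground truth."""

    spec: PseudoSpec
    cores: list[PseudoCore]
    width: int
    height: int
    provenance: dict = field(default_factory=dict)

    @property
    def centroids(self) -> np.ndarray:
        """(N, 2) array of true centroids, columns (x, y)."""
        if not self.cores:
            return np.empty((0, 2))
        return np.array([[c.x, c.y] for c in self.cores])

    def truth(self) -> list[tuple[int, int, int, float, float]]:
        """Ground truth rows ``(core_id, row, col, cx, cy)``."""
        return [(c.core_id, c.row, c.col, c.x, c.y) for c in self.cores]

    def render(self) -> np.ndarray:
        """Rasterize the slide as a boolean image (True = tissue)."""
        img = np.zeros((self.height, self.width), dtype=bool)
        for core in self.cores:
            vx = core.x + core.shape[:, 0]
            vy = core.y + core.shape[:, 1]
            rr, cc = _draw_polygon(vy, vx, shape=img.shape)
            img[rr, cc] = True
        return img

    def copy(self) -> "PseudoSlide":
        return PseudoSlide(
            spec=self.spec,
            cores=[replace(c, shape=c.shape.copy()) for c in self.cores],
            width=self.width,
            height=self.height,
            provenance=dict(self.provenance),
        )


def _core_shape(rng: np.random.Generator, spec: PseudoSpec) -> np.ndarray:
    """Random near-circular outline: jittered radius plus low-order wobble."""
    r0 = 0.5 * spec.core_diameter
    r0 *= 1.0 + rng.uniform(-spec.radius_jitter, spec.radius_jitter)
    phi = np.linspace(0.0, 2.0 * math.pi, _SHAPE_VERTICES, endpoint=False)
    wobble = np.zeros_like(phi)
    for h in (2, 3, 4):
        wobble += rng.normal(0, 1) * np.cos(h * phi) + rng.normal(0, 1) * np.sin(h * phi)
    r = r0 * (1.0 + spec.boundary_noise * wobble / math.sqrt(6.0))
    # keep cores disjoint at lattice pitch
    r = np.clip(r, 0.6 * r0, min(1.3 * r0, 0.5 * spec.pitch - 3.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def _normalize_canvas(slide: PseudoSlide) -> PseudoSlide:
    """Shift cores so the layout sits at the standard margin; resize canvas."""
    margin = slide.spec.margin
    if not slide.cores:
        side = int(math.ceil(2 * margin)) + 1
        slide.width = side
        slide.height = side
        return slide
    pts = slide.centroids
    shift_x = margin - pts[:, 0].min()
    shift_y = margin - pts[:, 1].min()
    for c in slide.cores:
        c.x += shift_x
        c.y += shift_y
    span_x = pts[:, 0].max() - pts[:, 0].min()
    span_y = pts[:, 1].max() - pts[:, 1].min()
    slide.width = int(math.ceil(span_x + 2 * margin)) + 1
    slide.height = int(math.ceil(span_y + 2 * margin)) + 1
    return slide


def make_template(spec: PseudoSpec | None = None) -> PseudoSlide:
    """Build the undistorted template slide: an ``n_rows x n_cols`` lattice.

    Cores are near-circular blobs (radius jitter and boundary wobble drawn
    from ``spec.seed``) centred on an equally spaced lattice.
    """
    spec = spec or PseudoSpec()
    rng = np.random.default_rng(spec.seed)
    cores = []
    cid = 0
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            cores.append(
                PseudoCore(
                    core_id=cid,
                    row=i,
                    col=j,
                    x=spec.margin + j * spec.pitch,
                    y=spec.margin + i * spec.pitch,
                    shape=_core_shape(rng, spec),
                )
            )
            cid += 1
    slide = PseudoSlide(spec=spec, cores=cores, width=0, height=0,
                        provenance={"ops": ["template"], "seed": spec.seed})
    return _normalize_canvas(slide)


def apply_missing(slide: PseudoSlide, k: int, seed: int | None = None) -> PseudoSlide:
    """Remove ``k`` uniformly chosen cores; survivors keep their indices."""
    if not 0 <= k <= len(slide.cores):
        raise ValueError(f"cannot remove {k} of {len(slide.cores)} cores")
    out = slide.copy()
    if k:
        rng = np.random.default_rng(seed)
        drop = set(rng.choice(len(out.cores), size=k, replace=False).tolist())
        out.cores = [c for i, c in enumerate(out.cores) if i not in drop]
    out.provenance.setdefault("ops", []).append(("missing", k, seed))
    return _normalize_canvas(out)


def apply_rotation(slide: PseudoSlide, theta: float) -> PseudoSlide:
    """Rigidly rotate the layout by ``theta`` degrees (clockwise on screen)."""
    if abs(theta) > 90:
        raise ValueError("|theta| must be <= 90 degrees")
    out = slide.copy()
    t = math.radians(theta)
    # clockwise on screen in (x, y-down) coordinates
    c, s = math.cos(t), math.sin(t)
    cx, cy = out.width / 2.0, out.height / 2.0
    for core in out.cores:
        dx, dy = core.x - cx, core.y - cy
        core.x = cx + c * dx - s * dy
        core.y = cy + s * dx + c * dy
        sx = core.shape[:, 0].copy()
        sy = core.shape[:, 1].copy()
        core.shape[:, 0] = c * sx - s * sy
        core.shape[:, 1] = s * sx + c * sy
    out.provenance.setdefault("ops", []).append(("rotation", theta))
    return _normalize_canvas(out)


def _edge_profile(idx: np.ndarray, n: int) -> np.ndarray:
    """Monotone difference-of-cosines profile: 0 at index 0, 1 at index n-1."""
    if n <= 1:
        return np.zeros_like(idx, dtype=float)
    return 0.5 * (1.0 - np.cos(math.pi * idx / (n - 1)))


def apply_stretch(
    slide: PseudoSlide,
    a_h: float = 0.0,
    a_v: float = 0.0,
    s: float | None = None,
) -> PseudoSlide:
    """Apply the non-linear cosine stretching model.

    Displacements grow monotonically from the fixed left edge toward the right
    edge of the lattice following a difference-of-cosines profile scaled by
    ``s``; a half-cosine row weight concentrates the displacement at the
    stretched corner.  ``a_h > 0`` / ``a_v > 0`` stretch at the top-right
    corner, negative amplitudes at the bottom-right corner.
    """
    out = slide.copy()
    spec = out.spec
    if s is None:
        s = spec.stretch_scale
    m, n = spec.n_rows, spec.n_cols
    for core in out.cores:
        g = float(_edge_profile(np.asarray(core.col, dtype=float), n))
        i = core.row
        if a_h:
            wi = i if a_h > 0 else (m - 1 - i)
            w = 0.5 * (1.0 + math.cos(math.pi * wi / (m - 1))) if m > 1 else 1.0
            core.x += abs(a_h) * s * g * w
        if a_v:
            wi = i if a_v > 0 else (m - 1 - i)
            w = 0.5 * (1.0 + math.cos(math.pi * wi / (m - 1))) if m > 1 else 1.0
            core.y += a_v * s * g * w
    if len(out.cores) >= 2:
        if pdist(out.centroids).min() < spec.core_diameter:
            raise ValueError("stretch collapses lattice")
    out.provenance.setdefault("ops", []).append(("stretch", a_h, a_v, s))
    return _normalize_canvas(out)


def generate_suite(
    seed: int,
    spec: PseudoSpec | None = None,
    missing_max: int = 31,
    rotation_max: float = 15.0,
    stretch_h_max: float = 3.0,
    stretch_v_max: float = 3.0,
    mixed_stretch_max: float = 2.0,
) -> list[PseudoSlide]:
    """Generate the 113-slide evaluation suite, deterministic under ``seed``.

    Five case sets are produced (sizes in :data:`SUITE_SET_SIZES`): missing
    cores with removal counts evenly spanning ``[0, missing_max]``, rotations
    evenly spanning ``[-rotation_max, rotation_max]`` degrees, horizontal and
    vertical stretch amplitudes evenly spanning their ranges, and randomly
    mixed cases combining all four degrees of freedom.
    """
    base = spec or PseudoSpec()
    rng = np.random.default_rng(seed)
    slides: list[PseudoSlide] = []

    def fresh_template() -> PseudoSlide:
        return make_template(replace(base, seed=int(rng.integers(0, 2**31 - 1))))

    ks = np.round(np.linspace(0, missing_max, SUITE_SET_SIZES["missing"])).astype(int)
    for k in ks:
        sl = apply_missing(fresh_template(), int(k), seed=int(rng.integers(0, 2**31 - 1)))
        sl.provenance.update(case_set="missing", params={"k": int(k)})
        slides.append(sl)

    for theta in np.linspace(-rotation_max, rotation_max, SUITE_SET_SIZES["rotation"]):
        sl = apply_rotation(fresh_template(), float(theta))
        sl.provenance.update(case_set="rotation", params={"theta": float(theta)})
        slides.append(sl)

    for a_h in np.linspace(-stretch_h_max, stretch_h_max, SUITE_SET_SIZES["stretch_h"]):
        sl = apply_stretch(fresh_template(), a_h=float(a_h))
        sl.provenance.update(case_set="stretch_h", params={"a_h": float(a_h)})
        slides.append(sl)

    for a_v in np.linspace(-stretch_v_max, stretch_v_max, SUITE_SET_SIZES["stretch_v"]):
        sl = apply_stretch(fresh_template(), a_v=float(a_v))
        sl.provenance.update(case_set="stretch_v", params={"a_v": float(a_v)})
        slides.append(sl)

    for _ in range(SUITE_SET_SIZES["mixed"]):
        k = int(rng.integers(0, missing_max + 1))
        theta = float(rng.uniform(-rotation_max, rotation_max))
        a_h = float(rng.uniform(-mixed_stretch_max, mixed_stretch_max))
        a_v = float(rng.uniform(-mixed_stretch_max, mixed_stretch_max))
        sl = apply_missing(fresh_template(), k, seed=int(rng.integers(0, 2**31 - 1)))
        sl = apply_stretch(sl, a_h=a_h, a_v=a_v)
        sl = apply_rotation(sl, theta)
        sl.provenance.update(
            case_set="mixed",
            params={"k": k, "theta": theta, "a_h": a_h, "a_v": a_v},
        )
        slides.append(sl)

    return slides
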