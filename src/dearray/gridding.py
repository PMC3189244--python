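"""Delaunay-triangulation gridding of segmented core centroids.

The stages mirror the de-arraying pipeline: build a Delaunay triangulation
over the centroids, discard long edges (smallest-2/3 rule plus an upper Tukey
fence), isolate the near-horizontal edge cluster with a seeded 1-D k-means
over edge angles (which also estimates the grid rotation), chain the retained
directed edges left-to-right with the traveling algorithm (inserting imaginary
vertices across gaps), assign row/column indices by median-residual shift
matching against the longest row, and post-process (row merging, imaginary
filling, adoption of stray vertices, boundary trimming).

Angles are measured from the +x axis with mathematically positive sense (a
clockwise-on-screen rotation of the slide therefore yields a negative
estimated angle, since image ``y`` points down), normalized to ``(-90, 90]``
degrees for undirected edges.
"""

from __future__ import annotations

import math
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "GriddingParams",
    "TriGraph",
    "EdgeTemplate",
    "RowList",
    "Cell",
    "GridAssignment",
    "build_triangulation",
    "filter_edges_by_length",
    "filter_edges_by_angle",
    "make_template",
    "travel",
    "assign_rows_and_columns",
    "postprocess",
    "grid_accuracy",
    "grid_points",
    "row_label",
]


@dataclass(frozen=True)
class GriddingParams:
    """Tunable factors of the gridding stage (all relative to the pitch D)."""

    neighbour_threshold_factor: float = 1.5
    stop_margin_factor: float = 0.75
    sector_radius_factor: float = 1.5
    sector_half_angle: float = 30.0
    row_merge_factor: float = 0.5
    length_outlier_k: float = 1.5
    kmeans_seeds: tuple[float, ...] = (-90.0, -45.0, 0.0, 45.0, 90.0)

    def __post_init__(self) -> None:
        for name in ("neighbour_threshold_factor", "stop_margin_factor",
                     "sector_radius_factor", "sector_half_angle",
                     "row_merge_factor", "length_outlier_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.kmeans_seeds) != 5:
            raise ValueError("exactly 5 k-means seeds are required")


@dataclass
class TriGraph:
    """Delaunay triangulation with per-edge length and normalized angle."""

    points: np.ndarray  # (N, 2) centroids, (x, y)
    simplices: np.ndarray  # (T, 3) vertex triples
    edges: np.ndarray  # (E, 2) undirected vertex pairs, a < b
    lengths: np.ndarray  # (E,)
    angles: np.ndarray  # (E,) degrees in (-90, 90]


@dataclass
class EdgeTemplate:
    """Directed left-to-right vectors retained for the traveling algorithm."""

    points: np.ndarray
    vectors: list[tuple[int, int]]  # (start, end) with x_start < x_end
    theta: float  # estimated grid rotation, degrees
    pitch: float  # estimated core-to-core distance D, px


@dataclass
class RowEntry:
    """One chain element: a real vertex id or an imaginary position."""

    vertex: int | None
    x: float
    y: float

    @property
    def real(self) -> bool:
        return self.vertex is not None


@dataclass
class RowList:
    """One traveled chain, ordered left to right."""

    entries: list[RowEntry]

    @property
    def mean_y(self) -> float:
        return float(np.mean([e.y for e in self.entries]))


@dataclass
class TravelResult:
    """Chains plus the context needed for index assignment."""

    rows: list[RowList]
    unassigned: list[int]
    points: np.ndarray
    theta: float
    pitch: float
    width: float


@dataclass
class Cell:
    """One grid cell: real vertex, imaginary placeholder, or empty."""

    kind: str  # "real" | "imaginary" | "empty"
    vertex: int | None = None
    x: float = math.nan
    y: float = math.nan


@dataclass
class GridAssignment:
    """Logical grid: cells[r][c] plus off-grid bookkeeping."""

    cells: list[list[Cell]]
    artefacts: list[int] = field(default_factory=list)
    unassigned: list[int] = field(default_factory=list)
    points: np.ndarray | None = None
    theta: float = 0.0
    pitch: float = float("nan")

    @property
    def n_rows(self) -> int:
        return len(self.cells)

    @property
    def n_cols(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def real_cells(self):
        """Yield ``(r, c, cell)`` for every real cell."""
        for r, row in enumerate(self.cells):
            for c, cell in enumerate(row):
                if cell.kind == "real":
                    yield r, c, cell


def row_label(index: int) -> str:
    """0-based row index -> spreadsheet-style letters: A..Z, AA, AB, ..."""
    letters = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        letters = string.ascii_uppercase[rem] + letters
    return letters


def _edge_angle(dx: float, dy: float) -> float:
    """Undirected edge angle in degrees, normalized to (-90, 90]."""
    ang = math.degrees(math.atan2(-dy, dx))  # y-down image coords
    if ang <= -90.0:
        ang += 180.0
    elif ang > 90.0:
        ang -= 180.0
    return ang


def build_triangulation(centroids: np.ndarray) -> TriGraph:
    """Delaunay-triangulate the centroids and annotate the edges."""
    pts = np.asarray(centroids, dtype=float)
    if len(pts) < 3:
        raise ValueError("degenerate point set: need at least 3 centroids")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError("degenerate point set") from exc
    if len(tri.simplices) == 0:
        raise ValueError("degenerate point set")
    pairs = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((int(simplex[i]), int(simplex[(i + 1) % 3])))
            pairs.add((a, b))
    edges = np.array(sorted(pairs))
    deltas = pts[edges[:, 1]] - pts[edges[:, 0]]
    lengths = np.hypot(deltas[:, 0], deltas[:, 1])
    angles = np.array([_edge_angle(dx, dy) for dx, dy in deltas])
    return TriGraph(points=pts, simplices=tri.simplices, edges=edges,
                    lengths=lengths, angles=angles)


def filter_edges_by_length(
    graph: TriGraph, params: GriddingParams | None = None
) -> np.ndarray:
    """Keep the shortest 2/3 of edges and drop upper-fence outliers.

    The cut keeps ties: every edge no longer than the 2/3-quantile edge is
    retained.  On top, any edge above ``Q3 + k * IQR`` of all edge lengths is
    removed.  Returns indices into ``graph.edges``.
    """
    params = params or GriddingParams()
    n = len(graph.lengths)
    if n < 3:
        raise ValueError("need at least 3 edges")
    cut_rank = max(1, math.ceil(2 * n / 3))
    cutoff = np.sort(graph.lengths)[cut_rank - 1]
    q1, q3 = np.percentile(graph.lengths, [25, 75])
    fence = q3 + params.length_outlier_k * (q3 - q1)
    keep = (graph.lengths <= cutoff) & (graph.lengths <= fence)
    return np.nonzero(keep)[0]


def _kmeans_1d(values: np.ndarray, seeds: np.ndarray, max_iter: int = 100):
    """Deterministic 1-D Lloyd's algorithm; empty clusters keep their seed."""
    centers = seeds.astype(float).copy()
    assign = np.zeros(len(values), dtype=int)
    for _ in range(max_iter):
        dist = np.abs(values[:, None] - centers[None, :])
        new_assign = dist.argmin(axis=1)
        new_centers = centers.copy()
        for k in range(len(centers)):
            members = values[new_assign == k]
            if len(members):
                new_centers[k] = members.mean()
        if np.array_equal(new_assign, assign) and np.allclose(new_centers, centers):
            break
        assign, centers = new_assign, new_centers
    return assign, centers


def filter_edges_by_angle(
    graph: TriGraph,
    params: GriddingParams | None = None,
    subset: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Isolate the near-horizontal angle cluster and estimate the rotation.

    A 1-D k-means with 5 clusters seeded at {-90, -45, 0, 45, 90} degrees is
    run over the edge angles; the cluster whose converged center is nearest
    0 degrees is returned, and that center is the rotation estimate.  With
    fewer than 5 edges, edges with ``|angle| <= 22.5`` degrees are selected
    instead.  Returns ``(edge indices, theta_hat)``.
    """
    params = params or GriddingParams()
    idx = np.arange(len(graph.edges)) if subset is None else np.asarray(subset)
    angles = graph.angles[idx]
    if len(angles) < len(params.kmeans_seeds):
        sel = np.abs(angles) <= 22.5
        theta = float(np.mean(angles[sel])) if sel.any() else 0.0
        return idx[sel], theta
    assign, centers = _kmeans_1d(angles, np.asarray(params.kmeans_seeds))
    k = int(np.abs(centers).argmin())
    return idx[assign == k], float(centers[k])


def make_template(
    graph: TriGraph,
    length_idx: np.ndarray,
    angle_idx: np.ndarray,
    theta: float,
) -> EdgeTemplate:
    """Intersect the two filtered edge sets into directed traveling vectors.

    Each surviving undirected edge becomes one left-to-right vector
    (``x_start < x_end``).  The pitch estimate D is the median length of the
    length-filtered set.
    """
    common = sorted(set(length_idx.tolist()) & set(angle_idx.tolist()))
    if not common:
        raise ValueError("no horizontal structure found")
    pts = graph.points
    vectors = []
    seen = set()
    for e in common:
        a, b = graph.edges[e]
        if (pts[a][0], pts[a][1]) > (pts[b][0], pts[b][1]):
            a, b = b, a
        if (a, b) not in seen:
            seen.add((a, b))
            vectors.append((int(a), int(b)))
    pitch = float(np.median(graph.lengths[length_idx]))
    return EdgeTemplate(points=pts, vectors=vectors, theta=theta, pitch=pitch)


def travel(
    template: EdgeTemplate,
    width: float,
    params: GriddingParams | None = None,
) -> TravelResult:
    """Chain template vectors left-to-right into row lists.

    Chains start at the unused vector with the smallest start ``x``.  At each
    terminal the next vector is matched head-to-tail; failing that, a
    circular sector (radius ``sector_radius_factor * D``, half-angle
    ``sector_half_angle`` about the estimated row direction) is searched for
    the nearest free vertex; failing that, an imaginary vertex is appended at
    the terminal plus the mean horizontal step.  A chain ends when its
    terminal ``x`` reaches ``width - stop_margin_factor * D``.
    """
    params = params or GriddingParams()
    if width <= 0:
        raise ValueError("image width must be positive")
    if not template.vectors:
        raise ValueError("empty template")
    pts = template.points
    D = template.pitch
    eps = params.stop_margin_factor * D
    radius = params.sector_radius_factor * D
    half_angle = params.sector_half_angle
    theta_rad = math.radians(template.theta)
    direction = np.array([math.cos(theta_rad), -math.sin(theta_rad)])
    steps = np.array([pts[b] - pts[a] for a, b in template.vectors])
    mean_step = steps.mean(axis=0)
    cap = max(10, int(3 * width / (0.5 * D)))

    by_start: dict[int, list[tuple[int, int]]] = {}
    for vec in template.vectors:
        by_start.setdefault(vec[0], []).append(vec)
    remaining = set(template.vectors)
    used = np.zeros(len(pts), dtype=bool)

    def vector_key(vec):
        dx, dy = pts[vec[1]] - pts[vec[0]]
        return (abs(_edge_angle(dx, dy) - template.theta),
                math.hypot(dx, dy))

    def next_vector(v: int):
        cands = [vec for vec in by_start.get(v, []) if vec in remaining]
        cands = [vec for vec in cands if not used[vec[1]]]
        if not cands:
            return None
        return min(cands, key=vector_key)

    def sector_search(pos: np.ndarray):
        free = ~used
        if not free.any():
            return None
        deltas = pts - pos
        dists = np.hypot(deltas[:, 0], deltas[:, 1])
        with np.errstate(invalid="ignore"):
            proj = deltas @ direction
        ok = free & (dists > 1e-9) & (dists <= radius)
        if not ok.any():
            return None
        # keep vertices whose bearing is within the sector half-angle
        cos_lim = math.cos(math.radians(half_angle))
        cosang = np.where(dists > 0, proj / np.maximum(dists, 1e-12), -1.0)
        ok &= cosang >= cos_lim
        if not ok.any():
            return None
        return int(np.nonzero(ok)[0][dists[ok].argmin()])

    rows: list[RowList] = []
    while remaining:
        start_vec = min(
            (vec for vec in remaining if not used[vec[0]] and not used[vec[1]]),
            key=lambda v: pts[v[0]][0],
            default=None,
        )
        if start_vec is None:
            # leftover vectors touch already-used vertices; drop them
            break
        remaining.discard(start_vec)
        a, b = start_vec
        entries = [RowEntry(a, *pts[a]), RowEntry(b, *pts[b])]
        used[a] = used[b] = True
        terminal = entries[-1]
        while True:
            if len(entries) > cap:
                warnings.warn("runaway chain aborted")
                break
            if terminal.real:
                vec = next_vector(terminal.vertex)
                if vec is not None:
                    remaining.discard(vec)
                    v = vec[1]
                    entries.append(RowEntry(v, *pts[v]))
                    used[v] = True
                    terminal = entries[-1]
                    continue
            if terminal.x >= width - eps:
                break
            pos = np.array([terminal.x, terminal.y])
            q = sector_search(pos)
            if q is not None:
                entries.append(RowEntry(q, *pts[q]))
                used[q] = True
            else:
                nxt = pos + mean_step
                entries.append(RowEntry(None, float(nxt[0]), float(nxt[1])))
            terminal = entries[-1]
        rows.append(RowList(entries))

    unassigned = [int(i) for i in np.nonzero(~used)[0]]
    return TravelResult(rows=rows, unassigned=unassigned, points=pts,
                        theta=template.theta, pitch=D, width=width)


def _derotate(x, y, theta: float):
    """Project image coords onto (along-row, across-row) axes."""
    t = math.radians(theta)
    u = x * math.cos(t) - y * math.sin(t)
    v = x * math.sin(t) + y * math.cos(t)
    return u, v


def assign_rows_and_columns(result: TravelResult) -> GridAssignment:
    """Sort chains into rows and align their columns against a reference.

    Chains are sorted by their across-row coordinate.  The longest chain is
    the reference; every other chain is slid over it by integer shifts and
    the shift minimizing the median absolute along-row residual wins
    (ties prefer the smaller absolute shift).  Shifts are then re-based so
    the leftmost occupied column becomes column 1.
    """
    rows = result.rows
    if not rows:
        raise ValueError("no rows to assign")
    theta = result.theta

    def coords(row: RowList) -> np.ndarray:
        return np.array([_derotate(e.x, e.y, theta) for e in row.entries])

    uv = [coords(r) for r in rows]
    order = np.argsort([c[:, 1].mean() for c in uv])
    rows = [rows[i] for i in order]
    uv = [uv[i] for i in order]

    def best_shift(u: np.ndarray, ref: np.ndarray) -> int:
        """Integer shift of ``u`` onto ``ref`` minimizing the median residual."""
        if len(ref) < 2:
            return 0
        best_key, shift_star = (math.inf, math.inf), 0
        min_overlap = max(1, min(len(u), len(ref)) // 2)
        for shift in range(-len(u) + 1, len(ref)):
            lo = max(0, -shift)
            hi = min(len(u), len(ref) - shift)
            if hi - lo < min_overlap:
                continue
            resid = float(np.median(np.abs(u[lo:hi] - ref[lo + shift:hi + shift])))
            key = (resid, abs(shift))
            if key < best_key:
                best_key, shift_star = key, shift
        return shift_star

    # anchor at the longest row; propagate shifts through adjacent rows so
    # that slowly varying stretch distortion never accumulates into a
    # full-pitch mismatch against a distant reference
    ref_i = int(np.argmax([len(r.entries) for r in rows]))
    offsets = [0] * len(rows)
    for i in range(ref_i + 1, len(rows)):
        offsets[i] = offsets[i - 1] + best_shift(uv[i][:, 0], uv[i - 1][:, 0])
    for i in range(ref_i - 1, -1, -1):
        offsets[i] = offsets[i + 1] + best_shift(uv[i][:, 0], uv[i + 1][:, 0])
    # re-base so the smallest column index is 0
    base = min(o for o in offsets)
    offsets = [o - base for o in offsets]
    n_cols = max(o + len(r.entries) for o, r in zip(offsets, rows))

    cells = [[Cell("empty") for _ in range(n_cols)] for _ in rows]
    artefacts: list[int] = []
    for r, (row, off) in enumerate(zip(rows, offsets)):
        for k, e in enumerate(row.entries):
            cell = cells[r][off + k]
            if cell.kind == "empty":
                cells[r][off + k] = Cell(
                    "real" if e.real else "imaginary",
                    vertex=e.vertex, x=e.x, y=e.y,
                )
            elif e.real:
                artefacts.append(e.vertex)
    return GridAssignment(cells=cells, artefacts=artefacts,
                          unassigned=list(result.unassigned),
                          points=result.points, theta=theta, pitch=result.pitch)


def _row_mean_v(row: list[Cell], theta: float) -> float:
    vs = [_derotate(c.x, c.y, theta)[1] for c in row if c.kind != "empty"]
    return float(np.mean(vs)) if vs else math.nan


def postprocess(
    grid: GridAssignment, params: GriddingParams | None = None
) -> GridAssignment:
    """Merge near-coincident rows, fill gaps, adopt strays, trim borders.

    Adjacent rows closer than ``row_merge_factor * D`` across-row are merged
    (collisions of two real cells mark the later one an artefact).  Empty
    cells are filled with imaginary centroids by per-row linear regression
    (falling back to columns).  Unassigned vertices within
    ``neighbour_threshold_factor * D`` of an imaginary centroid adopt its
    cell; the rest become artefacts.  All-imaginary boundary rows and columns
    are trimmed.
    """
    params = params or GriddingParams()
    D = grid.pitch
    theta = grid.theta
    cells = [list(row) for row in grid.cells]
    artefacts = list(grid.artefacts)

    # --- merge rows whose across-row spacing collapses
    merged = True
    while merged and len(cells) > 1:
        merged = False
        vs = [_row_mean_v(row, theta) for row in cells]
        for r in range(len(cells) - 1):
            if math.isnan(vs[r]) or math.isnan(vs[r + 1]):
                continue
            if abs(vs[r + 1] - vs[r]) < params.row_merge_factor * D:
                top, bottom = cells[r], cells[r + 1]
                out = []
                for a, b in zip(top, bottom):
                    if a.kind == "real" and b.kind == "real":
                        artefacts.append(b.vertex)
                        out.append(a)
                    elif a.kind == "real":
                        out.append(a)
                    elif b.kind == "real":
                        out.append(b)
                    elif a.kind != "empty":
                        out.append(a)
                    else:
                        out.append(b)
                cells[r:r + 2] = [out]
                merged = True
                break

    # --- fill empty cells with imaginary centroids
    n_rows = len(cells)
    n_cols = len(cells[0]) if cells else 0

    def fit_positions(known: list[tuple[int, Cell]], idx: int):
        ks = np.array([k for k, _ in known], dtype=float)
        xs = np.array([c.x for _, c in known])
        ys = np.array([c.y for _, c in known])
        if len(known) >= 2:
            px = np.polyfit(ks, xs, 1)
            py = np.polyfit(ks, ys, 1)
            return float(np.polyval(px, idx)), float(np.polyval(py, idx))
        return float(xs[0]), float(ys[0])

    for r in range(n_rows):
        known_r = [(c, cells[r][c]) for c in range(n_cols)
                   if cells[r][c].kind != "empty"]
        for c in range(n_cols):
            if cells[r][c].kind != "empty":
                continue
            known_c = [(rr, cells[rr][c]) for rr in range(n_rows)
                       if cells[rr][c].kind != "empty"]
            if len(known_r) >= 2:
                x, y = fit_positions(known_r, c)
            elif len(known_c) >= 2:
                x, y = fit_positions(known_c, r)
            elif known_r or known_c:
                x, y = fit_positions(known_r or known_c, c if known_r else r)
            else:
                x = y = math.nan
            cells[r][c] = Cell("imaginary", x=x, y=y)

    # --- adopt unassigned vertices or mark them artefacts
    pts = grid.points
    for v in grid.unassigned:
        best = None
        for r in range(n_rows):
            for c in range(n_cols):
                cell = cells[r][c]
                if cell.kind != "imaginary" or math.isnan(cell.x):
                    continue
                d = math.hypot(pts[v][0] - cell.x, pts[v][1] - cell.y)
                if best is None or d < best[0]:
                    best = (d, r, c)
        if best is not None and best[0] <= params.neighbour_threshold_factor * D:
            _, r, c = best
            cells[r][c] = Cell("real", vertex=v, x=float(pts[v][0]),
                               y=float(pts[v][1]))
        else:
            artefacts.append(v)

    # --- trim all-imaginary boundary rows/columns
    def row_all_imaginary(r):
        return all(c.kind == "imaginary" for c in cells[r])

    def col_all_imaginary(c):
        return all(row[c].kind == "imaginary" for row in cells)

    while cells and row_all_imaginary(0):
        cells.pop(0)
    while cells and row_all_imaginary(len(cells) - 1):
        cells.pop()
    while cells and cells[0] and col_all_imaginary(0):
        for row in cells:
            row.pop(0)
    while cells and cells[0] and col_all_imaginary(len(cells[0]) - 1):
        for row in cells:
            row.pop()

    return GridAssignment(cells=cells, artefacts=sorted(set(artefacts)),
                          unassigned=[], points=pts, theta=theta, pitch=D)


def grid_points(centroids: np.ndarray, width: float,
                params: GriddingParams | None = None) -> GridAssignment:
    """Full gridding chain: triangulate, filter, travel, assign, post-process."""
    params = params or GriddingParams()
    graph = build_triangulation(centroids)
    length_idx = filter_edges_by_length(graph, params)
    angle_idx, theta = filter_edges_by_angle(graph, params)
    template = make_template(graph, length_idx, angle_idx, theta)
    result = travel(template, width, params)
    grid = assign_rows_and_columns(result)
    return postprocess(grid, params)


def grid_accuracy(grid: GridAssignment, truth, tol: float = 5.0) -> float:
    """Fraction of true cores assigned their true (row, column) index.

    ``truth`` holds rows ``(core_id, row, col, cx, cy)`` with 0-based indices.
    Each real cell is matched to the nearest unmatched truth centroid within
    ``tol`` pixels; unmatched truth cores count as wrong.
    """
    truth = list(truth)
    if not truth:
        raise ValueError("empty ground truth")
    txy = np.array([[t[3], t[4]] for t in truth])
    claimed = np.zeros(len(truth), dtype=bool)
    correct = 0
    for r, c, cell in grid.real_cells():
        d = np.hypot(txy[:, 0] - cell.x, txy[:, 1] - cell.y)
        d[claimed] = np.inf
        j = int(d.argmin())
        if d[j] > tol:
            continue
        claimed[j] = True
        if truth[j][1] == r and truth[j][2] == c:
            correct += 1
    return correct / len(truth)
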