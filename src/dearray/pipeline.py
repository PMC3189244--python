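"""The three-phase de-arraying pipeline and its reporting plumbing.

``run_dearray`` executes segmentation, gridding and (optionally) mapping on a
thumbnail and writes the record tables, labeled mask and annotated overlay.
``run_suite_eval`` regenerates the pseudo-slide suite and scores gridding
accuracy against ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import gridding, pseudo_sim, segmentation
from .config import PipelineConfig
from .gridding import GridAssignment, grid_accuracy, row_label
from .mapping import DearrayRecord, TMAMapGrid, map_names, orient

__all__ = [
    "RunReport",
    "run_dearray",
    "run_suite_eval",
    "render_overlay",
    "load_thumbnail",
    "write_suite",
    "read_suite",
]


@dataclass
class RunReport:
    """Per-stage counts and estimates for one de-arraying run."""

    n_candidates: int = 0
    n_fragments_joined: int = 0
    n_rows: int = 0
    n_cols: int = 0
    n_gridded: int = 0
    n_artefacts: int = 0
    theta: float = 0.0
    pitch: float = float("nan")
    accuracy: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def check_conservation(self) -> bool:
        """Every candidate ends up either gridded or an artefact."""
        return self.n_gridded + self.n_artefacts == self.n_candidates


def load_thumbnail(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG thumbnail as a numpy array."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 2 and arr.dtype == np.uint8 and set(np.unique(arr)) <= {0, 1, 255}:
        return arr > 0  # binary mask image
    return arr


def run_dearray(
    image: np.ndarray | str | Path,
    tmamap: TMAMapGrid | None = None,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    truth=None,
) -> tuple[list[DearrayRecord] | None, GridAssignment, RunReport]:
    """Segment, grid, and (when a map is given) name the cores of one slide.

    Returns ``(records, grid, report)``; ``records`` is None without a map.
    When ``out_dir`` is set, the record CSV/JSON, grid CSV, labeled mask and
    overlay PNG are written there.
    """
    config = config or PipelineConfig()
    if not isinstance(image, np.ndarray):
        image = load_thumbnail(image)

    seg = segmentation.segment(image, config.segmentation)
    report = RunReport(
        n_candidates=len(seg.candidates),
        n_fragments_joined=seg.fragments_joined,
        warnings=list(seg.warnings),
    )
    if len(seg.candidates) < 3:
        raise ValueError(f"segmentation: only {len(seg.candidates)} candidates; "
                         "cannot grid")
    centroids = np.array([c.centroid for c in seg.candidates])
    grid = gridding.grid_points(centroids, image.shape[1], config.gridding)
    report.n_rows, report.n_cols = grid.n_rows, grid.n_cols
    report.n_gridded = sum(1 for _ in grid.real_cells())
    report.n_artefacts = len(grid.artefacts)
    report.theta = grid.theta
    report.pitch = grid.pitch
    if truth is not None:
        report.accuracy = grid_accuracy(grid, truth)

    records = None
    if tmamap is not None:
        oriented = orient(tmamap, config.orientation)
        bboxes = {i: c.bbox for i, c in enumerate(seg.candidates)}
        records = map_names(grid, oriented, bboxes, scale=config.downsample)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_grid_csv(grid, out / "grid.csv")
        _write_mask(seg.mask, out / "labels.png")
        overlay = render_overlay(image, grid, records)
        overlay.save(out / "overlay.png")
        if records is not None:
            _write_records(records, out / "records.csv")
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return records, grid, report


def _write_grid_csv(grid: GridAssignment, path: Path) -> None:
    rows = []
    for r, row in enumerate(grid.cells):
        for c, cell in enumerate(row):
            rows.append({
                "row_label": row_label(r), "col_index": c + 1,
                "kind": cell.kind, "cx": cell.x, "cy": cell.y,
            })
    for v in grid.artefacts:
        x, y = grid.points[v] if grid.points is not None else (np.nan, np.nan)
        rows.append({"row_label": "", "col_index": 0, "kind": "artefact",
                     "cx": x, "cy": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_mask(mask: np.ndarray, path: Path) -> None:
    from skimage import measure

    lbl = measure.label(mask, connectivity=2).astype(np.uint16)
    Image.fromarray(lbl).save(path)  # 16-bit PNG


def _write_records(records: list[DearrayRecord], path: Path) -> None:
    rows = []
    for rec in records:
        tb = rec.thumb_bbox or (None,) * 4
        sb = rec.slide_bbox or (None,) * 4
        rows.append({
            "name": rec.name, "row_label": rec.row_label,
            "col_index": rec.col_index, "kind": rec.kind,
            "thumb_x": tb[0], "thumb_y": tb[1], "thumb_w": tb[2], "thumb_h": tb[3],
            "slide_x": sb[0], "slide_y": sb[1], "slide_w": sb[2], "slide_h": sb[3],
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def render_overlay(
    image: np.ndarray,
    grid: GridAssignment,
    records: list[DearrayRecord] | None = None,
) -> Image.Image:
    """Draw cell labels onto the thumbnail.

    Real cells get their mapped name (or logical index without a map),
    missing positions ``M``, unoccupied cores ``U``, artefacts ``A``.
    """
    if image.dtype == bool:
        base = (np.where(image, 0, 255)).astype(np.uint8)
    else:
        base = image
    im = Image.fromarray(base).convert("RGB")
    draw = ImageDraw.Draw(im)
    labels: dict[tuple[int, int], str] = {}
    if records is not None:
        for rec in records:
            if rec.kind != "artefact":
                labels[(rec.row_label, rec.col_index)] = rec.name
    for r, row in enumerate(grid.cells):
        for c, cell in enumerate(row):
            if np.isnan(cell.x):
                continue
            key = (row_label(r), c + 1)
            if cell.kind == "real":
                text = labels.get(key, f"{key[0]}{key[1]}")
                color = (200, 30, 30)
            elif cell.kind == "imaginary" and key in labels:
                text = labels[key]  # "M"
                color = (30, 30, 200)
            else:
                continue
            draw.text((cell.x, cell.y), text, fill=color, anchor="mm")
    if grid.points is not None:
        for v in grid.artefacts:
            x, y = grid.points[v]
            draw.text((x, y), "A", fill=(30, 160, 30), anchor="mm")
    return im


def run_suite_eval(
    seed: int,
    config: PipelineConfig | None = None,
    slides: list[pseudo_sim.PseudoSlide] | None = None,
) -> pd.DataFrame:
    """Grid every suite slide and score against its ground truth.

    Returns one row per slide with the case set, its parameters, core counts
    and gridding accuracy.  Failures are recorded with accuracy 0 rather than
    raised, so a deliberately broken configuration degrades gracefully.
    """
    config = config or PipelineConfig()
    if slides is None:
        slides = pseudo_sim.generate_suite(seed)
    rows = []
    for i, slide in enumerate(slides):
        truth = slide.truth()
        entry = {
            "case": i,
            "case_set": slide.provenance.get("case_set", "custom"),
            "params": json.dumps(slide.provenance.get("params", {})),
            "n_cores": len(truth),
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, _, report = run_dearray(slide.render(), config=config,
                                           truth=truth)
            entry["accuracy"] = report.accuracy
            entry["n_gridded"] = report.n_gridded
        except ValueError as exc:
            entry["accuracy"] = 0.0
            entry["n_gridded"] = 0
            entry["error"] = str(exc)
        rows.append(entry)
    return pd.DataFrame(rows)


def write_suite(slides, out_dir: str | Path, seed: int | None = None) -> None:
    """Write suite slides as PNG masks + truth CSVs + a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, slide in enumerate(slides):
        stem = f"case_{i:03d}"
        img = slide.render()
        Image.fromarray((img * 255).astype(np.uint8)).save(out / f"{stem}.png")
        pd.DataFrame(slide.truth(),
                     columns=["core_id", "row", "col", "cx", "cy"]
                     ).to_csv(out / f"{stem}_truth.csv", index=False)
        manifest.append({
            "case": i, "image": f"{stem}.png", "truth": f"{stem}_truth.csv",
            "case_set": slide.provenance.get("case_set"),
            "params": slide.provenance.get("params"),
        })
    (out / "manifest.json").write_text(
        json.dumps({"seed": seed, "cases": manifest}, indent=2))


def read_suite(suite_dir: str | Path):
    """Load a directory written by :func:`write_suite`.

    Yields ``(case dict, image array, truth list)`` per case.
    """
    suite_dir = Path(suite_dir)
    manifest = json.loads((suite_dir / "manifest.json").read_text())
    for case in manifest["cases"]:
        img = load_thumbnail(suite_dir / case["image"])
        truth_df = pd.read_csv(suite_dir / case["truth"])
        truth = list(truth_df.itertuples(index=False, name=None))
        yield case, img, truth
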