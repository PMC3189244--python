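"""Correlating a grid assignment with a TMAMap of core names.

A TMAMap is a rectangular block of core names (CSV or XLSX) mirroring the
planned array layout.  After the user states the slide orientation (one of 8:
four right-angle rotations, each optionally preceded by a horizontal flip),
names are attached to grid cells; planned-but-empty positions are reported as
``U`` (unoccupied) and named-but-absent cores as ``M`` (missing).  Thumbnail
coordinates are scaled back to the original slide resolution by the
downsample factor (100 per axis by default).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gridding import GridAssignment, row_label

__all__ = [
    "TMAMapGrid",
    "ORIENTATIONS",
    "DearrayRecord",
    "parse_tmamap",
    "orient",
    "inverse_orientation",
    "map_names",
]

#: the 8 possible slide orientations: R<degrees clockwise>[F], F = horizontal
#: flip applied before the rotation
ORIENTATIONS = ("R0", "R90", "R180", "R270", "R0F", "R90F", "R180F", "R270F")

_INVERSE = {
    "R0": "R0", "R90": "R270", "R180": "R180", "R270": "R90",
    "R0F": "R0F", "R90F": "R90F", "R180F": "R180F", "R270F": "R270F",
}


@dataclass
class TMAMapGrid:
    """Rectangular matrix of core names; empty strings mark planned gaps."""

    names: list[list[str]]

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.names}
        if len(widths) > 1:
            raise ValueError("TMAMap rows are ragged")

    @property
    def n_rows(self) -> int:
        return len(self.names)

    @property
    def n_cols(self) -> int:
        return len(self.names[0]) if self.names else 0


@dataclass
class DearrayRecord:
    """One de-arrayed core: name, logical index and both-scale boxes."""

    name: str
    row_label: str
    col_index: int
    kind: str  # "real" | "imaginary" | "artefact"
    thumb_bbox: tuple[int, int, int, int] | None
    slide_bbox: tuple[int, int, int, int] | None


def _clean(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and np.isnan(value):
        return ""
    return str(value).strip()


def parse_tmamap(path: str | Path) -> TMAMapGrid:
    """Read a TMAMap name block from a CSV or XLSX file.

    Names are taken verbatim (bracket suffixes and all); blank cells are
    preserved as empty strings.  Fully blank border rows/columns are trimmed.
    CSV rows of unequal length raise an error naming the offending row.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
        ws = wb.active
        rows = [[_clean(c) for c in row] for row in ws.iter_rows(values_only=True)]
        wb.close()
        width = max((len(r) for r in rows), default=0)
        rows = [r + [""] * (width - len(r)) for r in rows]
    else:
        with open(path, newline="") as fh:
            rows = [[_clean(c) for c in row] for row in csv.reader(fh)]
        widths = {len(r) for r in rows}
        if len(widths) > 1:
            expected = len(rows[0])
            for i, r in enumerate(rows):
                if len(r) != expected:
                    raise ValueError(
                        f"TMAMap row {i + 1} has {len(r)} columns, "
                        f"expected {expected}"
                    )
    # trim fully blank border rows/columns (metadata padding)
    while rows and all(v == "" for v in rows[0]):
        rows.pop(0)
    while rows and all(v == "" for v in rows[-1]):
        rows.pop()
    if not rows:
        raise ValueError(f"TMAMap {path} contains no names")
    keep = [j for j in range(len(rows[0]))
            if any(r[j] != "" for r in rows)]
    lo, hi = keep[0], keep[-1]
    rows = [r[lo:hi + 1] for r in rows]
    return TMAMapGrid(names=rows)


def orient(tmamap: TMAMapGrid, code: str) -> TMAMapGrid:
    """Transform the name matrix into slide orientation ``code``.

    The flip (if any) is applied first, then the clockwise rotation.
    ``orient(orient(m, code), inverse_orientation(code))`` restores ``m``.
    """
    if code not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {code!r}; pick from {ORIENTATIONS}")
    arr = np.array(tmamap.names, dtype=object)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if code.endswith("F"):
        arr = np.fliplr(arr)
    k = int(code.lstrip("R").rstrip("F")) // 90
    arr = np.rot90(arr, k=-k)  # numpy rotates CCW; codes are clockwise
    return TMAMapGrid(names=[list(r) for r in arr])


def inverse_orientation(code: str) -> str:
    """Orientation code that undoes ``code``."""
    if code not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {code!r}")
    return _INVERSE[code]


def map_names(
    grid: GridAssignment,
    tmamap: TMAMapGrid,
    bboxes: dict[int, tuple[int, int, int, int]] | None = None,
    scale: int = 100,
) -> list[DearrayRecord]:
    """Attach TMAMap names to grid cells and scale coordinates up.

    Real cells take the planned name (or ``U`` when the map cell is blank);
    imaginary cells with a planned name become ``M`` records.  Artefact
    vertices are listed without names.  ``bboxes`` maps vertex id to the
    thumbnail bounding box ``(x, y, w, h)``; slide boxes are the same boxes
    with every number multiplied by ``scale``.
    """
    if (grid.n_rows, grid.n_cols) != (tmamap.n_rows, tmamap.n_cols):
        raise ValueError(
            f"grid shape {grid.n_rows}x{grid.n_cols} does not match "
            f"TMAMap shape {tmamap.n_rows}x{tmamap.n_cols}"
        )
    bboxes = bboxes or {}
    sizes = [(w, h) for (_, _, w, h) in bboxes.values()]
    med_w = int(np.median([w for w, _ in sizes])) if sizes else 0
    med_h = int(np.median([h for _, h in sizes])) if sizes else 0

    records: list[DearrayRecord] = []
    seen_names: set[str] = set()
    for r, row in enumerate(grid.cells):
        for c, cell in enumerate(row):
            name = tmamap.names[r][c]
            if cell.kind == "real":
                record_name = name if name else "U"
            elif cell.kind == "imaginary" and name:
                record_name = "M"
            else:
                continue
            if name and name in seen_names:
                warnings.warn(f"duplicate TMAMap name {name!r}")
            if name:
                seen_names.add(name)
            if cell.kind == "real" and cell.vertex in bboxes:
                tb = bboxes[cell.vertex]
            elif not np.isnan(cell.x) and med_w:
                tb = (int(round(cell.x - med_w / 2)),
                      int(round(cell.y - med_h / 2)), med_w, med_h)
            else:
                tb = None
            sb = tuple(v * scale for v in tb) if tb else None
            records.append(DearrayRecord(
                name=record_name, row_label=row_label(r), col_index=c + 1,
                kind=cell.kind, thumb_bbox=tb, slide_bbox=sb,
            ))
    for v in grid.artefacts:
        tb = bboxes.get(v)
        sb = tuple(val * scale for val in tb) if tb else None
        records.append(DearrayRecord(
            name="", row_label="", col_index=0, kind="artefact",
            thumb_bbox=tb, slide_bbox=sb,
        ))
    return records
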