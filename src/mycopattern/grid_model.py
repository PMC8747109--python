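"""Data model, I/O and rendering for coded microscopic-field grids.

A single microscopic field of a cleared and stained root fragment is scored
on a 10x10 grid. Each cell receives one integer code for the fungal
structure occupying it (hyphae, arbuscule, vesicle, spore, auxiliary cell,
entry point) or 0 for a non-colonized cell. Rows are transverse positions in
the field of view; columns run along the root axis. A dataset is a
collection of such grids, one per (replication, segment, field) triple.

Grids travel as long-format CSV tables (one row per non-empty cell) and are
rendered as color-coded colonization maps: hyphae blue, arbuscules red,
vesicles green, entry points purple, non-colonized cells white.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

logger = logging.getLogger(__name__)

GRID_SIZE = 10
N_CELLS = GRID_SIZE * GRID_SIZE

#: side length in pixels of one grid cell in exported PNG maps
CELL_PX = 16

GRID_TABLE_COLUMNS = ["replication", "segment", "field", "row", "col", "code"]


class StructureCode(enum.IntEnum):
    """Integer code for the fungal structure occupying one grid cell."""

    EMPTY = 0
    HYPHAE = 1
    ARBUSCULE = 2
    VESICLE = 3
    SPORE = 4
    AUXILIARY_CELL = 5
    ENTRY_POINT = 6

    @property
    def label(self) -> str:
        return self.name.lower()


#: map legend: every structure gets one fixed color. Spore/auxiliary-cell
#: colors are an artifact convention (they are rare and have no canonical
#: color); the rest follow the standard colonization-map palette.
CODE_COLORS: dict[StructureCode, str] = {
    StructureCode.EMPTY: "white",
    StructureCode.HYPHAE: "blue",
    StructureCode.ARBUSCULE: "red",
    StructureCode.VESICLE: "green",
    StructureCode.SPORE: "orange",
    StructureCode.AUXILIARY_CELL: "yellow",
    StructureCode.ENTRY_POINT: "purple",
}

COLOR_TO_CODE: dict[str, StructureCode] = {v: k for k, v in CODE_COLORS.items()}

#: one character per code for plain-text maps, indexed by code value
CODE_CHARS = ".HAVSXE"
CHAR_TO_CODE = {c: StructureCode(i) for i, c in enumerate(CODE_CHARS)}

#: RGB triples used in PNG export (CSS color names resolved once)
_COLOR_RGB: dict[str, tuple[int, int, int]] = {
    "white": (255, 255, 255),
    "blue": (43, 87, 184),
    "red": (205, 43, 30),
    "green": (39, 138, 62),
    "orange": (233, 133, 27),
    "yellow": (238, 210, 2),
    "purple": (122, 55, 160),
}


class GridTableError(ValueError):
    """Raised for malformed grid tables (bad codes, indices, duplicates)."""


class ObservationID(NamedTuple):
    """Identity of one microscopic field within the sampling design."""

    replication: int
    segment: int
    field: int


@dataclass
class ColonizationGrid:
    """One scored microscopic field: a 10x10 array of structure codes."""

    id: ObservationID
    cells: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells, dtype=np.int8)
        if cells.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"grid must be {GRID_SIZE}x{GRID_SIZE}, got {cells.shape}")
        if cells.min() < 0 or cells.max() > max(StructureCode):
            raise ValueError("cell codes must be in 0..6")
        self.cells = cells

    def counts(self) -> dict[StructureCode, int]:
        """Number of cells holding each structure code (including empty)."""
        binc = np.bincount(self.cells.ravel(), minlength=len(StructureCode))
        return {code: int(binc[code]) for code in StructureCode}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ColonizationGrid):
            return NotImplemented
        return self.id == other.id and np.array_equal(self.cells, other.cells)


@dataclass
class ColorMap:
    """Color-coded rendering of a grid (or a horizontal montage of grids).

    ``cell_colors`` holds one color name per cell; ``legend`` maps structure
    codes to colors and is bijective, so a ColorMap can be converted back to
    codes losslessly.
    """

    cell_colors: np.ndarray  # 2-D object array of color names
    legend: dict[StructureCode, str] = field(default_factory=lambda: dict(CODE_COLORS))

    def to_codes(self) -> np.ndarray:
        inv = {v: int(k) for k, v in self.legend.items()}
        return np.vectorize(inv.__getitem__, otypes=[np.int8])(self.cell_colors)

    def color_counts(self) -> dict[str, int]:
        colors, counts = np.unique(self.cell_colors, return_counts=True)
        return dict(zip(colors.tolist(), counts.tolist()))


# ---------------------------------------------------------------------------
# Grid-table I/O
# ---------------------------------------------------------------------------

def read_grid_table(path: str | Path) -> list[ColonizationGrid]:
    """Read a long-format grid table (CSV) into one grid per observation.

    The table has columns ``replication,segment,field,row,col,code`` with
    1-based row/col; cells absent from the table are non-colonized (code 0).
    Grids are returned sorted by (replication, segment, field).

    Raises
    ------
    GridTableError
        On missing columns, codes outside 0-6, row/col outside 1-10, or
        duplicate (observation, row, col) entries; messages carry the
        offending file line numbers (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in GRID_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GridTableError(f"{path}: missing columns {missing}")
    df = df[GRID_TABLE_COLUMNS].astype(int)
    # +2: pandas index 0 is file line 2 (after the header)
    lines = df.index + 2

    bad = ~df["code"].between(0, int(max(StructureCode)))
    if bad.any():
        raise GridTableError(
            f"{path}: code outside 0-6 at line(s) {lines[bad].tolist()}"
        )
    for col in ("row", "col"):
        bad = ~df[col].between(1, GRID_SIZE)
        if bad.any():
            raise GridTableError(
                f"{path}: {col} outside 1-{GRID_SIZE} at line(s) {lines[bad].tolist()}"
            )
    key = ["replication", "segment", "field", "row", "col"]
    dup = df.duplicated(key, keep=False)
    if dup.any():
        raise GridTableError(
            f"{path}: duplicate cell entries at lines {lines[dup].tolist()}"
        )

    grids = []
    for (rep, seg, fld), sub in df.groupby(["replication", "segment", "field"], sort=True):
        cells = np.zeros((GRID_SIZE, GRID_SIZE), dtype=np.int8)
        cells[sub["row"] - 1, sub["col"] - 1] = sub["code"]
        grids.append(ColonizationGrid(ObservationID(int(rep), int(seg), int(fld)), cells))
    return grids


def write_grid_table(grids: Sequence[ColonizationGrid], path: str | Path) -> Path:
    """Write grids as a sparse long-format CSV (one row per non-empty cell).

    An all-empty grid is represented by a single explicit code-0 row so that
    the observation survives the round trip. Output rows are sorted by
    observation id, then row, then col.
    """
    if not grids:
        raise ValueError("no grids to write")
    path = Path(path)
    rows = []
    for grid in sorted(grids, key=lambda g: g.id):
        rr, cc = np.nonzero(grid.cells)
        if len(rr) == 0:
            rows.append((*grid.id, 1, 1, 0))
            continue
        for r, c in zip(rr, cc):
            rows.append((*grid.id, int(r) + 1, int(c) + 1, int(grid.cells[r, c])))
    pd.DataFrame(rows, columns=GRID_TABLE_COLUMNS).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_map(grid: ColonizationGrid) -> ColorMap:
    """Convert a coded grid into its color-coded colonization map."""
    palette = np.array([CODE_COLORS[code] for code in StructureCode], dtype=object)
    return ColorMap(cell_colors=palette[grid.cells])


def concat_maps(maps: Sequence[ColorMap]) -> ColorMap:
    """Horizontal montage of several maps (e.g. the 15 fields of a segment)."""
    if not maps:
        raise ValueError("no maps to concatenate")
    return ColorMap(
        cell_colors=np.hstack([m.cell_colors for m in maps]),
        legend=dict(maps[0].legend),
    )


def map_to_text(cmap: ColorMap) -> str:
    """Plain-text map: one line per grid row, one character per cell."""
    codes = cmap.to_codes()
    return "\n".join("".join(CODE_CHARS[c] for c in row) for row in codes) + "\n"


def parse_text_map(text: str, id: ObservationID | None = None) -> ColonizationGrid:
    """Inverse of :func:`map_to_text` for a single 10x10 map."""
    rows = [line for line in text.splitlines() if line]
    cells = np.array([[int(CHAR_TO_CODE[ch]) for ch in line] for line in rows], dtype=np.int8)
    return ColonizationGrid(id or ObservationID(0, 0, 0), cells)


def _render_png(cmap: ColorMap, path: Path) -> None:
    nrow, ncol = cmap.cell_colors.shape
    legend_h = CELL_PX + 12
    img = Image.new("RGB", (ncol * CELL_PX, nrow * CELL_PX + legend_h), "white")
    draw = ImageDraw.Draw(img)
    for r in range(nrow):
        for c in range(ncol):
            rgb = _COLOR_RGB[cmap.cell_colors[r, c]]
            draw.rectangle(
                [c * CELL_PX, r * CELL_PX, (c + 1) * CELL_PX - 1, (r + 1) * CELL_PX - 1],
                fill=rgb,
            )
    # legend strip: one swatch per structure, in code order
    y0 = nrow * CELL_PX + 6
    x = 2
    for code, color in cmap.legend.items():
        draw.rectangle([x, y0, x + CELL_PX - 4, y0 + CELL_PX - 4],
                       fill=_COLOR_RGB[color], outline=(0, 0, 0))
        x += CELL_PX
    img.save(path, format="PNG")


def _render_svg(cmap: ColorMap, path: Path) -> None:
    nrow, ncol = cmap.cell_colors.shape
    s = CELL_PX
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{ncol * s}" height="{nrow * s + 2 * s}">'
    ]
    for r in range(nrow):
        for c in range(ncol):
            parts.append(
                f'<rect x="{c * s}" y="{r * s}" width="{s}" height="{s}" '
                f'fill="{cmap.cell_colors[r, c]}" stroke="gainsboro"/>'
            )
    x = 0
    for code, color in cmap.legend.items():
        parts.append(
            f'<rect x="{x}" y="{nrow * s + s // 2}" width="{s}" height="{s}" '
            f'fill="{color}" stroke="black"/>'
            f'<title>{StructureCode(code).label}</title>'
        )
        x += s + 2
    parts.append("</svg>")
    path.write_text("\n".join(parts))


def export_map_image(cmap: ColorMap, path: str | Path, format: str = "png") -> Path:
    """Export a colonization map as ``png``, ``svg`` or ``text``.

    PNG maps are exact tile rasters (CELL_PX pixels per cell plus a legend
    strip), so identical maps export byte-identically.
    """
    path = Path(path)
    if format == "png":
        _render_png(cmap, path)
    elif format == "svg":
        _render_svg(cmap, path)
    elif format == "text":
        path.write_text(map_to_text(cmap))
    else:
        raise ValueError(f"unknown map format {format!r} (use png, svg or text)")
    return path
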