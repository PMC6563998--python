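"""Raster data model and ESRI ASCII grid I/O.

Every layer in the pipeline — climate covariates, species presence maps,
protection masks — is a :class:`Grid`: a rectangular array of cells with a
cell size in metres, a lower-left origin, and an explicit nodata mask.
Conventions, fixed once for the whole package:

* indices are 0-based ``(row, col)`` with row 0 at the top (north);
* the origin is the lower-left corner, matching the ESRI ASCII dialect;
* two grids are *aligned* iff shape, cell size and origin all agree, and
  every cross-layer operation requires aligned inputs.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "Grid",
    "BinaryGrid",
    "StudyArea",
    "GridParseError",
    "AlignmentError",
    "read_ascii_grid",
    "write_ascii_grid",
    "majority_resample",
    "block_mean_resample",
    "require_aligned",
]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


class GridParseError(ValueError):
    """Raised when an ESRI ASCII grid file is malformed."""


class AlignmentError(ValueError):
    """Raised when an operation receives grids that are not aligned."""


@dataclasses.dataclass
class Grid:
    """A single-band raster.

    Parameters
    ----------
    values
        2-D float array of cell values. Entries under the nodata mask are
        ignored (and written out as the nodata sentinel).
    nodata_mask
        Boolean array, ``True`` where the cell carries no data.
    cellsize
        Cell edge length in metres.
    origin
        ``(x, y)`` of the lower-left corner of the grid.
    nodata_value
        Sentinel written to file for nodata cells.
    """

    values: np.ndarray
    nodata_mask: np.ndarray
    cellsize: float = 500.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.values.shape != self.nodata_mask.shape:
            raise ValueError("values and nodata_mask shapes differ")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def aligned_with(self, other: "Grid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.cellsize, other.cellsize)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
        )

    def copy_with(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "Grid":
        """A new grid sharing this grid's geometry."""
        mask = self.nodata_mask.copy() if nodata_mask is None else np.asarray(nodata_mask, bool)
        return type(self)(
            values=np.asarray(values, float).copy(),
            nodata_mask=mask,
            cellsize=self.cellsize,
            origin=self.origin,
            nodata_value=self.nodata_value,
        )

    def equals(self, other: "Grid") -> bool:
        """Geometry, masks and valid-cell values all equal."""
        if not self.aligned_with(other):
            return False
        if not np.array_equal(self.nodata_mask, other.nodata_mask):
            return False
        v = self.valid_mask
        return np.allclose(self.values[v], other.values[v], rtol=0, atol=1e-9)


class BinaryGrid(Grid):
    """A grid whose valid cells take values in {0, 1}."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = self.values[self.valid_mask]
        if vals.size and not np.all((vals == 0.0) | (vals == 1.0)):
            raise ValueError("BinaryGrid valid cells must be 0 or 1")

    @property
    def presence(self) -> np.ndarray:
        """Boolean array, True where the cell is valid and set to 1."""
        return (self.values == 1.0) & self.valid_mask

    @property
    def n_ones(self) -> int:
        return int(self.presence.sum())


@dataclasses.dataclass
class StudyArea:
    """The set of analyzable (island) cells.

    All species and protection layers must lie inside ``mask``.
    """

    mask: BinaryGrid

    @property
    def cells(self) -> np.ndarray:
        return self.mask.presence

    @property
    def n_cells(self) -> int:
        return self.mask.n_ones

    def contains(self, layer: BinaryGrid) -> bool:
        return bool(np.all(self.cells | ~layer.presence))


def require_aligned(*grids: Grid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.aligned_with(g):
            raise AlignmentError(
                f"grids are not aligned: shape/cellsize/origin "
                f"{(first.nrows, first.ncols, first.cellsize, first.origin)} vs "
                f"{(g.nrows, g.ncols, g.cellsize, g.origin)}"
            )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def read_ascii_grid(path, binary: bool = False) -> Grid:
    """Read an ESRI ASCII grid (.asc).

    The header must provide ncols, nrows, xllcorner, yllcorner, cellsize and
    may provide NODATA_value (default -9999). Raises
    :class:`GridParseError` naming the offending line on malformed input.
    """
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    nodata = -9999.0
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    for i, line in enumerate(lines):
        tokens = line.split()
        if not tokens:
            continue
        key = tokens[0].lower()
        if key in _HEADER_KEYS or key == "nodata_value":
            if len(tokens) != 2:
                raise GridParseError(f"{path}: malformed header line {i + 1}: {line!r}")
            try:
                value = float(tokens[1])
            except ValueError as exc:
                raise GridParseError(f"{path}: bad header value on line {i + 1}: {line!r}") from exc
            if key == "nodata_value":
                nodata = value
            else:
                header[key] = value
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridParseError(f"{path}: missing header keys {missing}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    for j in range(i, len(lines)):
        tokens = lines[j].split()
        if not tokens:
            continue
        try:
            row = [float(t) for t in tokens]
        except ValueError as exc:
            raise GridParseError(f"{path}: non-numeric data on line {j + 1}") from exc
        if len(row) != ncols:
            raise GridParseError(
                f"{path}: line {j + 1} has {len(row)} values, expected ncols={ncols}"
            )
        rows.append(row)
    if len(rows) != nrows:
        raise GridParseError(f"{path}: found {len(rows)} data rows, expected nrows={nrows}")
    values = np.asarray(rows, dtype=float)
    mask = values == nodata
    cls = BinaryGrid if binary else Grid
    return cls(
        values=np.where(mask, 0.0, values),
        nodata_mask=mask,
        cellsize=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata_value=nodata,
    )


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_ascii_grid(grid: Grid, path) -> None:
    """Write a grid as an ESRI ASCII file re-readable by :func:`read_ascii_grid`."""
    out = np.where(grid.nodata_mask, grid.nodata_value, grid.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {_fmt(grid.origin[0])}\n")
        fh.write(f"yllcorner {_fmt(grid.origin[1])}\n")
        fh.write(f"cellsize {_fmt(grid.cellsize)}\n")
        fh.write(f"NODATA_value {_fmt(grid.nodata_value)}\n")
        for row in out:
            fh.write(" ".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def _pad_to_factor(values: np.ndarray, mask: np.ndarray, factor: int):
    """Pad trailing rows/cols with nodata so factor divides both dimensions."""
    nrows, ncols = values.shape
    pr = (-nrows) % factor
    pc = (-ncols) % factor
    if pr or pc:
        values = np.pad(values, ((0, pr), (0, pc)), constant_values=0.0)
        mask = np.pad(mask, ((0, pr), (0, pc)), constant_values=True)
    return values, mask


def _block_view(a: np.ndarray, factor: int) -> np.ndarray:
    nr, nc = a.shape[0] // factor, a.shape[1] // factor
    return a.reshape(nr, factor, nc, factor).transpose(0, 2, 1, 3).reshape(nr, nc, -1)


def majority_resample(grid: BinaryGrid, factor: int) -> BinaryGrid:
    """Aggregate a binary grid by ``factor`` using a majority rule.

    An output cell is 1 iff at least half of its valid source cells are 1
    (ties resolve to presence: a false absence is the costlier error
    downstream), and nodata iff all source cells are nodata. Partial trailing
    blocks are padded with nodata rather than dropped.
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    values, mask = _pad_to_factor(grid.values, grid.nodata_mask, factor)
    vals = _block_view(values, factor)
    valid = _block_view(~mask, factor)
    n_valid = valid.sum(axis=2)
    n_ones = (vals * valid).sum(axis=2)
    out_mask = n_valid == 0
    out_vals = np.zeros(n_valid.shape)
    nz = ~out_mask
    out_vals[nz] = (2 * n_ones[nz] >= n_valid[nz]).astype(float)
    return BinaryGrid(
        values=out_vals,
        nodata_mask=out_mask,
        cellsize=grid.cellsize * factor,
        origin=grid.origin,
        nodata_value=grid.nodata_value,
    )


def block_mean_resample(grid: Grid, factor: int) -> Grid:
    """Aggregate a continuous grid by ``factor`` with a block mean over valid cells.

    Used to bring fine climate surfaces onto the coarser species grid.
    """
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    values, mask = _pad_to_factor(grid.values, grid.nodata_mask, factor)
    vals = _block_view(values, factor)
    valid = _block_view(~mask, factor)
    n_valid = valid.sum(axis=2)
    out_mask = n_valid == 0
    sums = (vals * valid).sum(axis=2)
    out_vals = np.zeros(n_valid.shape)
    nz = ~out_mask
    out_vals[nz] = sums[nz] / n_valid[nz]
    return Grid(
        values=out_vals,
        nodata_mask=out_mask,
        cellsize=grid.cellsize * factor,
        origin=grid.origin,
        nodata_value=grid.nodata_value,
    )
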