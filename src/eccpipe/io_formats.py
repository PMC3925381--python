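"""Grid rasters, environmental stacks, occurrence tables and run configuration.

All spatial layers are plain single-band grids co-registered on a shared
cell geometry.  The on-disk raster format is the ESRI ASCII grid
(``NCOLS/NROWS/XLLCORNER/YLLCORNER/CELLSIZE/NODATA_VALUE`` header followed
by rows of numbers, northernmost row first) — a text format that round-trips
losslessly and needs no GIS stack.  GeoTIFF input is rejected with an
explicit message.

Coordinate convention
---------------------
Row 0 is the northernmost row and cell indices are 0-based.  A map point
``(x, y)`` falls in column ``floor((x - x0) / cell_size)`` and row
``nrows - 1 - floor((y - y0) / cell_size)`` where ``(x0, y0)`` is the
lower-left corner of the grid.  Occurrence CSV files carry map coordinates,
not cell indices; conversion happens at read time.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("eccpipe")

__all__ = [
    "GridRaster",
    "EnvStack",
    "OccurrenceSet",
    "RunConfig",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "read_occurrences",
    "write_occurrences",
]


class RasterFormatError(ValueError):
    """Raised when a raster file cannot be parsed."""


@dataclass
class GridRaster:
    """One co-registered 2-D layer with a validity mask.

    ``mask`` is True on valid (island) cells and False on nodata/ocean
    cells.  ``values`` must be finite wherever ``mask`` is True; masked
    cells may hold anything (they are written out as nodata).
    """

    values: np.ndarray
    mask: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.mask.any() and not np.isfinite(self.values[self.mask]).all():
            raise ValueError(f"raster {self.name!r}: non-finite values on valid cells")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        """Values on valid cells, in row-major cell order."""
        return self.values[self.mask]

    def valid_cells(self) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.mask)
        return list(zip(rows.tolist(), cols.tolist()))

    def with_values(self, values: np.ndarray, name: str | None = None) -> "GridRaster":
        """A new raster on the same grid geometry and mask."""
        return replace(
            self, values=np.asarray(values, dtype=float), name=self.name if name is None else name
        )

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        col = math.floor((x - self.origin[0]) / self.cell_size)
        row = self.nrows - 1 - math.floor((y - self.origin[1]) / self.cell_size)
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def contains_cell(self, row: int, col: int) -> bool:
        return 0 <= row < self.nrows and 0 <= col < self.ncols and bool(self.mask[row, col])


@dataclass
class EnvStack:
    """An ordered, named collection of co-registered layers for one island.

    Must include a layer named ``"elevation"`` (metres).  Every other layer
    is treated as a climate layer.
    """

    layers: dict[str, GridRaster]
    island_id: str

    def __post_init__(self) -> None:
        if "elevation" not in self.layers:
            raise ValueError("EnvStack requires a layer named 'elevation'")
        ref = self.layers["elevation"]
        for name, layer in self.layers.items():
            if layer.values.shape != ref.values.shape:
                raise ValueError(f"layer {name!r} shape differs from elevation")
            if not np.array_equal(layer.mask, ref.mask):
                raise ValueError(f"layer {name!r} mask differs from elevation")
            if layer.cell_size != ref.cell_size or layer.origin != ref.origin:
                raise ValueError(f"layer {name!r} geometry differs from elevation")

    @property
    def elevation(self) -> GridRaster:
        return self.layers["elevation"]

    @property
    def mask(self) -> np.ndarray:
        return self.layers["elevation"].mask

    @property
    def climate_names(self) -> list[str]:
        return [n for n in self.layers if n != "elevation"]

    @property
    def n_valid(self) -> int:
        return self.layers["elevation"].n_valid

    def valid_cells(self) -> list[tuple[int, int]]:
        return self.layers["elevation"].valid_cells()


@dataclass
class OccurrenceSet:
    """Unique presence cells for one ecomorph on one island."""

    ecomorph: str
    island_id: str
    cells: list[tuple[int, int]]

    def __post_init__(self) -> None:
        cells = [(int(r), int(c)) for r, c in self.cells]
        if len(set(cells)) != len(cells):
            raise ValueError(
                f"duplicate cells in OccurrenceSet({self.ecomorph!r}, {self.island_id!r})"
            )
        self.cells = cells

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class RunConfig:
    """Tunable parameters for a full pipeline run.

    Defaults follow the study protocol this pipeline re-implements:
    100 replicate models per ecomorph per island, 5000 background points,
    25% of records held out for testing, k-means with k = 100 for the
    decorrelated point subsamples, and unit ECC weights.
    """

    seed: int = 0
    n_replicates: int = 100
    n_background: int = 5000
    test_fraction: float = 0.25
    regularization: float = 1.0
    ecc_weights: dict[str, float] | None = None
    kmeans_k: int = 100
    points_per_cluster: int = 1
    n_permutations: int = 9999
    elevation_dependence_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_background < 1:
            raise ValueError("n_replicates and n_background must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if not self.regularization > 0:
            raise ValueError("regularization must be > 0")
        if self.kmeans_k < 1 or self.points_per_cluster < 1:
            raise ValueError("kmeans_k and points_per_cluster must be >= 1")
        if not 0 <= self.elevation_dependence_threshold <= 1:
            raise ValueError("elevation_dependence_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__},
                fh,
                sort_keys=True,
            )


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_raster(path: str | Path) -> GridRaster:
    """Read a single-band ESRI ASCII grid.

    Nodata cells become ``mask = False``.  An all-nodata grid is returned
    with an empty mask and a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        raise RasterFormatError(
            f"{path}: GeoTIFF input is not supported; convert to ESRI ASCII grid"
        )
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2:
                raise RasterFormatError(f"{path}: malformed header line {line!r}")
            key = parts[0].lower()
            if key not in _HEADER_KEYS:
                raise RasterFormatError(f"{path}: unexpected header field {parts[0]!r}")
            try:
                header[key] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(
                    f"{path}: cannot parse header field {parts[0]!r} = {parts[1]!r}"
                ) from exc
        for key in _HEADER_KEYS:
            if key not in header:
                raise RasterFormatError(f"{path}: missing header field {key!r}")
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        body = np.loadtxt(fh, dtype=float)
    values = np.atleast_2d(body)
    if values.size != nrows * ncols:
        raise RasterFormatError(
            f"{path}: expected {nrows}x{ncols} values, found {values.size}"
        )
    values = values.reshape(nrows, ncols)
    nodata = header["nodata_value"]
    mask = ~np.isclose(values, nodata, rtol=0.0, atol=1e-9) & np.isfinite(values)
    if not mask.any():
        logger.warning("raster %s: every cell is nodata", path)
    return GridRaster(
        values=values,
        mask=mask,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        name=path.stem,
    )


def write_raster(raster: GridRaster, path: str | Path, nodata: float = -9999.0) -> None:
    """Write an ESRI ASCII grid; masked cells are written as nodata."""
    path = Path(path)
    out = np.where(raster.mask, raster.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"NCOLS {raster.ncols}\n")
        fh.write(f"NROWS {raster.nrows}\n")
        fh.write(f"XLLCORNER {raster.origin[0]:.10g}\n")
        fh.write(f"YLLCORNER {raster.origin[1]:.10g}\n")
        fh.write(f"CELLSIZE {raster.cell_size:.10g}\n")
        fh.write(f"NODATA_VALUE {nodata:.10g}\n")
        for row in out:
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# occurrence I/O
# ---------------------------------------------------------------------------

def read_occurrences(
    path: str | Path,
    stacks: EnvStack | Mapping[str, EnvStack],
) -> list[OccurrenceSet]:
    """Read an occurrence CSV (columns ``ecomorph, island, x, y``).

    Map coordinates are converted to cell indices; records falling off the
    island mask are dropped (count logged); duplicate records within one
    (ecomorph, island, cell) collapse to a single presence cell.  An island
    id with no matching stack is a hard error.
    """
    if isinstance(stacks, EnvStack):
        stacks = {stacks.island_id: stacks}
    df = pd.read_csv(path)
    required = {"ecomorph", "island", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing occurrence columns {sorted(missing)}")
    if df.empty:
        logger.warning("occurrence file %s is empty", path)
        return []
    out: list[OccurrenceSet] = []
    for (ecomorph, island), grp in df.groupby(["ecomorph", "island"], sort=True):
        if island not in stacks:
            raise ValueError(f"{path}: island {island!r} has no environmental stack")
        stack = stacks[island]
        grid = stack.elevation
        cells: list[tuple[int, int]] = []
        dropped = 0
        for x, y in zip(grp["x"], grp["y"]):
            row, col = grid.point_to_cell(float(x), float(y))
            if grid.contains_cell(row, col):
                cells.append((row, col))
            else:
                dropped += 1
        if dropped:
            logger.warning(
                "%s/%s: dropped %d off-mask occurrence record(s)", ecomorph, island, dropped
            )
        unique = sorted(set(cells))
        out.append(OccurrenceSet(ecomorph=str(ecomorph), island_id=str(island), cells=unique))
    return out


def write_occurrences(
    occs: Iterable[OccurrenceSet],
    stacks: Mapping[str, EnvStack],
    path: str | Path,
) -> None:
    """Write occurrence sets to CSV with map coordinates at cell centres."""
    rows = []
    for occ in occs:
        grid = stacks[occ.island_id].elevation
        for r, c in occ.cells:
            x, y = grid.cell_center(r, c)
            rows.append({"ecomorph": occ.ecomorph, "island": occ.island_id, "x": x, "y": y})
    pd.DataFrame(rows, columns=["ecomorph", "island", "x", "y"]).to_csv(path, index=False)


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys, fixed float formatting)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
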