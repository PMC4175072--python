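"""Minimal single-band raster container with ESRI ASCII grid I/O.

Grids are row-major numpy arrays registered to cell centers, row 0 at the
north-west origin. All layers of an analysis share one shape and cell size;
alignment is checked, never resampled. Nodata is carried as NaN in float
grids and as the ``nodata`` sentinel in integer grids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "require_aligned", "read_ascii_grid", "write_ascii_grid",
           "CELL_AREA_HA"]

DEFAULT_NODATA = -9999.0


def CELL_AREA_HA(cell_m: float) -> float:
    """Area of one square cell in hectares."""
    return cell_m**2 / 10_000.0


@dataclass
class Raster:
    values: np.ndarray
    cell_m: float = 30.0
    xll: float = 0.0
    yll: float = 0.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_m <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        if np.issubdtype(self.values.dtype, np.floating):
            return ~np.isnan(self.values) & (self.values != self.nodata)
        return self.values != self.nodata

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and self.cell_m == other.cell_m
            and self.xll == other.xll
            and self.yll == other.yll
        )

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Raster":
        """A new raster with this raster's georeferencing."""
        return Raster(values, self.cell_m, self.xll, self.yll,
                      self.nodata if nodata is None else nodata)


def require_aligned(*rasters: Raster) -> None:
    first = rasters[0]
    for r in rasters[1:]:
        if not first.aligned_with(r):
            raise ValueError(
                f"misaligned rasters: {first.shape}@{first.cell_m} m vs "
                f"{r.shape}@{r.cell_m} m"
            )


def read_ascii_grid(path: str | Path, dtype=float) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"ASCII grid header missing {key}")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    values = np.loadtxt(lines[i:], ndmin=2)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data shape does not match header")
    if dtype is float:
        values = values.astype(float)
        values[values == nodata] = np.nan
    else:
        values = values.astype(dtype)
    return Raster(
        values,
        cell_m=header["cellsize"],
        xll=header.get("xllcorner", 0.0),
        yll=header.get("yllcorner", 0.0),
        nodata=nodata if dtype is not float else np.nan,
    )


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.6g") -> None:
    """Write an ESRI ASCII grid (.asc); NaN cells become the nodata value."""
    vals = np.asarray(raster.values, dtype=float).copy()
    nodata = DEFAULT_NODATA
    vals[~raster.mask] = nodata
    header = (
        f"ncols {vals.shape[1]}\n"
        f"nrows {vals.shape[0]}\n"
        f"xllcorner {raster.xll}\n"
        f"yllcorner {raster.yll}\n"
        f"cellsize {raster.cell_m}\n"
        f"NODATA_value {nodata:g}\n"
    )
    body = "\n".join(" ".join(fmt % v for v in row) for row in vals)
    Path(path).write_text(header + body + "\n")
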