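"""Site-table and raster input/output, plus the two-point isotope normalization.

The site table is a plain :class:`pandas.DataFrame` with at least the columns
``site_id, x, y`` (projected metres, UTM convention — all geometry in this
package is Euclidean) and typically ``altitude`` plus isotope columns named
``d18O_2013, d18O_2014, d2H_2013, d2H_2014`` (per mil vs VSMOW).  Rasters are
carried by a small :class:`Raster` dataclass and serialized as ESRI ASCII
grids, which round-trip bit-exactly through repr-precision floats.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "ISOTOPE_COLUMNS",
    "Raster",
    "read_site_table",
    "write_site_table",
    "read_raster",
    "write_raster",
    "read_ascii_grid",
    "write_ascii_grid",
    "two_point_normalization",
]

log = logging.getLogger("dendroscape")

REQUIRED_COLUMNS = ("site_id", "x", "y")
ISOTOPE_COLUMNS = ("d18O_2013", "d18O_2014", "d2H_2013", "d2H_2014")
COVARIATE_COLUMNS = (
    "altitude",
    "mean_summer_temperature",
    "summer_radiation",
    "canopy_cover",
)


class SchemaError(ValueError):
    """Raised when a site table does not match the expected columns."""


@dataclass
class Raster:
    """Rectangular grid in projected metres.

    ``values`` is row-major with row 0 the northernmost row (as stored in
    ESRI ASCII files); ``x0, y0`` is the lower-left corner of the grid.
    Cell membership uses half-open intervals [edge, edge + cell_size), so a
    point exactly on an edge belongs to the cell whose lower edge it is.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)"""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell_size,
            self.y0 + self.nrows * self.cell_size,
        )

    def cell_index(self, x, y):
        """(row, col) array indices of the cells containing the points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.y0) / self.cell_size).astype(int)
        row = self.nrows - 1 - row_from_bottom
        return row, col

    def cell_centers(self):
        """x- and y-coordinates of cell centres (1-D arrays, map order)."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.y0 + (np.arange(self.nrows)[::-1] + 0.5) * self.cell_size
        return xs, ys

    def mask_valid(self) -> np.ndarray:
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(self.x0, self.y0, self.cell_size, np.array(values), self.nodata)


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------


def read_site_table(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a site-table CSV.

    ``schema`` maps file column names to canonical names (e.g. ``{"ID":
    "site_id", "Elev": "altitude"}``).  Duplicate (x, y) coordinates are
    averaged with a logged warning, since kriging systems are singular under
    exact duplicates.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path} is empty") from exc
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} lacks required columns: {missing}")
    if df.empty:
        raise SchemaError(f"{path} contains no rows")

    numeric_cols = [c for c in df.columns if c != "site_id"]
    for c in numeric_cols:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            raise ValueError(
                f"non-numeric value in column {c!r} at row(s) {list(bad[:5])}"
            ) from exc
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in site table")

    dup = df.duplicated(subset=["x", "y"], keep=False)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} rows share coordinates with another row; "
            "averaging duplicates"
        )
        agg = {c: "mean" for c in numeric_cols if c not in ("x", "y")}
        agg["site_id"] = "first"
        df = df.groupby(["x", "y"], as_index=False, sort=False).agg(agg)
        df = df[[c for c in ("site_id", "x", "y") if c in df.columns]
                + [c for c in df.columns if c not in ("site_id", "x", "y")]]
    if df["site_id"].duplicated().any():
        raise SchemaError("site_id values are not unique")
    return df.reset_index(drop=True)


def write_site_table(df: pd.DataFrame, path, header_lines: list[str] | None = None):
    """Write a site table as CSV; optional ``# key: value`` provenance lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        # default float formatting is shortest-round-trip repr: lossless
        df.to_csv(fh, index=False)
    return path


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ASCII grid header in {path}: missing {key}")
    body = " ".join(lines[i:]).split()
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(body) != nrows * ncols:
        raise ValueError(
            f"{path}: expected {nrows * ncols} cell values, found {len(body)}"
        )
    values = np.array(body, dtype=float).reshape(nrows, ncols)
    return Raster(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell_size=header["cellsize"],
        values=values,
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: Raster, path):
    """Write an ESRI ASCII grid; values at full repr precision round-trip."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.x0!r}\n")
        fh.write(f"yllcorner {raster.y0!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in raster.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    return path


def read_raster(path) -> Raster:
    path = Path(path)
    if path.suffix.lower() in (".asc", ".grd", ".txt"):
        return read_ascii_grid(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raise NotImplementedError(
            "GeoTIFF input requires the optional rasterio dependency; "
            "convert to ESRI ASCII grid (.asc) instead"
        )
    raise ValueError(f"unrecognized raster format: {path.suffix}")


def write_raster(raster: Raster, path):
    path = Path(path)
    if path.suffix.lower() in (".asc", ".grd", ".txt"):
        return write_ascii_grid(raster, path)
    raise ValueError(f"unsupported raster output format: {path.suffix}")


# ---------------------------------------------------------------------------
# isotope normalization
# ---------------------------------------------------------------------------


def two_point_normalization(
    measured_std_a: float,
    measured_std_b: float,
    ref_a: float,
    ref_b: float,
    sample,
):
    """Two-point (linear) normalization of raw delta values.

    Builds the affine map sending the measured values of two certified
    standards to their reference values (e.g. USGS54/USGS56 for δ2H) and
    applies it to ``sample``.  This is how raw instrument deltas are placed
    on the VSMOW scale.
    """
    if measured_std_a == measured_std_b:
        raise ZeroDivisionError(
            "degenerate calibration: the two standards measured identically"
        )
    slope = (ref_b - ref_a) / (measured_std_b - measured_std_a)
    sample = np.asarray(sample, dtype=float)
    out = ref_a + slope * (sample - measured_std_a)
    return float(out) if out.ndim == 0 else out
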