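"""Hydraulic covariate grids: container, finite-difference SVG, ESRI ASCII I/O.

The five covariates (flow velocity, depth, spatial velocity gradient, flow
direction, SVG direction) live on one aligned north-up grid.  Point lookups
use half-open cell intervals ``[x0, x0 + res)`` horizontally and
``(ytop - res, ytop]`` vertically, so a coordinate on a shared edge belongs to
exactly one cell.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInputError, FishSSFError

NODATA = -9999.0

COVARIATE_NAMES = ("velocity", "depth", "svg", "flow_dir", "svg_dir")


@dataclass
class HydraulicRasterStack:
    """Aligned covariate grids plus georeference.

    ``origin_x``/``origin_y`` are the lower-left corner of the grid; row 0 is
    the northernmost row.  ``river_mask`` marks wetted cells; ``usable_mask``
    additionally requires every covariate to be finite (bank cells can lose
    their SVG to one-sided differencing against no-data).
    """

    velocity: np.ndarray
    depth: np.ndarray
    svg: np.ndarray
    flow_dir: np.ndarray
    svg_dir: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    river_mask: np.ndarray
    nodata: float = NODATA
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        shapes = {getattr(self, n).shape for n in COVARIATE_NAMES}
        shapes.add(self.river_mask.shape)
        if len(shapes) != 1:
            raise FishSSFError(f"grids are not aligned: shapes {shapes}")
        self._usable = self.river_mask.copy()
        for name in COVARIATE_NAMES:
            self._usable &= np.isfinite(getattr(self, name))

    @property
    def n_rows(self) -> int:
        return self.depth.shape[0]

    @property
    def n_cols(self) -> int:
        return self.depth.shape[1]

    @property
    def x_max(self) -> float:
        return self.origin_x + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.origin_y + self.n_rows * self.cell_size

    @property
    def usable_mask(self) -> np.ndarray:
        return self._usable

    def cell_index(self, x, y):
        """Map coordinates to (row, col); out-of-extent points get -1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        # (ytop - res, ytop] vertical half-open interval, row 0 at the top:
        # t = (ytop - y)/res falls in [r, r+1) exactly for row r, with an
        # integral t belonging to row t (the closed upper edge of that cell).
        row = np.floor((self.y_max - y) / self.cell_size).astype(int)
        ok = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return np.where(ok, row, -1), np.where(ok, col, -1), ok

    def in_extent(self, x, y):
        _, _, ok = self.cell_index(x, y)
        return ok

    def is_usable(self, x, y):
        row, col, ok = self.cell_index(x, y)
        out = np.zeros_like(ok, dtype=bool)
        out[ok] = self._usable[row[ok], col[ok]]
        return out

    def sample(self, name: str, x, y):
        """Point-in-cell covariate lookup; NaN outside the usable area."""
        if name not in COVARIATE_NAMES:
            raise KeyError(f"unknown covariate grid: {name}")
        grid = getattr(self, name)
        scalar = np.ndim(x) == 0
        row, col, ok = self.cell_index(np.atleast_1d(x), np.atleast_1d(y))
        out = np.full(ok.shape, np.nan, dtype=float)
        good = ok.copy()
        good[ok] = self._usable[row[ok], col[ok]]
        out[good] = grid[row[good], col[good]]
        return float(out[0]) if scalar else out

    def sample_all(self, x, y) -> dict:
        """All five covariates at once (single cell lookup); NaN off-river."""
        row, col, ok = self.cell_index(x, y)
        good = ok.copy()
        good[ok] = self._usable[row[ok], col[ok]]
        out = {}
        for name in COVARIATE_NAMES:
            vals = np.full(np.shape(ok), np.nan, dtype=float)
            vals[good] = getattr(self, name)[row[good], col[good]]
            out[name] = vals
        return out

    def validate(self) -> None:
        m = self.river_mask
        if not m.any():
            raise EmptyInputError("river mask is empty")
        if np.nanmin(self.depth[m]) < 0 or np.nanmin(self.velocity[m]) < 0:
            raise FishSSFError("negative depth or velocity inside the river")
        for name in ("flow_dir", "svg_dir"):
            g = getattr(self, name)[self._usable]
            if g.size and (g.min() < 0 or g.max() >= 360):
                raise FishSSFError(f"{name} outside [0, 360)")


def derive_svg_fields(velocity: np.ndarray, cell_size: float, mask=None):
    """Spatial velocity gradient magnitude (1/s) and bearing of increase.

    Central differences in the interior, one-sided at edges (``np.gradient``),
    with masked cells propagating no-data into their neighbours.
    """
    v = np.asarray(velocity, dtype=float).copy()
    if mask is not None:
        v[~np.asarray(mask, dtype=bool)] = np.nan
    if not np.isfinite(v).any():
        raise EmptyInputError("all cells masked; cannot differentiate")
    if v.shape[0] < 3 or v.shape[1] < 3:
        raise EmptyInputError("need at least a 3x3 grid")
    d_row, d_col = np.gradient(v, cell_size)
    dx = d_col  # east
    dy = -d_row  # north (row index grows southward)
    svg = np.hypot(dx, dy)
    svg_dir = np.degrees(np.arctan2(dx, dy)) % 360.0
    svg_dir = np.where(svg == 0, 0.0, svg_dir)
    svg_dir = np.where(np.isfinite(svg), svg_dir, np.nan)
    if mask is not None:  # the masked cells themselves carry no-data too
        bad = ~np.asarray(mask, dtype=bool)
        svg[bad] = np.nan
        svg_dir[bad] = np.nan
    return svg, svg_dir


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(path, grid, origin_x, origin_y, cell_size, nodata=NODATA):
    g = np.asarray(grid, dtype=float)
    out = np.where(np.isfinite(g), g, nodata)
    header = (
        f"ncols {g.shape[1]}\n"
        f"nrows {g.shape[0]}\n"
        f"xllcorner {origin_x!r}\n"
        f"yllcorner {origin_y!r}\n"
        f"cellsize {cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path):
    """Parse an ESRI ASCII grid; returns (array with NaN no-data, header dict)."""
    header = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner",
                "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FishSSFError(f"{path}: missing ESRI ASCII header field {key}")
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FishSSFError(f"{path}: grid shape does not match header")
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    return data, header


def write_raster_stack(stack: HydraulicRasterStack, directory, discharge):
    """One ASCII file per covariate plus a sidecar naming covariate/discharge."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for name in COVARIATE_NAMES:
        grid = getattr(stack, name).copy()
        grid = np.where(stack.river_mask, grid, np.nan)
        fname = f"{name}_q{int(discharge):03d}.asc"
        write_ascii_grid(
            os.path.join(directory, fname), grid,
            stack.origin_x, stack.origin_y, stack.cell_size, stack.nodata,
        )
        paths[name] = fname
    sidecar = os.path.join(directory, f"stack_q{int(discharge):03d}.yaml")
    import yaml

    with open(sidecar, "w") as fh:
        yaml.safe_dump({"discharge_m3s": float(discharge), "files": paths}, fh)
    return sidecar


def read_raster_stack(sidecar_path) -> HydraulicRasterStack:
    import yaml

    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    directory = os.path.dirname(sidecar_path)
    grids, header = {}, None
    for name in COVARIATE_NAMES:
        grid, hdr = read_ascii_grid(os.path.join(directory, meta["files"][name]))
        if header is None:
            header = hdr
        elif grid.shape != (int(header["nrows"]), int(header["ncols"])):
            raise FishSSFError("covariate grids disagree in shape")
        grids[name] = grid
    mask = np.isfinite(grids["depth"])
    for name in ("flow_dir", "svg_dir"):  # keep directions in range after NaN
        grids[name] = np.where(np.isfinite(grids[name]), grids[name] % 360.0, np.nan)
    return HydraulicRasterStack(
        velocity=grids["velocity"], depth=grids["depth"], svg=grids["svg"],
        flow_dir=grids["flow_dir"], svg_dir=grids["svg_dir"],
        origin_x=header["xllcorner"], origin_y=header["yllcorner"],
        cell_size=header["cellsize"], river_mask=mask,
        meta={"discharge_m3s": meta.get("discharge_m3s")},
    )
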