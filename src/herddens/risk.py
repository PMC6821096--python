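"""Predator-risk surface: a bivariate-normal kernel utilization distribution.

Relocations of the dominant predator are pooled (equal weight per fix) into
a single kernel utilization distribution (UD).  The smoothing bandwidth is
a percentile of the empirical daily-displacement distribution (the 90th by
default), the kernel is an isotropic bivariate normal with SD ``h`` in both
coordinates, and the UD is evaluated on a regular grid (300 m cells by
default) and normalized to integrate to one over the grid.  Segment
midpoints sample the surface bilinearly; values are reported raw and
z-scored across the sampled set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator


def smoothing_bandwidth(daily_displacements, percentile: float = 90.0) -> float:
    """Percentile of daily displacement distances (linear interpolation)."""
    d = np.asarray(daily_displacements, dtype=float)
    if d.size == 0:
        raise ValueError("no displacement distances")
    if np.any(d < 0):
        raise ValueError("displacements must be non-negative")
    return float(np.percentile(d, percentile, method="linear"))


@dataclass
class UDGrid:
    """A gridded utilization distribution.

    ``values[i, j]`` is the density at cell center ``(x0 + j*cell,
    y0 + i*cell)``; densities are normalized so that
    ``values.sum() * cell**2 == 1`` up to grid truncation.
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + self.cell * np.arange(self.values.shape[1])

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + self.cell * np.arange(self.values.shape[0])


def kernel_ud(
    locations,
    h: float,
    cell_size: float = 300.0,
    extent: tuple[float, float, float, float] | None = None,
    *,
    pad_factor: float = 4.0,
) -> UDGrid:
    """Bivariate-normal kernel UD over pooled relocations.

    Parameters
    ----------
    locations
        Array-like of shape (n, 2) or a DataFrame with ``x``/``y`` columns.
    h
        Kernel SD (m), typically from :func:`smoothing_bandwidth`.
    cell_size
        Output grid resolution (m).
    extent
        ``(xmin, xmax, ymin, ymax)``; defaults to the data bounding box
        padded by ``pad_factor * h`` and is expanded (with a note) if it
        does not cover all locations.
    """
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if hasattr(locations, "columns"):
        pts = np.column_stack([locations["x"], locations["y"]]).astype(float)
    else:
        pts = np.asarray(locations, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 1:
        raise ValueError("at least one location required")

    pad = pad_factor * h
    xmin, xmax = pts[:, 0].min() - pad, pts[:, 0].max() + pad
    ymin, ymax = pts[:, 1].min() - pad, pts[:, 1].max() + pad
    if extent is not None:
        exmin, exmax, eymin, eymax = extent
        if exmin > pts[:, 0].min() or exmax < pts[:, 0].max() or (
            eymin > pts[:, 1].min() or eymax < pts[:, 1].max()
        ):
            import warnings

            warnings.warn("extent does not cover all locations; expanding")
            exmin, exmax = min(exmin, xmin), max(exmax, xmax)
            eymin, eymax = min(eymin, ymin), max(eymax, ymax)
        xmin, xmax, ymin, ymax = exmin, exmax, eymin, eymax

    nx = max(int(np.ceil((xmax - xmin) / cell_size)) + 1, 2)
    ny = max(int(np.ceil((ymax - ymin) / cell_size)) + 1, 2)
    xc = xmin + cell_size * np.arange(nx)
    yc = ymin + cell_size * np.arange(ny)

    # (ny, nx) evaluation; loop over points in chunks to bound memory
    vals = np.zeros((ny, nx))
    inv2h2 = 1.0 / (2.0 * h * h)
    norm = 1.0 / (2.0 * np.pi * h * h * pts.shape[0])
    for start in range(0, pts.shape[0], 512):
        chunk = pts[start : start + 512]
        dx2 = (xc[None, :] - chunk[:, 0, None]) ** 2  # (m, nx)
        dy2 = (yc[None, :] - chunk[:, 1, None]) ** 2  # (m, ny)
        vals += np.einsum(
            "my,mx->yx", np.exp(-dy2 * inv2h2), np.exp(-dx2 * inv2h2)
        )
    vals *= norm
    total = vals.sum() * cell_size**2
    if total > 0:
        vals /= total
    return UDGrid(x0=float(xmin), y0=float(ymin), cell=float(cell_size), values=vals)


def extract_standardized(grid: UDGrid, points) -> dict[str, np.ndarray]:
    """Sample the UD at points and z-score across the sampled set.

    Returns raw bilinear samples and their standardization (mean 0, SD 1,
    ``ddof=1``).  A zero-variance extraction yields NaN standardized values
    with ``zero_variance=True``.  Out-of-extent points raise with their
    indices.
    """
    if hasattr(points, "columns"):
        pts = np.column_stack([points["x"], points["y"]]).astype(float)
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
    interp = RegularGridInterpolator(
        (grid.y_centers, grid.x_centers), grid.values, method="linear",
        bounds_error=False, fill_value=np.nan,
    )
    raw = interp(np.column_stack([pts[:, 1], pts[:, 0]]))
    bad = np.flatnonzero(np.isnan(raw))
    if bad.size:
        raise ValueError(f"points outside grid extent at indices {bad.tolist()}")
    sd = raw.std(ddof=1) if raw.size > 1 else 0.0
    if sd > 0:
        z = (raw - raw.mean()) / sd
        zero_var = False
    else:
        z = np.full_like(raw, np.nan)
        zero_var = True
    return {"raw": raw, "standardized": z, "zero_variance": zero_var}


def write_ascii_grid(grid: UDGrid, path) -> None:
    """Write the UD as an ESRI ASCII raster (row 0 at the top)."""
    ny, nx = grid.values.shape
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {grid.x0 - grid.cell / 2}\n"
        f"yllcorner {grid.y0 - grid.cell / 2}\n"
        f"cellsize {grid.cell}\n"
        f"NODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values[::-1], fmt="%.10e")


def read_ascii_grid(path) -> UDGrid:
    """Read an ESRI ASCII raster written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        meta = {}
        for _ in range(6):
            k, v = fh.readline().split()
            meta[k.lower()] = float(v)
        vals = np.loadtxt(fh)
    cell = meta["cellsize"]
    return UDGrid(
        x0=meta["xllcorner"] + cell / 2,
        y0=meta["yllcorner"] + cell / 2,
        cell=cell,
        values=vals[::-1],
    )
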