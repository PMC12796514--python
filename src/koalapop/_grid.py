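"""Planar 1-km analysis grid helpers: closed-form distances and text raster IO.

Coordinates are planar km within the study extent (cell-centre convention,
0-based indices, row-major). Rasters are exchanged as ESRI ASCII grids,
which keeps every layer a plain-text file.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "cell_centres",
    "point_segment_distance",
    "min_distance_to_segments",
    "write_ascii_grid",
    "read_ascii_grid",
]


def cell_centres(extent: tuple[float, float], cell_size: float):
    """Return (xx, yy) arrays of cell-centre coordinates, shape (ny, nx).

    Row 0 is the southern edge (y increasing with row index).
    """
    width, height = extent
    nx = int(round(width / cell_size))
    ny = int(round(height / cell_size))
    if nx < 1 or ny < 1:
        raise ValueError(f"extent {extent} yields an empty grid at cell size {cell_size}")
    x = (np.arange(nx) + 0.5) * cell_size
    y = (np.arange(ny) + 0.5) * cell_size
    return np.meshgrid(x, y)


def point_segment_distance(px, py, ax, ay, bx, by):
    """Euclidean distance from points (px, py) to segment (a, b); broadcasts."""
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    dx, dy = bx - ax, by - ay
    seg2 = dx * dx + dy * dy
    if seg2 == 0.0:
        return np.hypot(px - ax, py - ay)
    t = np.clip(((px - ax) * dx + (py - ay) * dy) / seg2, 0.0, 1.0)
    return np.hypot(px - (ax + t * dx), py - (ay + t * dy))


def min_distance_to_segments(px, py, segments):
    """Minimum distance from points to a list of ((ax, ay), (bx, by)) segments."""
    px = np.asarray(px, dtype=float)
    if not segments:
        return np.full(px.shape, np.inf)
    dists = [point_segment_distance(px, py, ax, ay, bx, by) for (ax, ay), (bx, by) in segments]
    return np.minimum.reduce(dists)


def write_ascii_grid(path, grid, cell_size, xll=0.0, yll=0.0, nodata=-9999.0):
    """Write a 2-D array as an ESRI ASCII grid (row 0 = south)."""
    grid = np.asarray(grid, dtype=float)
    ny, nx = grid.shape
    header = (
        f"ncols {nx}\nnrows {ny}\nxllcorner {xll}\nyllcorner {yll}\n"
        f"cellsize {cell_size}\nNODATA_value {nodata}\n"
    )
    # ESRI convention stores the northern row first
    body = "\n".join(" ".join(f"{v:.8g}" for v in row) for row in grid[::-1])
    with open(path, "w") as fh:
        fh.write(header + body + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns (grid, cell_size) with row 0 = south."""
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh)
    grid = np.atleast_2d(grid)[::-1].copy()
    return grid, header["cellsize"]
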