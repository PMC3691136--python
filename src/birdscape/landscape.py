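"""Landscape composition and configuration metrics in circular buffers.

Implements the eight variables used to characterise habitat around survey
stops: percent forest and percent exurban cover (composition), and for the
forest class the area-weighted average patch size, the number of patches
larger than 0.45 ha, a proximity (isolation) index, and a morphological
partition of forest pixels into interior (core), fragment (islet) and edge
(edge + perforation) classes (configuration).

Conventions
-----------
* A cell belongs to a circular buffer iff its *centre* lies within the
  radius of the stop point.
* Forest patches use 8-connectivity by default (the FRAGSTATS convention);
  background components in the morphological analysis use 4-connectivity,
  the topological complement.
* Patch counting and patch-size metrics are computed on buffer-clipped
  patches; the proximity index searches neighbours on the full raster,
  since its 2500-m search radius exceeds both buffer radii.
* All areas are hectares, all proportions percentages in [0, 100].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .raster import EXURBAN, FOREST, RasterLandscape

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)

# morphological classes for forest cells
MSPA_NONE = 0
MSPA_CORE = 1
MSPA_EDGE = 2
MSPA_PERFORATION = 3
MSPA_ISLET = 4
MSPA_RESIDUAL = 5


class BufferError(ValueError):
    """A requested buffer is not fully contained in the raster."""


@dataclass
class BufferView:
    """A circular buffer over a raster: a window plus an in-circle mask."""

    raster: RasterLandscape
    center: tuple[float, float]
    radius_m: float
    rows: slice
    cols: slice
    mask: np.ndarray  # bool, shape of the window; True = inside the circle

    @property
    def grid(self) -> np.ndarray:
        return self.raster.grid[self.rows, self.cols]

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    def masked_class(self, code: int) -> np.ndarray:
        """Boolean window array: cells of ``code`` inside the buffer."""
        return (self.grid == code) & self.mask


def extract_buffer(
    raster: RasterLandscape,
    center: tuple[float, float],
    radius_m: float,
    stop_id: str | None = None,
) -> BufferView:
    """Extract the circular buffer of ``radius_m`` around ``center``.

    Raises :class:`BufferError` if the circle is clipped by the raster
    boundary (naming the stop when given).
    """
    xmin, ymin, xmax, ymax = raster.extent
    cx, cy = center
    if (cx - radius_m < xmin or cx + radius_m > xmax
            or cy - radius_m < ymin or cy + radius_m > ymax):
        who = f" for stop {stop_id}" if stop_id is not None else ""
        raise BufferError(
            f"buffer of radius {radius_m} m around ({cx}, {cy}){who} "
            "extends beyond the raster boundary"
        )
    nrows, ncols = raster.grid.shape
    cs = raster.cell_size
    # window of candidate cells
    c0 = max(0, int(np.floor((cx - radius_m - raster.origin[0]) / cs)))
    c1 = min(ncols, int(np.ceil((cx + radius_m - raster.origin[0]) / cs)))
    ytop = raster.origin[1] + nrows * cs
    r0 = max(0, int(np.floor((ytop - (cy + radius_m)) / cs)))
    r1 = min(nrows, int(np.ceil((ytop - (cy - radius_m)) / cs)))
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    xs = raster.origin[0] + (cols + 0.5) * cs
    ys = raster.origin[1] + (nrows - rows - 0.5) * cs
    dx = xs[None, :] - cx
    dy = ys[:, None] - cy
    mask = dx * dx + dy * dy <= radius_m * radius_m
    return BufferView(raster, (cx, cy), radius_m,
                      slice(r0, r1), slice(c0, c1), mask)


@dataclass
class PatchSet:
    """Connected components of one class: a label grid plus patch areas."""

    labels: np.ndarray  # int label grid, 0 = background
    areas_ha: np.ndarray  # area of patch i at index i-1
    cell_size: float

    @property
    def n_patches(self) -> int:
        return len(self.areas_ha)


def label_patches(
    class_mask: np.ndarray, cell_size: float, connectivity: int = 8
) -> PatchSet:
    """Label connected components of a boolean class mask.

    ``connectivity`` is 4 or 8; area is ``n_cells * cell_size**2 / 1e4`` ha.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    labels, n = ndimage.label(class_mask, structure=struct)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    areas = counts * cell_size**2 / 1e4
    return PatchSet(labels=labels, areas_ha=areas, cell_size=cell_size)


def composition(buf: BufferView) -> tuple[float, float]:
    """Percent forest and percent exurban cover within the buffer."""
    n = buf.n_cells
    if n == 0:
        raise BufferError("empty buffer")
    forest = int(buf.masked_class(FOREST).sum())
    exurban = int(buf.masked_class(EXURBAN).sum())
    return 100.0 * forest / n, 100.0 * exurban / n


def area_weighted_patch_size(patches: PatchSet) -> float:
    """Area-weighted average patch size, Σaᵢ²/Σaᵢ (ha); 0 with no patches."""
    a = patches.areas_ha
    if a.size == 0 or a.sum() == 0:
        return 0.0
    return float(np.sum(a**2) / np.sum(a))


def count_patches(patches: PatchSet, min_area_ha: float = 0.45) -> int:
    """Number of patches with area strictly greater than ``min_area_ha``."""
    if min_area_ha < 0:
        raise ValueError("min_area_ha must be >= 0")
    return int(np.sum(patches.areas_ha > min_area_ha))


def _edge_cells(labels: np.ndarray, patch_id: int) -> np.ndarray:
    """(row, col) array of the patch's boundary cells (4-neighbour rule;
    cells on the raster border count as boundary)."""
    mask = labels == patch_id
    interior = ndimage.binary_erosion(mask, structure=_STRUCT4, border_value=0)
    return np.argwhere(mask & ~interior)


def proximity_index(
    raster: RasterLandscape,
    full_patches: PatchSet,
    buf: BufferView,
    stop_xy: tuple[float, float],
    neighbor_min_area_ha: float = 100.0,
    search_radius_m: float = 2500.0,
) -> float:
    """Proximity (isolation) index for the focal forest patch at a stop.

    The focal patch is the full-raster forest patch containing the stop's
    cell; if that cell is not forest, the patch of the nearest forest cell
    inside the buffer is used.  The index sums, over forest patches of at
    least ``neighbor_min_area_ha`` whose nearest edge lies within
    ``search_radius_m`` of the focal patch's edge, the neighbour's area in
    m² divided by the squared edge-to-edge distance in m (cell-centre to
    cell-centre).  Returns 0 when there is no forest in the buffer or no
    qualifying neighbour.
    """
    row, col = raster.cell_of(*stop_xy)
    focal = int(full_patches.labels[row, col])
    if focal == 0:
        # nearest forest cell within the buffer
        fcells = np.argwhere(buf.masked_class(FOREST))
        if fcells.size == 0:
            logger.info("no forest within buffer at %s; proximity = 0", stop_xy)
            return 0.0
        rr = fcells[:, 0] + buf.rows.start
        cc = fcells[:, 1] + buf.cols.start
        d2 = (rr - row) ** 2 + (cc - col) ** 2
        k = int(np.argmin(d2))  # ties: first in row-major order
        focal = int(full_patches.labels[rr[k], cc[k]])
    cs = raster.cell_size
    focal_edges = _edge_cells(full_patches.labels, focal) * cs
    tree = cKDTree(focal_edges)
    # candidate neighbours: big enough, not the focal patch
    cand = np.flatnonzero(full_patches.areas_ha >= neighbor_min_area_ha) + 1
    total = 0.0
    for pid in cand:
        if pid == focal:
            continue
        edges = _edge_cells(full_patches.labels, int(pid)) * cs
        d, _ = tree.query(edges, k=1)
        h = float(d.min())
        if h <= search_radius_m and h > 0:
            area_m2 = full_patches.areas_ha[pid - 1] * 1e4
            total += area_m2 / h**2
    return total


def mspa_classify(
    raster: RasterLandscape | np.ndarray,
    target_class: int = FOREST,
    edge_width_cells: int = 1,
) -> np.ndarray:
    """Morphological spatial-pattern partition of the target class.

    Every target-class cell receives exactly one label:

    * ``core`` — Chebyshev distance to the nearest background cell
      exceeds ``edge_width_cells`` (8-neighbour erosion);
    * ``islet`` — member of a patch containing no core;
    * ``perforation`` — non-core cell of a core-bearing patch whose nearby
      background (within the edge width) is only enclosed holes;
    * ``edge`` — non-core cell of a core-bearing patch with outer
      background nearby (outer background wins over holes);
    * ``residual`` — any remaining non-core cell of a core-bearing patch
      (connector-like remnants; empty under the default edge width).

    Background components use 4-connectivity; a component is a hole iff it
    does not touch the raster border.
    """
    if edge_width_cells < 1:
        raise ValueError("edge_width_cells must be >= 1")
    grid = raster.grid if isinstance(raster, RasterLandscape) else np.asarray(raster)
    fg = grid == target_class
    out = np.zeros(fg.shape, dtype=np.int8)
    if not fg.any():
        return out

    core = ndimage.binary_erosion(
        fg, structure=_STRUCT8, iterations=edge_width_cells, border_value=0
    )
    labels, n = ndimage.label(fg, structure=_STRUCT8)
    has_core = np.zeros(n + 1, dtype=bool)
    has_core[np.unique(labels[core])] = True
    islet = fg & ~has_core[labels]

    bg = ~fg
    bg_labels, nb = ndimage.label(bg, structure=_STRUCT4)
    border_ids = np.unique(
        np.concatenate([
            bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]
        ])
    )
    outer = np.isin(bg_labels, border_ids[border_ids > 0])
    hole = bg & ~outer

    near_outer = ndimage.binary_dilation(
        outer, structure=_STRUCT8, iterations=edge_width_cells
    )
    # the area beyond the map acts as outer background (consistent with
    # the border rule of the core erosion)
    w = edge_width_cells
    near_outer[:w, :] = True
    near_outer[-w:, :] = True
    near_outer[:, :w] = True
    near_outer[:, -w:] = True
    near_hole = ndimage.binary_dilation(
        hole, structure=_STRUCT8, iterations=edge_width_cells
    )

    boundary = fg & ~core & ~islet
    out[core] = MSPA_CORE
    out[islet] = MSPA_ISLET
    out[boundary & near_outer] = MSPA_EDGE
    out[boundary & ~near_outer & near_hole] = MSPA_PERFORATION
    out[boundary & ~near_outer & ~near_hole] = MSPA_RESIDUAL
    return out


def buffer_metrics(
    raster: RasterLandscape,
    buf: BufferView,
    stop_xy: tuple[float, float],
    full_patches: PatchSet,
    mspa: np.ndarray,
    min_patch_area_ha: float = 0.45,
    neighbor_min_area_ha: float = 100.0,
    search_radius_m: float = 2500.0,
    connectivity: int = 8,
) -> dict:
    """All eight variables for one stop × radius × date."""
    forest_pct, exurban_pct = composition(buf)
    clipped = label_patches(buf.masked_class(FOREST), raster.cell_size,
                            connectivity=connectivity)
    n = buf.n_cells
    mspa_win = np.where(buf.mask, mspa[buf.rows, buf.cols], MSPA_NONE)
    counts = np.bincount(mspa_win.ravel(), minlength=6)
    return {
        "forest_pct": forest_pct,
        "exurban_pct": exurban_pct,
        "core_pct": 100.0 * counts[MSPA_CORE] / n,
        "islet_pct": 100.0 * counts[MSPA_ISLET] / n,
        "edge_pct": 100.0 * (counts[MSPA_EDGE] + counts[MSPA_PERFORATION]) / n,
        "residual_pct": 100.0 * counts[MSPA_RESIDUAL] / n,
        "awps_ha": area_weighted_patch_size(clipped),
        "n_patches_gt_045ha": count_patches(clipped, min_patch_area_ha),
        "proximity_index": proximity_index(
            raster, full_patches, buf, stop_xy,
            neighbor_min_area_ha=neighbor_min_area_ha,
            search_radius_m=search_radius_m,
        ),
    }


def write_class_grid(cls: np.ndarray, path, cell_size: float = 30.0,
                     origin: tuple[float, float] = (0.0, 0.0)) -> None:
    """Write a morphological class grid as an ESRI ASCII Grid file."""
    nrows, ncols = cls.shape
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {origin[0]:.6f}\nyllcorner {origin[1]:.6f}\n"
            f"cellsize {cell_size:.6f}\nNODATA_value -9999\n"
        )
        np.savetxt(fh, cls.astype(int), fmt="%d")


METRIC_COLUMNS = [
    "forest_pct", "exurban_pct", "core_pct", "islet_pct", "edge_pct",
    "residual_pct", "awps_ha", "n_patches_gt_045ha", "proximity_index",
]


def metrics_timeseries(
    rasters: list[RasterLandscape],
    stops: pd.DataFrame,
    radii: tuple[float, ...] = (400.0, 1000.0),
    connectivity: int = 8,
    edge_width_cells: int = 1,
) -> pd.DataFrame:
    """One :data:`METRIC_COLUMNS` record per stop × radius × raster date.

    ``stops`` needs columns ``stop``, ``x``, ``y``.
    """
    records = []
    for raster in rasters:
        full_patches = label_patches(raster.grid == FOREST, raster.cell_size,
                                     connectivity=connectivity)
        mspa = mspa_classify(raster, FOREST, edge_width_cells=edge_width_cells)
        for _, s in stops.iterrows():
            for radius in radii:
                buf = extract_buffer(raster, (s["x"], s["y"]), radius,
                                     stop_id=str(s["stop"]))
                rec = {"stop": s["stop"], "radius_m": radius, "date": raster.date}
                rec.update(buffer_metrics(raster, buf, (s["x"], s["y"]),
                                          full_patches, mspa,
                                          connectivity=connectivity))
                records.append(rec)
    return pd.DataFrame.from_records(records)


def summarize_metrics(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd over stops, per variable × radius × date (Table-style)."""
    g = metrics.groupby(["radius_m", "date"])[METRIC_COLUMNS]
    out = g.agg(["mean", "std"]).fillna(0.0)
    out.columns = [f"{v}_{s}" for v, s in out.columns]
    return out.reset_index()
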