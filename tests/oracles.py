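"""Independent brute-force implementations used to cross-check the
landscape metrics.  Everything here is deliberately naive: BFS flood
fill, per-cell distance scans, O(n^2) pairwise loops."""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components as a list of frozensets of (row, col)."""
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    nr, nc = mask.shape
    for r0 in range(nr):
        for c0 in range(nc):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = []
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                while q:
                    r, c = q.popleft()
                    comp.append((r, c))
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nr and 0 <= cc < nc and mask[rr, cc] \
                                and not seen[rr, cc]:
                            seen[rr, cc] = True
                            q.append((rr, cc))
                comps.append(frozenset(comp))
    return comps


def buffer_cells(raster, center, radius_m) -> set[tuple[int, int]]:
    """Cells whose centre lies within radius of the point, by direct scan."""
    out = set()
    nr, nc = raster.grid.shape
    for r in range(nr):
        for c in range(nc):
            x, y = raster.cell_center(r, c)
            if (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius_m**2:
                out.add((r, c))
    return out


def awps(areas: list[float]) -> float:
    tot = sum(areas)
    if tot == 0:
        return 0.0
    return sum(a * a for a in areas) / tot


def count_gt(areas: list[float], min_area: float) -> int:
    return sum(1 for a in areas if a > min_area)


def _patch_edge_cells(comp: frozenset, shape) -> list[tuple[int, int]]:
    nr, nc = shape
    out = []
    for (r, c) in comp:
        if r == 0 or r == nr - 1 or c == 0 or c == nc - 1:
            out.append((r, c))
            continue
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            if (r + dr, c + dc) not in comp:
                out.append((r, c))
                break
    return out


def proximity(raster, stop_xy, buffer_set, forest_code=1,
              neighbor_min_area_ha=100.0, search_radius_m=2500.0) -> float:
    """Proximity index by exhaustive pairwise edge-cell distances."""
    grid = raster.grid
    cs = raster.cell_size
    comps = flood_fill_label(grid == forest_code, 8)
    row, col = raster.cell_of(*stop_xy)
    focal = None
    for comp in comps:
        if (row, col) in comp:
            focal = comp
            break
    if focal is None:
        # nearest forest cell inside the buffer (row-major tie-break)
        best = None
        for (r, c) in sorted(buffer_set):
            if grid[r, c] == forest_code:
                d2 = (r - row) ** 2 + (c - col) ** 2
                if best is None or d2 < best[0]:
                    best = (d2, (r, c))
        if best is None:
            return 0.0
        for comp in comps:
            if best[1] in comp:
                focal = comp
                break
    fedges = _patch_edge_cells(focal, grid.shape)
    total = 0.0
    for comp in comps:
        if comp is focal:
            continue
        area_ha = len(comp) * cs**2 / 1e4
        if area_ha < neighbor_min_area_ha:
            continue
        h = min(
            np.hypot((r1 - r2) * cs, (c1 - c2) * cs)
            for (r1, c1) in fedges
            for (r2, c2) in _patch_edge_cells(comp, grid.shape)
        )
        if h <= search_radius_m:
            total += (area_ha * 1e4) / h**2
    return total


def mspa(grid: np.ndarray, forest_code=1, edge_width=1) -> np.ndarray:
    """Morphological partition by per-cell scans and flood fill.

    Returns the same label codes as the implementation:
    1 core, 2 edge, 3 perforation, 4 islet, 5 residual.
    """
    nr, nc = grid.shape
    fg = grid == forest_code
    out = np.zeros_like(grid, dtype=int)

    def chebyshev_bg_within(r, c, w):
        cells = []
        for rr in range(max(0, r - w), min(nr, r + w + 1)):
            for cc in range(max(0, c - w), min(nc, c + w + 1)):
                if not fg[rr, cc]:
                    cells.append((rr, cc))
        return cells

    # core: no background within Chebyshev distance edge_width, and not
    # within edge_width of the raster border (erosion border rule)
    core = np.zeros_like(fg)
    for r in range(nr):
        for c in range(nc):
            if not fg[r, c]:
                continue
            if (r < edge_width or r >= nr - edge_width
                    or c < edge_width or c >= nc - edge_width):
                continue
            if not chebyshev_bg_within(r, c, edge_width):
                core[r, c] = True

    patches = flood_fill_label(fg, 8)
    bg_comps = flood_fill_label(~fg, 4)
    outer_cells = set()
    hole_cells = set()
    for comp in bg_comps:
        touches = any(r in (0, nr - 1) or c in (0, nc - 1) for r, c in comp)
        (outer_cells if touches else hole_cells).update(comp)

    for comp in patches:
        has_core = any(core[r, c] for r, c in comp)
        for (r, c) in comp:
            if not has_core:
                out[r, c] = 4  # islet
            elif core[r, c]:
                out[r, c] = 1
            else:
                near = chebyshev_bg_within(r, c, edge_width)
                near_border = (r < edge_width or r >= nr - edge_width
                               or c < edge_width or c >= nc - edge_width)
                if any(cell in outer_cells for cell in near) or near_border:
                    out[r, c] = 2  # edge
                elif any(cell in hole_cells for cell in near):
                    out[r, c] = 3  # perforation
                else:
                    out[r, c] = 5  # residual
    return out
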