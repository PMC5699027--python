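"""Planar geometry helpers: bounded Voronoi tessellations.

All coordinates are planar kilometres.  Real geographic inputs must be
projected (e.g. equirectangular) before entering the pipeline; the synthetic
generators work directly in km so no projection ambiguity arises.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box


def bounded_voronoi(points: np.ndarray, extent: float) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to the square [0, extent]^2.

    The tessellation is made finite by mirroring every site across the four
    box edges before calling the Voronoi routine; the cell of each original
    site is then bounded and, after clipping, the cells tile the box exactly.

    Parameters
    ----------
    points:
        (n, 2) array of site coordinates inside the box.
    extent:
        Side length of the square domain.

    Returns
    -------
    list of shapely Polygons, one per input site, in input order.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n == 0:
        raise ValueError("at least one site is required")
    domain = box(0.0, 0.0, extent, extent)
    if n == 1:
        return [domain]

    mirrored = np.vstack(
        [
            pts,
            pts * [-1.0, 1.0],                      # across x = 0
            pts * [1.0, -1.0],                      # across y = 0
            np.column_stack([2 * extent - pts[:, 0], pts[:, 1]]),
            np.column_stack([pts[:, 0], 2 * extent - pts[:, 1]]),
        ]
    )
    vor = Voronoi(mirrored)
    cells: list[Polygon] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("unbounded Voronoi cell after mirroring")
        poly = Polygon(vor.vertices[region])
        cells.append(poly.intersection(domain))
    return cells


def overlap_weight_table(
    target_polys: dict[str, Polygon], source_polys: dict[str, Polygon]
) -> list[tuple[str, str, float]]:
    """Areal-overlap weights Area(t ∩ s) / Area(s) for intersecting pairs.

    Zero-area intersections are omitted.  Degenerate (zero-area) source
    polygons are skipped entirely.
    """
    rows = []
    for sid, spoly in source_polys.items():
        area_s = spoly.area
        if area_s <= 0.0:
            continue
        for tid, tpoly in target_polys.items():
            inter = tpoly.intersection(spoly)
            if inter.area > 0.0:
                rows.append((tid, sid, inter.area / area_s))
    return rows
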