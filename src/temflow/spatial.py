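"""Voronoi-tessellation density and cluster analysis of cell centroids.

Each classified cell centroid becomes a Voronoi site; the tessellation is
clipped to the rectangular field of view, the inverse cell area serves as a
local density estimate, and clusters are connected groups of unusually dense
sites.  Bounded cells are obtained exactly by mirroring the sites across the
four field edges before triangulating, so clipped areas tile the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

__all__ = ["VoronoiResult", "voronoi_tessellate", "detect_clusters"]


@dataclass
class VoronoiResult:
    """Clipped Voronoi tessellation of cell centroids within a field.

    ``roi`` is (xmin, ymin, xmax, ymax) in px; ``clusters`` maps each site to
    a cluster id (0 = unclustered) once :func:`detect_clusters` has run.
    """

    roi: tuple
    sites: np.ndarray            # (n, 2) x, y
    labels: np.ndarray | None    # optional per-site class labels
    polygons: list               # shapely Polygons, one per site
    areas: np.ndarray            # px^2
    densities: np.ndarray        # 1 / px^2
    adjacency: set               # frozenset pairs of site indices sharing an edge
    clusters: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "cell_id": np.arange(len(self.sites)),
            "x": self.sites[:, 0],
            "y": self.sites[:, 1],
            "area_px2": self.areas,
            "density": self.densities,
            "cluster_id": (self.clusters if self.clusters is not None
                           else np.zeros(len(self.sites), dtype=int)),
        })
        if self.labels is not None:
            df["class"] = self.labels
        df["polygon_wkt"] = [p.wkt for p in self.polygons]
        return df


def voronoi_tessellate(centroids, roi, labels=None) -> VoronoiResult:
    """Voronoi diagram of ``centroids`` clipped to the rectangle ``roi``.

    ``roi`` is (xmin, ymin, xmax, ymax).  All sites must lie strictly inside
    the rectangle and be distinct.  Clipped cell areas tile the rectangle
    exactly (up to floating-point rounding).
    """
    pts = np.asarray(centroids, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("centroids must be a non-empty (n, 2) array")
    xmin, ymin, xmax, ymax = map(float, roi)
    if not (xmin < xmax and ymin < ymax):
        raise ValueError("degenerate roi rectangle")
    inside = ((pts[:, 0] > xmin) & (pts[:, 0] < xmax)
              & (pts[:, 1] > ymin) & (pts[:, 1] < ymax))
    if not inside.all():
        raise ValueError(
            f"{(~inside).sum()} centroid(s) outside the roi {roi}")
    rounded = np.round(pts, 9)
    if len(np.unique(rounded, axis=0)) != len(pts):
        raise ValueError("duplicate centroids")
    if labels is not None:
        labels = np.asarray(labels, dtype=object)
        if len(labels) != len(pts):
            raise ValueError("labels length mismatch")

    rect = box(xmin, ymin, xmax, ymax)
    n = len(pts)
    if n == 1:
        return VoronoiResult(
            roi=tuple(map(float, roi)), sites=pts, labels=labels,
            polygons=[rect], areas=np.array([rect.area]),
            densities=np.array([1.0 / rect.area]), adjacency=set(),
            clusters=np.zeros(1, dtype=int))

    # mirror sites across the four edges: every cell of an original site is
    # then bounded and already clipped to the rectangle
    mirrors = [
        np.column_stack([2 * xmin - pts[:, 0], pts[:, 1]]),
        np.column_stack([2 * xmax - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymin - pts[:, 1]]),
        np.column_stack([pts[:, 0], 2 * ymax - pts[:, 1]]),
    ]
    allpts = np.vstack([pts] + mirrors)
    vor = Voronoi(allpts)

    polygons = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        # regions are convex: angular sort about the centroid is always a
        # valid vertex order
        centre = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - centre[1],
                                      verts[:, 0] - centre[0]))
        poly = Polygon(verts[order])
        poly = poly.intersection(rect)  # exact up to fp rounding
        polygons.append(poly)
    areas = np.array([p.area for p in polygons])
    densities = 1.0 / areas

    adjacency = set()
    for (a, b) in vor.ridge_points:
        if a < n and b < n:
            adjacency.add(frozenset((int(a), int(b))))

    return VoronoiResult(tuple(map(float, roi)), pts, labels, polygons,
                         areas, densities, adjacency,
                         np.zeros(n, dtype=int))


def detect_clusters(vres: VoronoiResult, density_factor: float = 2.0,
                    min_cluster_size: int = 3) -> np.ndarray:
    """Find clusters of dense sites.

    A site is *dense* when its density exceeds ``density_factor`` times the
    median density.  Clusters are connected components of dense sites in the
    edge-adjacency graph with at least ``min_cluster_size`` members; ids are
    assigned 1..k in order of the smallest member index, 0 = unclustered.
    The assignment is also stored on ``vres.clusters``.
    """
    n = len(vres.sites)
    clusters = np.zeros(n, dtype=int)
    if n == 0:
        vres.clusters = clusters
        return clusters
    dense = vres.densities > density_factor * np.median(vres.densities)

    # union-find over dense sites
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for pair in vres.adjacency:
        a, b = tuple(pair)
        if dense[a] and dense[b]:
            parent[find(a)] = find(b)

    comps = {}
    for i in np.nonzero(dense)[0]:
        comps.setdefault(find(i), []).append(int(i))
    next_id = 1
    for root in sorted(comps, key=lambda r: min(comps[r])):
        members = comps[root]
        if len(members) >= min_cluster_size:
            for m in members:
                clusters[m] = next_id
            next_id += 1
    vres.clusters = clusters
    return clusters
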