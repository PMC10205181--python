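"""Quadtree segmentation of recurring spark sites.

Spark centroids accumulated over a time window (default 15 s) are segmented
with a 2D quadtree: the bounding square is recursively split into four while
a node holds more than ``max_leaf_points`` points and its children would stay
at least ``min_leaf_size_nm`` wide. Leaves whose point density exceeds
``density_factor`` times the global mean density are "hot"; 8-connected hot
leaves merge into recurring-site regions. Leaves tile the square exactly
(half-open rectangles), so the segmentation is deterministic and
partition-complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from sparkmap.paint import ClusterMap

__all__ = ["QuadLeaf", "RecurringSite", "quadtree_segment", "site_cluster_overlap"]


@dataclass(frozen=True)
class QuadLeaf:
    """Half-open square [x0, x0+size) × [y0, y0+size) holding ``count`` points."""

    x0: float
    y0: float
    size: float
    count: int

    @property
    def density_per_um2(self) -> float:
        return self.count / (self.size / 1e3) ** 2


@dataclass
class RecurringSite:
    """Union of 8-connected hot quadtree leaves."""

    leaves: list[QuadLeaf] = field(default_factory=list)

    @property
    def centroid_count(self) -> int:
        return sum(l.count for l in self.leaves)

    @property
    def area_um2(self) -> float:
        return sum((l.size / 1e3) ** 2 for l in self.leaves)

    @property
    def density_per_um2(self) -> float:
        return self.centroid_count / self.area_um2

    @property
    def width_nm(self) -> float:
        """Maximum caliper width: the largest corner-to-corner distance."""
        corners = []
        for l in self.leaves:
            corners.extend(
                [(l.x0, l.y0), (l.x0 + l.size, l.y0), (l.x0, l.y0 + l.size),
                 (l.x0 + l.size, l.y0 + l.size)]
            )
        c = np.array(corners)
        d2 = ((c[:, None, :] - c[None, :, :]) ** 2).sum(-1)
        return float(np.sqrt(d2.max()))


def _subdivide(x0, y0, size, pts, max_leaf_points, min_leaf_size, out):
    if len(pts) > max_leaf_points and size / 2.0 >= min_leaf_size:
        half = size / 2.0
        for dx in (0.0, half):
            for dy in (0.0, half):
                sel = (
                    (pts[:, 0] >= x0 + dx) & (pts[:, 0] < x0 + dx + half)
                    & (pts[:, 1] >= y0 + dy) & (pts[:, 1] < y0 + dy + half)
                )
                _subdivide(x0 + dx, y0 + dy, half, pts[sel], max_leaf_points, min_leaf_size, out)
    else:
        out.append(QuadLeaf(x0, y0, size, len(pts)))


def _touch(a: QuadLeaf, b: QuadLeaf, eps: float = 1e-6) -> bool:
    # 8-connectivity: closed rectangles share at least a corner
    return (
        a.x0 <= b.x0 + b.size + eps and b.x0 <= a.x0 + a.size + eps
        and a.y0 <= b.y0 + b.size + eps and b.y0 <= a.y0 + a.size + eps
    )


def quadtree_segment(
    spark_centroids: np.ndarray,
    field_bounds: tuple[float, float, float, float],
    times_s: np.ndarray | None = None,
    time_window_s: float = 15.0,
    t_start_s: float = 0.0,
    max_leaf_points: int = 3,
    min_leaf_size_nm: float = 100.0,
    density_factor: float = 4.0,
) -> tuple[list[RecurringSite], list[QuadLeaf]]:
    """Segment recurring spark sites from a spark-centroid point pattern.

    ``field_bounds`` is (x0, y0, x1, y1) in nm; the quadtree root is the
    bounding square of this rectangle. When ``times_s`` is given, only sparks
    with ``t_start_s <= t < t_start_s + time_window_s`` are used. Returns
    (sites, all leaves).
    """
    pts = np.asarray(spark_centroids, float).reshape(-1, 2)
    if times_s is not None:
        t = np.asarray(times_s, float)
        keep = (t >= t_start_s) & (t < t_start_s + time_window_s)
        pts = pts[keep]
    if len(pts) == 0:
        return [], []
    x0, y0, x1, y1 = field_bounds
    side = max(x1 - x0, y1 - y0)
    leaves: list[QuadLeaf] = []
    _subdivide(x0, y0, side, pts, max_leaf_points, min_leaf_size_nm, leaves)
    global_density = len(pts) / (side / 1e3) ** 2
    hot = [l for l in leaves if l.count > 0 and l.density_per_um2 > density_factor * global_density]
    # union-find merge of 8-connected hot leaves
    parent = list(range(len(hot)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(hot)):
        for j in range(i + 1, len(hot)):
            if _touch(hot[i], hot[j]):
                parent[find(i)] = find(j)
    groups: dict[int, RecurringSite] = {}
    for i, leaf in enumerate(hot):
        groups.setdefault(find(i), RecurringSite()).leaves.append(leaf)
    return list(groups.values()), leaves


def site_cluster_overlap(sites: list[RecurringSite], cluster_map: ClusterMap) -> tuple[np.ndarray, dict]:
    """Per-site fraction of area overlapping the RyR2 cluster mask.

    Sites and mask must be in the same coordinate frame. Returns the
    per-site fractions and a summary (median, mean, n).
    """
    mask = cluster_map.mask
    px = cluster_map.render_px_nm
    h, w = mask.shape
    fractions = []
    for site in sites:
        n_px = 0
        n_in = 0
        for leaf in site.leaves:
            c0 = int(np.floor(leaf.x0 / px))
            c1 = int(np.ceil((leaf.x0 + leaf.size) / px))
            r0 = int(np.floor(leaf.y0 / px))
            r1 = int(np.ceil((leaf.y0 + leaf.size) / px))
            c0, c1 = max(0, c0), min(w, c1)
            r0, r1 = max(0, r0), min(h, r1)
            if c1 <= c0 or r1 <= r0:
                continue
            sub = mask[r0:r1, c0:c1]
            n_px += sub.size
            n_in += int(sub.sum())
        fractions.append(n_in / n_px if n_px else np.nan)
    frac = np.asarray(fractions)
    ok = frac[np.isfinite(frac)]
    summary = {
        "n_sites": len(sites),
        "median_overlap": float(np.median(ok)) if len(ok) else np.nan,
        "mean_overlap": float(ok.mean()) if len(ok) else np.nan,
    }
    return frac, summary
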