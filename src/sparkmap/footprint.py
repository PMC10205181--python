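"""Per-spark sampling of the local RyR2 organization ("spark footprint").

The footprint is a circular window centred on the (registered) spark
centroid with diameter equal to the spark's fitted FWHM. Inside it we count
RyR2 puncta and unique qualifying clusters (clusters of at least
``min_cluster_size`` puncta), and compute the mean nearest-neighbour distance
(NND) and the mean distance to each punctum's three nearest neighbours (3ND)
over the puncta that belong to qualifying clusters. Derived statistics
include the spark-mass-to-RyR2-count ratio, the quadratic mass-vs-count fit,
group comparisons (Mann-Whitney U, Bartlett) and the per-cluster mean spark
mass heat map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from sparkmap.align import AlignmentTransform, transform_points
from sparkmap.paint import ClusterMap
from sparkmap.sparks import SparkRecord

__all__ = [
    "FootprintSample",
    "footprint_sample",
    "sample_all",
    "mass_vs_count_fit",
    "mass_ratio_stats",
    "spark_mass_heatmap",
]

SAMPLE_COLUMNS = [
    "spark_id", "x_nm", "y_nm", "fwhm_um",
    "ryr_count", "cluster_count", "nnd_nm", "tnd_nm", "mass", "mass_ratio",
]


@dataclass
class FootprintSample:
    """Local structure under one spark.

    ``nnd_nm``/``tnd_nm``/``mass_ratio`` are NaN when undefined (fewer than
    2/4 qualifying puncta, or zero RyR2 count respectively).
    """

    spark_id: int
    ryr_count: int
    cluster_count: int
    nnd_nm: float
    tnd_nm: float
    mass: float
    mass_ratio: float
    x_nm: float = np.nan
    y_nm: float = np.nan
    fwhm_um: float = np.nan


def _neighbour_distances(points: np.ndarray, k: int) -> np.ndarray | None:
    """(n, k) distances to each point's k nearest neighbours, or None if n <= k."""
    if len(points) <= k:
        return None
    tree = cKDTree(points)
    d, _ = tree.query(points, k=k + 1)
    return d[:, 1:]


def footprint_sample(
    spark: SparkRecord,
    cluster_map: ClusterMap,
    transform: AlignmentTransform | None = None,
    min_cluster_size: int | None = None,
    spark_id: int = 0,
    window_diameter_um: float | None = None,
    cluster_inclusion: str = "any-punctum",
) -> FootprintSample:
    """Sample RyR2 puncta and clusters inside one spark's footprint.

    Inclusion is Euclidean distance from the transformed spark centroid
    <= FWHM/2, boundary inclusive. ``cluster_count`` counts distinct
    qualifying cluster ids among the included puncta (``'any-punctum'``) or
    clusters whose centroid falls inside the window
    (``'centroid-inside'``). NND and 3ND are computed over the included
    puncta belonging to qualifying clusters only.
    """
    if min_cluster_size is None:
        min_cluster_size = cluster_map.min_cluster_size
    centre = np.array([spark.x_nm, spark.y_nm])
    if transform is not None:
        centre = transform_points(centre, transform)[0]
    diameter_nm = (window_diameter_um if window_diameter_um is not None else spark.fwhm_um) * 1e3
    radius = diameter_nm / 2.0

    puncta = cluster_map.puncta
    ids = cluster_map.cluster_ids
    if len(puncta) == 0:
        return FootprintSample(spark_id, 0, 0, np.nan, np.nan, spark.mass, np.nan,
                               centre[0], centre[1], spark.fwhm_um)
    d = np.hypot(puncta[:, 0] - centre[0], puncta[:, 1] - centre[1])
    inc = d <= radius
    ryr_count = int(inc.sum())

    sizes = np.bincount(ids, minlength=int(ids.max(initial=0)) + 1)
    qualifying = np.zeros_like(sizes, bool)
    qualifying[1:] = sizes[1:] >= min_cluster_size

    if cluster_inclusion == "any-punctum":
        inc_ids = np.unique(ids[inc & qualifying[ids]])
        cluster_count = int(len(inc_ids))
    elif cluster_inclusion == "centroid-inside":
        cluster_count = 0
        for cid in np.flatnonzero(qualifying):
            cc = puncta[ids == cid].mean(axis=0)
            if np.hypot(cc[0] - centre[0], cc[1] - centre[1]) <= radius:
                cluster_count += 1
    else:
        raise ValueError("cluster_inclusion must be 'any-punctum' or 'centroid-inside'")

    qpts = puncta[inc & qualifying[ids]]
    nnd = tnd = np.nan
    d1 = _neighbour_distances(qpts, 1)
    if d1 is not None:
        nnd = float(d1.mean())
    d3 = _neighbour_distances(qpts, 3)
    if d3 is not None:
        tnd = float(d3.mean())

    mass = spark.mass
    ratio = mass / ryr_count if ryr_count > 0 else np.nan
    return FootprintSample(spark_id, ryr_count, cluster_count, nnd, tnd, mass, ratio,
                           centre[0], centre[1], spark.fwhm_um)


def sample_all(
    sparks: list[SparkRecord],
    cluster_map: ClusterMap,
    transform: AlignmentTransform | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Footprint-sample every spark; returns (table, summary).

    The summary holds the mean RyR2 count and mean unique-cluster count per
    spark and percentage histograms of both.
    """
    samples = [
        footprint_sample(s, cluster_map, transform, spark_id=i, **kwargs)
        for i, s in enumerate(sparks)
    ]
    df = pd.DataFrame(
        [
            (s.spark_id, s.x_nm, s.y_nm, s.fwhm_um, s.ryr_count, s.cluster_count,
             s.nnd_nm, s.tnd_nm, s.mass, s.mass_ratio)
            for s in samples
        ],
        columns=SAMPLE_COLUMNS,
    )
    summary: dict = {"n_sparks": len(df)}
    if len(df):
        summary["mean_ryr_count"] = float(df["ryr_count"].mean())
        summary["mean_cluster_count"] = float(df["cluster_count"].mean())
        for col in ("ryr_count", "cluster_count"):
            counts = df[col].value_counts(normalize=True).sort_index()
            summary[f"{col}_pct_histogram"] = {int(k): 100.0 * v for k, v in counts.items()}
    return df, summary


def mass_vs_count_fit(samples: pd.DataFrame, log10: bool = False) -> tuple[float, float, float]:
    """Least-squares fit of mass = a·count² + b over samples with count > 0.

    With ``log10=True`` both variables are log10-transformed before fitting
    the same quadratic form (the alternative reading of log-scaled
    scattergrams). Returns (a, b, residual variance).
    """
    df = samples[(samples["ryr_count"] > 0) & np.isfinite(samples["mass"])]
    if len(df) < 3:
        raise ValueError("need >= 3 samples with ryr_count > 0")
    x = df["ryr_count"].to_numpy(float)
    y = df["mass"].to_numpy(float)
    if log10:
        x, y = np.log10(x), np.log10(y)
    design = np.column_stack([x**2, np.ones_like(x)])
    if np.linalg.matrix_rank(design) < 2:
        raise ValueError("degenerate design: counts are all equal")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = max(len(y) - 2, 1)
    return float(coef[0]), float(coef[1]), float(resid @ resid / dof)


def mass_ratio_stats(samples_a: pd.DataFrame, samples_b: pd.DataFrame, column: str = "mass_ratio") -> dict:
    """Group comparison of spark mass ratios (or any sample column).

    Returns medians, means, s.d.s, Bartlett's homogeneity-of-variance
    statistic (conventional d.f. = k − 1 = 1) and the two-sided
    Mann-Whitney U. Bartlett is flagged unusable when a group has zero
    variance.
    """
    a = samples_a[column].dropna().to_numpy(float)
    b = samples_b[column].dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group")
    out = {
        "median_a": float(np.median(a)), "median_b": float(np.median(b)),
        "mean_a": float(a.mean()), "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)), "sd_b": float(b.std(ddof=1)),
        "n_a": len(a), "n_b": len(b), "bartlett_df": 1,
    }
    if out["sd_a"] == 0 or out["sd_b"] == 0:
        out["bartlett_stat"] = np.nan
        out["bartlett_p"] = np.nan
        out["bartlett_degenerate"] = True
    else:
        bs, bp = stats.bartlett(a, b)
        out["bartlett_stat"] = float(bs)
        out["bartlett_p"] = float(bp)
        out["bartlett_degenerate"] = False
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    out["mannwhitney_u"] = float(u)
    out["mannwhitney_p"] = float(p)
    return out


def spark_mass_heatmap(cluster_map: ClusterMap, samples: pd.DataFrame) -> tuple[dict[int, float], np.ndarray]:
    """Mean local spark mass per cluster and the pseudocoloured value image.

    A spark contributes to every cluster whose mask component intersects the
    spark's footprint disc. Clusters with no intersecting spark are NaN
    (no-data) in both outputs.
    """
    labels = cluster_map.labels
    px = cluster_map.render_px_nm
    n_labels = int(labels.max())
    masses: dict[int, list[float]] = {}
    label_pixels = {
        lab: np.argwhere(labels == lab) for lab in range(1, n_labels + 1)
    }
    for row in samples.itertuples(index=False):
        if not np.isfinite(row.mass):
            continue
        r_nm = row.fwhm_um * 1e3 / 2.0
        for lab, pix in label_pixels.items():
            if not len(pix):
                continue
            xy = (pix[:, ::-1] + 0.5) * px
            d2 = (xy[:, 0] - row.x_nm) ** 2 + (xy[:, 1] - row.y_nm) ** 2
            if (d2 <= r_nm**2).any():
                masses.setdefault(lab, []).append(float(row.mass))
    values = {lab: float(np.mean(v)) for lab, v in masses.items()}
    img = np.full(labels.shape, np.nan)
    for lab, val in values.items():
        img[labels == lab] = val
    return values, img
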