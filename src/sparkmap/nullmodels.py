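"""Uniform-randomization null models for spark and RyR2 positions.

Two controls isolate the contribution of spatial organization to the
footprint statistics: relocating the RyR2 channels uniformly over the cell
footprint (destroying clusters) or relocating the spark centroids uniformly
(destroying recurring sites), each preserving point counts and all
non-positional attributes. ``null_comparison`` contrasts footprint-sample
distributions between the real and randomized configurations with percentage
histograms on shared bins, median differences and two-sample
Kolmogorov-Smirnov distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["NullConfig", "randomize_points", "null_comparison"]

DEFAULT_METRICS = ("ryr_count", "nnd_nm", "tnd_nm")


@dataclass(frozen=True)
class NullConfig:
    """Randomization mode, region and replication."""

    mode: str = "randomize-ryr"           # or "randomize-sparks"
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("randomize-ryr", "randomize-sparks"):
            raise ValueError("mode must be 'randomize-ryr' or 'randomize-sparks'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def randomize_points(
    points: np.ndarray,
    region_mask: np.ndarray,
    px_nm: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Relocate points i.i.d. uniformly over the mask's pixels.

    Each relocated point lands on a uniformly chosen mask pixel with uniform
    sub-pixel jitter; the output has the same number of points as the input,
    so any per-point attributes carried alongside remain valid.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, cols = np.nonzero(region_mask)
    if len(rows) == 0:
        raise ValueError("region mask is empty")
    n = len(np.asarray(points).reshape(-1, 2))
    idx = rng.integers(0, len(rows), n)
    u = rng.random((n, 2))
    x = (cols[idx] + u[:, 0]) * px_nm
    y = (rows[idx] + u[:, 1]) * px_nm
    return np.column_stack([x, y])


def _pct_histogram(a: np.ndarray, b: np.ndarray, n_bins: int = 20):
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    ha = 100.0 * np.histogram(a, bins=edges)[0] / len(a)
    hb = 100.0 * np.histogram(b, bins=edges)[0] / len(b)
    return edges, ha, hb


def null_comparison(
    real_samples: pd.DataFrame,
    null_samples: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    n_bins: int = 20,
) -> dict:
    """Compare real vs randomized footprint-sample distributions per metric.

    For each metric: percentage histograms on shared bins, median difference
    (null − real), IQRs, and the two-sample KS distance with its p-value.
    """
    out: dict = {}
    for metric in metrics:
        a = real_samples[metric].dropna().to_numpy(float)
        b = null_samples[metric].dropna().to_numpy(float)
        if len(a) == 0 or len(b) == 0:
            out[metric] = {"n_real": len(a), "n_null": len(b)}
            continue
        edges, ha, hb = _pct_histogram(a, b, n_bins)
        ks = stats.ks_2samp(a, b)
        out[metric] = {
            "bin_edges": edges.tolist(),
            "real_pct": ha.tolist(),
            "null_pct": hb.tolist(),
            "median_real": float(np.median(a)),
            "median_null": float(np.median(b)),
            "median_shift": float(np.median(b) - np.median(a)),
            "iqr_real": float(np.subtract(*np.percentile(a, [75, 25]))),
            "iqr_null": float(np.subtract(*np.percentile(b, [75, 25]))),
            "ks_distance": float(ks.statistic),
            "ks_p": float(ks.pvalue),
            "n_real": len(a),
            "n_null": len(b),
        }
    return out
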