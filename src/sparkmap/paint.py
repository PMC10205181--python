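"""Single-molecule localization, super-resolution rendering and RyR2 cluster segmentation.

The DNA-PAINT branch of the correlative workflow: fit blinking events to
sub-pixel centroids, render the localizations into a density image at a few
nm per pixel, detect individual RyR2 puncta as local maxima, and segment
clusters with a global threshold that encapsulates a fixed fraction (default
80%) of the total above-background labelling intensity.

All positions are in nm with the origin at the field corner, x to the right
and y down; a pixel index ``i`` maps to the coordinate ``(i + 0.5) * px``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.feature import peak_local_max
from skimage.morphology import disk

__all__ = [
    "LocalizationTable",
    "ClusterMap",
    "DegenerateThresholdError",
    "localize_events",
    "render_image",
    "detect_puncta",
    "segment_clusters",
    "to_uint16",
]


LOCALIZATION_COLUMNS = ["x_nm", "y_nm", "frame", "intensity", "sigma_nm"]


class DegenerateThresholdError(ValueError):
    """Raised when the intensity-fraction threshold is undefined (uniform image)."""


@dataclass
class LocalizationTable:
    """Table of single-molecule events: one row per fitted blinking occurrence.

    Columns: ``x_nm, y_nm, frame, intensity, sigma_nm`` where ``sigma_nm`` is
    the per-event localization precision.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LOCALIZATION_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"localization table missing columns {missing}")
        if len(self.events) and (self.events["frame"] < 0).any():
            raise ValueError("negative frame index in localization table")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) positions in nm."""
        return self.events[["x_nm", "y_nm"]].to_numpy(float)

    @classmethod
    def from_arrays(cls, x_nm, y_nm, frame=None, intensity=None, sigma_nm=None) -> "LocalizationTable":
        x = np.asarray(x_nm, float)
        n = x.size
        df = pd.DataFrame(
            {
                "x_nm": x,
                "y_nm": np.asarray(y_nm, float),
                "frame": np.zeros(n, int) if frame is None else np.asarray(frame, int),
                "intensity": np.ones(n) if intensity is None else np.asarray(intensity, float),
                "sigma_nm": np.zeros(n) if sigma_nm is None else np.asarray(sigma_nm, float),
            }
        )
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "LocalizationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False, columns=LOCALIZATION_COLUMNS)


@dataclass
class ClusterMap:
    """Rendered super-resolution image with puncta, cluster mask and memberships.

    ``cluster_ids`` assigns each punctum the label of the mask component that
    contains it; 0 means unclustered or member of a component with fewer than
    ``min_cluster_size`` puncta.
    """

    rendered: np.ndarray
    render_px_nm: float
    puncta: np.ndarray          # (N, 2) nm
    mask: np.ndarray            # bool, same shape as rendered
    labels: np.ndarray          # int component labels, 0 = background
    cluster_ids: np.ndarray     # (N,) int per punctum
    min_cluster_size: int
    threshold: float = field(default=np.nan)

    @property
    def cluster_sizes(self) -> dict[int, int]:
        """Puncta count per retained cluster id (ids > 0 only)."""
        ids, counts = np.unique(self.cluster_ids[self.cluster_ids > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


def _gauss2d(coords, a, x0, y0, sigma, offset):
    x, y = coords
    return a * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * sigma**2)) + offset


def localize_events(
    paint_movie: np.ndarray,
    detection_threshold: float,
    camera_px_nm: float = 100.0,
    fit_halfwidth: int = 3,
    saturation_level: float = 65535.0,
) -> LocalizationTable:
    """Detect and fit single-molecule events, one per blinking spot.

    Per frame, local maxima exceeding ``detection_threshold`` above the frame
    median are fitted with a least-squares symmetric 2D Gaussian in a small
    window; the fitted centre gives the sub-pixel centroid. Saturated frames
    (any pixel at ``saturation_level``) are flagged with a warning but still
    processed.
    """
    movie = np.asarray(paint_movie, float)
    if movie.ndim != 3 or movie.shape[0] < 1:
        raise ValueError("paint movie must be a (frames, y, x) stack with >= 1 frame")
    rows: list[tuple] = []
    n_saturated = 0
    for t, frame in enumerate(movie):
        if (frame >= saturation_level).any():
            n_saturated += 1
        bg = float(np.median(frame))
        peaks = peak_local_max(
            frame, min_distance=fit_halfwidth, threshold_abs=bg + detection_threshold
        )
        h, w = frame.shape
        for r, c in peaks:
            r0, r1 = max(0, r - fit_halfwidth), min(h, r + fit_halfwidth + 1)
            c0, c1 = max(0, c - fit_halfwidth), min(w, c + fit_halfwidth + 1)
            patch = frame[r0:r1, c0:c1]
            yy, xx = np.mgrid[r0:r1, c0:c1]
            p0 = (patch.max() - bg, float(c), float(r), 1.2, bg)
            try:
                popt, _ = optimize.curve_fit(
                    _gauss2d, (xx.ravel(), yy.ravel()), patch.ravel(), p0=p0, maxfev=2000
                )
            except RuntimeError:
                continue
            amp, x0, y0, sig, _ = popt
            if amp <= 0 or not (c0 - 1 <= x0 <= c1) or not (r0 - 1 <= y0 <= r1):
                continue
            rows.append(
                (
                    (x0 + 0.5) * camera_px_nm,
                    (y0 + 0.5) * camera_px_nm,
                    t,
                    float(amp),
                    abs(sig) * camera_px_nm / max(np.sqrt(amp), 1.0),
                )
            )
    if n_saturated:
        warnings.warn(f"{n_saturated} saturated frame(s) in PAINT movie", stacklevel=2)
    df = pd.DataFrame(rows, columns=LOCALIZATION_COLUMNS)
    if not len(df):
        df = pd.DataFrame({c: [] for c in LOCALIZATION_COLUMNS})
    return LocalizationTable(df)


def render_image(
    table: LocalizationTable,
    field_size_nm: tuple[float, float],
    render_px_nm: float = 5.0,
    kernel: str = "gaussian",
    sigma_floor_nm: float = 5.0,
) -> np.ndarray:
    """Render a localization table into a density image at ``render_px_nm`` nm/px.

    ``kernel='gaussian'`` stamps each event as a unit-integral Gaussian of
    width max(event precision, ``sigma_floor_nm``); ``kernel='hist'`` bins
    events into pixels without smoothing (the raw localization spread, used
    when measuring image resolution). The returned float image integrates to
    the event count; :func:`to_uint16` converts it for 16-bit TIFF export.
    """
    w = int(round(field_size_nm[0] / render_px_nm))
    h = int(round(field_size_nm[1] / render_px_nm))
    img = np.zeros((h, w), float)
    if len(table) == 0:
        return img
    x = table.events["x_nm"].to_numpy(float)
    y = table.events["y_nm"].to_numpy(float)
    cols = np.floor(x / render_px_nm).astype(int)
    rows = np.floor(y / render_px_nm).astype(int)
    inside = (cols >= 0) & (cols < w) & (rows >= 0) & (rows < h)
    np.add.at(img, (rows[inside], cols[inside]), 1.0)
    if kernel == "hist":
        return img
    if kernel != "gaussian":
        raise ValueError(f"unknown render kernel {kernel!r}")
    sigma = max(float(np.median(table.events["sigma_nm"])), sigma_floor_nm) / render_px_nm
    return ndimage.gaussian_filter(img, sigma, mode="constant")


def to_uint16(rendered: np.ndarray) -> np.ndarray:
    """Scale a float density image to the full 16-bit range for TIFF export."""
    peak = rendered.max()
    if peak <= 0:
        return np.zeros_like(rendered, dtype=np.uint16)
    return np.clip(rendered / peak * 65535.0, 0, 65535).astype(np.uint16)


def detect_puncta(
    rendered: np.ndarray,
    render_px_nm: float = 5.0,
    min_separation_nm: float = 30.0,
    threshold_rel: float = 0.05,
) -> np.ndarray:
    """Detect punctum centroids (individual RyR2 channels) in a rendered image.

    Local maxima separated by at least ``min_separation_nm`` (about one RyR2
    footprint) and above ``threshold_rel`` of the image maximum, refined to
    sub-pixel by an intensity-weighted centroid in a small window. Returns an
    (N, 2) array of (x, y) in nm.
    """
    img = np.asarray(rendered, float)
    if img.max() <= 0:
        return np.empty((0, 2))
    # a peak survives if it is the maximum within a disk of min_separation/2,
    # so two channels min_separation apart are both retained
    radius = max(1, int(round(min_separation_nm / 2.0 / render_px_nm)))
    peaks = peak_local_max(img, footprint=disk(radius), threshold_rel=threshold_rel)
    out = []
    half = radius
    h, w = img.shape
    for r, c in peaks:
        r0, r1 = max(0, r - half), min(h, r + half + 1)
        c0, c1 = max(0, c - half), min(w, c + half + 1)
        patch = img[r0:r1, c0:c1]
        yy, xx = np.mgrid[r0:r1, c0:c1]
        tot = patch.sum()
        cx = (patch * xx).sum() / tot
        cy = (patch * yy).sum() / tot
        out.append(((cx + 0.5) * render_px_nm, (cy + 0.5) * render_px_nm))
    return np.array(out) if out else np.empty((0, 2))


def _modal_background(img: np.ndarray) -> float:
    # Modal pixel value on a 256-bin histogram; robust for images dominated
    # by empty background.
    hist, edges = np.histogram(img, bins=256)
    i = int(np.argmax(hist))
    return 0.5 * (edges[i] + edges[i + 1])


def fraction_threshold(img: np.ndarray, labelling_fraction: float) -> tuple[float, float]:
    """Global threshold encapsulating ``labelling_fraction`` of above-background intensity.

    Returns ``(threshold, background)`` such that the pixels with
    above-background value >= threshold integrate to the requested fraction of
    the total above-background intensity.
    """
    if not 0 < labelling_fraction <= 1:
        raise ValueError("labelling_fraction must be in (0, 1]")
    bg = _modal_background(img)
    above = np.clip(img - bg, 0, None)
    total = above.sum()
    if total <= 0:
        raise DegenerateThresholdError("image has no intensity above background")
    vals = np.sort(above[above > 0])[::-1]
    cum = np.cumsum(vals)
    k = int(np.searchsorted(cum, labelling_fraction * total))
    k = min(k, len(vals) - 1)
    return float(vals[k]), float(bg)


def segment_clusters(
    rendered: np.ndarray,
    puncta: np.ndarray,
    render_px_nm: float = 5.0,
    labelling_fraction: float = 0.80,
    min_cluster_size: int = 4,
    mask_smooth_nm: float = 30.0,
) -> ClusterMap:
    """Segment RyR2 clusters by the intensity-fraction global threshold.

    The mask is the set of pixels whose above-background intensity integrates
    to ``labelling_fraction`` of the total; 8-connected components define
    clusters. The threshold operates on a copy of the rendering smoothed to
    the RyR2-footprint scale (``mask_smooth_nm``) so that puncta of one
    cluster, ~38 nm apart, form a connected labelled area rather than
    isolated cores. Each punctum is assigned the label of the component
    containing it; components holding fewer than ``min_cluster_size`` puncta
    are given id 0 (unclustered).
    """
    img = np.asarray(rendered, float)
    work = ndimage.gaussian_filter(img, mask_smooth_nm / render_px_nm) if mask_smooth_nm > 0 else img
    thr, bg = fraction_threshold(work, labelling_fraction)
    mask = (work - bg) >= thr
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3), int))
    puncta = np.asarray(puncta, float).reshape(-1, 2)
    ids = np.zeros(len(puncta), int)
    h, w = img.shape
    for i, (x, y) in enumerate(puncta):
        c = int(x / render_px_nm)
        r = int(y / render_px_nm)
        if 0 <= r < h and 0 <= c < w:
            ids[i] = labels[r, c]
    # drop components with too few puncta
    if len(ids):
        counts = np.bincount(ids, minlength=labels.max() + 1)
        small = counts < min_cluster_size
        small[0] = False
        ids[small[ids]] = 0
    return ClusterMap(
        rendered=img,
        render_px_nm=render_px_nm,
        puncta=puncta,
        mask=mask,
        labels=labels,
        cluster_ids=ids,
        min_cluster_size=min_cluster_size,
        threshold=thr,
    )
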