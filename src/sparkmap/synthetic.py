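"""Ground-truthed synthetic scenes: RyR2 maps, DNA-PAINT tables and spark movies.

Emulates the imaging regime of correlative sub-plasmalemmal Ca2+ spark /
DNA-PAINT experiments in ventricular cardiomyocytes:

* RyR2 channels laid on jittered triangular lattices inside elliptical
  cluster footprints arranged along sarcomeric rows (~1.8 µm spacing), with
  an intra-cluster nearest-neighbour distance calibrated to ~38 nm. A
  ``fragmentation_fraction`` splits clusters into displaced sub-clusters with
  loosened packing, the "dissipated" disease phenotype.
* DNA-PAINT localization tables at ~90% labelling efficiency and nm-scale
  localization precision.
* TIRF spark movies at 10 Hz: 2D-Gaussian sparks (FWHM 1-6 µm, ~30-100 ms)
  on a noisy baseline calibrated so that the 10-frame-averaged reference
  image reaches a target SNR (default 17).

Coordinates are nm, origin at the field corner, x right / y down; pixel
index ``i`` corresponds to position ``(i + 0.5) * px``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from sparkmap.paint import LocalizationTable

__all__ = [
    "SceneParams",
    "SparkMovieParams",
    "GroundTruth",
    "generate_ryr_map",
    "simulate_paint_localizations",
    "simulate_spark_movie",
    "apply_known_shift",
    "measure_snr",
    "cell_mask",
    "cell_mask_image",
    "points_in_cell",
]

SPARK_TRUTH_COLUMNS = ["x_nm", "y_nm", "t_on_s", "duration_ms", "amplitude", "fwhm_um"]


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic RyR2 scene.

    Lengths are in the units given by the field name suffix. Defaults target
    a healthy ("ctrl-like") right-ventricular myocyte footprint: a 15 × 15 µm
    illumination field, sarcomeric rows 1.8 µm apart, ~38.23 nm intra-cluster
    nearest-neighbour spacing and 90% labelling efficiency.
    """

    field_size_um: tuple[float, float] = (15.0, 15.0)
    row_spacing_um: float = 1.8
    clusters_per_row: int = 6
    channels_per_cluster_mean: float = 14.0
    channels_per_cluster_shape: float = 1.5
    intra_cluster_nnd_nm: float = 38.23
    nnd_jitter_nm: float = 4.0
    fragmentation_fraction: float = 0.0
    labelling_efficiency: float = 0.90
    localization_precision_nm: float = 7.0
    events_per_channel: float = 15.0
    margin_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.field_size_um) <= 0 or self.row_spacing_um <= 0:
            raise ValueError("all lengths must be > 0")
        if self.intra_cluster_nnd_nm <= 0 or self.margin_um < 0:
            raise ValueError("all lengths must be > 0")
        for name in ("fragmentation_fraction", "labelling_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.field_size_um[1] <= 2 * self.margin_um + self.row_spacing_um:
            raise ValueError("field too small for the requested sarcomeric rows")

    @property
    def field_size_nm(self) -> tuple[float, float]:
        return (self.field_size_um[0] * 1e3, self.field_size_um[1] * 1e3)


@dataclass(frozen=True)
class SparkMovieParams:
    """Parameters of a synthetic TIRF Ca2+ spark time series.

    ``snr`` is defined on the 10-frame-averaged reference image as
    (mean in-cell baseline − mean background) / s.d. of background noise;
    the per-frame noise sigma is calibrated accordingly
    (sigma = contrast · sqrt(10) / snr).
    """

    frame_rate_hz: float = 10.0
    n_frames: int = 150
    camera_px_nm: float = 100.0
    baseline_f0: float = 100.0
    background: float = 10.0
    snr: float = 17.0
    spark_rate: float = 2.0                      # events / s over the cell footprint
    recurring_site_fraction: float = 0.0
    amplitude_range: tuple[float, float] = (1.5, 2.5)   # F/F0
    fwhm_range_um: tuple[float, float] = (1.5, 3.5)
    duration_range_ms: tuple[float, float] = (30.0, 100.0)
    baseline_texture: float = 0.5
    texture_psf_fwhm_nm: float = 250.0
    snr_avg_frames: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("snr and frame_rate must be > 0")
        if self.camera_px_nm <= 0 or self.n_frames < 1:
            raise ValueError("invalid movie geometry")


@dataclass
class GroundTruth:
    """Simulation truth: channel positions, cluster assignments and spark events.

    ``cell_mask_coarse`` is the myocyte footprint at ``cell_mask_px_nm``
    resolution; the irregular outline is what the cross-correlation
    registration locks onto, as for a real cell.
    """

    channel_positions: np.ndarray            # (N, 2) nm
    cluster_ids: np.ndarray                  # (N,) int, 1-based
    field_size_nm: tuple[float, float]
    margin_nm: float
    recurring_sites: np.ndarray              # (M, 2) nm, inter-cluster midpoints
    cell_mask_coarse: np.ndarray | None = None
    cell_mask_px_nm: float = 100.0
    spark_events: pd.DataFrame | None = None
    true_shift_nm: tuple[float, float] = (0.0, 0.0)
    params: SceneParams | None = None

    def __post_init__(self) -> None:
        if len(self.channel_positions) != len(self.cluster_ids):
            raise ValueError("every channel needs exactly one cluster id")


def _make_cell_outline(
    rng: np.random.Generator,
    field_size_nm: tuple[float, float],
    margin_nm: float,
    px_nm: float = 100.0,
    boundary_scale_nm: float = 1500.0,
    fill: float = 0.8,
) -> np.ndarray:
    """Irregular myocyte footprint: a smooth random blob inside the inset field.

    The unique outline is what makes a real cell registrable between
    modalities, so the synthetic cell boundary is modulated by band-limited
    noise rather than being a rectangle.
    """
    w = int(round(field_size_nm[0] / px_nm))
    h = int(round(field_size_nm[1] / px_nm))
    noise = ndimage.gaussian_filter(rng.normal(size=(h, w)), boundary_scale_nm / px_nm)
    xs = (np.arange(w) + 0.5) * px_nm
    ys = (np.arange(h) + 0.5) * px_nm
    rect = (
        ((xs >= margin_nm) & (xs <= field_size_nm[0] - margin_nm))[None, :]
        & ((ys >= margin_nm) & (ys <= field_size_nm[1] - margin_nm))[:, None]
    )
    thr = np.quantile(noise[rect], 1.0 - fill)
    mask = rect & (noise > thr)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def cell_mask_image(truth: "GroundTruth", px_nm: float) -> np.ndarray:
    """Resample the scene's cell footprint mask to ``px_nm`` resolution."""
    coarse = truth.cell_mask_coarse
    if coarse is None:
        return cell_mask(truth.field_size_nm, px_nm, truth.margin_nm)
    factor = truth.cell_mask_px_nm / px_nm
    if factor == 1.0:
        return coarse.copy()
    return ndimage.zoom(coarse.astype(np.uint8), factor, order=0).astype(bool)


def points_in_cell(truth: "GroundTruth", points: np.ndarray) -> np.ndarray:
    """Boolean: which (x, y) nm points fall inside the cell footprint."""
    pts = np.asarray(points, float).reshape(-1, 2)
    if truth.cell_mask_coarse is None:
        fx, fy = truth.field_size_nm
        m = truth.margin_nm
        return (
            (pts[:, 0] >= m) & (pts[:, 0] <= fx - m) & (pts[:, 1] >= m) & (pts[:, 1] <= fy - m)
        )
    px = truth.cell_mask_px_nm
    h, w = truth.cell_mask_coarse.shape
    c = np.clip((pts[:, 0] / px).astype(int), 0, w - 1)
    r = np.clip((pts[:, 1] / px).astype(int), 0, h - 1)
    return truth.cell_mask_coarse[r, c]


def _triangular_patch(n: int, spacing: float, aspect: float, angle: float) -> np.ndarray:
    """``n`` points of a triangular lattice closest to the origin under an
    anisotropic metric, giving an elliptical footprint elongated by ``aspect``."""
    k = int(np.ceil(np.sqrt(n))) + 3
    i, j = np.meshgrid(np.arange(-k, k + 1), np.arange(-k, k + 1))
    x = (i + 0.5 * (j % 2)) * spacing
    y = j * (np.sqrt(3.0) / 2.0) * spacing
    pts = np.column_stack([x.ravel(), y.ravel()])
    c, s = np.cos(angle), np.sin(angle)
    rot = pts @ np.array([[c, -s], [s, c]]).T
    metric = (rot[:, 0] / aspect) ** 2 + rot[:, 1] ** 2
    order = np.argsort(metric, kind="stable")
    return rot[order[:n]]


def generate_ryr_map(params: SceneParams) -> GroundTruth:
    """Lay RyR2 channels on jittered triangular lattices along sarcomeric rows.

    Cluster centres are placed along rows ``row_spacing_um`` apart; each
    cluster holds a negative-binomially distributed number of channels on a
    triangular lattice of constant ``intra_cluster_nnd_nm`` with Gaussian
    positional jitter. With ``fragmentation_fraction > 0`` the designated
    clusters are split into >= 2 sub-clusters displaced 50-200 nm, with
    loosened internal packing.
    """
    rng = np.random.default_rng([params.seed, 0])
    fx, fy = params.field_size_nm
    margin = params.margin_um * 1e3
    row_step = params.row_spacing_um * 1e3
    mask_px = 100.0
    cell = _make_cell_outline(rng, (fx, fy), margin, mask_px)
    ys = np.arange(margin + row_step / 2, fy - margin, row_step)

    positions: list[np.ndarray] = []
    ids: list[np.ndarray] = []
    centres: list[tuple[float, float, int]] = []  # (cx, cy, row index)
    cid = 0
    m = params.channels_per_cluster_mean
    r_shape = params.channels_per_cluster_shape
    for row_i, y0 in enumerate(ys):
        xs = np.linspace(margin, fx - margin, params.clusters_per_row + 1)
        xs = 0.5 * (xs[:-1] + xs[1:])
        for x0 in xs:
            cx = x0 + rng.uniform(-0.15, 0.15) * (fx - 2 * margin) / params.clusters_per_row
            cy = y0 + rng.normal(0.0, 80.0)
            n = 1 + rng.negative_binomial(r_shape, r_shape / (r_shape + m - 1.0))
            mr = min(int(cy / mask_px), cell.shape[0] - 1)
            mc = min(int(cx / mask_px), cell.shape[1] - 1)
            if not cell[mr, mc]:
                continue
            cid += 1
            aspect = rng.uniform(1.0, 2.0)
            angle = rng.normal(0.0, 0.15)  # roughly along the row
            # jitter shrinks the minimum over ~6 lattice neighbours; widen the
            # lattice constant to first order so the empirical NND matches the
            # nominal value (correction vanishes at zero jitter)
            spacing = params.intra_cluster_nnd_nm + 1.32 * params.nnd_jitter_nm
            pts = _triangular_patch(n, spacing, aspect, angle)
            pts = pts + rng.normal(0.0, params.nnd_jitter_nm, pts.shape)
            pts = pts + np.array([cx, cy])
            positions.append(pts)
            ids.append(np.full(n, cid))
            centres.append((cx, cy, row_i))

    n_clusters = cid
    if params.fragmentation_fraction > 0:
        n_frag = int(round(params.fragmentation_fraction * n_clusters))
        frag_ids = rng.choice(np.arange(1, n_clusters + 1), size=n_frag, replace=False)
        for fi in frag_ids:
            pts = positions[fi - 1]
            if len(pts) < 2:
                continue
            centre = pts.mean(axis=0)
            rel = pts - centre
            k = int(rng.integers(2, 4))
            theta = np.arctan2(rel[:, 1], rel[:, 0])
            group = np.floor((theta + np.pi) / (2 * np.pi) * k).astype(int) % k
            for g in range(k):
                sel = group == g
                if not sel.any():
                    continue
                phi = rng.uniform(0, 2 * np.pi)
                d = rng.uniform(50.0, 200.0)
                sub_c = rel[sel].mean(axis=0)
                # loosen packing and displace the sub-cluster
                rel[sel] = sub_c + (rel[sel] - sub_c) * 1.25 + d * np.array([np.cos(phi), np.sin(phi)])
            positions[fi - 1] = centre + rel

    pos = np.vstack(positions) if positions else np.empty((0, 2))
    cluster_ids = np.concatenate(ids) if ids else np.empty(0, int)
    # keep channels inside the cell footprint
    np.clip(pos[:, 0], margin, fx - margin, out=pos[:, 0])
    np.clip(pos[:, 1], margin, fy - margin, out=pos[:, 1])

    sites = []
    centres_arr = np.array([(c[0], c[1]) for c in centres])
    rows = np.array([c[2] for c in centres])
    for row_i in np.unique(rows):
        cc = centres_arr[rows == row_i]
        cc = cc[np.argsort(cc[:, 0])]
        for a, b in zip(cc[:-1], cc[1:]):
            sites.append(0.5 * (a + b))
    return GroundTruth(
        channel_positions=pos,
        cluster_ids=cluster_ids,
        field_size_nm=(fx, fy),
        margin_nm=margin,
        recurring_sites=np.array(sites) if sites else np.empty((0, 2)),
        cell_mask_coarse=cell,
        cell_mask_px_nm=mask_px,
        params=params,
    )


def simulate_paint_localizations(
    truth: GroundTruth, params: SceneParams, n_frames: int = 20000
) -> LocalizationTable:
    """Emit DNA-PAINT localization events for a ground-truth channel map.

    Each channel is retained with probability ``labelling_efficiency``; a
    retained channel emits ``1 + Poisson(events_per_channel - 1)`` events at
    its position plus isotropic Gaussian localization error of
    ``localization_precision_nm``, on uniformly random frames.
    """
    rng = np.random.default_rng([params.seed, 1])
    pos = truth.channel_positions
    keep = rng.random(len(pos)) < params.labelling_efficiency
    kept = pos[keep]
    xs, ys, frames = [], [], []
    n_events = 1 + rng.poisson(max(params.events_per_channel - 1.0, 0.0), size=len(kept))
    for (x, y), k in zip(kept, n_events):
        xs.append(x + rng.normal(0.0, params.localization_precision_nm, k))
        ys.append(y + rng.normal(0.0, params.localization_precision_nm, k))
        frames.append(rng.integers(0, n_frames, k))
    if xs:
        x_all = np.concatenate(xs)
        y_all = np.concatenate(ys)
        f_all = np.concatenate(frames)
    else:
        x_all = y_all = np.empty(0)
        f_all = np.empty(0, int)
    return LocalizationTable.from_arrays(
        x_all,
        y_all,
        frame=f_all,
        intensity=np.ones_like(x_all),
        sigma_nm=np.full_like(x_all, float(params.localization_precision_nm)),
    )


def cell_mask(field_size_nm, camera_px_nm: float, margin_nm: float) -> np.ndarray:
    """Boolean cell-footprint mask: the field rectangle inset by the margin."""
    w = int(round(field_size_nm[0] / camera_px_nm))
    h = int(round(field_size_nm[1] / camera_px_nm))
    mask = np.zeros((h, w), bool)
    xs = (np.arange(w) + 0.5) * camera_px_nm
    ys = (np.arange(h) + 0.5) * camera_px_nm
    in_x = (xs >= margin_nm) & (xs <= field_size_nm[0] - margin_nm)
    in_y = (ys >= margin_nm) & (ys <= field_size_nm[1] - margin_nm)
    mask[np.ix_(in_y, in_x)] = True
    return mask


def _spark_frame_weights(t_on_s, duration_ms, n_frames, frame_dt):
    """Per-frame temporal weights: the peak frame carries the full nominal
    amplitude, later frames decay exponentially with tau = duration / 2."""
    w = np.zeros(n_frames)
    k0 = int(t_on_s / frame_dt)
    if k0 >= n_frames:
        return w
    tau = duration_ms * 1e-3 / 2.0
    k = np.arange(k0, n_frames)
    w[k0:] = np.exp(-(k - k0) * frame_dt / tau)
    return w


def simulate_spark_movie(
    truth: GroundTruth,
    params: SparkMovieParams,
    spark_events: pd.DataFrame | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a TIRF Ca2+ spark movie for a scene, returning (movie, spark truth).

    The movie is baseline (cell interior at ``baseline_f0``, exterior at
    ``background``) plus one spatial 2D Gaussian per spark scaled so that the
    nominal F/F0 amplitude is reached at the peak frame, plus white noise
    calibrated to the target averaged-image SNR. Sparks may be passed in via
    ``spark_events`` (columns like :data:`SPARK_TRUTH_COLUMNS`); otherwise
    they are drawn at ``spark_rate`` per second, a ``recurring_site_fraction``
    of them at the scene's designated inter-cluster sites.
    """
    rng = np.random.default_rng([params.seed, 2])
    fx, fy = truth.field_size_nm
    px = params.camera_px_nm
    w = int(round(fx / px))
    h = int(round(fy / px))
    frame_dt = 1.0 / params.frame_rate_hz
    total_s = params.n_frames * frame_dt

    mask = cell_mask_image(truth, px)
    if mask.shape != (h, w):  # rounding of non-integer resampling factors
        fixed = np.zeros((h, w), bool)
        fixed[: mask.shape[0], : mask.shape[1]] = mask[:h, :w]
        mask = fixed
    # resting-fluorescence texture: the Ca image sees the couplon-dense cell
    # structure through the diffraction-limited TIRF PSF, so the averaged
    # reference image carries registrable intensity landscape, as real
    # averaged Ca images do (this is what intensity-based fine alignment uses)
    base_cell = np.full((h, w), float(params.baseline_f0))
    if params.baseline_texture > 0 and len(truth.channel_positions):
        pos = truth.channel_positions
        dens, _, _ = np.histogram2d(pos[:, 1], pos[:, 0], bins=(h, w), range=[[0, fy], [0, fx]])
        psf_sigma_px = params.texture_psf_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / px
        topo = ndimage.gaussian_filter(dens, psf_sigma_px)
        if topo.max() > 0:
            topo = topo / topo.max()
        t_amp = params.baseline_texture
        base_cell = params.baseline_f0 * (1.0 - t_amp / 2.0 + t_amp * topo)
    baseline = np.where(mask, base_cell, params.background)

    if spark_events is None:
        n_sparks = rng.poisson(params.spark_rate * total_s)
        recs = []
        for _ in range(n_sparks):
            if (
                params.recurring_site_fraction > 0
                and len(truth.recurring_sites)
                and rng.random() < params.recurring_site_fraction
            ):
                site = truth.recurring_sites[rng.integers(len(truth.recurring_sites))]
                x, y = site + rng.normal(0.0, 100.0, 2)
            else:
                for _ in range(200):  # rejection-sample inside the cell footprint
                    x = rng.uniform(truth.margin_nm, fx - truth.margin_nm)
                    y = rng.uniform(truth.margin_nm, fy - truth.margin_nm)
                    if points_in_cell(truth, [[x, y]])[0]:
                        break
            recs.append(
                (
                    x,
                    y,
                    rng.uniform(0.0, total_s - frame_dt),
                    rng.uniform(*params.duration_range_ms),
                    rng.uniform(*params.amplitude_range),
                    rng.uniform(*params.fwhm_range_um),
                )
            )
        spark_events = pd.DataFrame(recs, columns=SPARK_TRUTH_COLUMNS)
    else:
        spark_events = spark_events.copy()

    movie = np.broadcast_to(baseline, (params.n_frames, h, w)).astype(float).copy()
    xs = (np.arange(w) + 0.5) * px
    ys = (np.arange(h) + 0.5) * px
    xx, yy = np.meshgrid(xs, ys)
    for rec in spark_events.itertuples(index=False):
        if not (0 <= rec.x_nm <= fx and 0 <= rec.y_nm <= fy):
            warnings.warn("spark placed outside the field; clipped", stacklevel=2)
        sigma_nm = rec.fwhm_um * 1e3 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        g = np.exp(-((xx - rec.x_nm) ** 2 + (yy - rec.y_nm) ** 2) / (2.0 * sigma_nm**2))
        wts = _spark_frame_weights(rec.t_on_s, rec.duration_ms, params.n_frames, frame_dt)
        # scale by the local baseline so F/F0 at the peak equals the nominal amplitude
        dpeak = (rec.amplitude - 1.0) * g * baseline
        nz = np.nonzero(wts)[0]
        for k in nz:
            if wts[k] < 1e-3:
                continue
            movie[k] += dpeak * wts[k]

    if np.isfinite(params.snr):
        contrast = baseline[mask].mean() - params.background if mask.any() else params.baseline_f0
        sigma = contrast * np.sqrt(params.snr_avg_frames) / params.snr
        movie += rng.normal(0.0, sigma, movie.shape)
    truth.spark_events = spark_events
    return movie, spark_events


def measure_snr(movie: np.ndarray, mask: np.ndarray, n_avg: int = 10) -> float:
    """SNR of the ``n_avg``-frame-averaged image: (in-cell mean − background
    mean) / s.d. of the background on the averaged image."""
    avg = np.asarray(movie[:n_avg], float).mean(axis=0)
    inner = ndimage.binary_erosion(mask, iterations=2)
    bg = avg[~mask]
    if bg.size < 10:
        raise ValueError("mask leaves too few background pixels to estimate noise")
    return (avg[inner].mean() - bg.mean()) / bg.std()


def apply_known_shift(image: np.ndarray, shift_nm: tuple[float, float], px_nm: float) -> np.ndarray:
    """Translate an image by (dx, dy) nm with sub-pixel spline interpolation.

    Positive dx moves content to the right, positive dy down. The inverse
    shift restores the original within interpolation tolerance.
    """
    dx, dy = shift_nm
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ValueError("shift must be finite")
    return ndimage.shift(np.asarray(image, float), (dy / px_nm, dx / px_nm), order=3, mode="nearest")


def ctrl_like(seed: int = 0, **overrides) -> SceneParams:
    """Healthy-myocyte preset: compact clusters, no fragmentation."""
    return replace(SceneParams(seed=seed), **overrides)


def mct_like(seed: int = 0, **overrides) -> SceneParams:
    """Failing-myocyte preset: half the clusters fragmented and dispersed."""
    return replace(SceneParams(seed=seed, fragmentation_fraction=0.5), **overrides)
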