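"""End-to-end orchestration of the correlative spark / RyR2 workflow.

``run_correlative`` drives the full chain — spark detection, PAINT rendering
and segmentation, registration, footprint sampling, recurring-site
segmentation and optional null models — on either synthetic scenes or
on-disk inputs, writing every table, image and a machine-readable run
manifest. ``make_fixture`` materializes a ctrl-like or mct-like synthetic
dataset on disk.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from sparkmap import align, footprint, io, nullmodels, sites, sparks, synthetic
from sparkmap import paint as paint_mod

log = logging.getLogger("sparkmap")

__all__ = ["RunConfig", "run_correlative", "make_fixture"]


@dataclass
class RunConfig:
    """All pipeline parameters, with defaults at the conventional values:
    FWHM filter 1.0-6.0 µm, R² 0.5, 5 nm/px rendering, 80% labelling
    fraction, >= 4 puncta per cluster, 15 s site window, 250 nm PSF, SNR 17.
    """

    scene: synthetic.SceneParams = field(default_factory=synthetic.SceneParams)
    movie: synthetic.SparkMovieParams = field(default_factory=synthetic.SparkMovieParams)
    spark_filter: sparks.SparkFilterConfig = field(default_factory=sparks.SparkFilterConfig)
    detection_sigma: float = 5.0
    render_px_nm: float = 5.0
    labelling_fraction: float = 0.80
    min_cluster_size: int = 4
    avg_frames: int = 10
    psf_fwhm_nm: float = 250.0
    true_shift_nm: tuple[float, float] = (300.0, -200.0)
    site_window_s: float = 15.0
    site_max_leaf_points: int = 3
    site_min_leaf_size_nm: float = 100.0
    site_density_factor: float = 4.0
    run_null: bool = False
    null_mode: str = "randomize-ryr"
    null_replicates: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("field_size_um",):
            if key in d["scene"]:
                d["scene"][key] = list(d["scene"][key])
        return d


def _stage(name: str, n_in: int | None, n_out: int) -> None:
    log.info("stage=%s in=%s out=%d", name, n_in, n_out)


def run_correlative(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full correlative pipeline on a synthetic scene.

    Returns a results dict (tables, cluster map, transform, sites, summary)
    and writes CSV/TIFF/YAML/JSON outputs plus a run manifest into
    ``outdir``. Stage failures raise with the stage name; outputs written
    before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {"parameters": config.to_dict(), "stages": {}}

    # --- synthesis -------------------------------------------------------
    truth = synthetic.generate_ryr_map(config.scene)
    truth.true_shift_nm = tuple(config.true_shift_nm)
    locs = synthetic.simulate_paint_localizations(truth, config.scene)
    movie, spark_truth = synthetic.simulate_spark_movie(truth, config.movie)
    if any(config.true_shift_nm):
        movie = np.stack(
            [synthetic.apply_known_shift(f, config.true_shift_nm, config.movie.camera_px_nm)
             for f in movie]
        )
    locs.to_csv(outdir / "localizations.csv")
    io.write_movie_tiff(outdir / "ca_movie.tif", movie)
    spark_truth.to_csv(outdir / "spark_truth.csv", index=False)
    manifest["stages"]["synthetic"] = {
        "n_channels": len(truth.channel_positions),
        "n_localizations": len(locs),
        "n_true_sparks": len(spark_truth),
    }
    _stage("synthetic", None, len(spark_truth))

    # --- sparks ----------------------------------------------------------
    f0 = sparks.estimate_baseline(movie)
    cands = sparks.detect_sparks(
        movie, f0, detection_sigma=config.detection_sigma,
        camera_px_nm=config.movie.camera_px_nm,
    )
    records = sparks.fit_candidates(
        movie, f0, cands,
        camera_px_nm=config.movie.camera_px_nm,
        frame_rate_hz=config.movie.frame_rate_hz,
    )
    retained = sparks.filter_sparks(records, config.spark_filter)
    spark_df = sparks.records_to_frame(retained)
    spark_df.to_csv(outdir / "sparks.csv", index=False)
    results["sparks"] = retained
    manifest["stages"]["sparks"] = {
        "candidates": len(cands), "fitted": len(records), "retained": len(retained),
    }
    _stage("sparks", len(cands), len(retained))

    # --- paint -----------------------------------------------------------
    rendered = paint_mod.render_image(locs, truth.field_size_nm, config.render_px_nm)
    puncta = paint_mod.detect_puncta(rendered, config.render_px_nm)
    cmap = paint_mod.segment_clusters(
        rendered, puncta, config.render_px_nm,
        labelling_fraction=config.labelling_fraction,
        min_cluster_size=config.min_cluster_size,
    )
    io.write_rendered_tiff(outdir / "rendered.tif", rendered)
    io.write_rendered_tiff(outdir / "cluster_mask.tif", cmap.mask.astype(float))
    pd.DataFrame(
        {"x_nm": puncta[:, 0], "y_nm": puncta[:, 1], "cluster_id": cmap.cluster_ids}
    ).to_csv(outdir / "puncta.csv", index=False)
    results["cluster_map"] = cmap
    manifest["stages"]["paint"] = {"puncta": len(puncta), "clusters": cmap.n_clusters}
    _stage("paint", len(locs), len(puncta))

    # --- align -----------------------------------------------------------
    avg = align.average_frames(movie, n=config.avg_frames)
    up = align.upscale(avg, config.movie.camera_px_nm, config.render_px_nm)
    psf_sigma_px = config.psf_fwhm_nm / (2 * np.sqrt(2 * np.log(2))) / config.render_px_nm
    reference = ndimage.gaussian_filter(rendered, psf_sigma_px)
    rec = align.fine_align_xcorr(reference, up, px_nm=config.render_px_nm)
    transform = align.AlignmentTransform(
        scale=1.0, shift_nm=(-rec.shift_nm[0], -rec.shift_nm[1]), score=rec.score
    )
    io.write_yaml(outdir / "transform.yaml",
                  {"scale": transform.scale, "shift_nm": list(transform.shift_nm),
                   "score": transform.score})
    results["transform"] = transform
    manifest["stages"]["align"] = {
        "recovered_shift_nm": list(rec.shift_nm), "true_shift_nm": list(config.true_shift_nm),
        "score": rec.score,
    }
    _stage("align", None, 1)

    # --- footprint -------------------------------------------------------
    samples, summary = footprint.sample_all(
        retained, cmap, transform, min_cluster_size=config.min_cluster_size
    )
    samples.to_csv(outdir / "samples.csv", index=False)
    io.write_json(outdir / "summary.json", summary)
    results["samples"] = samples
    results["summary"] = summary
    manifest["stages"]["footprint"] = {"samples": len(samples)}
    _stage("footprint", len(retained), len(samples))

    # --- sites -----------------------------------------------------------
    fx, fy = truth.field_size_nm
    if len(samples):
        centroids = samples[["x_nm", "y_nm"]].to_numpy()
        times = spark_df["t_s"].to_numpy()
    else:
        centroids = np.empty((0, 2))
        times = np.empty(0)
    site_list, leaves = sites.quadtree_segment(
        centroids, (0.0, 0.0, fx, fy), times_s=times,
        time_window_s=config.site_window_s,
        max_leaf_points=config.site_max_leaf_points,
        min_leaf_size_nm=config.site_min_leaf_size_nm,
        density_factor=config.site_density_factor,
    )
    overlap, overlap_summary = sites.site_cluster_overlap(site_list, cmap)
    io.write_json(
        outdir / "sites.json",
        {
            "parameters": {
                "time_window_s": config.site_window_s,
                "max_leaf_points": config.site_max_leaf_points,
                "min_leaf_size_nm": config.site_min_leaf_size_nm,
                "density_factor": config.site_density_factor,
            },
            "sites": [
                {
                    "leaves": [[l.x0, l.y0, l.size] for l in s.leaves],
                    "centroid_count": s.centroid_count,
                    "density_per_um2": s.density_per_um2,
                    "width_nm": s.width_nm,
                    "cluster_overlap": float(overlap[i]) if len(overlap) else None,
                }
                for i, s in enumerate(site_list)
            ],
            "overlap_summary": overlap_summary,
        },
    )
    results["sites"] = site_list
    manifest["stages"]["sites"] = {"sites": len(site_list), "leaves": len(leaves)}
    _stage("sites", len(centroids), len(site_list))

    # --- null models (optional) -----------------------------------------
    if config.run_null:
        region = synthetic.cell_mask_image(truth, config.render_px_nm)
        null_cfg = nullmodels.NullConfig(config.null_mode, config.null_replicates, config.seed)
        comparisons = []
        for rep in range(null_cfg.n_replicates):
            rng = np.random.default_rng([null_cfg.seed, 3, rep])
            if null_cfg.mode == "randomize-ryr":
                new_pos = nullmodels.randomize_points(cmap.puncta, region, config.render_px_nm, rng)
                null_locs = paint_mod.LocalizationTable.from_arrays(
                    new_pos[:, 0], new_pos[:, 1],
                    sigma_nm=np.full(len(new_pos), config.scene.localization_precision_nm),
                )
                null_rendered = paint_mod.render_image(null_locs, truth.field_size_nm, config.render_px_nm)
                null_puncta = paint_mod.detect_puncta(null_rendered, config.render_px_nm)
                null_cmap = paint_mod.segment_clusters(
                    null_rendered, null_puncta, config.render_px_nm,
                    labelling_fraction=config.labelling_fraction,
                    min_cluster_size=config.min_cluster_size,
                )
                null_samples, _ = footprint.sample_all(
                    retained, null_cmap, transform, min_cluster_size=config.min_cluster_size
                )
            else:
                new_pos = nullmodels.randomize_points(
                    samples[["x_nm", "y_nm"]].to_numpy(), region, config.render_px_nm, rng
                )
                moved = [
                    dataclasses.replace(s, x_nm=new_pos[i, 0], y_nm=new_pos[i, 1])
                    for i, s in enumerate(retained)
                ]
                null_samples, _ = footprint.sample_all(
                    moved, cmap, None, min_cluster_size=config.min_cluster_size
                )
            null_samples.to_csv(outdir / f"null_samples_rep{rep}.csv", index=False)
            comparisons.append(nullmodels.null_comparison(samples, null_samples))
        io.write_json(outdir / "null_comparison.json", comparisons)
        results["null_comparisons"] = comparisons
        manifest["stages"]["null"] = {"replicates": null_cfg.n_replicates, "mode": null_cfg.mode}
        _stage("null", len(samples), null_cfg.n_replicates)

    io.write_json(outdir / "manifest.json", manifest)
    results["manifest"] = manifest
    return results


def make_fixture(preset: str, seed: int, outdir: str | Path) -> dict:
    """Write a ctrl-like or mct-like synthetic dataset to disk.

    mct-like sets fragmentation_fraction = 0.5 and doubles the spark rate
    (qualitative disease preset); both presets share the field geometry.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if preset == "ctrl-like":
        scene = synthetic.ctrl_like(seed)
        movie_params = synthetic.SparkMovieParams(seed=seed)
    elif preset == "mct-like":
        scene = synthetic.mct_like(seed)
        movie_params = synthetic.SparkMovieParams(seed=seed, spark_rate=4.0)
    else:
        raise ValueError("preset must be 'ctrl-like' or 'mct-like'")
    truth = synthetic.generate_ryr_map(scene)
    locs = synthetic.simulate_paint_localizations(truth, scene)
    movie, spark_truth = synthetic.simulate_spark_movie(truth, movie_params)
    io.write_movie_tiff(outdir / "ca_movie.tif", movie)
    locs.to_csv(outdir / "localizations.csv")
    pd.DataFrame(
        {
            "x_nm": truth.channel_positions[:, 0],
            "y_nm": truth.channel_positions[:, 1],
            "cluster_id": truth.cluster_ids,
        }
    ).to_csv(outdir / "truth.csv", index=False)
    spark_truth.to_csv(outdir / "spark_truth.csv", index=False)
    io.write_yaml(
        outdir / "config.yaml",
        {"preset": preset, "scene": dataclasses.asdict(scene) | {"field_size_um": list(scene.field_size_um)},
         "movie": dataclasses.asdict(movie_params)
         | {"amplitude_range": list(movie_params.amplitude_range),
            "fwhm_range_um": list(movie_params.fwhm_range_um),
            "duration_range_ms": list(movie_params.duration_range_ms)}},
    )
    return {"truth": truth, "localizations": locs, "movie": movie, "spark_truth": spark_truth}
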