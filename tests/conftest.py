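"""Shared synthetic fixtures; everything is generated at test time."""

import numpy as np
import pandas as pd
import pytest

from sparkmap import paint, synthetic


@pytest.fixture(scope="session")
def ctrl_scene():
    """Healthy-like scene with the default geometry, fixed seed."""
    params = synthetic.SceneParams(seed=7)
    truth = synthetic.generate_ryr_map(params)
    return params, truth


@pytest.fixture(scope="session")
def ctrl_localizations(ctrl_scene):
    params, truth = ctrl_scene
    return synthetic.simulate_paint_localizations(truth, params)


@pytest.fixture(scope="session")
def ctrl_rendering(ctrl_scene, ctrl_localizations):
    _, truth = ctrl_scene
    return paint.render_image(ctrl_localizations, truth.field_size_nm)


@pytest.fixture(scope="session")
def ctrl_cluster_map(ctrl_scene, ctrl_rendering):
    _, truth = ctrl_scene
    puncta = paint.detect_puncta(ctrl_rendering)
    return paint.segment_clusters(ctrl_rendering, puncta)


@pytest.fixture(scope="session")
def noisy_spark_movie(ctrl_scene):
    """SNR-17 movie with its spark truth table."""
    params, truth = ctrl_scene
    movie_params = synthetic.SparkMovieParams(seed=7, n_frames=150)
    movie, spark_truth = synthetic.simulate_spark_movie(truth, movie_params)
    return movie, spark_truth, movie_params


def single_spark_movie(
    amplitude=2.0,
    fwhm_um=2.0,
    x_nm=9850.0,   # deep-interior point of the seed-5 cell footprint
    y_nm=5050.0,
    t_on_s=0.55,
    snr=np.inf,
    n_frames=20,
    seed=5,
):
    """Noise-free (by default) movie holding exactly one constructed spark."""
    params = synthetic.SceneParams(seed=seed)
    truth = synthetic.generate_ryr_map(params)
    movie_params = synthetic.SparkMovieParams(seed=seed, n_frames=n_frames, snr=snr)
    events = pd.DataFrame(
        [[x_nm, y_nm, t_on_s, 80.0, amplitude, fwhm_um]],
        columns=synthetic.SPARK_TRUTH_COLUMNS,
    )
    movie, _ = synthetic.simulate_spark_movie(truth, movie_params, spark_events=events)
    return movie, truth, movie_params
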