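"""Footprint sampling, NND/3ND, mass statistics and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from sparkmap import footprint, paint, sparks


def make_cluster_map(puncta, cluster_ids, min_cluster_size=4, render_px=5.0):
    puncta = np.asarray(puncta, float).reshape(-1, 2)
    return paint.ClusterMap(
        rendered=np.zeros((10, 10)),
        render_px_nm=render_px,
        puncta=puncta,
        mask=np.zeros((10, 10), bool),
        labels=np.zeros((10, 10), int),
        cluster_ids=np.asarray(cluster_ids, int),
        min_cluster_size=min_cluster_size,
    )


def spark_at(x, y, fwhm_um=1.0, amplitude=2.0):
    return sparks.SparkRecord(x, y, 0, 0.0, fwhm_um, amplitude, 0.9)


class TestFootprintSample:
    def test_boundary_inclusive_radius(self):
        # radii 0.30, 0.49, 0.51 um around origin-spark with FWHM 1.0 um
        puncta = [(300.0, 0.0), (0.0, 490.0), (510.0, 0.0)]
        cm = make_cluster_map(puncta, [1, 1, 1], min_cluster_size=1)
        s = footprint.footprint_sample(spark_at(0.0, 0.0, 1.0), cm)
        assert s.ryr_count == 2

    def test_collinear_hand_geometry(self):
        puncta = [(0.0, 0.0), (38.0, 0.0), (100.0, 0.0)]
        cm = make_cluster_map(puncta, [1, 1, 1], min_cluster_size=3)
        s = footprint.footprint_sample(spark_at(50.0, 0.0, 1.0), cm, min_cluster_size=3)
        assert s.ryr_count == 3
        assert s.nnd_nm == pytest.approx((38.0 + 38.0 + 62.0) / 3.0)
        assert np.isnan(s.tnd_nm)  # 3ND needs at least 4 qualifying puncta

    def test_empty_window_flagged(self):
        cm = make_cluster_map([(5000.0, 5000.0)], [1], min_cluster_size=1)
        s = footprint.footprint_sample(spark_at(0.0, 0.0, 1.0), cm)
        assert s.ryr_count == 0
        assert np.isnan(s.nnd_nm) and np.isnan(s.mass_ratio)

    def test_counts_and_distances_match_bruteforce(self):
        rng = np.random.default_rng(8)
        puncta = rng.uniform(0, 10000, (500, 2))
        ids = rng.integers(1, 40, 500)
        sizes = np.bincount(ids, minlength=41)
        cm = make_cluster_map(puncta, ids)
        for _ in range(50):
            cx, cy = rng.uniform(0, 10000, 2)
            fwhm = rng.uniform(0.5, 3.0)
            s = footprint.footprint_sample(spark_at(cx, cy, fwhm), cm)
            r = fwhm * 1e3 / 2
            d = np.hypot(puncta[:, 0] - cx, puncta[:, 1] - cy)
            inc = d <= r
            assert s.ryr_count == inc.sum()
            qual = sizes[ids] >= 4
            assert s.cluster_count == len(np.unique(ids[inc & qual]))
            qpts = puncta[inc & qual]
            if len(qpts) >= 2:
                dm = np.hypot(
                    qpts[:, 0:1] - qpts[:, 0], qpts[:, 1:2] - qpts[:, 1]
                )
                np.fill_diagonal(dm, np.inf)
                assert s.nnd_nm == pytest.approx(np.sort(dm, axis=1)[:, 0].mean())
                if len(qpts) >= 4:
                    assert s.tnd_nm == pytest.approx(np.sort(dm, axis=1)[:, :3].mean())
                    assert s.nnd_nm <= s.tnd_nm
            else:
                assert np.isnan(s.nnd_nm)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        puncta = rng.uniform(0, 5000, (100, 2))
        ids = rng.integers(1, 10, 100)
        shift = np.array([1234.5, -678.9])
        cm_a = make_cluster_map(puncta, ids)
        cm_b = make_cluster_map(puncta + shift, ids)
        sp = spark_at(2500.0, 2500.0, 2.0)
        sp_shifted = spark_at(2500.0 + shift[0], 2500.0 + shift[1], 2.0)
        a = footprint.footprint_sample(sp, cm_a)
        b = footprint.footprint_sample(sp_shifted, cm_b)
        assert a.ryr_count == b.ryr_count and a.cluster_count == b.cluster_count
        assert a.nnd_nm == pytest.approx(b.nnd_nm, nan_ok=True)

    def test_transform_applied_before_sampling(self):
        cm = make_cluster_map([(1000.0, 1000.0), (1010.0, 1000.0),
                               (1000.0, 1010.0), (1010.0, 1010.0)], [1, 1, 1, 1])
        from sparkmap.align import AlignmentTransform

        t = AlignmentTransform(scale=1.0, shift_nm=(1000.0, 1000.0))
        s = footprint.footprint_sample(spark_at(5.0, 5.0, 0.5), cm, transform=t)
        assert s.ryr_count == 4


class TestSampleAll:
    def test_empty_spark_list(self, ctrl_cluster_map):
        df, summary = footprint.sample_all([], ctrl_cluster_map)
        assert len(df) == 0 and summary["n_sparks"] == 0

    def test_single_spark_covering_everything(self):
        rng = np.random.default_rng(1)
        puncta = rng.uniform(0, 1000, (30, 2))
        cm = make_cluster_map(puncta, np.ones(30, int))
        df, summary = footprint.sample_all([spark_at(500.0, 500.0, 4.0)], cm)
        assert df["ryr_count"].iloc[0] == 30
        assert summary["mean_ryr_count"] == 30


class TestMassVsCountFit:
    def test_exact_quadratic_recovered(self):
        x = np.arange(1, 40, dtype=float)
        y = 0.272 * x**2 - 0.3
        df = pd.DataFrame({"ryr_count": x, "mass": y})
        a, b, rv = footprint.mass_vs_count_fit(df)
        assert a == pytest.approx(0.272, abs=1e-6)
        assert b == pytest.approx(-0.3, abs=1e-6)
        assert rv < 1e-12

    def test_constant_response_gives_zero_curvature(self):
        df = pd.DataFrame({"ryr_count": np.arange(1, 20, dtype=float), "mass": 5.0})
        a, b, _ = footprint.mass_vs_count_fit(df)
        assert a == pytest.approx(0.0, abs=1e-9)
        assert b == pytest.approx(5.0, abs=1e-9)

    def test_noise_scales_residual_variance(self):
        rng = np.random.default_rng(5)
        x = np.tile(np.arange(1, 30, dtype=float), 4)
        out = []
        for noise in (0.5, 2.0):
            y = 0.1 * x**2 + rng.normal(0, noise, len(x))
            _, _, rv = footprint.mass_vs_count_fit(pd.DataFrame({"ryr_count": x, "mass": y}))
            out.append(rv)
        assert out[1] > 4 * out[0]

    def test_too_few_samples_rejected(self):
        df = pd.DataFrame({"ryr_count": [1.0, 2.0], "mass": [1.0, 2.0]})
        with pytest.raises(ValueError):
            footprint.mass_vs_count_fit(df)


class TestMassRatioStats:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"mass_ratio": rng.normal(1, 0.2, 300)})
        out = footprint.mass_ratio_stats(a, a)
        assert out["bartlett_p"] == pytest.approx(1.0)
        assert out["mannwhitney_p"] == pytest.approx(1.0)

    def test_complete_separation_u_zero(self):
        a = pd.DataFrame({"mass_ratio": [1.0, 2.0, 3.0]})
        b = pd.DataFrame({"mass_ratio": [4.0, 5.0, 6.0]})
        out = footprint.mass_ratio_stats(a, b)
        assert out["mannwhitney_u"] == 0.0

    def test_bartlett_power_on_variance_difference(self):
        rng = np.random.default_rng(6)
        rejections = 0
        for _ in range(100):
            a = pd.DataFrame({"mass_ratio": rng.normal(0, 1, 500)})
            b = pd.DataFrame({"mass_ratio": rng.normal(0, 2, 500)})
            out = footprint.mass_ratio_stats(a, b)
            rejections += out["bartlett_p"] < 0.01
        assert rejections >= 95

    def test_zero_variance_flagged(self):
        a = pd.DataFrame({"mass_ratio": [1.0, 1.0, 1.0]})
        b = pd.DataFrame({"mass_ratio": [1.0, 2.0, 3.0]})
        out = footprint.mass_ratio_stats(a, b)
        assert out["bartlett_degenerate"]


class TestSparkMassHeatmap:
    def make_map_with_labels(self):
        labels = np.zeros((100, 100), int)
        labels[10:20, 10:20] = 1
        labels[60:70, 60:70] = 2
        puncta = np.array([[75.0, 75.0], [80.0, 75.0], [75.0, 80.0], [80.0, 80.0],
                           [325.0, 325.0], [330.0, 325.0], [325.0, 330.0], [330.0, 330.0]])
        return paint.ClusterMap(
            rendered=np.zeros((100, 100)), render_px_nm=5.0, puncta=puncta,
            mask=labels > 0, labels=labels, cluster_ids=np.array([1] * 4 + [2] * 4),
            min_cluster_size=4,
        )

    def test_mean_of_overlapping_sparks(self):
        cm = self.make_map_with_labels()
        samples = pd.DataFrame(
            [
                {"x_nm": 75.0, "y_nm": 75.0, "fwhm_um": 0.2, "mass": 10.0},
                {"x_nm": 75.0, "y_nm": 75.0, "fwhm_um": 0.2, "mass": 20.0},
            ]
        )
        values, img = footprint.spark_mass_heatmap(cm, samples)
        assert values == {1: 15.0}
        assert np.nanmax(img) == 15.0
        assert np.isnan(img[65, 65])  # cluster 2 has no sparks: no-data

    def test_high_mass_sites_rank_highest(self):
        cm = self.make_map_with_labels()
        samples = pd.DataFrame(
            [
                {"x_nm": 75.0, "y_nm": 75.0, "fwhm_um": 0.2, "mass": 5.0},
                {"x_nm": 325.0, "y_nm": 325.0, "fwhm_um": 0.2, "mass": 50.0},
            ]
        )
        values, _ = footprint.spark_mass_heatmap(cm, samples)
        assert values[2] > values[1]
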