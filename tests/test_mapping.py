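"""En-face map assembly, classification, rendering, comparison."""

import numpy as np
import pytest

from octatten import (
    AttenuationMap,
    AveragingSpec,
    ClassificationRule,
    MapConfig,
    OCTVolume,
    SimulationConfig,
    TailSpec,
    build_map,
    classify,
    compare_maps,
    render,
    simulate_volume,
)
from octatten.mapping import (
    LABEL_HIGH_CANCER,
    LABEL_LOW_CANCER,
    LABEL_UNKNOWN,
    read_map_csv,
)

SMALL_AVG = AveragingSpec(window_alines=64, step_alines=16)


def noiseless_cfg(**kwargs):
    defaults = dict(
        n_depth=900, n_alines=256, n_frames=2, mu_field=3.0,
        surface_height=0.05, speckle=False, noise_floor=0.0, seed=0,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def tiny_map(mu, mask=None):
    mu = np.asarray(mu, dtype=float)
    if mask is None:
        mask = np.isfinite(mu)
    return AttenuationMap(
        mu=mu, mask=np.asarray(mask, bool),
        x_mm=np.arange(mu.shape[1], dtype=float),
        y_mm=np.arange(mu.shape[0], dtype=float),
    )


class TestBuildMap:
    def test_homogeneous_noiseless_pipeline_identity(self):
        vol, ref, _ = simulate_volume(noiseless_cfg())
        amap = build_map(vol, ref, MapConfig(method="FD", averaging=SMALL_AVG))
        assert amap.n_valid == amap.mu.size
        np.testing.assert_allclose(amap.mu, 3.0, atol=1e-6)

    def test_fd_and_ef_maps_identical_noiseless(self):
        vol, ref, _ = simulate_volume(noiseless_cfg())
        fd = build_map(vol, ref, MapConfig(method="FD", averaging=SMALL_AVG))
        ef = build_map(vol, ref, MapConfig(method="EF", averaging=SMALL_AVG))
        np.testing.assert_allclose(fd.mu, ef.mu, atol=1e-6)

    def test_two_region_boundary_localized(self):
        """A step in the attenuation field must appear in the map within
        one averaging window of the programmed x position."""
        split_mm = 0.125
        cfg = noiseless_cfg(
            mu_field=lambda x, y: 3.0 if x < split_mm else 7.0, n_alines=256
        )
        vol, ref, _ = simulate_volume(cfg)
        amap = build_map(vol, ref, MapConfig(method="FD", averaging=SMALL_AVG))
        row = amap.mu[0]
        # cells fully left of the split ~3, fully right ~7
        window_mm = SMALL_AVG.window_alines * vol.dx
        left = amap.x_mm < split_mm - window_mm / 2
        right = amap.x_mm > split_mm + window_mm / 2
        np.testing.assert_allclose(row[left], 3.0, atol=1e-6)
        np.testing.assert_allclose(row[right], 7.0, atol=1e-6)
        crossings = np.flatnonzero(np.diff(row > 5.0))
        assert crossings.size == 1
        assert abs(amap.x_mm[crossings[0]] - split_mm) <= window_mm

    def test_zero_volume_fully_masked_without_exception(self):
        vol = OCTVolume(
            np.zeros((1, 128, 200)), dz=0.001, dx=0.002, dy=0.01
        )
        _, ref, _ = simulate_volume(noiseless_cfg(n_depth=200, dz=0.001))
        amap = build_map(vol, ref, MapConfig(
            method="FD", data_length_mm=0.1, averaging=AveragingSpec(32, 16)))
        assert amap.n_valid == 0

    def test_reference_dz_mismatch_rejected(self):
        vol, ref, _ = simulate_volume(noiseless_cfg(n_depth=200))
        bad = OCTVolume(vol.data, dz=vol.dz * 2, dx=vol.dx, dy=vol.dy)
        from octatten.signal_model import GeometryError

        with pytest.raises(GeometryError):
            build_map(bad, ref, MapConfig(averaging=SMALL_AVG))

    def test_lf_band_shrinks_with_data_length_relative_to_fd(self):
        """With few-scattering, lengthening the window drags LF below
        threshold sooner than FD: LF's supra-threshold area shrinks
        relative to FD's."""
        split_mm = 0.125
        cfg = noiseless_cfg(
            n_depth=1400,
            mu_field=lambda x, y: 6.5 if x < split_mm else 2.0,
            tail=TailSpec(enabled=True, c=0.2, alpha=0.3),
        )
        vol, ref, _ = simulate_volume(cfg)
        # band threshold placed between the two methods' tail-biased
        # long-window estimates of the high-mu region; the check is the
        # direction of the band shrinkage, not a diagnostic cutoff
        rule_mu = 2.6
        areas = {}
        for method in ("FD", "LF"):
            for window in (0.35, 1.05):
                amap = build_map(vol, ref, MapConfig(
                    method=method, data_length_mm=window, averaging=SMALL_AVG))
                areas[(method, window)] = int(
                    np.sum(amap.mu[amap.mask] > rule_mu)
                )
        assert areas[("LF", 1.05)] < areas[("FD", 1.05)]
        assert areas[("LF", 1.05)] < areas[("LF", 0.35)]


class TestClassify:
    def test_threshold_and_tie_rule(self):
        amap = tiny_map([[5.4, 5.5, 6.0, np.nan]])
        labels = classify(amap, ClassificationRule(threshold_mm1=5.5))
        assert labels[0, 0] == LABEL_HIGH_CANCER
        assert labels[0, 1] == LABEL_LOW_CANCER  # tie goes to "above"
        assert labels[0, 2] == LABEL_LOW_CANCER
        assert labels[0, 3] == LABEL_UNKNOWN

    def test_idempotent_and_total(self):
        rng = np.random.default_rng(0)
        amap = tiny_map(rng.uniform(0, 10, size=(4, 5)))
        rule = ClassificationRule()
        l1 = classify(amap, rule)
        l2 = classify(amap, rule)
        np.testing.assert_array_equal(l1, l2)
        assert np.all(l1 != LABEL_UNKNOWN)


class TestCompareMaps:
    def test_identical_maps_give_zero(self):
        a = tiny_map([[1.0, 2.0], [3.0, 4.0]])
        mean_d, sd_d = compare_maps(a, a)
        assert mean_d == 0.0 and sd_d == 0.0

    def test_constant_shift(self):
        a = tiny_map([[1.0, 2.0], [3.0, 4.0]])
        b = tiny_map(a.mu + 0.5)
        mean_d, sd_d = compare_maps(b, a)
        assert mean_d == pytest.approx(0.5)
        assert sd_d == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_maps(tiny_map([[1.0]]), tiny_map([[1.0, 2.0]]))

    def test_methods_agree_on_average_speckled(self):
        """FD and EF maps from one speckled, 300-line-averaged volume
        agree in the mean to better than 0.1 /mm."""
        cfg = SimulationConfig(
            n_depth=900, n_alines=512, n_frames=2, mu_field=3.0,
            surface_height=0.05, speckle=True, noise_floor=1e-3, seed=3,
        )
        vol, ref, _ = simulate_volume(cfg)
        avg = AveragingSpec(window_alines=300, step_alines=64)
        fd = build_map(vol, ref, MapConfig(method="FD", averaging=avg))
        ef = build_map(vol, ref, MapConfig(method="EF", averaging=avg))
        mean_d, _ = compare_maps(fd, ef)
        assert abs(mean_d) < 0.1


class TestRender:
    def test_csv_round_trip_and_png(self, tmp_path):
        rng = np.random.default_rng(1)
        mu = rng.uniform(2, 8, size=(3, 5))
        mu[1, 2] = np.nan
        amap = tiny_map(mu)
        paths = render(amap, ClassificationRule(), tmp_path / "m", mu_range=(2, 8))
        assert paths["png"].exists()
        back = read_map_csv(paths["csv"])
        valid = amap.mask
        np.testing.assert_allclose(back.mu[valid], amap.mu[valid], rtol=1e-5)
        np.testing.assert_array_equal(back.mask, amap.mask)

    def test_colormap_endpoints_and_masked_gray(self, tmp_path):
        from PIL import Image
        import matplotlib

        amap = tiny_map([[2.0, 8.0, np.nan]])
        paths = render(amap, ClassificationRule(), tmp_path / "m", mu_range=(2, 8))
        rgb = np.asarray(Image.open(paths["png"]))
        cmap = matplotlib.colormaps["RdYlGn"]
        lo = np.asarray(cmap(0.0)[:3]) * 255
        hi = np.asarray(cmap(1.0)[:3]) * 255
        assert np.allclose(rgb[0, 0], lo, atol=1)
        assert np.allclose(rgb[0, 1], hi, atol=1)
        assert np.allclose(rgb[0, 2], 127.5, atol=1)  # gray for masked
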