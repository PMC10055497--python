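import numpy as np
import pytest

from sbrnet import (AttenuationParams, BackgroundParams, NoiseParams,
                    add_mpg_noise, apply_attenuation, compose_measurement,
                    free_space_measurement, make_background, mean_signal,
                    solve_alpha)
from sbrnet.forward import free_space_only
from sbrnet.volume import rasterize_volume, sample_emitters
from tests.test_volume import make_emitters


@pytest.fixture(scope="module")
def tiny_psf(tiny_config):
    from sbrnet import DisparityModel, synth_psf_stack
    disp = DisparityModel.from_config(tiny_config, slope_magnitude_px_per_um=0.02)
    return synth_psf_stack(tiny_config, disp)


def volume_with_deltas(config, deltas):
    """A bare voxel volume (no rasterisation) with given (slice,row,col,val)."""
    vox = np.zeros((config.n_slices, config.grid_px, config.grid_px))
    for s, r, c, v in deltas:
        vox[s, r, c] = v
    em = make_emitters(config, np.empty((0, 3)), 15.0, 0.8)
    from sbrnet.volume import GroundTruthVolume
    return GroundTruthVolume(vox, em, config)


class TestFreeSpaceMeasurement:
    def test_zero_volume_zero_image(self, tiny_config, tiny_psf):
        vol = volume_with_deltas(tiny_config, [])
        assert not free_space_measurement(vol, tiny_psf).any()

    def test_single_voxel_reproduces_shifted_psf(self, tiny_config, tiny_psf):
        g = tiny_config.grid_px
        k, r, c = 5, g // 2 + 3, g // 2 - 4
        vol = volume_with_deltas(tiny_config, [(k, r, c, 1.0)])
        out = free_space_measurement(vol, tiny_psf)
        expected = np.zeros_like(out)
        dr, dc = r - g // 2, c - g // 2
        plane = tiny_psf.planes[k]
        expected[max(dr, 0):g + min(dr, 0), max(dc, 0):g + min(dc, 0)] = \
            plane[max(-dr, 0):g + min(-dr, 0), max(-dc, 0):g + min(-dc, 0)]
        assert np.allclose(out, expected, atol=1e-12)

    def test_two_voxel_superposition(self, tiny_config, tiny_psf):
        # brute-force superposition: response of two voxels equals the sum of
        # the individual responses
        a = volume_with_deltas(tiny_config, [(3, 40, 40, 0.7)])
        b = volume_with_deltas(tiny_config, [(12, 55, 50, 0.4)])
        ab = volume_with_deltas(tiny_config, [(3, 40, 40, 0.7),
                                              (12, 55, 50, 0.4)])
        lhs = free_space_measurement(ab, tiny_psf)
        rhs = (free_space_measurement(a, tiny_psf)
               + free_space_measurement(b, tiny_psf))
        assert np.allclose(lhs, rhs, atol=1e-6 * rhs.max())

    def test_slice_count_mismatch_rejected(self, tiny_config, tiny_psf):
        vol = volume_with_deltas(tiny_config, [])
        short = tiny_psf.subset(tiny_psf.z_positions_um[:10])
        with pytest.raises(ValueError, match="slices"):
            free_space_measurement(vol, short)


class TestMeanSignal:
    def test_two_isolated_peaks_average(self):
        img = np.zeros((32, 32))
        img[8, 8] = 0.4
        img[20, 20] = 0.8
        assert mean_signal(img) == pytest.approx(0.6)

    def test_single_delta(self):
        img = np.zeros((16, 16))
        img[7, 9] = 1.0
        assert mean_signal(img) == pytest.approx(1.0)

    def test_constant_image_degenerate(self):
        with pytest.raises(ValueError):
            mean_signal(np.full((16, 16), 0.5))

    def test_faint_peaks_below_floor_excluded(self):
        img = np.zeros((32, 32))
        img[8, 8] = 1.0
        img[20, 20] = 0.005  # below 1% of max
        assert mean_signal(img) == pytest.approx(1.0)

    def test_plateau_counts_once(self):
        img = np.zeros((32, 32))
        img[10:12, 10:12] = 0.6  # 4-pixel plateau
        img[25, 25] = 0.2
        assert mean_signal(img) == pytest.approx(0.4)


class TestSolveAlpha:
    def test_closed_form_and_roundtrip(self):
        alpha = solve_alpha(0.5, 0.25, 2.0)
        assert alpha == pytest.approx(0.5)
        assert (alpha * 0.5 + 0.25) / 0.25 == pytest.approx(2.0, abs=1e-9)

    def test_unity_sbr_gives_zero_alpha(self):
        assert solve_alpha(0.7, 0.3, 1.0) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            solve_alpha(0.5, 0.25, 0.9)
        with pytest.raises(ValueError):
            solve_alpha(0.0, 0.25, 2.0)


@pytest.fixture(scope="module")
def parts(tiny_config, tiny_psf):
    rng = np.random.default_rng(21)
    em = sample_emitters(tiny_config, rng, density_mean=20000)
    vol = rasterize_volume(em, tiny_config)
    g0 = free_space_measurement(vol, tiny_psf)
    bg = make_background(BackgroundParams(), tiny_config, rng)
    return g0, bg


class TestComposeMeasurement:

    def test_sbr_roundtrip_exact(self, parts):
        g0, bg = parts
        for sbr in (1.1, 1.7, 3.0):
            m = compose_measurement(g0, bg, sbr)
            assert m.recompute_sbr() == pytest.approx(sbr, abs=1e-9)

    def test_unity_sbr_is_pure_background(self, parts):
        g0, bg = parts
        m = compose_measurement(g0, bg, 1.0)
        assert m.alpha == 0.0
        assert np.allclose(m.g, bg.pixels / bg.pixels.max())

    def test_g_is_composition_of_stored_parts(self, parts):
        g0, bg = parts
        m = compose_measurement(g0, bg, 2.5)
        recomposed = m.alpha * g0 / g0.max() + bg.pixels / bg.pixels.max()
        assert np.allclose(m.g, recomposed, rtol=1e-6)

    def test_zero_inputs_rejected(self, parts, tiny_config):
        _, bg = parts
        with pytest.raises(ValueError):
            compose_measurement(np.zeros((8, 8)), bg, 2.0)

    def test_free_space_variant_contract(self, parts):
        g0, _ = parts
        m = free_space_only(g0)
        assert m.kind == "free_space"
        assert m.alpha == 1.0
        assert m.bg is None


class TestAttenuation:
    def test_infinite_scattering_length_is_identity(self, tiny_config):
        vol = volume_with_deltas(tiny_config, [(k, 30, 30, 0.8)
                                               for k in range(24)])
        out = apply_attenuation(vol, AttenuationParams(1e12))
        assert np.allclose(out.voxels, vol.voxels, rtol=1e-9)

    def test_one_scattering_length_decay(self, tiny_config):
        vol = volume_with_deltas(tiny_config, [(k, 30, 30, 1.0)
                                               for k in range(24)])
        # slice exactly one scattering length deep is scaled by e^-1
        ls = 4 * tiny_config.z_step_um  # slice 4 sits at z' = ls
        out = apply_attenuation(vol, AttenuationParams(ls))
        assert out.voxels[4, 30, 30] == pytest.approx(np.exp(-1.0), rel=1e-12)
        assert out.voxels[0, 30, 30] == 1.0  # surface unchanged

    @pytest.mark.parametrize("ls", [80.0, 160.0, 320.0])
    def test_per_slice_totals_follow_beer_lambert(self, tiny_config, ls):
        rng = np.random.default_rng(4)
        vox = rng.uniform(0.1, 1.0, size=(24, 16, 16))
        vol = volume_with_deltas(tiny_config, [])
        vol = vol.with_voxels(np.pad(vox, ((0, 0), (0, 80), (0, 80))))
        out = apply_attenuation(vol, AttenuationParams(ls))
        depths = tiny_config.z_step_um * np.arange(24)
        ratios = out.voxels.sum(axis=(1, 2)) / vol.voxels.sum(axis=(1, 2))
        assert np.allclose(ratios, np.exp(-depths / ls), rtol=1e-12)

    def test_invalid_params_rejected(self, tiny_config):
        with pytest.raises(ValueError):
            AttenuationParams(-5.0)
        vol = volume_with_deltas(tiny_config, [])
        with pytest.raises(ValueError):
            apply_attenuation(vol, AttenuationParams(100.0, surface_slice=99))


class TestMPGNoise:
    def test_zero_parameters_noiseless(self, rng):
        g = np.linspace(0, 1, 100).reshape(10, 10)
        f = add_mpg_noise(g, NoiseParams(0.0, 0.0), rng)
        assert np.array_equal(f, g)

    def test_variance_at_constant_level(self):
        # var(f - g) at g = 0.5 approximates a*0.5 + b over 10^6 pixels
        rng = np.random.default_rng(10)
        p = NoiseParams()
        g = np.full((1000, 1000), 0.5)
        f = add_mpg_noise(g, p, rng)
        assert (f - g).var() == pytest.approx(p.a * 0.5 + p.b, rel=0.02)

    def test_variance_regression_recovers_parameters(self):
        # linear fit of per-level variance on g recovers slope a and
        # intercept b within 5%
        rng = np.random.default_rng(11)
        p = NoiseParams()
        levels = np.arange(0.1, 0.95, 0.1)
        variances = []
        for g0 in levels:
            g = np.full((512, 512), g0)
            f = add_mpg_noise(g, p, rng)
            variances.append((f - g).var())
        slope, intercept = np.polyfit(levels, variances, 1)
        assert slope == pytest.approx(p.a, rel=0.05)
        assert intercept == pytest.approx(p.b, rel=0.05)

    def test_negative_signal_rejected(self, rng):
        with pytest.raises(ValueError):
            add_mpg_noise(np.array([[-0.1]]), NoiseParams(), rng)

    def test_randomized_draw_truncated_positive(self):
        rng = np.random.default_rng(12)
        p = NoiseParams()
        draws = [p.draw(rng) for _ in range(500)]
        assert all(d.a >= 0.1 * p.a for d in draws)
        assert all(d.b >= 0.1 * p.b for d in draws)
        # randomisation spreads the values
        assert np.std([d.a for d in draws]) > 0

    def test_output_clipped_at_zero(self):
        rng = np.random.default_rng(13)
        f = add_mpg_noise(np.zeros((200, 200)), NoiseParams(b=1e-2), rng)
        assert f.min() >= 0
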