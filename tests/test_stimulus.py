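"""Stimulus-generation tests: noise movie statistics, step-protocol
regions, timing, and surround conditions."""

import numpy as np
import pytest

from contrastnorm.errors import GeometryError
from contrastnorm.stimulus import (
    DYNAMICS_ONSET,
    STEP_OFFSET,
    STEP_ONSET,
    SURROUND_CONDITIONS,
    ScreenGeometry,
    StepProtocolSpec,
    StimulusMovie,
    _gaussian_kernel,
    make_noise_stimulus,
    make_step_protocol,
    region_masks,
)


class TestGeometry:
    def test_default_grid_covers_screen(self, geometry):
        assert geometry.n_azimuth * geometry.pixel_size == pytest.approx(180.0)
        assert geometry.n_elevation * geometry.elevation_pixel_size == pytest.approx(105.0)
        assert geometry.pixel_size == pytest.approx(2.8125)

    def test_nearest_pixel_at_origin(self, geometry):
        row, col = geometry.nearest_pixel(0.0, 0.0)
        assert abs(geometry.azimuths[col]) <= geometry.pixel_size / 2
        assert abs(geometry.elevations[row]) <= geometry.elevation_pixel_size / 2


class TestNoiseStimulus:
    def test_deterministic_from_seed(self, geometry):
        a = make_noise_stimulus(geometry, 2.0, 20.0, seed=5)
        b = make_noise_stimulus(geometry, 2.0, 20.0, seed=5)
        assert np.array_equal(a.frames, b.frames)
        c = make_noise_stimulus(geometry, 2.0, 20.0, seed=6)
        assert not np.array_equal(a.frames, c.frames)

    def test_luminance_bounds_and_mean(self, geometry):
        mov = make_noise_stimulus(geometry, 10.0, 20.0, seed=0)
        assert mov.frames.min() >= 0.0 and mov.frames.max() <= 1.0
        assert mov.frames.mean() == pytest.approx(0.5, abs=0.01)

    def test_temporal_autocorrelation_matches_kernel(self):
        """Empirical per-pixel autocorrelation equals the Gaussian smoothing
        kernel's own autocorrelation (white noise in, kernel correlation
        out), within Monte-Carlo tolerance."""
        geo = ScreenGeometry(n_azimuth=16, n_elevation=12)
        rate, sigma = 20.0, 0.09
        mov = make_noise_stimulus(geo, 120.0, rate, temporal_sigma=sigma, seed=3)
        x = mov.frames.reshape(mov.n_frames, -1)
        x = x - x.mean(axis=0)
        kernel = _gaussian_kernel(sigma * rate)
        expected = np.correlate(kernel, kernel, mode="full")
        expected = expected / expected.max()
        mid = expected.size // 2
        for lag in (1, 2, 3):
            emp = (x[:-lag] * x[lag:]).mean() / x.var()
            assert emp == pytest.approx(expected[mid + lag], abs=0.05)

    def test_vanishing_sigma_gives_independent_frames(self):
        geo = ScreenGeometry(n_azimuth=16, n_elevation=12)
        mov = make_noise_stimulus(geo, 60.0, 20.0, temporal_sigma=1e-9, seed=4)
        x = mov.frames.reshape(mov.n_frames, -1)
        x = x - x.mean(axis=0)
        corr = (x[:-1] * x[1:]).mean() / x.var()
        assert abs(corr) < 0.05

    def test_binary_variant_is_binary(self, geometry):
        mov = make_noise_stimulus(geometry, 2.0, 20.0, seed=0, binarize=True)
        assert set(np.unique(mov.frames)) <= {0.0, 1.0}

    def test_invalid_arguments(self, geometry):
        with pytest.raises(ValueError):
            make_noise_stimulus(geometry, -1.0, 20.0)
        with pytest.raises(ValueError):
            make_noise_stimulus(geometry, 1.0, 0.0)


class TestStepProtocol:
    def test_event_times_and_ordering(self, geometry):
        mov = make_step_protocol(
            StepProtocolSpec(surround_condition="moving_grating"), geometry
        )
        ev = mov.events
        assert ev["surround_onset"] == 0.0
        assert ev["dynamics_onset"] == DYNAMICS_ONSET
        assert ev["step_offset"] - ev["step_onset"] == pytest.approx(1.0)
        times = [ev[k] for k in ("surround_onset", "dynamics_onset",
                                 "step_onset", "step_offset", "surround_offset")]
        assert times == sorted(times)

    def test_static_conditions_have_no_dynamics_event(self, geometry):
        mov = make_step_protocol(StepProtocolSpec(surround_condition="gray"), geometry)
        assert "dynamics_onset" not in mov.events

    def test_gray_surround_uniform(self, geometry):
        spec = StepProtocolSpec(surround_condition="gray")
        mov = make_step_protocol(spec, geometry)
        masks = region_masks(spec, geometry)
        outside = ~masks["center"]
        assert np.all(mov.frames[:, outside] == 0.5)

    @pytest.mark.parametrize("polarity,amplitude,pre,during", [
        ("ON", 0.75, 0.0, 0.75),
        ("ON", 1.0, 0.0, 1.0),
        ("OFF", 1.0, 1.0, 0.0),
        ("OFF", 0.5, 1.0, 0.5),
    ])
    def test_center_step_trace(self, geometry, polarity, amplitude, pre, during):
        spec = StepProtocolSpec(polarity=polarity, step_amplitude=amplitude)
        mov = make_step_protocol(spec, geometry)
        trace = mov.pixel_trace(0.0, 0.0)
        in_step = (mov.times >= STEP_ONSET) & (mov.times < STEP_OFFSET)
        assert np.all(trace[in_step] == pytest.approx(during))
        assert np.all(trace[~in_step] == pytest.approx(pre))

    def test_annulus_constant_gray(self, geometry):
        spec = StepProtocolSpec(surround_condition="stochastic_noise")
        mov = make_step_protocol(spec, geometry, seed=2)
        masks = region_masks(spec, geometry)
        assert np.all(mov.frames[:, masks["annulus"]] == 0.5)

    def test_moving_grating_one_second_periodicity(self, geometry):
        spec = StepProtocolSpec(surround_condition="moving_grating")
        mov = make_step_protocol(spec, geometry, frame_rate=60.0)
        sur = region_masks(spec, geometry)["surround"]
        i = round(2.4 * 60)  # drifting at 1 Hz: identical 1 s apart
        assert np.array_equal(mov.frames[i][sur], mov.frames[i + 60][sur])

    def test_moving_grating_is_shifted_stationary_grating(self, geometry):
        """Half a temporal period after dynamics onset the moving grating is
        the stationary pattern displaced by half a wavelength."""
        static = make_step_protocol(
            StepProtocolSpec(surround_condition="stationary_grating"), geometry
        )
        moving = make_step_protocol(
            StepProtocolSpec(surround_condition="moving_grating"), geometry
        )
        masks = region_masks(StepProtocolSpec(), geometry)
        sur = masks["surround"]
        i_half = round((DYNAMICS_ONSET + 0.5) * 60)  # phase = 10° = half period
        # shift of half a wavelength flips the square wave
        flipped = 1.0 - static.frames[0]
        mismatch = np.mean(moving.frames[i_half][sur] != flipped[sur])
        # pixels whose centers sit within a pixel of a grating edge may land
        # on either side of the flipped edge
        assert mismatch < 0.2
        # before dynamics onset the moving grating equals the stationary one
        assert np.array_equal(moving.frames[0], static.frames[0])

    def test_center_and_annulus_identical_across_conditions(self, geometry):
        frames = {}
        for cond in SURROUND_CONDITIONS:
            spec = StepProtocolSpec(surround_condition=cond)
            frames[cond] = make_step_protocol(spec, geometry, seed=3)
        masks = region_masks(StepProtocolSpec(), geometry)
        inner = masks["center"] | masks["annulus"]
        ref = frames["gray"].frames[:, inner]
        for cond in SURROUND_CONDITIONS[1:]:
            assert np.array_equal(frames[cond].frames[:, inner], ref)

    def test_all_conditions_share_mean_luminance(self, geometry):
        """Mean surround luminance over one grating/noise period is 0.5 for
        every condition, within sampling tolerance."""
        masks = region_masks(StepProtocolSpec(), geometry)
        sur = masks["surround"]
        for cond in SURROUND_CONDITIONS:
            spec = StepProtocolSpec(surround_condition=cond)
            mov = make_step_protocol(spec, geometry, seed=4)
            period = (mov.times >= DYNAMICS_ONSET) & (mov.times < DYNAMICS_ONSET + 1.0)
            mean_lum = mov.frames[period][:, sur].mean()
            assert mean_lum == pytest.approx(0.5, abs=0.05)

    def test_offscreen_annulus_raises_geometry_error(self, geometry):
        spec = StepProtocolSpec(center=(80.0, 0.0))
        with pytest.raises(GeometryError):
            make_step_protocol(spec, geometry)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            StepProtocolSpec(step_amplitude=0.0)
        with pytest.raises(ValueError):
            StepProtocolSpec(center_diameter=40.0)
        with pytest.raises(ValueError):
            StepProtocolSpec(surround_condition="plaid")


class TestMovieIO:
    def test_hdf5_roundtrip(self, geometry, tmp_path):
        spec = StepProtocolSpec(surround_condition="moving_grating",
                                step_amplitude=0.75)
        mov = make_step_protocol(spec, geometry, seed=1)
        path = tmp_path / "movie.h5"
        mov.to_hdf5(path)
        back = StimulusMovie.from_hdf5(path)
        assert np.array_equal(back.frames, mov.frames)
        assert back.events == mov.events
        assert back.condition == mov.condition
        assert back.step_amplitude == 0.75
        assert back.geometry == mov.geometry

    def test_yaml_spec_loading(self, tmp_path):
        path = tmp_path / "protocol.yaml"
        path.write_text(
            "protocol:\n  center: [10.0, -5.0]\n  polarity: OFF\n"
            "  surround_condition: stochastic_noise\n  step_amplitude: 0.5\n"
        )
        spec = StepProtocolSpec.from_yaml(path)
        assert spec.center == (10.0, -5.0)
        assert spec.polarity == "OFF"
        assert spec.step_amplitude == 0.5

    def test_out_of_range_luminance_rejected(self, geometry):
        with pytest.raises(ValueError):
            StimulusMovie(
                frames=np.full((2, geometry.n_elevation, geometry.n_azimuth), 1.5),
                frame_rate=60.0,
                geometry=geometry,
            )
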