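"""Preprocessing chain: OD, TDDR, Beer-Lambert inversion, filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from nirsdyn.preprocess import (
    _tddr_1d,
    antialias_downsample,
    highpass_detrend,
    intensity_to_od,
    load_extinction_coefficients,
    mbll_matrix,
    od_to_concentration,
    preprocess_recording,
    znormalize,
)
from nirsdyn.simulate import generate_recording


class TestIntensityToOD:
    def test_constant_intensity_gives_zero_od(self, small_recording):
        od = intensity_to_od(small_recording)
        assert od.values[0] == pytest.approx(0.0)

    def test_log_identity_halving_intensity(self, small_recording):
        od1 = intensity_to_od(small_recording).values
        import dataclasses

        # halving every sample after the reference adds ln 2 to its OD
        data = small_recording.data.copy()
        data[1:] /= 2.0
        scaled = dataclasses.replace(small_recording, data=data)
        od2 = intensity_to_od(scaled).values
        np.testing.assert_allclose(od2[1:], od1[1:] + np.log(2.0), atol=1e-12)

    def test_single_sample_attenuation(self, small_recording):
        import dataclasses

        data = small_recording.data.copy()
        data[10] = data[0] * np.exp(-1.0)
        rec = dataclasses.replace(small_recording, data=data)
        od = intensity_to_od(rec, reference_mode="first_sample")
        np.testing.assert_allclose(od.values[10], 1.0, atol=1e-12)

    def test_non_positive_sample_named_in_error(self, small_recording):
        import dataclasses

        rec = dataclasses.replace(small_recording, data=small_recording.data.copy())
        rec.data[5, 1, 0] = -1.0  # construction validates, so corrupt after
        with pytest.raises(ValueError, match=r"sample 5.*CH02"):
            intensity_to_od(rec)


class TestTDDR:
    rate = 130.0

    def _trace(self, seed=3, dur=90.0):
        t = np.arange(int(dur * self.rate)) / self.rate
        rng = np.random.default_rng(seed)
        clean = 0.02 * np.sin(2 * np.pi * 0.05 * t) + 0.01 * np.sin(2 * np.pi * 0.2 * t + 1.0)
        return t, clean + 0.005 * rng.standard_normal(t.size)

    def test_matches_reference_implementation(self):
        """Dual-route check against the published reference implementation."""
        from mne.preprocessing.nirs._tddr import _TDDR

        _, x = self._trace()
        x_step = x.copy()
        x_step[x.size // 2 :] += 0.1
        for trace in (x, x_step):
            np.testing.assert_allclose(
                _tddr_1d(trace.copy(), self.rate), _TDDR(trace.copy(), self.rate),
                atol=1e-12,
            )

    def test_artifact_free_shape_preserved(self):
        _, x = self._trace()
        out = _tddr_1d(x, self.rate)
        assert np.corrcoef(out, x)[0, 1] > 0.95

    def test_step_shift_removed(self):
        """A 10-SD baseline shift is reduced >= 90% (before/after means)."""
        t, x = self._trace()
        mid = t[t.size // 2]
        step = np.where(t >= mid, 10.0 * np.std(x), 0.0)
        out = _tddr_1d(x + step, self.rate)

        def amp(v):
            pre = v[(t >= mid - 20) & (t < mid)].mean()
            post = v[(t >= mid) & (t < mid + 20)].mean()
            return post - pre

        raw = amp(x + step) - amp(x)
        corrected = amp(out) - amp(x)
        assert abs(corrected) < 0.1 * abs(raw)

    def test_spike_low_frequency_footprint_removed(self):
        """A realistic (0.4 s decay) 10-SD spike's footprint in the <= 0.5 Hz
        band — the band the downstream analysis uses — is strongly reduced."""
        t, x = self._trace()
        s = t.size // 2
        spike = np.zeros_like(t)
        spike[s:] = 10.0 * np.std(x) * np.exp(-np.arange(t.size - s) / (0.4 * self.rate))
        out = _tddr_1d(x + spike, self.rate)
        b, a = signal.butter(4, 0.5 / (self.rate / 2.0))
        lp = lambda v: signal.filtfilt(b, a, v)  # noqa: E731
        raw_foot = np.max(np.abs(lp(x + spike) - lp(x)))
        cor_foot = np.max(np.abs(lp(out) - lp(x)))
        assert cor_foot < 0.5 * raw_foot


class TestBeerLambertInversion:
    def test_zero_od_gives_zero_concentration(self, small_recording):
        od = intensity_to_od(small_recording)
        od.values[:] = 0.0
        hemo = od_to_concentration(od)
        np.testing.assert_array_equal(hemo.hbo, 0.0)
        np.testing.assert_array_equal(hemo.hhb, 0.0)

    def test_identity_extinction_matrix_returns_od(self, small_recording):
        od = intensity_to_od(small_recording)
        rng = np.random.default_rng(1)
        od.values = rng.standard_normal(od.values.shape)
        unit = 1.0 / (np.log(10.0) * 1e-6)  # cancels the decadic/molar scale
        ext = {735.0: (unit, 0.0), 850.0: (0.0, unit)}
        hemo = od_to_concentration(od, distance_cm=1.0, dpf=1.0, extinction=ext)
        np.testing.assert_allclose(hemo.hbo, od.values[..., 0], atol=1e-10)
        np.testing.assert_allclose(hemo.hhb, od.values[..., 1], atol=1e-10)

    def test_singular_extinction_matrix_rejected(self, small_recording):
        od = intensity_to_od(small_recording)
        ext = {735.0: (1.0, 1.0), 850.0: (2.0, 2.0)}
        with pytest.raises(np.linalg.LinAlgError):
            od_to_concentration(od, extinction=ext)

    def test_extinction_table_well_conditioned(self):
        table = load_extinction_coefficients()
        assert set(table) == {735.0, 850.0}
        E = mbll_matrix((735.0, 850.0))
        assert np.linalg.cond(E) < 20


class TestAntialiasDownsample:
    def test_five_minute_recording_yields_300_samples(self):
        x = np.random.default_rng(0).standard_normal(39_000)
        assert antialias_downsample(x).shape[0] == 300

    def test_dc_preserved(self):
        out = antialias_downsample(np.full(39_000, 3.7))
        np.testing.assert_allclose(out, 3.7, atol=1e-9)

    def test_passband_and_stopband_match_analytic_response(self):
        """0.05 Hz passes within 2%; 0.45 Hz is attenuated exactly per the
        zero-phase (squared-magnitude) Butterworth response."""
        t = np.arange(39_000) / 130.0
        b, a = signal.butter(4, 0.5 / 65.0)
        for f0 in (0.05, 0.45):
            x = np.sin(2 * np.pi * f0 * t)
            y = antialias_downsample(x)
            amp = np.sqrt(2.0) * np.std(y[20:-20])
            _, h = signal.freqz(b, a, worN=[2 * np.pi * f0 / 130.0])
            expected = np.abs(h[0]) ** 2  # filtfilt applies |H|^2
            assert amp == pytest.approx(expected, rel=0.02)
        # and the 0.05 Hz tone is essentially unattenuated
        _, h = signal.freqz(b, a, worN=[2 * np.pi * 0.05 / 130.0])
        assert np.abs(h[0]) ** 2 > 0.98

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            antialias_downsample(np.zeros(1000), in_rate=130.0, out_rate=0.7)


class TestHighpassDetrend:
    def test_constant_input_removed(self):
        out = highpass_detrend(np.full(300, 5.0))
        assert np.max(np.abs(out)) < 1e-8

    def test_respiratory_band_preserved(self):
        t = np.arange(300)
        x = np.sin(2 * np.pi * 0.2 * t)
        y = highpass_detrend(x)
        amp = np.sqrt(2.0) * np.std(y[30:-30])
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_linear_ramp_detrended(self):
        x = np.linspace(0.0, 10.0, 300)
        y = highpass_detrend(x)
        assert np.std(y) < 0.05 * np.std(x)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            highpass_detrend(np.zeros(5))


class TestZNormalize:
    def test_exact_moments(self):
        x = np.random.default_rng(2).standard_normal((300, 3)) * 7.0 + 4.0
        z = znormalize(x)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.var(axis=0), 1.0, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            znormalize(np.ones(10))

    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_affine_invariance_and_idempotence(self, seed, scale, offset):
        x = np.random.default_rng(seed).standard_normal(64)
        z = znormalize(x)
        np.testing.assert_allclose(znormalize(scale * x + offset), z, atol=1e-8)
        np.testing.assert_allclose(znormalize(z), z, atol=1e-10)


class TestFullPipeline:
    def test_oscillator_peaks_survive_preprocessing(
        self, schedule, constant_lf, constant_hf
    ):
        """The 1 Hz output's spectral maxima sit within 0.02 Hz of the
        generator's LF/HF settings (artifact-free, constant-phase input)."""
        rec = generate_recording(
            schedule, n_channels=1, lf=constant_lf, hf=constant_hf,
            noise_sd=0.02, seed=21, artifacts=False,
        )
        hemo = preprocess_recording(rec)
        assert hemo.n_samples == 300
        assert hemo.normalized
        f, p = signal.periodogram(hemo.hbo[:, 0], fs=1.0)
        lf_peak = f[(f > 0.02) & (f < 0.125)][np.argmax(p[(f > 0.02) & (f < 0.125)])]
        hf_sel = (f >= 0.125) & (f <= 0.35)
        hf_peak = f[hf_sel][np.argmax(p[hf_sel])]
        assert abs(lf_peak - constant_lf.center_frequency) < 0.02
        assert abs(hf_peak - constant_hf.center_frequency) < 0.02

    def test_pipeline_deterministic(self, small_recording):
        a = preprocess_recording(small_recording)
        b = preprocess_recording(small_recording)
        np.testing.assert_array_equal(a.hbo, b.hbo)
        np.testing.assert_array_equal(a.hhb, b.hhb)
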