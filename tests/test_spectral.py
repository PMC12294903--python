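"""Phase-pooled OLS AR identification and pole-residue PSD decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from nirsdyn.protocol import ProtocolSchedule, build_phase_windows
from nirsdyn.simulate import ar2_coefficients, generate_tvar_process
from nirsdyn.spectral import (
    ARModel,
    WindowedAR,
    band_summary,
    build_phase_regressors,
    compute_aic,
    decompose_psd,
    ols_identify,
)
from nirsdyn.tvar import stationary_variance


def random_stable_ar4(rng) -> ARModel:
    """Random AR(4) from two conjugate pole pairs inside the unit circle."""
    moduli = rng.uniform(0.5, 0.95, 2)
    angles = rng.uniform(0.15 * np.pi, 0.85 * np.pi, 2)
    poly = np.array([1.0])
    for m, th in zip(moduli, angles):
        pair = np.array([1.0, -2.0 * m * np.cos(th), m * m])
        poly = np.convolve(poly, pair)
    return ARModel(coefficients=-poly[1:], innovation_variance=rng.uniform(0.5, 2.0))


class TestPhaseRegressors:
    def test_construction_counts_and_no_window_mixing(self):
        x = np.arange(100, dtype=float)  # value == index: lags are explicit
        windows = [np.arange(10, 20), np.arange(40, 60)]
        X, W = build_phase_regressors(x, windows, p=4)
        assert X.shape == (30,)
        assert W.shape == (4, 30)
        np.testing.assert_array_equal(X, np.concatenate([x[10:20], x[40:60]]))
        for col, present in enumerate(X):
            np.testing.assert_array_equal(W[:, col], present - np.arange(1, 5))

    def test_window_shorter_than_lags_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            build_phase_regressors(np.arange(50.0), [np.arange(10, 13)], p=4)

    def test_single_window_ols_equals_contiguous_ols(self):
        """On one stationary window the pooled-regressor OLS coincides with
        textbook OLS on the contiguous series (independent construction)."""
        x, _ = generate_tvar_process(ar2_coefficients(0.2, 0.85, 1.0), 1.0,
                                     n_samples=400, seed=0)
        p = 4
        window = np.arange(p, 400)
        X, W = build_phase_regressors(x, [window], p=p)
        model = ols_identify(X, W)
        # textbook construction: design matrix of lagged columns
        design = np.column_stack([x[p - k : 400 - k] for k in range(1, p + 1)])
        ref, *_ = np.linalg.lstsq(design, x[p:400], rcond=None)
        np.testing.assert_allclose(model.coefficients, ref, atol=1e-10)


class TestOLSIdentify:
    def test_noise_free_recursion_recovered_exactly(self):
        coeffs = ar2_coefficients(0.1, 0.98, 1.0)
        x = np.zeros(120)
        x[:2] = [1.0, 0.5]
        for t in range(2, 120):
            x[t] = coeffs[0] * x[t - 1] + coeffs[1] * x[t - 2]
        X, W = build_phase_regressors(x, [np.arange(2, 120)], p=2)
        model = ols_identify(X, W)
        np.testing.assert_allclose(model.coefficients, coeffs, atol=1e-8)
        assert model.innovation_variance < 1e-16

    def test_white_noise_coefficients_within_sampling_error(self):
        x, _ = generate_tvar_process(np.zeros(4), 1.0, n_samples=1000, seed=1)
        X, W = build_phase_regressors(x, [np.arange(4, 1000)], p=4)
        model = ols_identify(X, W)
        assert np.all(np.abs(model.coefficients) < 3.0 / np.sqrt(996))

    def test_ar4_coefficient_recovery(self):
        rng = np.random.default_rng(2)
        errs = []
        for s in range(20):
            truth = random_stable_ar4(rng)
            x, _ = generate_tvar_process(
                truth.coefficients, np.sqrt(truth.innovation_variance),
                n_samples=1254, seed=s,
            )
            X, W = build_phase_regressors(x, [np.arange(4, 1254)], p=4)
            est = ols_identify(X, W)
            errs.append(np.sqrt(np.mean((est.coefficients - truth.coefficients) ** 2)))
        assert np.mean(errs) < 0.05


class TestAIC:
    def test_doubling_innovation_variance_adds_n_ln2(self):
        m1 = ARModel(np.zeros(4), 1.0, n_effective=500)
        m2 = ARModel(np.zeros(4), 2.0, n_effective=500)
        assert compute_aic(m2) - compute_aic(m1) == pytest.approx(500 * np.log(2.0))

    def test_extra_order_at_identical_fit_adds_two(self):
        m1 = ARModel(np.zeros(4), 1.3, n_effective=500)
        m2 = ARModel(np.zeros(5), 1.3, n_effective=500)
        assert compute_aic(m2) - compute_aic(m1) == pytest.approx(2.0)

    def test_order_selection_recovers_ar4_range(self):
        """AIC minimum lands in [4, 6] for most AR(4) realizations."""
        rng = np.random.default_rng(3)
        hits = 0
        n_seeds = 50
        for s in range(n_seeds):
            truth = random_stable_ar4(rng)
            x, _ = generate_tvar_process(
                truth.coefficients, np.sqrt(truth.innovation_variance),
                n_samples=1262, seed=1000 + s,
            )
            aics = []
            for p in range(1, 13):
                X, W = build_phase_regressors(x, [np.arange(12, 1262)], p=p)
                aics.append(compute_aic(ols_identify(X, W)))
            best = int(np.argmin(aics)) + 1
            hits += 4 <= best <= 6
        assert hits >= 0.8 * n_seeds


class TestDecomposePSD:
    def test_ar1_single_real_pole_closed_form(self):
        dec = decompose_psd(ARModel(np.array([0.9]), 2.0))
        assert len(dec.components) == 1
        c = dec.components[0]
        assert c.frequency == 0.0
        assert c.power == pytest.approx(2.0 / (1.0 - 0.81), rel=1e-10)
        assert dec.process_variance == pytest.approx(2.0 * 5.263157894736842, rel=1e-10)

    def test_ar2_pole_placement_frequency(self):
        dec = decompose_psd(ARModel(np.array([0.55623, -0.81]), 1.0))
        assert len(dec.components) == 1
        assert dec.components[0].frequency == pytest.approx(0.2, abs=1e-5)

    def test_component_sum_identity_and_variance_conservation(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            model = random_stable_ar4(rng)
            dec = decompose_psd(model, grid_size=1024)
            total = np.sum([c.psd for c in dec.components], axis=0)
            assert np.max(np.abs(total - dec.psd)) / np.max(dec.psd) < 1e-6
            lyap = stationary_variance(model.coefficients, model.innovation_variance)
            assert abs(dec.process_variance - lyap) / lyap < 1e-6
            assert np.all(dec.psd >= 0.0)

    def test_parseval_numeric_integral(self):
        rng = np.random.default_rng(5)
        model = random_stable_ar4(rng)
        dec = decompose_psd(model, grid_size=4096)
        # PSD is even: two-sided integral = 2x the [0, fs/2] integral
        integral = 2.0 * np.trapezoid(dec.psd, dec.frequencies)
        assert abs(integral - dec.process_variance) / dec.process_variance < 1e-3

    def test_component_power_matches_profile_integral(self):
        rng = np.random.default_rng(6)
        model = random_stable_ar4(rng)
        dec = decompose_psd(model, grid_size=4096)
        for c in dec.components:
            integral = 2.0 * np.trapezoid(c.psd, dec.frequencies)
            assert abs(integral - c.power) / abs(c.power) < 1e-3

    def test_unstable_model_reflected_and_flagged(self):
        with pytest.warns(UserWarning, match="reflected"):
            dec = decompose_psd(ARModel(np.array([1.1]), 1.0))
        assert dec.reflected
        assert np.all(np.abs(dec.poles) < 1.0)
        assert np.all(dec.psd >= 0.0)

    def test_repeated_poles_rejected(self):
        # (z - 0.5)^2: a1 = 1.0, a2 = -0.25
        with pytest.raises(ValueError, match="repeated"):
            decompose_psd(ARModel(np.array([1.0, -0.25]), 1.0))

    def test_peak_agrees_with_periodogram(self):
        coeffs = ar2_coefficients(0.2, 0.9, 1.0)
        x, _ = generate_tvar_process(coeffs, 1.0, n_samples=10_000, seed=7)
        f, p = signal.welch(x, fs=1.0, nperseg=2048)
        welch_peak = f[np.argmax(p)]
        dec = decompose_psd(ARModel(coeffs, 1.0))
        assert abs(dec.components[0].frequency - welch_peak) < 0.02


class TestBandSummary:
    def test_components_assigned_to_their_bands(self):
        lf = ar2_coefficients(0.05, 0.9, 1.0)
        hf = ar2_coefficients(0.22, 0.9, 1.0)
        poly = np.convolve(np.concatenate([[1.0], -lf]), np.concatenate([[1.0], -hf]))
        dec = decompose_psd(ARModel(-poly[1:], 1.0))
        bands = band_summary(dec)
        assert bands["LF"]["peak_frequency"] == pytest.approx(0.05, abs=0.001)
        assert bands["HF"]["peak_frequency"] == pytest.approx(0.22, abs=0.001)

    def test_band_without_component_reported_missing(self):
        dec = decompose_psd(ARModel(ar2_coefficients(0.05, 0.9, 1.0), 1.0))
        bands = band_summary(dec)
        assert bands["HF"]["peak_frequency"] is None
        assert bands["HF"]["power"] is None
        assert bands["HF"]["n_components"] == 0

    def test_band_power_sums_assigned_components(self):
        lf = ar2_coefficients(0.05, 0.85, 1.0)
        hf = ar2_coefficients(0.2, 0.85, 1.0)
        poly = np.convolve(np.concatenate([[1.0], -lf]), np.concatenate([[1.0], -hf]))
        dec = decompose_psd(ARModel(-poly[1:], 1.0))
        bands = band_summary(dec)
        total = bands["LF"]["power"] + bands["HF"]["power"]
        in_band = sum(c.power for c in dec.components if c.frequency >= 0.04)
        assert total == pytest.approx(in_band, rel=1e-10)


class TestWindowedARModel:
    @given(seed=st.integers(0, 500))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_variance_conservation_on_fitted_models(self, seed):
        """Sum of component powers equals the fitted model's variance for
        every stable phase-pooled estimate."""
        x, _ = generate_tvar_process(
            ar2_coefficients(0.2, 0.8, 1.0), 1.0, n_samples=300, seed=seed
        )
        sched = ProtocolSchedule()
        windows = build_phase_windows(sched, p=4).apnea
        res = WindowedAR(x, windows, order=4).fit()
        dec = res.spectrum()
        if not dec.reflected:
            lyap = stationary_variance(res.params, res.innovation_variance)
            assert abs(dec.process_variance - lyap) / lyap < 1e-6

    def test_phase_separated_fits_recover_distinct_hf_frequencies(self):
        """Apnea 0.20 Hz vs breath 0.25 Hz HF oscillations are recovered by
        the two independent phase fits (average over seeds)."""
        sched = ProtocolSchedule()
        windows = build_phase_windows(sched, p=4)
        t = np.arange(300)
        cond = sched.condition_at(t.astype(float))
        est_a, est_b = [], []
        for s in range(100):
            rng = np.random.default_rng(s)
            hf_traj = np.empty((300, 2))
            hf_traj[cond == "apnea"] = ar2_coefficients(0.20, 0.95, 1.0)
            hf_traj[cond == "breath"] = ar2_coefficients(0.25, 0.95, 1.0)
            hf, _ = generate_tvar_process(hf_traj, 1.0, seed=int(rng.integers(2**31)))
            lf, _ = generate_tvar_process(
                ar2_coefficients(0.05, 0.85, 1.0), 1.0, n_samples=300,
                seed=int(rng.integers(2**31)),
            )
            x = lf + hf + 0.05 * rng.standard_normal(300)
            for cond_name, store in (("apnea", est_a), ("breath", est_b)):
                bands = WindowedAR(x, windows.windows(cond_name), order=4).fit().band_summary()
                if bands["HF"]["peak_frequency"] is not None:
                    store.append(bands["HF"]["peak_frequency"])
        assert abs(np.mean(est_a) - 0.20) < 0.02
        assert abs(np.mean(est_b) - 0.25) < 0.02

    def test_summary_reports_bands(self):
        x, _ = generate_tvar_process(
            ar2_coefficients(0.2, 0.85, 1.0), 1.0, n_samples=300, seed=1
        )
        windows = build_phase_windows(ProtocolSchedule(), p=4).breath
        text = WindowedAR(x, windows, order=4).fit().summary()
        assert "order p" in text
        assert "LF" in text and "HF" in text
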