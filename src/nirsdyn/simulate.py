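"""Synthetic breath-hold fNIRS recordings with known ground truth.

No public fNIRS breath-hold dataset accompanies the analysis this package
implements, so every downstream stage is exercised against simulated
recordings whose generating parameters are known exactly.  The generator
emulates the study conditions: five-minute, 16-channel dual-wavelength
(735/850 nm) intensity recordings at 130 Hz containing

* a low-frequency vascular (Mayer-wave-like) oscillation near 0.05 Hz,
* a respiratory oscillation near 0.2 Hz whose frequency, damping and
  amplitude differ between apnea and normal-breathing phases (higher
  frequency and a stronger, more regular oscillation while breathing),
* broadband measurement noise, slow drift, and optional motion artifacts
  (spikes and baseline shifts).

Oscillators are realized as stochastic AR(2) resonances (complex-conjugate
pole pairs driven by white noise) rather than deterministic sinusoids, so
the signals live in the model class of the downstream autoregressive
analyses while remaining realistically irregular.  Hemodynamics are
synthesized at the 1 Hz analysis rate, band-limited-interpolated to 130 Hz,
and pushed through the forward modified Beer-Lambert law to obtain raw
intensities, making the generator the exact inverse of the preprocessing
chain (up to filtering effects).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .preprocess import mbll_matrix
from .protocol import ProtocolSchedule

__all__ = [
    "OscillatorSpec",
    "RawRecording",
    "generate_tvar_process",
    "generate_hemodynamics",
    "hemo_to_intensity",
    "inject_artifacts",
    "generate_recording",
    "write_recording",
    "read_recording",
    "DEFAULT_LF",
    "DEFAULT_HF",
]

WAVELENGTHS = (735.0, 850.0)
RAW_RATE = 130.0
#: HHb is generated as an anticorrelated, scaled copy of HbO2.
HHB_SCALE = -0.6


@dataclass(frozen=True)
class OscillatorSpec:
    """One stochastic oscillator: an AR(2) complex-conjugate pole pair.

    ``center_frequency`` (Hz) is the pole argument, ``pole_modulus`` in
    (0, 1) sets the resonance sharpness, and ``amplitude_scale`` scales the
    innovation standard deviation.  ``phase_dependence`` optionally maps a
    condition name to ``(frequency, modulus, amplitude)`` overrides, which
    is how apnea/breath modulation is expressed.
    """

    center_frequency: float
    pole_modulus: float
    amplitude_scale: float = 1.0
    phase_dependence: dict[str, tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        for f, m, a in [(self.center_frequency, self.pole_modulus, self.amplitude_scale)] + (
            list(self.phase_dependence.values()) if self.phase_dependence else []
        ):
            if not 0.0 < m < 1.0:
                raise ValueError(f"pole modulus {m} outside (0, 1): unstable oscillator")
            if f <= 0.0:
                raise ValueError(f"center frequency {f} must be positive")
            if a < 0.0:
                raise ValueError("amplitude scale must be non-negative")

    def params_for(self, condition: str) -> tuple[float, float, float]:
        if self.phase_dependence and condition in self.phase_dependence:
            return self.phase_dependence[condition]
        return (self.center_frequency, self.pole_modulus, self.amplitude_scale)


#: Vascular (Mayer-wave band) oscillator.  Normal breathing entrains a more
#: regular vascular rhythm (higher pole modulus, smaller innovation), which
#: yields a higher-power, sharper 0.05 Hz resonance during breath phases.
DEFAULT_LF = OscillatorSpec(
    center_frequency=0.05,
    pole_modulus=0.88,
    amplitude_scale=1.0,
    phase_dependence={
        "apnea": (0.05, 0.88, 1.0),
        "breath": (0.05, 0.97, 0.7),
    },
)
#: Respiratory oscillator: a slower, more damped residual rhythm during
#: apnea; faster and markedly more regular during normal breathing.  The
#: sharper breath-phase resonance carries more band power and makes the
#: signal more predictable (higher information storage, lower conditional
#: entropy) even though its innovation amplitude is smaller.
DEFAULT_HF = OscillatorSpec(
    center_frequency=0.20,
    pole_modulus=0.85,
    amplitude_scale=1.2,
    phase_dependence={
        "apnea": (0.20, 0.85, 1.2),
        "breath": (0.25, 0.96, 0.8),
    },
)


@dataclass
class RawRecording:
    """Raw dual-wavelength intensity recording.

    ``data`` has shape ``(n_samples, n_channels, n_wavelengths)`` with
    strictly positive intensities sampled at ``rate`` Hz.
    """

    data: np.ndarray
    rate: float
    wavelengths: tuple[float, ...]
    channel_labels: tuple[str, ...]
    schedule: ProtocolSchedule
    rng_seed: int | None = None
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (n_samples, n_channels, n_wavelengths)")
        if np.any(self.data <= 0):
            raise ValueError("raw intensities must be strictly positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


def _companion(coeffs: np.ndarray) -> np.ndarray:
    p = coeffs.shape[0]
    F = np.zeros((p, p))
    F[0] = coeffs
    if p > 1:
        F[1:, :-1] = np.eye(p - 1)
    return F


def _check_stability(coeffs: np.ndarray) -> None:
    """Reject coefficient trajectories with any unstable frozen model."""
    coeffs = np.atleast_2d(coeffs)
    uniq, inverse = np.unique(coeffs, axis=0, return_inverse=True)
    bad = np.zeros(uniq.shape[0], dtype=bool)
    for i, row in enumerate(uniq):
        bad[i] = np.max(np.abs(np.linalg.eigvals(_companion(row)))) >= 1.0
    if bad.any():
        first = int(np.argmax(bad[inverse]))
        raise ValueError(f"unstable AR coefficients at time step {first}")


def generate_tvar_process(
    coefficient_trajectory: np.ndarray,
    innovation_sd: float | np.ndarray = 1.0,
    n_samples: int | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Simulate ``X_n = sum_k a_{k,n} X_{n-k} + U_n`` by direct recursion.

    ``coefficient_trajectory`` is either a constant coefficient vector of
    length ``p`` (then ``n_samples`` is required) or an ``(N, p)`` array of
    per-time coefficients.  Every frozen coefficient vector must define a
    stable AR model.  Returns the realization together with a ground-truth
    dict carrying the coefficients and innovation SD used at each step.
    """
    traj = np.asarray(coefficient_trajectory, dtype=float)
    if traj.ndim == 1:
        if n_samples is None:
            raise ValueError("n_samples required with a constant coefficient vector")
        traj = np.broadcast_to(traj, (n_samples, traj.shape[0])).copy()
    n, p = traj.shape
    _check_stability(traj)
    sd = np.broadcast_to(np.asarray(innovation_sd, dtype=float), (n,))
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n) * sd
    x = np.zeros(n)
    for t in range(n):
        acc = u[t]
        for j in range(1, min(p, t) + 1):
            acc += traj[t, j - 1] * x[t - j]
        x[t] = acc
    truth = {"coefficients": traj, "innovation_sd": np.array(sd)}
    return x, truth


def ar2_coefficients(frequency: float, modulus: float, rate: float) -> np.ndarray:
    """AR(2) coefficients of a pole pair ``modulus * exp(±2πi f/rate)``."""
    theta = 2.0 * np.pi * frequency / rate
    return np.array([2.0 * modulus * np.cos(theta), -(modulus**2)])


def _oscillator_series(
    spec: OscillatorSpec,
    conditions: np.ndarray,
    rate: float,
    rng: np.random.Generator,
    warmup: int = 100,
) -> tuple[np.ndarray, dict]:
    """Realize one phase-modulated AR(2) oscillator at the analysis rate."""
    n = conditions.shape[0]
    freq = np.empty(n)
    mod = np.empty(n)
    amp = np.empty(n)
    for cond in np.unique(conditions):
        f, m, a = spec.params_for(str(cond))
        if f >= rate / 2.0:
            raise ValueError(f"oscillator frequency {f} Hz at/above Nyquist of {rate} Hz")
        sel = conditions == cond
        freq[sel], mod[sel], amp[sel] = f, m, a
    # warm-up samples (discarded) let the recursion reach steady state
    freq_e = np.concatenate([np.full(warmup, freq[0]), freq])
    mod_e = np.concatenate([np.full(warmup, mod[0]), mod])
    amp_e = np.concatenate([np.full(warmup, amp[0]), amp])
    coeffs = np.stack(
        [2.0 * mod_e * np.cos(2.0 * np.pi * freq_e / rate), -(mod_e**2)], axis=1
    )
    x, _ = generate_tvar_process(coeffs, innovation_sd=amp_e, seed=int(rng.integers(2**31)))
    truth = {"frequency": freq, "modulus": mod, "innovation_sd": amp}
    return x[warmup:], truth


def generate_hemodynamics(
    schedule: ProtocolSchedule,
    lf: OscillatorSpec = DEFAULT_LF,
    hf: OscillatorSpec = DEFAULT_HF,
    noise_sd: float = 0.1,
    seed: int | None = None,
    rate: float = RAW_RATE,
    analysis_rate: float = 1.0,
    drift_amplitude: float = 0.3,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate paired HbO2/HHb concentration series at the raw rate.

    Each phase segment is a realization of a stochastic process with the two
    complex-conjugate pole pairs placed per the phase-dependent oscillator
    specs; white measurement noise and a slow sinusoidal drift are added at
    the raw rate.  HHb is a negatively scaled copy of HbO2 plus independent
    noise.  Returns ``(hbo, hhb, truth)`` where ``truth`` carries the
    per-sample (at the analysis rate) pole parameters of both oscillators
    and the condition labels.
    """
    rng = np.random.default_rng(seed)
    n1 = int(round(schedule.total_duration * analysis_rate))
    t1 = np.arange(n1) / analysis_rate
    conditions = schedule.condition_at(t1)

    lf_series, lf_truth = _oscillator_series(lf, conditions, analysis_rate, rng)
    hf_series, hf_truth = _oscillator_series(hf, conditions, analysis_rate, rng)
    slow = lf_series + hf_series

    factor = int(round(rate / analysis_rate))
    fast = signal.resample_poly(slow, factor, 1)
    n_raw = int(round(schedule.total_duration * rate))
    fast = fast[:n_raw]

    t_raw = np.arange(n_raw) / rate
    drift_phase = rng.uniform(0, 2 * np.pi)
    drift = drift_amplitude * np.sin(2 * np.pi * 0.008 * t_raw + drift_phase)

    hbo = fast + drift + noise_sd * rng.standard_normal(n_raw)
    hhb = HHB_SCALE * fast - 0.5 * drift + noise_sd * rng.standard_normal(n_raw)
    truth = {
        "time_s": t1,
        "condition": conditions,
        "lf": lf_truth,
        "hf": hf_truth,
        "components_1hz": {"lf": lf_series, "hf": hf_series},
        "hhb_scale": HHB_SCALE,
    }
    return hbo, hhb, truth


def hemo_to_intensity(
    hbo: np.ndarray,
    hhb: np.ndarray,
    schedule: ProtocolSchedule,
    baseline_intensity: tuple[float, float] = (1.0, 1.0),
    pathlength_cm: float = 3.0,
    dpf: float = 6.0,
    rate: float = RAW_RATE,
    channel_labels: tuple[str, ...] | None = None,
    rng_seed: int | None = None,
    ground_truth: dict | None = None,
) -> RawRecording:
    """Forward modified Beer-Lambert law: concentrations -> raw intensities.

    ``hbo``/``hhb`` are micromolar concentration changes with shape ``(n,)``
    or ``(n, n_channels)``.  The output satisfies
    ``I(lambda) = Io(lambda) * exp(-E @ c)`` so that the preprocessing
    module's OD + Beer-Lambert inversion recovers the inputs exactly when no
    filtering is applied.
    """
    io = np.asarray(baseline_intensity, dtype=float)
    if np.any(io <= 0):
        raise ValueError("baseline intensity must be strictly positive")
    hbo = np.atleast_2d(np.asarray(hbo, dtype=float).T).T
    hhb = np.atleast_2d(np.asarray(hhb, dtype=float).T).T
    if hbo.shape != hhb.shape:
        raise ValueError("hbo and hhb must have identical shapes")
    E = mbll_matrix(WAVELENGTHS, pathlength_cm, dpf)
    conc = np.stack([hbo, hhb], axis=-1)  # (n, ch, 2)
    od = conc @ E.T  # (n, ch, n_wl)
    data = io[None, None, :] * np.exp(-od)
    n_ch = data.shape[1]
    labels = channel_labels or tuple(f"CH{i + 1:02d}" for i in range(n_ch))
    return RawRecording(
        data=data,
        rate=rate,
        wavelengths=WAVELENGTHS,
        channel_labels=labels,
        schedule=schedule,
        rng_seed=rng_seed,
        ground_truth=ground_truth,
    )


def inject_artifacts(
    rec: RawRecording,
    spike_rate: float = 1.0,
    shift_rate: float = 0.5,
    spike_magnitude: float = 0.05,
    shift_magnitude: float = 0.02,
    seed: int | None = None,
    spike_tau_s: float = 0.4,
) -> tuple[RawRecording, list[dict]]:
    """Add motion artifacts — spikes and baseline shifts — to a recording.

    Rates are events per minute per channel-pair; spikes are short
    multiplicative exponential transients (time constant ``spike_tau_s``)
    and shifts are multiplicative steps persisting to the end of the
    recording, both applied coherently to the channel's two wavelengths.
    Returns the corrupted recording and a log of sample indices and signed
    magnitudes.
    """
    if spike_rate < 0 or shift_rate < 0:
        raise ValueError("artifact rates must be non-negative")
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    n, n_ch, _ = data.shape
    minutes = n / rec.rate / 60.0
    t = np.arange(n)
    log: list[dict] = []
    for ch in range(n_ch):
        for _ in range(rng.poisson(spike_rate * minutes)):
            s = int(rng.integers(0, n))
            m = spike_magnitude * rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
            shape = np.exp(-(t[s:] - s) / (spike_tau_s * rec.rate))
            data[s:, ch, :] *= (1.0 + m * shape)[:, None]
            log.append({"kind": "spike", "channel": ch, "sample": s, "magnitude": m})
        for _ in range(rng.poisson(shift_rate * minutes)):
            s = int(rng.integers(0, n))
            m = shift_magnitude * rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5)
            data[s:, ch, :] *= 1.0 + m
            log.append({"kind": "shift", "channel": ch, "sample": s, "magnitude": m})
    out = replace(rec, data=data)
    return out, log


def generate_recording(
    schedule: ProtocolSchedule | None = None,
    n_channels: int = 16,
    lf: OscillatorSpec = DEFAULT_LF,
    hf: OscillatorSpec = DEFAULT_HF,
    noise_sd: float = 0.1,
    channel_gain_sd: float = 0.2,
    channel_noise_sd: float = 0.2,
    seed: int | None = None,
    artifacts: bool = False,
    **artifact_kwargs,
) -> RawRecording:
    """Generate a full multi-channel raw recording.

    All channels share the two oscillator realizations (the underlying
    systemic hemodynamics) with channel-specific log-normal gains, plus a
    channel-specific in-band noise process (local vascular variability,
    white in the analysis band, SD ``channel_noise_sd`` in concentration
    units) and broadband measurement noise, then pass through the forward
    Beer-Lambert model.  With ``artifacts=True`` motion artifacts are
    injected and logged in ``ground_truth['artifact_log']``.
    """
    schedule = schedule or ProtocolSchedule()
    rng = np.random.default_rng(seed)
    hbo1, hhb1, truth = generate_hemodynamics(
        schedule, lf=lf, hf=hf, noise_sd=0.0, seed=int(rng.integers(2**31)),
        drift_amplitude=0.0,
    )
    n_raw = hbo1.shape[0]
    n_1hz = int(round(schedule.total_duration))
    factor = int(round(RAW_RATE))
    gains = np.exp(channel_gain_sd * rng.standard_normal(n_channels))
    t_raw = np.arange(n_raw) / RAW_RATE
    hbo = np.empty((n_raw, n_channels))
    hhb = np.empty((n_raw, n_channels))
    for ch in range(n_channels):
        drift = 0.3 * np.sin(2 * np.pi * 0.008 * t_raw + rng.uniform(0, 2 * np.pi))
        # channel-local hemodynamic variability, white in the 0-0.5 Hz band
        local_o = signal.resample_poly(
            channel_noise_sd * rng.standard_normal(n_1hz), factor, 1
        )[:n_raw]
        local_h = signal.resample_poly(
            channel_noise_sd * rng.standard_normal(n_1hz), factor, 1
        )[:n_raw]
        hbo[:, ch] = gains[ch] * hbo1 + local_o + drift + noise_sd * rng.standard_normal(n_raw)
        hhb[:, ch] = gains[ch] * hhb1 + local_h - 0.5 * drift + noise_sd * rng.standard_normal(n_raw)
    truth = dict(truth, channel_gains=gains)
    rec = hemo_to_intensity(
        hbo, hhb, schedule, rng_seed=seed, ground_truth=truth
    )
    if artifacts:
        rec, art_log = inject_artifacts(
            rec, seed=int(rng.integers(2**31)), **artifact_kwargs
        )
        rec.ground_truth["artifact_log"] = art_log
    return rec


def write_recording(rec: RawRecording, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write a recording as a wide CSV plus a JSON sidecar.

    The CSV holds a time column and one column per channel x wavelength
    (``CH01_735nm`` ...); the sidecar stores the schedule, sampling rate,
    wavelengths and seed.  Returns the two paths.
    """
    import pandas as pd

    prefix = Path(path_prefix)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    cols = {"time_s": np.arange(rec.n_samples) / rec.rate}
    for c, label in enumerate(rec.channel_labels):
        for w, wl in enumerate(rec.wavelengths):
            cols[f"{label}_{int(wl)}nm"] = rec.data[:, c, w]
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.9g")
    sidecar = {
        "rate_hz": rec.rate,
        "wavelengths_nm": list(rec.wavelengths),
        "channel_labels": list(rec.channel_labels),
        "schedule": rec.schedule.to_dict(),
        "rng_seed": rec.rng_seed,
    }
    json_path.write_text(json.dumps(sidecar, indent=2))
    return csv_path, json_path


def read_recording(path_prefix: str | Path) -> RawRecording:
    """Read a recording written by :func:`write_recording`."""
    import pandas as pd

    prefix = Path(path_prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    labels = tuple(meta["channel_labels"])
    wavelengths = tuple(float(w) for w in meta["wavelengths_nm"])
    data = np.empty((len(df), len(labels), len(wavelengths)))
    for c, label in enumerate(labels):
        for w, wl in enumerate(wavelengths):
            data[:, c, w] = df[f"{label}_{int(wl)}nm"].to_numpy()
    return RawRecording(
        data=data,
        rate=float(meta["rate_hz"]),
        wavelengths=wavelengths,
        channel_labels=labels,
        schedule=ProtocolSchedule.from_dict(meta["schedule"]),
        rng_seed=meta.get("rng_seed"),
    )
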