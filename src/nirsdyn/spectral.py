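"""Phase-wise AR identification and pole-residue PSD decomposition.

For each experimental condition (apnea / breath) a stationary AR(p) model

.. math:: X_n = \\sum_{k=1}^{p} a_k X_{n-k} + U_n

is identified by ordinary least squares on regressors pooled across that
condition's five protocol windows, never letting a lagged regressor cross a
window boundary.  The model's power spectral density

.. math:: P(z) = \\sigma_U^2\\, H(z) H^*(1/z^*), \\qquad
          H(z) = \\frac{z^p}{\\prod_k (z - p_k)}

is then expanded by the Heaviside partial-fraction (residue) method into one
additive component per pole,

.. math:: P(z) = \\sum_k \\Big[ \\frac{r_k p_k}{z - p_k}
                              - \\frac{r_k p_k^{-1}}{z - p_k^{-1}} \\Big],

so each oscillation is characterized by a central frequency
``f_k = arg(p_k)/(2 pi) * fs`` and a power ``sigma_k^2`` (``r_k`` for a real
pole, ``r_k + r_k*`` for a conjugate pair) with the exact accounting
``sum_k sigma_k^2 = sigma_X^2``.  Components are assigned to the
low-frequency (vascular, 0.04-0.15 Hz) and high-frequency (respiratory,
0.15-0.4 Hz) bands by their central frequency; the band power is the
full-spectrum integral of the assigned components' profiles, i.e. the sum
of their ``sigma_k^2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .protocol import PhaseWindows, build_phase_windows  # noqa: F401  (re-export)
from .tvar import stationary_variance

__all__ = [
    "ARModel",
    "SpectralDecomposition",
    "BandComponent",
    "build_phase_regressors",
    "ols_identify",
    "compute_aic",
    "decompose_psd",
    "band_summary",
    "WindowedAR",
    "WindowedARResults",
    "LF_BAND",
    "HF_BAND",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
DEFAULT_GRID = 1024


@dataclass
class ARModel:
    """A stationary AR(p) model with innovation variance and sampling rate."""

    coefficients: np.ndarray  # (p,)
    innovation_variance: float
    rate: float = 1.0
    n_effective: int | None = None  # observations used in the fit

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]

    @property
    def poles(self) -> np.ndarray:
        """Roots of ``z^p - a_1 z^{p-1} - ... - a_p``."""
        return np.roots(np.concatenate([[1.0], -self.coefficients]))

    @property
    def stable(self) -> bool:
        return bool(np.all(np.abs(self.poles) < 1.0))

    def process_variance(self) -> float:
        """Stationary variance from the companion-form Lyapunov solution."""
        return stationary_variance(self.coefficients, self.innovation_variance)


def build_phase_regressors(
    x: np.ndarray, windows: tuple[np.ndarray, ...] | list[np.ndarray], p: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pool present samples and lag matrices across phase windows.

    For each window the present vector takes the in-window samples and each
    regressor column holds the ``p`` preceding samples of its present entry
    (the window shifted one temporal unit into the past, up to ``p`` lags);
    because windows already start ``p + 1`` samples after a phase
    transition, no regressor crosses a window boundary into the other
    condition.  Returns ``(X, W)`` with ``X`` of length ``M`` (total window
    samples) and ``W`` of shape ``(p, M)``.
    """
    x = np.asarray(x, dtype=float).ravel()
    xs, ws = [], []
    for idx in windows:
        idx = np.asarray(idx, dtype=int)
        if idx.size <= p:
            raise ValueError(f"window of length {idx.size} shorter than p + 1 = {p + 1}")
        if idx[0] < p:
            raise ValueError("window starts before p samples of history exist")
        xs.append(x[idx])
        ws.append(np.stack([x[idx - k] for k in range(1, p + 1)], axis=0))
    return np.concatenate(xs), np.concatenate(ws, axis=1)


def ols_identify(
    X: np.ndarray, W: np.ndarray, rate: float = 1.0
) -> ARModel:
    """Estimate AR coefficients by ordinary least squares.

    Solves ``A = X W^T [W W^T]^{-1}`` (via a least-squares solve); the
    innovation variance is the variance of the residual series
    ``U = X - A W``.  A rank-deficient regressor matrix falls back to the
    minimum-norm solution with a warning.
    """
    X = np.asarray(X, dtype=float).ravel()
    W = np.asarray(W, dtype=float)
    p, m = W.shape
    if X.shape[0] != m:
        raise ValueError("X and W have inconsistent numbers of observations")
    if np.linalg.matrix_rank(W) < p:
        warnings.warn("regressor matrix is rank deficient; minimum-norm solution",
                      stacklevel=2)
    a, *_ = np.linalg.lstsq(W.T, X, rcond=None)
    resid = X - a @ W
    return ARModel(
        coefficients=a,
        innovation_variance=float(np.var(resid)),
        rate=rate,
        n_effective=m,
    )


def compute_aic(model: ARModel, n_effective: int | None = None) -> float:
    """Akaike information criterion ``n ln(sigma_U^2) + 2p`` of an AR fit."""
    n = n_effective if n_effective is not None else model.n_effective
    if n is None:
        raise ValueError("number of effective observations required")
    if model.innovation_variance <= 0:
        raise ValueError("innovation variance must be positive")
    return float(n * np.log(model.innovation_variance) + 2 * model.order)


@dataclass
class BandComponent:
    """One merged spectral component (a real pole or a conjugate pair)."""

    frequency: float  # Hz, arg(pole)/(2 pi) * fs
    power: float  # sigma_k^2, variance units
    pole: complex  # representative pole (Im >= 0)
    psd: np.ndarray  # component profile on the frequency grid


@dataclass
class SpectralDecomposition:
    """Pole-residue decomposition of an AR power spectral density.

    ``psd`` integrates to the process variance over ``[-fs/2, fs/2]`` (the
    grid covers ``[0, fs/2]``; the PSD is even).  ``components`` merge
    complex-conjugate pole pairs; ``sum(c.power) == process_variance`` up to
    numerical tolerance.  ``reflected`` flags that an unstable estimate was
    stabilized by reflecting poles inside the unit circle (innovation
    variance rescaled so the PSD is unchanged).
    """

    poles: np.ndarray
    residues: np.ndarray
    frequencies: np.ndarray  # Hz, grid on [0, fs/2]
    psd: np.ndarray
    components: list[BandComponent]
    process_variance: float
    rate: float
    reflected: bool = False

    @property
    def component_frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.components])

    @property
    def component_powers(self) -> np.ndarray:
        return np.array([c.power for c in self.components])


def _residues(poles: np.ndarray, innovation_variance: float) -> np.ndarray:
    """Residue weights r_k of the pole-residue PSD expansion.

    ``r_k = c_k / p_k`` where ``c_k`` is the residue of
    ``P(z) = sigma_U^2 / prod_j[(z - p_j)(z^{-1} - p_j)]`` at ``z = p_k``.
    """
    r = np.empty(poles.shape[0], dtype=complex)
    for k, pk in enumerate(poles):
        others = np.delete(poles, k)
        denom = np.prod(pk - others) * np.prod(1.0 / pk - poles)
        r[k] = innovation_variance / denom / pk
    return r


def decompose_psd(model: ARModel, grid_size: int = DEFAULT_GRID) -> SpectralDecomposition:
    """Decompose an AR model's PSD into per-pole spectral components.

    Poles are the roots of the characteristic polynomial; residues are
    evaluated numerically from the partial-fraction limit formula, and the
    expansion is exact: the component profiles sum to the total PSD on the
    grid, and the component powers sum to the process variance.  Repeated
    poles are unsupported; an unstable model has its outside poles
    reflected (``p -> 1/conj(p)``) with a variance-preserving innovation
    rescale and is flagged.
    """
    fs = model.rate
    su2 = model.innovation_variance
    poles = model.poles
    reflected = False
    outside = np.abs(poles) >= 1.0
    if outside.any():
        su2 = su2 / np.prod(np.abs(poles[outside]) ** 2)
        poles = np.where(outside, 1.0 / np.conj(poles), poles)
        reflected = True
        warnings.warn("unstable AR estimate: poles reflected inside the unit circle",
                      stacklevel=2)
    if poles.size > 1:
        dist = np.abs(poles[:, None] - poles[None, :])
        np.fill_diagonal(dist, np.inf)
        if dist.min() < 1e-8:
            raise ValueError("repeated poles are unsupported by the residue expansion")

    res = _residues(poles, su2)
    freqs = np.linspace(0.0, fs / 2.0, grid_size)
    z = np.exp(2j * np.pi * freqs / fs)
    # per-pole profiles of the partial-fraction expansion, 1/fs scaled so
    # the two-sided integral over [-fs/2, fs/2] equals the variance
    prof = (
        res[:, None] * poles[:, None] / (z[None, :] - poles[:, None])
        - (res[:, None] / poles[:, None]) / (z[None, :] - 1.0 / poles[:, None])
    ) / fs

    # merge conjugate pairs: keep Im >= 0 representative
    used = np.zeros(poles.size, dtype=bool)
    components: list[BandComponent] = []
    order = np.argsort(-poles.imag)  # positive-imag first so they are kept
    for k in order:
        if used[k]:
            continue
        pk = poles[k]
        used[k] = True
        if abs(pk.imag) < 1e-10:  # real pole
            power = res[k].real
            psd_k = prof[k].real
            frequency = 0.0 if pk.real >= 0 else fs / 2.0
        else:
            partner = np.where(~used & (np.abs(poles - np.conj(pk)) < 1e-8))[0]
            if partner.size == 0:
                raise ValueError("complex pole without conjugate partner")
            j = partner[0]
            used[j] = True
            power = (res[k] + res[j]).real
            psd_k = (prof[k] + prof[j]).real
            frequency = abs(np.angle(pk)) / (2.0 * np.pi) * fs
        components.append(
            BandComponent(frequency=frequency, power=power, pole=pk, psd=psd_k)
        )

    # A(z) = 1 - sum a_k z^{-k} = prod_k (1 - p_k/z), from the (possibly
    # reflected) poles so the total matches the decomposed components
    a_of_z = np.prod(1.0 - poles[:, None] / z[None, :], axis=0)
    psd_total = su2 / (np.abs(a_of_z) ** 2) / fs
    sigma_x2 = float(sum(c.power for c in components))
    return SpectralDecomposition(
        poles=poles,
        residues=res,
        frequencies=freqs,
        psd=psd_total,
        components=components,
        process_variance=sigma_x2,
        rate=fs,
        reflected=reflected,
    )


def band_summary(
    dec: SpectralDecomposition,
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
) -> dict[str, dict]:
    """Per-band peak frequency and power from a spectral decomposition.

    A component belongs to a band if its central frequency falls in
    ``[lo, hi)`` (the upper edge is exclusive so the 0.15 Hz boundary is
    unambiguous; the HF upper edge is inclusive).  Band power sums the
    assigned components' ``sigma_k^2`` — equivalently the full-spectrum
    integral of their profiles — and the band frequency is the central
    frequency of the maximum-power assigned component.  A band with no
    component is reported as missing (``None`` fields), never as zero.
    """
    out: dict[str, dict] = {}
    for name, (lo, hi), last in (("LF", lf_band, False), ("HF", hf_band, True)):
        members = [
            c
            for c in dec.components
            if (lo <= c.frequency < hi) or (last and np.isclose(c.frequency, hi))
        ]
        if not members:
            out[name] = {"peak_frequency": None, "power": None, "n_components": 0}
            continue
        top = max(members, key=lambda c: c.power)
        out[name] = {
            "peak_frequency": top.frequency,
            "power": float(sum(c.power for c in members)),
            "n_components": len(members),
        }
    return out


class WindowedAR:
    """Stationary AR model of one condition, pooled across phase windows.

    Parameters
    ----------
    endog
        The full preprocessed 1 Hz series (one channel, one species).
    windows
        The condition's index windows (e.g. ``phase_windows.apnea``); pass
        a single ``np.arange`` window to fit a contiguous stretch.
    order
        AR order ``p`` (default 4, the fixed order of the analysis).
    rate
        Sampling rate in Hz.
    """

    def __init__(
        self,
        endog: np.ndarray,
        windows: tuple[np.ndarray, ...] | list[np.ndarray],
        order: int = 4,
        rate: float = 1.0,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.windows = tuple(np.asarray(w, dtype=int) for w in windows)
        self.order = int(order)
        self.rate = float(rate)

    def fit(self) -> "WindowedARResults":
        X, W = build_phase_regressors(self.endog, self.windows, self.order)
        model = ols_identify(X, W, rate=self.rate)
        return WindowedARResults(self, model)


class WindowedARResults:
    """OLS AR fit with spectral-decomposition accessors."""

    def __init__(self, model: WindowedAR, ar: ARModel) -> None:
        self.model = model
        self.ar = ar
        self._dec: SpectralDecomposition | None = None

    @property
    def params(self) -> np.ndarray:
        return self.ar.coefficients

    @property
    def innovation_variance(self) -> float:
        return self.ar.innovation_variance

    @property
    def aic(self) -> float:
        return compute_aic(self.ar)

    def spectrum(self, grid_size: int = DEFAULT_GRID) -> SpectralDecomposition:
        if self._dec is None or self._dec.frequencies.size != grid_size:
            self._dec = decompose_psd(self.ar, grid_size=grid_size)
        return self._dec

    def band_summary(
        self,
        lf_band: tuple[float, float] = LF_BAND,
        hf_band: tuple[float, float] = HF_BAND,
        grid_size: int = DEFAULT_GRID,
    ) -> dict[str, dict]:
        return band_summary(self.spectrum(grid_size), lf_band, hf_band)

    def summary(self) -> str:
        dec = self.spectrum()
        bands = self.band_summary()
        lines = [
            "Windowed AR spectral results",
            "=" * 33,
            f"order p              {self.ar.order}",
            f"observations         {self.ar.n_effective}",
            f"innovation variance  {self.ar.innovation_variance:.4g}",
            f"process variance     {dec.process_variance:.4g}",
            f"stable               {not dec.reflected}",
            "-" * 33,
        ]
        for name, info in bands.items():
            if info["peak_frequency"] is None:
                lines.append(f"{name}: no spectral component in band")
            else:
                lines.append(
                    f"{name}: f = {info['peak_frequency']:.3f} Hz, "
                    f"power = {info['power']:.4g} "
                    f"({info['n_components']} component(s))"
                )
        return "\n".join(lines)
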