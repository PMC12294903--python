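"""Time-varying AR identification and time-resolved information measures.

A zero-mean signal :math:`X` is modeled as a time-varying autoregressive
(TV-AR) process,

.. math:: X_n = \\sum_{k=1}^{p} a_{k,n} X_{n-k} + U_n,

whose coefficients are tracked online by recursive least squares (RLS) with
exponential forgetting.  With adaptation factor :math:`c \\in (0, 1)` and
past-state vector :math:`W_n = [X_{n-1}, \\dots, X_{n-p}]^\\top`, each step
updates

.. math::

    \\Sigma_{W_n} = (1-c)\\,\\Sigma_{W_{n-1}} + W_n W_n^\\top, \\qquad
    K_n = \\Sigma_{W_n}^{-1} W_n,

    Z_n = X_n - A_{n-1} W_n, \\qquad A_n = A_{n-1} + Z_n K_n^\\top,

and the innovation variance recursively as
:math:`\\sigma^2_{U_n} = \\sigma^2_{U_{n-1}} + c\\,(Z_n^2 - \\sigma^2_{U_{n-1}})`.
The forgetting factor :math:`1-c` (default 0.975) sets the bias-variance
trade-off of the tracker.

Under a Gaussian assumption the time-resolved information measures follow in
closed form from the innovation variance :math:`\\sigma^2_{U_n}` and the
process variance :math:`\\sigma^2_{X_n}` of the model frozen at time *n*:

* entropy  ``H_n = 1/2 ln(2 pi e sigma_Xn^2)`` — overall uncertainty,
* conditional entropy  ``CE_n = 1/2 ln(2 pi e sigma_Un^2)`` — new
  information not predictable from the past (complexity),
* information storage  ``IS_n = H_n - CE_n = 1/2 ln(sigma_Xn^2/sigma_Un^2)``
  — predictability of the present from the past.

All logarithms are natural, so measures are in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

__all__ = [
    "TVARTrajectory",
    "InfoMeasureSeries",
    "rls_identify",
    "process_variance",
    "info_measures",
    "TimeVaryingAR",
    "TimeVaryingARResults",
]

DEFAULT_ORDER = 4
DEFAULT_FORGETTING = 0.975  # = 1 - c
DEFAULT_BURN_IN = 20


@dataclass
class TVARTrajectory:
    """State of an RLS-identified TV-AR model.

    Arrays are aligned with the input series (length ``N``); entries before
    ``n = order`` — where the recursion is undefined — are NaN.  The full
    per-step gain and a-priori error are kept so that the recursion can be
    audited.
    """

    x: np.ndarray
    order: int
    adaptation: float  # c
    coefficients: np.ndarray  # (N, p)
    innovation_variance: np.ndarray  # (N,)
    gains: np.ndarray = field(repr=False)  # (N, p)
    apriori_errors: np.ndarray = field(repr=False)  # (N,)
    correlation: np.ndarray = field(repr=False)  # final Sigma_W (p, p)
    process_variance: np.ndarray | None = None  # (N,)
    unstable: np.ndarray | None = None  # bool flags where frozen model unstable

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    @property
    def forgetting(self) -> float:
        return 1.0 - self.adaptation

    @property
    def valid(self) -> np.ndarray:
        """Mask of time steps where the recursion is defined."""
        v = np.zeros(self.n_samples, dtype=bool)
        v[self.order :] = True
        return v


@dataclass
class InfoMeasureSeries:
    """Time-resolved entropy, conditional entropy and information storage.

    ``storage`` is computed as ``entropy - conditional_entropy`` so the
    decomposition identity holds exactly at every sample.  ``flags`` marks
    samples that are undefined (recursion warm-up, non-positive variance)
    or where an unstable frozen model's variance was carried forward.
    """

    entropy: np.ndarray
    conditional_entropy: np.ndarray
    storage: np.ndarray
    flags: np.ndarray  # bool, True = unreliable/missing

    def __post_init__(self) -> None:
        assert self.entropy.shape == self.conditional_entropy.shape == self.storage.shape


def rls_identify(
    x: np.ndarray,
    order: int = DEFAULT_ORDER,
    forgetting: float = DEFAULT_FORGETTING,
    ridge_rtol: float = 1e-8,
) -> TVARTrajectory:
    """Identify a TV-AR model by recursive least squares.

    Initial conditions are scale-matched and neutral: the coefficient vector
    starts at zero, the past-state correlation at the identity scaled by the
    variance of the first ``p`` samples, and the innovation variance at the
    variance of the first ``2p`` samples.  A ridge term
    ``ridge_rtol * trace`` regularizes the gain solve when the correlation
    matrix is ill-conditioned (e.g. constant input), with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.shape[0]
    p = int(order)
    if not 0.0 < forgetting < 1.0:
        raise ValueError("forgetting factor must lie in (0, 1)")
    c = 1.0 - forgetting
    if n <= 2 * p + 1:
        raise ValueError(f"series of length {n} too short for order {p} RLS")

    scale = float(np.var(x[:p])) if p > 1 else float(np.var(x[: max(2, p)]))
    sigma_w = np.eye(p) * (scale if scale > 0 else 1.0)
    a = np.zeros(p)
    su2 = float(np.var(x[: 2 * p]))
    if su2 <= 0:
        su2 = 1.0

    coeffs = np.full((n, p), np.nan)
    innov = np.full(n, np.nan)
    gains = np.full((n, p), np.nan)
    zs = np.full(n, np.nan)
    warned = False
    for t in range(p, n):
        w = x[t - p : t][::-1]  # [x_{t-1}, ..., x_{t-p}]
        sigma_w = forgetting * sigma_w + np.outer(w, w)
        try:
            k = np.linalg.solve(sigma_w, w)
            if not np.all(np.isfinite(k)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            k = np.linalg.solve(
                sigma_w + ridge_rtol * np.trace(sigma_w) * np.eye(p), w
            )
            if not warned:
                warnings.warn(
                    "ill-conditioned past-state correlation; using ridge-"
                    "regularized gain", stacklevel=2,
                )
                warned = True
        z = x[t] - a @ w
        a = a + z * k
        su2 = su2 + c * (z * z - su2)
        coeffs[t] = a
        innov[t] = su2
        gains[t] = k
        zs[t] = z
    return TVARTrajectory(
        x=x,
        order=p,
        adaptation=c,
        coefficients=coeffs,
        innovation_variance=innov,
        gains=gains,
        apriori_errors=zs,
        correlation=sigma_w,
    )


def _companion(coeffs: np.ndarray) -> np.ndarray:
    p = coeffs.shape[0]
    F = np.zeros((p, p))
    F[0] = coeffs
    if p > 1:
        F[1:, :-1] = np.eye(p - 1)
    return F


def stationary_variance(coeffs: np.ndarray, innovation_variance: float) -> float:
    """Stationary variance of the AR model frozen at given coefficients.

    Solves the companion-form discrete Lyapunov equation
    ``S = F S F^T + Q`` with ``Q = sigma_U^2 e_1 e_1^T``; the process
    variance is ``S[0, 0]``.  Raises for unstable coefficients.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    F = _companion(coeffs)
    if np.max(np.abs(np.linalg.eigvals(F))) >= 1.0:
        raise ValueError("frozen AR model is unstable")
    q = np.zeros_like(F)
    q[0, 0] = innovation_variance
    return float(sla.solve_discrete_lyapunov(F, q)[0, 0])


def process_variance(
    traj: TVARTrajectory, method: str = "lyapunov"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample process variance ``sigma_Xn^2`` of the TV-AR model.

    ``method='lyapunov'`` (default) takes, at each *n*, the stationary
    variance of the model frozen at ``(A_n, sigma_Un^2)`` from the discrete
    Lyapunov solution; samples whose frozen model is unstable carry the
    previous valid value forward and are flagged.  ``method='smoothing'``
    instead tracks the empirical variance of the (zero-mean) signal with the
    same exponential memory as the RLS recursion,
    ``sigma_Xn^2 = sigma_Xn-1^2 + c (x_n^2 - sigma_Xn-1^2)``.

    Returns ``(variance, flags)`` and caches both on the trajectory.
    """
    n, p = traj.n_samples, traj.order
    var = np.full(n, np.nan)
    flags = np.zeros(n, dtype=bool)
    if method == "lyapunov":
        last = np.nan
        for t in range(p, n):
            a = traj.coefficients[t]
            F = _companion(a)
            if np.max(np.abs(np.linalg.eigvals(F))) < 1.0:
                q = np.zeros((p, p))
                q[0, 0] = traj.innovation_variance[t]
                last = float(sla.solve_discrete_lyapunov(F, q)[0, 0])
            else:
                flags[t] = True  # unstable: carry previous valid value
            var[t] = last
        if np.all(np.isnan(var[p:])):
            raise ValueError("frozen TV-AR model unstable at every time step")
        flags[np.isnan(var)] = True
    elif method == "smoothing":
        c = traj.adaptation
        v = float(np.var(traj.x[: 2 * p]))
        if v <= 0:
            v = 1.0
        for t in range(p, n):
            v = v + c * (traj.x[t] ** 2 - v)
            var[t] = v
    else:
        raise ValueError(f"unknown process-variance method {method!r}")
    traj.process_variance = var
    traj.unstable = flags
    return var, flags


def info_measures(traj: TVARTrajectory) -> InfoMeasureSeries:
    """Time-resolved H, CE and IS (nats) from an identified trajectory.

    Requires :func:`process_variance` to have run (it is invoked with the
    default method if not).  Samples with non-positive or undefined
    variances are flagged as missing.
    """
    if traj.process_variance is None:
        process_variance(traj)
    sx2 = traj.process_variance
    su2 = traj.innovation_variance
    bad = ~(np.isfinite(sx2) & np.isfinite(su2) & (sx2 > 0) & (su2 > 0))
    flags = bad | (traj.unstable if traj.unstable is not None else False)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 0.5 * np.log(2.0 * np.pi * np.e * sx2)
        ce = 0.5 * np.log(2.0 * np.pi * np.e * su2)
    h = np.where(bad, np.nan, h)
    ce = np.where(bad, np.nan, ce)
    return InfoMeasureSeries(
        entropy=h, conditional_entropy=ce, storage=h - ce, flags=flags
    )


class TimeVaryingAR:
    """Time-varying AR model of one zero-mean series, fitted by RLS.

    Parameters
    ----------
    endog
        The analyzed series (a preprocessed, normalized hemoglobin series).
    order
        AR model order ``p`` (default 4).
    forgetting
        RLS forgetting factor ``1 - c`` in (0, 1), default 0.975.
    rate
        Sampling rate in Hz (1 Hz for the standard pipeline).
    burn_in
        Samples after the recursion start excluded from summary averages,
        covering the RLS transient (default 20).
    variance_method
        ``'lyapunov'`` (frozen-model stationary variance) or ``'smoothing'``
        (exponentially smoothed empirical variance).

    Examples
    --------
    >>> res = TimeVaryingAR(x, order=4, forgetting=0.975).fit()
    >>> res.storage  # time-resolved information storage, nats
    """

    def __init__(
        self,
        endog: np.ndarray,
        order: int = DEFAULT_ORDER,
        forgetting: float = DEFAULT_FORGETTING,
        rate: float = 1.0,
        burn_in: int = DEFAULT_BURN_IN,
        variance_method: str = "lyapunov",
    ) -> None:
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.order = int(order)
        self.forgetting = float(forgetting)
        self.rate = float(rate)
        self.burn_in = int(burn_in)
        self.variance_method = variance_method

    def fit(self) -> "TimeVaryingARResults":
        traj = rls_identify(self.endog, self.order, self.forgetting)
        process_variance(traj, method=self.variance_method)
        measures = info_measures(traj)
        return TimeVaryingARResults(self, traj, measures)


class TimeVaryingARResults:
    """Results of an RLS TV-AR fit: coefficient trajectory + info measures."""

    def __init__(
        self, model: TimeVaryingAR, trajectory: TVARTrajectory, measures: InfoMeasureSeries
    ) -> None:
        self.model = model
        self.trajectory = trajectory
        self.measures = measures

    @property
    def coefficients(self) -> np.ndarray:
        return self.trajectory.coefficients

    @property
    def innovation_variance(self) -> np.ndarray:
        return self.trajectory.innovation_variance

    @property
    def process_variance(self) -> np.ndarray:
        return self.trajectory.process_variance

    @property
    def entropy(self) -> np.ndarray:
        return self.measures.entropy

    @property
    def conditional_entropy(self) -> np.ndarray:
        return self.measures.conditional_entropy

    @property
    def storage(self) -> np.ndarray:
        return self.measures.storage

    @property
    def flags(self) -> np.ndarray:
        return self.measures.flags

    def steady_mask(self) -> np.ndarray:
        """Samples past warm-up + burn-in with defined, unflagged measures."""
        m = np.zeros(self.trajectory.n_samples, dtype=bool)
        m[self.model.order + self.model.burn_in :] = True
        return m & ~self.measures.flags

    def time_average(self, measure: str = "storage") -> float:
        """Post-burn-in time average of ``'entropy'|'conditional_entropy'|'storage'``."""
        values = getattr(self.measures, measure)
        mask = self.steady_mask()
        return float(np.nanmean(values[mask]))

    def to_frame(self, subject: str = "S01", channel: str = "CH01", species: str = "HbO2"):
        """Tidy table: subject, channel, species, time_s, H, CE, IS, flagged."""
        import pandas as pd

        n = self.trajectory.n_samples
        return pd.DataFrame(
            {
                "subject": subject,
                "channel": channel,
                "species": species,
                "time_s": np.arange(n) / self.model.rate,
                "H": self.entropy,
                "CE": self.conditional_entropy,
                "IS": self.storage,
                "flagged": self.flags,
            }
        )

    def summary(self) -> str:
        m = self.model
        lines = [
            "Time-varying AR (RLS) results",
            "=" * 33,
            f"n samples            {self.trajectory.n_samples}",
            f"order p              {m.order}",
            f"forgetting (1 - c)   {m.forgetting:.4f}",
            f"variance method      {m.variance_method}",
            f"burn-in (excluded)   {m.burn_in}",
            "-" * 33,
            f"mean H  [nats]       {self.time_average('entropy'):8.4f}",
            f"mean CE [nats]       {self.time_average('conditional_entropy'):8.4f}",
            f"mean IS [nats]       {self.time_average('storage'):8.4f}",
            f"flagged samples      {int(self.flags.sum())}",
        ]
        return "\n".join(lines)
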