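"""Phase-wise aggregation and small-sample statistical comparisons.

Each time-resolved measure is averaged within every protocol window of a
condition and then across that condition's windows, giving one value per
(subject, channel, species, measure, condition).  Apnea and breath values
are compared per channel with the paired Wilcoxon signed-rank test (exact
two-sided p-values at the study's n = 6), the effect size is quantified by
Cohen's d for equally sized groups,

.. math:: d = \\frac{\\mu_{S_1} - \\mu_{S_2}}
               {\\sqrt{(\\sigma_{S_1}^2 + \\sigma_{S_2}^2)/2}},

and the post hoc power of each test is estimated by Monte-Carlo simulation
of the exact Wilcoxon test under Gaussian paired differences with
standardized shift d (a noncentral-t approximation is available as an
alternative).  Tests are reported per channel without multiplicity
correction by default; an optional Benjamini-Hochberg FDR mode changes
only the significance flags, never the p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sstats

__all__ = [
    "ChannelTestResult",
    "window_average",
    "wilcoxon_paired",
    "cohens_d",
    "posthoc_power",
    "compare_conditions",
]

ALPHA = 0.05


@dataclass
class ChannelTestResult:
    """Paired-comparison result for one channel/measure."""

    p_value: float
    statistic: float
    effect_size: float
    power: float
    n_pairs: int
    significant: bool
    underpowered: bool = False
    undefined: bool = False


def window_average(
    values: np.ndarray,
    windows: tuple[np.ndarray, ...] | list[np.ndarray],
    flags: np.ndarray | None = None,
) -> float:
    """Mean within each window, then mean across windows.

    Flagged (or NaN) samples are excluded from the within-window means; a
    window with no usable sample is dropped with a warning.
    """
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values)
    if flags is not None:
        keep &= ~np.asarray(flags, dtype=bool)
    means = []
    for i, idx in enumerate(windows):
        idx = np.asarray(idx, dtype=int)
        good = idx[keep[idx]]
        if good.size == 0:
            warnings.warn(f"window {i + 1} entirely flagged; dropped", stacklevel=2)
            continue
        means.append(values[good].mean())
    if not means:
        raise ValueError("no usable window for aggregation")
    return float(np.mean(means))


@lru_cache(maxsize=32)
def _signed_rank_pmf(n: int) -> np.ndarray:
    """Exact null PMF of the signed-rank statistic W+ for sample size n."""
    pmf = np.array([1.0])
    for k in range(1, n + 1):
        new = np.zeros(pmf.size + k)
        new[: pmf.size] += pmf
        new[k:] += pmf
        pmf = new
    return pmf / 2.0**n


def wilcoxon_paired(
    apnea: np.ndarray, breath: np.ndarray, alpha: float = ALPHA
) -> ChannelTestResult:
    """Two-sided paired Wilcoxon signed-rank test, exact for small samples.

    Zero differences are discarded (classic Wilcoxon convention) and ties
    are mid-ranked; the exact permutation distribution is used up to n = 25.
    Fewer than 5 non-zero pairs flags the result as underpowered (the
    p-value is still computed); all-zero differences leave the test
    undefined.  Effect size and power are filled in by
    :func:`compare_conditions`; here they are NaN.
    """
    a = np.asarray(apnea, dtype=float).ravel()
    b = np.asarray(breath, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    nz = diff[diff != 0.0]
    if nz.size == 0:
        return ChannelTestResult(
            p_value=np.nan, statistic=np.nan, effect_size=np.nan, power=np.nan,
            n_pairs=0, significant=False, undefined=True,
        )
    method = "exact" if nz.size <= 25 else "approx"
    res = sstats.wilcoxon(
        nz, zero_method="wilcox", alternative="two-sided", method=method
    )
    return ChannelTestResult(
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        effect_size=np.nan,
        power=np.nan,
        n_pairs=int(nz.size),
        significant=bool(res.pvalue < alpha),
        underpowered=nz.size < 5,
    )


def cohens_d(s1: np.ndarray, s2: np.ndarray) -> float:
    """Cohen's d for equally sized groups, pooled-variance denominator."""
    s1 = np.asarray(s1, dtype=float).ravel()
    s2 = np.asarray(s2, dtype=float).ravel()
    if s1.size < 2 or s2.size < 2:
        raise ValueError("both groups need at least two observations")
    v1, v2 = np.var(s1, ddof=1), np.var(s2, ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("both groups have zero variance")
    return float((s1.mean() - s2.mean()) / np.sqrt((v1 + v2) / 2.0))


def posthoc_power(
    d: float,
    n: int,
    alpha: float = ALPHA,
    reps: int = 2000,
    seed: int | None = None,
    method: str = "simulation",
) -> float:
    """Power of the paired exact Wilcoxon test at standardized shift ``d``.

    ``method='simulation'`` (default) draws ``reps`` sets of ``n`` Gaussian
    paired differences with mean ``d`` and unit SD, runs the exact two-sided
    signed-rank test on each and returns the rejection fraction.
    ``method='t_approx'`` returns the noncentral-t power of the analogous
    paired t-test (noncentrality ``d * sqrt(n)``).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if method == "t_approx":
        t_crit = sstats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
        nc = d * np.sqrt(n)
        return float(
            sstats.nct.sf(t_crit, df=n - 1, nc=nc)
            + sstats.nct.cdf(-t_crit, df=n - 1, nc=nc)
        )
    if method != "simulation":
        raise ValueError(f"unknown power method {method!r}")
    if reps < 1:
        raise ValueError("reps must be positive")
    rng = np.random.default_rng(seed)
    diffs = rng.standard_normal((reps, n)) + d
    ranks = sstats.rankdata(np.abs(diffs), axis=1)
    w_plus = np.sum(ranks * (diffs > 0), axis=1)
    pmf = _signed_rank_pmf(n)
    cdf = np.cumsum(pmf)
    sf_incl = 1.0 - np.concatenate([[0.0], cdf[:-1]])  # P(W >= w)
    w_idx = np.round(w_plus).astype(int)
    p = np.minimum(1.0, 2.0 * np.minimum(cdf[w_idx], sf_incl[w_idx]))
    return float(np.mean(p < alpha))


def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    finite = np.isfinite(pvals)
    reject = np.zeros(pvals.shape, dtype=bool)
    if finite.any():
        reject[finite] = multipletests(pvals[finite], alpha=alpha, method="fdr_bh")[0]
    return reject


def compare_conditions(
    subject_values: "pd.DataFrame",  # noqa: F821
    alpha: float = ALPHA,
    power_reps: int = 2000,
    power_seed: int | None = 0,
    power_method: str = "simulation",
    fdr: bool = False,
) -> "pd.DataFrame":  # noqa: F821
    """Channel-wise apnea-vs-breath tests over a subject-value table.

    ``subject_values`` is the tidy aggregation output with columns
    ``subject, channel, species, measure, condition, value``.  Returns one
    row per (channel, species, measure) with the Wilcoxon p, Cohen's d,
    post hoc power and significance flag; with ``fdr=True`` the flags (and
    only the flags) reflect Benjamini-Hochberg correction across channels.
    """
    import pandas as pd

    rows = []
    grouped = subject_values.groupby(["channel", "species", "measure"], sort=True)
    for (channel, species, measure), grp in grouped:
        wide = grp.pivot_table(
            index="subject", columns="condition", values="value"
        ).dropna()
        if wide.shape[0] < 2 or not {"apnea", "breath"} <= set(wide.columns):
            continue
        a = wide["apnea"].to_numpy()
        b = wide["breath"].to_numpy()
        test = wilcoxon_paired(a, b, alpha=alpha)
        try:
            d = cohens_d(a, b)
        except ValueError:
            d = np.nan
        power = (
            posthoc_power(
                abs(d), wide.shape[0], alpha=alpha, reps=power_reps,
                seed=power_seed, method=power_method,
            )
            if np.isfinite(d)
            else np.nan
        )
        rows.append(
            {
                "channel": channel,
                "species": species,
                "measure": measure,
                "n_pairs": test.n_pairs,
                "p_value": test.p_value,
                "cohens_d": d,
                "power": power,
                "significant": test.significant,
                "underpowered": test.underpowered,
                "undefined": test.undefined,
                "mean_apnea": float(a.mean()),
                "mean_breath": float(b.mean()),
            }
        )
    out = pd.DataFrame(rows)
    if fdr and len(out):
        for (species, measure), idx in out.groupby(["species", "measure"]).groups.items():
            out.loc[idx, "significant"] = _bh_reject(
                out.loc[idx, "p_value"].to_numpy(), alpha
            )
    return out
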