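# nirsdyn

Time-resolved information dynamics and parametric spectral analysis of
multi-channel fNIRS recordings acquired during a breath-holding protocol.

Functional near-infrared spectroscopy (fNIRS) measures oxy- and
deoxyhemoglobin concentration changes (HbO2, HHb) in scalp and brain tissue
from dual-wavelength light attenuation.  During a breath-hold task the
recorded hemodynamics are shaped by two systemic oscillations — a vascular
(Mayer-wave) rhythm near 0.05 Hz and a respiratory rhythm near 0.2 Hz — and
the question this package addresses is how voluntary apnea modulates the
*regularity, predictability and spectral content* of those signals.  It is
written for physiological signal-processing researchers who want a tested,
reusable implementation of this analysis, with a synthetic-data generator
standing in for recordings that are not publicly deposited.

## The models

**Time-resolved information measures.**  Each preprocessed, normalized
series is modeled as a time-varying autoregressive (TV-AR) process

$$X_n = \sum_{k=1}^{p} a_{k,n}\,X_{n-k} + U_n ,$$

identified online by recursive least squares (RLS) with forgetting factor
$1-c = 0.975$ and order $p = 4$.  Under a Gaussian assumption, the
innovation variance $\sigma^2_{U_n}$ and the process variance
$\sigma^2_{X_n}$ give closed-form, time-resolved measures (in nats):

- entropy $H_n = \tfrac12\ln(2\pi e\,\sigma^2_{X_n})$ — overall uncertainty;
- conditional entropy $CE_n = \tfrac12\ln(2\pi e\,\sigma^2_{U_n})$ — new
  information unexplained by the past (complexity);
- information storage $IS_n = H_n - CE_n =
  \tfrac12\ln(\sigma^2_{X_n}/\sigma^2_{U_n})$ — predictability of the
  present from the past.

**Pole–residue spectral decomposition.**  Per experimental condition
(apnea / breath) a stationary AR(4) model is fitted by ordinary least
squares on regressors pooled across the protocol's five windows, and its
power spectral density is expanded by the Heaviside partial-fraction method
into one component per pole.  Each oscillation gets a central frequency
$f_k = \arg(p_k)/2\pi$ and a power $\sigma_k^2$ from the residue, with the
exact accounting $\sum_k \sigma_k^2 = \sigma_X^2$.  Components are assigned
to the LF ([0.04–0.15] Hz, vascular) and HF ([0.15–0.4] Hz, respiratory)
bands; per channel the apnea and breath values are compared across subjects
with exact paired Wilcoxon signed-rank tests, Cohen's d, and simulated
post hoc power.

## Worked example

```python
from nirsdyn import (generate_recording, preprocess_recording,
                     build_phase_windows, TimeVaryingAR, WindowedAR)

rec = generate_recording(seed=42)          # 16 channels, 300 s at 130 Hz
hemo = preprocess_recording(rec)           # OD -> TDDR -> MBLL -> 1 Hz, z-scored
x = hemo.series(0, "HbO2")                 # one channel, N = 300 samples

res = TimeVaryingAR(x, order=4, forgetting=0.975,
                    variance_method="smoothing").fit()
print(res.summary())
```

```
Time-varying AR (RLS) results
=================================
n samples            300
order p              4
forgetting (1 - c)   0.9750
variance method      smoothing
burn-in (excluded)   20
---------------------------------
mean H  [nats]         1.3716
mean CE [nats]         0.7191
mean IS [nats]         0.6525
flagged samples      4
```

The time-averaged information storage of 0.65 nats says that, on average,
knowing the previous four seconds removes about half of the signal's
log-variance uncertainty; `res.storage` holds the per-second trajectory
used for the phase-wise comparison.

```python
windows = build_phase_windows(rec.schedule, p=4)
print(WindowedAR(x, windows.windows("breath"), order=4).fit().summary())
```

```
Windowed AR spectral results
=================================
order p              4
observations         142
innovation variance  0.1715
process variance     1.139
stable               True
---------------------------------
LF: f = 0.051 Hz, power = 0.9346 (1 component(s))
HF: f = 0.260 Hz, power = 0.2044 (1 component(s))
```

The breath-phase fit finds the vascular component at 0.051 Hz and the
respiratory component at 0.26 Hz; the same channel's apnea fit (not shown)
places the HF pole near 0.25 Hz with roughly half the power — the
modulation the cohort statistics then test across subjects.  The full
six-subject pipeline is one call (or `nirsdyn all --out run/` from a
shell):

```python
from nirsdyn import RunConfig, run_pipeline
result = run_pipeline(RunConfig(seed=1))
print(result.stats.head())     # per-channel Wilcoxon p, Cohen's d, power
```

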