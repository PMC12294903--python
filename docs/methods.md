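# Methods

This note documents the models implemented in `nirsdyn`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Signal model and preprocessing

Raw dual-wavelength (735/850 nm) intensities sampled at 130 Hz are
processed strictly in this order:

1. **Optical density** `OD = -ln(I/Io)`, with `Io` the first sample of each
   channel/wavelength by default (`initial_window_mean`, the mean of the
   first 5 s, is available when the first sample is unreliable).
2. **Motion correction** with Temporal Derivative Distribution Repair
   (TDDR): the trace is split at 0.5 Hz; the slow component's temporal
   derivative is iteratively reweighted with Tukey's biweight (tuning
   constant 4.685, at most 50 iterations), re-integrated, and recombined
   with the untouched fast component.  Our implementation agrees to
   machine precision with the reference implementation distributed in
   `mne`, which the test suite checks directly.  Two properties of the
   canonical algorithm are worth stating plainly: (i) it shrinks the
   sub-0.5 Hz band by the mean biweight factor (roughly 8–20% depending on
   the derivative's distribution), a scale effect that is irrelevant here
   because every series is later z-normalized; (ii) it corrects only the
   slow component, so an isolated single-sample spike at 130 Hz is left to
   the anti-alias filter, while its low-frequency footprint — the only part
   that would reach the analysis — is removed.  Tests assert step-shift
   removal (≥ 90% by before/after means) and spike-footprint removal in
   the ≤ 0.5 Hz band.
3. **Modified Beer–Lambert inversion**: per-sample 2×2 solve of
   `ΔOD(λ) = ln10 · ε(λ) · Δc · d · DPF` with source–detector distance
   d = 3 cm and DPF = 6 (both configurable), using decadic molar extinction
   coefficients from a standard compilation (735 nm interpolated between
   the 730 and 740 nm entries); concentrations are in micromolar.
4. **Anti-aliased downsampling**: zero-phase 4th-order Butterworth low-pass
   at 0.5 Hz, then decimation by 130 to 1 Hz.  A 300 s recording yields
   exactly N = 300 samples.
5. **Detrending and normalization**: zero-phase 2nd-order Butterworth
   high-pass at 0.018 Hz, then exact z-scoring (mean 0, variance 1).  The
   filter orders are our choices — only the cutoffs and the zero-phase IIR
   character are fixed by the analysis design; the realized magnitude
   responses are pinned down in tests against the analytic Butterworth
   response.

## Time-resolved information measures

The 1 Hz series is modeled as a TV-AR(p) process identified by RLS with
adaptation factor c (Σ_Wn update, gain, a-priori error, coefficient update,
and the recursive innovation variance
σ²_Un = σ²_U(n−1) + c(Z²_n − σ²_U(n−1))).  Defaults p = 4 and
(1−c) = 0.975 follow the analysis design this package implements (AIC
selects orders 4–6 on matched synthetic data; the order is fixed at 4 to
avoid duplicate or negative spectral peaks).  Initialization is neutral and
scale-matched: zero coefficients, Σ_W = I times the variance of the first p
samples, σ²_U = variance of the first 2p samples.  The gain solve is
ridge-regularized (ε = 1e−8 × trace) if Σ_W is ill-conditioned.  The first
`burn_in = 20` samples after the recursion start (≈ half the 1/c ≈ 40
sample memory) are excluded from window averages.

The **process variance** σ²_Xn required by H and IS is not uniquely pinned
down by the estimator's published description, so both defensible readings
are implemented:

- `lyapunov` — the stationary variance of the model frozen at
  (A_n, σ²_Un), from the companion-form discrete Lyapunov equation.  This
  guarantees σ²_Xn ≥ σ²_Un, hence IS_n ≥ 0, and matches the stationary
  closed forms best (it is the default of `TimeVaryingAR`).  Samples whose
  frozen model is momentarily unstable carry the last valid value forward
  and are flagged; flagged samples are excluded from aggregates.
- `smoothing` — the empirical variance tracked with the same exponential
  memory, σ²_Xn = σ²_X(n−1) + c(x²_n − σ²_X(n−1)).  This responds to a
  variance change immediately rather than through the coefficients.

The breath-hold pipeline defaults to `smoothing`: with 17–35 s phases and
a ≈ 40-sample RLS memory, the frozen-coefficient route (whose IS depends on
the tracked coefficients alone) attenuates the between-phase IS contrast
roughly ninefold and the per-channel tests lose sensitivity, while the
recursive empirical variance preserves the contrast.  Both methods
reproduce the directional effects; the choice affects sensitivity, not
direction.  All logarithms are natural (nats), and IS is computed as
H − CE so the decomposition identity holds exactly at every sample.

## Spectral decomposition

Per condition, present samples and lag matrices are pooled across the five
protocol windows (`m_i = [O_i+p+1, …, B_i−1]`,
`l_i = [B_i+p+1, …, O_{i+1}−1]`); no regressor crosses a window boundary,
which prevents discontinuity artifacts while maximizing the number of
observations.  Coefficients come from OLS; σ̂²_U is the residual variance.

The PSD `P(z) = σ²_U / Π_k (z−p_k)(z⁻¹−p_k)` is expanded into partial
fractions with poles p_k (inside the unit circle) and their reciprocals.
Residues are evaluated numerically from the limit formula
`r_k = Res_{z=p_k} P(z) / p_k` — the grid identity Σ_k P⁽ᵏ⁾(f) = P(f) and
the variance identity Σ_k σ²_k = σ²_X are the authoritative contracts, and
both are enforced to 1e−6 relative error in tests (they hold to machine
precision in practice).  Conjugate pole pairs are merged into one real
component (power r_k + r̄_k, frequency |arg p_k|/2π); repeated poles are
rejected.  An unstable estimated model (possible on short windows) has its
outside poles reflected to 1/p̄_k with the innovation variance rescaled by
Π|p_k|⁻², which leaves the PSD unchanged; the result is flagged.  PSDs are
scaled so that the two-sided integral over [−fs/2, fs/2] equals the process
variance (checked numerically by a Parseval test at grid 4096).

Components are assigned to LF [0.04, 0.15) Hz and HF [0.15, 0.4] Hz by
central frequency; band power sums the assigned σ²_k, band frequency is the
maximum-power component's f_k, and a band with no component is reported as
missing, never as zero.

## Statistics

Subject-level condition values average each measure within each window and
then across a condition's five windows.  Apnea vs breath is compared per
channel and species with the two-sided paired Wilcoxon signed-rank test —
exact permutation distribution up to n = 25, zeros discarded, ties
mid-ranked; at n = 6 the smallest attainable two-sided p is 2/2⁶ = 0.03125.
Effect size is Cohen's d with the pooled-variance denominator.  Post hoc
power is estimated by Monte-Carlo simulation of the exact test under
Gaussian paired differences with standardized shift d (2000 replicates by
default, seeded); a noncentral-t approximation is available.  Because the
test is discrete, the rejection rate at d = 0 equals the attainable size
(0.03125 at n = 6), not α.  No multiplicity correction is applied by
default, matching the per-channel reporting convention; a
Benjamini–Hochberg mode changes only the significance flags.

## Synthetic-data generator

The generator emulates the study conditions: 5-minute, 16-channel
recordings at 130 Hz with apnea onsets at 8, 50, 110, 170 and 230 s and
subject-specific breath resumes (apnea duration ~ N(25 s, 2 s), clipped to
keep all windows non-empty).  Hemodynamics are the sum of two stochastic
AR(2) resonances realized at the 1 Hz analysis rate — so they live exactly
in the analysis model class — band-limited-interpolated to 130 Hz, given
channel-specific log-normal gains (SD 0.2 in log units), channel-specific
in-band white noise (SD 0.2 concentration units), slow sinusoidal drift and
broadband sensor noise, and pushed through the forward Beer–Lambert model.
HHb is −0.6 × HbO2 plus independent noise.  Motion artifacts (multiplicative
exponential spikes, τ = 0.4 s, ~0.5/min; persistent baseline shifts,
~0.2/min) are injected and logged by default.

Default oscillator settings define the simulated physiology:

| component | apnea | breath |
|---|---|---|
| LF (vascular) | 0.05 Hz, ρ = 0.88, amp 1.0 | 0.05 Hz, ρ = 0.97, amp 0.7 |
| HF (respiratory) | 0.20 Hz, ρ = 0.85, amp 1.2 | 0.25 Hz, ρ = 0.96, amp 0.8 |

These were fixed from closed-form theory (Kolmogorov one-step prediction
error and Lyapunov variances of the mixtures), not tuned on test output:
breathing entrains *sharper* (higher-modulus, lower-innovation) resonances,
which is the only regime in which all the study's directional findings
coexist — higher HF frequency, higher LF and HF band power, lower CE and
higher IS during breath.  The naive alternative of simply scaling the
breath oscillation up raises the broadband spectral floor and provably
reverses the CE/IS directions.

What passing the synthetic tests shows — and does not.  The generator
matches the analysis model class by construction, so estimator correctness,
identities and tracking latency transfer to real data; but real fNIRS
contains 1/f noise, heartbeat harmonics, nonstationary artifact spectra and
cross-channel structure from optode geometry that the generator does not
model, so the cohort-level significance rates are statements about this
simulated physiology, not about any real cohort.  At the default cohort the
three headline effects are significant in ≈ 78–81% of the 32 channel
series and directionally correct in all of them; across other cohort seeds
the directions reproduce universally while the per-channel
majority-significance fluctuates — the expected behavior of an exact paired
test at n = 6, and the same small-sample power limitation the original
study reports.

## Numerical choices and degenerate inputs

- Constant (zero-variance) input: z-normalization refuses it; the RLS gain
  solve falls back to a ridge-regularized inverse with a warning.
- Non-positive intensities are rejected with channel and sample named.
- Innovation-variance floor: the recursive update keeps σ²_U > 0 whenever
  it starts positive; non-positive variances (possible only through
  corrupted state) are flagged as missing measures, not silently clipped.
- Pole matching in recovery tests pairs estimated and true conjugate pairs
  by sorted frequency.
- All randomness flows from integer seeds through `numpy` Generators;
  identical seeds give bit-identical outputs at every stage.

## Problem sizes

Test and acceptance runs use: 200 random AR(4) models for the spectral
identities; 100 seeds × 1250 effective samples for OLS recovery; 100 seeds
× 2000 samples for RLS tracking; 10 seeds × 2000 samples for the
information-measure closed forms; and one 6-subject, 16-channel, 5-minute
cohort for the end-to-end run.  The full suite runs in well under a minute
of compute for the numerics plus ~20 s for the cohort.

## Known limitations

- The exact design of the zero-phase high-pass filter used in the original
  acquisition chain is not recoverable; only its 0.018 Hz cutoff is
  honored (2nd-order Butterworth here).
- The frozen-model (Lyapunov) information-storage route is insensitive to
  fast variance modulation at this protocol's phase lengths; see the
  process-variance discussion above.
- LF band power is estimated from 17–35 s windows of a 0.05 Hz rhythm
  (1–2 cycles): per-subject LF power values are near the estimability
  limit and their between-condition comparison is weak by construction.
- Apnea-phase HF peak frequencies inherit a small upward bias from
  breath-phase bleed across window margins (the process correlation time
  exceeds the p+1-sample margin) and from the in-band noise floor; the
  paired within-subject difference, which the statistics use, is
  direction-correct throughout.
- SNIRF I/O is not provided; recordings are exchanged as wide CSV plus a
  JSON sidecar.
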