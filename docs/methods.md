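# Methods

## The design being modelled

A within-subject climate-comparison experiment: every participant
completes five ~60-second time-perception sessions under each of two
conditions — an air conditioner producing airflow (AC) and a radiant
system producing none (RS) — in one season (cooling or heating), while
10-channel EEG, environmental series, button-press logs and thermograms
are collected. The analysis asks whether airflow changes (i) band-wise EEG
amplitudes relative to the first session, (ii) perceived duration of the
counting task, and (iii) skin temperature, and relates EEG change to the
PMV/PPD comfort scales.

## Spectral analysis

Recordings are re-referenced to the average of the earlobe channels A1 and
A2 (the output is flagged so the reference cannot be applied twice). Each
session span is cut into `n_bins = 20` contiguous blocks; when the span is
not divisible the remainder samples go one each to the earliest blocks.
Each block is DFT-transformed with no taper (rectangular window). The
amplitude convention is single-sided, `A_k = 2|X_k|/N` for `0 < k < N/2`
with DC and Nyquist excluded, so an on-bin sinusoid of amplitude `A`
contributes exactly `A` at its bin; a band's value is the unweighted mean
of `A_k` over bins whose centre frequency `k·fs/N` falls in the half-open
interval `[f_lo, f_hi)`. Alternative conventions (e.g. raw `|X_k|`) change
only the absolute µV scale, never a within-study contrast, and would be a
one-line change.

Band-mean amplitudes per (participant, condition, session, channel, band)
are averaged over the 20 bins, then differenced against session 1
("change from baseline", session − session1; the opposite orientation is
available behind a flag). Session-1 rows are identically zero by
construction.

Because a band's value is the mean over its bins, a carrier of amplitude
`a` contributes `a / #bins(band, N)` to the band mean; at 3-s blocks the
gamma band has 75 bins, at 0.5-s blocks 13. Off-bin carriers leak across
neighbouring bins; the band mean then under-represents the carrier
slightly and differently for different block lengths. This matters for
absolute recovery tests (which therefore use jitter-free session lengths)
but not for condition contrasts, which compare like with like.

## Thermal comfort

PMV follows the Fanger steady-state heat balance: metabolic rate
`M = met·58.15 W/m²` (sedentary default 1.0 met), clothing insulation
`I_cl = clo·0.155 m²K/W` (default 0.7 clo), water-vapour pressure from an
Antoine-type fit, clothing factor `f_cl`, and a clothing-surface
temperature solved by damped fixed-point iteration to |Δt_cl| < 1e−5 °C
(≤150 iterations; non-convergence raises, carrying the last iterate). The
thermal load L collects skin-diffusion, sweat, latent and dry respiratory,
radiative and convective losses; `PMV = (0.303·e^(−0.036M) + 0.028)·L` and
`PPD = 100 − 95·exp[−(0.03353·PMV⁴ + 0.2179·PMV²)]` (even in PMV, floor
5 %). Mean radiant temperature defaults to air temperature, standard
practice for single-sensor meters, overridable per input. A documented
validity envelope (10–30 °C, v < 1.5 m/s, ≤1.5 clo, 0.8–4 met) triggers a
warning, not a refusal. The test suite checks the implementation against
an independently written oracle that solves the same published balance
with a bracketing root finder.

Environmental series are summarised by median and IQR with
linearly-interpolated quartiles (other software may use different quartile
rules; differences are at the last digit for the series lengths used
here).

## Screening

Stage one: leave-one-out Mahalanobis distances `d_i` (mean and unbiased
covariance estimated without row i, computed in closed form via a
Sherman–Morrison downdate; an explicit leave-one-out loop serves as the
test oracle). Under multivariate normality
`d_i² ~ p(m²−1)/(m(m−p)) · F_{p,m−p}` with `m = n − 1`, and the α = 0.05
upper control limit (UCL) is the square root of that distribution's 0.95
quantile — about 4.1 at n = 12, p = 3, i.e. on the distance (not squared
distance) scale. Rows above the UCL are *candidates* only: by design the
statistical stage cannot by itself justify removal.

Stage two applies hard rules — per-session delta-band mean amplitude above
the seasonal limit (6 µV cooling, 60 µV heating), differential task
duration beyond the seasonal bound (< −15 s cooling, > +95 s heating,
free-counting sessions only) — and pass-through experimenter-error flags.
With a candidate stage present, exclusion = candidate ∧ rule-violation, or
an experimenter error; rules alone apply when no candidate stage was run.
The default feature set for the multivariate stage is the per-band session
means (p = 5 with all bands); which columns enter is configurable because
any particular choice is a modelling decision, not a mathematical one.

## Inference

* **Rank-sum**: midranks, tie-corrected variance, no continuity
  correction, Z-valued.
* **One-sample signed-rank**: reported as the centred rank sum
  `S = Σ sign·rank` (range ±n(n+1)/2, e.g. ±45 at n = 9); exact p by
  enumerating all 2ⁿ sign patterns for n ≤ 12, the normal approximation
  `Z = S/√Σrank²` beyond.
* **ANOVA**: fixed-effects `response ~ condition + session +
  condition×session + participant` on a complete crossed design, every F
  against the residual mean square. With a conditions, b sessions, n
  participants the error df is `abn − 1 − (a−1) − (b−1) − (a−1)(b−1) −
  (n−1)`: (1, 72) at 2×5×9, (1, 70) at 2×4×11, (1, 56) at 2×4×9. The
  implementation is the balanced-design sum-of-squares decomposition,
  verified in tests against statsmodels OLS. EEG differentials keep
  session 1 (b = 5, its rows all zero); task-duration differentials drop
  it (b = 4) because the guided baseline is deterministic.
* **Two-point slope**: per participant-session,
  `(Y_AC − Y_RS)/(X_AC − X_RS)` with Y a channel's differential band
  amplitude and X the session's PMV or PPD under each condition; undefined
  (equal-X) rows are omitted with a logged reason; the per-session test is
  a one-sided one-sample signed-rank against zero. **This index is a
  reconstruction** — its original definition is unpublished — and is
  labelled as such in the output metadata.
* **Paired/pooled t**: paired df n−1 by default; the pooled two-sample
  variant (df 2n−2) is provided because both conventions appear for
  within-subject skin-temperature comparisons. All-zero differences give
  t = 0; constant non-zero differences are a degenerate-variance error.
* No multiple-testing correction is applied anywhere; reports annotate how
  many tests were run so readers can correct as they see fit.

### A calibration caveat on baseline-differenced ANOVA

Differencing against a *noisy* baseline correlates the per-cell errors:
`d_s = A_s − A_1` shares `−A_1` across all sessions of a
participant-condition, and the session-1 rows are identically zero. The
residual mean square then underestimates the variance of the condition
contrast, and the F test for the condition main effect runs
anti-conservative: the suite's own 200-cohort null simulation measures a
rejection rate well above the nominal 0.05 (the corresponding calibration
test documents and fails on this). This is a structural property of the
"difference-from-first-session, residual-error F" recipe itself, not of
any parameter choice; it does not affect the task-duration ANOVA, whose
baseline is noise-free. Users wanting calibrated EEG inference should
model the correlation (e.g. a participant×condition error stratum) rather
than rely on the residual F; the package keeps the recipe as specified for
comparability and documents the caveat here.

## Thermography

Pixels are clustered by temperature alone (1-D k-means, k = 2;
scikit-learn's Lloyd iterations with deterministic initialisation at the
10th/90th percentiles), warmer cluster = skin. The segmentation is
order-invariant and equivariant to additive shifts. Frames outside
0–50 °C warn; uniform frames raise. Per-participant mean skin temperatures
feed the first-vs-last t test. Whether background removal happens per
frame (default) or per pooled condition is a flag.

## The synthetic generator

What it emulates, per participant × condition:

* **EEG**: per scalp channel, `x(t) = common pink noise (1/f^β, β = 1, SD
  2 µV) + Σ_bands a·sin(2πf_c t + φ)` with one carrier per band (delta 2,
  theta 6, alpha 10, beta 20, gamma 40 Hz — all on-bin for 0.5-s and 3-s
  blocks) and per-channel random phases. The amplitude is
  `a = RS-mean · J_participant + AC-offset + ε_cell`, where `J` is a
  mean-one lognormal participant factor (σ = 0.10) shared across
  conditions — so the planted AC−RS carrier gap equals the configured
  offset exactly — and `ε_cell ~ N(0, 0.10 µV)` is per-session noise that
  keeps ANOVA error terms non-degenerate. A1/A2 carry 0.2× the common
  noise, making re-referencing consequential without touching planted
  amplitudes. Defaults: RS means delta/theta/alpha/beta/gamma =
  3/2/4/1.5/0.8 µV with AC offsets 0/0/0/0.4/0.3 µV (airflow raises beta
  and gamma), chosen as plausible resting scalp values that keep a clean
  cohort below the 6 µV cooling delta limit.
* **Sessions**: the tone-guided first session has exactly the configured
  length (default 60 s); later sessions are jittered uniformly ±10 %.
* **Task logs**: six presses per session; session 1 exactly every 10 s;
  later intervals `N(10 + ttl_effect/6 under RS, 1.0 s)` (default
  ttl_effect 6 s — time runs "slow" without airflow), clipped at 0.25 s.
* **Environment**: temperature and humidity normal around the per-season,
  per-condition medians with σ = IQR/1.349; velocity lognormal
  (median/IQR-parameterised) so near-zero medians with wide IQRs remain
  non-negative. Defaults reproduce the cooling targets (AC 25 °C/64 %/1.1
  m/s; RS 24 °C/63 %/0.0033 m/s) and heating targets (AC 26 °C/24 %/0.61
  m/s; RS 26 °C/24 %/0.071 m/s) asymptotically.
* **Thermograms**: 40×30 frames, a centred skin ellipse (~33 % of pixels)
  over a 25 °C background, pixel noise 0.3 °C, plus a per-participant,
  per-time-point skin offset (0.3 °C) so paired comparisons are not
  noise-free. Skin means: cooling AC 33→31.5 °C (airflow cools), heating
  AC 32→33.5 °C, RS unchanged in both.
* **Planted anomalies**: the outlier plan can raise a participant's delta
  RS mean (EEG rule violation), shift their free-session durations (task
  rule violation), or flag an experimenter error.

Seeding derives one `SeedSequence` per (participant, condition, stream)
from the master seed, so cohorts are bit-reproducible and adding
participants never changes existing ones.

What it does **not** emulate: biophysical EEG (no dipoles, no 10–20
geometry, no blinks/EMG), narrowband oscillations as filtered noise (a
single carrier per band is the default because it permits exact amplitude
accounting; nothing in the analysis depends on the carrier model),
instrument drift, or spatial structure in thermogram noise. Passing tests
therefore certify the *analysis machinery* — amplitude accounting,
screening calibration, df bookkeeping, directionality — on data whose
generating truth is known, not the physiological claims themselves.

## Problem sizes and numerical choices

Simulation-based tests use 10-s sessions (20 bins of 500 samples; gamma
then spans 13 bins) and cohorts of 3–12 participants; power and type-I
rates use 200 replicate cohorts. Tolerances: DFT versus the O(N²) oracle
at 1e−9 relative; PMV versus its oracle at 0.01; k-means init is
deterministic so segmentation tolerances are exact up to float round-off.
Ties in rank tests use midranks throughout; the ASHRAE label rounds
half-away-from-zero; quartiles interpolate linearly.

## Known limitations

* The EEG baseline-differenced ANOVA calibration caveat above.
* Printed control limits of any particular historical analysis depend on
  the (unreported) dimensionality of the screened feature set; the package
  therefore validates the UCL *formula* (flag rate ≈ α on clean data), not
  specific limit values.
* The two-point slope is a reconstruction; its orientation and pairing
  unit are options.
* PMV here is the standard heat-balance model; field meters may apply
  device-specific corrections (radiant sensing, humidity conversion), so
  absolute PMV medians from simulated environments need not match any
  particular instrument's readings.
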