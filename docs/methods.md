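# Methods

This note documents the models, estimators, defaults and numerical choices
behind `ojipsuite`, and what the synthetic-data tests do and do not
demonstrate about real instrument data.

## Signals and units

All traces are stored as (time, value) pairs with time in microseconds
internally; file dialects declare their own unit (µs/ms/s). Microseconds are
the finest grain any analysis needs, since F_o is defined at 20 µs. PF and
DF values are non-negative instrument counts; MR values are arbitrary
reflection units (sign-free), normalized before analysis. Only delimited
text is parsed — no proprietary instrument export format is documented well
enough to support. Within one file, rows sharing a (channel, group,
replicate) label are split into separate sweeps wherever the time column
decreases; an exact duplicate time is a format error.

## JIP test

Markers are read by piecewise-linear interpolation of intensity against
log10(time) — the scale on which OJIP transients are acquired and plotted —
at t = 20 µs (F_o), 300 µs (F_K), 2 ms (F_J) and 30 ms (F_I); the J-step
time is configurable (some instruments label it at 3 ms). F_m is the trace
maximum, earliest sample on ties, with an optional 5-point median
pre-smoothing (off by default; noise-free tests need the exact maximum,
noisy instrument data may prefer it on).

The initial slope uses the standard four-point approximation
M_o = 4(F_K − F_o)/F_v per ms rather than a fitted tangent: it is
deterministic, needs no bandwidth choice, and is the convention the per-RC
fluxes assume. The flux equations are the classical energy-flux
(so-called JIP-test) set; two approximations deserve note:

- ABS/CS_M is approximated by F_m (and ABS/CS_o by F_o for RC/CS_o). Per-CS
  outputs therefore carry the units of the input trace; the ~10⁴ magnitudes
  of published RC/CS values correspond to instrument-count F_m scales.
- γ_RC, the probability that a chlorophyll functions as RC, is computed as
  1/(1 + ABS/RC); in the V_J → 0 limit ABS/RC is undefined and γ_RC is
  reported as NaN while the remaining yields take their limit values.

Degenerate transients (F_v ≤ 0, V_J ∈ {0, 1} where a quantity divides by
zero) raise typed errors; in batch tables these become per-replicate failure
records rather than dropped rows.

## MR 820 nm slopes

The analysis curve is MR/MR_o with MR_o interpolated at 0.7 ms (the first
reliable sample of the modulated channel). V_PSI and V_PSII−PSI are the
extrema of the first derivative on the 0.7–20 ms and 20–300 ms windows
(window bounds configurable). The derivative is estimated by resampling each
window to a uniform linear-ms grid (default 1000 points) and applying a
Savitzky–Golay filter (window 7, order 2, `deriv=1`); negative estimates in
the "increase" window clamp to zero for noise robustness, and sub-epsilon
filter residue on flat curves is reported as exactly 0. Slopes are per ms by
default (`per_s` available); published slope magnitudes cannot be
unit-checked, so the only identity asserted against external values is the
unit-free additivity V_PSII = V_PSI + V_PSII−PSI, which holds exactly by
construction. t_min is the argmin of the lightly smoothed curve on a dense
uniform grid over the full window.

Against the closed-form valley model (below) the estimator is within 2% of
the analytic derivative extrema at 10³ samples and 0.5% at 10⁴.

## DF features and decay

I₁ and I₂ are the highest local maxima (scipy `find_peaks` on a lightly
smoothed curve, prominence floor 1% of range) in the 2–20 ms and 20–300 ms
windows; the late window starts at 20 ms so a second maximum anywhere from
tens of ms to the end of the record is accepted. D₂ is the global minimum
between the two maxima, or of the whole curve when one is missing; missing
features are flagged, not raised. Decay at I₁ is fitted as a sum of one or
two exponentials by least squares with a fixed deterministic initialization
(log-linear regression on the tail for the slow component, peeling of the
residual head for the fast one); components are reported ordered by τ. The
module takes already-constructed induction/decay curves as input; it does
not reconstruct the induction curve from raw light/dark interval records.

## Pigments

Lichtenthaler linear combinations in two solvent dialects (80% acetone and
95% ethanol); the dialect only rescales coefficients and defaults to
acetone80. Concentrations convert to mg/g fresh weight by
× volume / (1000 × mass). Negative solved concentrations (possible for noisy
near-zero extracts) clamp to zero with a logged warning. Chlorophyll a/b
ratios are computed per replicate and then averaged — the mean of ratios, not
the ratio of means, which is what published per-replicate tables report.

## Group statistics

Per-group summaries are mean ± SE with SE = sd/√n. Comparison is one-way
ANOVA plus Fisher's LSD at α = 0.05: significance requires both the omnibus
p < α and |Δmean| > t₍α/2,df_w₎·√(MSW(1/nᵢ+1/nⱼ)). For two groups F = t²
of the pooled t test and the p-values are identical. No multiple-testing
correction is applied across parameters by default (matching common practice
in the physiology tables this mirrors); Benjamini–Hochberg is available as
an option. A summary-statistics entry point accepts published (n, mean, SE)
per group, with a Welch variant. Zero within-group variance with unequal
means reports p = 1e-300 (a floor, not NaN) and infinite F.

## Synthetic generator

The generator is descriptive, not mechanistic — it reproduces the features
the analyzers extract without asserting any photochemistry:

- **PF:** relative variable fluorescence V(t) is a monotone
  shape-preserving (PCHIP) interpolant through the anchor points
  (20 µs, 0), (300 µs, v_K), (2 ms, v_J), (30 ms, v_I), (300 ms, 1) on
  log10-time, rescaled by F = F_o + V·(F_m − F_o). Anchor times are inserted
  into the log-spaced sampling grid, so noise-free transients reproduce the
  anchors *exactly* and analyzer recovery can be asserted to 1e-9.
  v_K defaults to 0.25·v_J so M_o is positive and well-defined.
- **MR:** MR/MR_o(t) = 1 − A(1 − e^(−t/a))e^(−t/b) (t in ms), times an
  arbitrary gain so normalization is exercised downstream. The minimum lies
  at t_min = a·ln((a+b)/a) — a closed form used as the slope-analyzer
  oracle. Defaults (A=0.05, a=8 ms, b=70 ms) put t_min ≈ 18.2 ms, inside
  the empirically observed 15–20 ms window.
- **DF:** induction is two log-normal bumps (width 0.25 log10 units) over a
  fast-decaying baseline; bump centers are adjusted by a short fixed-point
  iteration so the *composite* curve peaks exactly at the nominal times
  (each bump's tail would otherwise shift the other's maximum by a few
  tenths of a percent). Decay is a sum of two exponentials.
- **Absorbances** are obtained by inverting the pigment equations from
  ground-truth concentrations, giving machine-precision forward–inverse
  round trips.
- Noise is i.i.d. Gaussian per sample (no autocorrelation model), seeded per
  trace as master_seed·1000003 + CRC32(group/replicate/channel) mod 2³¹.

The default study design is two groups ("WT", "MT") × 3 replicates. WT PF
anchors encode F_v/F_m = 0.82, ψ_o = 0.70, φ_Ro = 0.20 at F_m = 26000
counts; MT encodes 0.73/0.43/0.12 at F_m = 24000 with a larger K-step
fraction, so the per-cross-section quantities behave like the observed
mutant (RC/CS_M roughly halved, DI₀/CS_M higher) at similar ABS/CS_M. PF
noise is 1% of F_m. MR noise is 1e-4 on the normalized curve — the 820 nm
channel is heavily modulation-averaged, and this level gives slope estimates
with the few-percent replicate spread reported for such measurements.

**What passing tests show:** the analyzers are exact on clean signals,
well-calibrated statistically, and directionally reliable at the modeled
noise. **What they do not show:** robustness to baseline drift, correlated
detector noise, light-source artifacts, or transients whose shape departs
from a monotone O–K–J–I–P rise (e.g. K-band stress dips), none of which the
generator emulates.

## Problem sizes

Defaults keep everything interactive on one core: 600-point log grids per
trace, 1000-point window resampling for derivatives, n = 3 replicates per
group. The stochastic checks in the test suite use 100-seed direction/power
loops and a 2000-replicate null calibration of the type-I error; the whole
suite runs in well under a minute.

## Known limitations

- Normalized difference kinetics (L/K bands), performance indices (PI_abs,
  PI_total) and P700/plastocyanin deconvolution of the MR signal are out of
  scope.
- Published per-CS magnitudes are only reproducible up to the instrument's
  count scale; the package asserts identities and directions, not absolute
  per-CS values.
- Decay fitting supports at most two exponential components.
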