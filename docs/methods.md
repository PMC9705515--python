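# Methods

## Signal model and T1 estimation

MOLLI samples the post-inversion longitudinal recovery under repeated
balanced-SSFP readouts, so the measured recovery is governed by an apparent
time constant T1\* rather than the true T1. `relaxometry` fits the standard
three-parameter model

    s(t) = a − b·exp(−t/T1*)

to polarity-restored samples by unweighted nonlinear least squares
(Levenberg–Marquardt via `scipy.optimize.least_squares`) and applies the
Look-Locker correction T1 = T1\*·(b/a − 1). The model is written with the
conventional negative exponent; source material sometimes prints the
exponent without the sign, which is treated as a typographical variant of
the same model. Signals are assumed polarity-restored: magnitude-image
polarity recovery is out of scope, as is pixel-wise map generation.

Initialisation is a = max(s), b = max(s) − min(s), T1\* = median(t), which
is robust for IR curves that cross the null point; convergence is a
relative parameter/objective change below 1e−8 or 1500 function
evaluations. A fit that converges to T1\* ≤ 0, a ≤ 0 or a non-positive
Look-Locker T1 (b ≤ a) is reported as a failure carrying the best iterate —
values are never clamped, because a clamped T1 would silently contaminate
downstream statistics. The model is linear in (a, b) given T1\*, which is
what the test suite's independent grid-search oracle exploits (1 ms grid
over T1\*, exact linear solve per grid point).

## Phantom calibration

A calibration phantom provides, per tube: the manufacturer ground-truth T1
(T1_GT), a gold-standard IR spin-echo measurement (T1_GS), and MOLLI
measurements (T1_ML) at several simulated RR intervals. Pairing schemes:

| scheme | source | target | interpretation |
|---|---|---|---|
| GC | T1_GS | T1_GT | corrects the spin-echo reference itself |
| MC | T1_ML | T1_GT | corrects MOLLI against absolute truth |
| IC | T1_ML | T1_GS | corrects MOLLI against the site reference |

The correction function is a univariate OLS polynomial (degree 1–3) of
target on source — the correction equations contain only powers of the
uncorrected T1, so no other covariate exists. The fit solves the
least-squares Vandermonde system with `numpy.linalg.lstsq` (numerically
equivalent to the normal equations, which the tests verify to 1e−8
relative); R² = 1 − SS_res/SS_tot is stored with the coefficients. At
least degree + 1 distinct source values are required; duplicate-only
sources are rejected as rank-deficient.

A fitted function with R² > 0.99 over strictly increasing pairs is checked
for strict monotonicity inside the calibration span (256-point grid); a
violation emits a warning rather than an error, since quadratics fitted to
saturating data can place their vertex inside the span while still being
usable over a narrower measurement range. The packaged reference
equations have vertices far above 4500 ms and are strictly increasing over
the physiologic window.

MOLLI-based schemes come in **static** (phantom acquisition at RRI 900 ms,
an error if that acquisition is missing) and **adaptive** (acquisition
nearest the subject's RRI, equidistant ties resolved toward the smaller
RRI) variants. GC does not involve MOLLI and therefore has no adaptive
variant.

**Method selection.** Each candidate scheme × degree × RRI-mode corrects
the cohort's native segment values; values are averaged per subject over
the region; the pooled CoV (sample SD over mean, all institutions
concatenated) is the selection criterion. Pooled — rather than CoV of
institution means — is used because the reference study's printed CoV
values are exactly recoverable as pooled-SD/pooled-mean from its
per-institution summaries. Candidates within 1e−9 relative of the minimum
are treated as tied and resolved toward the simplest function: lower
degree, then MC before GC before IC, then static before adaptive.

## Correction application and ECV

Corrections are applied per segment record with the map-type-matched
(native vs post-contrast) institution function; artifact-flagged records
pass through untouched. A corrected value ≤ 0 raises an explicit
out-of-calibration-range error. Blood-pool T1 is corrected with the same
institution functions by default (`correct_blood=True`) so that all T1
values entering ECV share the standardized scale; the switch exists because
forming ECV from uncorrected blood values is an equally defensible
convention and the choice is not dictated by the correction method itself.

ECV = (1 − Hct)·ΔR1_myo/ΔR1_blood is computed at subject level from
region-aggregated myocardial T1 (the reporting granularity of normal-range
studies); per-segment ECV is available through the same equation. ECV is
carried as a fraction internally and rendered as percent only in reports,
which round to 0.1 ms / 0.1 percentage point.

## Cohort statistics

Per-subject regional means use non-artifact segments only; a subject with
no usable segment in a region yields a missing aggregate and is dropped
from that region's statistics. Mid septum defaults to AHA segments 8–9
(mid anteroseptal + mid inferoseptal), configurable because conventions
for "septal" segments vary.

Outlier exclusion applies Tukey fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR] to the
per-subject uncorrected global native T1 within each institution and drops
flagged subjects entirely (both phases, both quantities), mirroring
map-level quality exclusion; quartiles use linear interpolation between
order statistics (the "type 7" convention — the rule is configurable via
the k multiplier, and the tests pin it against a brute-force oracle).
Institutions with fewer than 4 subjects skip the rule, as quartiles are
unstable there.

Sample (n−1) SD is used throughout; pooled mean/SD combine per-group
(n, mean, SD) through the exact within/between sum-of-squares
decomposition, so summary-level pooling equals direct computation on
concatenated raw values, and the reference study's pooled row is exactly
reconstructible from its per-institution rows. CoV is reported as percent.
Institutions with a single subject are reported as mean-only and excluded
from pooled variance.

## Synthetic data generator

The generator models a scanner as a strictly monotone bias function
true → measured plus Gaussian measurement noise and an additive RR-interval
offset table (linearly interpolated at the subject's RRI). Biases can be
given as polynomials, or as the functional inverse of a polynomial
correction relation (`kind="inverse_poly"`, root-solved numerically). The
inverse form exists because the exact inverse of a quadratic is not a
quadratic: with a literal quadratic bias of realistic curvature
(~1.4e−4 ms⁻¹) the best degree-2 correction leaves several-ms residuals
over a 250–2200 ms tube span, so exact noiseless round-trips are only
possible when the *correction relation* is polynomial. Default institution
biases invert the packaged reference equations, making the ideal MC2
correction exactly quadratic and placing uncorrected cohort means near the
reference study's per-institution values.

Cohort defaults encode the reference study conditions: 28/15/26 subjects
for institutions A/B/C; true native T1 ~ N(1290, 32) ms; ECV ~ N(0.25,
0.027); hematocrit ~ N(0.423, 0.037); blood T1 ~ N(1900, 70) pre and
N(450, 30) ms post; RRI ~ N(918.8, 144.1) ms native and N(922.3, 129.7) ms
post; 6 % per-segment artifact rate (≈ the study's 67 artifact segments in
69 × 16). Intra-subject segment spread (25 ms native, 10 ms post) is drawn
zero-mean so the segment average equals the subject-level truth exactly;
per-segment in-vivo measurement noise defaults to 20 ms and phantom tube
noise to 5 ms. The true post-contrast myocardial T1 is derived by
inverting the ECV equation from the drawn ECV, hematocrit and blood values
(draws are rounded to the emitted CSV precision before inversion), so ECV
recomputed from noise-free tables reproduces the drawn truth to numerical
precision. Identical spec and seed give byte-identical CSV output.

What the generator does **not** emulate: image-domain effects (banding,
off-resonance, partial volume), heart-rate-dependent MOLLI physics beyond
an additive offset, T2 dependence, temperature drift of phantom tubes, or
inter-segment spatial correlation. Passing tests therefore demonstrate
correctness of the calibration/statistics machinery and recoverability of
polynomial-relation scanner bias — not that any particular clinical
cohort's bias is polynomial.

## Problem sizes and numerical choices

The test suite and demo run cohorts of 9–72 subjects and 9-tube phantoms,
which keeps the full suite in seconds while leaving every statistical
contrast (bias inflation, CoV reduction, outlier exclusion) well resolved.
The end-to-end recovery test uses 24 subjects × 3 institutions with 5 ms
phantom and 20 ms segment noise; the noiseless variant asserts ≤ 0.1 ms
ground-truth recovery. Polynomial inversion for `inverse_poly` biases uses
Brent root-finding on [1, 4500] ms with 1e−10 absolute tolerance. R² is
clipped to [0, 1] against floating-point round-off. CSV floats are parsed
with round-trip precision so write/read cycles are exact.

## Known limitations

- The packaged reference equations are specific to three 3-T scanner
  installations of one vendor; they are defaults and examples, not
  universal constants.
- Adaptive-RRI correction assumes the phantom RRI grid brackets subject
  RRIs; outside the grid the nearest acquisition is used without
  extrapolation of the offset.
- Whether blood T1 should be corrected before ECV is a convention; both
  behaviors are provided and the default (corrected) is a package choice.
- Correction functions applied far outside their calibration span fail
  loudly rather than extrapolating silently; users calibrating post-contrast
  maps should use a phantom whose tubes cover short T1 values.
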