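# t1calib

Phantom-based calibration and harmonization of myocardial MOLLI T1 maps and
extracellular volume fraction (ECV) across MRI scanners.

## The problem

Native myocardial T1 measured with MOLLI (Modified Look-Locker Inversion
recovery) is a biomarker for diffuse fibrosis and edema, but its absolute
value depends on the scanner: hardware, installation and sequence tuning
shift normal ranges by tens of milliseconds between institutions, which
blocks multi-center studies and cross-site comparison of patient values.
`t1calib` implements a phantom-based correction: each site scans a
standardized multi-tube relaxometry phantom (T1MES-style) whose tube T1
values are known, fits a site-specific polynomial mapping from measured to
true T1, and applies that mapping to every myocardial measurement. The
package is for imaging scientists and CMR researchers who need to harmonize
T1/ECV values across sites or to evaluate harmonization strategies on
synthetic data with known ground truth.

## The method

Pixel signal in MOLLI follows the three-parameter inversion-recovery model
with an apparent relaxation time T1\*:

    s(t) = a − b·exp(−t/T1*),        T1 = T1*·(b/a − 1)   (Look-Locker correction)

For each site, calibration pairs are built from the phantom under three
schemes — GC (gold-standard IR spin-echo T1 → ground truth), MC (MOLLI T1 →
ground truth), IC (MOLLI T1 → gold standard) — using the phantom MOLLI
acquisition at a static 900 ms simulated RR interval, or adaptively at the
RR interval nearest the subject's. A polynomial correction of degree 1–3 is
fitted by ordinary least squares:

    T1c = a·T1u³ + b·T1u² + c·T1u + d

and the scheme × degree × RRI-mode combination with the lowest pooled
coefficient of variation (CoV = SD/mean) of corrected native T1 across the
cohort is selected. ECV is computed from pre/post-contrast T1 of myocardium
and blood and the hematocrit (Hct):

    ECV = (1 − Hct) · (1/T1_myo_post − 1/T1_myo_pre) / (1/T1_blood_post − 1/T1_blood_pre)

Cohorts are summarized per institution and pooled (mean ± SD, CoV), with
subject-level Tukey-fence outlier exclusion and per-segment artifact flags
on the AHA 16-segment model (mid septum = segments 8–9).

The core estimators follow the scikit-learn protocol
(`PolynomialT1Correction`, `InversionRecoveryT1` with `fit`/`predict`), so
they compose with sklearn pipelines and model selection; the module-level
functions are thin wrappers.

## Worked example

Run the end-to-end synthetic demonstration: it simulates three institutions
(28/15/26 subjects, scanner biases that depress native T1 toward
~1199/1218/1233 ms as in the reference three-site study), calibrates the
full correction-method grid from matching synthetic phantom scans, selects
the best method by CoV, and reports before/after statistics:

```bash
t1calib demo --seed 7
```

prints (abridged):

```
Selected method: MC2S

### Native T1 (ms) — global

| group | before | after | CoV before (%) | CoV after (%) |
|---|---|---|---|---|
| A | 1215.0 ± 37.0 (n=28) | 1299.4 ± 35.7 (n=28) | 3.0 | 2.7 |
| B | 1215.0 ± 36.9 (n=15) | 1293.3 ± 35.3 (n=15) | 3.0 | 2.7 |
| C | 1236.9 ± 31.7 (n=25) | 1294.0 ± 29.1 (n=25) | 2.6 | 2.3 |
| pooled | 1223.0 ± 36.2 (n=68) | 1296.1 ± 33.0 (n=68) | 3.0 | 2.5 |

Pooled native-T1 CoV (global): 2.66% -> 2.24%
Pooled native-T1 CoV (mid_septum): 2.96% -> 2.54%
```

The MOLLI-based second-degree static-RRI correction (MC2S) wins; corrected
institution means converge near the common true mean (~1290 ms) and the
pooled CoV drops — the harmonization effect the method is designed to
produce. One subject was excluded by the Tukey rule (listed in the report).
The same pipeline is available stepwise as `simulate`, `calibrate`,
`correct`, `ecv` and `cohort-stats` subcommands operating on CSV/JSON files.

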