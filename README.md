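# renaldosim

Renal dosimetry for ¹⁷⁷Lu-dotatate peptide receptor radionuclide therapy
(PRRT): a reference hybrid planar/SPECT dosimetry method, a menu of
simplified per-cycle dose estimators, biologically effective dose (BED) under
the linear-quadratic model, and the statistical machinery to compare the
simplifications against the reference — exercised on a synthetic patient
cohort with realistic ¹⁷⁷Lu-dotatate kidney pharmacokinetics.

The package is aimed at medical physicists and method developers who want to
study, under controlled conditions, how much dosimetric accuracy is lost when
the imaging burden of per-cycle kidney dosimetry is reduced — e.g. replacing
four serial whole-body scans plus a SPECT/CT by a single SPECT/CT at 96 h.

## The model in brief

For each kidney and treatment cycle the time–dose-rate curve is

```
R(t) = line through (t₁, R₁) and (t₂, R₂)      0 ≤ t < t₂   (t₁ ≈ 1 h, t₂ ≈ 24 h)
R(t) = R₂ · exp(−λ (t − t₂))                    t ≥ t₂
```

with the mono-exponential tail fitted by weighted least squares to the last
three time points and the absorbed dose D = ∫R dt in closed form.  The
reference method P obtains the curve shape from serial planar imaging and its
absolute scale from one quantitative SPECT/CT (hybrid rescaling
R(t) = A_P(t)/A_P(t_S)·R(t_S)).  Simplified estimators include
administered-activity scaling (D_n = D₁·A_n/A₁), dose-rate-ratio scaling,
a fixed population half-time (D = R(t_S)/λ_ref·e^{λ_ref t_S}), and the
single-time-point approximation

```
D ≈ 2 t_ref / ln 2 · R(t_ref),    t_ref = 96 h,
```

whose fractional error for a mono-exponential washout is exactly
E₁(f) = 2f·2^(−f) − 1 with f = t_ref/T½ (zero at f = 1 and f = 2).

BED per cycle is computed from the fitted dose-rate curve via the
Lea–Catcheside dose-protraction integral with α/β = 2.6 Gy and a repair
half-time of 2.8 h; for a mono-exponential curve it reduces to
BED = D·(1 + G·D/(α/β)) with G = λ/(λ+μ).  Method agreement is summarised by
Bland–Altman limits of agreement whose SD comes from one-way random-effects
ANOVA (patient as factor), and cumulative doses carry a 10 % (1 SD) per-cycle
uncertainty propagated in quadrature.

## Worked example

Simulate a dosimetry-guided virtual trial of 20 patients, run the reference
method P plus two simplified methods, and compare them:

```
$ renaldosim simulate -n 20 --seed 42 --out-dir demo
simulated 20 patients, 109 cycles -> demo
$ renaldosim dosimetry --cohort demo/cohort.csv --methods P,E,G --out-dir demo
wrote 327 dose estimates -> demo
$ renaldosim compare --estimates demo/estimates.csv --out-dir demo
compared ['E', 'G'] against P -> demo
$ renaldosim sweep --cohort demo/cohort.csv --out-dir demo
sweep over 31 imaging times; RMSD minimal at 96 h -> demo
```

`demo/comparison.csv` then holds the per-cycle Bland–Altman summary (percent
of the mean dose of the two methods):

```
method_id  mean_diff  sd_total  loa_low  loa_high  n_patients  n_obs
        E        0.1       7.8    -15.4      15.6          20    109
        G        1.1       5.4     -9.7      11.9          20    109
```

i.e. one SPECT/CT at 96 h per cycle (method G) agrees with the full hybrid
protocol to 1 ± 11 % per cycle, and `demo/consistency_counts.csv` shows its
cumulative dose falling inside the reference ±2 SD interval for 20 of 20
patients.  `demo/trial.csv` records how the BED targets steer each patient's
number of cycles (here 5–11 cycles, cumulative renal BED ≈ 25–40 Gy
depending on risk group):

```
patient_id  n_cycles  cum_bed_gy  target_bed_gy
     pt001        11        39.4           40.0
     pt004         5        25.2           27.0
```

`demo/sweep.png` plots the single-time-point error against the imaging time:
the theoretical error E₁, the cohort mean/SD of the patient-based error E₂,
and its RMSD, which bottoms out near 96 h.

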