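# Methods

## The problem

Circulating miRNAs are measured as qPCR cycle thresholds (C_T): the cycle
at which amplification fluorescence crosses a fixed threshold, inversely
and logarithmically related to the starting quantity. A biomarker study of
this kind has two phases: a broad screen (hundreds of probes, one
measurement per sample, few samples) to shortlist candidates, and a
targeted validation (few miRNAs, triplicate wells, larger cohort) to
confirm them and assess their diagnostic value. circmir implements both
phases plus the simulator that makes them testable.

## Synthetic cohorts

`CohortSpec` parameterises a case/control cohort on the C_T scale. A
well's true C_T decomposes as

    probe baseline                 ~ Normal(baseline_ct_mean, baseline_ct_sd)
    + per-sample technical offset  ~ Normal(0, sample_offset_sd)   (common to all probes)
    + biological variation         ~ Normal(0, biological_sd)      (per sample x probe)
    + planted case shift             delta_ct_shift on planted probes in cases
    + replicate noise              ~ Normal(0, replicate_sd)       (per well)

Defaults (cycles): baseline 28 ± 3 across probes, sample offset SD 0.5,
biological SD 0.8, replicate SD 0.12, planted shift +2.0. Positive shift
means later amplification, i.e. *lower* expression in cases, matching the
reduced circulating expression this class of study reports. Non-detection
is a logistic function of true C_T centred at `dropout_ct50` (slope 1 per
cycle) with hard censoring at 40 cycles; non-detected wells carry the
literal token `Undetermined`. One row is emitted per well either way, so a
screen of 20 samples × 381 probes always has 7,620 rows.

Two defaults deserve justification:

* **replicate_sd = 0.12.** The validation QC gate rejects triplicates with
  SD > 0.28 cycles; an assay in routine use therefore has per-well noise
  well below that (sample SD of 3 draws at σ = 0.12 exceeds 0.28 about 1%
  of the time). Larger values would make most wells fail QC, which models a
  broken assay, not a study.
* **biological_sd = 0.8.** Between-subject variation is what limits
  biomarker performance in practice (≈ 1.7-fold geometric SD per miRNA).
  It is shared across a sample's replicate wells and independent across
  miRNAs; the reference miRNA (miR-16) is held biologically stable — that
  stability is the rationale for using it as the endogenous control.

Covariates copy the structure of a validation cohort of 44 cases and 46
controls: case age Normal(59.86, 13.45), control age Normal(44.21, 20.61),
both truncated to [18, 100]; grade/nodal/stage frequencies and per-variable
missingness rates (e.g. invasive size missing in 22/44) are drawn at the
observed proportions; controls carry no tumour covariates. Tissue cohorts
reuse the generator with tumour/TAN pairs sharing a subject offset.

Triplicate plates add an additive per-plate run shift (Normal(0, plate_sd),
default 0.15) and place one inter-assay control (IAC) sample — a single
shared truth — on every plate. Dilution series place point *k* at
`top_ct + k·log(10)/log(1 + E/100)` so the generating efficiency is exactly
recoverable from the regression slope.

All generation is a pure function of (spec, seed); named substreams derived
from the seed keep stages independent of evaluation order.

## RQ-PCR processing

* **Triplicate QC.** Mean/SD over numeric wells per (sample, miRNA, plate).
  SD ≤ 0.28 passes. If SD > 0.28 and dropping exactly one well leaves a
  pair with SD ≤ 0.28, the pair is used and flagged `rescued_pair` (the
  drop minimising the pair SD; the threshold is stated practice, the rescue
  is standard qPCR remediation and never silent). Fewer than two numeric
  wells fail as undetected — one well cannot demonstrate reproducibility,
  which is why `n_used` is 0, 2 or 3, never 1.
* **Inter-plate calibration.** Per plate, subtract (plate IAC mean − grand
  IAC mean), averaged over the IAC miRNAs passing QC on every plate. Plate
  effects are multiplicative on quantity, hence additive on C_T. Correction
  is applied to aggregated means.
* **Efficiency gate.** OLS of C_T on log10 input;
  `E = (10^(−1/slope) − 1) × 100`; accepted in 90–110%. Efficiency is an
  acceptance gate only — quantification always assumes doubling (factor 2),
  not the Pfaffl efficiency correction.
* **ΔCT quantification.** `RQ = 2^(maxCT − CT)` per miRNA (anchored at the
  lowest-expressing QC-passing sample, so min RQ = 1), `NRQ = RQ/RQ(miR-16)`.
  `Undetermined` wells in validation data are missing, never imputed —
  imputing C_T 40 would fabricate expression values. Samples whose
  reference fails QC are dropped with a warning. Note the anchor makes the
  NRQ column scale depend on which sample is lowest-expressing; ratios
  between samples (the ΔΔCT identity `log2(NRQ_i/NRQ_j) = −(ΔCT_i − ΔCT_j)`)
  are anchor-free and hold to numerical precision.

## ANN probe ranking

The screen matrix caps `Undetermined` at C_T 40, drops probes detected in
under 50% of samples of *both* groups (detection in one group alone is
itself a signal), converts to the expression scale 40 − C_T and min-max
scales each probe to [0, 1] (zero-range columns map to 0). The 40-cap is
used only here; it makes "not detected" the lowest expression value, which
is the correct reading for a screen.

Each probe is scored alone by a 1–2–1 network: sigmoid hidden and output
units, online (per-pattern) gradient descent on squared error with learning
rate 0.1 and momentum 0.5, weights initialised Uniform(±0.5), patterns
reshuffled every epoch. After each epoch the validation MSE is recorded;
training stops at 3,000 epochs or after 100 epochs without improvement, and
the best-validation weights are returned. Accuracy (threshold 0.5) and AUC
are computed on the blind test split only. The split is stratified
60/20/20, repeated 50 times (Monte Carlo cross-validation); the defaults
are config-exposed. Ranking is by mean blind accuracy, ties broken by blind
AUC, then validation MSE, then probe id. Per-probe RNG streams are derived
from (seed, crc32(probe_id)), making the ranking reproducible and invariant
to probe column order.

Numerical notes: the training loop is JIT-compiled (numba) with an
identical pure-Python fallback; per-epoch pattern orders are pre-drawn so
both paths consume the generator identically. The defaults are tuned for
monotone single-probe signals; representing a non-monotone rule (an
interval indicator is a difference of two sigmoids) needs a wider
initialisation range and longer patience, both exposed on `TrainConfig`.
Squared error is the default loss; cross-entropy is available.

## Association statistics

Normality is tested by Kolmogorov–Smirnov distance to a normal with
estimated mean/SD, with the null simulated by 10,000 seeded Monte Carlo
draws per sample size (the Lilliefors correction — table-free and exact up
to MC error; null distributions are cached per n). Non-normal positive data
get a log10 recommendation; still-non-normal data get nonparametric tests.
Two-group comparisons use Welch's t when the gate passes (pooling is unsafe
under unequal group sizes), else Mann–Whitney U — exact when both n ≤ 8
without ties, tie- and continuity-corrected normal approximation otherwise.
Factors with ≥ 2 usable levels get one-way ANOVA; continuous covariates get
Pearson (gated) or Spearman. Missing values are dropped pairwise per test;
every result records the transform applied. Raw p < 0.05 is the reported
convention; Benjamini–Hochberg adjustment is available but off by default.

## Panel evaluation

Logistic regression is fitted by IRLS on log10 NRQ (logit linearity is more
plausible on the log scale): convergence when the max coefficient step
< 1e-8 within 100 iterations; constant and collinear predictors dropped
with warnings; complete separation (all fitted probabilities within 0.001
of their labels) flagged, with coefficients reported at the iteration cap.
ROC thresholds sit at the unique score values; AUC is the trapezoid area,
identical to the case/control concordance with ties counting ½ (and to
U/(n₁n₂) on tie-free scores); the operating point maximises Youden's J,
ties preferring sensitivity. Combination search is exhaustive over all
non-empty subsets up to `max_size` (≤ 15 candidates), ranked by AUC, ties
to the smaller panel then lexicographic.

The headline AUC is in-sample — fit and ROC share the samples, the
discovery-stage convention. This is optimistic by construction: under
permuted labels the in-sample AUC of a 3-predictor fit at n = 90 centres
near 0.59, not 0.5. `evaluate_panel(cv_folds=k)` provides stratified k-fold
cross-validated scores whose null is centred at 0.5; the label-permutation
null of the AUC for a fixed score at n = 44/46 has SD ≈ 0.061, putting 95%
of replicates within about ±0.12 of 0.5.

## Packaged experiments and problem sizes

`circmir.experiments` fixes the three study-scale experiments the test
suite and the acceptance script run:

* **recovery** — 100 probes, 5 planted, n = 10 + 10, screen noise chosen so
  total per-observation SD ≈ 1 cycle (biological 0.8, offset 0.5, replicate
  0.33) making the 2-cycle shift a 2-SD separation; 50 MCCV repeats.
* **null calibration** — the same screen with no planted effect, 25 MCCV
  repeats (the chance-level bounds it checks do not depend on the repeat
  count); the winning probe is retrained and scored on a fresh 200-sample
  cohort.
* **panel regime** — 3 planted miRNAs + miR-16 in a 44/46 triplicate
  cohort. The shift of 0.52 cycles comes from inverting
  AUC = Φ(δ/(√2·σ_e)) with per-sample noise σ_e = √(0.8² + 0.12²/3) ≈ 0.80
  for a target single-miRNA AUC of ≈ 0.675; three such independent markers
  combine to a panel AUC of ≈ 0.78–0.81 in expectation.

## What passing tests do and do not show

The generator reproduces the statistical skeleton of a circulating-miRNA
study: planted mean shifts, replicate and plate structure, logistic
dropout, covariate missingness. It does not model hemolysis or RNA-quality
artefacts, probe cross-hybridisation, card-position effects, correlated
miRNA co-regulation, or non-normal biological distributions. Passing the
recovery and panel-regime tests shows the pipeline's machinery is correct
and calibrated on data obeying its own assumptions — not that any
particular real cohort would yield the same shortlist or panel.

## Known limitations

* The ΔCT engine assumes perfect doubling; efficiency enters only as a gate.
* In-sample panel AUC is optimistic (see above); the CV mode is the honest
  estimate.
* The exhaustive panel search is bounded at 15 candidates by design.
* Exact Mann–Whitney is limited to both groups ≤ 8 without ties; beyond
  that the corrected normal approximation is used.
* The 2-hidden-node network with default hyper-parameters can fail to learn
  non-monotone single-probe rules; wider initialisation and longer patience
  recover them.
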