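# Methods note

This document records the analysis model, the parameter choices and their
rationale, the synthetic-cohort generator's realism and limits, and the
numerical decisions that make runs exactly reproducible.

## 1. Problem and model

The pipeline asks whether preoperative scalp EEG carries a signature of
long-term VNS response in pediatric drug-resistant epilepsy, and whether that
signature improves an individual-level responder/nonresponder (R50/NR50)
classification over clinical variables alone. Two complementary markers are
extracted:

- **α-band functional network efficiency.** Phase lag index (PLI)
  connectivity between all channel pairs, sparsity-thresholded into a weighted
  graph, summarized by global and nodal efficiency. The working hypothesis is
  that responders show stronger parieto-occipital α-band phase coupling and
  hence higher efficiency over the posterior ROI.
- **θ-band spectral regularity.** Hilbert–Huang spectral entropy (HHSE) of
  each channel's marginal Hilbert spectrum restricted to the θ band. More
  rhythmic (narrowband) θ activity gives lower entropy; the hypothesis is
  lower central-frontal θ HHSE in responders.

Both markers feed a linear SVM together with the clinical covariates.

## 2. Processing chain and parameters

| Stage | Parameter | Default | Rationale |
|---|---|---|---|
| Recording | channels | 19, 10–20 montage | standard clinical EEG |
| Recording | duration / rate | ≥ 360 s at 500 Hz | ≥ 6 min of resting EEG; 500 Hz typical clinical sampling |
| Re-reference | common average | — | removes reference bias; requires ≥ 2 channels |
| Broadband filter | 1–30 Hz FIR + 50 Hz notch | zero-phase, 1 Hz transitions | EEG band of interest; zero-phase preserves relative phase for PLI |
| Bands | δ 1–4, θ 4–8, α 8–13, low β 13–20, high β 20–29 Hz | — | conventional clinical bands |
| Epoching | 2 s, trailing partial dropped | — | stationarity vs. sample count trade-off |
| Edge trim | 1 s per side | configurable | discards Hilbert/filter boundary transients |
| PLI bootstrap | 20% of epochs × 5 repeats | mean over drawn values | stabilizes the per-pair estimate against outlier epochs |
| Sparsity | 0.20 (sweep 0.1–0.5 available) | round-half-even edge count | equal edge density across subjects; 0.2 keeps graphs connected at 19 nodes while discarding weak noise edges |
| Edge length | 1 / PLI weight | — | stronger coupling = shorter path |
| HHSE binning | 0.5 Hz bins over 1–30 Hz | band-local normalization | θ band = 8 bins → entropy ∈ [0, ln 8 ≈ 2.079] |
| EMD | Cauchy SD stop 0.2, ≤ 10 sifts | mirror extension, 2 extrema | standard sifting criteria; cap bounds runtime |
| SVM | linear kernel, C ∈ 10⁻³…10³ | MinMaxScaler in-pipeline | interpretable weights at n = 65; log grid spans under/over-regularized |
| Nested CV | outer 10 / inner 5, stratified | RFECV optional, per-fold | unbiased outer estimate; selection inside training folds |
| Permutation test | ≥ 100 label permutations | p = (1 + count) / (1 + n) | add-one estimator never returns 0 |

ROIs: α — C3, C4, Cz, T5, T6, P3, P4, Pz, O1, O2 (parieto-occipital);
θ — Fz, Cz, C3, C4 (central-frontal).

The clinical block encodes 7 continuous variables, prior surgery, gender, 3
multi-label seizure-type flags, and drop-first dummies for etiology (reference:
structural), syndrome (reference: unclassified) and MRI finding (reference:
negative) — 20 columns, so the full panel is 31 features.

## 3. Synthetic cohort generator

Each subject's channel signal is a sum of:

- **pink (1/f) background** shaped in the frequency domain, SD 10 µV —
  matches the broadband spectral slope of resting EEG;
- **α rhythm** on the parieto-occipital ROI channels: a common 10 Hz
  oscillator mixed with independent 8–13 Hz narrowband noise in proportion
  √c : √(1−c), where the coupling c is the group parameter (responders 0.5,
  nonresponders 0.2). Fixed per-channel phase lags (0.3 + 0.15k rad) make the
  coupling visible to PLI, which ignores zero-lag synchrony by construction;
- **θ rhythm** on the central-frontal ROI channels: band-limited noise
  centered at 6 Hz whose bandwidth is the group parameter (responders 1.0 Hz,
  nonresponders 2.5 Hz), amplitude 12 µV — narrower bandwidth means more
  regular θ and lower HHSE.

The clinical table draws from lognormal/normal/multinomial marginals typical
of a pediatric VNS cohort (seizure frequency, BMI, onset age, epilepsy
duration, implantation age, ASM counts, etiology, syndrome, MRI, seizure
types); an optional `clinical_effect` parameter shifts responder continuous
variables for prediction experiments. Default group sizes are 38 responders /
27 nonresponders (58.5% responder rate).

Realism limits: the generator produces stationary signals without artifacts,
eye blinks, sleep-stage changes, or genuine cross-frequency structure; group
effects are planted in exactly the two mechanisms the pipeline measures. It
validates detection machinery (power and type-I error under known ground
truth) — it does not validate the clinical hypothesis itself.

Determinism: subject k of a cohort with seed S is generated from
`SeedSequence([S, k])`, and clinical rows from `SeedSequence([S, 10⁶ + k])`,
so cohorts are bitwise reproducible and individual subjects can be regenerated
in isolation.

## 4. Numerical choices

- **PLI with absolute value.** PLI is defined as the absolute time-averaged
  sign of the wrapped phase difference, keeping it in [0, 1] and symmetric in
  channel order.
- **Phase wrapping** uses `π − mod(π − Δφ, 2π)`, mapping onto (−π, π] so that
  a zero-lag pair yields sign 0 exactly.
- **Sparsity edge count** uses round-half-even; cutoff ties are broken by
  (row, col) lexicographic order, making thresholding deterministic.
- **Shortest paths** use Dijkstra on inverse-weight lengths; disconnected
  pairs contribute 0 (1/∞) to efficiency. The test suite cross-checks against
  a Floyd–Warshall brute force.
- **EMD completeness is exact by construction** (the residue is the signal
  minus the IMF sum); envelope interpolation mirrors two extrema at each
  boundary and falls back to linear interpolation when fewer than two knots
  exist.
- **Instantaneous frequency** is the gradient of the unwrapped analytic phase
  scaled by fs/2π, smoothed with a 5-point moving average; samples with
  non-positive or out-of-range frequency are excluded from the spectrum (and
  counted).
- **Histogram tie guard:** frequency-to-bin assignment adds 1e−9 before the
  floor so values sitting exactly on a bin edge bin deterministically.
- **Statistics:** Mann–Whitney is exact when n₁ + n₂ ≤ 12 without ties, else
  asymptotic with tie correction; Cohen's d uses the pooled SD with n − 1
  weights; FDR is Benjamini–Hochberg within declared feature families;
  sparse categorical tables use Fisher (2×2) or a seeded Monte-Carlo χ².
- **Leakage safety:** min–max scaling and feature selection are fitted inside
  each training fold by default. A `global_normalization` flag reproduces
  cohort-wide scaling for comparison with analyses that normalized before
  cross-validation; the default avoids that optimistic bias. A
  `pipeline_factory` injection point lets tests place a spy transformer
  inside the CV to prove no fit ever sees held-out rows.
- **Byte reproducibility:** every output embeds a 16-hex-digit SHA-256 digest
  of the canonical config JSON; CSV floats use `%.12g` with fixed line
  terminators; the run summary excludes wall-clock time from persisted files.
  Reruns of the same config produce byte-identical bundles.

## 5. Problem sizes

Full-scale defaults reflect the study conditions: 65 subjects (38/27), ≥ 360 s
of 19-channel EEG at 500 Hz, 10-fold outer / 5-fold inner CV. For validation
and documentation this package also defines two reduced sizes chosen so the
complete test and acceptance runs fit comfortably on one CPU:

- **desk scale** (`desk_config`): 8 subjects (5/3), 16 s at 250 Hz, α+θ
  bands, 3-fold outer / 2-fold inner CV, no feature selection — seconds per
  run; used for end-to-end determinism and CLI checks.
- **mechanism-study scale** (`mechanism_study`): 30 + 30 subjects per seed,
  16 s at 125 Hz, HHSE on the 4 θ-ROI channels — tens of seconds per seed;
  used to estimate detection power (with the planted contrasts) and type-I
  error (without) across replicate cohorts. 16 s at 125 Hz retains 7 usable
  2-s epochs and > 8 cycles of the slowest band per epoch, enough for the
  planted effects to dominate estimation noise at n = 30 per group.

These sizes are validation choices, not analysis recommendations; for real
cohorts use the full-scale defaults.
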