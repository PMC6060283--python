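# Methods

`pesp` implements a patient-specific seizure-prediction pipeline for
continuous intracranial EEG: per-channel permutation-entropy features,
a binary preictal/interictal SVM, firing-power alarm post-processing,
and sensitivity / false-prediction-rate / prediction-horizon evaluation
with distance-based model selection. This note records the model, its
assumptions, the parameter choices, and what the synthetic-data tests
do and do not establish.

## Feature: permutation entropy

For a scalar series `x(1..N)`, embedding dimension `m` and delay `λ`
(samples), each vector `X(i) = (x(i), x(i+λ), …, x(i+(m−1)λ))` is
mapped to the permutation `(j₁…j_m)` sorting it ascending; equal values
keep ascending index order (stable sort). With pattern probabilities
`P_g = n_g / (N − (m−1)λ)`,

    H_p = − Σ_g P_g ln P_g / ln(m!)  ∈ [0, 1].

Natural logarithms throughout; only the normalised value is reported.
PE is rank-based, hence invariant to any strictly increasing transform
of the signal — amplifier gain and offset cannot affect the feature.

Variants, all normalised to `[0, 1]` (uniform pattern distribution →
1, single pattern → 0):

* Rényi: `RPE_q = ln(Σ P_g^q) / (1−q) / ln(m!)`;
* Tsallis: `TPE_q = (1 − Σ P_g^q)/(q−1)`, divided by its uniform-
  distribution maximum `(1 − (m!)^{1−q})/(q−1)` — this normalisation is
  the standard choice that makes the measures comparable on one scale;
* min-entropy: `MPE = −ln(max_g P_g)/ln(m!)` (the `q → ∞` Rényi limit).

Default order `q = 2` for TPE/RPE, the common choice in the ordinal-
entropy literature; both `q` and the measure are configuration.

**Defaults and units.** `m = 4`, `λ = 1`: at 256 Hz, patterns span
~16 ms, long enough to populate the 24 possible patterns within a
window yet short enough to track fast dynamics. Features are computed
on non-overlapping 5-s windows (1280 samples; `x = ⌊L/(5·256)⌋`
windows per channel, trailing partial window discarded, no padding) —
5 s is the usual compromise between resolution and the local
stationarity the ordinal statistics assume. Six channels yield 6-dim
feature vectors, one per window.

## Preprocessing

Zero-phase (forward–backward) second-order IIR notch at 50 Hz, default
bandwidth 1 Hz — zero phase so no group delay shifts onset-relative
timing. Polyphase resampling with anti-alias filtering for rate
conversion (e.g. 512 → 256 Hz). Channel selection is explicit
configuration: for the Freiburg recordings the convention is three
focal plus three extra-focal electrodes, but no fixed choice is baked
in. Time is seconds from recording start, 0-based, half-open intervals
`[a, b)` everywhere.

## Labels, splits, balancing

A window is **preictal** if its interval intersects
`[onset − horizon, onset)`; windows touching an ictal interval or the
post-ictal margin after it are **excluded** (exclusion wins over the
preictal label); the rest are **interictal**. Horizon default 50 min —
the Freiburg convention, consistent with observed mean prediction
horizons around an hour; post-ictal exclusion default 30 min. Both are
configuration, as is the intersect-rather-than-contain rule (it
maximises preictal sample count; boundary windows are ambiguous under
either convention).

Evaluation is leave-one-seizure-out and requires ≥ 3 seizures: the
held-out seizure's full continuous recording is the test segment; the
other seizures' preictal windows plus the interictal pool form the
training set. Provenance tags make the no-leakage property checkable.
The majority class is randomly undersampled (without replacement,
seeded) to the minority count before training.

## Classifier

RBF-kernel SVM. `(C, g)` from an exhaustive grid search maximising
mean accuracy under stratified six-fold cross-validation of the
balanced training set (stratification keeps fold class ratios stable;
accuracy is the natural criterion on a balanced set). Ties prefer
smaller `C`, then smaller `g` — the least complex model. Default grid
`C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}`, `g ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}`; the experiment
driver defaults to a coarser 6 × 5 sub-grid of the same ranges, which
keeps a full leave-one-seizure-out run on a multi-hour patient at
interactive scale. PE features are already commensurate on `[0, 1]`,
so no feature scaling is applied. The classifier sits behind a
fit/predict contract; alternates can be swapped without touching the
pipeline.

## Firing-power alarms

Window labels `tg_i ∈ {0,1}` are regularised by counting:

* **two-step** — sums over non-overlapping 2-min short windows (24
  labels); count ≥ p ⇒ the short window is preictal
  (`p ∈ {1, …, 12}`); three consecutive short windows form a 6-min
  long window, and ≥ k preictal shorts (k ∈ {1,2,3}) raise one alarm;
* **one-step** — a single count threshold per non-overlapping 6-min
  block (72 labels). The candidate thresholds are {3, 6, …, 36},
  the two-step `p` range scaled by 3 so both variants sweep the same
  count-fraction range.

Long windows are a fixed partition (consecutive non-overlapping
triples), not a sliding triple; the decision is evaluated at window
end and the alarm timestamped at the window's start. Firing mid-window
as soon as the k-th preictal short completes would be the natural
online variant; it changes timestamps by < 6 min and is not
implemented. A refractory period (default = the preictal horizon)
suppresses alarms after a kept alarm; without one, a single sustained
preictal-like stretch would count as many false predictions and the
false-prediction rate would be ill-defined. It is configurable,
including off.

## Evaluation and model selection

`SS = Nc/Nt` (a seizure counts as predicted iff ≥ 1 alarm falls in
`[onset − horizon, onset)`); `FPR = Nf/NT` with **NT the total record
time**, preictal included — much of the literature divides by
interictal time only, which yields slightly higher rates. SPH is
measured from the *first* in-horizon alarm; later in-horizon alarms are
neither hits nor false alarms. The commonly cited chance level
0.15 h⁻¹ is exposed as a constant and a convenience flag.

Candidates are compared by distance to the ideal corner after
normalising FPR across the candidate set (raw rates crowd near zero):

    fprn(u) = fpr(u)/max_v fpr(v) · 100     (all-zero set ⇒ all zeros)
    ed(u) = √((ss%(u) − 100)² + fprn(u)²),

minimised over candidates; ties prefer higher SS, then lower raw FPR.
Cohort summaries are unweighted arithmetic means across patients. The
shipped 19-patient benchmark table's distance columns average to 11.46
(two-step) and 22.89 (one-step); those recomputed column means are the
values this package reports.

Operating-point selection is leakage-guarded by default: each fold
picks `(p, k)` by minimum `ed` on a validation seizure taken from its
own training seizures, never on the held-out seizure.
`selection="in_sample"` instead picks one operating point on the
aggregated test-fold scores — optimistic, but it reproduces the common
practice of quoting the best post-hoc operating point.

## Synthetic data

The generator reproduces the *feature-level* structure the pipeline
needs, not physiological EEG. Per channel: unit-variance AR(1) noise
(φ = 0.9) plus sinusoids whose amplitudes follow the regime schedule —
interictal 8-Hz amplitude 3 (PE ≈ 0.78), preictal amplitude 6
(PE ≈ 0.57), ictal 3-Hz amplitude 10 with noise attenuated to 0.3
(PE ≈ 0.40). These amplitudes were calibrated once against the PE
targets (interictal 0.75–0.8, preictal 0.5–0.75, sharp ictal decline)
and then frozen; only the PE targets are contractual, the waveform
recipe is internal. Regime transitions cross-fade linearly over 60 s
(ictal onset over 5 s — seizure onset is abrupt) so no step artifact
leaks into the ordinal statistics. Channels share the schedule but get
independent noise, individual phases and slightly jittered
frequencies. Everything is deterministic per seed.

The default synthetic patient is three 1-h seizure recordings (onset
at 55 min, so the full 50-min horizon is contained) plus one 1.5-h
interictal recording — sizes chosen to exercise the full pipeline,
grid search included, in about a minute. What passing tests show: the
pipeline recovers a planted, strongly separated preictal signature
end-to-end (SS = 1, FPR = 0 at some (p, k)). What they do not show:
performance on real iEEG, where preictal changes are weaker,
non-stationary, inconsistent across seizures and contaminated by
artifacts; the benchmark table documents the realistic spread
(per-patient SS from 0.708 to 1.0).

## Numerical choices and edge cases

* Pattern counting is vectorised (stable argsort + mixed-radix
  encoding + bincount); an independent brute-force enumerator backs it
  in tests to 1e−12.
* Monotone series → single pattern → entropy exactly 0; series shorter
  than `(m−1)λ + 1` are rejected, as are non-finite values.
* `normalized_fpr` of an all-zero candidate set is defined as all
  zeros, so `ed = 0 ⟺ SS = 100 % ∧ FPR = 0` holds degenerately.
* An alarm exactly at onset is outside the half-open preictal interval
  and counts as false.
* Grid-search tie-breaking is deterministic (ascending scan, strict
  improvement), making whole-experiment runs reproducible bit-for-bit
  given a seed.

## Known limitations

* The matrix reader loads whole recordings into memory; multi-day
  records need chunking that is not provided.
* TPE/RPE/MPE use the standard literature forms and normalisations
  noted above; other normalisation conventions exist.
* The per-patient aggregation behind fractional benchmark sensitivities
  (e.g. 0.708 with ≤ 5 seizures) is not derivable from per-fold counts
  alone; this package reports per-fold results and their mean.
* No artifact rejection, re-referencing or montage construction; no
  streaming/online operation.
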