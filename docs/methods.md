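# Methods

This note records the conventions, defaults and open design choices behind
`seizeeg`, in the spirit of a model-documentation page: what is computed,
under which assumptions, and what the synthetic experiments do and do not
demonstrate.

## Signal model and conditioning

Input is a single-channel EEG window (nominally 4097 samples at 173.61 Hz
for the plain-ASCII dialect, 1024 samples at 200 Hz for the MAT dialect;
lengths are not enforced at read time so shorter windows remain usable).

Conditioning is a 4th-order Butterworth filter applied forward–backward
(zero phase, so later features see no phase distortion), followed by db4
wavelet-shrinkage denoising. Two numerical points deserve note:

* **Near-Nyquist upper edges.** A band-pass whose upper edge reaches the
  Nyquist frequency is degenerate; when `high >= 0.99 * fs/2` the filter
  degrades to a high-pass at the lower edge (with a logged warning). The
  practical intent of a "0.01 Hz to Nyquist" band is full band minus drift,
  and that is what the high-pass delivers.
* **Transients at very low cutoffs.** A 0.01 Hz high-pass has an impulse
  response of order 100 s — longer than a typical 23.6 s segment. With
  reflection padding, forward–backward filtering then injects boundary
  transients comparable to the signal itself (we measured a mid-band tone's
  RMS inflated by ~37%). The implementation therefore removes the linear
  trend first and uses the minimal-transient (Gust) initial-condition
  method. With these choices a mid-band tone's RMS is preserved to well
  under 1% and slow drift is strongly attenuated.

Denoising uses the universal threshold σ̂·√(2 ln N) with
σ̂ = median(|D1|)/0.6745 estimated from the finest detail coefficients,
soft thresholding on all detail levels, symmetric boundary extension (the
common convention for shrinkage denoising). A noise-free signal yields
σ̂ ≈ 0 and passes through essentially unchanged. The threshold rule is a
single function and is straightforward to swap.

## Subband decomposition

Four-level db4 DWT giving D1–D4 and A4. Band edges are dyadic:
D1 = [fs/4, fs/2), each deeper level halves the band, A4 = [0, fs/32).
Published tables for fs = 173.61 Hz print one-decimal **truncated** edges
(10.8 for 10.850625), and `truncate_hz` reproduces that display form.

Decomposition defaults to **periodization** boundary handling, which keeps
the db4 filter bank orthonormal: summed single-subband reconstructions
reproduce the input and coefficient energies partition signal energy, both
to machine precision. (Symmetric extension, retained for denoising, breaks
exact energy partition at the boundaries.) Features are computed on
**reconstructed** subband signals by default — each subband inverted to
full length with the others zeroed — with raw coefficients available via
`representation="coefficients"`.

## Features

Per subband: population standard deviation (divisor N) and three
entropies, all using the Chebyshev distance, with the tolerance resolved
per subband as r·SD(subband) (each subband has its own amplitude scale):

* **ApEn** (Pincus): N−m+1 templates at dimension m, self-match included,
  Φᵐ the mean log match fraction; ApEn = Φᵐ − Φᵐ⁺¹.
* **SampEn** (Richman–Moorman): self-matches excluded, N−m templates at
  *both* dimensions so pattern counts are comparable; −ln(A/B) over matched
  pair counts. When A or B is zero the statistic is undefined; the library
  raises a typed error, and the feature extractor substitutes the
  conventional cap ln(N−m) + ln(N−m−1) − ln 2 (the value corresponding to
  a single matched pair) rather than silently dropping segments.
* **FuzzyEn** (Chen): baseline-removed templates, membership
  exp(−(d/r)ⁿ), N−m templates at both dimensions; ln φᵐ − ln φᵐ⁺¹.

Defaults m = 2, r = 0.2·SD, n = 2 — the canonical choices in the entropy
literature; all are exposed. Subbands that are constant up to floating-point
dust (relative SD ≤ 1e−12) report zero entropy by convention instead of the
entropy of rounding noise.

The fast paths compute pairwise Chebyshev distances as a running maximum
over lag-shifted scalar difference matrices (O(N²) time, O(N²) memory, no
(N², m) tensor). An independent module of naive pure-Python double loops
(`seizeeg.oracles`) is kept as the test-time arbiter; the suite requires
agreement to 1e−12 on sequences up to N = 300.

## Feature selection

Importance of feature j is the mean over K bootstrap-trained CART trees
(Gini splits, unlimited depth, √p features per split, bootstrap size n) of
the drop in that tree's out-of-bag accuracy when column j is permuted
within the OOB rows; permutations are seeded per (seed, tree, feature).
This per-tree accuracy-drop statistic is computed explicitly — it is not
the impurity-based importance forests usually report, which is a different
quantity. Accuracy is overall OOB accuracy (not class-balanced).

Selection is backward elimination with **re-ranking every round**: fit the
forest, drop the single lowest-importance feature (ties broken by
lexicographically last name, recorded in the audit trace), refit on the
survivors, repeat until k = 10 remain. K defaults to 200 trees. Trees with
an empty OOB set contribute zero deltas and are counted.

## Classifier

A deliberately small 1-D CNN over the 10-feature vector, implemented in
NumPy with explicit backpropagation: conv(16 filters, kernel 2, stride 1) →
batch-norm → ReLU → max-pool(2, stride 1) → conv(32, kernel 2) →
batch-norm → ReLU → max-pool(2, stride 1) → flatten →
fully-connected 192→32 (ReLU) → 32→n_classes (softmax). Length
walk-through: 10 → 9 → 8 → 7 → 6; 6·32 = 192. Specs that would collapse a
length below 1 are rejected at construction. Overlapping stride-1 pooling
is unusual but intentional, matching the stated layer sizes exactly;
average pooling is implemented and exposed but unused by default.

Choices the architecture statement leaves open and how they were fixed:
ReLU activation after batch-norm; hidden fully-connected width 32; He
initialisation; Adam with lr 1e−3, batch size 32, 100 epochs. Inputs are
standardised per feature using training-fold statistics (the 20 features
span very different scales). Batches with fewer than 2 rows are skipped
(batch-norm needs a batch). Everything is seeded: identical data, config
and seed give bit-identical parameters and predictions on one machine.

An RBF-kernel SVM adapter behind the same fit/predict contract is included
for comparative reporting only.

## Evaluation protocol

Repeated stratified 3:1 train/test splits (default 10 repeats; the
acceptance runs use 3), mean ± SD reported alongside per-repeat values.
Feature extraction is per-segment and stateless, so it runs once before
splitting; every *fitted* stage — selection and the CNN — runs inside each
training fold. A `selection_scope="global"` mode (select once on all rows)
is provided because some published protocols do this, but the strict
per-fold default is what the tests assert. Zero-denominator metrics are
reported as an explicit undefined marker, never a silent 0.

How published single-figure accuracies on the public datasets were
aggregated (single split, mean of runs, windowed sub-segments) is not
stated in the source material; both single-split and repeated-split modes
exist here, and no claim is made that either reproduces a particular
published number. Those data- and split-dependent values are outside this
package's test surface.

## Synthetic data

The generator emulates the qualitative class contrasts, not physiology:

* **background** — band-limited 1/f^β Gaussian noise, β = 1 (pink),
  matching broadband EEG qualitatively; unit SD before scaling.
* **interictal_like** — background plus sparse biphasic (~70 ms) spikes at
  a Poisson rate (default 0.5 events/s).
* **ictal_like** — a 3 Hz spike-and-wave train (sawtooth wave plus a sharp
  Gaussian spike convolved with a periodic impulse train; 3 Hz is the
  classic absence-seizure signature and lies inside the A4 band) with a
  reduced-variance (0.15×) noise floor.

Class amplitude scales default to 1.0 / 1.2 / 4.0 — the 4× ictal-to-
background ratio keeps the desk-scale classes well separated, mirroring the
pronounced amplitude contrast of seizure EEG. Seeds are hierarchical
(master seed → per-(class, replicate) seeds via `SeedSequence`), so
enlarging a dataset never reshuffles existing segments.

The default desk-scale study uses 100 segments per class of 1024 samples at
173.61 Hz (the shorter of the two public-record lengths), which keeps the
full pipeline — featurization, per-fold selection, CNN training, three
repeats — in the minutes range. Passing on this data shows the pipeline's
plumbing, determinism, leak-freedom and its ability to exploit amplitude
and regularity contrasts; it does **not** show robustness to artifacts,
electrode variation, non-stationarity, patient heterogeneity or subtle
interictal-vs-background distinctions, none of which the generator models.
With the amplitude ratio driven toward 1 and matched spectra, end-to-end
accuracy falls toward chance — the shuffled-label control in the acceptance
run demonstrates the chance floor directly.

## Known limitations

* Entropy fast paths are O(N²) memory in the template count; full-length
  4097-sample segments cost ~17 s per segment for all 20 features. For
  large batches, shorten windows or parallelise externally.
* SampEn's undefined-case cap introduces a ceiling artifact for extremely
  regular, low-tolerance settings.
* The CNN trains on CPU in NumPy; it is sized for 10-feature inputs, not
  raw waveforms.
* Only single-channel, single-vector record formats are read; EDF/BDF and
  multi-channel montages are out of scope.
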