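# Methods

## Pipeline overview

The package classifies single-channel EEG segments into seizure-related
classes in three phases: wavelet feature extraction, a moth-flame search
over classifier parameters, and closed-form training of an extreme
learning machine (ELM) under the best parameters found.

## Wavelet features

Each segment is decomposed with a discrete wavelet transform using the
Daubechies-2 (db2) wavelet to level 4. The analysis low-pass filter is
the closed form `((1+√3), (3+√3), (3−√3), (1−√3)) / (4√2)`; the
high-pass is its quadrature mirror. The default extension mode is
**periodization**: on signal lengths divisible by 2⁴ the transform is
orthonormal, so the coefficient count and the signal energy are
preserved exactly — properties the test suite asserts against an
independent circular-convolution implementation. Symmetric extension is
available for compatibility with common toolboxes but sacrifices these
exact invariants (coefficient counts grow slightly with filter
overhang).

Sub-bands are ordered D1 (finest) → D4, then A4. Six statistics
summarize each band: mean absolute value, average power (mean square),
population standard deviation, population skewness, population excess
kurtosis, and the Shannon entropy (nats) of the normalized squared
coefficients p_k = c_k²/Σc². Zero-variance bands define skewness and
kurtosis as 0, and an all-zero band has entropy 0, so every feature is
finite on degenerate inputs. Five bands × six statistics give the
30-dimensional feature vector; population (divisor-n) moments were
chosen over sample moments so single-coefficient bands (A4 and D4 at
short lengths) remain well-defined.

Features are computed from the wavelet *coefficients*, not from
band-limited reconstructions — the conventional choice, and the cheaper
one; the two differ only by the synthesis filtering, which the
statistics largely absorb.

## Extreme learning machine

The classifier is a single-hidden-layer feedforward network
`f(x) = Σ_{i=1}^H v_i h(a_i(x))` whose hidden parameters are drawn
randomly once and never trained. Output weights solve `M v = Y` in
closed form, where `M` is the N×H hidden activation matrix and `Y` the
one-hot class matrix (class order = sorted labels): the minimum-norm
least-squares solution at ridge 0, or the Tikhonov-regularized normal
equations `(MᵀM + λI)v = MᵀY` for λ > 0. Prediction is arg-max over
class scores with ties going to the first class in sorted order.

Ten activations are provided in two dialects:

* **projection** — `a_i(x) = w_i·x + β_i` with `w, β ~ U(−s, s)`
  (default s = 1): sine, tanh, tribas `max(0, 1−|a|)`, inv_tribas,
  sigmoid, hardlim `1[a>0]`, softlim `clamp(a, 0, 1)`;
* **distance** — `a_i(x) = ‖x − c_i‖/σ_i` with centers uniform in the
  per-feature training box and widths set to the median pairwise
  distance among the centers (fallback 1 when the box is degenerate):
  gaussian `e^{−d²}`, multiquadric `√(d²+c²)`, inverse multiquadric
  `1/√(d²+c²)`, with shape constant c = 1.

The defaults are 500 hidden units and the multiquadric activation —
the configuration found best in the activation sweep; the inverse
multiquadric remains one flag away. The split into projection and
distance dialects follows the standard reading of the multiquadric
family as radial-basis constructs.

A practical capacity note: when the hidden-unit count approaches the
training-set size, the ridge-0 interpolating solution generalizes
poorly (the classic interpolation-threshold peak). Keep H well below or
well above n_train, or use a small ridge; the desk-scale configurations
in the tests use H = 100 against 240-sample training folds.

## Moth-flame optimization

MFO maintains N moths (candidate positions) and an elite archive of
flames (the best N positions seen, merged and sorted each iteration).
Moth i spirals toward flame min(i, n_flames−1):

    new_k = L_k · exp(b·t_k) · cos(2π·t_k) + flame_k,  L_k = |flame_k − moth_k|

with helix constant b = 1 and path coefficient t drawn per dimension
uniformly from [r, 1], where r decreases linearly from −1 to −2 over
the run, tightening the spiral. The flame count decays linearly from N
to 1 (`round(N − l(N−1)/T)`, clamped to ≥ 1), concentrating late
iterations on the best solution. Positions are clamped into the search
box after each move; best-so-far fitness is non-increasing by
construction of the merge-sort flame update. The population size (50),
iteration budget (1000) and 30-dimensional search space are the
full-scale defaults; desk-scale runs use 10 agents and 20 iterations.

The search box for the classifier parameters defaults to [−1, 1] per
dimension; the raw benchmark default is [−100, 100]. Objectives are
minimized; the classifier objective is `1 − mean CV accuracy`.

## The DM-ELM hybrid

The position vector is interpreted in one of two modes:

* **feature_scaling** (default) — one multiplicative weight per feature;
  dimension equals the feature count (30). The all-ones position
  reproduces the plain ELM exactly. One moth is seeded at the identity,
  so by flame elitism the optimized frozen-fold objective is never worse
  than the plain ELM's — the hybrid ≥ baseline comparison is structural,
  not statistical.
* **input_weights** — the position encodes the hidden weights and biases
  of a reduced network (`n_hidden_search` units, projection activations
  only), replacing the random draw; dimension H′·(d+1).

Fold assignment (stratified, seeded shuffle) and the ELM seed are frozen
when the objective is created, making the objective deterministic per
position and the whole fit reproducible from its seed. After the search,
a final ELM is refit on the full table under the best parameters.

Which classifier parameters the swarm should tune is genuinely open in
this design space; feature scaling was chosen as the default because it
matches the 30-dimensional search space to the 30 features while the
full network would need thousands of dimensions, and because it yields
the exact plain-ELM nesting above.

## Evaluation

Multi-class sensitivity, specificity and F-score are macro-averaged
one-vs-rest values (unweighted mean of per-class rates) with 0/0 ratios
defined as 0; accuracy is trace/total of the confusion matrix.
Cross-validation reports mean ± population std over the k fold-level
values (default k = 10; desk scale 5). The activation sweep compares all
ten activations on one frozen fold split; the validation curve reports
mean train and CV accuracy over an ascending grid of hidden-unit counts.

## Synthetic data generator

Three stylized classes mimic the healthy/interictal/ictal structure of
the Bonn A/D/E sets, differing in wavelet sub-band energy exactly where
the features look:

* **normal** — unit-amplitude sinusoid at a per-segment frequency drawn
  from 8–13 Hz (alpha band) plus white noise;
* **interictal** — the same background plus Poisson-timed biphasic
  spikes (difference of two offset Gaussians, width ≈ 60 ms, amplitude
  5× the background RMS, random polarity);
* **ictal** — a 3 Hz spike-wave rhythm built from a fundamental plus
  decaying 2nd/3rd harmonics (unit-RMS shape), scaled to
  `ictal_amp_ratio` × background RMS, plus noise.

Defaults: 4096 samples per segment at 173.61 Hz, noise sd 1.8 (in
background-amplitude units), spike rate 0.8/s, amplitude ratio 3.5,
100 segments per class. These were calibrated once so that the classes
are clearly separable by the wavelet statistics (plain-ELM 5-fold CV
accuracy ≈ 0.93–0.96) yet below the accuracy ceiling, leaving the
optimizer measurable headroom. All randomness derives from a single
root seed via spawned per-class streams, so datasets are byte-identical
on repeat.

What the generator does **not** emulate: 1/f background spectra,
amplitude nonstationarity, artifacts (eye blinks, muscle), channel
referencing effects, or physiologic seizure evolution. Passing tests on
this data demonstrate the pipeline's correctness and the optimizer's
behavior, not clinical performance; real-EEG accuracy must be
established on real recordings (e.g. the Bonn sets via
`io_eeg.assemble_set`).

## Numerical choices and edge cases

* Least squares via `numpy.linalg.lstsq` (rank-revealing SVD, default
  cutoff); minimum-norm solution under rank deficiency.
* Arg-max ties break to the lowest class index; `hardlim(0) = 0`.
* Non-finite inputs, single-class training sets, dimension mismatches
  and unstratifiable splits raise `ValueError` before any computation.
* A non-finite objective value aborts the MFO run with the offending
  position in the message.
* Signals shorter than 2^level are rejected with the minimum length
  named.

## Desk-scale problem sizes

The test suite and the reproduction script run the classifier
comparison at 100 segments/class, 5 folds, 100 hidden units, 10 agents
and 20 iterations (≈200 objective evaluations, ≈1000 ELM fits per
seed) — sizes chosen so a full run completes in about a minute on one
CPU while preserving every qualitative property of the full-scale
configuration.

## Known limitations

* No EDF/BDF readers or multi-channel support; input is the Bonn ASCII
  dialect.
* Only the Daubechies family is exercised; no wavelet packets or CWT.
* No significance testing between classifiers and no ROC analysis.
* The MFO search is serial; determinism, not speed, was the priority.
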