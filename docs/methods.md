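# Methods

## Model

`amdml` fits a shared discriminative subspace to M feature views of the
same N binary-labelled samples.  Each view is a matrix `X^m ∈ R^{D×N}`
(features in rows).  Three graph structures are built once from the data:

* **Intraclass graph** `G^m`: an edge joins samples i, j when they share a
  label and one is among the k₁ Euclidean-nearest *same-class* neighbours
  of the other in view m (symmetric OR rule).  Nonzero entries equal
  1/|Xs|, the reciprocal of the number of same-label pairs, so the graph's
  quadratic form is an average over the supervised pair set.
* **Interclass graph** `P^m`: the same construction over different-label
  pairs with k₂ opposite-class neighbours and weight 1/|Xd|.
* **Global-structure adjacency** `W`: the uniform matrix with every entry
  1/N² (diagonal included) and degree matrix diag(1/N).  With this
  convention `X L_W Xᵀ` equals the biased sample covariance of the view —
  an identity the test suite verifies to 1e−8 — so the associated trace
  term is a PCA-like regulariser.

The objective combines, per view, a Fisher discriminative trace
`a_m(H) = Tr(Hᵀ X^m (L_G^m − L_P^m) X^mᵀ H)` and a structure trace
`b_m(H) = Tr(Hᵀ X^m L_W X^mᵀ H) ≥ 0`:

    min J = Σ_m Θ_m^t (γ² a_m − γ b_m)   s.t. HᵀH = I, Θ on the simplex.

The exponent t > 1 keeps the view weights away from a one-hot solution:
at t → 1⁺ all weight collapses onto the cheapest view, larger t smooths
towards uniform.  Default t = 2.

## Optimisation

Block coordinate descent, initialised with uniform Θ and γ = 1:

1. **Θ**: with per-view cost `c_m = γ²a_m − γb_m`, the simplex stationary
   point is `Θ_m ∝ (1/c_m)^{1/(t−1)}`, exact for all-positive costs.
2. **γ**: the unconstrained minimiser `γ = Σ Θ^t b / (2 Σ Θ^t a)`, exact
   and positive when the weighted Fisher trace `Σ Θ^t a` is positive.
3. **H**: the d algebraically smallest eigenvectors of the symmetric
   system matrix `Σ_m Θ_m^t (γ² X^m(L_G−L_P)X^mᵀ − γ X^m L_W X^mᵀ)`,
   an exact minimisation under HᵀH = I.

The loop stops when |J(t) − J(t−1)| ≤ δ (default 1e−5) or after t_max
(default 100) iterations, and the result records the full objective trace
plus a step-level trace marking which updates were exact.

**Degenerate costs.**  On strongly discriminative data the Fisher trace is
negative (interclass spread dominates), which breaks both closed forms:
the Θ formula takes fractional powers of negative numbers and the γ
formula returns a non-positive value.  The implementation then (a) shifts
the costs, `c_m ← max(c_m − min_k c_k + ε, ε)`, before the Θ update, and
(b) floors γ at ε (default 1e−10), recording both as *clamp events* in the
fitted model.  These clamped steps are no longer exact minimisations and
the objective may increase across them — the step trace lets users audit
exactly where.  A consequence worth knowing: once γ takes its closed-form
value (half a weighted mediant of the ratios b_m/a_m), at least one
per-view cost is necessarily non-positive, so on most real fits the shift
activates from the second iteration onward.  Runs can also oscillate
between the γ floor and large γ values when `Σ Θ^t a` flips sign; such
runs stop at t_max with `converged=False` and their clamp log shows why.
Exact steps are asserted non-increasing (1e−8) by the test suite.

## Feature views

* **WPD** — log energies of the 2^level terminal nodes of a Daubechies-4
  wavelet-packet tree (default level 3 → 8 coordinates), in frequency
  order, with a 1e−12 floor inside the log.
* **STFT** — log mean power in n_bands equal frequency bands of a Hann
  spectrogram (defaults: 256-sample window, hop 128, 8 bands), suited to
  the 173.6 Hz sampling rate of Bonn-style segments.
* **KPCA** — kernel PCA on the raw segment vectors, Gaussian kernel with
  the median pairwise-distance bandwidth heuristic, component signs fixed
  by the largest-magnitude training score.

All views must share one output dimension D (default 8) because a single
projection H is applied to each.  Per-feature standardisation (mean 0,
variance 1) is on by default; in cross-validation the standardisation
statistics and the KPCA map are refitted on each training fold only, so no
test information reaches the fitted model.

## Classification and evaluation

Test samples are projected per view and fused; the default fusion stacks
`Θ_m Hᵀ X^m`, whose squared Euclidean distances decompose as
`Σ_m Θ_m² ‖Hᵀ(x_i^m − x_j^m)‖²`.  The built-in classifier is an odd-K
nearest-neighbour majority vote (ties broken by sample index); any
estimator with fit/predict can be plugged in.  Evaluation reports
accuracy, per-class accuracies and the balanced loss
`l_bal = 1 − (ACC₊ + ACC₋)/2`.  The protocol is stratified 10-fold
cross-validation (seeded, deterministic); `n_folds = N` degrades to
leave-one-out.  The sensitivity harness reruns CV over k₁ = k₂ ∈ {2..10}
with K = 7, and over K ∈ {1,3,5,7,9} with k₁ = k₂ = 5.

## Synthetic data

The multi-view generator draws two balanced Gaussian classes whose means
sit at ±(Δ·informativeness_m)/2 along a random unit direction per view,
with isotropic noise σ (defaults Δ = 3, σ = 1, 50 samples per class).
Informativeness 0 yields a pure-noise view.  This makes separability and
per-view information analytically controllable; it does not mimic the
heavy tails, autocorrelation or nonstationarity of real EEG features, so
passing tests demonstrate correctness of the machinery, not clinical
performance.  The EEG-like generator produces 1/f-weighted background
noise and, for the seizure-like class, adds 1–3 Hann-windowed oscillatory
bursts at random frequencies in 3–12 Hz (amplitude 3× the background SD),
giving a reliably elevated low-frequency band power.

## Numerical choices and problem sizes

* Eigen-decompositions via symmetric `eigh` after explicit
  symmetrisation; eigenvector signs fixed (largest-magnitude entry
  positive) for bit-reproducibility.
* Neighbour ties broken by lower sample index; Euclidean distance in raw
  view space.
* Subspace dimension d defaults to 8 (≤ D); for D = 8 views a smaller
  d (e.g. 4) is typical in the CV harness.
* Pipeline-scale checks use 30 segments per class of 1024 samples, 50
  simulation seeds for weight recovery, and 20 label permutations for the
  null — sizes at which every reported quantity is stable yet the full
  suite runs in seconds.

## Limitations

* Binary tasks only; the pair-set construction and l_bal assume two
  classes.
* The closed-form updates presume positive per-view costs; outside that
  regime the clamped dynamics are a heuristic and monotone descent is not
  guaranteed (clamp events and the step trace expose this).
* Graphs are dense N×N constructions — fine for hundreds of samples, not
  for tens of thousands.
* The feature extractors implement exactly three views; artifact removal
  or other EEG preprocessing is out of scope.
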