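# amdml — auto-weighted multi-view discriminative metric learning

`amdml` learns a single discriminative metric space from several feature
*views* of the same labelled samples, with per-view weights obtained in
closed form rather than tuned by hand.  It was built for binary epileptic
EEG classification — the Bonn-style setting where each single-channel
segment is represented by wavelet-packet (WPD), short-time Fourier (STFT)
and kernel-PCA (KPCA) features — but the learner itself is generic: any
collection of `D × N` view matrices over a shared ±1 label vector works.

## The model

Given M views `X^m` (features in columns-per-sample layout) with labels,
the method builds, per view, a k₁-NN *intraclass* graph `G^m` (same-label
pairs, weight 1/|Xs|) and a k₂-NN *interclass* graph `P^m` (different-label
pairs, weight 1/|Xd|), plus one shared uniform adjacency `W` with every
entry 1/N² whose Laplacian satisfies `X L_W Xᵀ = biased sample covariance`.
It then minimises, over a column-orthonormal projection `H ∈ R^{D×d}`,
simplex view weights `Θ`, and a constraint weight `γ > 0`,

    J(H, Θ, γ) = Σ_m Θ_m^t ( γ² Tr(Hᵀ X^m (L_G^m − L_P^m) X^mᵀ H)
                             − γ Tr(Hᵀ X^m L_W X^mᵀ H) ),
    s.t. HᵀH = I,  Σ_m Θ_m = 1,  Θ_m ≥ 0,  t > 1.

The first trace is a Fisher discriminative term (compact same-class
neighbours, separated different-class neighbours); the second is a
PCA-like global-structure term.  Block coordinate descent alternates a
closed-form simplex update of `Θ`, a closed-form update of `γ`, and an
eigendecomposition for `H` (the d algebraically smallest eigenvectors of
the weighted system matrix), until |ΔJ| ≤ δ.  Classification happens in
the fused space — by default the stacked `Θ_m · Hᵀ X^m` — with an odd-K
nearest-neighbour vote, scored by accuracy and the balanced loss
`l_bal = 1 − (ACC₊ + ACC₋)/2`.

## Worked example

```python
import numpy as np
from amdml import AMDML, FitConfig, SynthSpec, generate_multiview, cross_validate

ds = generate_multiview(SynthSpec(n_per_class=50, D=8, M=3,
                                  informativeness=(1.0, 0.6, 0.0),
                                  class_separation=3.0, noise_sd=1.0, seed=0))
res = AMDML(ds, FitConfig(k1=5, k2=5, d=4)).fit()
print(res.summary())
cv = cross_validate(ds, FitConfig(k1=5, k2=5, d=4), classifier=7, n_folds=10, seed=0)
print(f"10-fold CV accuracy: {cv.accuracy:.3f}   l_bal: {cv.l_bal:.3f}")
```

prints

```
AMDML fit results
==================================================
views (M):          3
samples (N):        100
feature dim (D):    8
subspace dim (d):   4
k1 / k2:            5 / 5
exponent t:         2.0
converged:          True (2 iterations)
final objective J:  -3.2899e-10
gamma:              1e-10
--------------------------------------------------
view weights Theta:
  view1            0.6604
  view2            0.1553
  view3            0.1844
clamp events: [(1, 'theta-shift'), (1, 'gamma-floor'), (2, 'theta-shift'), (2, 'gamma-floor')]

10-fold CV accuracy: 0.920   l_bal: 0.080
```

The three views were generated with informativeness (1.0, 0.6, 0.0): the
learner assigns by far the largest weight to the fully informative view
and keeps the pure-noise view's weight small, and 10-fold cross-validated
accuracy in the fused space is 92%.  The `clamp events` line is the audit
trail of the closed-form updates: on discriminative data the Fisher trace
is negative, so the γ update hits its positivity floor and the Θ update
uses shifted costs (see `docs/methods.md`).

## Command line

```sh
amdml simulate --n-per-class 50 --views 2 --separation 6 --out views.tsv
amdml fit views.tsv --k1 5 --k2 5 --dim 4 --out model.json
amdml evaluate views.tsv --knn-k 7 --folds 10
amdml sweep views.tsv --out sweep.tsv
amdml extract BONN_DIR --task 3 --out task3.tsv   # Bonn-layout directories
```

Exit codes distinguish validation (2), I/O (3) and numerical (4) failures.

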