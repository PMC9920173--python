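# sdhmm — scaled-Dirichlet hidden Markov models with variational Bayes

`sdhmm` is a toolkit for unsupervised segmentation and clustering of
**compositional time series**: sequences of proportion vectors (non-negative,
summing to one) with temporal persistence, such as normalized wearable-sensor
features in human-activity recognition, where activities form hidden states
that persist over many consecutive samples.

Gaussian emission models are a poor fit for data confined to the probability
simplex. `sdhmm` instead gives each hidden state a mixture of **scaled
Dirichlet (SD)** emission densities

```
SD(x | α, β) =  Γ(Σ_d α_d) / Π_d Γ(α_d) · Π_d β_d^{α_d} x_d^{α_d−1} / (Σ_d β_d x_d)^{Σ_d α_d}
```

with shape vector α > 0 and scale vector β > 0. For equal scales the SD
reduces to the Dirichlet; the extra scale vector skews the distribution and
gives the model its flexibility. The full generative model is a first-order
hidden Markov chain: initial distribution π, transition matrix B, per-state
mixing weights C over M components, and an SD density per (state, component).

All parameters are learned by **mean-field variational inference** with
conjugate-style priors (Dirichlet on π, rows of B and C, and on each scale
vector; Gamma on each shape entry). The E-step substitutes expected
"tilde" parameters exp⟨ln π⟩, exp⟨ln B⟩, exp⟨ln C⟩ and posterior-mean
emission parameters into an exact scaled forward–backward recursion; the
M-step updates the Dirichlet weights with expected assignment counts and the
emission hyperparameters with linearized corrections. Fitted state sequences
are decoded from posterior marginals and, for evaluation against held-back
labels, aligned by Hungarian matching before computing accuracy, precision,
recall and F1.

The package also ships the standard conditioning chain for raw sensor tables
(median imputation, min–max scaling, simplex projection, SMOTE class
balancing) and a seeded synthetic-data module that generates both exact
SD-HMM sequences and an activity-like labeled fixture (sticky four-state
chain, 59.7/17.4/19.9/3 % occupancy, missing values), so everything can be
exercised without external downloads.

## Worked example

`examples/02_simulate_and_fit.py` simulates one sequence (T = 2000) from a
known two-state SD-HMM and refits it blind:

```
converged in 33 iterations, final monitor 1926.1
transition matrix (fitted vs generating):
  [0.937 0.063]   [0.95 0.05]
  [0.058 0.942]   [0.05 0.95]
shape vectors (fitted vs generating):
  [1.058 0.805 0.627]   [1.  0.8 0.6]
  [0.652 0.759 1.002]   [0.6 0.8 1. ]
worst transition-row L1 error: 0.0264; worst shape relative error: 8.6%
```

The fitted transition rows and shape vectors match the generator up to the
sampling noise of a single sequence. `examples/03_activity_pipeline.py` runs
the full unsupervised pipeline on the activity-like fixture (impute → scale →
simplex → fit K=4 → decode → Hungarian match):

```
Method        Accuracy  Precision   Recall  F1-Score
SD-HMM           96.30      73.63    74.61     74.12
```

Accuracy is the per-step agreement between decoded states and the held-back
activity labels; macro precision/recall are lower because the rarest
activity (3 % of steps) is hardest to pin down.

Library use in three lines:

```python
from sdhmm import fit, FitConfig
result = fit(X, FitConfig(K=4, seed=0))          # X: (T, D) rows on the simplex
states = result.decode(X)                        # most probable state per step
```

A thin CLI wraps the same pipeline: `sdhmm simulate | preprocess | fit |
predict | evaluate` (see `sdhmm --help`).

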