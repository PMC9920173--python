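# Methods

## Model

An observation sequence X = (x_1, …, x_T) of D-dimensional compositions
(rows on the simplex interior) is modelled by a K-state hidden Markov chain
with per-state mixtures of M scaled Dirichlet (SD) components:

- h_1 ~ Categorical(π), h_t | h_{t−1} ~ Categorical(B[h_{t−1}, ·]),
- m_t | h_t ~ Categorical(C[h_t, ·]),
- x_t | h_t = i, m_t = j ~ SD(α_{ij}, β_{ij}).

The SD density on the (D−1)-simplex is

SD(x | α, β) = Γ(A)/Π_d Γ(α_d) · Π_d β_d^{α_d} x_d^{α_d−1} / (β·x)^A,
A = Σ_d α_d.

Two algebraic facts shape the implementation. First, when all β_d are equal
the β terms cancel and the density is Dirichlet(α); the package asserts
this reduction to 1e-10 in tests. Second, the density is invariant to
β → cβ for any c > 0, so β is stored in canonical sum-to-one form and its
prior/posterior are Dirichlet. Equivalently, if y_d = β_d x_d / (β·x) then
y ~ Dirichlet(α); the sampler inverts this transform (draw y, map back),
and the transformation-group structure means inference about α is exactly
as hard (or easy) whatever the true β is.

Assumptions: first-order Markov dynamics, conditionally independent
emissions, constant parameters over time, observations strictly inside the
simplex (boundary handling below).

## Variational inference

Priors: Dirichlet(φ^π), Dirichlet(φ^B) per transition row, Dirichlet(φ^C)
per mixing row, Gamma(u, v) per shape entry (shape/rate), Dirichlet(h) per
scale vector. Defaults φ = 1, u = 1, v = 0.1, h = 1 — weakly informative,
prior mean α = 10 with standard deviation 10 per entry, uniform prior mean
scale. The mean-field posterior factorizes as
q(π) q(B) q(C) q(α) q(β) q(S, L).

**E-step.** Dirichlet posteriors contribute quasi-parameters
π̃_i = exp[ψ(w^π_i) − ψ(Σ w^π)] (and analogous rows for B and C), which are
sub-normalized by Jensen's inequality; rows are renormalized before the
forward–backward recursion, as a proper dynamic program requires. Emission
densities are evaluated at the posterior means ᾱ = u*/v* and
β̄ = h*/Σ h*. The recursion is the classical scaled forward–backward: a
per-step maximum shift plus per-step normalization constants whose logs
accumulate into the sequence log-likelihood; mixture components are
collapsed by log-sum-exp and their within-state posterior restored
afterwards. It returns state–component responsibilities γ^C, pairwise
responsibilities ξ, the initial-state posterior and the log-likelihood.

**Structural M-step.** Conjugate count updates:
w^π = γ^π + φ^π, w^B_ij = Σ_{t≥2} ξ_t[i,j] + φ^B_ij,
w^C_ij = Σ_t γ^C_t[i,j] + φ^C_ij. With several sequences the transition and
mixing counts accumulate across sequences and γ^π averages over sequence
starts.

**Emission M-step.** The SD likelihood is not conjugate to the Gamma/
Dirichlet priors, so the expected log-likelihood is linearized around the
current posterior means. With per-observation weight Z = γ^C_t[i,j]:

- shape: u* = u + η, v* = v − θ, where
  η_d = Σ Z · ᾱ_d [ψ(A) − ψ(ᾱ_d) + ψ′(A) Σ_{s≠d} ᾱ_s(⟨ln α_s⟩ − ln ᾱ_s)]
  and θ_d = Σ Z [ln β̄_d + ln x_d − ln(β̄·x)]. θ is a sum of logs of
  numbers in (0, 1], hence never positive, so the rate v* only grows. The
  fixed point of this update is exactly the maximum-likelihood stationarity
  condition ψ(ᾱ_d) − ψ(A) = Σ Z ln(β̄_d x_d/(β̄·x)) / Σ Z, which is what
  makes parameter recovery work.

- scale: the first-order stationarity condition for the scale mean is
  E_Z[β_d x_d / (β·x)] = ᾱ_d / A. A naive additive correction built from
  its gradient is a zero-sum O(N) vector that overshoots the simplex in one
  step and collapses the posterior; instead the package solves the
  condition directly by a short multiplicative fixed point (≈30 sweeps of
  b_d ← b_d · target_d / realized_d, renormalized) and converts the solved
  direction b into proper Dirichlet pseudo-counts τ = (Σ Z) · b, so
  h* = h + τ. This keeps the posterior proper, concentrates it at the rate
  of the data mass, reduces exactly to the prior for an empty component,
  and has the correct fixed point. The scale solve uses the freshly updated
  shape mean (Gauss–Seidel ordering); using the stale shape mean makes the
  coupled shape/scale iteration drift to boundary attractors.

All posterior hyperparameters are floored at 1e-6 (with a warning) as a
last guard; in normal operation the floor never triggers because θ ≤ 0 and
τ ≥ 0 by construction.

**Monitor and stopping.** The monitor is the data log-likelihood under the
substituted expected parameters, recomputed at each E-step. A literal
"repeat until the likelihood change is ≥ 0" never terminates, so training
stops when the relative change falls below `tol` (default 1e-6) or after
`max_iter` (default 200) sweeps. Because the updates optimize a bound on a
different functional, the monitor is not guaranteed monotone; empirically
it is non-decreasing in well over 95 % of iterations and the final relative
change is below tolerance.

**Initialization and restarts.** Observations are partitioned into K·M
cells by a small seeded Lloyd iteration (15 sweeps, centers drawn from the
data); responsibilities start as smoothed one-hot (0.9 on the assigned
cell, the rest uniform). The shape is initialized by a Dirichlet method of
moments on the pooled data (β uniform, α from the mean and first-coordinate
variance, clamped to [0.1, 100]) and perturbed per component by log-normal
noise (σ = 0.25). With `n_restarts > 1`, independent seeded restarts run to
convergence and the best final monitor wins; a merged-state local optimum
is typically hundreds to thousands of nats below the good optima, so the
monitor separates them cleanly. Everything derives from a single integer
seed and is bit-reproducible.

**Component pruning.** `prune_components` flags components whose expected
mixing weight falls below a threshold and renormalizes the surviving
weights. Note a caveat: when M exceeds the true component count, the
variational optimum frequently *splits* a cluster across two near-identical
components rather than starving one, and a weight threshold cannot detect
a split; pruning is therefore a tool for removing clearly starved
components, not an automatic order-selection method.

## Preprocessing

Order: median imputation → per-feature min–max scaling → optional SMOTE →
simplex projection (clamp to ≥1e-10, divide by row sum). Median imputation
is robust to outliers; a fully missing feature is an error naming the
column. Constant features map to 0.5 after scaling (the min–max formula is
0/0 there; keeping the feature neutral beats dropping it silently). SMOTE
interpolates synthetic minority rows between k nearest same-class
neighbors in the scaled [0,1] box, before simplex projection, so synthetic
rows project to valid compositions; synthetic rows are flagged. Because
interpolation between non-adjacent time steps has no temporal meaning,
SMOTE-balanced tables are treated as bags of observations (e.g. for
per-class emission fits); transition structure must come from the original
ordered runs. Synthetic rows receive no time positions.

## Evaluation protocol

Fitted states are anonymous, so evaluation against held-back labels first
solves the accuracy-maximizing one-to-one assignment between states and
labels (Hungarian algorithm on the contingency matrix); surplus states map
to their modal label. Accuracy is per-step agreement of the mapped states.
Precision and recall are computed one-vs-rest per class and macro-averaged
by default (micro and weighted are available); F1 = 2PR/(P+R) on the
averaged P and R. A class never predicted contributes precision 0 with a
warning. Matching can only improve on the identity mapping, and all
metrics are invariant under consistent relabeling.

## Synthetic data

`simulate` is exact ancestral sampling of the generative model and is the
oracle for inference and recovery tests. `make_har_fixture` emulates the
statistical shape of a wearable-sensor activity recording: a four-state
sticky chain (diagonal 0.95, off-diagonal mass proportional to the target
shares, which makes the target occupancy 59.7/17.4/19.9/3 % the exact
stationary distribution), one well-separated SD emission per state
(shape 12 on a state-specific pair of dimensions, 1.5 elsewhere; mildly
non-uniform scales), a log-normal per-row amplitude (σ = 0.3) mimicking
sensor magnitude variation, and entries knocked out completely at random
per feature (default rate 2 %). Defaults T = 3000, D = 6 keep end-to-end
runs under a minute. What the fixture does *not* emulate: sensor noise
autocorrelation, drift, real activity semantics, or feature correlations
beyond compositional structure — passing the pipeline benchmark shows the
chain of operations is correct and the model recovers planted structure,
not that any particular real dataset would reach the same accuracy.

The two-state recovery benchmark (`recovery_ground_truth`) uses mirrored
low-concentration shapes α = (1.0, 0.8, 0.6)/(0.6, 0.8, 1.0) with opposing
scale skews β = (0.25, 0.30, 0.45)/(0.45, 0.30, 0.25) and a balanced sticky
chain (diagonal 0.95), T = 2000. The design follows a power analysis with a
direct maximum-likelihood oracle: per-entry relative error of the shape
estimate at ~1000 observations per state is dominated by a shape/scale
information ridge, and only low-concentration shapes (entries ≲ 1.5, where
draws reach the simplex boundary and the (α_d−1) ln x_d terms are highly
informative) have an ML error floor comfortably inside a 15 % band. The
opposing scale skews separate the two states' mean compositions — keeping
responsibilities crisp and the transition estimates sharp — without
affecting the shape error floor (the transformation-group structure makes
that floor invariant to the true β). Recovery is scored up to state
permutation, with the permutation taken from Hungarian matching of decoded
states (matching near-symmetric transition rows is ill-posed).

## Numerical choices

- Boundary clamp: all incoming compositions are clamped to
  [1e-10, 1−1e-10] and renormalized before density evaluation; the density
  is singular at x_d = 0 for α_d < 1 and real tables contain exact zeros.
- All density work in log space via log-gamma; no direct Γ evaluation.
- Forward–backward uses per-step scaling plus a per-step max shift;
  log-sum-exp appears only in the mixture collapse.
- Decoding ties break toward the lower state index; marginal (per-step)
  decoding is the default because per-step label agreement is what the
  evaluation measures; Viterbi is available.
- States and components are 0-based internally, 1-based in CLI outputs.
- Degenerate inputs: single-observation moment init is an error;
  zero-variance data fall back to α = 1; an all-(-∞) emission column
  raises an error naming the time step; K·M exceeding the number of
  observations is an error.

## Limitations

- The emission M-step is a linearized surrogate, not a closed-form ELBO
  ascent; the monitor can decrease on rare iterations.
- Order selection (K, M) is out of scope beyond threshold pruning, and
  pruning cannot detect split components (above).
- Shape recovery for high-concentration components is information-limited
  at moderate sample sizes; expect per-entry errors of tens of percent for
  concentrations ≫ 1 at n ≈ 1000, whatever the estimator.
- SMOTE outputs break temporal ordering by construction.
- No support for semi-Markov durations, covariates, or streaming inference.
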