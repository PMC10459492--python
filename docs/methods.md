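# Methods

## Problem and model

`evostack` identifies single-input/single-output nonlinear dynamic systems
from stimulus-evoked time series. The design target is the EEG
wrist-perturbation protocol: a robotic manipulator applies periodic
multisine perturbations `u(t)` to the wrist while the evoked cortical
response `y(t)` (one independent component of the EEG, arbitrary units) is
recorded at 256 Hz; each participant contributes seven perturbation
signals, six for training and the seventh for testing, and one model is
fitted per participant.

The predictor is a NARX structure,

    y(t) = f( y(t-1..t-ny), u(t-1..t-nu), u_F(t-1) ) + e(t),

with `ny = 5`, `nu = 3`, and six engineered input features `u_F(t-1)`:
rolling mean, standard deviation and moment skewness of `u` over the three
samples ending at `t-1`, the difference `u(t-1) - u(t-2)`, the cube
`u(t-1)^3`, and a signed logarithm `sign(u) ln(1+|u|)` of `u(t-1)`. All
regressors are strictly causal; each trial loses `max(ny, nu, window) = 5`
burn-in rows and lags never cross trial boundaries.

`f` is a two-layer stacked ensemble. Layer 0 holds five base regressors —
LASSO, a one-hidden-layer MLP (sigmoid hidden units, identity output), a
Gaussian process and a support-vector regressor with RBF kernels, and
gradient boosting with a linear booster — whose hyperparameters come from
a leave-one-signal-out 6-fold cross-validated grid search on RMSE
(first-in-grid tie-break). Their out-of-fold predictions form the
meta-input matrix `Z`, so the layer-1 learner never sees a prediction made
by a model trained on that row's fold. Layer 1 is a Cubist-style
rule-based committee model whose two integer hyperparameters — committees
in [0, 60] and neighbors in [0, 20] — are tuned by JADE to maximize mean
6-fold cross-validated VAF on `(Z, y)`; the meta-learner is then refitted
on all rows at the tuned pair.

## Metrics

Variance accounted for, the headline criterion:

    VAF = 100 (1 - var(y - yhat) / var(y)),

computed with the sample variance (divisor n-1) in both terms; it is blind
to a constant prediction offset and can be negative. RMSE is the root mean
squared residual. Result tables are summarized with the arithmetic mean
and the population standard deviation (divisor n), the convention of the
packaged literature tables.

## JADE

The tuner is adaptive differential evolution with optional external
archive. Per generation, each individual `x_i` builds a mutant

    v_i = x_i + F_i (x_pbest - x_i) + F_i (x_r1 - x~_r2),

with `x_pbest` uniform over the best `ceil(p NP)` members, `r1` from the
population and `x~_r2` from population plus archive (all distinct from
`i`). Binomial crossover with per-individual `CR_i` and one forced
coordinate yields the trial; a strictly better trial replaces its parent,
which is archived (the archive is trimmed at random to `NP` entries).
`F_i ~ Cauchy(mu_F, 0.1)` resampled while non-positive and capped at 1;
`CR_i ~ Normal(mu_CR, 0.1)` clipped to [0, 1]. After each generation
`mu_F` moves toward the Lehmer mean of successful `F` values and `mu_CR`
toward the arithmetic mean of successful `CR` values, both with memory
factor `c`. Defaults: `c = 0.1`, `p = 0.05`, initial `mu_F = mu_CR = 0.5`
(the canonical JADE settings), `NP = 10` and 10 generations for the
meta-tuning box, exactly the reference budget. Integer dimensions are
rounded half-away-from-zero (then clamped) at evaluation time only, so the
search itself stays continuous. Out-of-bounds mutant coordinates are
repaired to the midpoint between the violated bound and the parent.
Non-finite objective values are logged and treated as worst-possible
fitness rather than aborting a run. The classic baseline is
`DE/rand/1/bin` with fixed `F` and `CR` (reference settings `NP = 100`,
`CR = 0.5`, `F = 0.2`).

Implementation note: for the native rule-meta backend the CV tuning
objective is served from per-fold committee chains fitted once up to the
committees upper bound. Committee member `j` depends only on members
`< j`, so every integer pair can be evaluated from cached member
predictions; this is mathematically identical to refitting per candidate
and cuts tuning from thousands of tree fits to 360.

## Rule-based meta-learner

The meta-learner is a documented Cubist-style approximation, not a port:

* a model tree is grown by variance-reduction splits (minimum leaf size 8,
  depth cap 8, no splitting of near-pure nodes whose residual spread falls
  below 5% of the root's);
* it is pruned bottom-up by comparing complexity-adjusted linear-model
  errors: a node's own least-squares fit with SSE inflated by
  `(n + 2p)/(n - 2p)` survives unless the subtree undercuts it by more
  than `prune_factor` (default 1%). A training-error-only prune rule was
  tried first and could not control overfitting — deeper trees nearly
  always cut training error while degrading CV VAF — so the
  complexity-adjusted form is used;
* leaves become rules (path conditions plus a linear model with small
  standardized coefficients pruned); a global linear fallback guarantees a
  finite prediction for any input;
* committees: member 1 trains on `y`; member `j > 1` on the corrected
  pseudo-target `y + (y - avg of members 1..j-1)`; the committee predicts
  with the member average. Committees 0 and 1 both mean a single member;
* neighbors: for `k >= 1` the committee prediction `m(x)` is blended 50/50
  with a `1/(d + 0.5)`-weighted average of `y_n + m(x) - m(x_n)` over the
  `k` nearest training rows (Euclidean distance on features standardized
  by training mean/sd). `k = 0` disables the correction; `k` larger than
  the training set is clamped with a log entry.

Because the `k`-neighbor average converges to the committee prediction as
`k` grows, the tuning landscape is nearly flat along the neighbor axis at
large `k`; ties there are effectively broken by the optimizer's sampling
path, which is why tuned neighbor counts scatter while the achieved CV VAF
is stable.

An adapter seam (`MetaBackend`) lets an external Cubist implementation
replace this model without touching the tuner or the stack; behavioral
equivalence with any particular Cubist release is explicitly not claimed.

## Multi-step prediction

Recursive strategy: the one-step predictor is iterated `h` times, and for
step `s` the output lag `j < s` is replaced by the model's own
`(s-j)`-step prediction of `t-j`; the input `u` is an exogenous designed
perturbation, so all input-derived features stay computed from the
observed signal. At `h = 1` the code path is identical to one-step
prediction. Origins whose predecessors precede the burn-in keep the
observed lags. Errors made early in the horizon feed back into the lag
slots, which is the mechanism behind the VAF drop from one to three steps.

## Statistical comparison

Models are compared across participants on per-participant VAF with the
Friedman test (within-participant ranks, average ranks on ties, mean-rank
form of the statistic, chi-squared reference with k-1 df). When the
omnibus rejects, the Nemenyi critical difference

    CD = (q_{inf,k,alpha} / sqrt(2)) sqrt(k (k+1) / (6 n))

is applied pairwise; the studentized-range quantiles are bundled as a text
table for k = 2..20 and alpha in {0.05, 0.10} (other parameters raise).
The residual-whiteness check standardizes the one-step residuals and
applies a one-sample Kolmogorov–Smirnov test against the standard normal.

The packaged literature tables include more models than entered the
published omnibus tests. The subsets used here were inferred from the
published degrees of freedom (10 one-step, 8 three-step, hence 11 and 9
models): the five base learners, the JADE- and DE-tuned stacks, and the
literature models (NARMAX-HNN, NARMAX-P, plus the two Volterra variants
at one step) — the only subset family consistent with the published
three-step statistic and p-value. The one-step statistic recomputed from
the published rounded table values is 93.45 rather than the published
93.29, which evidently used unrounded per-participant values that were
never released; the discrepancy is inherent to the printed data, not to
the rank arithmetic.

## Synthetic benchmark

The reference EEG dataset is confidential, so testing uses a generator
that reproduces the protocol shape with known ground truth:

* inputs: random-phase multisines, 256 samples per one-second period,
  seven signals per participant, flat amplitude across harmonics 1–10
  scaled to unit input variance (the reference perturbation spectrum is
  unpublished; this is a documented choice), 5 s per signal by default at
  desk scale (the reference records 30 s);
* system: a Wiener-type surrogate per participant —

      z(t) = a1 z(t-1) + a2 z(t-2) + b1 u(t-1) + w(t)
      y(t) = c1 z(t) + c3 z(t)^3 + e(t)

  with poles drawn in polar form (radius 0.55–0.8, angle pi/8–pi/3), `b1`
  normalized so the state has unit sd under the actual excitation, `c1 =
  1`, `c3 ~ U(0.05, 0.15)`. The cubic stands in for the strong
  nonlinearity the EEG benchmark is known for; the surrogate's role is
  testability (known dynamics and noise floor), not biological fidelity;
* noise: measurement noise `e` with sd chosen so the achievable one-step
  VAF bound `100 (1 - sigma^2 / var(y))` lands in a target range (default
  92–96%, the accuracy regime of the reference study), plus state
  innovations `w` with sd 0.12 (about 1.5% of state variance). The process
  noise makes output lags genuinely informative and longer horizons
  genuinely harder — with measurement noise alone the state is a
  deterministic function of the input and recursive multi-step prediction
  would not degrade. It also means the closed-form bound is a slight
  overestimate of what any causal predictor can reach (by roughly 1.5–3
  VAF points at these settings), which the recovery checks absorb.

What passing synthetic tests does not show: robustness to non-stationary
dynamics, trial-to-trial variability, artifacts, or model mismatch beyond
the Wiener family — the generator has none of these.

## Problem sizes and numerical choices

Tests and the reproduction script run at desk scale as the package's own
choice of simulation size: 1–2 s signals (1 500–3 000 design rows per
participant), full grids for the noise-free recovery check and single-point
grids for multi-seed simulation studies (`fast_specs`). The GP uses a
fixed RBF kernel (no marginal-likelihood optimization) with the kernel
width on the `exp(-sigma ||dx||^2)` scale and a small grid over the nugget;
the MLP trains with seeded L-BFGS (400 iterations, tol 1e-6); the gradient
booster runs single-threaded coordinate descent so runs are bit
reproducible. A single global seed is fanned out through
`numpy.random.SeedSequence` to every learner, the tuner and the generator;
identical configuration plus seed reproduces every artifact byte for byte.

## Known limitations

* The meta-learner approximates Cubist semantics; rule sets will not match
  any specific Cubist release rule for rule.
* Base-learner grids bracket the reference study's selected values but the
  original grids are unpublished; selected hyperparameters on real data
  need not coincide.
* Free-run simulation (feeding back predictions indefinitely) is out of
  scope; the recursive strategy is implemented for finite horizons only.
* The synthetic noise bound is an upper bound, not the exact achievable
  VAF, once process noise is present (see above).
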