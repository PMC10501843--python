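# Methods

## Model and procedure

The split feasibility problem (SFP) is: given closed convex sets
`C = {w : c(w) ≤ 0}` and `Q = {v : q(v) ≤ 0}` and a matrix `A`, find
`w ∈ C` with `Aw ∈ Q`.  The solvers never project onto `C` or `Q`
directly.  At iteration `n` they build relaxations from one function
value and one subgradient at an anchor point `y`:

    C_n = {w : c(y) ≤ ⟨ϱ, y − w⟩ − (α/2)‖y − w‖²},   ϱ ∈ ∂c(y), α ≥ 0,

and likewise `Q_n` from `q` at `Ay` with curvature `β`.  Convexity of `c`
guarantees `C ⊆ C_n` for every anchor, so projecting onto the relaxation
never excludes a solution.  With `α = 0` the set is a half-space; with
`α > 0` completing the square turns it into the ball with center
`y − ϱ/α` and squared radius `‖ϱ‖²/α² − 2c(y)/α` (an empty ball —
negative squared radius — is a hard error: it signals an invalid
curvature choice, and there is no principled fallback).  The split
residual and its gradient are

    f_n(x) = ½‖(I − P_{Q_n})Ax‖²,    ∇f_n(x) = Aᵀ(I − P_{Q_n})Ax.

One iteration of the inertial modified relaxed CQ Mann scheme (`imrcqm`):

1. extrapolation factor `σ_n` (below); `ρ_n = ω_n + σ_n(ω_n − ω_{n−1})`;
2. `Q_n` anchored at `Aρ_n` with curvature `β`;
3. `y_n = ρ_n − λ_n ∇f_n(ρ_n)`;
4. `C_n` anchored at `y_n` with curvature `α`;
5. `t_n = y_n − λ_n ∇f_n(y_n)` (same `Q_n`); `z_n = P_{C_n}(t_n)`;
6. Mann average `ω_{n+1} = (1 − α_n) y_n + α_n z_n`.

The relaxed sets are defined with a single anchor sequence, which is
circular as written (`y_n` needs `∇f_n`, which needs `Q_n`, which is
anchored at `y_n`).  We anchor `Q_n` at `Aρ_n` — the only point available
when `Q_n` is first needed — and reuse it for the `t_n` step, while `C_n`
is anchored at `y_n`; the convergence analysis evaluates `∇f_n` at both
`ρ_n` and `y_n` against a single `Q_n` per iteration, which this choice
reproduces.

The comparison schemes: `dang` (inertial relaxed CQ,
`ω_{n+1} = P_{C_n}(ρ_n − λ∇f_n(ρ_n))` with the capped factor
`σ̄_n = min(σ, 1/max(n²‖Δ‖², n²‖Δ‖))`), `igrcq` (same update with the
self-adaptive step `λ_n = ε_n f_n(ρ_n)/‖∇f_n(ρ_n)‖²`), and `byrne`
(classic CQ with exact projections).  The printed form of the
self-adaptive step anchors `f_n` at `ω_n` while the update uses `ρ_n`; we
default to the `ρ_n` anchor so the step matches the gradient actually
taken, with `igrcq_step_anchor="omega"` switching to the literal form.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `sigma` | 0.9999 | base extrapolation factor, in [0, 1) |
| `lambda_rel` | 0.9999 | step = `lambda_rel / max eig(AᵀA)`, admissible in (0, 2) |
| `alpha_mann` | 1/1.2 | Mann averaging weight, in (0, 1) |
| `epsilon_n` | 0.1 | self-adaptive step factor, in (0, 4) |
| `curvature_c`, `curvature_q` | 0 | relaxation curvatures α, β (0 = half-spaces) |
| `tol` | 1e-10 | stop when the monitored residual falls below (0 disables) |
| γ | 7 (L1) / 17 (L2) | norm budget of the classifier's constraint set |
| M | 160 | hidden nodes of the ELM |

The Mann weight 1/1.2 reads a garbled printed value ("11.2") as a
collapsed fraction; it is configurable.  The curvatures default to 0 —
the experimental values are not recoverable from the source material, and
0 recovers the classic half-space relaxations.  The extrapolation factor
follows the decaying schedule

    σ_n = σ / (n² max{‖Δ_n‖², ‖Δ_n‖})   if n > N and Δ_n ≠ 0,   else σ,

with `Δ_n = ω_n − ω_{n−1}`.  The decay threshold `N` defaults to 0
(always decaying): the summability condition
`Σ σ_n max{‖Δ_n‖², ‖Δ_n‖} < ∞` that underwrites convergence is enforced
by comparison with `Σ 1/n² = π²/6` only on the decay branch, so a
positive `N` would leave the first `N` iterations uncovered.  `N` remains
configurable.  The branch condition compares `Δ_n` to zero exactly (the
schedule's own degenerate branch), not to an epsilon; consequently the
Mann average is computed as `y + α(z − y)`, which is exact when `z = y`,
so a solution is an exact fixed point and one ulp of rounding cannot
re-arm the extrapolation.

Stopping combines a residual tolerance with an iteration cap.  The
monitored residual is `f_n` at the gradient anchor (`y_n` for `imrcqm`,
`ρ_n` for the inertial comparisons, `ω_n` for the baseline).  Because the
residual is measured against the *relaxed* set, a large step
(`lambda_rel` near 2) can land inside the current half-space and produce
an exactly-zero residual at a non-solution; `tol = 0` therefore disables
the early stop entirely rather than matching such spurious zeros.

## The classifier

Training the ELM output weight is the constrained least-squares problem
`min ½‖Hw − R‖²` over an L1 ball (`c₁(w) = ‖w‖₁ − γ`) or L2 ball
(`c₂(w) = ‖w‖₂² − γ`), encoded as an SFP with `A = H` and the singleton
target set `Q = {R}` described by `q(v) = ½‖v − R‖²`.  Design choices the
source setting leaves open, fixed here once:

* targets are a single 0/1 column (malignant = 1), matching the binary
  cross-entropy loss and the 0.5 decision threshold;
* hidden weights and biases are drawn uniformly on [−1, 1] from a stated
  seed;
* features are standardized (z-scored with training-fold moments) before
  the hidden layer, the common ELM practice; toggleable;
* the final iterate receives one exact projection onto `C` before being
  stored, so the returned weight satisfies its norm budget at any finite
  stopping iteration (relaxed-CQ iterates are only asymptotically
  feasible); this is a no-op whenever the constraint is inactive;
* the L1 subgradient takes 0 at zero coordinates — a valid element that
  keeps the relaxation as large as possible and the oracle deterministic;
* raw network outputs are clipped to [1e-7, 1 − 1e-7] before the
  cross-entropy logarithm (ELM outputs are unbounded).

With the defaults (standardized features, 0/1 targets, M = 160, 300
iterations), the fitted weight stays far inside both norm budgets
(‖w‖₁ ≈ 2, ‖w‖₂² ≈ 0.07), so the L1- and L2-constrained runs coincide;
the budgets bind only for longer runs, larger targets, or unstandardized
features.  Validation loss/accuracy curves are produced by replaying the
solver's iterate trace against the held-out fold — how the original
figures were produced is unstated, and this is the only construction that
needs no extra training runs.  Note that with a zero initial weight the
raw outputs are 0, not 0.5, so the replayed loss starts near
`−log(1e-7)/2 ≈ 8` for balanced classes rather than `ln 2`; a `ln 2`
start would require outputs near 0.5, which the raw-output-clipping
convention cannot produce at `w = 0`.

Evaluation: accuracy, precision, recall, F1 in percent from pooled or
per-fold confusion counts (unweighted arithmetic mean over folds; the
aggregation convention of the source comparison is unstated, and both are
exposed).  One published rendering of the recall formula divides by
TN + FN; the standard TP/(TP + FN) is the default, with
`literal_recall=True` reproducing the printed variant.  Folds are
stratified and seeded via scikit-learn's `StratifiedKFold`.

## Synthetic data

`make_sfp_instance` draws a Gaussian `A`, plants `w*` at half the norm
budget (strictly inside `C`), and sets `Q` to a ball of radius 0.1 around
`Aw*` (or the singleton), so the solution set is nonempty by construction.
The ball default gives `Q` an interior, which is what makes finite-time
residual targets achievable for all four schemes.

`make_classification_table` draws two Gaussian clusters in the
five-attribute space (BI-RADS, age, shape, margin, density) whose pooled
marginals default to the published summary statistics of the real data
set (means 4.33, 55.78, 2.78, 2.81, 2.92; sds 0.63, 14.67, 1.24, 1.57,
0.35), with class means split ±separation/2 sds, default separation 1.0 —
chosen as a realistic overlap for this kind of clinical tabular data,
where the best published classifiers sit in the low-to-mid 80s percent
accuracy.  Ordinal attributes are rounded and clipped into their
published ranges; 445/961 positive prevalence by default.  What the
generator does **not** emulate: the correlation structure between
attributes (real BI-RADS, shape and margin are strongly dependent), the
ordinal measurement process, or the real missingness mechanism.  Passing
tests on this generator therefore demonstrate correctness of the
optimization and evaluation machinery, not clinical performance on the
real data.

## Problem sizes and numerical choices

The test suite and the acceptance script work at desk scale: 20×10 SFP
instances (10–20 seeds), 961-sample synthetic tables with M = 160 for
classification metrics, and 400-sample tables for the planted-separable
checks.  The pseudoinverse-agreement and plant-a-solution checks use a
compact hidden layer (M = 6, condition number of H below ~10²), because
at M = 160 the sigmoid features make `HᵀH` numerically singular and no
first-order method can reach the pseudoinverse residual in reasonable
iterations; with the compact layer the gap closes to ~1e-15 in 3·10⁴
iterations.  Operator norms come from an exact symmetric eigensolver on
the Gram matrix (`max eig(AᵀA)`) rather than a power method: the matrices
are small and the result deterministic.

## Known limitations

* Matrix-free (operator-only) problems and multiple-set SFPs are out of
  scope; `A` is a dense array.
* The residual-based stop is measured against the relaxed sets and can
  fire late on inconsistent systems (where the relaxed residual
  approaches a positive limit only slowly); use a fixed iteration budget
  for least-squares training.
* Replication of the original mammographic-mass benchmark numbers
  requires the external UCI download and depends on an unstated cleaning
  rule, target encoding, and unseeded hidden-layer initialization; with
  the documented cleaning (drop missing, drop out-of-range) the
  benchmark command reproduces the experiment's structure, and mid-80s
  accuracy is the plausible band, but exact figures are not
  reproducible from the published description.  This path is therefore a
  replication note, not a gated test.
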