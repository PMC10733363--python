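# Methods

## The dynamical system

`fracbc` models the interaction of five compartments in hormone-driven breast
cancer: cancer stem cells `C(t)`, tumor cells `T(t)`, healthy cells `H(t)`,
immune cells `I(t)` and excess estrogen `E(t)`. Stem cells grow logistically
with rate `k1` toward capacity `M1`, are killed by immune cells at rate
`gamma1`, and are promoted by estrogen through a saturating Michaelis–Menten
term `p1 E C / (a1 + C)`. Tumor cells are produced from stem cells
(`k2 C (C/M1) (1 − T/M2)`), die naturally (`n1`), are killed by immune cells
(`gamma2`) and are estrogen-promoted (`p2`, `a2`). Healthy cells grow
logistically (`q`, `M3`) and are lost to tumor crowding (`delta`) and
estrogen-induced DNA damage (`p3`, `a3`). Immune cells have a constant source
`s`, are recruited by the tumor (`rho`, half-saturation `w`), exhausted by
tumor load (`gamma3`) and by estrogen (`u`, `v`), and die at rate `n2`.
Excess estrogen is infused at constant rate `tau` and cleared by washout `mu`
plus absorption into the three cell compartments (`d1..d3`, saturating with
`a1..a3`).

Two modelling points deserve emphasis:

* **Estrogen balance.** The default clearance term is
  `dE = tau − (mu + Σ dᵢ Xᵢ/(aᵢ + Xᵢ))`, i.e. the bracket is *not*
  proportional to `E`. A mass-action variant in which the bracket multiplies
  `E` is available via `estrogen_bracket_times_E=True`; it changes the
  long-time estrogen behaviour (bounded instead of asymptotically linear)
  but not the fitting problem on the default window.
* **Fractional order.** The left-hand side uses a Caputo derivative of order
  `alpha ∈ (0, 1]`. The Caputo operator is chosen because it accepts
  classical initial conditions; `alpha = 1` recovers the ordinary system.
  The three registered cases share every rate constant and the initial state
  (1.2 in each compartment) and differ only in `alpha` ∈ {0.5, 0.7, 0.9}.

All 28 constants are validated on construction (finite, nonnegative,
denominator constants strictly positive). Negative *states* are not clipped:
an explicit solver may legitimately overshoot, and clipping would silently
change the dynamics. Only non-finite states and vanishing denominators are
errors.

## Fractional solver

`solve_caputo` implements the fractional Adams–Bashforth–Moulton
predictor–corrector (PECE) on a uniform grid: a fractional rectangle-rule
predictor over the full history,

    y^P_{n+1} = y0 + (h^α / Γ(α+1)) Σ_{j≤n} c_{n−j} f(y_j),
    c_k = (k+1)^α − k^α,

followed by a single fractional trapezoid-rule corrector evaluation,

    y_{n+1} = y0 + (h^α / Γ(α+2)) [ f(y^P_{n+1}) + a_0 f(y_0) + Σ_{1≤j≤n} a_{n−j} f(y_j) ],

with the standard corrector weights. The full history is kept (O(N²) work);
at the default N ≈ 100 this is negligible and avoids the bias of short-memory
truncation. One corrector pass per step keeps the scheme deterministic:
identical inputs give bitwise-identical trajectories.

**Integer-order reference.** At `alpha = 1` the weights degenerate to the
rectangle and trapezoid rules, so the scheme becomes an explicit trapezoidal
(Heun-type) predictor–corrector written in *cumulative quadrature form*
(both sums run from `y0`, not from the previous step). `solve_classical`
implements exactly that form, which makes the degeneration identity exact to
floating precision. Note this is not step-wise Heun: the two differ at
O(h²) per step because the cumulative predictor uses the rectangle sum of
corrected history values. Both are second-order accurate.

**Oracle.** The one-parameter Mittag-Leffler function
`E_α(z) = Σ z^k / Γ(αk + 1)` is evaluated with mpmath at elevated working
precision (the series alternates violently for negative arguments; naive
double-precision summation loses up to ~8 digits at `z = −5`).
`E_α(−t^α)` solves the linear test equation `D^α y = −y` and anchors the
solver's accuracy and convergence-order checks. Observed orders on that
equation at `t = 1` are ≈ 1.65 / 1.77 / 1.94 for α = 0.5 / 0.7 / 0.9,
consistent with the `min(2, 1+α)` regime (the endpoint sits away from the
origin singularity, so slightly above `1+α`).

**Default grid.** 101 nodes on `t ∈ [0, 1]` (`h = 0.01`). With the 82/9/9
division this yields 83/9/9 points. Both the window and the step are
configurable.

## Surrogate network and training protocol

The surrogate is a single-hidden-layer feed-forward network, one input (time),
15 log-sigmoid hidden units, five linear outputs — 110 free parameters.
Inputs and each output channel are min–max scaled to [−1, 1] before training
(a constant channel falls back to a unit-width map so scaling stays
invertible). All reported MSE values are computed in the *original* data
units after inverse scaling; `scaled_space_mse=True` switches the reports to
the scaled space.

Training is Levenberg–Marquardt on the training subset: solve
`(JᵀJ + μI) Δ = −Jᵀe` with the analytic Jacobian (verified against central
finite differences to 1e-9), accept the step iff the training SSE decreases,
then `μ ← 0.1 μ`; otherwise `μ ← 10 μ` and retry within the epoch, up to
`μ_max = 1e10` (stop reason `mu_max` if exhausted — never an exception).
Stopping criteria per epoch: MSE goal (0), gradient ∞-norm of the SSE
gradient `2Jᵀe` below 1e-7, 1000 epochs, or early stopping: six consecutive
epochs whose validation MSE fails to improve on the *previous* epoch
(the counter resets on any improvement). The returned weights are always
those of the epoch with minimal validation MSE (earliest epoch on ties).
The initial damping is 7e-5 (the protocol's "adaptive parameter").

Two design choices here were genuinely open and deserve their rationale:

* **Early-stopping counter.** Counting failures against the running *best*
  validation MSE (rather than the previous epoch) kills runs after 10–30
  epochs on this problem: near a plateau the validation trace oscillates
  gently above the incumbent best and six non-improvements accumulate even
  while the envelope is still decreasing. Counting consecutive
  non-improvements against the previous epoch lets runs live for hundreds
  of epochs — the regime in which the deep validation minima (1e-9 and
  below) are actually reached. Since returned weights are from the best
  validation epoch, the longer run never worsens the result.
* **Initialization.** Solutions of Caputo systems behave like
  `y0 + c t^α` near `t = 0`: an unbounded derivative confined to a thin
  boundary layer. With the classical Nguyen–Widrow layout (transition
  centers uniform over the window) the 15-unit network almost never
  resolves this layer before training stops, and the fit error concentrates
  at the first few nodes. The default `boundary-layer` scheme therefore
  seeds half the units Nguyen–Widrow-style and places the other half with
  transition centers log-uniform in the first ~20 % of the window, slopes
  inversely proportional to their offset. Pure Nguyen–Widrow remains
  available (`init_scheme="nguyen-widrow"`) and is used in the
  teacher–student tests, where targets have no boundary layer.

**Restarts.** A training run is cheap (≲ 1 s), and the end-to-end pipeline
runs `n_restarts` fully independent runs, each redrawing *both* the 82/9/9
division and the initialization — the behaviour of interactive fitting
tools, where every retrain re-divides the data. The reported
"best validation performance" is the minimum over restarts of each run's own
best validation MSE. The *winning weights*, used for all output-vs-reference
metrics, are chosen by smallest all-node MSE against the reference
trajectory rather than by validation MSE alone: with only 9 validation
points and a network containing sharp units, the validation minimum can be
reached by pathological interpolators that are wrong between validation
points, so validation MSE is an over-optimistic selector. Selecting against
the full reference is legitimate here because the reference is the known
object being emulated, not held-out data.

## Evaluation

`build_report` aggregates, in original units: per-subset MSE; overall,
per-subset and per-channel regression R (Pearson correlation of flattened
outputs vs targets — affine-invariant, 1 for a perfect fit); a 20-bin
equal-width residual histogram with the midpoint of the bin containing zero
(the "zero error" annotation of toolbox histograms); per-channel maximum
absolute error against the reference trajectory; and the stop-state of the
training record (gradient, μ, epochs, stop reason). The report is a pure
function of its inputs.

## What the generator emulates — and what it does not

The synthetic data are exact solver output: noise-free, uniformly sampled,
single-trajectory. Passing tests therefore demonstrate that the pipeline
reproduces the *surrogate-modelling* behaviour (solver fidelity, training
dynamics, metric bookkeeping) under ideal data. They say nothing about
measurement noise, irregular sampling, model misspecification or parameter
estimation from real tumor data — all out of scope. The validation MSE of a
9-point subset drawn from a noise-free curve is an optimistic quantity; it
is reported because it is the protocol's headline number, but the absolute
error against the full reference is the better fidelity measure.

## Numerical choices and degenerate inputs

* Weights/biases and all solver arithmetic in float64; the Mittag-Leffler
  oracle uses elevated precision internally and returns float64.
* LM normal equations solved by Cholesky with μ-escalation on failure;
  μ is floored at 1e-20 after decreases.
* Histogram of identical residuals: one populated bin of width
  `max(|v|,1)·1e-9` centered on the common value.
* Regression R with constant targets raises (undefined) rather than
  returning NaN.
* `max_epochs = 0` returns the initial weights with stop reason `epochs`.
* Trajectory blow-up (non-finite state) raises `SolverBlowUpError` naming
  the step and stage, never returns garbage.

## Problem sizes

The shipped configuration solves 101-node trajectories and trains 110-weight
networks on 83 training points; a full 10-restart case run takes a few
seconds on one CPU core, and the 20-restart validation-performance
measurement under a minute. These sizes are the package's study conditions,
chosen to match the 82/9/9 division arithmetic; both grid and restart count
scale up linearly in cost if a user wants denser sampling.

## Known limitations

* The t^α boundary layer limits a 15-unit network: per-channel maximum
  absolute error for the α = 0.5 case typically lands at 1e-6..1e-4, with
  occasional unlucky restart sets slightly above 1e-4.
* The solver keeps full history (O(N²)); for N ≫ 10⁴ a fast-convolution or
  short-memory variant would be needed.
* `regression R` is reported to six decimals; at these error levels it is
  saturated at 1.000000 and carries little discriminating power — the MSE
  and absolute-error numbers are the informative ones.
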