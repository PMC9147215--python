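# Methods

## The modeling problem

A comprehensive metabolic panel is drawn from a patient at irregular
intervals — here on the order of 40 draws over a year — and reports, among
others, nine indices with low missingness: glucose, BUN, creatinine, anion
gap, CO2, chloride, sodium, potassium and calcium.  `panelcast` treats these
nine indices as the state vector of a patient-specific discrete dynamical
system and learns its transition map from the patient's own history with a
stacked LSTM recurrent network, so that the fitted model can trace the
recorded trajectory and forecast the next half-day step (or a few steps)
ahead.

## Preprocessing

The pipeline order is fixed and enforced:

1. **Imputation.** A missing interior value of index *j* at visit *i* is
   replaced by the mean of its two nearest visit neighbors,
   (x[i−1,j] + x[i+1,j]) / 2.  Two consecutive interior missing values in
   one index are rejected rather than chained.  A missing boundary value
   (no second neighbor) takes the single nearest neighbor's value; this
   case is logged, as it extends the neighbor-mean rule.
2. **Winsorization.** Per index, the mean μ and sample (n−1) standard
   deviation σ are computed once over the visit rows; values outside
   μ ± 2σ are set to the nearer bound in a single pass.  The unbiased σ is
   used for consistency with the standardization step.  Note that
   moment-based winsorization is *not* idempotent under recomputed
   statistics — clipping shrinks both moments, so a second pass with
   freshly computed μ, σ would clip further.  Re-applying the *same*
   thresholds is exactly the identity, and `winsorize` accepts an explicit
   `stats=(mu, sigma)` pair for that purpose.  Winsorization statistics
   always come from the visit rows, never from the interpolated grid.
3. **Interpolation.** First-order (piecewise-linear) interpolation
   resamples the visit series onto a uniform grid of step 0.5 days running
   from the first to the last visit date inclusive.  For a whole-day span
   *D* the grid holds 2·D + 1 rows; the reference configuration (42 visits
   spanning 369 days) yields 739 rows.  Grid points that coincide with
   visit dates reproduce the visit values exactly.
4. **Split.** The grid is divided chronologically in a 9:1 ratio:
   the first floor(0.9·n) rows train, the rest test (739 → 665/74).
   No shuffling.
5. **Standardization.** Per index, μ_j and the unbiased σ_j of the
   *training rows only* define the map x̃ = (x − μ_j)/σ_j.  Test rows are
   standardized with the training statistics; predictions are mapped back
   by ŷ = ȳ·σ_j + μ_j before any metric is computed.

A reporting step computes the full pairwise correlation matrix of the
interpolated grid and flags any pair with |r| ≥ 0.80; a flagged pair would
suggest one index is redundant as a state variable.

## Window constructions

From the standardized series x_1..x_n three supervised designs are built
(T = window length, S = stack number, L = horizon; S > 1 and L > 1 are
never combined):

* one-step: input (x_i..x_{i+T−1}), target x_{i+T}; N = n − T pairs;
* input-stacked: tokens X_i = [x_i..x_{i+S−1}] (9S-vectors), input
  (X_i..X_{i+T−1}), per-step targets (x_{i+S}..x_{i+T+S−1});
  N = n − T − S + 1;
* multi-step: input as one-step, target the next L vectors flattened;
  N = n − T − L + 1.

Pairs are built on the **full** series and then partitioned by where their
targets fall: a test pair's targets lie entirely beyond the train/test
boundary while its inputs may reach back into training rows.  On the
739/665 reference split this gives 665 − T training pairs and exactly 74
test pairs for every T in 1..10.  Pairs whose targets straddle the boundary
(possible when S > 1 or L > 1) belong to neither side.

## Model

Each LSTM cell applies the standard forget/input/output-gate recurrence
with candidate state tanh and zero initial hidden/cell state; two cells are
stacked in series (cell 2 consumes cell 1's hidden sequence; a deeper stack
is a config option), and a fully connected head maps the top hidden state
to the output — the final state for the one-step and multi-step designs,
every step's state for the sequence-output stacked design.

Design choices where the design was genuinely open:

* **Output activation is linear** by default.  A sigmoid head cannot reach
  zero-mean standardized targets, which lie outside (0, 1); the sigmoid
  option is retained as a config flag for squashed-output experiments.
* **Hidden width 64** per cell: small enough to train on ~700 grid points
  in seconds on one CPU, ample for a 9-channel state.
* **Head is a single affine layer** by default; extra tanh layers are a
  config option.
* Initialization is uniform in ±1/√hidden, seeded.

The forward/backward passes are implemented directly in NumPy: exact
backpropagation through time across the stacked recurrence and head.  Two
independent correctness anchors are tested: a deliberately scalar,
loop-based reference implementation of the cell recurrence (the vectorized
forward must agree to ≤1e−6; measured agreement is ~1e−10), and central
finite differences for every gradient path (agreement ~1e−9).

## Training protocol

Mini-batch Adam (batch 16, learning rate 0.001, customary moment
parameters), batches reshuffled each epoch under a seeded stream.  The
loss is the mean squared error per scalar element: for a one-step batch
(1/M)·Σ‖x̂ − x‖²/9, divided by 9L for multi-step targets, and by 9T with an
additional average over pairs for the sequence-output design.

After every epoch whose full-training-set loss falls below the tolerance
ε (0.01 one-step, 0.05 stacked, 1 multi-step), the test loss is evaluated
and the parameters snapshotted; after the fixed epoch budget (default 300)
the snapshot with minimal test loss is returned.  If ε is never reached the
final-epoch model is returned with a warning flag rather than an exception.
Test pairs contribute no gradients; the suite asserts that replacing the
test targets leaves the training trajectory bit-identical.

The time-step sweep trains one model per T, tabulates the dimensional
relative L1 (mean over indices) and relative L∞ (max over indices) test
errors, and selects the T minimizing a configurable metric (default the
worst-case relative error).

**Transfer learning** initializes a new patient's model from a trained
master's weights and retrains *all* parameters under unchanged
hyperparameters on the new patient's pairs, standardized with the new
patient's own training statistics.  Epochs-to-tolerance is recorded so warm
and cold starts can be compared; on paired synthetic patients the warm
start reaches tolerance in roughly a third of the cold-start epochs in the
median.

## Evaluation

Per index, after de-standardization: RMSE, Nash–Sutcliffe efficiency
(1 − SSE/SST against the observed mean; exactly 1 for a perfect predictor
and exactly 0 for the constant-mean predictor), relative L1 error
(mean |y − ŷ|/|y|, the MAPE) and relative L∞ error (the max).  Multi-step
predictions pool all L horizons into one number per index by default, with
a per-horizon breakdown behind a flag.  Relative errors are undefined when
an observation is zero; such indices are flagged and RMSE/NSE still
reported — the familiar failure mode of ratio metrics on near-zero
analytes.  RMSE and the relative errors are scale-dependent and therefore
only meaningful after de-standardization; NSE is affine-invariant, and the
suite asserts both facts.

## Synthetic data

Real panels are protected health information, so the generator emulates
their structure, not any particular patient:

* **Visit dates**: day 0 and day `span_days` fixed, interior dates drawn as
  distinct integer days (guaranteeing the 1-day minimum gap), default 42
  visits over 369 days.
* **Values**: a stationary first-order vector autoregression with
  transition φI (φ = 0.3) and innovation covariance (1 − φ²)·Σ, so the
  stationary covariance equals Σ = D·R·D for the target correlation R and
  index scales D.  Σ is factored spectrally; a non-positive-semi-definite
  target is rejected naming the offending eigenvalue.  Default means and
  standard deviations are order-of-magnitude plausible per index (e.g.,
  sodium 138 ± 2.5 mmol/L, creatinine 0.6 ± 0.15 mg/dL) with no claim of
  clinical realism.
* **Default correlation target**: a metabolic-panel-like pattern (glucose
  anticorrelated with CO2 and calcium, BUN with chloride, max magnitude
  0.79) shrunk towards the identity by a factor 0.75.  The shrinkage is
  deliberate: at 42 visits the empirical correlation of the *interpolated
  grid* overshoots the latent target substantially (interpolation weights
  long gaps heavily and the sampling noise of r at this n is ~0.2), so the
  deflated latent target makes the observed grid correlations land at the
  intended moderate magnitude, typically peaking just below the 0.80
  collinearity bar.  Isolated realizations can still exceed it — an
  irreducible small-sample effect the correlation screen is there to
  surface.
* **Pathologies**: exactly `missing_cells` cells masked (never in the first
  or last row, never two consecutive in a column, so the imputation rule
  always applies) and `outlier_cells` values displaced by 6 column-SDs, far
  enough that a single 2σ pass provably clips them even after they inflate
  the column moments.

What the generator does **not** emulate: treatment events and their
physiological aftermath, circadian or assay effects, level shifts,
heavy-tailed measurement error, or informative visit timing (sicker
patients are drawn more often in reality).  Passing tests on this generator
therefore demonstrate that the pipeline's arithmetic, training protocol and
transfer mechanics behave as specified — not that forecasts of this quality
are attainable on real clinical data.

The **toy dynamical system** used for forecast-recovery tests is a
noiseless 4-dimensional latent state (two weakly damped planar oscillators
with incommensurate periods, ~20- and ~8.5-day cycles on the 0.5-day grid)
observed through a fixed full-column-rank linear readout centered at the
clinical baselines.  The next observation is an exact linear function of
the current one, so a competent one-step forecaster can reach near-zero
error while a persistence forecast cannot; the exact map is available as an
oracle (`toy_true_onestep_map`).

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at the reference
configuration (739 grid points, 665/74 split).  Forecast-recovery training
uses the full 300-epoch budget; the warm/cold transfer comparison uses 5
paired patients with a 60-epoch cap, chosen because tolerance is reached by
epoch ~25 in every observed run, warm or cold.  Ties in the time-step sweep
resolve to the smallest T (first minimum).  Degenerate inputs are rejected
with named errors: constant training columns (σ = 0) for standardization,
series too short to window or split, batch sizes exceeding the pair count.
Constant columns in winsorization are a logged no-op rather than an error,
since clipping a constant is well-defined as the identity.

## Known limitations

* Linear interpolation manufactures correlated in-fill between visits; the
  739-point grid has far fewer than 739 independent observations, and test
  error on interpolated segments flatters the model relative to true
  held-out draws.
* Metrics are point estimates; no bootstrap or other uncertainty is
  attached.
* The sequence-output stacked design shares its evaluation path with the
  others by pooling per-step predictions; per-step weighting schemes are
  out of scope.
* Training is plain NumPy on one CPU; it is fast at this problem size
  (seconds per model) but not built for wide hyperparameter searches.
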