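# Methods

`rfctx` implements and compares two families of receptive-field (RF) models
for spiking sensory neurons driven by binary bar stimuli: **context models**
(an RF whose elements are multiplicatively gated by local stimulus context)
and **multifilter linear-nonlinear (LN) models** (a low-dimensional stimulus
subspace followed by a free nonlinearity).  It also provides bias-corrected
single-spike-information evaluation and a leaky integrate-and-fire (LIF)
complex-cell simulator that generates all test data.

## Stimulus representation

The stimulus is a binary bar array (16 bars by default) refreshed at 60 Hz.
The model input for frame *t* is the space-time window covering the most
recent `n_lags = 16` frames (267 ms), flattened **bar-major** — index
`j = bar * n_lags + lag`, with lag 0 the oldest frame and the most recent
frame in the last lag column.  Frames with incomplete history are dropped, so
a stimulus of `n` frames yields `n - n_lags + 1` samples, each paired with
the spike count of its final frame.

Raw bar values are ±1.  The *bright* basis codes bright bars as 1 and dark as
0; the *dark* basis reverses this; the concatenated bright+dark basis stacks
both, doubling the bar dimension into a space-time-intensity input on which a
double-CF context model can mark bright and dark sensitivity separately.
Context windows never cross the bright/dark plane boundary.

## Context models

The similarity score of a context model with context fields (CFs) indexed by
*l* is

    z_i = w0 + sum_l sum_{j in ctx_l} w_j^rf x_ij (1 + sum_k w_k^{cf_l} x~_ijk)

where `x~_ij` is the local context patch around stimulus element `x_ij`.  The
same score can be written linearly in the RF (CFs fixed) or linearly in the
CFs (RF fixed); the two representations agree identically and both are used
by the fitter.  Setting all CF weights to zero recovers the ordinary linear
score of an LN model.

**Context window.**  Default 9 bars x 9 lags.  The origin — the cell of the
window aligned with the RF element being gated — sits at the spatial center
and three elements in from the right (most recent) edge, leaving two columns
for the immediately following frames, whose stimuli can still suppress or
enhance the response.  The CF coefficient at the origin is structurally fixed
to zero so that the field carries interaction terms only.  Cells outside the
stimulus are zero-padded; zeros contribute nothing to CF dot products, so
padding never changes interior context vectors.

**Fitting.**  The joint problem is nonconvex, but with either field held
fixed the other solves a convex generalized-linear subproblem.  The
alternating fitter iterates RF-step / CF-steps with the data term scaled by
`C = 0.1` until the relative loss decrease falls below 0.01%, then runs one
final iteration in which `C` is chosen for each step by 5-fold
cross-validation on the training data (contiguous folds; grid
10^-3 … 10^2, 11 logarithmic points; ties go to the smallest, most
regularizing `C`).  CV is performed independently for the RF step and each CF
step.  Subproblem families:

* *linear* — identity nonlinearity; closed-form ridge solution
  `w = (A'A + Γ'Γ/(2C))^-1 A'(y - k)` (pseudoinverse fallback, flagged, if
  the unregularized system is singular);
* *logistic* — signed targets `y~ = -1` iff `y = 0` and per-sample weights
  `β = max(y, 1)` so multi-spike frames count multiple times;
* *poisson* — exponential nonlinearity.

The logistic/Poisson subproblems are solved by a damped Newton method with
backtracking line search, using the analytic gradient and Hessian and the
per-sample offset `k_i` (the fixed-field contribution) inside the score —
that offset is why generic GLM solvers cannot be dropped in.  Solver
tolerance 1e-3; at most 100 outer iterations (a safety bound, normally
unreached).  The training objective is checked to be non-increasing across
outer iterations; an increase aborts the fit with diagnostics.

**Initialization.**  RF from a regularized GLM fit with zero CFs (this is
simply the first RF-step); CF weights start at zero plus tiny seeded jitter
(sd 1e-3) to escape the degenerate all-zero-CF stationary point.

**Regularization.**  `Γ` is either the identity (l2) or the 2-D discrete
Laplacian over the field grid with one-sided (Neumann) boundary stencils,
which penalizes roughness and annihilates constant fields.  The bias
coordinate is never penalized.

**Sign convention.**  RF/CF products make jointly sign-flipped fields
near-equivalent solutions.  When a fit ends with `|min(RF)| > max(RF)`, both
fields are negated and the fit rerun to completion (`flip_and_restart`).

**Double-CF intensity models.**  On the concatenated bright+dark design the
model is fitted in two stages: first with a single CF shared by all RF
indices, then with two CFs (one per intensity plane) initialized from the
shared solution.

## Multifilter LN models

* **STA/STC** — count-weighted spike-triggered mean and covariance.  STC
  filters are eigenvectors ranked by |eigenvalue − stimulus variance|, so
  both variance-expanded (excitatory) and variance-shrunk (suppressive)
  directions rank first.  *Null filters* are the eigenvectors with
  eigenvalues closest to the stimulus variance; they carry (approximately) no
  information and calibrate the estimation bias (below).  Binary bar stimuli
  violate the Gaussian assumption behind STC; the estimator is applied as-is
  and the evaluation stage reveals the consequences.
* **iSTAC** — greedy sequential search for an orthonormal basis maximizing
  the Gaussian single-spike information
  `I = [Tr(B'(Λ+μμ')B) − log|B'ΛB| − m] / (2 ln 2)` bits, i.e. the KL
  divergence between N(B'μ, B'ΛB) and N(0, I) under a whitened stimulus.
  Each new column is seeded from the best of the STA direction and the
  leading STC eigenvectors and polished by projected gradient ascent with QR
  re-orthonormalization (500-step cap, tolerance 1e-6).  Whitening is the
  caller's responsibility; the pipeline z-scores the design first.
* **MNE / low-rank QN** — logistic model of spiking with score
  `z = c + x'v + x'Jx`, fitted by L-BFGS on the weighted logistic likelihood
  with l2 penalties on `v` and `J` (never materializing the n x d² feature
  matrix; `J` is kept symmetric).  A fixed filter count is obtained by taking
  the `n−1` eigenvectors of `J` with the largest |eigenvalue|, projecting
  them out of `v`, and letting the last filter be the `v`-residual or the
  next eigenvector, whichever carries more information.  The diagonalized
  filters are then refined by gradient descent on the same loss, with the
  regularization strength and the stopping point chosen on a hold-out
  validation set.  The first-stage `C` is chosen by training-set performance
  (it yields structured rather than noisy filters); the refinement is robust
  to that choice.

## Single-spike information and MID

The single-spike information of a (1-D or 2-D) score `z` is

    I = sum_bins P(z|spike) log2[ P(z|spike) / P(z) ]   (bits/spike)

with both distributions estimated by histograms on shared edges; every sample
contributes once to P(z), and sample *i* contributes `y_i` times to
P(z|spike).  Histogram estimation restricts direct use to at most two score
dimensions.

MID refinement maximizes I directly by gradient ascent from any initial model
(STC, iSTAC, MNE, or a fitted context model).  The gradient uses bin-wise
conditional mean score-gradients and a finite-difference derivative of the
density ratio across bins; for LN filters the score gradient is the stimulus
projection, for context models the RF/CF design rows.  Declared defaults: 15
bins per dimension during ascent (coarser than evaluation, to tame gradient
noise), step `0.05 ‖θ‖/‖∇‖` with geometric backoff, at most 200 steps.
Early stopping: the returned iterate is the one with the highest
validation-set information, so refinement never ends below its
initialization on that measure.

## Evaluation

**Nonlinearity.**  `f(z) = P(spike) P(z|spike) / P(z)` on 20 bins per
dimension (20 parameters for 1-D scores, 400 for 2-D).  Empty bins inherit
the global mean rate; out-of-range test scores clamp to edge bins.  By
construction `sum_b f(b) p_z(b)` equals the mean training rate.

**Bias-corrected information.**  Naive histogram estimates are biased upward,
increasingly so with resolution and dimensionality.  The null-feature
correction measures the apparent information of null-filter projections as a
function of the average number of occupied bins in P(z) and P(z|spike),
interpolates that curve (linear, constant extrapolation) at the occupancy of
the score being evaluated, and subtracts.  The final estimate is the mean of
corrected values over resolutions 25–35 bins per dimension; 10 null features
by default.  The alternative quadratic-extrapolation (QE) correction fits
naive I against 1/N over random subsamples (fractions 1.0 … 0.5, 10 repeats,
seeded) and keeps the 1/N → 0 intercept.  The two methods agree on synthetic
scores; QE fluctuates more.

**Protocol.**  Five-fold training/testing with contiguous temporal blocks
(respecting temporal dependence); within the four remaining folds the first
80% is training and the last 20% validation, so 1,000 usable samples split
200 / 640 / 160 (test/train/validation).  Reported values are per-fold test
information (bias-corrected) and Pearson correlation between predicted and
observed counts, plus mean ± SE.  Cross-model tables divide each model's
score by the per-cell best (`I/Imax`, `r/rmax`).

## The simulator

`simulate_complex_network` realizes the hierarchical description of a
complex cell: `n` LIF input cells with identical but spatially shifted linear
RFs drive one LIF output cell through excitatory synapses.

* **LIF constants** (declared defaults, config-exposed): membrane τ = 20 ms,
  rest/reset 0, threshold 1, refractory 2 ms, dt = 1 ms.  Input drive is the
  template-stimulus dot product per frame, scaled by a gain.
* **Input RF template**: Gabor-like, center-surround over 3 bars
  ([−0.5, 1, −0.5]) and biphasic over 10 frames (167 ms), peaking just before
  the present with an earlier opposite-sign rebound.  The temporal extent
  deliberately exceeds the 9-lag context window, so neither model family can
  trivially absorb the full input kernel.  Nine inputs shift the template by
  one bar each, centered on the 16-bar array; the simplified two-input
  variant uses bank positions 4 and 6 with depression off.
* **Depressing synapses**: release fraction u = 0.9, recovery
  τ_rec = 200 ms; recovery uses the exact exponential solution so periodic
  drive reproduces the closed-form steady state.  On a spike the output
  membrane receives an instantaneous kick `weight · u · R` (or `weight` with
  depression off).
* **Rates**: the declared gains/weights (9-input: gain 2.2, weight 0.7;
  2-input: gain 0.7, weight 1.5) put the output in a sparse, strongly
  stimulus-locked regime (a few spikes per second), where the per-spike
  information of the output is high and the contrast between the model
  families is expressed clearly.
* Output spikes are binned per stimulus frame.  Fixed seeds make every run
  bit-identical; the inner loop is compiled with numba when available, with
  an equivalent numpy fallback.

What the simulator emulates: the geometry and statistics of pseudo-random
bar experiments (16 binary bars, 60 Hz, 10^4–10^5 frames) and the two
network motifs — pooling of shifted subunits with depressing synapses, and a
genuinely two-dimensional relay.  What it does not emulate: membrane noise,
trial-to-trial variability, adaptation beyond synaptic depression,
extraclassical surrounds, or correlated natural stimuli.  Passing tests on
these data therefore demonstrate correct estimation under the stated
assumptions, not performance on real recordings.

The generic `generate_ln_poisson` / `generate_context_poisson` helpers draw
Poisson counts from a known model and are used for parameter-recovery tests.

## Benchmark experiments

`rfctx.benchmarks` runs the two headline experiments at 50,000 frames
(~14 min of stimulus): simulate a network, split 64/16/20% into
train/validation/test blocks, fit a single-CF context model (linear family,
l2, final cross-validated C) and a two-filter LN model (centered STA plus
leading STC deviation eigenvector, refined by MID), and report each model's
bias-corrected held-out information.  On the depressing nine-input network
the context model wins clearly and its CF shows the input template with an
opposite-sign trailing tail — the signature of synaptic depression; that
tail shrinks sharply when depression is switched off.  The `cf_tail_energy`
statistic quantifies this: it locates the template subfield (the
largest-magnitude cell in the rightmost third of the CF window), averages
the opposite-sign weight over the earliest quarter of the lag columns in the
same row, and normalizes by the subfield peak.  The earliest lags are used
because the input template's own biphasic rebound also produces a short
opposite-sign region; only the depression tail persists to the far end of
the window (its recovery constant, 200 ms, spans twelve frames).  On the two-input relay the situation reverses: the
mapping is two-dimensional and the two-filter LN model's free 2-D
nonlinearity beats the context model's one-dimensional score.

A note on problem sizes: simulations use 50,000 frames and recovery tests
8,000–30,000 frames; these sizes give stable fits on a single CPU while
keeping the full suite fast.

## Numerical choices and limitations

* Histogram edges span the observed score range; constant scores occupy a
  single bin and carry zero information by convention.
* The CV score is the held-out subproblem data loss; contiguous folds.
* `solve_glm_subproblem` clips scores at ±500 inside exp/logistic terms as
  an overflow guard (inactive at fitted scales).
* The alternating fitter's loss trace is reported for the fixed-C phase;
  after the final CV iteration the objective is no longer comparable across
  C values.
* Eigen-selection in the low-rank QN model is invariant to eigenvector sign;
  score terms are quadratic in the filters.
* Known limitations: MID is restricted to ≤ 2 histogram dimensions; STC and
  iSTAC inherit their Gaussian-stimulus assumption and underperform on
  binary stimuli; the MNE fit over all of `J` is quadratic in dimension and
  is intended for designs up to a few hundred dimensions.
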