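# Methods

This note documents the models, procedures and numerical choices behind
`spikedecode`: what each component assumes, which knobs matter, and what the
synthetic benchmarks do and do not establish about real recordings.

## Problem setting and data formatting

Decoding means predicting a continuous behavioral variable (2-D cursor
velocity, 2-D position, ...) from the simultaneous spiking of N neurons.
Both signals are discretized into bins of length R seconds: spike counts per
bin per neuron, and the within-bin mean of the output samples.  Each output
bin is predicted from a window of B neural bins — `bins_before` preceding
bins, optionally the concurrent bin, and `bins_after` following bins —
so the usable output bins number K = n_bins − bins_before − bins_after.

Two layouts serve the two decoder classes: a flat K × (N·B) design matrix
(column order: lag-major, neuron-minor) for regression-style decoders, and
a K × N × B tensor for recurrent networks, which consume the window one bin
at a time.  Flattening the tensor lag-major reproduces the design matrix
exactly; this identity is enforced by tests.

Conventions chosen where several were defensible:

- Bins are half-open [tR, (t+1)R); a spike exactly on a boundary belongs to
  the later bin; a trailing partial bin is dropped (spike conservation over
  full bins plus remainder is asserted exactly).
- Output bins with no samples are filled by linear interpolation between
  neighboring filled bins; leading/trailing gaps hold the nearest value.
  This preserves the continuity that state-space decoders assume.
- Counts, not rates, are stored; conversion to rates happens only where a
  decoder needs it.

Preprocessing is strictly fold-local: the input z-score and the output
centering are estimated on training rows only and applied unchanged to
validation and test rows; predictions are mapped back to original units
before scoring.  SVR additionally z-scores its regression target internally
(it helps the epsilon-insensitive loss) and inverts the transform on
predict.

## Decoders

**Wiener filter** — ordinary least squares from the lagged counts to the
output, intercept always included.  Rank-deficient designs fall back to the
least-norm solution with a warning.  An optional ridge penalty is exposed as
a hyperparameter but defaults to 0.

**Wiener cascade** — per output dimension, the Wiener filter followed by a
static polynomial (default degree 3, search range 1–5) fitted by least
squares on the Vandermonde expansion of the stage-1 training predictions.
Because the polynomial family contains the identity, the cascade's training
MSE never exceeds the linear stage's; degree 1 reproduces the Wiener filter
exactly.

**Kalman filter** — the hidden state is the kinematics itself: for d output
axes, position, velocity and acceleration per axis (s = 3d; derivatives by
central finite differences over the bin grid, one-sided at the edges).
A, W, H, Q are estimated by least squares and residual covariances on
training data.  Decoding runs the standard predict/update recursion from
the training-mean state and training state covariance.  Two hyperparameters:
`noise_scale` (C) multiplies the fitted transition noise W at decode time
(C = 1 is the classical decoder; larger C lets the filter weight the spikes
more than the smoothness prior), and `lag` shifts the pairing between
neural observations and kinematic state by −2…+2 bins.  After each update
the covariance is symmetrized, and eigenvalues are clipped at zero (with a
warning) if roundoff drives it indefinite.

**Naive Bayes** — a Bayesian population decoder.  Output space is
discretized (100 cells in 1-D, 30 × 30 in 2-D by default — chosen to keep
exhaustive posterior evaluation cheap); each neuron's tuning curve is the
occupancy-normalized mean count per decoding window, Gaussian-smoothed over
the grid (bandwidth 1 cell by default, a hyperparameter), floored at 0.01
expected counts per window to avoid log 0.  Spike counts are summed over the
same lag window the other decoders see.  Under a Poisson likelihood and
conditional independence across neurons the log posterior of grid cell g is
`sum_i [n_i log f_i(g) − f_i(g)] + log P(g)`, computed in log space
throughout; the prediction is the grid value at the argmax (ties: lowest
index).  An optional Gaussian transition prior penalizes squared distance
from the previously decoded value, with bandwidth defaulting to the
training data's per-bin displacement RMS.

**Learned decoders** — SVR (RBF kernel; per-output-dimension fits; C is the
main hyperparameter; the solver iteration cap defaults to 4000, which on
desk-scale problems reaches the same accuracy as running to convergence in
a fraction of the time) and gradient-boosted regression trees
(per-output-dimension; depth/trees/learning-rate hyperparameters) delegate
to scikit-learn and XGBoost.  The feedforward network (two equal-width ReLU
hidden layers, dropout after each, linear readout of all outputs jointly)
and the simple RNN, GRU and LSTM (one recurrent layer reading the B-bin
window; the final hidden state is linearly mapped to the output) are
implemented in numpy inside the package, with hand-written backpropagation
(through time) verified against finite differences in the test suite.  All
networks minimize mean squared error with Adam (learning rate 3e-3,
minibatch 128, 10 epochs and dropout 0.3 by default — dropout matters: on
~10^4-sample training sets the undropped networks memorize the training
data and lose ~0.1 R² on held-out blocks).  Exposed hyperparameters and
search ranges: units 50–1000, dropout 0–0.5, epochs 2–20 for all networks;
depth 2–8, trees 100–1000, learning rate 0.01–0.3 for boosted trees;
C 1–10^4 for SVR.  Network fits are bit-reproducible given the seed.

**Ensemble** — the predictions of the eight flat/sequence decoders (the
Kalman filter and Naive Bayes are excluded; their input conventions differ)
are stacked into a K × 8d matrix and fed to a second-tier model, by default
a one-hidden-layer feedforward network, optionally plain least squares.
The stacker is always trained on predictions made for rows the bases did
not train on; inside cross-validation this is the fold's validation block.
Training it on base training-set predictions would systematically favor
overfit bases.

## Evaluation protocol

**Score.**  R² = 1 − SS_res/SS_tot per output dimension (fraction of
variance accounted for, not a squared correlation), averaged over
dimensions.  It is negative whenever the decoder does worse than predicting
the test-set mean — common on held-out blocks of autocorrelated signals.

**Splits.**  J-fold cross-validation over the K design rows with contiguous
validation and test blocks.  The test block always spans K/J rows and
rotates from the end of the recording backwards, so the J test blocks tile
the rows exactly once; the validation block (10% of rows) sits immediately
before the test block (after it when the test block is at the start);
training is the remainder.  J = 10 gives the 80/10/10 plan.  For J = 2 a
10% validation share is no longer meaningful next to a 50% test block, so
the remainder is split evenly (25/25/50) with a warning.

**Uncertainty.**  Across folds the SEM is σ·sqrt(1/J + 1/(J−1)) — the
overlap of training sets across folds makes the naive σ/√J an
underestimate.  For a single test set, confidence intervals come from a
block bootstrap: the test rows are cut into 20 contiguous segments and
resampled with replacement 1000 times; percentile intervals of the
resampled R² respect the temporal correlation that plain row-resampling
would destroy.  Default level 95%; 68% (≈ SEM) available.

**Hyperparameter search.**  Selection maximizes validation-set R² only;
the test block is scored exactly once per fold, after selection.  Three
strategies: grid, random, and Bayesian optimization (Gaussian-process
surrogate with a Matérn-5/2 kernel and expected-improvement acquisition
over the unit-cube-encoded space; integer and categorical parameters are
rounded/indexed).  The full evaluation log is returned.

## Synthetic benchmarks

The generators provide ground-truth datasets with the summary statistics of
typical recordings, so every decoder and evaluation procedure can be
exercised without any data download.

**Cortical mode** (default 50 ms bins).  2-D velocity is a smoothed
mean-reverting Gaussian process with ~0.5 s correlation time — about the
timescale of discrete reaching movements; mean reversion keeps the signal
stationary so held-out blocks are statistically like the training data.
Rates follow the classic motor-cortex encoding model with a speed term:
`rate_i = softplus(b0 + m_i·(v_x cosθ_i + v_y sinθ_i) + s_i·speed)`.
The cosine/velocity term alone is *linear* in the decoded variable, which
would make the optimal decoder essentially linear; the signed speed term
(speed is a nonlinear function of velocity) and the softplus rectification
of deeply modulated neurons are what give nonlinear decoders genuine
structure to exploit.  Per-neuron mean rates are lognormal with population
mean 6.7 and median 3.4 spikes/s, and baselines are calibrated by bisection
so each neuron hits its target rate exactly.

**Hippocampal mode** (default 200 ms bins).  Position is a reflected
smoothed random walk in a 100 × 100 box (per-bin displacement ≈ field
width / 5); rates are Gaussian place fields plus a 0.02 spikes/s floor.
Per-neuron average rates are lognormal with population mean 1.7 and median
0.2 spikes/s — the hallmark skew of hippocampal populations — and each
field's peak is calibrated against the trajectory's occupancy of that field.

**Linear-Gaussian mode** draws exact trajectories from a specified state
-space model, serving as the oracle input for Kalman equivalence and
recovery tests.

What the synthetic results do **not** show: real recordings have
non-Poisson dispersion, spike-history and network dependencies,
nonstationarity (electrode drift, behavioral state), and measurement
artifacts.  Passing the ordering properties here demonstrates that the
pipeline is correct and that the decoders exploit nonlinear structure when
it exists — not that any particular decoder will win on a given real
dataset.

## Problem sizes used in the shipped checks

The ordering checks and the acceptance script run the full 10-fold
80/10/10 protocol on 10^4 bins (500 s at 50 ms) from 30 neurons with a
5-bin lag window, hyperparameters at their defaults (search budget 0);
parameter-recovery checks use 10^4 time steps.  These sizes keep a complete
run on a single CPU core in the minutes range while leaving the fold-level
noise well below the effect sizes being asserted.

## Known limitations

- Recurrent networks train on CPU in plain numpy; they are adequate at
  desk scale (10^4 samples, ≤ 200 units) but not tuned for large recordings.
- The Naive Bayes decoder enumerates the full grid posterior; cost grows as
  the product of per-dimension resolutions, so high-resolution 2-D grids
  (≫ 30 × 30) get slow.
- The Kalman filter assumes linear dynamics and linear count readout;
  no extended/unscented variants or point-process filters are provided.
- Classification decoding, online/closed-loop use, and feature-importance
  analyses are out of scope.
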