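# Methods

## Generative models

The switching model is a recurrent switching linear dynamical system: per
frame a discrete behavior state `y_t` (K classes), a continuous latent
`z_t` (Dz dimensions), and an observation `x_t` (Dx features).

- `y_1 ~ Cat(π)`, `z_1 ~ N(0, I)`.
- Transitions `y_t | y_{t-1}, z_{t-1} ~ Cat(softmax(R_{y_{t-1}} z_{t-1} +
  r_{y_{t-1}}))`. Setting all `R_k = 0` removes the recurrence and leaves a
  plain Markov switching model; this z-free special case is what the exact
  oracle (below) requires.
- Latent dynamics `z_t ~ N(A_{y_t} z_{t-1} + b_{y_t}, Q_{y_t})`.
- Emission `x_t ~ N(g(z_t), S)` with `g` shared across states — either a
  linear map `C z + d` or a one-hidden-layer dense network. The emission
  noise `S` is a single shared covariance, learned with everything else.
- The nonlinear variant swaps each linear dynamics/recurrence map for a
  one-hidden-layer dense network whose hidden width equals Dz (tanh hidden
  units).

All covariances (`Q_k`, `S`, and the static model's emission covariance) are
diagonal, parameterized by their logarithms so positivity is unconstrained
during optimization. Diagonal structure keeps every KL in closed form and
every sampler trivially seedable; correlated noise can be absorbed into the
latent dimension in practice.

The static Gaussian-mixture deep generative model removes all temporal
coupling: `y ~ Cat(π)`, `z | y ~ N(f(y), diag σ²(y))`, `x | z ~ N(g(z), R)`.
Its emission covariance is stored as `emission_logcov` because the symbol R
is already taken by the recurrence weights.

## Approximate posteriors

The variational family factorizes per frame,
`q(y_t, z_t | x_Tt) = q(y_t | x_Tt) q(z_t | x_Tt, y_t)`, with `x_Tt` the
±τ-frame window that the backbone can see. Two separate dilated TCN
backbones are used, one per factor. The class-conditional Gaussian encoder
is realized as K parallel `(μ, log σ²)` output heads on a shared trunk, so
all class conditions are evaluated in one pass — the unlabeled bound sums
over every class at every frame, which makes this the natural layout.
Log-variance heads are clamped to [-10, 10]. The static model's posteriors
replace the TCNs with per-frame one-hidden-layer dense networks (32 hidden
units); the hybrid keeps the static generative model but uses the temporal
TCN posteriors.

### TCN backbone

Dilation blocks of (dilated conv → leaky ReLU → dropout 0.10) sub-layers
with a residual connection per block; dilation doubles per block. Kernels
are symmetric with half-width `temporal_lags`, so the receptive-field
half-width is `lags × sublayers × Σ_b 2^(b-1)` — 24 frames for the default
(2, 2, 4, 32-filter) configuration, i.e. 49-frame windows: 0.70 s at 70 Hz,
1.96 s at 25 Hz, 0.82 s at 60 Hz. Sequence edges are zero-padded so every
frame gets an output; when block input and output widths differ the
residual uses a learned width-1 projection; the final head is a width-1
linear map with no nonlinearity.

## Objectives

The fully labeled bound is reconstruction plus discrete log-probabilities
minus latent KLs; the fully unlabeled bound weights every term by the
classifier rows, with a K×K sum coupling consecutive frames in the dynamics
KL and a categorical KL against the recurrent transition distribution. The
mixed loss substitutes one-hot vectors for classifier rows on labeled
frames and adds `α Σ_{t∈T_L} w_{y_t} log q(y_t | x_Tt)` with α = 100 and
class weights inversely proportional to labeled class frequency, normalized
to mean 1 (the proportionality pins only the ratios; mean-1 keeps α
comparable across label distributions).

Numerical and estimator choices:

- One reparameterized sample per (frame, class) per evaluation; the
  transition and dynamics terms at frame t reuse the samples drawn for
  frame t-1, keeping cost O(T K²) per sequence.
- The labeled bound is implemented as an independent transcription (log
  probabilities of observed states, single-head Gaussian terms), so the
  term-by-term one-hot reduction of the unlabeled bound is a genuine tested
  identity rather than a shared code path.
- Annealing multiplies the four KL-type terms (initial-latent, dynamics,
  initial-state categorical, transition categorical — the latter two absorb
  the discrete log-prior terms in the one-hot case); reconstruction and
  classification are never annealed. The ramp is linear from 0 to 1 over
  the first 100 epochs.
- In the static model's unlabeled bound the classifier entropy enters with
  a **plus** sign (`Σ_k q_k L_l(x,k) + H(q)`), which is what the algebra of
  `−Σ_y q log q` forces; the decomposition is verified against a direct
  Monte-Carlo estimate of `E_q[log p(x,y,z) − log q(y,z|x)]` in the tests.
- `0 log 0 = 0` is handled by flooring probabilities at 1e-12 inside
  `x log x` terms; background frames (sentinel −2) are treated as unlabeled
  everywhere and never enter the classification loss or the metrics.

## Training protocol

Adam with learning rate 1e-4; batches of 8 non-overlapping contiguous
1000-frame chunks (shorter sessions/remainders are kept whole); 500 epochs
by default. Each chunk is zero-padded at its own boundaries and its first
frame uses the `N(0, I)` initial-latent prior. The loss minimized is the
negative objective normalized per frame, which makes the learning rate
insensitive to batch geometry. 10% of chunks are held out and the
best-validation snapshot (evaluated every 5 epochs with annealing weight 1)
is restored at the end. A non-finite loss aborts with the name of the
offending term. Generative initialization: `A_k = 0.99 I`,
`b_k ~ N(0, 0.01)`, `Q_k = 0.1 I`, zero recurrence, emission map from the
top-Dz PCA loadings of the (standardized) training features — a standard
warm start for switching-model fitting.

All networks train in float32; the objective arithmetic and all
correctness-critical tests run in float64 (the autodiff core preserves
dtype and casts gradients back at the boundary).

## Feature engineering

Position-velocity features concatenate `x_t` with `x_t − x_{t-1}`; the
frame-0 velocity is the zero vector, which keeps T unchanged and is exact
for a still start. Features are z-scored per column with training-split
statistics that are stored with the model and re-applied at prediction
time; Gaussian emissions with a shared covariance behave poorly on
heterogeneous scales, and the transform is invertible so nothing is lost.
The latent dimensionality defaults to the smallest number of principal
components explaining 95% of feature variance. DeepLabCut-style files have
their likelihood columns dropped, not thresholded — occlusion handling
belongs upstream of this package.

## Synthetic data

The ancestral samplers are the package's data generators. The reference
condition (`well_separated_preset`) is a two-state instance with distinct
latent fixed points at ±(1, 1) (`A = 0.9 I`, `b = ±0.1·(1,1)`), latent
noise `Q = 0.02 I`, a fixed 4×2 linear emission with observation noise
`S = 0.05 I`, and sticky z-free transitions with self-probability 0.98
(expected dwell ≈ 50 frames, comparable to behavioral bout durations).
Labels are revealed in contiguous 100-frame bouts, mirroring how annotators
label video. These values were chosen once to represent a well-separated
but noisy regime in which ground truth is recoverable.

What this emulates — and does not: the generator matches the model family
exactly, so recovery tests measure inference and optimization correctness,
not robustness. Real pose data has outliers, nonstationary noise,
class-dependent emission noise, heavy class imbalance, and annotation
error; passing these tests says nothing about those. The metric suite and
the file interfaces are the parts exercised identically on real data.

Problem sizes in the test suite are desk-scale by design: state recovery
trains one 20 000-frame session (10% labeled) for 200 epochs; the
label-budget sweep uses 6 000-frame sessions for 80 epochs over
{5%, 20%, 100%} × 3 seeds; the bound-dominance battery uses K ≤ 3, T ≤ 5
instances against exact enumeration with 2 000-draw averages.

## Exact oracle

For non-recurrent, linear-emission instances the marginal likelihood is
computed exactly: enumerate all K^T discrete sequences (budget-capped at
10⁶), score each prior with π and the softmax(r) transition matrix, and
evaluate each conditional with a Kalman filter; log-sum-exp combines them.
Recurrence is rejected because z-dependent transitions break the
decomposition; bound checks for recurrent models use the one-hot reduction
identity instead, which is exact for every term.

## Design choices that were genuinely open

- Sentinels: −1 unlabeled, −2 background; background frames are unlabeled
  for every objective and excluded from every metric.
- Ties in majority-overlap state matching break to the lowest class index;
  states never seen on labeled frames map to UNMATCHED.
- F1 is the standard harmonic mean of precision and recall, macro-averaged
  over classes; entropies use natural log.
- The K-heads class conditioning (rather than concatenating a one-hot to
  the encoder input) was chosen so the unlabeled bound's per-class sums
  need a single forward pass.
- Full-covariance noise is not implemented; the diagonal parameterization
  covers every use in the package and keeps the oracle and the KLs simple.

## Known limitations

- Inference is windowed and per-frame-factorized: no forward-backward
  smoothing over the discrete chain, so predicted ethograms can show rapid
  state switches that a sequence-level decoder would suppress.
- The oracle is exponential in T and only valid without recurrence.
- Training is CPU-bound NumPy; the implementation is sized for
  desk-scale experiments, not million-frame corpora.
- No semi-unsupervised mode (extra unlabeled states beyond the labeled
  classes) and no sticky/HDP state priors.
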