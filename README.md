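# ethoseg

Semi-supervised action segmentation for behavioral time series: switching
(non)linear dynamical systems trained by amortized variational inference on a
mixture of labeled and unlabeled frames, their static Gaussian-mixture
ablations, a supervised dilated-TCN classifier baseline, and the metric suite
used to compare them.

## The problem

Action segmentation assigns a discrete behavior class (still, walk, groom, ...)
to every frame of a behavioral recording, given per-frame features such as pose
estimates or derived kinematics. Dense manual annotation does not scale, so the
central question is how much a classifier can gain from the vast majority of
frames that carry no label. `ethoseg` answers this with a semi-supervised
switching dynamical system whose amortized posterior *is* a frame classifier,
making it directly comparable to a purely supervised network.

## Models

**Switching dynamical system.** Discrete state `y_t ∈ {1..K}`, continuous
latent `z_t ∈ R^Dz`, observation `x_t ∈ R^Dx`:

    y_1 ~ Cat(π),  z_1 ~ N(0, I)
    y_t | y_{t-1}, z_{t-1} ~ Cat(softmax(R_{y_{t-1}} z_{t-1} + r_{y_{t-1}}))
    z_t | z_{t-1}, y_t     ~ N(A_{y_t} z_{t-1} + b_{y_t}, Q_{y_t})
    x_t | z_t              ~ N(g(z_t), S)

Each behavior class owns one set of linear latent dynamics `(A_k, b_k, Q_k)`;
the recurrence `R_k, r_k` lets switches depend on the latent trajectory.
`g` is shared across states (linear, or a one-hidden-layer network). The
nonlinear variant replaces the dynamics and recurrence maps with
one-hidden-layer networks as well.

**Amortized posteriors.** Per frame,
`q(y_t, z_t | x_Tt) = q(y_t | x_Tt) q(z_t | x_Tt, y_t)` where `x_Tt` is a
window of observations centered at `t`. Both factors are heads on dilated
temporal convolutional networks (2 dilation blocks × 2 sub-layers, 4 temporal
lags, 32 filters ⇒ a ±24-frame receptive field). The categorical factor is the
classifier used at prediction time.

**Objective.** The labeled and unlabeled evidence lower bounds share
term-by-term structure; the mixed semi-supervised loss substitutes a one-hot
vector for the classifier row on labeled frames and adds an α-weighted
(α = 100), class-weighted cross-entropy over the labeled set. KL terms are
linearly annealed over the first 100 epochs. Training uses Adam (lr 1e-4) over
batches of 8 × 1000-frame chunks.

**Ablations.** A static Gaussian-mixture deep generative model
(`x | z`, `z | y`, `y ~ Cat(π)`, no temporal coupling) with per-frame dense
posteriors; a hybrid pairing the static generative model with the temporal TCN
posteriors; and the fully supervised TCN classifier.

No external dataset is required: the ancestral samplers double as synthetic
data generators, and a brute-force enumeration/Kalman oracle provides exact
log marginals on tiny non-recurrent instances for bound checks.

## Worked example

```python
import numpy as np
from ethoseg import (FeatureSequence, LabelSequence, SemiSupervisedSLDS,
                     TrainConfig, sample_rslds, well_separated_preset)
from ethoseg.features import mask_labels

params = well_separated_preset()                 # 2-state reference instance
traj = sample_rslds(params, 6000, seed=0)
features = FeatureSequence(traj.x)
labels = LabelSequence(mask_labels(traj.y, labeled_fraction=0.2, seed=0),
                       ["state0", "state1"])

model = SemiSupervisedSLDS([(features, labels)], ["state0", "state1"],
                           n_latents=2, use_velocity=True, seed=0)
results = model.fit(TrainConfig(n_epochs=80, seed=0, model_kind="s3lds"))
print(results.summary())

test = sample_rslds(params, 3000, seed=900)
report = results.evaluate([(FeatureSequence(test.x),
                            LabelSequence(test.y, ["state0", "state1"]))])
print(f"held-out macro-F1: {report.macro_f1:.3f}")
```

Output:

```
Action segmentation results
=============================================
model kind:        s3lds
classes (K):       2
input dim:         8
latent dim (Dz):   2
parameters:        61128
epochs trained:    80
best val loss:     18.1150
---------------------------------------------
final epoch objective terms (per batch mean):
  recon            -52021.7234
  kl_z_init         2.8220
  kl_z_dyn          18131.1798
  kl_y_init         0.6264
  kl_y_trans        2248.5193
  classification   -164.0908
  total            -84533.4923
held-out macro-F1: 0.944
```

The model sees labels on 20% of frames (in contiguous bouts, as annotators
label video) and recovers the ground-truth state on held-out data with
macro-F1 0.944. `results.predict_proba`, `.predict_states` and `.latents`
expose the classifier rows, argmax ethogram, and posterior latent embedding;
`results.history` holds the per-epoch objective terms.

A command-line interface covers the same pipeline:

```bash
ethoseg simulate --out data/ --n-frames 10000 --labeled-fraction 0.1
ethoseg train --config run.yaml
ethoseg predict --config run.yaml --checkpoint out/checkpoint.npz
ethoseg evaluate --pred out/predictions_test0.csv \
    --labels data/session0_labels.csv --class-names state0,state1 --out out/
```

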