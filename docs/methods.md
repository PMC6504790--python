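# Methods

## Problem

Resting-state fMRI carries stable individual differences: given a short
window of brain activity, it is possible to say *which* subject produced
it. The classical approach summarizes a scan by its static functional
connectivity (FC) — the matrix of pairwise Pearson correlations between
region-of-interest (ROI) time series — and matches a new scan to the
most correlated stored profile. `connprint` implements a learned
alternative: a convolutional recurrent network that reads the raw ROI
time series directly and classifies the subject, exploiting temporal
dynamics as well as spatial covariance, together with the
interpretation machinery needed to ask *where* the identifying
information lives.

## Data model and preprocessing

The spatial unit is an ROI: a sphere (default 10 mm diameter) around an
atlas coordinate in MNI millimetres. Voxels whose centers fall within
the sphere radius (Euclidean distance, boundary inclusive) are averaged
per frame. ROIs are kept in atlas order, which places functionally
related regions next to each other; this ordering is what makes a 1-D
convolution along the ROI axis meaningful.

Each session is demeaned and scaled to unit variance per ROI over time
before segmentation, using the population (divide-by-N) variance
convention throughout the package. Constant columns cannot be scaled;
they are set to zero and flagged rather than rejected, the same "no
signal" convention the occlusion analysis uses. Sessions are segmented
into non-overlapping clips aligned to frame 0, with any remainder
dropped (1200 frames at window 100 gives exactly 12 clips). Normalizing
before segmentation (rather than per clip) keeps every clip of a session
on a common scale.

Session roles follow the two-day design positionally: all but the last
two sessions train the model, the second-to-last is validation, the
last is test. A manifest `role` column overrides this when the
positional convention does not apply.

## Architecture

The classifier is a stack of ConvLSTM layers. A ConvLSTM cell is a
standard LSTM in which the input-to-state and state-to-state
transformations are 1-D convolutions along the ROI axis, so hidden and
cell states have shape `K x filters` and every intermediate map stays
in register with the atlas. Gate pre-activations are split from a
stacked `4 * filters` channel block in the fixed order (i, f, g, o):

    i = sigmoid(x * W_xi + h * W_hi + b_i)        (* = conv1d, "same")
    f = sigmoid(x * W_xf + h * W_hf + b_f)
    g = tanh   (x * W_xg + h * W_hg + b_g)
    o = sigmoid(x * W_xo + h * W_ho + b_o)
    c' = f . c + i . g
    h' = o . tanh(c')

with no peephole connections. Convolution is cross-correlation (the
deep-learning convention), "same"-padded so spatial length is always K;
for the default even kernel size 2 the single extra zero pad sits at
the high-index end, so output position `p` sees inputs `p` and `p+1`.

Defaults: two layers with 8 and 16 filters, kernel size 2. Each layer's
hidden-state sequence passes through batch normalization (per channel,
statistics shared over batch x time x ROI) and ReLU. The final layer's
post-activation sequence is averaged over all time steps, flattened
ROI-major to `K * 16` features (3776 for 236 ROIs), passed through 50%
dropout (training only) and a dense softmax over subjects.

Parameter accounting includes the batch-normalization moving statistics,
matching the "total params" convention of framework model summaries:
the two recurrent layers hold 3,840 parameters (640 + 3,200) and the
classifier 377,700, for a total of 381,540 — which rounds to the 3.8K /
382K split the architecture is designed around. The extreme asymmetry
is the point: feature extraction is about one hundredth of the model.

Initialization: Xavier-uniform input and classifier kernels (bound
`sqrt(6 / (fan_in + fan_out))`), recurrent kernels from QR-orthogonalized
Gaussian matrices of shape `(kernel_size * filters) x (4 * filters)`,
zero biases, identity batch norm.

## Training recipe

Mean cross-entropy plus an un-normalized L2 penalty
`lambda * sum(recurrent_kernel^2)` applied to recurrent kernels only.
Adam (initial learning rate 0.001), minibatches of 128 reshuffled each
epoch from a seeded generator, and per-step clipping of the *global*
gradient norm to 1. After each epoch the model is scored on validation
clips and checkpointed only on strict improvement; the returned model
is always the checkpoint, never the final weights. The learning rate is
halved (`lr_reduce_factor`, default 0.5) after `lr_patience` epochs
without validation improvement, and training stops early after
`early_stop_patience` epochs without improvement, or once validation
accuracy is perfect (the checkpoint can no longer change at that
point; the stop can be disabled). A grid over
lambda in {0.1, 0.01, 0.001, 0.0001} selects the best validation
accuracy, ties broken toward the smaller value.

Batch-norm moving statistics use momentum 0.9, chosen so that inference
statistics track the training distribution within a few tens of
optimizer steps — relevant because a full training run here is short.
BN statistics are accumulated in float64; epsilon is 1e-5.

## Numerical implementation

The network and its gradients are implemented in NumPy. Backpropagation
through time is hand-derived and verified in the suite against central
finite differences on small float64 instances (worst relative error
~1e-6), and the forward pass against independent loop-based references
at 1e-8.

Two precision regimes coexist: public single-clip operations
(`forward`, `layer_forward`, `convlstm_step`, `conv1d_same`) run in
float64; the batched training/inference engine runs in float32 for
throughput, casting checkpoints back to float64. The engine hoists the
input-to-state convolution of all time steps into one matrix product
per gate, keeps each gate in its own contiguous array, and recycles
large work arrays from a grow-only pool instead of reallocating them
per batch; the pool makes the engine single-threaded by design.
Training is bit-reproducible for a fixed seed on a single-threaded
BLAS; with threaded BLAS reductions reproducibility is statistical.

## Synthetic cohorts

Real resting-state data with repeat sessions is access-restricted, so
the package ships a generator whose output the whole pipeline is
exercised on. Each subject `s` carries a session-stable signature: a
loading matrix `L_s` (ROIs x latent factors, i.i.d. Gaussian scaled by
`signature_strength`) and a per-ROI AR(1) coefficient vector `a_s`.
Frames evolve as

    x[t] = a_s . x[t-1] + L_s z[t] + sigma eps[t]

with `z[t]` a shared standard-Gaussian latent vector (rank-`latent_dim`
spatial covariance — the FC fingerprint) and white noise `eps`
(`sigma = 1` by default). A 100-frame burn-in is discarded, sufficient
for |a| <= 0.8. The stationary covariance has the closed form
`S_ij = Q_ij / (1 - a_i a_j)` with `Q = L L^T + sigma^2 I`, which the
suite checks against long-run sample covariance.

`signature_strength` dials subject identity in *both* channels: it
scales `L_s` directly and interpolates `a_s` between the midpoint of
`ar_coeff_range` and the subject's uniform draw (clipped to the range).
At strength 1 the AR marginal is exactly uniform on the range; at
strength 0 all subjects share identical dynamics, so identification is
at chance — the property the identifiability tests rely on. Streams
derive from `(seed, subject, session)` seed sequences, so enlarging a
cohort never changes existing subjects.

The default cohort is 20 subjects x 4 sessions x 1200 frames x 236
ROIs (TR 0.72 s), the largest shape a single CPU trains in minutes; the
emulated study design has the same sessions, frames and ROI count at
100 subjects. What the generator does *not* emulate: hemodynamic
response convolution, physiological noise spectra, motion artifacts,
scanner drift, or spatial autocorrelation tied to anatomy. Passing
tests therefore demonstrate that the pipeline recovers planted,
session-stable spatiotemporal identity — not performance on real fMRI.

## Evaluation and interpretation

Identification accuracy is argmax over the inference-mode softmax.
Because the model is recurrent it accepts any window length without
retraining; the window curve re-segments test sessions at several
lengths (default grid 1–1200) and scores each. The FC baseline builds
one profile per subject — the vectorized upper triangle of the Pearson
correlation matrix of the concatenated training sessions — and assigns
a clip to the subject with the most correlated profile; undefined
correlations from zero-variance columns inside short windows become 0
with a warning, and exact ties go to the lowest subject index.

Occlusion zeroes one ROI column of the *normalized* input at a time
(the ROI then contributes its session-mean signal) and records the
accuracy drop; contributions are reported as |degradation| normalized
by its maximum, so the most informative ROI scores 1 and an
uninformative map is all zeros. Test clips are used. Activation maps
average each layer's post-ReLU output over clips and time, one value
per (filter, ROI). The feature embedding delegates t-SNE to
scikit-learn (default perplexity 30, recorded seed) on the 3776-d
pre-classifier vectors. Because all layers preserve the ROI axis, every
map is exported as a per-ROI table with atlas geometry for external
surface renderers; cortical rendering itself is out of scope.

## Test problem sizes

The suite trains the default 20-subject cohort with the full recipe at
reduced epochs (<= 12, stopping at perfect validation) for the
end-to-end identification check, and uses 5–6-subject cohorts with
16–24 ROIs for the statistical properties (strength dial, window-curve
shape, memorization, recipe invariants), sizes at which a training run
takes seconds. The acceptance script recomputes only the analytically
forced architecture quantities and needs no training.

## Known limitations

- The volumetric sphere extraction replaces surface-based (CIFTI)
  extraction; the network consumes ROI matrices either way.
- Batch normalization uses time-shared statistics; per-time-step
  statistics are a plausible alternative reading and are not
  implemented.
- The generator's identity planted in low-rank covariance plus AR(1)
  dynamics is far easier than real between-session variability; synthetic
  accuracies should not be compared with accuracies on real cohorts.
- The dense-transition RNN baseline of earlier fingerprinting work is
  not included; its exact layout is not recoverable from the
  architecture description this package follows.
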