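"""Convolutional recurrent network for connectome fingerprinting.

The classifier takes a ``W x K`` window of normalized ROI signals (time
by atlas-ordered ROIs) and predicts which subject produced it.  Its core
is a ConvLSTM cell: a standard LSTM in which the input-to-state and
state-to-state transformations are 1-D convolutions along the ROI axis,
so hidden and cell states keep the shape ``K x filters`` and spatial
topology is preserved end to end.  The default architecture stacks two
ConvLSTM layers (8 then 16 filters, kernel size 2, "same" padding), each
followed by batch normalization and ReLU on the hidden-state sequence;
the final post-activation sequence is averaged over time, flattened to a
``K * 16 = 3776``-dimensional feature vector, passed through dropout
(training only) and a dense softmax over subjects.

Conventions fixed here (and recorded in checkpoints):

* gate order within the stacked ``4 * filters`` channel block is
  ``(i, f, g, o)``; no peephole connections;
* convolution is cross-correlation (no kernel flip); for even kernel
  sizes the single extra "same" pad sits at the high-index end;
* batch-norm statistics are shared across time and space (per channel,
  over batch x time x ROI);
* the flattened feature index is ``roi * filters + filter`` (ROI-major).

Everything is implemented in NumPy.  Public single-clip operations run
in float64; the batched engine used by training and evaluation defaults
to float32 for throughput.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import ShapeError, ValidationError

GATE_ORDER = "ifgo"
BN_EPS = 1e-5
CHECKPOINT_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# configuration and weight containers


@dataclass(frozen=True)
class ModelConfig:
    n_rois: int = 236
    n_classes: int = 100
    layer_filters: tuple[int, ...] = (8, 16)
    kernel_size: int = 2
    padding: str = "same"
    dropout_rate: float = 0.5
    recurrent_l2: float = 0.0
    bn_momentum: float = 0.9

    def __post_init__(self) -> None:
        if self.kernel_size < 1:
            raise ValidationError("kernel_size must be >= 1")
        if self.padding != "same":
            raise ValidationError("only 'same' padding preserves the spatial length")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.recurrent_l2 < 0:
            raise ValidationError("recurrent_l2 must be non-negative")
        object.__setattr__(self, "layer_filters", tuple(int(f) for f in self.layer_filters))

    @property
    def n_layers(self) -> int:
        return len(self.layer_filters)

    def in_channels(self, layer_index: int) -> int:
        return 1 if layer_index == 0 else self.layer_filters[layer_index - 1]

    @property
    def feature_dim(self) -> int:
        return self.n_rois * self.layer_filters[-1] if self.layer_filters else 0


@dataclass
class ConvLstmLayerWeights:
    """Parameters of one ConvLSTM layer plus its batch normalization.

    Kernels stack the four gates along the output-channel axis in
    :data:`GATE_ORDER`; ``input_kernel`` is ``(kernel_size, in_channels,
    4 * filters)`` and ``recurrent_kernel`` is ``(kernel_size, filters,
    4 * filters)``.
    """

    input_kernel: np.ndarray
    recurrent_kernel: np.ndarray
    bias: np.ndarray
    bn_gamma: np.ndarray
    bn_beta: np.ndarray
    bn_moving_mean: np.ndarray
    bn_moving_var: np.ndarray

    @property
    def filters(self) -> int:
        return self.recurrent_kernel.shape[1]

    def validate(self) -> None:
        k, _, four_f = self.input_kernel.shape
        f = self.filters
        if four_f != 4 * f or self.recurrent_kernel.shape != (k, f, 4 * f):
            raise ShapeError("inconsistent ConvLSTM kernel shapes")
        if self.bias.shape != (4 * f,):
            raise ShapeError("bias must have length 4 * filters")
        for name in ("bn_gamma", "bn_beta", "bn_moving_mean", "bn_moving_var"):
            if getattr(self, name).shape != (f,):
                raise ShapeError(f"{name} must have length filters")
        if np.any(self.bn_moving_var < 0):
            raise ValidationError("bn_moving_var must be non-negative")


@dataclass
class ModelWeights:
    layers: list[ConvLstmLayerWeights]
    classifier_weight: np.ndarray
    classifier_bias: np.ndarray

    def validate(self) -> None:
        for lw in self.layers:
            lw.validate()
        if self.classifier_weight.ndim != 2:
            raise ShapeError("classifier_weight must be 2-D")
        if self.classifier_bias.shape != (self.classifier_weight.shape[1],):
            raise ShapeError("classifier_bias length must match n_classes")

    def trainable_arrays(self) -> list[tuple[str, np.ndarray]]:
        """Trainable parameters in the fixed serialization order.

        Batch-norm moving statistics are excluded: they are updated by
        the forward pass, not by the optimizer.
        """
        out: list[tuple[str, np.ndarray]] = []
        for i, lw in enumerate(self.layers):
            for name in ("input_kernel", "recurrent_kernel", "bias", "bn_gamma", "bn_beta"):
                out.append((f"layers/{i}/{name}", getattr(lw, name)))
        out.append(("classifier/weight", self.classifier_weight))
        out.append(("classifier/bias", self.classifier_bias))
        return out

    def all_arrays(self) -> list[tuple[str, np.ndarray]]:
        out: list[tuple[str, np.ndarray]] = []
        for i, lw in enumerate(self.layers):
            for f in dataclasses.fields(ConvLstmLayerWeights):
                out.append((f"layers/{i}/{f.name}", getattr(lw, f.name)))
        out.append(("classifier/weight", self.classifier_weight))
        out.append(("classifier/bias", self.classifier_bias))
        return out

    def astype(self, dtype) -> "ModelWeights":
        return ModelWeights(
            layers=[
                ConvLstmLayerWeights(
                    **{
                        f.name: getattr(lw, f.name).astype(dtype)
                        for f in dataclasses.fields(ConvLstmLayerWeights)
                    }
                )
                for lw in self.layers
            ],
            classifier_weight=self.classifier_weight.astype(dtype),
            classifier_bias=self.classifier_bias.astype(dtype),
        )


@dataclass
class CellState:
    """Hidden and cell state of one ConvLSTM layer, ``K x filters`` each."""

    h: np.ndarray
    c: np.ndarray

    @classmethod
    def zeros(cls, n_rois: int, filters: int, dtype=float) -> "CellState":
        return cls(
            h=np.zeros((n_rois, filters), dtype=dtype),
            c=np.zeros((n_rois, filters), dtype=dtype),
        )


@dataclass
class ConvRnnModel:
    """Bundle of architecture, parameters, and the training label map."""

    config: ModelConfig
    weights: ModelWeights
    label_map: dict[str, int] | None = None


# ---------------------------------------------------------------------------
# convolution primitives


def _pad_bounds(kernel_size: int) -> tuple[int, int]:
    lo = (kernel_size - 1) // 2
    return lo, kernel_size - 1 - lo


def _im2col(x: np.ndarray, kernel_size: int) -> np.ndarray:
    """Stack "same"-padded taps: ``(B, K, C) -> (B, K, kernel_size * C)``.

    Taps are ordered tap-major, matching a C-order reshape of a
    ``(kernel_size, C, out)`` kernel to ``(kernel_size * C, out)``.
    """
    if kernel_size == 1:
        return x
    n_space = x.shape[1]
    lo, hi = _pad_bounds(kernel_size)
    xp = np.pad(x, ((0, 0), (lo, hi), (0, 0)))
    return np.concatenate([xp[:, u : u + n_space] for u in range(kernel_size)], axis=2)


def _col2im(dwin: np.ndarray, kernel_size: int, n_space: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter tap gradients back to inputs."""
    if kernel_size == 1:
        return dwin
    n_batch = dwin.shape[0]
    channels = dwin.shape[2] // kernel_size
    lo, _ = _pad_bounds(kernel_size)
    dxp = np.zeros((n_batch, n_space + kernel_size - 1, channels), dtype=dwin.dtype)
    for u in range(kernel_size):
        dxp[:, u : u + n_space] += dwin[:, :, u * channels : (u + 1) * channels]
    return dxp[:, lo : lo + n_space]


def conv1d_same(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded cross-correlation along the ROI axis.

    ``x`` is ``(K, C)`` or ``(B, K, C)``; ``kernel`` is ``(kernel_size,
    C, out_channels)``.  The output keeps the spatial length ``K``.  For
    even kernel sizes the single extra zero pad is at the high-index
    end, so ``out[j]`` sees ``x[j] .. x[j + kernel_size - 1]``.
    """
    x = np.asarray(x)
    kernel = np.asarray(kernel)
    if kernel.ndim != 3:
        raise ShapeError(f"kernel must be 3-D (k, in, out), got shape {kernel.shape}")
    k, cin, cout = kernel.shape
    single = x.ndim == 2
    xb = x[None] if single else x
    if xb.ndim != 3 or xb.shape[2] != cin:
        raise ShapeError(
            f"input shape {x.shape} incompatible with kernel input channels {cin}"
        )
    cols = _im2col(xb, k)
    out = cols.reshape(-1, k * cin) @ kernel.reshape(k * cin, cout)
    out = out.reshape(xb.shape[0], xb.shape[1], cout)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# single-step / single-clip reference operations


def convlstm_step(x_t: np.ndarray, state: CellState, w: ConvLstmLayerWeights) -> CellState:
    """One ConvLSTM time step on a ``K x in_channels`` input.

    Gate pre-activations are the sum of the input and recurrent
    convolutions plus the bias, split into ``(i, f, g, o)``; the state
    update is the standard peephole-free LSTM form
    ``c' = f c + i g``, ``h' = o tanh(c')``.
    """
    f = w.filters
    z = (
        conv1d_same(x_t, w.input_kernel)
        + conv1d_same(state.h, w.recurrent_kernel)
        + w.bias
    )
    gi = expit(z[:, 0 * f : 1 * f])
    gf = expit(z[:, 1 * f : 2 * f])
    gg = np.tanh(z[:, 2 * f : 3 * f])
    go = expit(z[:, 3 * f : 4 * f])
    c_new = gf * state.c + gi * gg
    h_new = go * np.tanh(c_new)
    return CellState(h=h_new, c=c_new)


def layer_forward(clip: np.ndarray, w: ConvLstmLayerWeights, mode: str = "inference") -> np.ndarray:
    """Run one ConvLSTM layer (plus BN and ReLU) over a ``W x K x C`` clip.

    The recurrence starts from zero states.  In ``"train"`` mode batch
    normalization uses statistics over time x ROI of this clip (and
    updates the layer's moving statistics); in ``"inference"`` mode it
    uses the stored moving statistics.
    """
    _check_mode(mode)
    clip = np.asarray(clip, dtype=float)
    if clip.ndim != 3:
        raise ShapeError("clip must be W x K x in_channels")
    xseq = clip[:, None]  # (W, 1, K, C)
    hseq, _, _, _ = _layer_seq_forward(xseq, w, keep_cache=False)
    aseq, _, _ = _bn_relu_forward(hseq, w, training=(mode == "train"), momentum=0.9)
    if not np.all(np.isfinite(aseq)):
        raise FloatingPointError("non-finite activations in ConvLSTM layer")
    return aseq[:, 0]


def forward(
    model: ConvRnnModel,
    clip: np.ndarray,
    mode: str = "inference",
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify one ``W x K`` clip.

    Returns ``(probabilities, features)`` where ``features`` is the
    flattened temporal average of the last layer's post-activation
    sequence (length ``config.feature_dim``) and ``probabilities`` is
    the softmax over subjects.  Dropout is applied only in ``"train"``
    mode, using ``rng`` (a fresh seeded generator when omitted).
    """
    _check_mode(mode)
    clip = np.asarray(clip, dtype=float)
    if clip.ndim != 2:
        raise ShapeError("clip must be a W x K matrix")
    if clip.shape[1] != model.config.n_rois:
        raise ShapeError(
            f"clip has {clip.shape[1]} ROIs, model expects {model.config.n_rois}"
        )
    if mode == "train" and rng is None:
        rng = np.random.default_rng(0)
    out = _model_forward(
        model.weights,
        model.config,
        clip[None],
        training=(mode == "train"),
        dropout_rng=rng,
        keep_cache=False,
        dtype=np.float64,
    )
    return out["probs"][0], out["feat"][0]


def _check_mode(mode: str) -> None:
    if mode not in ("train", "inference"):
        raise ValidationError(f"mode must be 'train' or 'inference', got {mode!r}")


# ---------------------------------------------------------------------------
# parameter accounting and initialization


def count_parameters(config: ModelConfig) -> tuple[int, int]:
    """Exact parameter totals ``(total, feature_extraction)``.

    Counts every container in :class:`ModelWeights`, including the four
    batch-normalization vectors (moving statistics included, following
    the "total params" convention of framework model summaries).
    ``feature_extraction`` excludes the classifier.
    """
    k = config.kernel_size
    feature = 0
    for i, f in enumerate(config.layer_filters):
        cin = config.in_channels(i)
        feature += k * cin * 4 * f  # input kernel
        feature += k * f * 4 * f  # recurrent kernel
        feature += 4 * f  # bias
        feature += 4 * f  # gamma, beta, moving mean, moving var
    classifier = config.feature_dim * config.n_classes + config.n_classes
    return feature + classifier, feature


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    """Matrix with orthonormal rows (rows <= cols) or columns (rows >= cols)."""
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q if rows >= cols else q.T


def initialize_weights(config: ModelConfig, seed: int = 0) -> ModelWeights:
    """Deterministic initial weights.

    Input and classifier kernels use the Xavier (Glorot) uniform scheme
    with bound ``sqrt(6 / (fan_in + fan_out))``; recurrent kernels are
    random orthogonal matrices obtained by QR-orthogonalizing a Gaussian
    ``(kernel_size * filters) x (4 * filters)`` matrix; biases start at
    zero; batch normalization starts at identity (gamma 1, beta 0,
    moving mean 0, moving variance 1).
    """
    rng = np.random.default_rng(seed)
    k = config.kernel_size
    layers = []
    for i, f in enumerate(config.layer_filters):
        cin = config.in_channels(i)
        fan_in, fan_out = k * cin, k * 4 * f
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        input_kernel = rng.uniform(-bound, bound, size=(k, cin, 4 * f))
        recurrent_kernel = _orthogonal(rng, k * f, 4 * f).reshape(k, f, 4 * f)
        layers.append(
            ConvLstmLayerWeights(
                input_kernel=input_kernel,
                recurrent_kernel=recurrent_kernel,
                bias=np.zeros(4 * f),
                bn_gamma=np.ones(f),
                bn_beta=np.zeros(f),
                bn_moving_mean=np.zeros(f),
                bn_moving_var=np.ones(f),
            )
        )
    fdim = config.feature_dim
    bound = np.sqrt(6.0 / (fdim + config.n_classes)) if fdim + config.n_classes else 0.0
    weights = ModelWeights(
        layers=layers,
        classifier_weight=rng.uniform(-bound, bound, size=(fdim, config.n_classes)),
        classifier_bias=np.zeros(config.n_classes),
    )
    weights.validate()
    return weights


# ---------------------------------------------------------------------------
# batched engine (training=float32 by default)


_POOL: dict[tuple, np.ndarray] = {}


def _buf(tag: tuple, shape: tuple[int, ...], dtype) -> np.ndarray:
    """Reusable scratch array from the grow-only workspace pool.

    Large per-batch work arrays are recycled between engine calls
    instead of being reallocated, which avoids repeated page-fault
    storms on fresh memory.  A buffer is valid only until the next
    engine call that requests the same tag; the engine is therefore
    single-threaded by design.
    """
    key = (tag, np.dtype(dtype).str)
    size = int(np.prod(shape))
    flat = _POOL.get(key)
    if flat is None or flat.size < size:
        flat = np.empty(size, dtype=dtype)
        _POOL[key] = flat
    return flat[:size].reshape(shape)


def clear_workspace() -> None:
    """Release the engine's pooled scratch memory."""
    _POOL.clear()


def _sigmoid_inplace(a: np.ndarray) -> None:
    """sigma(x) = (tanh(x/2) + 1) / 2, via the SIMD-vectorized tanh."""
    a *= 0.5
    np.tanh(a, out=a)
    a += 1.0
    a *= 0.5


def _im2col_into(x: np.ndarray, k: int, out: np.ndarray) -> np.ndarray:
    """Windowed "same"-padding taps: ``(N, K, C)`` into ``out (N, K, k*C)``."""
    n_space = x.shape[1]
    c = x.shape[2]
    lo, _ = _pad_bounds(k)
    for u in range(k):
        s = u - lo
        j0, j1 = max(0, -s), min(n_space, n_space - s)
        block = out[:, :, u * c : (u + 1) * c]
        if j0 > 0:
            block[:, :j0] = 0.0
        if j1 < n_space:
            block[:, j1:] = 0.0
        block[:, j0:j1] = x[:, j0 + s : j1 + s]
    return out


def _col2im_into(dwin: np.ndarray, k: int, out: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`_im2col_into`: scatter-add tap gradients."""
    n_space = out.shape[1]
    c = out.shape[2]
    lo, _ = _pad_bounds(k)
    out.fill(0.0)
    for u in range(k):
        s = u - lo
        j0, j1 = max(0, -s), min(n_space, n_space - s)
        out[:, j0 + s : j1 + s] += dwin[:, j0:j1, u * c : (u + 1) * c]
    return out


def _gate_blocks(kernel: np.ndarray, f: int, dtype) -> list[np.ndarray]:
    """Per-gate ``(k * c, f)`` weight matrices from a ``(k, c, 4f)`` kernel."""
    k, c, _ = kernel.shape
    return [
        np.ascontiguousarray(kernel[:, :, g * f : (g + 1) * f].astype(dtype, copy=False)).reshape(
            k * c, f
        )
        for g in range(4)
    ]


def _layer_seq_forward(
    xseq: np.ndarray, w: ConvLstmLayerWeights, keep_cache: bool, tag: str = "pub"
) -> tuple[np.ndarray, list[np.ndarray] | None, np.ndarray | None, np.ndarray | None]:
    """Unroll one ConvLSTM layer over a time-major ``(W, B, K, Cin)`` batch.

    The input-to-state convolution for every time step is hoisted into
    one matrix product per gate; only the state-to-state convolution
    runs inside the time loop, and each gate lives in its own
    contiguous ``(W, B, K, F)`` array.  Returns the pre-normalization
    hidden sequence plus, when ``keep_cache`` is set, the activated
    per-gate sequences, the cell sequence, and the windowed input
    columns needed by backpropagation through time.
    """
    n_time, n_batch, n_space, cin = xseq.shape
    k = w.input_kernel.shape[0]
    f = w.filters
    dtype = xseq.dtype
    lo, _ = _pad_bounds(k)
    wxg = _gate_blocks(w.input_kernel, f, dtype)
    whg = _gate_blocks(w.recurrent_kernel, f, dtype)
    bias = w.bias.astype(dtype, copy=False)

    xwin = _buf((tag, "xwin"), (n_time * n_batch, n_space, k * cin), dtype)
    _im2col_into(xseq.reshape(n_time * n_batch, n_space, cin), k, xwin)
    xwin2 = xwin.reshape(-1, k * cin)
    z = [_buf((tag, "z", g), (n_time, n_batch, n_space, f), dtype) for g in range(4)]
    for g in range(4):
        np.matmul(xwin2, wxg[g], out=z[g].reshape(-1, f))
        z[g] += bias[g * f : (g + 1) * f]

    hseq = _buf((tag, "hseq"), (n_time, n_batch, n_space, f), dtype)
    cseq = _buf((tag, "cseq"), (n_time if keep_cache else 2, n_batch, n_space, f), dtype)
    hpad = _buf(("scratch", "hpad"), (n_batch, n_space + k - 1, f), dtype)
    hpad.fill(0.0)
    hwin = _buf(("scratch", "hwin"), (n_batch * n_space, k * f), dtype)
    hwin3 = hwin.reshape(n_batch, n_space, k * f)
    zstep = _buf(("scratch", "zstep"), (n_batch, n_space, f), dtype)
    zstep2 = zstep.reshape(n_batch * n_space, f)
    tmp = _buf(("scratch", "tmp"), (n_batch, n_space, f), dtype)
    c_prev = None
    for t in range(n_time):
        if t > 0:
            hpad[:, lo : lo + n_space] = hseq[t - 1]
            for u in range(k):
                hwin3[..., u * f : (u + 1) * f] = hpad[:, u : u + n_space]
            for g in range(4):
                np.matmul(hwin, whg[g], out=zstep2)
                z[g][t] += zstep
        zi, zf, zg, zo = z[0][t], z[1][t], z[2][t], z[3][t]
        _sigmoid_inplace(zi)
        _sigmoid_inplace(zf)
        np.tanh(zg, out=zg)
        _sigmoid_inplace(zo)
        c = cseq[t] if keep_cache else cseq[t % 2]
        if t == 0:
            np.multiply(zi, zg, out=c)  # c_{-1} = 0
        else:
            np.multiply(zf, c_prev, out=c)
            np.multiply(zi, zg, out=tmp)
            c += tmp
        np.tanh(c, out=tmp)
        np.multiply(zo, tmp, out=hseq[t])
        c_prev = c
    return (
        hseq,
        (z if keep_cache else None),
        (cseq if keep_cache else None),
        (xwin if keep_cache else None),
    )


def _bn_relu_forward(
    hseq: np.ndarray,
    w: ConvLstmLayerWeights,
    training: bool,
    momentum: float,
    tag: str = "pub",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-channel batch normalization over (time, batch, ROI), then ReLU.

    Batch statistics are accumulated in float64 regardless of the
    working precision.
    """
    dtype = hseq.dtype
    f = hseq.shape[3]
    n = hseq.shape[0] * hseq.shape[1] * hseq.shape[2]
    if training:
        flat = hseq.reshape(-1, f)
        s1 = flat.sum(axis=0, dtype=np.float64)
        s2 = np.einsum("nf,nf->f", flat, flat, dtype=np.float64)
        mean64 = s1 / n
        var64 = np.maximum(s2 / n - mean64**2, 0.0)
        w.bn_moving_mean[...] = momentum * w.bn_moving_mean + (1.0 - momentum) * mean64
        w.bn_moving_var[...] = momentum * w.bn_moving_var + (1.0 - momentum) * var64
        mean = mean64.astype(dtype)
        var = var64.astype(dtype)
    else:
        mean = w.bn_moving_mean.astype(dtype, copy=False)
        var = w.bn_moving_var.astype(dtype, copy=False)
    inv = (1.0 / np.sqrt(var.astype(np.float64) + BN_EPS)).astype(dtype)
    gamma = w.bn_gamma.astype(dtype, copy=False)
    beta = w.bn_beta.astype(dtype, copy=False)
    scale = (gamma * inv).astype(dtype, copy=False)
    shift = (beta - gamma * mean * inv).astype(dtype, copy=False)
    aseq = _buf((tag, "aseq"), hseq.shape, dtype)
    np.multiply(hseq, scale, out=aseq)
    aseq += shift
    np.maximum(aseq, 0.0, out=aseq)
    return aseq, np.asarray(mean, dtype=dtype), np.asarray(inv, dtype=dtype)


def _bn_relu_backward(
    dpost: np.ndarray,
    aseq: np.ndarray,
    hseq: np.ndarray,
    bn_mean: np.ndarray,
    bn_inv: np.ndarray,
    gamma: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backward through ReLU and (training-mode) batch normalization.

    Overwrites ``aseq`` with the gradient w.r.t. the pre-normalization
    hidden sequence (it is no longer needed once the mask is taken).
    """
    dtype = aseq.dtype
    n = aseq.shape[0] * aseq.shape[1] * aseq.shape[2]
    mask = _buf(("scratch", "relu_mask"), aseq.shape, np.bool_)
    np.greater(aseq, 0.0, out=mask)
    dy = aseq
    np.multiply(dpost, mask, out=dy)
    xhat = _buf(("scratch", "xhat"), hseq.shape, dtype)
    np.subtract(hseq, bn_mean, out=xhat)
    xhat *= bn_inv
    dgamma = np.einsum("tbkf,tbkf->f", dy, xhat)
    dbeta = dy.sum(axis=(0, 1, 2))
    # dh = gamma*inv/n * (n*dy - dbeta - xhat*sum(dy*xhat)), in place in dy
    xhat *= dgamma
    dy *= float(n)
    dy -= dbeta
    dy -= xhat
    dy *= gamma * bn_inv / float(n)
    return dgamma, dbeta, dy


def _layer_seq_backward(
    dhseq: np.ndarray,
    xwin: np.ndarray,
    hseq: np.ndarray,
    gates: list[np.ndarray],
    cseq: np.ndarray,
    w: ConvLstmLayerWeights,
    need_dx: bool,
    tag: str = "pub",
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Backpropagation through time for one ConvLSTM layer.

    Consumes the forward cache: the per-gate activation arrays are
    overwritten in place with gate pre-activation gradients, so the
    input-kernel gradient and the input gradient can be formed by
    hoisted matrix products after the time loop.
    """
    n_time, n_batch, n_space, f = hseq.shape
    k = w.input_kernel.shape[0]
    cin = xwin.shape[2] // k
    dtype = hseq.dtype
    lo, _ = _pad_bounds(k)
    wxg = _gate_blocks(w.input_kernel, f, dtype)
    whg = _gate_blocks(w.recurrent_kernel, f, dtype)
    d_whg = [np.zeros((k * f, f), dtype=dtype) for _ in range(4)]

    hpad = _buf(("scratch", "hpad"), (n_batch, n_space + k - 1, f), dtype)
    hpad.fill(0.0)
    hwin = _buf(("scratch", "hwin"), (n_batch * n_space, k * f), dtype)
    hwin3 = hwin.reshape(n_batch, n_space, k * f)
    dh = _buf(("scratch", "dh"), (n_batch, n_space, f), dtype)
    dc = _buf(("scratch", "dc"), (n_batch, n_space, f), dtype)
    dc_next = _buf(("scratch", "dc_next"), (n_batch, n_space, f), dtype)
    tc = _buf(("scratch", "tc"), (n_batch, n_space, f), dtype)
    tmp = _buf(("scratch", "tmp"), (n_batch, n_space, f), dtype)
    tmp2 = _buf(("scratch", "tmp2"), (n_batch, n_space, f), dtype)
    dhwin = _buf(("scratch", "dhwin"), (n_batch, n_space, k * f), dtype)
    dhwin2 = dhwin.reshape(n_batch * n_space, k * f)
    dhwtmp = _buf(("scratch", "dhwtmp"), (n_batch * n_space, k * f), dtype)

    for t in range(n_time - 1, -1, -1):
        if t == n_time - 1:
            np.copyto(dh, dhseq[t])
        else:
            dh += dhseq[t]
        zi, zf, zg, zo = gates[0][t], gates[1][t], gates[2][t], gates[3][t]
        np.tanh(cseq[t], out=tc)
        # dc = dc_next + dh * o * (1 - tanh(c)^2)
        np.multiply(tc, tc, out=dc)
        np.subtract(1.0, dc, out=dc)
        dc *= zo
        dc *= dh
        if t < n_time - 1:
            dc += dc_next
        np.multiply(dc, zf, out=dc_next)  # c-path gradient, before zf is overwritten
        # overwrite gate arrays with pre-activation gradients, ordered so
        # every gradient still sees the gate values it needs
        np.multiply(dh, tc, out=tmp)  # output gate: dz_o = dh*tanh(c)*o*(1-o)
        np.subtract(1.0, zo, out=tmp2)
        zo *= tmp2
        zo *= tmp
        np.multiply(dc, zi, out=tmp)  # saved for dz_g
        np.subtract(1.0, zi, out=tmp2)  # dz_i = dc*g*i*(1-i)
        zi *= tmp2
        zi *= zg
        zi *= dc
        np.multiply(zg, zg, out=zg)  # dz_g = dc*i*(1-g^2)
        np.subtract(1.0, zg, out=zg)
        zg *= tmp
        if t > 0:
            np.subtract(1.0, zf, out=tmp2)  # dz_f = dc*c_{t-1}*f*(1-f)
            zf *= tmp2
            zf *= cseq[t - 1]
            zf *= dc
        else:
            zf[...] = 0.0  # c_{-1} = 0, the forget gate sees no gradient
        if t > 0:
            hpad[:, lo : lo + n_space] = hseq[t - 1]
            for u in range(k):
                hwin3[..., u * f : (u + 1) * f] = hpad[:, u : u + n_space]
            for g in range(4):
                dzg2 = gates[g][t].reshape(n_batch * n_space, f)
                d_whg[g] += hwin.T @ dzg2
                if g == 0:
                    np.matmul(dzg2, whg[g].T, out=dhwin2)
                else:
                    np.matmul(dzg2, whg[g].T, out=dhwtmp)
                    dhwin2 += dhwtmp
            _col2im_into(dhwin, k, dh)
    # hoisted input-side gradients over all time steps at once
    xwin2 = xwin.reshape(-1, k * cin)
    d_wx = np.empty((k * cin, 4 * f), dtype=dtype)
    d_b = np.empty(4 * f, dtype=dtype)
    dxseq = None
    dxw = None
    if need_dx:
        dxw = _buf((tag, "dxw"), (n_time * n_batch, n_space, k * cin), dtype)
        dxw2 = dxw.reshape(-1, k * cin)
        dxwtmp = _buf(("scratch", "dxwtmp"), (n_time * n_batch * n_space, k * cin), dtype)
    for g in range(4):
        dzg2 = gates[g].reshape(-1, f)
        np.matmul(xwin2.T, dzg2, out=d_wx[:, g * f : (g + 1) * f])
        d_b[g * f : (g + 1) * f] = dzg2.sum(axis=0, dtype=np.float64).astype(dtype)
        if need_dx:
            if g == 0:
                np.matmul(dzg2, wxg[g].T, out=dxw2)
            else:
                np.matmul(dzg2, wxg[g].T, out=dxwtmp)
                dxw2 += dxwtmp
    d_wh = np.concatenate(d_whg, axis=1)
    if need_dx:
        dxseq = _buf((tag, "dxseq"), (n_time, n_batch, n_space, cin), dtype)
        _col2im_into(dxw, k, dxseq.reshape(n_time * n_batch, n_space, cin))
    return (
        d_wx.reshape(k, cin, 4 * f),
        d_wh.reshape(k, f, 4 * f),
        d_b,
        dxseq,
    )


def _model_forward(
    weights: ModelWeights,
    config: ModelConfig,
    clips: np.ndarray,
    training: bool,
    dropout_rng: np.random.Generator | None = None,
    keep_cache: bool = False,
    dtype=np.float32,
) -> dict:
    """Full forward pass over a ``(B, W, K)`` batch of clips."""
    clips = np.asarray(clips, dtype=dtype)
    if clips.ndim != 3:
        raise ShapeError("batch must be (n_clips, W, K)")
    n_batch, n_time, n_space = clips.shape
    if n_space != config.n_rois:
        raise ShapeError(f"clips have {n_space} ROIs, model expects {config.n_rois}")
    xseq = np.ascontiguousarray(clips.transpose(1, 0, 2))[..., None]
    caches: list[dict] = []
    for li, lw in enumerate(weights.layers):
        hseq, gates, cseq, xwin = _layer_seq_forward(
            xseq, lw, keep_cache=keep_cache, tag=f"L{li}"
        )
        aseq, bn_mean, bn_inv = _bn_relu_forward(
            hseq, lw, training=training, momentum=config.bn_momentum, tag=f"L{li}"
        )
        caches.append(
            {
                "xwin": xwin,
                "hseq": hseq,
                "gates": gates,
                "cseq": cseq,
                "aseq": aseq,
                "bn_mean": bn_mean,
                "bn_inv": bn_inv,
            }
        )
        xseq = aseq
    if weights.layers:
        feat = np.ascontiguousarray(xseq.mean(axis=0)).reshape(n_batch, -1)
    else:
        feat = np.zeros((n_batch, 0), dtype=dtype)
    drop_mask = None
    feat_dropped = feat
    if training and config.dropout_rate > 0.0:
        if dropout_rng is None:
            dropout_rng = np.random.default_rng(0)
        keep = 1.0 - config.dropout_rate
        drop_mask = (dropout_rng.random(feat.shape) < keep).astype(dtype) / dtype(keep)
        feat_dropped = feat * drop_mask
    logits = feat_dropped @ weights.classifier_weight.astype(dtype, copy=False)
    logits += weights.classifier_bias.astype(dtype, copy=False)
    shifted = logits - logits.max(axis=1, keepdims=True)
    ex = np.exp(shifted)
    probs = ex / ex.sum(axis=1, keepdims=True)
    return {
        "probs": probs,
        "logits": logits,
        "feat": feat,
        "feat_dropped": feat_dropped,
        "drop_mask": drop_mask,
        "caches": caches if keep_cache else None,
    }


def _model_backward(
    weights: ModelWeights,
    config: ModelConfig,
    out: dict,
    labels: np.ndarray,
    recurrent_l2: float = 0.0,
) -> dict:
    """Gradients of mean cross-entropy (+ recurrent L2) w.r.t. all trainables.

    Requires the cache from ``_model_forward(..., keep_cache=True)``.
    Returns a dict keyed like :meth:`ModelWeights.trainable_arrays`.
    """
    caches = out["caches"]
    probs = out["probs"]
    n_batch = probs.shape[0]
    dtype = probs.dtype
    dlogits = probs.copy()
    dlogits[np.arange(n_batch), labels] -= 1.0
    dlogits /= n_batch
    grads: dict[str, np.ndarray] = {
        "classifier/weight": out["feat_dropped"].T @ dlogits,
        "classifier/bias": dlogits.sum(axis=0),
    }
    dfeat = dlogits @ weights.classifier_weight.astype(dtype, copy=False).T
    if out["drop_mask"] is not None:
        dfeat = dfeat * out["drop_mask"]
    last = caches[-1]
    n_time = last["aseq"].shape[0]
    f_last = config.layer_filters[-1]
    davg = dfeat.reshape(n_batch, config.n_rois, f_last) / n_time
    dpost: np.ndarray = np.broadcast_to(davg, last["aseq"].shape)
    for li in range(len(caches) - 1, -1, -1):
        cch = caches[li]
        lw = weights.layers[li]
        dgamma, dbeta, dhseq = _bn_relu_backward(
            dpost,
            cch["aseq"],
            cch["hseq"],
            cch["bn_mean"],
            cch["bn_inv"],
            lw.bn_gamma.astype(dtype, copy=False),
        )
        d_wx, d_wh, d_b, dx = _layer_seq_backward(
            dhseq,
            cch["xwin"],
            cch["hseq"],
            cch["gates"],
            cch["cseq"],
            lw,
            need_dx=(li > 0),
            tag=f"L{li}",
        )
        if recurrent_l2:
            d_wh = d_wh + 2.0 * recurrent_l2 * lw.recurrent_kernel.astype(dtype, copy=False)
        grads[f"layers/{li}/input_kernel"] = d_wx
        grads[f"layers/{li}/recurrent_kernel"] = d_wh
        grads[f"layers/{li}/bias"] = d_b
        grads[f"layers/{li}/bn_gamma"] = dgamma
        grads[f"layers/{li}/bn_beta"] = dbeta
        if li > 0:
            dpost = dx
    return grads


def predict_proba(
    model: ConvRnnModel,
    clips: np.ndarray,
    batch_size: int = 128,
    dtype=np.float32,
) -> np.ndarray:
    """Inference-mode class probabilities for a ``(N, W, K)`` clip array."""
    clips = np.asarray(clips)
    probs = np.empty((clips.shape[0], model.config.n_classes), dtype=float)
    for start in range(0, clips.shape[0], batch_size):
        out = _model_forward(
            model.weights,
            model.config,
            clips[start : start + batch_size],
            training=False,
            dtype=dtype,
        )
        probs[start : start + batch_size] = out["probs"]
    return probs


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: ConvRnnModel, path: str | os.PathLike) -> None:
    """Write weights to HDF5 with a JSON sidecar describing the model.

    The sidecar (``<path>.json``) records the configuration, the gate
    order and padding conventions, the label map, and a format version.
    """
    import h5py

    path = os.fspath(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = CHECKPOINT_FORMAT_VERSION
        for name, arr in model.weights.all_arrays():
            f.create_dataset(name, data=arr)
    sidecar = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": dataclasses.asdict(model.config),
        "gate_order": GATE_ORDER,
        "padding": "same-high",
        "feature_order": "roi_major",
        "label_map": model.label_map,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path: str | os.PathLike) -> ConvRnnModel:
    import h5py

    path = os.fspath(path)
    with open(path + ".json") as fh:
        sidecar = json.load(fh)
    if sidecar.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported checkpoint format version {sidecar.get('format_version')}"
        )
    cfg_dict = dict(sidecar["config"])
    cfg_dict["layer_filters"] = tuple(cfg_dict["layer_filters"])
    config = ModelConfig(**cfg_dict)
    with h5py.File(path, "r") as f:
        layers = [
            ConvLstmLayerWeights(
                **{
                    fld.name: np.array(f[f"layers/{i}/{fld.name}"])
                    for fld in dataclasses.fields(ConvLstmLayerWeights)
                }
            )
            for i in range(config.n_layers)
        ]
        weights = ModelWeights(
            layers=layers,
            classifier_weight=np.array(f["classifier/weight"]),
            classifier_bias=np.array(f["classifier/bias"]),
        )
    weights.validate()
    label_map = sidecar.get("label_map")
    if label_map is not None:
        label_map = {str(k): int(v) for k, v in label_map.items()}
    return ConvRnnModel(config=config, weights=weights, label_map=label_map)
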