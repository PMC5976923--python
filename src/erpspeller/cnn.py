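"""Two-layer topology-aware CNN for single-input ERP classification.

The network mirrors the architecture used for speller decoding: a 6x20
spatial-temporal filter bank over the 14x300 wrapped electrode matrix, 2x2
max-pooling, a 1x12 temporal filter bank (~100 ms at 256 Hz), 1x10
max-pooling, one hidden dense layer with dropout, and a 2-way softmax whose
first element scores target affiliation.

Everything is plain numpy with analytic gradients and an Adam loop, fully
seeded: weight initialisation, minibatch shuffling, dropout masks and the
validation split all derive from ``CnnSpec.seed``.  Convolutions are valid
(no padding), pooling drops remainders (floor division), so a 14x300 input
realises the shape chain 9x281 -> 4x140 -> 4x129 -> 4x12.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = [
    "CnnSpec",
    "TrainedCnn",
    "desk_spec",
    "full_spec",
    "layer_shapes",
    "init_params",
    "forward",
    "forward_activations",
    "loss_and_grads",
    "train",
    "epoch_label",
    "save_checkpoint",
    "load_checkpoint",
]


# --------------------------------------------------------------------------
# Specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CnnSpec:
    """Architecture and training hyper-parameters.

    Kernel and pool sizes default to the speller architecture and should not
    normally be changed; filter counts, dense width and the optimiser knobs
    are free.  ``class_weighting`` applies inverse-frequency weights to the
    cross-entropy, compensating the 1:5 target:non-target imbalance of the
    oddball paradigm.
    """

    l1_filters: int = 8
    l1_kernel: tuple[int, int] = (6, 20)
    m1_pool: tuple[int, int] = (2, 2)
    l2_filters: int = 9
    l2_kernel: tuple[int, int] = (1, 12)
    m2_pool: tuple[int, int] = (1, 10)
    f1_units: int = 128
    dropout_rate: float = 0.5
    output_units: int = 2
    learning_rate: float = 1e-3
    iterations: int = 2000
    batch_size: int = 32
    class_weighting: bool = True
    validation_fraction: float = 0.25
    record_every: int = 100
    seed: int = 0
    dtype: str = "float32"
    input_shape: tuple[int, int] = (14, 300)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.output_units != 2:
            raise ValueError("the speller CNN is a 2-way (target/non-target) classifier")
        if self.iterations < 1 or self.batch_size < 1:
            raise ValueError("iterations and batch_size must be positive")
        layer_shapes(self)  # raises if the kernels do not fit the input


def desk_spec(**overrides) -> CnnSpec:
    """Desk-scale profile: 2000 Adam steps at batch 16, well under a minute
    per subject on one CPU."""
    return CnnSpec(**{"iterations": 2000, "batch_size": 16, **overrides})


def full_spec(**overrides) -> CnnSpec:
    """Full-scale profile: 10,000 Adam steps per subject."""
    return CnnSpec(**{"iterations": 10_000, **overrides})


def _conv_shape(shape: tuple[int, int], kernel: tuple[int, int], name: str) -> tuple[int, int]:
    h = shape[0] - kernel[0] + 1
    w = shape[1] - kernel[1] + 1
    if h < 1 or w < 1:
        raise ValueError(f"{name}: kernel {kernel} does not fit input of shape {shape}")
    return (h, w)


def _pool_shape(shape: tuple[int, int], pool: tuple[int, int], name: str) -> tuple[int, int]:
    h, w = shape[0] // pool[0], shape[1] // pool[1]
    if h < 1 or w < 1:
        raise ValueError(f"{name}: pool {pool} larger than input of shape {shape}")
    return (h, w)


def layer_shapes(spec: CnnSpec) -> dict[str, tuple[int, int]]:
    """Closed-form (rows, cols) of every feature map for ``spec.input_shape``.

    Valid convolution maps (H, W) to (H-h+1, W-w+1); non-overlapping pooling
    floor-divides each dimension.
    """
    shapes = {"input": tuple(spec.input_shape)}
    shapes["l1"] = _conv_shape(shapes["input"], spec.l1_kernel, "L1")
    shapes["m1"] = _pool_shape(shapes["l1"], spec.m1_pool, "M1")
    shapes["l2"] = _conv_shape(shapes["m1"], spec.l2_kernel, "L2")
    shapes["m2"] = _pool_shape(shapes["l2"], spec.m2_pool, "M2")
    return shapes


# --------------------------------------------------------------------------
# Primitive layers (forward + backward)
# --------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Patch matrix (B*Ho*Wo, C*kh*kw) for a valid convolution."""
    b, c, h, w = x.shape
    ho, wo = h - kh + 1, w - kw + 1
    sb, sc, sh, sw = x.strides
    view = as_strided(x, (b, ho, wo, c, kh, kw), (sb, sh, sw, sc, sh, sw))
    return np.ascontiguousarray(view).reshape(b * ho * wo, c * kh * kw)


def conv_forward(x: np.ndarray, w: np.ndarray, bias: np.ndarray,
                 cols: np.ndarray | None = None):
    """Valid 2-D convolution (cross-correlation). x:(B,C,H,W), w:(F,C,kh,kw).

    ``cols`` lets callers reuse a precomputed patch matrix when the inputs
    are fixed across iterations (first layer of the training loop).
    """
    f, c, kh, kw = w.shape
    b, cx, h, wd = x.shape
    if cx != c:
        raise ValueError(f"conv: input has {cx} channels, kernel expects {c}")
    ho, wo = h - kh + 1, wd - kw + 1
    if cols is None:
        cols = _im2col(x, kh, kw)
    out = cols @ w.reshape(f, -1).T
    out += bias
    out = out.reshape(b, ho, wo, f).transpose(0, 3, 1, 2)
    return out, cols


def conv_backward(dout: np.ndarray, cols: np.ndarray, w: np.ndarray,
                  x_shape: tuple, need_dx: bool = True):
    """Gradients of a valid convolution; dx via transposed convolution."""
    f, c, kh, kw = w.shape
    b = x_shape[0]
    dr = dout.transpose(0, 2, 3, 1).reshape(-1, f)
    dw = (dr.T @ cols).reshape(w.shape)
    db = dr.sum(axis=0)
    dx = None
    if need_dx:
        pad = ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1))
        dpad = np.pad(dout, pad)
        wt = np.ascontiguousarray(w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        dx, _ = conv_forward(dpad, wt, np.zeros(c, dtype=dout.dtype))
    return dw, db, dx


def maxpool_forward(x: np.ndarray, pool: tuple[int, int]):
    """Non-overlapping max pooling with floor-division boundaries."""
    p, q = pool
    b, c, h, w = x.shape
    hp, wq = h // p, w // q
    r = x[:, :, : hp * p, : wq * q]
    r = r.reshape(b, c, hp, p, wq, q).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(b, c, hp, wq, p * q)
    idx = r.argmax(axis=-1)
    out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape, pool)


def maxpool_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx, x_shape, (p, q) = cache
    b, c, h, w = x_shape
    hp, wq = h // p, w // q
    dr = np.zeros((b, c, hp, wq, p * q), dtype=dout.dtype)
    np.put_along_axis(dr, idx[..., None], dout[..., None], axis=-1)
    dr = dr.reshape(b, c, hp, wq, p, q).transpose(0, 1, 2, 4, 3, 5)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    dx[:, :, : hp * p, : wq * q] = dr.reshape(b, c, hp * p, wq * q)
    return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# Network
# --------------------------------------------------------------------------

def init_params(spec: CnnSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-normal initialisation of all weights, zero biases."""
    dt = np.dtype(spec.dtype)
    shapes = layer_shapes(spec)
    flat = spec.l2_filters * shapes["m2"][0] * shapes["m2"][1]

    def he(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dt)

    kh1, kw1 = spec.l1_kernel
    kh2, kw2 = spec.l2_kernel
    return {
        "W1": he((spec.l1_filters, 1, kh1, kw1), kh1 * kw1),
        "b1": np.zeros(spec.l1_filters, dtype=dt),
        "W2": he((spec.l2_filters, spec.l1_filters, kh2, kw2),
                 spec.l1_filters * kh2 * kw2),
        "b2": np.zeros(spec.l2_filters, dtype=dt),
        "Wf": he((flat, spec.f1_units), flat),
        "bf": np.zeros(spec.f1_units, dtype=dt),
        "Wo": he((spec.f1_units, spec.output_units), spec.f1_units),
        "bo": np.zeros(spec.output_units, dtype=dt),
    }


def _check_input(spec: CnnSpec, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=spec.dtype)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[1:] != tuple(spec.input_shape):
        raise ValueError(
            f"L1 input: expected (batch, {spec.input_shape[0]}, {spec.input_shape[1]}) "
            f"matrices, got array of shape {x.shape}"
        )
    return x[:, None]  # add the single channel axis


def _forward_full(params: dict, spec: CnnSpec, x4: np.ndarray,
                  dropout_rng: np.random.Generator | None = None,
                  l1_cols: np.ndarray | None = None) -> dict:
    """Full forward pass returning every intermediate needed for backprop
    or feature-map extraction.  Dropout is active only when a generator is
    passed (training mode)."""
    z1, cols1 = conv_forward(x4, params["W1"], params["b1"], cols=l1_cols)
    a1 = np.maximum(z1, 0)
    m1, mcache1 = maxpool_forward(a1, spec.m1_pool)
    z2, cols2 = conv_forward(m1, params["W2"], params["b2"])
    a2 = np.maximum(z2, 0)
    m2, mcache2 = maxpool_forward(a2, spec.m2_pool)
    flat = m2.reshape(m2.shape[0], -1)
    zf = flat @ params["Wf"] + params["bf"]
    af = np.maximum(zf, 0)
    mask = None
    if dropout_rng is not None and spec.dropout_rate > 0:
        keep = 1.0 - spec.dropout_rate
        mask = (dropout_rng.random(af.shape) < keep).astype(af.dtype) / keep
        af = af * mask
    logits = af @ params["Wo"] + params["bo"]
    probs = _softmax(logits.astype(np.float64)).astype(af.dtype)
    return {
        "z1": z1, "a1": a1, "cols1": cols1, "mcache1": mcache1, "m1": m1,
        "z2": z2, "a2": a2, "cols2": cols2, "mcache2": mcache2, "m2": m2,
        "flat": flat, "zf": zf, "af": af, "mask": mask,
        "logits": logits, "probs": probs, "x_shape": x4.shape,
    }


def forward(model_or_params, x: np.ndarray, spec: CnnSpec | None = None) -> np.ndarray:
    """Inference scores. Returns (2,) for a single matrix, (B, 2) for a batch.

    Element 0 is the target score, element 1 the non-target score; they are
    softmax outputs in (0, 1) summing to 1.
    """
    if spec is None:
        params, spec = model_or_params.params, model_or_params.spec
    else:
        params = model_or_params
    single = np.asarray(x).ndim == 2
    x4 = _check_input(spec, x)
    probs = _forward_full(params, spec, x4)["probs"]
    return probs[0] if single else probs


def forward_activations(model: "TrainedCnn", x: np.ndarray) -> dict[str, np.ndarray]:
    """Post-ReLU conv activations and pooled maps for one input matrix.

    Returns arrays without the batch axis: ``l1`` (l1_filters, 9, 281),
    ``m1``, ``l2`` (l2_filters, 4, 129), ``m2`` for default shapes.
    """
    x4 = _check_input(model.spec, x)
    acts = _forward_full(model.params, model.spec, x4)
    return {"l1": acts["a1"][0], "m1": acts["m1"][0],
            "l2": acts["a2"][0], "m2": acts["m2"][0]}


def loss_and_grads(params: dict, spec: CnnSpec, x: np.ndarray, y: np.ndarray,
                   sample_weights: np.ndarray | None = None,
                   dropout_rng: np.random.Generator | None = None,
                   l1_cols: np.ndarray | None = None):
    """Weighted cross-entropy loss and analytic gradients for one batch.

    ``y`` holds class indices (0 = target, 1 = non-target).  The loss is
    sum(w_i * nll_i) / sum(w_i); unweighted when ``sample_weights`` is None.
    """
    x4 = x if x.ndim == 4 else _check_input(spec, x)
    acts = _forward_full(params, spec, x4, dropout_rng=dropout_rng, l1_cols=l1_cols)
    n = x4.shape[0]
    probs = acts["probs"].astype(np.float64)
    if sample_weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weights, dtype=np.float64)
    wsum = w.sum()
    nll = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None))
    loss = float((w * nll).sum() / wsum)

    dt = np.dtype(spec.dtype)
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits = (dlogits * (w / wsum)[:, None]).astype(dt)

    grads: dict[str, np.ndarray] = {}
    grads["Wo"] = acts["af"].T @ dlogits
    grads["bo"] = dlogits.sum(axis=0)
    daf = dlogits @ params["Wo"].T
    if acts["mask"] is not None:
        daf = daf * acts["mask"]
    dzf = daf * (acts["zf"] > 0)
    grads["Wf"] = acts["flat"].T @ dzf
    grads["bf"] = dzf.sum(axis=0)
    dflat = dzf @ params["Wf"].T
    dm2 = dflat.reshape(acts["m2"].shape)
    da2 = maxpool_backward(dm2, acts["mcache2"])
    dz2 = da2 * (acts["z2"] > 0)
    grads["W2"], grads["b2"], dm1 = conv_backward(
        dz2, acts["cols2"], params["W2"], acts["m1"].shape, need_dx=True)
    da1 = maxpool_backward(dm1, acts["mcache1"])
    dz1 = da1 * (acts["z1"] > 0)
    grads["W1"], grads["b1"], _ = conv_backward(
        dz1, acts["cols1"], params["W1"], acts["x_shape"], need_dx=False)
    return loss, grads


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

@dataclass
class TrainedCnn:
    """Fitted weights plus the spec and per-interval training history.

    ``history`` maps column name -> list, with one entry per recorded
    interval: iteration, train/validation correct-rate ((TP+TN)/total over
    per-input binary labels) and train/validation FP and FN rates.
    """

    spec: CnnSpec
    params: dict[str, np.ndarray]
    history: dict[str, list] = field(default_factory=dict)


def epoch_label(model: TrainedCnn, x: np.ndarray) -> bool | np.ndarray:
    """Binary label for input matrices: positive iff target score exceeds the
    non-target score.  An exact tie is labelled negative."""
    scores = forward(model, x)
    if scores.ndim == 1:
        return bool(scores[0] > scores[1])
    return scores[:, 0] > scores[:, 1]


def _rates(params: dict, spec: CnnSpec, x4: np.ndarray, y: np.ndarray,
           batch: int = 128, cols: np.ndarray | None = None,
           per_input: int = 0) -> tuple[float, float, float]:
    """(correct_rate, fp_rate, fn_rate) of current params on a labelled set."""
    pos = np.empty(len(y), dtype=bool)
    for i in range(0, len(y), batch):
        j = min(i + batch, len(y))
        l1_cols = cols[i * per_input: j * per_input] if cols is not None else None
        probs = _forward_full(params, spec, x4[i:j], l1_cols=l1_cols)["probs"]
        pos[i:j] = probs[:, 0] > probs[:, 1]
    truth_pos = y == 0
    tp = int(np.sum(pos & truth_pos))
    fp = int(np.sum(pos & ~truth_pos))
    fn = int(np.sum(~pos & truth_pos))
    tn = int(np.sum(~pos & ~truth_pos))
    correct = (tp + tn) / len(y)
    fp_rate = fp / (fp + tn) if fp + tn else np.nan
    fn_rate = fn / (fn + tp) if fn + tp else np.nan
    return correct, fp_rate, fn_rate


def _batches(n: int, batch_size: int, iterations: int,
             rng: np.random.Generator) -> Iterator[tuple[int, int]]:
    """Seeded stream of exactly ``iterations`` contiguous (start, stop) slices.

    The training set is shuffled once up front (see :func:`train`); each pass
    then walks contiguous minibatches from a seeded random offset, so the
    remainder samples dropped at the end of a pass differ between passes.
    Contiguous slices keep the cached first-layer patch matrix usable without
    per-iteration gathers.
    """
    done = 0
    if n <= batch_size:
        while done < iterations:
            yield 0, n
            done += 1
        return
    remainder = n % batch_size
    while done < iterations:
        off = int(rng.integers(0, remainder + 1))
        for i in range(off, n - batch_size + 1, batch_size):
            yield i, i + batch_size
            done += 1
            if done >= iterations:
                return


def train(spec: CnnSpec, inputs: np.ndarray, labels: np.ndarray) -> TrainedCnn:
    """Fit the CNN with Adam on labelled input matrices.

    Parameters
    ----------
    inputs : (N, 14, 300) array of wrapped input matrices.
    labels : (N,) array-like; truthy = target.  Internally class 0 = target,
        class 1 = non-target (matching the output-vector convention).

    The validation split (``spec.validation_fraction``), weight init,
    shuffling and dropout are all driven by ``spec.seed``.  Raises on
    single-class data or non-finite loss.
    """
    labels = np.asarray(labels)
    y = np.where(labels.astype(bool), 0, 1)
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class; need both "
                         "target and non-target inputs")
    x4 = _check_input(spec, np.asarray(inputs))

    root = np.random.SeedSequence(spec.seed)
    init_rng, split_rng, shuffle_rng, drop_rng = (
        np.random.default_rng(s) for s in root.spawn(4))

    # stratified validation split so both classes appear on each side
    idx_pos = np.flatnonzero(y == 0)
    idx_neg = np.flatnonzero(y == 1)
    val_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for idx in (idx_pos, idx_neg):
        idx = split_rng.permutation(idx)
        n_val = int(round(len(idx) * spec.validation_fraction))
        n_val = min(max(n_val, 1 if spec.validation_fraction > 0 else 0), len(idx) - 1)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    tr = shuffle_rng.permutation(np.concatenate(train_idx))
    va = np.concatenate(val_idx)
    x_tr, y_tr = x4[tr], y[tr]
    x_va, y_va = x4[va], y[va]

    if spec.class_weighting:
        counts = np.bincount(y_tr, minlength=2)
        class_w = len(y_tr) / (2.0 * counts)
    else:
        class_w = np.ones(2)

    params = init_params(spec, init_rng)
    # Adam state
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    lr = spec.learning_rate

    # Patch matrix of the (fixed, pre-shuffled) training inputs, built once;
    # contiguous minibatch slices view into it without copying.
    kh1, kw1 = spec.l1_kernel
    shapes = layer_shapes(spec)
    per_input = shapes["l1"][0] * shapes["l1"][1]
    cols_all = _im2col(x_tr, kh1, kw1)

    history: dict[str, list] = {k: [] for k in (
        "iteration", "loss", "train_correct", "val_correct",
        "train_fp", "train_fn", "val_fp", "val_fn")}

    def record(it: int, loss: float) -> None:
        tc, tfp, tfn = _rates(params, spec, x_tr, y_tr,
                              cols=cols_all, per_input=per_input)
        vc, vfp, vfn = _rates(params, spec, x_va, y_va)
        for key, val in zip(history, (it, loss, tc, vc, tfp, tfn, vfp, vfn)):
            history[key].append(val)

    step = 0
    loss = np.nan
    for lo, hi in _batches(len(y_tr), spec.batch_size, spec.iterations, shuffle_rng):
        step += 1
        l1_cols = cols_all[lo * per_input: hi * per_input]
        xb, yb = x_tr[lo:hi], y_tr[lo:hi]
        loss, grads = loss_and_grads(
            params, spec, xb, yb,
            sample_weights=class_w[yb],
            dropout_rng=drop_rng if spec.dropout_rate > 0 else None,
            l1_cols=l1_cols)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at iteration {step}; "
                "reduce the learning rate")
        t = step
        for k in params:
            g = grads[k]
            m[k] = beta1 * m[k] + (1 - beta1) * g
            v[k] = beta2 * v[k] + (1 - beta2) * (g * g)
            mhat = m[k] / (1 - beta1 ** t)
            vhat = v[k] / (1 - beta2 ** t)
            params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(params[k].dtype)
        if step % spec.record_every == 0 or step == spec.iterations:
            record(step, loss)

    return TrainedCnn(spec=spec, params=params, history=history)


# --------------------------------------------------------------------------
# Checkpoint I/O: flat plain-text container
# --------------------------------------------------------------------------

def save_checkpoint(model: TrainedCnn, path) -> None:
    """Write spec (JSON line) and named weight arrays as a flat text file."""
    with open(path, "w") as fh:
        spec_dict = {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in vars(model.spec).items()}
        fh.write("#spec " + json.dumps(spec_dict) + "\n")
        for name, arr in model.params.items():
            fh.write(f"#array {name} {','.join(map(str, arr.shape))}\n")
            fh.write(" ".join(format(x, ".17g") for x in arr.ravel().tolist()))
            fh.write("\n")


def load_checkpoint(path) -> TrainedCnn:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#spec "):
            raise ValueError(f"{path}: not a checkpoint file")
        raw = json.loads(header[len("#spec "):])
        for key in ("l1_kernel", "m1_pool", "l2_kernel", "m2_pool", "input_shape"):
            raw[key] = tuple(raw[key])
        spec = CnnSpec(**raw)
        params = {}
        for line in fh:
            if not line.startswith("#array "):
                raise ValueError(f"{path}: malformed array header {line!r}")
            _, name, shape_s = line.split()
            shape = tuple(int(s) for s in shape_s.split(","))
            vals = np.array(fh.readline().split(), dtype=np.float64)
            params[name] = vals.reshape(shape).astype(spec.dtype)
    return TrainedCnn(spec=spec, params=params, history={})
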