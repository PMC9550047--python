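"""Encoder–decoder segmentation network, combined loss, training, inference.

The network is a small configurable U-Net: ``depth`` resolution stages with
channel doubling on the way down, a symmetric decoder with skip connections,
instance normalization and leaky-ReLU activations, and a 1×1 output
convolution producing per-voxel class scores.  It is built on the numpy
layer kit in :mod:`cuffseg._nn` and trains on CPU in seconds at toy scale.

The loss is the sum of a weighted cross-entropy term and a soft-Dice term

    L = WCE(y, ŷ) + 1 − mean_c (2|y_c ∩ ŷ_c| + ε) / (|y_c| + |ŷ_c| + ε)

with the Dice mean taken over foreground classes only (background dominance
would otherwise swamp the term) and ε guarding empty-empty classes, for
which the Dice ratio is exactly 1 and the contribution exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _nn
from .preprocess import AugmentParams, PatchSpec, augment, normalize_intensity, sample_patches
from .volio import ImageVolume, LabelMap

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "Prediction",
    "UNet",
    "build_network",
    "combined_loss",
    "train",
    "predict",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the segmentation network.

    ``pool_factors`` controls per-axis downsampling at each stage; the 3-D
    default pools every axis by 2 (use (1, 2, 2) to spare a thin slice axis).
    """

    dimensionality: int = 3
    n_classes: int = 5
    base_channels: int = 8
    depth: int = 2
    pool_factors: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3):
            raise ValueError(f"dimensionality must be 2 or 3, got {self.dimensionality}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.pool_factors is not None and len(self.pool_factors) != self.dimensionality:
            raise ValueError("pool_factors must match dimensionality")

    @property
    def pools(self) -> tuple[int, ...]:
        if self.pool_factors is not None:
            return tuple(int(f) for f in self.pool_factors)
        return (2,) * self.dimensionality


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults mirror a conventional patch-based setup (batch size 8, SGD with
    momentum, early stopping on the tuning loss); tests shrink
    ``steps_per_epoch`` and ``max_epochs`` to desk scale.
    """

    batch_size: int = 8
    max_epochs: int = 1000
    steps_per_epoch: int = 250
    learning_rate: float = 0.05
    momentum: float = 0.9
    patience: int = 30
    epsilon: float = 1e-5
    class_weights: tuple[float, ...] | None = None
    dice_classes: tuple[int, ...] | None = None  # None: every foreground class
    lr_decay_power: float | None = None  # polynomial decay exponent; None = fixed
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("class_weights must be >= 0 and not all zero")


@dataclass
class Prediction:
    """Per-class probabilities plus their argmax label map."""

    probabilities: np.ndarray  # (n_classes, slice, row, col)
    argmax_labels: LabelMap

    def __post_init__(self) -> None:
        s = self.probabilities.sum(axis=0)
        if not np.allclose(s, 1.0, atol=1e-5):
            raise ValueError("per-voxel probabilities must sum to 1")


class _ConvBlock:
    """(Conv -> InstanceNorm -> LeakyReLU) x 2."""

    def __init__(self, in_ch, out_ch, ndim, rng):
        self.layers = []
        for i, ic in enumerate((in_ch, out_ch)):
            self.layers += [
                _nn.ConvNd(ic, out_ch, 3, ndim, rng),
                _nn.InstanceNorm(out_ch),
                _nn.LeakyReLU(),
            ]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def params(self):
        return [p for l in self.layers for p in l.params()]


class UNet:
    """Configurable 2-D / 3-D U-Net over the numpy layer kit."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        nd = cfg.dimensionality
        ch = [cfg.base_channels * 2**d for d in range(cfg.depth + 1)]

        self.enc = []
        in_ch = 1
        for d in range(cfg.depth):
            self.enc.append(_ConvBlock(in_ch, ch[d], nd, rng))
            in_ch = ch[d]
        self.pool = _nn.MaxPool(cfg.pools)
        self.bottleneck = _ConvBlock(in_ch, ch[-1], nd, rng)
        self.up = _nn.Upsample(cfg.pools)
        self.dec = []
        for d in reversed(range(cfg.depth)):
            # input: upsampled deeper features + skip connection
            self.dec.append(_ConvBlock(ch[d + 1] + ch[d], ch[d], nd, rng))
        self.head = _nn.ConvNd(ch[0], cfg.n_classes, 1, nd, rng)

    # -- bookkeeping -------------------------------------------------------
    def params(self) -> list[_nn.Param]:
        out = []
        for b in self.enc:
            out += b.params()
        out += self.bottleneck.params()
        for b in self.dec:
            out += b.params()
        out += self.head.params()
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def get_state(self):
        return [p.value.copy() for p in self.params()]

    def set_state(self, state) -> None:
        for p, v in zip(self.params(), state):
            p.value[...] = v

    def validate_patch(self, spatial_shape: tuple[int, ...]) -> None:
        """Raise if pooling ``depth`` times is impossible for this patch."""
        sizes = list(spatial_shape)
        for _ in range(self.cfg.depth):
            for i, f in enumerate(self.cfg.pools):
                if sizes[i] % f or sizes[i] // f < 1:
                    raise ValueError(
                        f"depth {self.cfg.depth} incompatible with patch "
                        f"{tuple(spatial_shape)}: axis {i} reaches size "
                        f"{sizes[i]}/{f} (must stay a positive multiple of {f})"
                    )
                sizes[i] //= f

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, *spatial) -> logits (N, n_classes, *spatial)."""
        self.validate_patch(x.shape[2:])
        self._pools = []
        self._skips = []
        h = x.astype(np.float32)
        for blk in self.enc:
            h = blk.forward(h)
            self._skips.append(h)
            pool = _nn.MaxPool(self.cfg.pools)
            h = pool.forward(h)
            self._pools.append(pool)
        h = self.bottleneck.forward(h)
        self._ups = []
        self._concat_ch = []
        for blk, skip in zip(self.dec, reversed(self._skips)):
            up = _nn.Upsample(self.cfg.pools)
            h = up.forward(h)
            self._ups.append(up)
            self._concat_ch.append((h.shape[1], skip.shape[1]))
            h = np.concatenate([h, skip], axis=1)
            h = blk.forward(h)
        return self.head.forward(h)

    def backward(self, g_logits: np.ndarray) -> None:
        g = self.head.backward(g_logits)
        skip_grads = []
        # reverse pass over decoder stages
        for i in reversed(range(len(self.dec))):
            g = self.dec[i].backward(g)
            c_up = self._concat_ch[i][0]
            g_up, g_skip = g[:, :c_up], g[:, c_up:]
            skip_grads.append(g_skip)
            g = self._ups[i].backward(g_up)
        g = self.bottleneck.backward(g)
        # walking the decoder in reverse build order appends skip gradients
        # already in encoder order: dec[i] pairs with enc[depth-1-i]
        for d in reversed(range(len(self.enc))):
            g = self._pools[d].backward(g)
            g = g + skip_grads[d]
            g = self.enc[d].backward(g)


def build_network(cfg: NetworkConfig, seed: int = 0,
                  patch_shape: tuple[int, ...] | None = None) -> UNet:
    """Construct a seeded U-Net; optionally validate depth against a patch."""
    net = UNet(cfg, seed=seed)
    if patch_shape is not None:
        net.validate_patch(tuple(patch_shape))
    return net


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def combined_loss(probabilities, target_onehot, weights=None, epsilon: float = 1e-5,
                  foreground_classes=None) -> float:
    """Weighted cross-entropy plus (1 − mean foreground soft Dice).

    ``probabilities`` and ``target_onehot`` share shape ``(C, *spatial)`` or
    ``(N, C, *spatial)``.  The cross-entropy is the *sum* over voxels of
    ``−w_y · log p_y``; the Dice mean runs over ``foreground_classes``
    (default: every class index ≥ 1).
    """
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(target_onehot, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape} vs target {y.shape}")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if p.ndim == 4:  # single sample (C, z, y, x) -> add batch axis
        p, y = p[None], y[None]
    n_classes = p.shape[1]
    w = np.ones(n_classes) if weights is None else np.asarray(weights, dtype=np.float64)

    logp = np.log(np.clip(p, 1e-12, None))
    wshape = (1, n_classes) + (1,) * (p.ndim - 2)
    wce = -float((y * logp * w.reshape(wshape)).sum())

    if foreground_classes is None:
        foreground_classes = range(1, n_classes)
    dice_terms = []
    for c in foreground_classes:
        inter = (p[:, c] * y[:, c]).sum()
        sums = p[:, c].sum() + y[:, c].sum()
        dice_terms.append((2.0 * inter + epsilon) / (sums + epsilon))
    dice_loss = 1.0 - float(np.mean(dice_terms))
    return float(wce + dice_loss)


def _loss_and_grad(logits, target_int, weights, epsilon, dice_classes=None):
    """Training-time loss (per-voxel-mean CE + Dice) and d/d logits.

    The cross-entropy is normalized by voxel count here so the gradient
    scale — hence usable learning rates — is independent of patch size; the
    public :func:`combined_loss` keeps the sum form.
    """
    N = logits.shape[0]
    C = logits.shape[1]
    spatial = logits.shape[2:]
    nv = N * int(np.prod(spatial))
    p = softmax(logits.astype(np.float64), axis=1)
    onehot = np.moveaxis(np.eye(C, dtype=np.float64)[target_int], -1, 1)
    w = np.ones(C) if weights is None else np.asarray(weights, dtype=np.float64)

    logp = np.log(np.clip(p, 1e-12, None))
    wv = w[target_int]  # per-voxel weight of the true class, (N, *spatial)
    ce = -(wv * np.take_along_axis(logp, target_int[:, None], axis=1)[:, 0]).sum() / nv
    g_ce = wv[:, None] * (p - onehot) / nv

    fg = list(range(1, C)) if dice_classes is None else list(dice_classes)
    dice_sum = 0.0
    g_p = np.zeros_like(p)
    for c in fg:
        inter = (p[:, c] * onehot[:, c]).sum()
        sums = p[:, c].sum() + onehot[:, c].sum()
        d = (2.0 * inter + epsilon) / (sums + epsilon)
        dice_sum += d
        # d(dice_c)/d(p_c,v) = (2 y_v (sums+eps) - (2 inter + eps)) / (sums+eps)^2
        g_p[:, c] = -(2.0 * onehot[:, c] * (sums + epsilon) - (2.0 * inter + epsilon)) / (
            (sums + epsilon) ** 2
        ) / len(fg)
    dice_loss = 1.0 - dice_sum / len(fg)
    # chain rule through the softmax: dL/dz = p * (g - sum_c g_c p_c)
    g_dice = p * (g_p - (g_p * p).sum(axis=1, keepdims=True))

    loss = float(ce + dice_loss)
    return loss, (g_ce + g_dice).astype(np.float32)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _batch_from_patches(pairs, ndim):
    imgs = np.stack([p[0] for p in pairs]).astype(np.float32)
    lbls = np.stack([p[1] for p in pairs])
    if ndim == 2:  # drop the singleton slice axis of 2-D-mode patches
        imgs, lbls = imgs[:, 0], lbls[:, 0]
    return imgs[:, None], lbls.astype(np.int64)


def train(
    train_cases,
    tune_cases,
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    patch_spec: PatchSpec,
    augment_params: AugmentParams | None = None,
):
    """SGD training over augmented patches with early stopping on tuning loss.

    Case images are intensity-normalized internally; callers of
    :func:`predict` must apply the same normalization.  Returns
    ``(model, history)`` where ``history`` is a list of per-epoch dicts with
    ``train_loss`` and ``tune_loss``; the returned model carries the
    parameters of the best tuning epoch.
    """
    if not train_cases or not tune_cases:
        raise ValueError("need at least one train case and one tune case")
    if train_cfg.class_weights is not None and len(train_cfg.class_weights) != net_cfg.n_classes:
        raise ValueError("class_weights length must equal n_classes")

    from .phantom import PhantomCase  # local import to avoid a cycle

    def _prep(case):
        img = normalize_intensity(case.image)
        return PhantomCase(
            image=img, truth=case.truth, confuser_mask=np.zeros(img.shape, bool),
            tear_category=getattr(case, "tear_category", "intact"), case_id=case.case_id,
        )

    train_prep = [_prep(c) for c in train_cases]
    tune_prep = [_prep(c) for c in tune_cases]

    net = build_network(net_cfg, seed=train_cfg.seed)
    probe = patch_spec.shape_for(train_prep[0].image.shape)
    net.validate_patch(probe[1:] if net_cfg.dimensionality == 2 else probe)
    opt = _nn.SGD(net.params(), lr=train_cfg.learning_rate, momentum=train_cfg.momentum)
    rng = np.random.default_rng(train_cfg.seed)

    # fixed tuning patches so tune losses are comparable across epochs
    tune_rng = np.random.default_rng(train_cfg.seed + 1)
    tune_pairs = []
    for case in tune_prep:
        tune_pairs += sample_patches(case, patch_spec, max(2, train_cfg.batch_size // 2), tune_rng)

    history = []
    best_tune = np.inf
    best_state = net.get_state()
    stall = 0
    total_steps = max(1, train_cfg.max_epochs * train_cfg.steps_per_epoch)
    step_no = 0
    for epoch in range(train_cfg.max_epochs):
        ep_loss = 0.0
        for _ in range(train_cfg.steps_per_epoch):
            if train_cfg.lr_decay_power is not None:
                frac = 1.0 - step_no / total_steps
                opt.lr = train_cfg.learning_rate * frac**train_cfg.lr_decay_power
            step_no += 1
            pairs = []
            for _ in range(train_cfg.batch_size):
                case = train_prep[rng.integers(len(train_prep))]
                (img, lbl), = sample_patches(case, patch_spec, 1, rng)
                if augment_params is not None:
                    img, lbl = augment(img, lbl, augment_params, rng)
                pairs.append((img, lbl))
            x, yb = _batch_from_patches(pairs, net_cfg.dimensionality)
            logits = net.forward(x)
            loss, g = _loss_and_grad(logits, yb, train_cfg.class_weights,
                                     train_cfg.epsilon, train_cfg.dice_classes)
            opt.zero_grad()
            net.backward(g)
            opt.step()
            ep_loss += loss
        ep_loss /= train_cfg.steps_per_epoch

        # tuning loss on the frozen patch set
        tune_loss = 0.0
        nb = 0
        for i in range(0, len(tune_pairs), train_cfg.batch_size):
            x, yb = _batch_from_patches(
                tune_pairs[i : i + train_cfg.batch_size], net_cfg.dimensionality
            )
            logits = net.forward(x)
            l, _ = _loss_and_grad(logits, yb, train_cfg.class_weights,
                                  train_cfg.epsilon, train_cfg.dice_classes)
            tune_loss += l
            nb += 1
        tune_loss /= max(nb, 1)
        history.append({"epoch": epoch, "train_loss": ep_loss, "tune_loss": tune_loss})

        if tune_loss < best_tune - 1e-9:
            best_tune = tune_loss
            best_state = net.get_state()
            stall = 0
        else:
            stall += 1
            if stall >= train_cfg.patience:
                break

    net.set_state(best_state)
    return net, history


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_model(model: UNet, path) -> None:
    """Serialize a model (config + parameters) to an .npz checkpoint."""
    cfg = model.cfg
    meta = np.array(
        [cfg.dimensionality, cfg.n_classes, cfg.base_channels, cfg.depth, model.seed],
        dtype=np.int64,
    )
    pools = np.array(cfg.pools, dtype=np.int64)
    state = {f"p{i}": v for i, v in enumerate(model.get_state())}
    np.savez(path, _meta=meta, _pools=pools, **state)


def load_model(path) -> UNet:
    """Restore a model saved by :func:`save_model`."""
    with np.load(path) as npz:
        meta = npz["_meta"]
        cfg = NetworkConfig(
            dimensionality=int(meta[0]),
            n_classes=int(meta[1]),
            base_channels=int(meta[2]),
            depth=int(meta[3]),
            pool_factors=tuple(int(f) for f in npz["_pools"]),
        )
        net = UNet(cfg, seed=int(meta[4]))
        state = [npz[f"p{i}"] for i in range(len(net.params()))]
    net.set_state(state)
    return net


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def _window_starts(size: int, patch: int) -> list[int]:
    """Start offsets of 50%-overlap windows covering [0, size)."""
    if size <= patch:
        return [0]
    stride = max(1, patch // 2)
    starts = list(range(0, size - patch, stride))
    starts.append(size - patch)
    return starts


def predict(model: UNet, vol: ImageVolume, patch_spec: PatchSpec) -> Prediction:
    """Sliding-window inference with 50% overlap and probability averaging.

    The volume must have been preprocessed (normalized) identically to the
    training data.  Volumes smaller than the patch are zero-padded, predicted
    and cropped back.
    """
    cfg = model.cfg
    pshape = patch_spec.shape_for(vol.shape)
    vals = vol.values.astype(np.float32)
    orig_shape = vals.shape
    pad = [max(0, p - s) for p, s in zip(pshape, orig_shape)]
    if any(pad):
        vals = np.pad(vals, [(0, q) for q in pad])
    shape = vals.shape

    prob_sum = np.zeros((cfg.n_classes, *shape), dtype=np.float64)
    hits = np.zeros(shape, dtype=np.float64)
    starts = [
        (a, b, c)
        for a in _window_starts(shape[0], pshape[0])
        for b in _window_starts(shape[1], pshape[1])
        for c in _window_starts(shape[2], pshape[2])
    ]
    for (a, b, c) in starts:
        sl = (slice(a, a + pshape[0]), slice(b, b + pshape[1]), slice(c, c + pshape[2]))
        patch = vals[sl]
        if cfg.dimensionality == 2:
            logits = model.forward(patch[:, None])  # slices as the batch axis
            probs = softmax(logits, axis=1)  # (n_slices, C, row, col)
            probs = np.moveaxis(probs, 1, 0)
        else:
            logits = model.forward(patch[None, None])
            probs = softmax(logits, axis=1)[0]
        prob_sum[(slice(None),) + sl] += probs
        hits[sl] += 1.0

    assert hits.min() >= 1.0
    probs = prob_sum / hits[None]
    probs /= probs.sum(axis=0, keepdims=True)
    crop = tuple(slice(0, s) for s in orig_shape)
    probs = probs[(slice(None),) + crop]
    labels = np.argmax(probs, axis=0).astype(np.int16)
    return Prediction(
        probabilities=probs.astype(np.float32),
        argmax_labels=LabelMap(labels=labels, spacing_mm=vol.spacing_mm, n_classes=cfg.n_classes),
    )
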