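"""A 4-class U-Net for EM patch segmentation, implemented in pure numpy.

The network is the classic encoder-decoder: four levels of two 3x3
"same"-padded convolutions + ReLU followed by 2x2 max-pooling, a two-conv
bridge, then four decoder levels of 2x2 transposed convolution, skip
concatenation and two more conv+ReLU blocks, closed by a 1x1 convolution to
per-pixel class scores and a softmax.  Counting every Conv (including the
final 1x1), ReLU, MaxPool, TransposedConv and the Softmax as one layer each
(skip concatenations are wiring, not layers) the default depth-4 model has
4*5 + 4 + 4*5 + 1 + 1 = 46 layers.

Training minimises unweighted per-pixel cross-entropy with Adam.  Forward,
backward and the optimiser are written against BLAS-backed matrix products
(im2col convolutions), so desk-scale models (small ``base_channels``, 64-px
patches) train in seconds-to-minutes on one CPU; the full-scale defaults
(base 64 channels, 128-px patches, 15 epochs, batch 64) match the study
configuration and are supported but slow without hardware acceleration.

Inference on slices of arbitrary size is tiled: overlapping tiles are
predicted and only each tile's central block is mosaicked into the output,
with reflective padding at the borders.

All tensors are NHWC float32; class maps are uint8 over the 4-code alphabet.
Argmax ties break toward the lowest class code.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .volume_io import N_CLASSES


class UNetError(Exception):
    pass


@dataclass
class UNetConfig:
    """U-Net hyperparameters; defaults are the full-study settings."""

    depth: int = 4
    in_patch: int = 128
    n_classes: int = N_CLASSES
    base_channels: int = 64
    epochs: int = 15
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise UNetError("n_classes must be >= 2")
        if self.depth < 1:
            raise UNetError("depth must be >= 1")
        if self.in_patch % (2 ** self.depth) != 0:
            raise UNetError(
                f"in_patch {self.in_patch} must be divisible by 2^depth = {2 ** self.depth}")


# ---------------------------------------------------------------------------
# layers


class _Layer:
    name = "layer"
    counts = True  # participates in the layer count

    def params(self):
        return []


class _Conv2D(_Layer):
    """3x3 (or 1x1) same-padded convolution via im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 name: str):
        self.k, self.cin, self.cout, self.name = k, cin, cout, name
        fan_in = k * k * cin
        self.w = (rng.standard_normal((k, k, cin, cout)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols = None

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    @staticmethod
    def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
        if pad:
            x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # (N, H, W, C, k, k) -> (N*H*W, k*k*C) with (a, b, c) ordering
        n, h, w = win.shape[:3]
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, -1)
        return np.ascontiguousarray(cols, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        pad = self.k // 2
        cols = self._im2col(x, self.k, pad)
        y = cols @ self.w.reshape(-1, self.cout) + self.b
        if train:
            self._cols = cols
            self._in_shape = x.shape
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        dyf = dy.reshape(-1, self.cout).astype(np.float32)
        self.dw = (self._cols.T @ dyf).reshape(self.w.shape)
        self.db = dyf.sum(axis=0)
        self._cols = None
        # dx = "full" correlation of dy with the flipped, transposed kernel
        pad2 = self.k - 1 - self.k // 2
        w2 = self.w[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,Cout,Cin)
        cols2 = self._im2col(dy, self.k, pad2)
        dx = cols2 @ w2.reshape(-1, self.cin)
        return dx.reshape(self._in_shape)


class _ReLU(_Layer):
    def __init__(self, name: str):
        self.name = name

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class _MaxPool2(_Layer):
    def __init__(self, name: str):
        self.name = name

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        if train:
            self._mask = xr == y[:, :, None, :, None, :]
            # break ties so gradient is routed to exactly one input
            flat = self._mask.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
            first = flat.argmax(axis=-1)
            onehot = np.eye(4, dtype=bool)[first]
            self._mask = onehot.reshape(n, h // 2, w // 2, c, 2, 2) \
                               .transpose(0, 1, 4, 2, 5, 3)
            self._in_shape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, c = dy.shape
        dxr = self._mask * dy[:, :, None, :, None, :]
        return dxr.reshape(self._in_shape)


class _ConvTranspose2(_Layer):
    """2x2 transposed convolution with stride 2 (exact x2 upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str):
        self.cin, self.cout, self.name = cin, cout, name
        self.w = (rng.standard_normal((2, 2, cin, cout)) *
                  np.sqrt(2.0 / cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        y = np.einsum("nijc,abco->niajbo", x, self.w, optimize=True)
        y = y.reshape(n, 2 * h, 2 * w, self.cout) + self.b
        if train:
            self._x = x
        return y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h2, w2, _ = dy.shape
        dyr = dy.reshape(n, h2 // 2, 2, w2 // 2, 2, self.cout)
        self.dw = np.einsum("nijc,niajbo->abco", self._x, dyr, optimize=True) \
                    .astype(np.float32)
        self.db = dy.sum(axis=(0, 1, 2))
        dx = np.einsum("niajbo,abco->nijc", dyr, self.w, optimize=True)
        self._x = None
        return dx.astype(np.float32)


class _Softmax(_Layer):
    """Listed in the summary; the numerics live in the loss function."""

    def __init__(self):
        self.name = "softmax"


# ---------------------------------------------------------------------------
# model


class UNet:
    """Depth-``d`` encoder/decoder built from the layers above."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        b, d = config.base_channels, config.depth
        self.enc: list[tuple[_Conv2D, _ReLU, _Conv2D, _ReLU, _MaxPool2]] = []
        cin = 1
        for lvl in range(d):
            cout = b * 2 ** lvl
            self.enc.append((
                _Conv2D(cin, cout, 3, rng, f"enc{lvl}_conv1"), _ReLU(f"enc{lvl}_relu1"),
                _Conv2D(cout, cout, 3, rng, f"enc{lvl}_conv2"), _ReLU(f"enc{lvl}_relu2"),
                _MaxPool2(f"enc{lvl}_pool")))
            cin = cout
        cb = b * 2 ** d
        self.bridge = (
            _Conv2D(cin, cb, 3, rng, "bridge_conv1"), _ReLU("bridge_relu1"),
            _Conv2D(cb, cb, 3, rng, "bridge_conv2"), _ReLU("bridge_relu2"))
        self.dec: list[tuple[_ConvTranspose2, _Conv2D, _ReLU, _Conv2D, _ReLU]] = []
        cin = cb
        for lvl in reversed(range(d)):
            cskip = b * 2 ** lvl
            self.dec.append((
                _ConvTranspose2(cin, cskip, rng, f"dec{lvl}_up"),
                _Conv2D(cskip * 2, cskip, 3, rng, f"dec{lvl}_conv1"), _ReLU(f"dec{lvl}_relu1"),
                _Conv2D(cskip, cskip, 3, rng, f"dec{lvl}_conv2"), _ReLU(f"dec{lvl}_relu2")))
            cin = cskip
        self.head = _Conv2D(cin, config.n_classes, 1, rng, "head_conv1x1")
        self.softmax = _Softmax()

    # -- structure ---------------------------------------------------------
    def layers(self) -> list[_Layer]:
        out: list[_Layer] = []
        for blk in self.enc:
            out.extend(blk)
        out.extend(self.bridge)
        for blk in self.dec:
            out.extend(blk)
        out.append(self.head)
        out.append(self.softmax)
        return out

    @property
    def layer_count(self) -> int:
        return len(self.layers())

    def summary(self) -> str:
        lines = [f"{i + 1:3d}  {layer.name}" for i, layer in enumerate(self.layers())]
        lines.append(f"total layers: {self.layer_count}")
        return "\n".join(lines)

    def params(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    # -- compute -----------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, H, W, 1) float32 in [0,1]; returns logits (N, H, W, K)."""
        if x.ndim != 4:
            raise UNetError(f"expected NHWC input, got shape {x.shape}")
        h, w = x.shape[1:3]
        f = 2 ** self.config.depth
        if h % f or w % f:
            raise UNetError(f"spatial dims {h}x{w} must be divisible by {f}")
        skips = []
        for c1, r1, c2, r2, pool in self.enc:
            x = r1.forward(c1.forward(x, train), train)
            x = r2.forward(c2.forward(x, train), train)
            skips.append(x)
            x = pool.forward(x, train)
        c1, r1, c2, r2 = self.bridge
        x = r1.forward(c1.forward(x, train), train)
        x = r2.forward(c2.forward(x, train), train)
        self._skip_channels = []
        for (up, c1, r1, c2, r2), skip in zip(self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[-1])
            x = np.concatenate([skip, x], axis=-1)
            x = r1.forward(c1.forward(x, train), train)
            x = r2.forward(c2.forward(x, train), train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for (up, c1, r1, c2, r2), cs in zip(reversed(self.dec),
                                            reversed(self._skip_channels)):
            d = c1.backward(r1.backward(c2.backward(r2.backward(dx))))
            dskip, dup = d[..., :cs], d[..., cs:]
            dskips.append(dskip)
            dx = up.backward(dup)
        c1, r1, c2, r2 = self.bridge
        dx = c1.backward(r1.backward(c2.backward(r2.backward(dx))))
        for (c1, r1, c2, r2, pool), dskip in zip(reversed(self.enc), reversed(dskips)):
            dx = pool.backward(dx) + dskip
            dx = c1.backward(r1.backward(c2.backward(r2.backward(dx))))


def build_unet(config: UNetConfig | None = None) -> UNet:
    """Construct a U-Net from a config (default: the full-study settings)."""
    return UNet(config or UNetConfig())


# ---------------------------------------------------------------------------
# loss / optimiser / training


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean per-pixel cross-entropy and its gradient w.r.t. the logits."""
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=-1, keepdims=True)
    n = targets.size
    idx = (*np.indices(targets.shape), targets)
    loss = float(-np.log(np.clip(p[idx], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[idx] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    """Adam over the model's parameters; gradients are re-read from the model
    every step (layers rebuild their gradient arrays on each backward pass)."""

    def __init__(self, model: UNet, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in model.params()]
        self.v = [np.zeros_like(w) for w, _ in model.params()]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (w, g) in enumerate(self.model.params()):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            w -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


def pairs_to_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    """PatchPair list -> (X float32 NHW1 in [0,1], Y int labels NHW)."""
    x = np.stack([np.asarray(p.image, dtype=np.float32) / 255.0 for p in pairs])[..., None]
    y = np.stack([np.asarray(p.label) for p in pairs]).astype(np.int64)
    return x, y


def train(model: UNet, pairs, config: UNetConfig | None = None,
          checkpoint: str | Path | None = None):
    """Train with Adam on per-pixel cross-entropy.

    Returns ``(model, loss_trace)`` where the trace holds one mean loss per
    epoch.  A fixed config seed reproduces the trace exactly on one device.
    A batch size above the pair count simply yields single-batch epochs.
    """
    if config is None:
        config = model.config
    if not pairs:
        raise UNetError("empty training set")
    x, y = pairs_to_arrays(pairs) if not isinstance(pairs, tuple) else pairs
    n = x.shape[0]
    rng = np.random.default_rng(config.seed)
    opt = Adam(model, config.learning_rate)
    trace = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            logits = model.forward(x[sel], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[sel])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    if checkpoint is not None:
        save_model(model, checkpoint)
    return model, trace


def save_model(model: UNet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": w for i, (w, _) in enumerate(model.params())}
    np.savez(path, config=json.dumps(asdict(model.config)), **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_model(path: str | Path) -> UNet:
    with np.load(path, allow_pickle=False) as z:
        config = UNetConfig(**json.loads(str(z["config"])))
        model = UNet(config)
        for i, (w, _) in enumerate(model.params()):
            w[...] = z[f"p{i}"]
    return model


# ---------------------------------------------------------------------------
# inference


def _pad_reflect(img: np.ndarray, pads: tuple[tuple[int, int], tuple[int, int]]):
    """Reflective padding that tolerates pads larger than the image."""
    out = img
    for axis, (lo, hi) in enumerate(pads):
        while lo > 0 or hi > 0:
            m = out.shape[axis] - 1
            a, b = min(lo, m), min(hi, m)
            pad = [(0, 0), (0, 0)]
            pad[axis] = (a, b)
            out = np.pad(out, pad, mode="reflect")
            lo, hi = lo - a, hi - b
    return out


def predict_patch(model: UNet, patch: np.ndarray) -> np.ndarray:
    """Class map for a single patch whose dims divide 2^depth."""
    x = np.asarray(patch, dtype=np.float32)[None, ..., None] / 255.0
    logits = model.forward(x, train=False)
    return logits[0].argmax(axis=-1).astype(np.uint8)


def predict_slice(model: UNet, slice_: np.ndarray,
                  tile: int | None = None) -> np.ndarray:
    """Tiled inference over a slice of arbitrary size.

    Tiles of side *tile* (default: the model's training patch size) are
    predicted at stride tile/2 and only each tile's central tile/2 block is
    kept for the mosaic; borders use reflective padding.  Slices smaller
    than one tile are padded out and cropped back.
    """
    img = np.asarray(slice_)
    if img.ndim != 2:
        raise UNetError(f"expected a 2D slice, got shape {img.shape}")
    t = tile or model.config.in_patch
    keep = t // 2
    margin = (t - keep) // 2
    h, w = img.shape
    nr = -(-h // keep)   # ceil
    nc = -(-w // keep)
    hp = (nr - 1) * keep + t
    wp = (nc - 1) * keep + t
    padded = _pad_reflect(img.astype(np.float32),
                          ((margin, hp - h - margin), (margin, wp - w - margin)))
    # batch all tiles through the network at once when small, else chunk
    tiles = []
    for i in range(nr):
        for j in range(nc):
            tiles.append(padded[i * keep:i * keep + t, j * keep:j * keep + t])
    tiles = np.stack(tiles)[..., None] / 255.0
    out = np.zeros((hp - 2 * margin, wp - 2 * margin), dtype=np.uint8)
    chunk = max(1, 2 ** 22 // (t * t))   # keep activation memory bounded
    preds = []
    for s in range(0, len(tiles), chunk):
        logits = model.forward(tiles[s:s + chunk], train=False)
        preds.append(logits.argmax(axis=-1).astype(np.uint8))
    preds = np.concatenate(preds)
    k = 0
    for i in range(nr):
        for j in range(nc):
            out[i * keep:(i + 1) * keep, j * keep:(j + 1) * keep] = \
                preds[k, margin:margin + keep, margin:margin + keep]
            k += 1
    return out[:h, :w]


def predict_volume(model: UNet, volume, tile: int | None = None) -> np.ndarray:
    """Per-slice tiled inference over a stack; returns a uint8 class volume."""
    data = volume.data if not isinstance(volume, np.ndarray) and hasattr(volume, "data") \
        else np.asarray(volume)
    return np.stack([predict_slice(model, sl, tile) for sl in data])
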