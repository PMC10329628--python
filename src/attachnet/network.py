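"""3D U-shaped convolutional network for voxel attachment segmentation.

Maps F distance-field channels on the embedding grid to a per-voxel
attachment probability. Trained with the sum of binary cross-entropy and
soft-Dice complement, optimized with AdamW at batch size 5.

The network is small enough (three resolution levels, two 3x3x3
convolutions + instance norm + ReLU per level, 2x max-pool down,
nearest-neighbor up-sampling with skip concatenation, final 1x1x1
convolution + sigmoid) that it runs on a desktop CPU; forward and
backward passes are written directly in numpy, with convolutions lowered
to GEMMs through an im2col transform. Inputs are zero-padded per axis to
the next multiple of 2**(levels-1) and predictions cropped back.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetConfig",
    "Prediction",
    "UNet3D",
    "loss",
    "train",
    "predict",
    "predict_legacy",
    "save_model",
    "load_model",
]


@dataclass
class NetConfig:
    in_channels: int = 3           # F (frames), or 4 for the legacy variant
    grid_dims: tuple[int, int, int] = (31, 32, 26)
    levels: int = 3
    base_channels: int = 16
    lr: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 5
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    threshold: float = 0.5
    val_fraction: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass
class Prediction:
    prob: np.ndarray  # (nx, ny, nz) in [0, 1]
    mask: np.ndarray  # binarized at the config threshold (uint8)


# ---------------------------------------------------------------------------
# Layers (forward + backward, float32)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, D, H, W) -> (B*D*H*W, C*27) patch matrix (3x3x3, pad 1)."""
    b, c, d, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    v = np.lib.stride_tricks.sliding_window_view(xp, (3, 3, 3), axis=(2, 3, 4))
    # (B, C, D, H, W, 3, 3, 3) -> (B, D, H, W, C, 3, 3, 3)
    return np.ascontiguousarray(v.transpose(0, 2, 3, 4, 1, 5, 6, 7)).reshape(
        b * d * h * w, c * 27)


class _Conv3d:
    """3x3x3 convolution, padding 1 (or 1x1x1 when kernel=1)."""

    def __init__(self, cin: int, cout: int, kernel: int = 3):
        self.cin, self.cout, self.kernel = cin, cout, kernel

    def init(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        k = self.kernel
        fan_in = self.cin * k ** 3
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        return {"W": rng.normal(0, std, (self.cout, self.cin, k, k, k)).astype(np.float32),
                "b": np.zeros(self.cout, dtype=np.float32)}

    def forward(self, p, x):
        b, c, d, h, w = x.shape
        self._shape = x.shape
        if self.kernel == 1:
            self._cols = x.transpose(0, 2, 3, 4, 1).reshape(-1, c)
        else:
            self._cols = _im2col(x)
        wm = p["W"].reshape(self.cout, -1)
        y = self._cols @ wm.T + p["b"]
        return y.reshape(b, d, h, w, self.cout).transpose(0, 4, 1, 2, 3)

    def backward(self, p, gy):
        b, c, d, h, w = self._shape
        gym = np.ascontiguousarray(gy.transpose(0, 2, 3, 4, 1)).reshape(-1, self.cout)
        gW = (gym.T @ self._cols).reshape(p["W"].shape)
        gb = gym.sum(axis=0)
        if self.kernel == 1:
            gx = (gym @ p["W"].reshape(self.cout, c)).reshape(b, d, h, w, c)
            gx = gx.transpose(0, 4, 1, 2, 3)
        else:
            # full correlation with the spatially flipped, transposed kernel
            gy5 = gy.reshape(b, self.cout, d, h, w)
            cols2 = _im2col(gy5)
            wf = p["W"][:, :, ::-1, ::-1, ::-1]          # (Cout, Cin, 3,3,3)
            wf = wf.transpose(0, 2, 3, 4, 1).reshape(self.cout * 27, self.cin)
            gx = (cols2 @ wf).reshape(b, d, h, w, self.cin).transpose(0, 4, 1, 2, 3)
        self._cols = None
        return {"W": gW, "b": gb}, np.ascontiguousarray(gx)


class _InstanceNorm:
    def __init__(self, c: int):
        self.c = c
        self.eps = 1e-5

    def init(self, rng):
        return {"g": np.ones(self.c, dtype=np.float32),
                "b": np.zeros(self.c, dtype=np.float32)}

    def forward(self, p, x):
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        var = x.var(axis=(2, 3, 4), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return p["g"][None, :, None, None, None] * self._xhat \
            + p["b"][None, :, None, None, None]

    def backward(self, p, gy):
        gg = (gy * self._xhat).sum(axis=(0, 2, 3, 4))
        gb = gy.sum(axis=(0, 2, 3, 4))
        n = np.prod(gy.shape[2:])
        gxh = gy * p["g"][None, :, None, None, None]
        gx = self._inv / n * (n * gxh - gxh.sum(axis=(2, 3, 4), keepdims=True)
                              - self._xhat * (gxh * self._xhat).sum(axis=(2, 3, 4),
                                                                    keepdims=True))
        self._inv = self._xhat = None
        return {"g": gg, "b": gb}, gx.astype(np.float32)


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, gy):
        g = gy * self._m
        self._m = None
        return g


def _maxpool(x):
    b, c, d, h, w = x.shape
    xr = x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
    xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d // 2, h // 2, w // 2, 8)
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, (idx, x.shape)


def _maxpool_back(gy, cache):
    idx, shape = cache
    b, c, d, h, w = shape
    g = np.zeros((b, c, d // 2, h // 2, w // 2, 8), dtype=gy.dtype)
    np.put_along_axis(g, idx[..., None], gy[..., None], axis=-1)
    g = g.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
    return g.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(shape)


def _upsample(x):
    return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)


def _upsample_back(gy):
    b, c, d, h, w = gy.shape
    return gy.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


# ---------------------------------------------------------------------------
# The U-Net
# ---------------------------------------------------------------------------

class UNet3D:
    """Encoder-decoder with skip connections; parameters in a flat dict."""

    def __init__(self, config: NetConfig):
        self.config = config
        L, base = config.levels, config.base_channels
        self.pad_to = 2 ** (L - 1)
        chans = [base * 2 ** i for i in range(L)]
        self.layers: dict[str, object] = {}

        def block(name, cin, cout):
            self.layers[f"{name}.conv0"] = _Conv3d(cin, cout)
            self.layers[f"{name}.norm0"] = _InstanceNorm(cout)
            self.layers[f"{name}.relu0"] = _ReLU()
            self.layers[f"{name}.conv1"] = _Conv3d(cout, cout)
            self.layers[f"{name}.norm1"] = _InstanceNorm(cout)
            self.layers[f"{name}.relu1"] = _ReLU()

        cin = config.in_channels
        for i in range(L):
            block(f"enc{i}", cin, chans[i])
            cin = chans[i]
        for i in range(L - 2, -1, -1):
            block(f"dec{i}", chans[i + 1] + chans[i], chans[i])
        self.layers["head"] = _Conv3d(chans[0], 1, kernel=1)

        self.trained = False
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        for name, layer in self.layers.items():
            if hasattr(layer, "init"):
                for k, v in layer.init(rng).items():
                    self.params[f"{name}.{k}"] = v

    # -- padding ---------------------------------------------------------
    def _pad(self, x):
        dims = np.array(x.shape[2:])
        tgt = -(-dims // self.pad_to) * self.pad_to
        extra = tgt - dims
        self._crop = tuple(slice(0, d) for d in dims)
        return np.pad(x, ((0, 0), (0, 0), (0, extra[0]), (0, extra[1]), (0, extra[2])))

    def _block_forward(self, name, x):
        for i in range(2):
            conv = self.layers[f"{name}.conv{i}"]
            x = conv.forward({"W": self.params[f"{name}.conv{i}.W"],
                              "b": self.params[f"{name}.conv{i}.b"]}, x)
            norm = self.layers[f"{name}.norm{i}"]
            x = norm.forward({"g": self.params[f"{name}.norm{i}.g"],
                              "b": self.params[f"{name}.norm{i}.b"]}, x)
            x = self.layers[f"{name}.relu{i}"].forward(x)
        return x

    def _block_backward(self, name, gy, grads):
        for i in (1, 0):
            gy = self.layers[f"{name}.relu{i}"].backward(gy)
            g, gy = self.layers[f"{name}.norm{i}"].backward(
                {"g": self.params[f"{name}.norm{i}.g"],
                 "b": self.params[f"{name}.norm{i}.b"]}, gy)
            grads[f"{name}.norm{i}.g"] = g["g"]
            grads[f"{name}.norm{i}.b"] = g["b"]
            g, gy = self.layers[f"{name}.conv{i}"].backward(
                {"W": self.params[f"{name}.conv{i}.W"],
                 "b": self.params[f"{name}.conv{i}.b"]}, gy)
            grads[f"{name}.conv{i}.W"] = g["W"]
            grads[f"{name}.conv{i}.b"] = g["b"]
        return gy

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, F, nx, ny, nz) float32 -> logits (B, nx, ny, nz)."""
        if x.shape[1:] != (self.config.in_channels,) + tuple(self.config.grid_dims):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match the configured "
                f"{(self.config.in_channels,) + tuple(self.config.grid_dims)}")
        x = self._pad(np.asarray(x, dtype=np.float32))
        L = self.config.levels
        skips = []
        self._pool_caches = []
        for i in range(L):
            x = self._block_forward(f"enc{i}", x)
            if i < L - 1:
                skips.append(x)
                x, cache = _maxpool(x)
                self._pool_caches.append(cache)
        self._skip_chans = []
        for i in range(L - 2, -1, -1):
            x = _upsample(x)
            s = skips[i]
            self._skip_chans.append((s.shape[1], x.shape[1]))
            x = np.concatenate([x, s], axis=1)
            x = self._block_forward(f"dec{i}", x)
        head = self.layers["head"]
        x = head.forward({"W": self.params["head.W"], "b": self.params["head.b"]}, x)
        c = self._crop
        return x[:, 0, c[0], c[1], c[2]]

    def backward(self, glogits: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate d(loss)/d(logits); returns parameter gradients."""
        L = self.config.levels
        dims = np.array(self.config.grid_dims)
        tgt = -(-dims // self.pad_to) * self.pad_to
        g = np.zeros((glogits.shape[0], 1) + tuple(tgt), dtype=np.float32)
        c = self._crop
        g[:, 0, c[0], c[1], c[2]] = glogits
        grads: dict[str, np.ndarray] = {}
        gp, g = self.layers["head"].backward(
            {"W": self.params["head.W"], "b": self.params["head.b"]}, g)
        grads["head.W"] = gp["W"]
        grads["head.b"] = gp["b"]
        skip_grads = []
        for j, i in enumerate(range(0, L - 1)):
            g = self._block_backward(f"dec{i}", g, grads)
            nskip, nup = self._skip_chans[::-1][j]
            gskip = g[:, nup:]
            skip_grads.append(gskip)
            g = _upsample_back(g[:, :nup])
        for i in range(L - 1, -1, -1):
            if i < L - 1:
                g = _maxpool_back(g, self._pool_caches[i])
                g = g + skip_grads[::-1][L - 2 - i]
            g = self._block_backward(f"enc{i}", g, grads)
        return grads

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params.values()))


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

_DICE_EPS = 1.0


def loss(prob: np.ndarray, target: np.ndarray) -> float:
    """Training loss of one prediction: mean binary cross-entropy plus the
    soft-Dice complement, loss = BCE(p, M) + (1 - 2*sum(p*m)+eps /
    (sum(p)+sum(m)+eps)), eps = 1."""
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prob.shape != target.shape:
        raise ValueError("probability and target shapes differ")
    if not np.all((target == 0) | (target == 1)):
        raise ValueError("target mask must be binary")
    p = np.clip(prob, 1e-7, 1.0 - 1e-7)
    bce = float(-(target * np.log(p) + (1 - target) * np.log(1 - p)).mean())
    dice = (2.0 * (p * target).sum() + _DICE_EPS) / (p.sum() + target.sum() + _DICE_EPS)
    return bce + (1.0 - float(dice))


def _loss_and_grad(logits: np.ndarray, masks: np.ndarray):
    """Batched loss and d(loss)/d(logits). BCE is computed from logits for
    stability; the Dice term and its gradient go through the sigmoid."""
    z = np.asarray(logits, dtype=np.float64)
    m = np.asarray(masks, dtype=np.float64)
    b = z.shape[0]
    nvox = z[0].size
    p = 1.0 / (1.0 + np.exp(-z))
    bce = float((np.logaddexp(0.0, z) - m * z).sum() / (b * nvox))
    gz = (p - m) / (b * nvox)
    ax = tuple(range(1, z.ndim))
    num = 2.0 * (p * m).sum(axis=ax) + _DICE_EPS
    den = p.sum(axis=ax) + m.sum(axis=ax) + _DICE_EPS
    dice = num / den
    # d(1-dice)/dp = (dice - 2 m) / den ; chain through sigmoid'
    expand = (...,) + (None,) * (z.ndim - 1)
    gdice = (dice[expand] - 2.0 * m) / den[expand] * p * (1.0 - p) / b
    total = bce + float((1.0 - dice).mean())
    return total, (gz + gdice).astype(np.float32), float(dice.mean())


def hard_dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = float(np.logical_and(a > 0, b > 0).sum())
    s = float((a > 0).sum() + (b > 0).sum())
    return 1.0 if s == 0 else 2.0 * inter / s


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _AdamW:
    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, p in params.items():
            g = grads[k].astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            upd = (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)
            # decoupled decay on weights only (not on norm scales/biases)
            if k.endswith(".W"):
                p -= self.lr * self.wd * p
            p -= self.lr * upd


def train(df: np.ndarray, masks: np.ndarray, config: NetConfig,
          verbose: bool = False):
    """Train a U-Net on a dataset of (F-channel distance field, mask) pairs.

    df : (N, F, nx, ny, nz); masks : (N, nx, ny, nz) binary.
    Returns (model, log): the model restored to its best-validation-loss
    parameters, and a per-epoch log of train/val loss and validation DSC.
    """
    df = np.asarray(df, dtype=np.float32)
    masks = np.asarray(masks)
    if len(df) == 0:
        raise ValueError("empty dataset")
    if df.shape[1] != config.in_channels:
        raise ValueError(f"dataset has {df.shape[1]} frame channels, "
                         f"network expects {config.in_channels}")
    model = UNet3D(config)
    rng = np.random.default_rng(config.seed + 1)
    n = len(df)
    perm = rng.permutation(n)
    if config.val_fraction <= 0 or n < 2:
        n_val = 0
    else:
        n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = perm, perm[:0]
    # bias the head toward the empty-mask prior: attachments occupy a
    # small voxel fraction, and starting near the prior avoids the early
    # all-positive phase that destabilizes the Dice term
    pos = max(float(np.mean(masks > 0)), 1e-4)
    model.params["head.b"][...] = np.float32(np.log(pos / (1.0 - pos)))
    opt = _AdamW(model.params, config.lr, config.weight_decay)
    log = {"train_loss": [], "val_loss": [], "val_dice": []}
    best = (np.inf, {k: v.copy() for k, v in model.params.items()}, -1)
    bad_epochs = 0

    for epoch in range(config.max_epochs):
        # cosine decay to ~0 over the epoch budget stabilizes late training
        opt.lr = config.lr * (0.05 + 0.95 * 0.5 * (1.0 + np.cos(np.pi * epoch / config.max_epochs)))
        order = rng.permutation(tr_idx)
        tl = 0.0
        nb = 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s:s + config.batch_size]
            logits = model.forward(df[idx])
            l, gz, _ = _loss_and_grad(logits, masks[idx])
            grads = model.backward(gz)
            opt.step(model.params, grads)
            tl += l
            nb += 1
        tl /= max(nb, 1)
        if len(val_idx):
            vl = vd = 0.0
            nv = 0
            for s in range(0, len(val_idx), config.batch_size):
                idx = val_idx[s:s + config.batch_size]
                logits = model.forward(df[idx])
                l, _, _ = _loss_and_grad(logits, masks[idx])
                pm = (1.0 / (1.0 + np.exp(-logits)) >= config.threshold)
                d = np.mean([hard_dice(pm[i], masks[idx][i]) for i in range(len(idx))])
                vl += l * len(idx)
                vd += d * len(idx)
                nv += len(idx)
            vl /= nv
            vd /= nv
        else:
            vl, vd = tl, np.nan
        log["train_loss"].append(tl)
        log["val_loss"].append(vl)
        log["val_dice"].append(vd)
        if verbose:
            print(f"epoch {epoch:3d}  train {tl:.4f}  val {vl:.4f}  val DSC {vd:.3f}")
        if vl < best[0] - 1e-6:
            best = (vl, {k: v.copy() for k, v in model.params.items()}, epoch)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if len(val_idx) and bad_epochs >= config.patience:
                break
    model.params = best[1]
    model.trained = True
    log["best_epoch"] = best[2]
    return model, log


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict(model: UNet3D, df: np.ndarray,
            restrict_to: np.ndarray | None = None) -> Prediction:
    """Deterministic inference on one F-channel distance-field stack of
    shape (F, nx, ny, nz). If ``restrict_to`` (a binary voxel field) is
    given, the binarized mask is intersected with it — used to confine
    predictions to surface-node voxels, where attachments live."""
    df = np.asarray(df, dtype=np.float32)
    expected = (model.config.in_channels,) + tuple(model.config.grid_dims)
    if df.shape != expected:
        raise ValueError(f"input shape {df.shape}, expected {expected}")
    logits = model.forward(df[None])[0]
    prob = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
    mask = (prob >= model.config.threshold)
    if restrict_to is not None:
        mask = mask & (np.asarray(restrict_to) > 0)
    return Prediction(prob=prob, mask=mask.astype(np.uint8))


def predict_legacy(model: UNet3D, tensor: np.ndarray,
                   restrict_to: np.ndarray | None = None) -> Prediction:
    """Inference for the displacement-input variant: tensor of shape
    (4, gx, gy, gz) — three Gaussian-splatted displacement channels plus
    the rest-geometry signed distance field (64^3 at full scale)."""
    if model.config.in_channels != 4:
        raise ValueError("legacy model must have 4 input channels")
    return predict(model, tensor, restrict_to=restrict_to)


def save_model(model: UNet3D, path: str | Path, extra: dict | None = None) -> None:
    cfg = asdict(model.config)
    cfg["grid_dims"] = list(cfg["grid_dims"])
    np.savez(str(path), __config__=json.dumps({**cfg, **(extra or {})}),
             **model.params)


def load_model(path: str | Path) -> UNet3D:
    data = np.load(str(path), allow_pickle=False)
    cfg = json.loads(str(data["__config__"]))
    known = {f.name for f in NetConfig.__dataclass_fields__.values()}
    cfg = {k: v for k, v in cfg.items() if k in known}
    cfg["grid_dims"] = tuple(cfg["grid_dims"])
    model = UNet3D(NetConfig(**cfg))
    for k in model.params:
        model.params[k] = data[k]
    model.trained = True
    return model
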