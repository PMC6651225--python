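"""Capsule network for two-class motor-imagery images.

Architecture (for the default 3 x 14 x 14 input):

* convolution, 4 kernels 3 x 3, stride 1, valid, SELU -> 4 x 12 x 12
* PrimaryCaps: convolution to 128 channels x 4-dim capsules (512 maps),
  3 x 3 stride 2 valid -> 5 x 5 grid -> 3200 capsules of dim 4, each
  squashed
* MI-Caps: one 8-dimensional capsule per class (left / right), computed by
  dynamic routing by agreement between the 3200 primary capsules and the
  2 class capsules
* a three-layer decoder (512, 1024, 588 units) reconstructs the input
  image from the masked class capsules as a regularizer

The capsule norm ``|v_j|`` plays the role of class probability; training
minimizes a margin loss on the norms plus 0.0005 x the reconstruction
sum-of-squares.  All forward/backward passes are plain NumPy; gradients
are exact (verified against finite differences), including backprop
through the unrolled routing iterations.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._nn import (
    SELU_ALPHA,
    SELU_SCALE,
    conv2d,
    conv2d_backward,
    dense,
    dense_backward,
    relu,
    relu_backward,
    selu,
    selu_backward,
    sigmoid,
    sigmoid_backward,
    softmax,
    softmax_backward,
    squash,
    squash_backward,
)

__all__ = [
    "CapsNetConfig",
    "RoutingState",
    "CapsNetModel",
    "selu",
    "squash",
    "coupling_softmax",
    "prediction_vectors",
    "dynamic_routing",
    "margin_loss",
    "total_loss",
    "predict",
    "init_params",
    "save_checkpoint",
    "load_checkpoint",
    "finite_difference_check",
]

CHECKPOINT_SCHEMA = 1


@dataclass(frozen=True)
class CapsNetConfig:
    """Architecture and loss hyperparameters.

    Defaults are the best configuration of the source study: 4 convolution
    channels, 128 primary-capsule channels of dimension 4, 8-dimensional
    class capsules, a single routing iteration, reconstruction enabled.
    """

    image_shape: tuple[int, int, int] = (3, 14, 14)
    conv_channels: int = 4
    conv_kernel: int = 3  # stride 1, valid
    primary_channels: int = 128
    primary_dim: int = 4
    primary_kernel: int = 3  # stride 2, valid
    primary_stride: int = 2
    mi_dim: int = 8
    n_classes: int = 2
    routing_iters: int = 1
    reconstruction: bool = True
    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_margin: float = 0.5
    lambda_rec: float = 0.0005
    selu_scale: float = SELU_SCALE
    selu_alpha: float = SELU_ALPHA
    decoder_sizes: tuple[int, int, int] = (512, 1024, 588)

    def __post_init__(self) -> None:
        if self.routing_iters < 1:
            raise ValueError("routing_iters must be >= 1")
        if not (0.0 <= self.m_minus < self.m_plus <= 1.0):
            raise ValueError("need 0 <= m_minus < m_plus <= 1")
        if self.lambda_rec <= 0:
            raise ValueError("lambda_rec must be positive")
        n_pix = int(np.prod(self.image_shape))
        if self.decoder_sizes[-1] != n_pix:
            raise ValueError(
                f"decoder output {self.decoder_sizes[-1]} must equal pixel count {n_pix}"
            )
        if self.primary_grid < 1 or self.conv_out < 1:
            raise ValueError("capsule grid is empty for this configuration")

    @property
    def conv_out(self) -> int:
        return self.image_shape[1] - self.conv_kernel + 1

    @property
    def primary_grid(self) -> int:
        return (self.conv_out - self.primary_kernel) // self.primary_stride + 1

    @property
    def n_primary_caps(self) -> int:
        return self.primary_channels * self.primary_grid**2

    @property
    def n_pixels(self) -> int:
        return int(np.prod(self.image_shape))


@dataclass
class RoutingState:
    """Per-forward-pass capsule quantities (final routing iteration)."""

    u: np.ndarray  # (B, N_in, primary_dim)
    u_hat: np.ndarray  # (B, N_in, n_classes, mi_dim)
    b: np.ndarray  # (B, N_in, n_classes) logits entering the final softmax
    c: np.ndarray  # (B, N_in, n_classes) coupling coefficients
    s: np.ndarray  # (B, n_classes, mi_dim)
    v: np.ndarray  # (B, n_classes, mi_dim)
    a: np.ndarray  # (B, N_in, n_classes) agreements v_j . u_hat_{j|i}


# ------------------------------------------------------------- primitives


def coupling_softmax(b_row: np.ndarray) -> np.ndarray:
    """Coupling coefficients for one input capsule: softmax over classes."""
    return softmax(np.asarray(b_row, dtype=float), axis=-1)


def prediction_vectors(u: np.ndarray, W: np.ndarray) -> np.ndarray:
    """u_hat_{j|i} = W_ij u_i for every (input capsule i, class j) pair.

    u: (..., N_in, primary_dim); W: (N_in, n_classes, mi_dim, primary_dim).
    Returns (..., N_in, n_classes, mi_dim).
    """
    u = np.asarray(u)
    if u.shape[-1] != W.shape[-1] or u.shape[-2] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: u {u.shape} vs W {W.shape} "
            "(expect u (..., N_in, d_in), W (N_in, n_classes, d_out, d_in))"
        )
    return np.einsum("ijkd,...id->...ijk", W, u, optimize=True)


def dynamic_routing(u_hat: np.ndarray, r: int):
    """Routing by agreement between input and class capsules.

    u_hat: (..., N_in, n_classes, mi_dim).  Starting from zero logits, each
    of the ``r`` iterations computes couplings by softmax, the per-class
    weighted sum, squashes it, and increases the logit of every (i, j) pair
    by the dot product between the prediction and the class output.
    Returns ``(v, c, b)`` from the final iteration.
    """
    if r < 1:
        raise ValueError("routing requires at least one iteration")
    u_hat = np.asarray(u_hat, dtype=float)
    b = np.zeros(u_hat.shape[:-1], dtype=u_hat.dtype)
    for _ in range(r):
        c = softmax(b, axis=-1)
        s = np.einsum("...ij,...ijk->...jk", c, u_hat, optimize=True)
        v = squash(s, axis=-1)
        b = b + np.einsum("...jk,...ijk->...ij", v, u_hat, optimize=True)
    return v, c, b


def margin_loss(
    class_norms: np.ndarray, target_onehot: np.ndarray, cfg: CapsNetConfig = CapsNetConfig()
) -> float | np.ndarray:
    """Sum over classes of T_k max(0, m+ - |v_k|)^2 + lam (1-T_k) max(0, |v_k| - m-)^2."""
    norms = np.asarray(class_norms, dtype=float)
    T = np.asarray(target_onehot, dtype=float)
    present = np.maximum(0.0, cfg.m_plus - norms) ** 2
    absent = np.maximum(0.0, norms - cfg.m_minus) ** 2
    per_class = T * present + cfg.lambda_margin * (1.0 - T) * absent
    out = per_class.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def total_loss(
    margin: float, reconstruction_sse: float, cfg: CapsNetConfig = CapsNetConfig()
) -> float:
    """margin + lambda_rec * reconstruction sum of squared pixel errors."""
    if not cfg.reconstruction:
        return float(margin)
    return float(margin + cfg.lambda_rec * reconstruction_sse)


def predict(class_norms: np.ndarray) -> np.ndarray | int:
    """Argmax over capsule norms; ties break toward the lower class index."""
    norms = np.asarray(class_norms)
    out = np.argmax(norms, axis=-1)
    return int(out) if out.ndim == 0 else out


# ------------------------------------------------------------- parameters


def init_params(
    cfg: CapsNetConfig, seed: int = 0, dtype=np.float32
) -> dict[str, np.ndarray]:
    """Seeded init: N(0, 0.1) routing weights, fan-in-scaled conv/dense."""
    rng = np.random.default_rng(seed)

    def _fan_in(shape):
        fan = int(np.prod(shape[1:]))
        return rng.normal(0.0, np.sqrt(1.0 / fan), size=shape)

    c_in = cfg.image_shape[0]
    k, pk = cfg.conv_kernel, cfg.primary_kernel
    d0, d1, d2 = cfg.decoder_sizes
    dec_in = cfg.n_classes * cfg.mi_dim
    params = {
        "conv_W": _fan_in((cfg.conv_channels, c_in, k, k)),
        "conv_b": np.zeros(cfg.conv_channels),
        "prim_W": _fan_in(
            (cfg.primary_channels * cfg.primary_dim, cfg.conv_channels, pk, pk)
        ),
        "prim_b": np.zeros(cfg.primary_channels * cfg.primary_dim),
        "W": rng.normal(
            0.0, 0.1, size=(cfg.n_primary_caps, cfg.n_classes, cfg.mi_dim, cfg.primary_dim)
        ),
        "dec_W1": rng.normal(0.0, np.sqrt(1.0 / dec_in), size=(dec_in, d0)),
        "dec_b1": np.zeros(d0),
        "dec_W2": rng.normal(0.0, np.sqrt(1.0 / d0), size=(d0, d1)),
        "dec_b2": np.zeros(d1),
        "dec_W3": rng.normal(0.0, np.sqrt(1.0 / d1), size=(d1, d2)),
        "dec_b3": np.zeros(d2),
    }
    return {k_: v.astype(dtype) for k_, v in params.items()}


# ------------------------------------------------------------- model


class CapsNetModel:
    """Stateful wrapper: config + parameters + forward/backward.

    ``dtype`` selects 32-bit (training default) or 64-bit (oracle and
    gradient-check) arithmetic.
    """

    def __init__(
        self,
        cfg: CapsNetConfig = CapsNetConfig(),
        seed: int = 0,
        dtype=np.float32,
        params: dict[str, np.ndarray] | None = None,
    ):
        self.cfg = cfg
        self.dtype = np.dtype(dtype)
        self.params = (
            {k: np.asarray(v, dtype=self.dtype) for k, v in params.items()}
            if params is not None
            else init_params(cfg, seed=seed, dtype=self.dtype)
        )

    # -- forward -------------------------------------------------------

    def _check_images(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=self.dtype)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.cfg.image_shape:
            raise ValueError(
                f"images must have shape (B,)+{self.cfg.image_shape}, got {x.shape}"
            )
        return x

    def forward(self, images: np.ndarray, mask_labels: np.ndarray | None = None):
        """Full forward pass.

        Returns ``(class_norms, v, reconstruction, state)``.  When
        ``mask_labels`` is None the decoder is masked by the predicted
        class (evaluation); otherwise by the given true labels (training).
        """
        x = self._check_images(images)
        out = self._forward_cache(x, mask_labels)
        return out["norms"], out["v"], out["recon"], out["state"]

    def _forward_cache(self, x: np.ndarray, mask_labels: np.ndarray | None) -> dict:
        cfg, p = self.cfg, self.params
        B = x.shape[0]
        z1, conv_cache = conv2d(x, p["conv_W"], p["conv_b"], stride=1)
        a1 = selu(z1)
        z2, prim_cache = conv2d(a1, p["prim_W"], p["prim_b"], stride=cfg.primary_stride)
        g = cfg.primary_grid
        # (B, channels, dim, g, g) -> (B, channels, g, g, dim) -> capsules
        u_pre = (
            z2.reshape(B, cfg.primary_channels, cfg.primary_dim, g, g)
            .transpose(0, 1, 3, 4, 2)
            .reshape(B, cfg.n_primary_caps, cfg.primary_dim)
        )
        u = squash(u_pre, axis=-1)
        u_hat = prediction_vectors(u, p["W"])

        # unrolled routing with per-iteration caches for backprop
        b = np.zeros((B, cfg.n_primary_caps, cfg.n_classes), dtype=u_hat.dtype)
        iters = []
        for t in range(cfg.routing_iters):
            c = softmax(b, axis=-1)
            s = np.einsum("bij,bijk->bjk", c, u_hat, optimize=True)
            v = squash(s, axis=-1)
            iters.append({"b": b, "c": c, "s": s, "v": v})
            if t < cfg.routing_iters - 1:
                b = b + np.einsum("bjk,bijk->bij", v, u_hat, optimize=True)
        v = iters[-1]["v"]
        norms = np.linalg.norm(v, axis=-1)

        if mask_labels is None:
            mask_idx = np.argmax(norms, axis=-1)
        else:
            mask_idx = np.asarray(mask_labels, dtype=np.int64)
        mask = np.zeros((B, cfg.n_classes), dtype=v.dtype)
        mask[np.arange(B), mask_idx] = 1.0
        dec_in = (v * mask[:, :, None]).reshape(B, cfg.n_classes * cfg.mi_dim)
        h1z, d1c = dense(dec_in, p["dec_W1"], p["dec_b1"])
        h1 = relu(h1z)
        h2z, d2c = dense(h1, p["dec_W2"], p["dec_b2"])
        h2 = relu(h2z)
        h3z, d3c = dense(h2, p["dec_W3"], p["dec_b3"])
        recon = sigmoid(h3z)

        a = np.einsum("bjk,bijk->bij", v, u_hat, optimize=True)
        state = RoutingState(
            u=u, u_hat=u_hat, b=iters[-1]["b"], c=iters[-1]["c"],
            s=iters[-1]["s"], v=v, a=a,
        )
        return {
            "x": x, "z1": z1, "conv_cache": conv_cache, "a1": a1, "z2": z2,
            "prim_cache": prim_cache, "u_pre": u_pre, "u": u, "u_hat": u_hat,
            "iters": iters, "v": v, "norms": norms, "mask": mask,
            "dec_in": dec_in, "d1c": d1c, "h1z": h1z, "h1": h1, "d2c": d2c,
            "h2z": h2z, "h2": h2, "d3c": d3c, "recon": recon, "state": state,
        }

    def decoder_reconstruct(
        self, v: np.ndarray, label_mask: np.ndarray
    ) -> np.ndarray:
        """Reconstruct pixels from class capsules with non-selected rows zeroed.

        ``label_mask``: (B, n_classes) one-hot rows.  Output values lie
        strictly in (0, 1) (sigmoid pixels).
        """
        p, cfg = self.params, self.cfg
        v = np.asarray(v, dtype=self.dtype)
        if v.ndim == 2:
            v = v[None]
        mask = np.atleast_2d(np.asarray(label_mask, dtype=self.dtype))
        onehot_ok = np.all(np.isin(mask, (0.0, 1.0))) and np.all(mask.sum(axis=-1) == 1)
        if not onehot_ok:
            raise ValueError("label_mask rows must be one-hot")
        dec_in = (v * mask[:, :, None]).reshape(v.shape[0], cfg.n_classes * cfg.mi_dim)
        h1 = relu(dense(dec_in, p["dec_W1"], p["dec_b1"])[0])
        h2 = relu(dense(h1, p["dec_W2"], p["dec_b2"])[0])
        return sigmoid(dense(h2, p["dec_W3"], p["dec_b3"])[0])

    # -- loss + gradients ----------------------------------------------

    def loss_and_grads(self, images: np.ndarray, labels: np.ndarray):
        """Mean total loss over the batch, its exact gradients, and predictions."""
        cfg, p = self.cfg, self.params
        x = self._check_images(images)
        y = np.asarray(labels, dtype=np.int64)
        B = x.shape[0]
        out = self._forward_cache(x, mask_labels=y)
        norms, v, recon = out["norms"], out["v"], out["recon"]
        T = np.zeros((B, cfg.n_classes), dtype=x.dtype)
        T[np.arange(B), y] = 1.0

        margins = margin_loss(norms, T, cfg)
        x_flat = x.reshape(B, cfg.n_pixels)
        if cfg.reconstruction:
            sse = ((recon - x_flat) ** 2).sum(axis=1)
            loss = float(np.mean(margins + cfg.lambda_rec * sse))
        else:
            sse = np.zeros(B, dtype=x.dtype)
            loss = float(np.mean(margins))
        preds = np.argmax(norms, axis=-1)

        grads = {k: np.zeros_like(val) for k, val in p.items()}

        # margin loss -> norms
        dnorm = (
            T * -2.0 * np.maximum(0.0, cfg.m_plus - norms)
            + cfg.lambda_margin * (1.0 - T) * 2.0 * np.maximum(0.0, norms - cfg.m_minus)
        ) / B
        n_safe = np.where(norms > 0, norms, 1.0)
        dv = dnorm[:, :, None] * v / n_safe[:, :, None]

        # reconstruction branch -> decoder params and masked v
        if cfg.reconstruction:
            drecon = (2.0 * cfg.lambda_rec / B) * (recon - x_flat)
            dh3z = sigmoid_backward(drecon, recon)
            dh2, grads["dec_W3"], grads["dec_b3"] = dense_backward(dh3z, out["d3c"])
            dh2z = relu_backward(dh2, out["h2z"])
            dh1, grads["dec_W2"], grads["dec_b2"] = dense_backward(dh2z, out["d2c"])
            dh1z = relu_backward(dh1, out["h1z"])
            ddec_in, grads["dec_W1"], grads["dec_b1"] = dense_backward(dh1z, out["d1c"])
            dv = dv + ddec_in.reshape(B, cfg.n_classes, cfg.mi_dim) * out["mask"][:, :, None]

        # backprop through the unrolled routing loop
        u_hat = out["u_hat"]
        du_hat = np.zeros_like(u_hat)
        dB_logits = np.zeros(u_hat.shape[:-1], dtype=u_hat.dtype)
        dv_cur = dv
        for t in range(cfg.routing_iters - 1, -1, -1):
            it = out["iters"][t]
            ds = squash_backward(dv_cur, it["s"], axis=-1)
            dc = np.einsum("bjk,bijk->bij", ds, u_hat, optimize=True)
            du_hat += np.einsum("bij,bjk->bijk", it["c"], ds, optimize=True)
            dB_logits += softmax_backward(dc, it["c"], axis=-1)
            if t > 0:
                v_prev = out["iters"][t - 1]["v"]
                du_hat += dB_logits[:, :, :, None] * v_prev[:, None, :, :]
                dv_cur = np.einsum("bij,bijk->bjk", dB_logits, u_hat, optimize=True)

        grads["W"] = np.einsum("bijk,bid->ijkd", du_hat, out["u"], optimize=True)
        du = np.einsum("ijkd,bijk->bid", p["W"], du_hat, optimize=True)

        du_pre = squash_backward(du, out["u_pre"], axis=-1)
        g = cfg.primary_grid
        dz2 = (
            du_pre.reshape(B, cfg.primary_channels, g, g, cfg.primary_dim)
            .transpose(0, 1, 4, 2, 3)
            .reshape(B, cfg.primary_channels * cfg.primary_dim, g, g)
        )
        da1, grads["prim_W"], grads["prim_b"] = conv2d_backward(dz2, out["prim_cache"])
        dz1 = selu_backward(da1, out["z1"])
        _, grads["conv_W"], grads["conv_b"] = conv2d_backward(dz1, out["conv_cache"])
        return loss, grads, preds

    def predict(self, images: np.ndarray, batch_size: int = 200) -> np.ndarray:
        """Predicted class indices (argmax of capsule norms)."""
        x = self._check_images(images)
        preds = []
        for i in range(0, x.shape[0], batch_size):
            norms, *_ = self.forward(x[i : i + batch_size])
            preds.append(np.argmax(norms, axis=-1))
        return np.concatenate(preds)

    def batch_loss(self, images: np.ndarray, labels: np.ndarray) -> float:
        """Mean total loss without gradients (used for validation curves)."""
        x = self._check_images(images)
        y = np.asarray(labels, dtype=np.int64)
        out = self._forward_cache(x, mask_labels=y)
        T = np.zeros((x.shape[0], self.cfg.n_classes), dtype=x.dtype)
        T[np.arange(x.shape[0]), y] = 1.0
        margins = margin_loss(out["norms"], T, self.cfg)
        if self.cfg.reconstruction:
            sse = ((out["recon"] - x.reshape(x.shape[0], -1)) ** 2).sum(axis=1)
            return float(np.mean(margins + self.cfg.lambda_rec * sse))
        return float(np.mean(margins))


# ------------------------------------------------------------- checkpoints


def save_checkpoint(path: str, model: CapsNetModel, extra: dict | None = None) -> None:
    """Single-file archive: JSON config + all weight arrays."""
    meta = {
        "schema": CHECKPOINT_SCHEMA,
        "arch": "capsnet",
        "config": asdict(model.cfg),
        "dtype": model.dtype.name,
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.params)


def load_checkpoint(path: str) -> CapsNetModel:
    with np.load(path) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        params = {k: f[k] for k in f.files if k != "__meta__"}
    if meta.get("schema") != CHECKPOINT_SCHEMA:
        raise ValueError(f"unsupported checkpoint schema {meta.get('schema')}")
    cfg_d = meta["config"]
    for key in ("image_shape", "decoder_sizes"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = CapsNetConfig(**cfg_d)
    return CapsNetModel(cfg, dtype=np.dtype(meta["dtype"]), params=params)


# ------------------------------------------------------------- gradient check


def finite_difference_check(
    model: CapsNetModel,
    images: np.ndarray,
    labels: np.ndarray,
    n_entries: int = 5,
    step: float = 1e-5,
    seed: int = 0,
    param_names: tuple[str, ...] = ("W", "conv_W", "prim_W", "dec_W2"),
) -> float:
    """Max relative error between analytic and central-difference gradients.

    Samples ``n_entries`` coordinates of each named parameter; intended to
    run on a 64-bit model.
    """
    rng = np.random.default_rng(seed)
    loss0, grads, _ = model.loss_and_grads(images, labels)
    worst = 0.0
    for name in param_names:
        p = model.params[name]
        flat_idx = rng.choice(p.size, size=min(n_entries, p.size), replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, p.shape)
            orig = p[idx]
            p[idx] = orig + step
            lp, _, _ = model.loss_and_grads(images, labels)
            p[idx] = orig - step
            lm, _, _ = model.loss_and_grads(images, labels)
            p[idx] = orig
            fd = (lp - lm) / (2 * step)
            an = grads[name][idx]
            denom = max(abs(fd), abs(an), 1e-8)
            worst = max(worst, abs(fd - an) / denom)
    return worst
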