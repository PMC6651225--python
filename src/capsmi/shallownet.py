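"""Shallow ConvNet baseline for raw 3 x 500 epochs.

Two blocks: temporal convolution (40 kernels 1 x 25) followed by a spatial
convolution across all electrodes (40 kernels E x 1), batch norm and a
squaring nonlinearity; then average pooling (1 x 75, stride 100), log
activation, dropout and a dense softmax classifier.  For a 3 x 500 input
the shape chain is 40x3x476 -> 40x1x476 -> 1x40x5 -> flatten 200 -> 2.

The pool stride is not part of the published table; 100 is the unique
stride for which floor((476 - 75)/100) + 1 = 5 matches the printed output
width (and hence the flatten size 200).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import (
    batchnorm,
    batchnorm_backward,
    conv2d,
    conv2d_backward,
    dense,
    dense_backward,
    softmax,
)

__all__ = ["ShallowNetConfig", "ShallowNetModel", "softmax", "shallownet_forward"]


@dataclass(frozen=True)
class ShallowNetConfig:
    n_temporal_filters: int = 40
    temporal_kernel: int = 25  # 1 x 25
    n_spatial_filters: int = 40
    n_electrodes: int = 3  # E in the spatial kernel E x 1
    n_samples: int = 500
    pool_width: int = 75
    pool_stride: int = 100
    dropout_rate: float = 0.5
    log_epsilon: float = 1e-6
    n_classes: int = 2

    @property
    def conv_len(self) -> int:
        return self.n_samples - self.temporal_kernel + 1  # 476

    @property
    def pool_out(self) -> int:
        return (self.conv_len - self.pool_width) // self.pool_stride + 1  # 5

    @property
    def flat_size(self) -> int:
        return self.n_spatial_filters * self.pool_out  # 200


def _avgpool1d(x: np.ndarray, width: int, stride: int) -> np.ndarray:
    """Average pool along the last axis; windows [k*stride, k*stride+width)."""
    n_out = (x.shape[-1] - width) // stride + 1
    return np.stack(
        [x[..., k * stride : k * stride + width].mean(axis=-1) for k in range(n_out)],
        axis=-1,
    )


def _avgpool1d_backward(dout: np.ndarray, n_in: int, width: int, stride: int) -> np.ndarray:
    dx = np.zeros(dout.shape[:-1] + (n_in,), dtype=dout.dtype)
    for k in range(dout.shape[-1]):
        dx[..., k * stride : k * stride + width] += dout[..., k : k + 1] / width
    return dx


class ShallowNetModel:
    """Trainable ShallowNet with the same loss/gradient interface as CapsNet."""

    def __init__(
        self,
        cfg: ShallowNetConfig = ShallowNetConfig(),
        seed: int = 0,
        dtype=np.float32,
        params: dict[str, np.ndarray] | None = None,
    ):
        self.cfg = cfg
        self.dtype = np.dtype(dtype)
        self._rng = np.random.default_rng(seed + 101)  # dropout stream
        if params is not None:
            self.params = {k: np.asarray(v, dtype=self.dtype) for k, v in params.items()}
        else:
            rng = np.random.default_rng(seed)
            c = cfg
            self.params = {
                k: v.astype(self.dtype)
                for k, v in {
                    "tW": rng.normal(0, np.sqrt(1.0 / c.temporal_kernel),
                                     (c.n_temporal_filters, 1, 1, c.temporal_kernel)),
                    "tb": np.zeros(c.n_temporal_filters),
                    "sW": rng.normal(0, np.sqrt(1.0 / (c.n_temporal_filters * c.n_electrodes)),
                                     (c.n_spatial_filters, c.n_temporal_filters, c.n_electrodes, 1)),
                    "sb": np.zeros(c.n_spatial_filters),
                    "bn_gamma": np.ones(c.n_spatial_filters),
                    "bn_beta": np.zeros(c.n_spatial_filters),
                    "fc_W": rng.normal(0, np.sqrt(1.0 / c.flat_size), (c.flat_size, c.n_classes)),
                    "fc_b": np.zeros(c.n_classes),
                }.items()
            }
        self.running = {
            "mean": np.zeros(cfg.n_spatial_filters, dtype=self.dtype),
            "var": np.ones(cfg.n_spatial_filters, dtype=self.dtype),
        }

    def _check(self, epochs: np.ndarray) -> np.ndarray:
        x = np.asarray(epochs, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        c = self.cfg
        if x.shape[1:] != (c.n_electrodes, c.n_samples):
            raise ValueError(
                f"epochs must have shape (B, {c.n_electrodes}, {c.n_samples}), got {x.shape}"
            )
        return x[:, None]  # (B, 1, E, T)

    def _forward(self, x4: np.ndarray, train: bool, dropout_mask: np.ndarray | None):
        p, c = self.params, self.cfg
        z1, c1 = conv2d(x4, p["tW"], p["tb"], stride=1)  # (B,40,3,476)
        z2, c2 = conv2d(z1, p["sW"], p["sb"], stride=1)  # (B,40,1,476)
        bn, bnc = batchnorm(z2, p["bn_gamma"], p["bn_beta"], self.running, train)
        sq = bn**2
        resh = sq.transpose(0, 2, 1, 3)  # (B,1,40,476)
        pooled = _avgpool1d(resh, c.pool_width, c.pool_stride)  # (B,1,40,5)
        clamped = np.maximum(pooled, c.log_epsilon)
        logged = np.log(clamped)
        flat = logged.reshape(x4.shape[0], c.flat_size)
        if dropout_mask is not None:
            flat = flat * dropout_mask
        logits, fcc = dense(flat, p["fc_W"], p["fc_b"])
        probs = softmax(logits, axis=-1)
        return {
            "c1": c1, "c2": c2, "bnc": bnc, "bn": bn, "sq_in": bn,
            "pooled": pooled, "clamped": clamped, "resh_shape": resh.shape,
            "flat": flat, "fcc": fcc, "probs": probs,
        }

    def forward(self, epochs: np.ndarray) -> np.ndarray:
        """Class probabilities (B, 2) in evaluation mode (no dropout, running BN)."""
        x4 = self._check(epochs)
        return self._forward(x4, train=False, dropout_mask=None)["probs"]

    def loss_and_grads(self, epochs: np.ndarray, labels: np.ndarray,
                       dropout: bool = True):
        """Mean cross-entropy, exact gradients, predictions (training mode)."""
        p, c = self.params, self.cfg
        x4 = self._check(epochs)
        y = np.asarray(labels, dtype=np.int64)
        B = x4.shape[0]
        if dropout and c.dropout_rate > 0:
            keep = 1.0 - c.dropout_rate
            mask = (self._rng.random((B, c.flat_size)) < keep).astype(self.dtype) / keep
        else:
            mask = None
        out = self._forward(x4, train=True, dropout_mask=mask)
        probs = out["probs"]
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + eps)))
        preds = np.argmax(probs, axis=-1)

        grads = {}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        dflat, grads["fc_W"], grads["fc_b"] = dense_backward(dlogits, out["fcc"])
        if mask is not None:
            dflat = dflat * mask
        dlog = dflat.reshape(B, 1, c.n_spatial_filters, c.pool_out)
        dclamp = dlog / out["clamped"] * (out["pooled"] > c.log_epsilon)
        dpool = _avgpool1d_backward(dclamp, out["resh_shape"][-1], c.pool_width, c.pool_stride)
        dsq = dpool.transpose(0, 2, 1, 3)  # back to (B,40,1,476)
        dbn = dsq * 2.0 * out["sq_in"]
        dz2, grads["bn_gamma"], grads["bn_beta"] = batchnorm_backward(dbn, out["bnc"])
        dz1, grads["sW"], grads["sb"] = conv2d_backward(dz2, out["c2"])
        _, grads["tW"], grads["tb"] = conv2d_backward(dz1, out["c1"])
        return loss, grads, preds

    def predict(self, epochs: np.ndarray, batch_size: int = 200) -> np.ndarray:
        x = np.asarray(epochs, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        preds = []
        for i in range(0, x.shape[0], batch_size):
            preds.append(np.argmax(self.forward(x[i : i + batch_size]), axis=-1))
        return np.concatenate(preds)

    def batch_loss(self, epochs: np.ndarray, labels: np.ndarray) -> float:
        probs = self.forward(epochs)
        y = np.asarray(labels, dtype=np.int64)
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))


def shallownet_forward(
    epoch: np.ndarray, model: ShallowNetModel | None = None,
    cfg: ShallowNetConfig = ShallowNetConfig(), seed: int = 0,
) -> np.ndarray:
    """Class probabilities for one 3 x 500 epoch (convenience wrapper)."""
    model = model if model is not None else ShallowNetModel(cfg, seed=seed)
    return model.forward(np.asarray(epoch)[None])[0]
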