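"""Neural-network building blocks on top of the autodiff tensor.

Conv2d uses an im2col formulation so both the forward pass and the gradient
reduce to matrix products; the col2im scatter in the backward pass is the
only explicit loop (over the k*k kernel offsets).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation of ``x`` (B,C,H,W) with kernels ``w`` (O,C,k,k)."""
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    O, Cw, k, k2 = wd.shape
    if C != Cw or k != k2:
        raise ValueError(f"kernel shape {wd.shape} incompatible with input {xd.shape}")
    s, p = stride, padding
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]  # B,C,Ho,Wo,k,k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * k * k)
    wmat = wd.reshape(O, -1).T
    out = cols @ wmat
    if b is not None:
        out = out + b.data
    out_data = out.reshape(B, Ho, Wo, O).transpose(0, 3, 1, 2)

    def backward(g: np.ndarray) -> None:
        gmat = g.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, O)
        if w.requires_grad:
            w._accum((cols.T @ gmat).T.reshape(wd.shape))
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if x.requires_grad:
            dcols = (gmat @ wmat.T).reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[..., i, j]
            x._accum(dxp[:, :, p:p + H, p:p + W] if p else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return x._make(out_data, parents, backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B,C,H,W) -> (B,C) spatial mean."""
    return x.mean(axis=(2, 3))


def batch_norm(z: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each column of a (B,D) batch to zero mean, unit variance."""
    mu = z.mean(axis=0, keepdims=True)
    centered = z - mu
    var = (centered * centered).mean(axis=0, keepdims=True)
    return centered / (var + eps).sqrt()


def l2_normalize(z: Tensor, eps: float = 1e-12) -> Tensor:
    """Normalize each row of a (B,D) batch to unit Euclidean norm."""
    norm = ((z * z).sum(axis=1, keepdims=True) + eps).sqrt()
    return z / norm


class Module:
    """Base class with named-parameter bookkeeping and train/eval modes."""

    training: bool = True

    def train(self) -> "Module":
        self.training = True
        for m in self._submodules():
            m.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for m in self._submodules():
            m.eval()
        return self

    def _submodules(self) -> List["Module"]:
        subs: List[Module] = []
        for attr in vars(self).values():
            if isinstance(attr, Module):
                subs.append(attr)
            elif isinstance(attr, (list, tuple)):
                subs.extend(a for a in attr if isinstance(a, Module))
        return subs

    def named_parameters(self, prefix: str = "") -> List[Tuple[str, Tensor]]:
        out: List[Tuple[str, Tensor]] = []
        for name, attr in vars(self).items():
            if isinstance(attr, Tensor):
                out.append((f"{prefix}{name}", attr))
            elif isinstance(attr, Module):
                out.extend(attr.named_parameters(f"{prefix}{name}."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{prefix}{name}.{i}."))
        return out

    def parameters(self) -> List[Tensor]:
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = state[name].astype(np.float64).copy()

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 padding: int = 0, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Tensor(rng.normal(0.0, scale, (c_out, c_in, kernel, kernel)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, f_in: int, f_out: int, bias: bool = True,
                 rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / f_in)
        self.weight = Tensor(rng.normal(0.0, scale, (f_in, f_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(f_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class BatchNorm2d(Module):
    """Per-channel normalization over (batch, height, width) with learned
    affine; running statistics are used in eval mode."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = Tensor(np.zeros(channels))
        self.running_var = Tensor(np.ones(channels))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean.data = ((1 - m) * self.running_mean.data
                                      + m * mu.data.ravel())
            self.running_var.data = ((1 - m) * self.running_var.data
                                     + m * var.data.ravel())
        else:
            mu = Tensor(self.running_mean.data.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.data.reshape(1, -1, 1, 1))
            centered = x - mu
        xhat = centered / (var + self.eps).sqrt()
        c = self.gamma.data.shape[0]
        return (xhat * self.gamma.reshape(1, c, 1, 1)
                + self.beta.reshape(1, c, 1, 1))


class ConvEncoder(Module):
    """Small strided-convolution backbone for grayscale patches.

    Each stage halves the spatial resolution (3x3 kernels, stride 2, pad 1)
    and ends with a ReLU; :meth:`features` global-average-pools the final
    maps into a ``channels[-1]``-dimensional representation. The final
    feature maps stay accessible for class-activation mapping.
    """

    def __init__(self, channels: Sequence[int] = (8, 16, 32, 64),
                 in_channels: int = 1, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.convs = [Conv2d(cin, cout, kernel=3, stride=2, padding=1, rng=rng)
                      for cin, cout in zip((in_channels, *channels[:-1]), channels)]
        self.bns = [BatchNorm2d(c) for c in channels]
        self.out_dim = channels[-1]

    def forward(self, x: Tensor) -> Tensor:
        """Return final convolutional feature maps (B, C, h, w)."""
        for conv, bn in zip(self.convs, self.bns):
            x = bn(conv(x)).relu()
        return x

    def features(self, x: Tensor) -> Tensor:
        """Pooled (B, C) representation used by downstream heads."""
        return global_avg_pool(self.forward(x))


class MLP(Module):
    """Stack of linear layers with ReLU between (none after the last)."""

    def __init__(self, dims: Sequence[int], rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng()
        self.layers = [Linear(a, b, rng=rng) for a, b in zip(dims[:-1], dims[1:])]

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    pos_weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy on raw scores, numerically stable.

    ``pos_weight`` scales the positive-class term, the usual mitigation for
    class imbalance.
    """
    t = np.asarray(targets, dtype=np.float64).reshape(logits.shape)
    # BCE = -w*t*log(sigma(x)) - (1-t)*log(1-sigma(x)); the epsilon floor
    # guards log(0) when a logit saturates.
    sig = logits.sigmoid()
    eps = 1e-12
    loss = -(pos_weight * Tensor(t) * (sig + eps).log()
             + Tensor(1.0 - t) * (1.0 - sig + eps).log())
    return loss.mean()
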