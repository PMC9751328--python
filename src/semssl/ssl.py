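"""Self-supervised representation learning on unlabeled patches.

Two variants over a shared encoder + projector:

* **contrastive** — momentum contrast. A query encoder embeds one augmented
  view, a slowly-moving momentum encoder embeds the other; the InfoNCE loss
  discriminates the matching key from a FIFO queue of past keys::

      L(q) = -log  exp(q.k+ / tau) / (exp(q.k+ / tau) + sum_k- exp(q.k- / tau))

  with temperature ``tau`` scaling the cosine similarities. After every
  step the momentum parameters are updated as
  ``theta_m <- m*theta_m + (1-m)*theta_q`` and the fresh keys are enqueued.

* **noncontrastive** — redundancy reduction (Barlow-Twins style). Both
  views pass through the same network; the batch-normalized embeddings
  ``z^A, z^B`` form a cross-correlation matrix

      C_ij = sum_b z_bi^A z_bj^B / (sqrt(sum_b (z_bi^A)^2) sqrt(sum_b (z_bj^B)^2))

  and the loss drives C toward identity:
  ``sum_i (1-C_ii)^2 + lambda * sum_{i != j} C_ij^2``.

Only positive pairs are needed for the second variant, which is why it
tolerates small batches — the property that makes it attractive for
low-volume microscopy data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage import transform as sktransform

from . import nn
from .nn import Tensor
from .patches import Patch

__all__ = [
    "AugmentPolicy", "augment_pair", "NegativeQueue", "EncoderState",
    "PretrainConfig", "info_nce", "momentum_update", "enqueue",
    "cross_correlation", "barlow_twins_loss", "pretrain",
]

ArrayOrTensor = Union[np.ndarray, Tensor]


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

@dataclass
class AugmentPolicy:
    """Train-time random-resized-crop + horizontal flip; eval center crop."""

    output_size: int = 56
    crop_scale: Tuple[float, float] = (0.6, 1.0)   # fraction of patch area
    flip_prob: float = 0.5

    def validate(self, patch_size: int) -> None:
        if self.output_size > patch_size:
            raise ValueError(
                f"output_size {self.output_size} exceeds patch size {patch_size}")
        lo, hi = self.crop_scale
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("crop_scale must satisfy 0 < low <= high <= 1")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")


def _as_float_patch(patch: Union[Patch, np.ndarray]) -> np.ndarray:
    arr = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    return arr.astype(np.float64) / 255.0 if arr.dtype == np.uint8 else arr.astype(np.float64)


def _one_view(arr: np.ndarray, policy: AugmentPolicy,
              rng: np.random.Generator) -> np.ndarray:
    m = arr.shape[0]
    scale = rng.uniform(*policy.crop_scale)
    side = max(policy.output_size // 2 + 1, int(round(np.sqrt(scale) * m)))
    side = min(side, m)
    r0 = int(rng.integers(0, m - side + 1))
    c0 = int(rng.integers(0, m - side + 1))
    crop = arr[r0:r0 + side, c0:c0 + side]
    if side != policy.output_size:
        crop = sktransform.resize(crop, (policy.output_size, policy.output_size),
                                  order=1, mode="reflect", anti_aliasing=False,
                                  preserve_range=True)
    if rng.uniform() < policy.flip_prob:
        crop = crop[:, ::-1]
    return np.ascontiguousarray(crop)


def augment_pair(patch: Union[Patch, np.ndarray], policy: AugmentPolicy,
                 seed: int) -> Tuple[np.ndarray, np.ndarray]:
    """Two independently augmented views of one patch, deterministic in seed."""
    arr = _as_float_patch(patch)
    if arr.shape[0] < policy.output_size or arr.shape[1] < policy.output_size:
        raise ValueError(
            f"patch {arr.shape} smaller than output_size {policy.output_size}")
    policy.validate(min(arr.shape))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    return _one_view(arr, policy, rng), _one_view(arr, policy, rng)


def center_crop(patch: Union[Patch, np.ndarray], output_size: int) -> np.ndarray:
    """Eval-time view: the central output_size x output_size window."""
    arr = _as_float_patch(patch)
    m, n = arr.shape
    if m < output_size or n < output_size:
        raise ValueError("patch smaller than output_size")
    r0 = (m - output_size) // 2
    c0 = (n - output_size) // 2
    return np.ascontiguousarray(arr[r0:r0 + output_size, c0:c0 + output_size])


# ---------------------------------------------------------------------------
# queue and encoder state
# ---------------------------------------------------------------------------

class NegativeQueue:
    """FIFO buffer of momentum-encoder keys, evicting oldest past capacity."""

    def __init__(self, capacity: int, dim: int):
        if capacity < 1 or dim < 1:
            raise ValueError("capacity and dim must be >= 1")
        self.capacity = int(capacity)
        self.dim = int(dim)
        self.keys = np.empty((0, dim), dtype=np.float64)

    @property
    def size(self) -> int:
        return self.keys.shape[0]

    def enqueue(self, keys: np.ndarray) -> "NegativeQueue":
        keys = np.atleast_2d(np.asarray(keys, dtype=np.float64))
        if keys.shape[1] != self.dim:
            raise ValueError(
                f"key dimension {keys.shape[1]} does not match queue dim {self.dim}")
        self.keys = np.concatenate([self.keys, keys], axis=0)[-self.capacity:]
        return self

    def fill_random(self, rng: np.random.Generator) -> "NegativeQueue":
        """Warm-up with random unit vectors so training starts at capacity."""
        k = rng.standard_normal((self.capacity, self.dim))
        self.keys = k / np.linalg.norm(k, axis=1, keepdims=True)
        return self


def enqueue(queue: NegativeQueue, keys: np.ndarray) -> NegativeQueue:
    """FIFO append (functional alias of :meth:`NegativeQueue.enqueue`)."""
    return queue.enqueue(keys)


@dataclass
class EncoderState:
    """Query/momentum encoders + projector and the loss hyperparameters."""

    variant: str
    encoder: nn.ConvEncoder
    projector: nn.MLP
    momentum_encoder: Optional[nn.ConvEncoder] = None
    momentum_projector: Optional[nn.MLP] = None
    momentum_coefficient: float = 0.999
    temperature: float = 0.2
    lambda_bt: float = 0.02
    queue: Optional[NegativeQueue] = None
    config: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in ("contrastive", "noncontrastive"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0.0 <= self.momentum_coefficient <= 1.0:
            raise ValueError("momentum coefficient must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.lambda_bt < 0:
            raise ValueError("lambda_bt must be >= 0")

    # parameter views -------------------------------------------------------
    def query_params(self) -> Dict[str, np.ndarray]:
        return {**{f"encoder.{k}": v for k, v in self.encoder.state_dict().items()},
                **{f"projector.{k}": v for k, v in self.projector.state_dict().items()}}

    def momentum_params(self) -> Dict[str, np.ndarray]:
        if self.momentum_encoder is None:
            raise ValueError("state has no momentum branch")
        return {**{f"encoder.{k}": v
                   for k, v in self.momentum_encoder.state_dict().items()},
                **{f"projector.{k}": v
                   for k, v in self.momentum_projector.state_dict().items()}}

    def embed(self, views: np.ndarray, momentum: bool = False) -> Tensor:
        """Projector output for a (B, s, s) or (B, 1, s, s) view batch."""
        v = np.asarray(views, dtype=np.float64)
        if v.ndim == 3:
            v = v[:, None]
        x = Tensor(v)
        if momentum:
            return self.momentum_projector(self.momentum_encoder.features(x))
        return self.projector(self.encoder.features(x))


def momentum_update(state: EncoderState) -> EncoderState:
    """theta_m <- m*theta_m + (1-m)*theta_q, elementwise; query untouched."""
    m = state.momentum_coefficient
    q = {**dict(self_named(state.encoder, "encoder.")),
         **dict(self_named(state.projector, "projector."))}
    mom = {**dict(self_named(state.momentum_encoder, "encoder.")),
           **dict(self_named(state.momentum_projector, "projector."))}
    if set(q) != set(mom):
        raise ValueError("query and momentum parameter sets differ")
    for name, qp in q.items():
        mp = mom[name]
        if mp.data.shape != qp.data.shape:
            raise ValueError(f"shape mismatch for parameter {name}")
        mp.data = m * mp.data + (1.0 - m) * qp.data
    return state


def self_named(module: Optional[nn.Module], prefix: str):
    if module is None:
        raise ValueError("state has no momentum branch")
    return module.named_parameters(prefix)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def info_nce(q: ArrayOrTensor, k_pos: ArrayOrTensor,
             queue: Union[NegativeQueue, np.ndarray], tau: float = 0.2) -> Tensor:
    """InfoNCE with the positive key as class zero of a softmax.

    Inputs are expected row-L2-normalized; ``queue`` holds the negative
    keys. Returns the batch-mean loss as a scalar tensor (``.item()`` for
    the value).
    """
    if tau <= 0:
        raise ValueError("temperature must be > 0")
    negatives = queue.keys if isinstance(queue, NegativeQueue) else np.atleast_2d(queue)
    if negatives.shape[0] == 0:
        raise ValueError("negative queue is empty")
    q_t = q if isinstance(q, Tensor) else Tensor(np.atleast_2d(q))
    if q_t.ndim == 1:
        q_t = q_t.reshape(1, -1)
    k_arr = k_pos.data if isinstance(k_pos, Tensor) else np.atleast_2d(k_pos)
    if q_t.shape != k_arr.shape or q_t.shape[1] != negatives.shape[1]:
        raise ValueError("embedding dimensions disagree")
    inv_tau = 1.0 / tau
    l_pos = (q_t * Tensor(k_arr)).sum(axis=1, keepdims=True) * inv_tau   # (B,1)
    l_neg = (q_t @ Tensor(negatives.T)) * inv_tau                        # (B,K)
    logits = nn.concat([l_pos, l_neg], axis=1)
    shift = logits.data.max(axis=1, keepdims=True)                       # detached
    lse = (logits - shift).exp().sum(axis=1, keepdims=True).log() + shift
    return (lse - l_pos).mean()


def cross_correlation(zA: ArrayOrTensor, zB: ArrayOrTensor) -> Tensor:
    """C_ij = sum_b zA_bi zB_bj / (||zA_.i|| ||zB_.j||), a D x D matrix."""
    a = zA if isinstance(zA, Tensor) else Tensor(zA)
    b = zB if isinstance(zB, Tensor) else Tensor(zB)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("embedding batches must share a (B, D) shape")
    na = np.sqrt((a.data ** 2).sum(axis=0))
    nb = np.sqrt((b.data ** 2).sum(axis=0))
    if (na < 1e-12).any() or (nb < 1e-12).any():
        raise FloatingPointError("zero-variance embedding dimension in "
                                 "cross-correlation denominator")
    num = a.T @ b
    denom = Tensor(np.outer(na, nb))
    # the denominator is treated as a constant normalizer; with
    # batch-normalized inputs it equals the batch size exactly
    return num / denom


def barlow_twins_loss(C: ArrayOrTensor, lambda_bt: float = 5e-3) -> Tensor:
    """Invariance term + lambda * redundancy-reduction term, >= 0."""
    c = C if isinstance(C, Tensor) else Tensor(C)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("cross-correlation matrix must be square")
    if lambda_bt < 0:
        raise ValueError("lambda must be >= 0")
    eye = np.eye(c.shape[0])
    diag_dev = (c - eye) * eye          # (C_ii - 1) on the diagonal, else 0
    off = c * (1.0 - eye)
    return (diag_dev * diag_dev).sum() + lambda_bt * (off * off).sum()


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------

@dataclass
class PretrainConfig:
    encoder_channels: Tuple[int, ...] = (8, 16, 32, 64)
    projector_hidden: int = 128
    projector_dim: int = 64
    batch_size: int = 64
    epochs: int = 30
    lr: Optional[float] = None   # None -> per-variant default (see lr_for)
    sgd_momentum: float = 0.9
    weight_decay: float = 1e-5
    temperature: float = 0.2
    momentum_coefficient: float = 0.99
    queue_capacity: int = 512
    lambda_bt: float = 0.02
    augment: AugmentPolicy = field(default_factory=AugmentPolicy)
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.lr is not None and self.lr <= 0:
            raise ValueError("lr must be > 0")

    def lr_for(self, variant: str) -> float:
        """The contrastive objective tolerates a larger step size than the
        cross-correlation one, whose gradients are comparatively large."""
        if self.lr is not None:
            return self.lr
        return 0.02 if variant == "contrastive" else 0.003


def init_state(variant: str, cfg: PretrainConfig) -> EncoderState:
    """Fresh encoder/projector (and momentum twin + queue if contrastive)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 11]))
    encoder = nn.ConvEncoder(cfg.encoder_channels, rng=rng)
    d = encoder.out_dim
    if variant == "noncontrastive":
        # backbone followed by three linear layers
        projector = nn.MLP([d, cfg.projector_hidden, cfg.projector_hidden,
                            cfg.projector_dim], rng=rng)
    else:
        # two-layer MLP head of the momentum-contrast configuration
        projector = nn.MLP([d, cfg.projector_hidden, cfg.projector_dim], rng=rng)
    state = EncoderState(
        variant=variant, encoder=encoder, projector=projector,
        momentum_coefficient=cfg.momentum_coefficient,
        temperature=cfg.temperature, lambda_bt=cfg.lambda_bt,
        config={"encoder_channels": list(cfg.encoder_channels),
                "projector_dim": cfg.projector_dim,
                "projector_hidden": cfg.projector_hidden,
                "variant": variant, "seed": cfg.seed})
    if variant == "contrastive":
        state.momentum_encoder = copy.deepcopy(encoder)
        state.momentum_projector = copy.deepcopy(projector)
        for _, p in (state.momentum_encoder.named_parameters()
                     + state.momentum_projector.named_parameters()):
            p.requires_grad = False
        state.queue = NegativeQueue(cfg.queue_capacity, cfg.projector_dim)
        state.queue.fill_random(
            np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 12])))
    return state


def pretrain(patches: Sequence[Union[Patch, np.ndarray]], variant: str,
             cfg: Optional[PretrainConfig] = None
             ) -> Tuple[EncoderState, List[float]]:
    """Train the chosen SSL variant; returns state and per-epoch mean loss."""
    cfg = cfg or PretrainConfig()
    cfg.validate()
    if variant not in ("contrastive", "noncontrastive"):
        raise ValueError(f"unknown variant {variant!r}")
    n = len(patches)
    if n == 0:
        raise ValueError("representation set is empty")
    if cfg.batch_size > n:
        raise ValueError(f"batch size {cfg.batch_size} exceeds dataset size {n}")

    arrays = [_as_float_patch(p) for p in patches]
    cfg.augment.validate(min(a.shape[0] for a in arrays))
    state = init_state(variant, cfg)
    opt = nn.SGD(state.encoder.parameters() + state.projector.parameters(),
                 lr=cfg.lr_for(variant), momentum=cfg.sgd_momentum,
                 weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 13]))

    if variant == "contrastive" and cfg.epochs > 0:
        # warm the queue with real momentum-encoder keys so the first
        # epoch's negatives are representative rather than random vectors
        warm = rng.choice(n, size=state.queue.capacity,
                          replace=n < state.queue.capacity)
        for start in range(0, len(warm), cfg.batch_size):
            views = np.stack([
                _one_view(arrays[i], cfg.augment, rng)
                for i in warm[start:start + cfg.batch_size]])[:, None]
            keys = nn.l2_normalize(state.embed(views, momentum=True)).data
            state.queue.enqueue(keys)

    trace: List[float] = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            pairs = [augment_pair(arrays[i], cfg.augment,
                                  seed=int(rng.integers(0, 2 ** 31)))
                     for i in idx]
            v1 = np.stack([p[0] for p in pairs])[:, None]
            v2 = np.stack([p[1] for p in pairs])[:, None]
            opt.zero_grad()
            if variant == "contrastive":
                # symmetrized objective: each view serves once as query and
                # once as (momentum-encoded) key, doubling the learning
                # signal per batch — important at desk-scale step counts
                k2 = nn.l2_normalize(state.embed(v2, momentum=True)).data
                k1 = nn.l2_normalize(state.embed(v1, momentum=True)).data
                q1 = nn.l2_normalize(state.embed(v1))
                q2 = nn.l2_normalize(state.embed(v2))
                loss = (info_nce(q1, k2, state.queue, state.temperature)
                        + info_nce(q2, k1, state.queue, state.temperature)) * 0.5
                loss.backward()
                opt.step()
                momentum_update(state)
                state.queue.enqueue(np.concatenate([k1, k2]))
            else:
                zA = nn.batch_norm(state.embed(v1))
                zB = nn.batch_norm(state.embed(v2))
                loss = barlow_twins_loss(cross_correlation(zA, zB),
                                         state.lambda_bt)
                loss.backward()
                opt.step()
            losses.append(loss.item())
        trace.append(float(np.mean(losses)) if losses else float("nan"))
    return state, trace
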