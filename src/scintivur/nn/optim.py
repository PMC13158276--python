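"""Optimisers and losses."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["AdamW", "cross_entropy", "bce_with_logits"]


class AdamW:
    """Adam with decoupled weight decay.

    update: p <- p - lr * (m_hat / (sqrt(v_hat) + eps) + weight_decay * p)
    """

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; targets are integer class indices."""
    targets = np.asarray(targets, dtype=int)
    n = logits.shape[0]
    logp = _log_softmax(logits)
    picked = logp[np.arange(n), targets]
    return -picked.mean()


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Binary cross-entropy on the positive-class logit (sigmoid link).

    For two-class logits the positive score is logit[:,1] - logit[:,0].
    """
    targets = np.asarray(targets, dtype=float)
    if logits.ndim == 2 and logits.shape[1] == 2:
        z = logits[:, 1] - logits[:, 0]
    else:
        z = logits.reshape(logits.shape[0])
    p = z.sigmoid()
    eps = 1e-12
    t = Tensor(targets)
    return -(t * (p + eps).log() + (1.0 - t) * (1.0 - p + eps).log()).mean()


def _log_softmax(logits: Tensor) -> Tensor:
    # numerically stable: z - log(sum(exp(z))) with a constant max shift
    shift = Tensor(logits.data.max(axis=-1, keepdims=True))
    z = logits - shift
    return z - z.exp().sum(axis=-1, keepdims=True).log()
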