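"""Adversarial segmentation losses.

The discriminator minimizes a two-class cross entropy over real/fake
provenance:  L_D = -(1-q) log(1 - D(S(x))) - q log D(y),  where q = 0 marks
a generator output and q = 1 a ground truth.  The generator minimizes

    L_seg = L_ce + lambda_adv * L_adv,

the per-pixel two-class cross entropy L_ce = -sum_{h,w} sum_c y_c log S(x)_c
plus the adversarial term L_adv = -log D(S(x)) that rewards fooling the
discriminator (default lambda_adv = 0.1).

Every function accepts either plain NumPy values (returning a float) or
:class:`~sadgan.nn.Tensor` values (returning a Tensor on the autodiff graph,
for training).  Log arguments are clamped at ``epsilon`` so boundary scores
0/1 stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = ["LossConfig", "discriminator_loss", "cross_entropy_loss",
           "adversarial_loss", "generator_loss"]


@dataclass
class LossConfig:
    lambda_adv: float = 0.1
    epsilon: float = 1e-12
    reduction: str = "mean"   # "mean" (size-invariant) or "sum" (literal form)

    def validate(self) -> "LossConfig":
        if self.lambda_adv < 0:
            raise ValueError("lambda_adv must be nonnegative")
        if not 0 < self.epsilon <= 1e-3:
            raise ValueError("epsilon must lie in (0, 1e-3]")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")
        return self


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _neg_log(t: Tensor, eps: float) -> Tensor:
    return -(t.clamp_min(eps).log())


def discriminator_loss(d_on_fake=None, d_on_real=None, q: int | None = None,
                       epsilon: float = 1e-12):
    """Real/fake cross entropy for one sample.

    q = 0 (generator output): -log(1 - D(S(x))) over ``d_on_fake``;
    q = 1 (ground truth):     -log D(y)          over ``d_on_real``.
    With a spatial discriminator head the per-cell losses are averaged.
    """
    if q not in (0, 1):
        raise ValueError("q must be 0 (generator sample) or 1 (ground truth)")
    if q == 0:
        if d_on_fake is None:
            raise ValueError("q=0 requires d_on_fake")
        t, is_tensor = _as_tensor(d_on_fake)
        loss = _neg_log(1.0 - t, epsilon).mean()
    else:
        if d_on_real is None:
            raise ValueError("q=1 requires d_on_real")
        t, is_tensor = _as_tensor(d_on_real)
        loss = _neg_log(t, epsilon).mean()
    return loss if is_tensor else loss.item()


def cross_entropy_loss(pred, truth, reduction: str = "sum", epsilon: float = 1e-12):
    """Two-class pixel cross entropy against a binary mask.

    ``pred`` is a probability map: H×W×2 (NumPy convention) or a Tensor
    (N,2,H,W).  ``truth`` is H×W (or N,H,W) in {0,1}, one-hot encoded over
    the two classes internally.  reduction='sum' is the literal summed form;
    'mean' divides by the pixel count so the magnitude is image-size
    invariant.
    """
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    pred_t, is_tensor = _as_tensor(pred)
    truth = np.asarray(truth)
    if is_tensor:
        if pred_t.ndim != 4 or pred_t.shape[1] != 2:
            raise ValueError(f"Tensor pred must be (N,2,H,W), got {pred_t.shape}")
        n, _, h, w = pred_t.shape
        if truth.shape not in ((n, h, w), (h, w)):
            raise ValueError(f"truth shape {truth.shape} does not match pred {pred_t.shape}")
        onehot = np.zeros(pred_t.shape, dtype=pred_t.dtype)
        tr = truth.reshape(n, h, w) if truth.ndim == 3 else truth[None]
        onehot[:, 1][tr == 1] = 1
        onehot[:, 0][tr == 0] = 1
        pix = n * h * w
    else:
        if pred_t.ndim != 3 or pred_t.shape[2] != 2:
            raise ValueError(f"pred must be H×W×2, got {pred_t.shape}")
        if truth.shape != pred_t.shape[:2]:
            raise ValueError(f"truth shape {truth.shape} != pred {pred_t.shape[:2]}")
        onehot = np.zeros(pred_t.shape, dtype=np.float64)
        onehot[..., 1][truth == 1] = 1
        onehot[..., 0][truth == 0] = 1
        pix = truth.size
    ll = pred_t.clamp_min(epsilon).log() * Tensor(onehot)
    loss = -(ll.sum())
    if reduction == "mean":
        loss = loss * (1.0 / pix)
    return loss if is_tensor else loss.item()


def adversarial_loss(d_on_fake, epsilon: float = 1e-12):
    """-log D(S(x)): the generator's reward for fooling the discriminator."""
    t, is_tensor = _as_tensor(d_on_fake)
    loss = _neg_log(t, epsilon).mean()
    return loss if is_tensor else loss.item()


def generator_loss(pred, truth, d_on_fake, cfg: LossConfig | None = None):
    """L_seg = cross entropy + lambda_adv * adversarial term."""
    cfg = (cfg or LossConfig()).validate()
    ce = cross_entropy_loss(pred, truth, reduction=cfg.reduction, epsilon=cfg.epsilon)
    adv = adversarial_loss(d_on_fake, epsilon=cfg.epsilon)
    if isinstance(ce, Tensor) or isinstance(adv, Tensor):
        ce_t, _ = _as_tensor(ce)
        adv_t, _ = _as_tensor(adv)
        return ce_t + cfg.lambda_adv * adv_t
    return ce + cfg.lambda_adv * adv
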