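"""Hybrid segmentation objective: class-weighted cross-entropy + soft Dice.

Lesion pixels are vastly outnumbered by background (a microaneurysm may be a
handful of pixels in a 1.4-megapixel image), so the cross-entropy term weights
classes by omega = (100, 100, 50, 30, 1) for (MA, HE, SE, EX, background).
The Dice term uses *soft* (probabilistic) true-positive / false-negative /
false-positive sums, no thresholding.  The two are mixed as

    L = L_cross + lambda * L_dice,        lambda = 1.0 by default,

with the ablation encoding lambda = -1 meaning "Dice only" and lambda = 0
"cross-entropy only"; values in (-1, 0) are undefined and rejected.  The same
hybrid loss is applied to the main (fused) output and to the deep-supervision
head, summed with weight ``aux_weight``.

Cross-entropy is averaged over counted pixels so that lambda's scale does not
depend on resolution; Dice sums are taken over counted pixels.  With
``fov_masked`` on (the default), pixels outside the field-of-view mask are
excluded from both terms.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import softmax

__all__ = [
    "LossConfig",
    "DiceTerms",
    "weighted_cross_entropy",
    "dice_terms",
    "dice_loss",
    "hybrid_loss",
    "hybrid_loss_and_grads",
    "LOG_CLAMP",
    "DICE_EPS",
]

LOG_CLAMP = 1e-7
DICE_EPS = 1e-7


@dataclasses.dataclass(frozen=True)
class LossConfig:
    n_classes: int = 5
    class_weights: tuple[float, ...] = (100.0, 100.0, 50.0, 30.0, 1.0)
    lam: float = 1.0
    aux_weight: float = 1.0
    fov_masked: bool = True

    def __post_init__(self) -> None:
        if len(self.class_weights) != self.n_classes:
            raise ValueError("need one class weight per class")
        if any(w <= 0 for w in self.class_weights):
            raise ValueError("class weights must be positive")
        if -1.0 < self.lam < 0.0:
            raise ValueError("lambda in (-1, 0) is undefined; use -1 for "
                             "Dice-only or values >= 0")
        if self.aux_weight < 0:
            raise ValueError("aux_weight must be non-negative")


@dataclasses.dataclass
class DiceTerms:
    """Soft per-class confusion sums: TP(c), FN(c), FP(c)."""

    tp: np.ndarray
    fn: np.ndarray
    fp: np.ndarray

    @property
    def true_mass(self) -> np.ndarray:
        """TP(c) + FN(c): the total ground-truth mass of each class."""
        return self.tp + self.fn


def _as_batch(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    return a[None] if a.ndim == 3 else a


def _counted(p: np.ndarray, fov: np.ndarray | None) -> np.ndarray | None:
    """Boolean (N, H, W) pixel mask, or None when every pixel counts."""
    if fov is None:
        return None
    fov = np.asarray(fov, bool)
    if fov.ndim == 2:
        fov = fov[None]
    if fov.shape != (p.shape[0], p.shape[2], p.shape[3]):
        raise ValueError("FOV mask geometry does not match predictions")
    return fov


def _check_proba(p: np.ndarray) -> None:
    if not np.isfinite(p).all():
        bad = int((~np.isfinite(p)).sum())
        raise ValueError(f"probabilities contain {bad} non-finite value(s)")


def weighted_cross_entropy(p: np.ndarray, y: np.ndarray, config: LossConfig,
                           fov: np.ndarray | None = None) -> float:
    """Mean over counted pixels of ``-sum_c omega_c * y_c * log(p_c)``."""
    p, y = _as_batch(p).astype(np.float64), _as_batch(y)
    _check_proba(p)
    w = np.asarray(config.class_weights, np.float64)
    pix = -(w[None, :, None, None] * y * np.log(np.maximum(p, LOG_CLAMP))
            ).sum(axis=1)
    counted = _counted(p, fov if config.fov_masked else None)
    if counted is None:
        return float(pix.mean())
    n = counted.sum()
    if n == 0:
        raise ValueError("no counted pixels (empty FOV mask)")
    return float(pix[counted].sum() / n)


def dice_terms(p: np.ndarray, y: np.ndarray,
               fov: np.ndarray | None = None) -> DiceTerms:
    """Soft confusion sums TP = sum p*y, FP = sum p*(1-y), FN = sum (1-p)*y."""
    p, y = _as_batch(p).astype(np.float64), _as_batch(y).astype(np.float64)
    _check_proba(p)
    counted = _counted(p, fov)
    if counted is not None:
        sel = counted[:, None]
        p = p * sel
        y = y * sel
    tp = (p * y).sum(axis=(0, 2, 3))
    fp = (p * (1 - y)).sum(axis=(0, 2, 3)) if counted is None else \
        (p.sum(axis=(0, 2, 3)) - tp)
    fn = y.sum(axis=(0, 2, 3)) - tp
    return DiceTerms(tp=tp, fn=fn, fp=fp)


def dice_loss(terms: DiceTerms, config: LossConfig) -> float:
    """``M - sum_c 2 TP / (2 TP + FN + FP + eps)``; 0 at perfect prediction.

    The epsilon guards classes with no true or predicted mass: an entirely
    absent class contributes 0 to the sum (not NaN), so an all-background
    image predicted perfectly scores M-1 under this convention.
    """
    m = config.n_classes
    summand = 2.0 * terms.tp / (2.0 * terms.tp + terms.fn + terms.fp + DICE_EPS)
    return float(m - summand.sum())


def hybrid_loss(main_logits: np.ndarray, aux_logits: np.ndarray, y: np.ndarray,
                config: LossConfig, fov: np.ndarray | None = None) -> float:
    """Total hybrid loss over the main and deep-supervision heads."""
    total, _, _, _ = hybrid_loss_and_grads(main_logits, aux_logits, y, config,
                                           fov, need_grads=False)
    return total


def _head_loss_and_grad(logits: np.ndarray, y: np.ndarray, config: LossConfig,
                        fov: np.ndarray | None, need_grads: bool):
    logits = _as_batch(logits)
    y = _as_batch(y).astype(np.float64)
    if not np.isfinite(logits).all():
        raise ValueError("logits contain non-finite values")
    p = softmax(logits.astype(np.float64), axis=1)
    w = np.asarray(config.class_weights, np.float64)[None, :, None, None]
    counted = _counted(p, fov if config.fov_masked else None)
    if counted is None:
        n_pix = p.shape[0] * p.shape[2] * p.shape[3]
        sel = 1.0
    else:
        n_pix = int(counted.sum())
        if n_pix == 0:
            raise ValueError("no counted pixels (empty FOV mask)")
        sel = counted[:, None].astype(np.float64)

    pc = np.maximum(p, LOG_CLAMP)
    ce_pix = -(w * y * np.log(pc)).sum(axis=1, keepdims=True) * sel
    ce = float(ce_pix.sum() / n_pix)

    py = p * y * sel
    tp = py.sum(axis=(0, 2, 3))
    psum = (p * sel).sum(axis=(0, 2, 3))
    ysum = (y * sel).sum(axis=(0, 2, 3))
    q = psum + ysum + DICE_EPS  # = 2TP + FN + FP + eps
    dice = float(config.n_classes - (2.0 * tp / q).sum())

    lam = config.lam
    loss = dice if lam == -1.0 else ce + lam * dice
    if not need_grads:
        return loss, ce, dice, None

    g_ce = -(w * y) / pc / n_pix
    numer = 2.0 * tp
    g_dice = ((numer[None, :, None, None] - 2.0 * y * q[None, :, None, None])
              / (q ** 2)[None, :, None, None])
    g = g_dice if lam == -1.0 else g_ce + lam * g_dice
    g = g * sel
    dz = p * (g - (g * p).sum(axis=1, keepdims=True))
    return loss, ce, dice, dz.astype(np.float32)


def hybrid_loss_and_grads(main_logits: np.ndarray, aux_logits: np.ndarray,
                          y: np.ndarray, config: LossConfig,
                          fov: np.ndarray | None = None,
                          need_grads: bool = True):
    """Hybrid loss on both heads plus gradients w.r.t. both logit maps.

    Returns ``(total, components, dmain, daux)`` where components is a dict
    with per-head cross-entropy and Dice values.
    """
    l_main, ce_m, di_m, dmain = _head_loss_and_grad(main_logits, y, config, fov,
                                                    need_grads)
    l_aux, ce_a, di_a, daux = _head_loss_and_grad(aux_logits, y, config, fov,
                                                  need_grads)
    total = l_main + config.aux_weight * l_aux
    comps = {"main": l_main, "aux": l_aux, "ce_main": ce_m, "dice_main": di_m,
             "ce_aux": ce_a, "dice_aux": di_a}
    if need_grads and daux is not None:
        daux = (config.aux_weight * daux).astype(np.float32)
    return total, comps, dmain, daux
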