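"""Training protocol: SGD + momentum, Poly learning-rate decay, ablations.

The schedule follows the published recipe: SGD with momentum 0.9 and weight
decay 5e-4, batch size 2, 200 epochs, initial learning rate 0.01 decayed
once per epoch by the Poly rule

    lr(epoch) = initial_lr * (1 - epoch/total_epochs)**0.9 .

The FOV mask enters training as loss masking only (no extra input channel).
Checkpoint selection uses a seeded 80/20 train/validation split on the
manifest and keeps the state with the best validation mAUPR; repeated runs
use seeds (seed, seed+1, ...) and report the mean.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .losses import LossConfig, hybrid_loss_and_grads
from .model import ModelConfig, MSLFNet
from .nn import SGD
from .preprocessing import (PreprocessConfig, augment, encode_one_hot,
                            letterbox_resize, load_manifest, load_sample)
from .synthetic import FundusSample, _splitmix64

__all__ = ["TrainConfig", "TrainResult", "poly_lr", "train", "run_ablation",
           "repeat_train_evaluate", "save_checkpoint", "load_checkpoint"]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 200
    batch_size: int = 2
    initial_lr: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0005
    poly_power: float = 0.9
    seed: int = 0
    n_runs: int = 5
    val_fraction: float = 0.2
    eval_every: int = 1  # epochs between validation evaluations; 0 = never
    clip_grad_norm: float | None = 5.0  # global-norm clip; None disables

    def __post_init__(self) -> None:
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.poly_power <= 0:
            raise ValueError("poly_power must be positive")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")


def poly_lr(epoch: int, config: TrainConfig) -> float:
    """Poly decay: ``initial_lr * (1 - epoch/epochs)**poly_power``."""
    if not 0 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs}]")
    return float(config.initial_lr *
                 (1.0 - epoch / config.epochs) ** config.poly_power)


def _clip_global_norm(params, max_norm: float) -> None:
    """Rescale all gradients so their joint L2 norm is at most ``max_norm``.

    Guards the from-scratch network against the early large-gradient phase
    induced by the heavy lesion class weights.
    """
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale


@dataclasses.dataclass
class TrainResult:
    log: list[dict]
    final_state: dict[str, np.ndarray]
    best_state: dict[str, np.ndarray] | None
    best_val_maupr: float | None
    checkpoint_last: Path | None = None
    checkpoint_best: Path | None = None


def save_checkpoint(model: MSLFNet, path: str | Path) -> Path:
    """Write model weights as .npz with a sidecar YAML of the ModelConfig."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    cfg = dataclasses.asdict(model.config)
    cfg["input_size"] = list(cfg["input_size"])
    cfg["base_channels"] = list(cfg["base_channels"])
    path.with_suffix(".yaml").write_text(yaml.safe_dump(cfg))
    return path


def load_checkpoint(path: str | Path) -> tuple[MSLFNet, ModelConfig]:
    path = Path(path)
    cfg_raw = yaml.safe_load(path.with_suffix(".yaml").read_text())
    cfg_raw["input_size"] = tuple(cfg_raw["input_size"])
    cfg_raw["base_channels"] = tuple(cfg_raw["base_channels"])
    config = ModelConfig(**cfg_raw)
    model = MSLFNet(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, config


def _resolve_samples(data, pre_cfg: PreprocessConfig) -> list[FundusSample]:
    if isinstance(data, (str, Path)):
        rows = load_manifest(data)
        samples = [load_sample(r) for r in rows]
    else:
        samples = [s if isinstance(s, FundusSample) else load_sample(s)
                   for s in data]
    target = (pre_cfg.target_height, pre_cfg.target_width)
    out = []
    for s in samples:
        if s.image.shape[:2] != target:
            s = letterbox_resize(s, pre_cfg)
        out.append(s)
    return out


def train(model: MSLFNet, data, train_cfg: TrainConfig, loss_cfg: LossConfig,
          pre_cfg: PreprocessConfig, out_dir: str | Path | None = None,
          progress: bool = False) -> TrainResult:
    """Run the epoch loop; returns per-epoch log plus final/best weights.

    ``data`` is a manifest path, a list of manifest rows, or a list of
    ``FundusSample``.  Deterministic for a fixed seed.  A non-finite loss
    aborts with the offending batch index.
    """
    samples = _resolve_samples(data, pre_cfg)
    if not samples:
        raise ValueError("no training samples")
    rng = np.random.default_rng(train_cfg.seed)
    perm = rng.permutation(len(samples))
    n_val = int(round(train_cfg.val_fraction * len(samples)))
    n_val = min(n_val, len(samples) - 1)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    val_samples = [samples[i] for i in val_idx]

    opt = SGD(model.params(), lr=train_cfg.initial_lr,
              momentum=train_cfg.momentum,
              weight_decay=train_cfg.weight_decay)
    log: list[dict] = []
    best_state: dict | None = None
    best_maupr: float | None = None
    log_fh = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        log_fh = open(out_dir / "train_log.jsonl", "w")

    try:
        epochs = range(train_cfg.epochs)
        if progress:
            from tqdm import tqdm

            epochs = tqdm(epochs, desc="epochs")
        for epoch in epochs:
            opt.lr = poly_lr(epoch, train_cfg)
            order = rng.permutation(tr_idx)
            sums = {"ce": 0.0, "dice": 0.0, "loss": 0.0}
            n_batches = 0
            for b0 in range(0, len(order), train_cfg.batch_size):
                batch = order[b0:b0 + train_cfg.batch_size]
                xs, ys, fovs = [], [], []
                for j, i in enumerate(batch):
                    s = samples[i]
                    label = encode_one_hot(s.lesion_masks)
                    if pre_cfg.augment:
                        aug_seed = _splitmix64(
                            (train_cfg.seed << 40) ^ (epoch << 20) ^ int(i)
                        ) & 0x7FFFFFFF
                        s, label = augment(s, label, pre_cfg, aug_seed)
                    xs.append(s.image.transpose(2, 0, 1))
                    ys.append(label.y)
                    fovs.append(s.fov_mask)
                x = np.stack(xs).astype(np.float32)
                y = np.stack(ys)
                fov = np.stack(fovs)
                main, aux = model.forward(x, train=True)
                total, comps, dmain, daux = hybrid_loss_and_grads(
                    main, aux, y, loss_cfg, fov)
                if not np.isfinite(total):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, "
                        f"batch {b0 // train_cfg.batch_size}")
                opt.zero_grad()
                model.backward(dmain, daux)
                if train_cfg.clip_grad_norm is not None:
                    _clip_global_norm(opt.parameters, train_cfg.clip_grad_norm)
                opt.step()
                sums["ce"] += comps["ce_main"] + loss_cfg.aux_weight * comps["ce_aux"]
                sums["dice"] += comps["dice_main"] + loss_cfg.aux_weight * comps["dice_aux"]
                sums["loss"] += total
                n_batches += 1
            entry = {"epoch": epoch, "lr": opt.lr,
                     "ce": sums["ce"] / max(n_batches, 1),
                     "dice": sums["dice"] / max(n_batches, 1),
                     "loss": sums["loss"] / max(n_batches, 1)}
            if (val_samples and train_cfg.eval_every
                    and (epoch + 1) % train_cfg.eval_every == 0):
                res = evaluation.evaluate(model, val_samples)
                entry["val_maupr"] = res.maupr
                if best_maupr is None or res.maupr > best_maupr:
                    best_maupr = res.maupr
                    best_state = {k: v.copy()
                                  for k, v in model.state_dict().items()}
            log.append(entry)
            if log_fh is not None:
                log_fh.write(json.dumps(entry) + "\n")
                log_fh.flush()
    finally:
        if log_fh is not None:
            log_fh.close()

    result = TrainResult(log=log, final_state=model.state_dict(),
                         best_state=best_state, best_val_maupr=best_maupr)
    if out_dir is not None:
        result.checkpoint_last = save_checkpoint(model, out_dir / "last.npz")
        if best_state is not None:
            current = model.state_dict()
            model.load_state_dict(best_state)
            result.checkpoint_best = save_checkpoint(model, out_dir / "best.npz")
            model.load_state_dict(current)
    return result


def repeat_train_evaluate(model_cfg: ModelConfig, data, train_cfg: TrainConfig,
                          loss_cfg: LossConfig, pre_cfg: PreprocessConfig,
                          n_runs: int | None = None):
    """Train ``n_runs`` models with seeds (seed, seed+1, ...) and average.

    Mirrors the report-the-mean-of-repeated-experiments protocol.  Returns
    ``(train_results, averaged_pr_result)``.
    """
    n = train_cfg.n_runs if n_runs is None else n_runs
    if n <= 0:
        raise ValueError("n_runs must be positive")
    results, evals = [], []
    for k in range(n):
        t_cfg = dataclasses.replace(train_cfg, seed=train_cfg.seed + k)
        model = MSLFNet(dataclasses.replace(model_cfg, seed=model_cfg.seed + k))
        results.append(train(model, data, t_cfg, loss_cfg, pre_cfg))
        evals.append(evaluation.evaluate(model, _resolve_samples(data, pre_cfg)))
    return results, evaluation.average_results(evals)


_COMPONENT_ROWS = [
    ("Baseline", dict(use_msfe=False, use_mlff=False)),
    ("+MSFE", dict(use_msfe=True, use_mlff=False)),
    ("+MLFF", dict(use_msfe=True, use_mlff=True)),
]
_AUGMENT_ROWS = [
    ("baseline", dict(augment=False, fov_masked=False)),
    ("+Augmentation", dict(augment=True, fov_masked=False)),
    ("+FOV", dict(augment=True, fov_masked=True)),
]


def run_ablation(axis: str, grid, data, model_cfg: ModelConfig,
                 train_cfg: TrainConfig, loss_cfg: LossConfig,
                 pre_cfg: PreprocessConfig) -> pd.DataFrame:
    """Train/evaluate one model per ablation cell; returns the results table.

    Axes: ``components`` (Baseline / +MSFE / +MLFF), ``lambda`` (hybrid-loss
    mix sweep; -1 = Dice only) and ``augmentation`` (baseline /
    +Augmentation / +FOV).  ``grid=None`` selects the default grid for the
    axis; an explicitly empty grid yields an empty table.  Each cell is
    trained on ``data`` and evaluated on the same samples (desk-scale usage).
    """
    if axis == "components":
        cells = _COMPONENT_ROWS if grid is None else \
            [r for r in _COMPONENT_ROWS if r[0] in grid]
    elif axis == "lambda":
        lam_grid = [-1.0, 0.0, 1.0] if grid is None else list(grid)
        cells = [(lam, {"lam": float(lam)}) for lam in lam_grid]
    elif axis == "augmentation":
        cells = _AUGMENT_ROWS if grid is None else \
            [r for r in _AUGMENT_ROWS if r[0] in grid]
    else:
        raise ValueError(f"unknown ablation axis {axis!r}; expected "
                         "'components', 'lambda' or 'augmentation'")

    rows = []
    for label, overrides in cells:
        m_cfg, l_cfg, p_cfg = model_cfg, loss_cfg, pre_cfg
        if axis == "components":
            m_cfg = dataclasses.replace(model_cfg, **overrides)
        elif axis == "lambda":
            l_cfg = dataclasses.replace(loss_cfg, **overrides)
        else:
            p_cfg = dataclasses.replace(pre_cfg, augment=overrides["augment"])
            l_cfg = dataclasses.replace(loss_cfg,
                                        fov_masked=overrides["fov_masked"])
        model = MSLFNet(m_cfg)
        train(model, data, train_cfg, l_cfg, p_cfg)
        res = evaluation.evaluate(
            model, _resolve_samples(data, p_cfg))
        row = {("lambda" if axis == "lambda" else "config"): label}
        for name, cls_pr in res.per_class.items():
            row[name.upper()] = cls_pr.aupr
        row["mAUPR"] = res.maupr
        rows.append(row)
    cols = (["lambda" if axis == "lambda" else "config"]
            + [c.upper() for c in ("ma", "he", "se", "ex")] + ["mAUPR"])
    return pd.DataFrame(rows, columns=cols if rows else None)
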