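"""Training protocol, evaluation, and checkpointing.

Reference schedule: Adam (1e-4 initial lr, x0.9 decay every 10 epochs,
weight decay 1e-4, batch 8) for 100 epochs at 512x512.  Small-scale runs
shrink epochs/scene counts/resolution through TrainConfig; the schedule
shape is unchanged.  Checkpoints are .npz archives embedding the resolved
model configuration, so a checkpoint is self-describing.
"""
from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .losses import LossConfig, segmentation_loss
from .metrics import ConfusionMatrix, miou_mpa, per_class_report
from .model import ModelConfig, SegmentationModel, build_model
from .nn import Tensor, no_grad
from .nn.optim import Adam, step_decay_lr
from .synthetic import load_split, read_dataset


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    initial_lr: float = 1e-4
    lr_decay: float = 0.9
    lr_decay_every: int = 10
    batch_size: int = 8
    weight_decay: float = 1e-4
    seed: int = 0
    augment: bool = False
    loss: LossConfig = field(default_factory=LossConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.lr_decay_every) < 1 \
                or self.initial_lr <= 0 or self.lr_decay <= 0:
            raise ValueError("training hyperparameters must be positive")


def _config_dict(obj):
    if dataclasses.is_dataclass(obj):
        d = {}
        for f in dataclasses.fields(obj):
            d[f.name] = _config_dict(getattr(obj, f.name))
        return d
    if isinstance(obj, frozenset):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_checkpoint(model: SegmentationModel, path, extra: dict | None = None):
    meta = {"model": _config_dict(model.cfg)}
    meta.update(extra or {})
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[SegmentationModel, dict]:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]))
        sd = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    mc = dict(meta["model"])
    mc["input_size"] = tuple(mc["input_size"])
    mc["aspp_rates"] = tuple(mc["aspp_rates"])
    mc["simam_positions"] = frozenset(mc["simam_positions"])
    model = build_model(ModelConfig(**mc))
    model.load_state_dict(sd)
    return model, meta


def fuse_checkpoint(src, dst, probe_size=(64, 64), seed: int = 0) -> dict:
    """Reparameterize a checkpoint; record the max output deviation fingerprint."""
    model, meta = load_checkpoint(src)
    model.eval()
    fused = model.fuse()
    rng = np.random.default_rng(seed)
    probe = Tensor(rng.normal(0, 1, (1, 3, *probe_size)).astype(np.float32))
    with no_grad():
        a, b = model(probe).data, fused(probe).data
    dev = float(np.abs(a - b).max())
    rel = dev / max(1.0, float(np.abs(a).max()))
    save_checkpoint(fused, dst, {"fingerprint": {"probe_size": list(probe_size),
                                                 "probe_seed": seed,
                                                 "max_abs_deviation": dev,
                                                 "max_rel_deviation": rel}})
    return {"max_abs_deviation": dev, "max_rel_deviation": rel}


def evaluate(model: SegmentationModel, images: np.ndarray, masks: np.ndarray,
             batch_size: int = 8, class_names=None) -> dict:
    """Confusion-matrix metrics of a model on stacked (images, masks)."""
    model.eval()
    cm = ConfusionMatrix(model.cfg.num_classes)
    with no_grad():
        for i in range(0, len(images), batch_size):
            logits = model(Tensor(images[i:i + batch_size]))
            pred = np.argmax(logits.data, axis=1)
            cm.update(pred, masks[i:i + batch_size])
    miou, mpa = miou_mpa(cm)
    return {"miou": miou, "mpa": mpa, "confusion": cm,
            "report": per_class_report(cm, class_names)}


def evaluate_split(checkpoint, dataset_root, split: str = "val") -> dict:
    model, _ = load_checkpoint(checkpoint)
    man = read_dataset(dataset_root)
    x, y = load_split(man, split)
    return evaluate(model, x, y, class_names=list(man.class_names))


def train(cfg: TrainConfig, dataset_root, out_dir, log=print) -> dict:
    """Full protocol: per-epoch train loss + val metrics, best-val checkpoint."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    man = read_dataset(dataset_root)
    if not man.splits.get("train") or not man.splits.get("val"):
        raise ValueError("empty train or val split")
    xtr, ytr = load_split(man, "train")
    xva, yva = load_split(man, "val")
    rng = np.random.default_rng(cfg.seed)
    model = build_model(cfg.model, rng=rng)
    opt = Adam(model.parameters(), lr=cfg.initial_lr, weight_decay=cfg.weight_decay)
    history, best = [], (-1.0, None)
    log_path = out_dir / "train_log.jsonl"
    with log_path.open("w") as fh:
        fh.write(json.dumps({"config": _config_dict(cfg)}) + "\n")
    for epoch in range(cfg.epochs):
        opt.lr = step_decay_lr(cfg.initial_lr, epoch, cfg.lr_decay, cfg.lr_decay_every)
        model.train()
        order = rng.permutation(len(xtr))
        losses = []
        t0 = time.time()
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            if cfg.augment and rng.random() < 0.5:
                xb, yb = xb[..., ::-1].copy(), yb[..., ::-1].copy()
            loss = segmentation_loss(model(Tensor(xb)), yb, cfg.loss)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {i // cfg.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        res = evaluate(model, xva, yva, cfg.batch_size)
        rec = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses)),
               "val_miou": res["miou"], "val_mpa": res["mpa"],
               "seconds": round(time.time() - t0, 2)}
        history.append(rec)
        with log_path.open("a") as fh:
            fh.write(json.dumps(rec) + "\n")
        log(f"epoch {epoch:3d} lr {opt.lr:.2e} loss {rec['train_loss']:.4f} "
            f"val mIoU {res['miou']:.2f}% mPA {res['mpa']:.2f}%")
        if res["miou"] > best[0]:
            best = (res["miou"], epoch)
            save_checkpoint(model, out_dir / "best.npz",
                            {"epoch": epoch, "val_miou": res["miou"]})
    save_checkpoint(model, out_dir / "last.npz", {"epoch": cfg.epochs - 1})
    return {"history": history, "best_val_miou": best[0], "best_epoch": best[1],
            "model": model}


def overfit_one_batch(model: SegmentationModel, images: np.ndarray,
                      masks: np.ndarray, steps: int = 150, lr: float = 2e-3,
                      loss_cfg: LossConfig = LossConfig()) -> list:
    """Sanity optimization: repeatedly fit one batch; returns the loss trace."""
    opt = Adam(model.parameters(), lr=lr)
    trace = []
    model.train()
    for _ in range(steps):
        loss = segmentation_loss(model(Tensor(images)), masks, loss_cfg)
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(loss.item())
    return trace
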