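"""Dataset reading, augmentation, training loop, folds and ablation builder.

Datasets are directories of image files with ``<stem>_segmentation.png``
companion masks (the public archive layout, which the synthetic generator
also writes).  Images are resized bilinearly to the working resolution and
scaled to [0, 1], then channel-standardized with statistics of the training
pool; masks are nearest-neighbor resized and binarized at 127.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy import ndimage

from . import metrics as M
from .catm import ROUTINGS
from .network import ModelConfig, ScaleFusionNet, compound_loss
from .nn import AdamW, Tensor, clip_grad_norm, no_grad

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "AblationSpec",
    "ABLATION_TABLE",
    "load_dataset",
    "split_stems",
    "kfold_splits",
    "augment",
    "train",
    "evaluate",
    "build_ablation",
]

_IMG_EXTS = (".png", ".jpg", ".jpeg")
_MASK_SUFFIX = "_segmentation.png"


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    epochs: int = 200
    batch_size: int = 8
    input_size: int = 256
    rotation_degrees: float = 30.0
    flip: bool = True
    grad_clip: float = 1.0
    warmup_steps: int = 0   # linear LR ramp; 0 keeps the constant-LR recipe
    seed: int = 0
    folds: int = 5

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("invalid optimizer hyperparameters")


# ----------------------------------------------------------------- data IO
def _discover_pairs(directory: Path) -> List[Tuple[Path, Path]]:
    images = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in _IMG_EXTS and not p.name.endswith(_MASK_SUFFIX)
    )
    if not images:
        raise FileNotFoundError(f"no images found in {directory}")
    pairs, missing = [], []
    for img in images:
        mask = directory / (img.stem + _MASK_SUFFIX)
        if mask.exists():
            pairs.append((img, mask))
        else:
            missing.append(img.stem)
    if missing:
        raise FileNotFoundError(
            f"images without masks in {directory}: {', '.join(missing)}"
        )
    return pairs


def _load_pair(img_path: Path, mask_path: Path, size: int):
    img = Image.open(img_path).convert("RGB").resize(
        (size, size), Image.BILINEAR
    )
    mask = Image.open(mask_path).convert("L").resize(
        (size, size), Image.NEAREST
    )
    x = np.asarray(img, dtype=np.float32) / 255.0        # (H, W, 3)
    y = (np.asarray(mask) > 127).astype(np.float32)      # (H, W)
    return x.transpose(2, 0, 1), y[None]


def split_stems(n: int, ratio: Tuple[int, int, int] = (8, 1, 1),
                seed: int = 0) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic shuffled index split at the given ratio."""
    order = np.random.default_rng(seed).permutation(n)
    total = sum(ratio)
    n_train = round(n * ratio[0] / total)
    n_val = round(n * ratio[1] / total)
    return (order[:n_train], order[n_train:n_train + n_val],
            order[n_train + n_val:])


def kfold_splits(n: int, folds: int, seed: int = 0):
    """Yield (train_idx, test_idx) pairs of a seeded k-fold partition."""
    order = np.random.default_rng(seed).permutation(n)
    for chunk in np.array_split(order, folds):
        yield np.setdiff1d(order, chunk, assume_unique=True), chunk


@dataclass
class SegmentationDataset:
    images: np.ndarray                 # (N, 3, S, S) float32, standardized
    masks: np.ndarray                  # (N, 1, S, S) float32 in {0, 1}
    stems: List[str]
    splits: Dict[str, np.ndarray] = field(default_factory=dict)
    channel_mean: Optional[np.ndarray] = None
    channel_std: Optional[np.ndarray] = None

    def subset(self, name: str):
        idx = self.splits[name]
        return self.images[idx], self.masks[idx]


def load_dataset(directory, input_size: int = 256,
                 ratio: Tuple[int, int, int] = (8, 1, 1),
                 seed: int = 0, standardize: bool = True) -> SegmentationDataset:
    """Read an archive-layout directory into memory with a seeded split."""
    directory = Path(directory)
    pairs = _discover_pairs(directory)
    xs, ys = zip(*(_load_pair(i, m, input_size) for i, m in pairs))
    images = np.stack(xs)
    masks = np.stack(ys)
    tr, va, te = split_stems(len(pairs), ratio=ratio, seed=seed)
    mean = std = None
    if standardize:
        mean = images[tr].mean(axis=(0, 2, 3), keepdims=True)
        std = images[tr].std(axis=(0, 2, 3), keepdims=True) + 1e-6
        images = (images - mean) / std
    return SegmentationDataset(
        images=images, masks=masks,
        stems=[i.stem for i, _ in pairs],
        splits={"train": tr, "val": va, "test": te},
        channel_mean=mean, channel_std=std,
    )


# -------------------------------------------------------------- augmentation
def augment(image: np.ndarray, mask: np.ndarray, seed: int,
            rotation_degrees: float = 30.0, flip: bool = True):
    """Identical geometric transform on image (bilinear) and mask (nearest).

    Flips are applied with probability 0.5 each; rotation angle is uniform
    in +-rotation_degrees.  The mask is re-binarized after interpolation.
    """
    rng = np.random.default_rng(seed)
    img, msk = image.copy(), mask.copy()
    if flip and rng.random() < 0.5:
        img, msk = img[..., ::-1], msk[..., ::-1]
    if flip and rng.random() < 0.5:
        img, msk = img[..., ::-1, :], msk[..., ::-1, :]
    angle = float(rng.uniform(-rotation_degrees, rotation_degrees))
    if angle and rotation_degrees > 0:
        img = ndimage.rotate(img, angle, axes=(-2, -1), reshape=False,
                             order=1, mode="nearest")
        msk = ndimage.rotate(msk, angle, axes=(-2, -1), reshape=False,
                             order=0, mode="constant", cval=0.0)
    return (np.ascontiguousarray(img, dtype=np.float32),
            (np.ascontiguousarray(msk) > 0.5).astype(np.float32))


# ------------------------------------------------------------------ training
def _batch_dsc(prob: np.ndarray, target: np.ndarray) -> float:
    pred = prob > 0.5
    t = target > 0.5
    denom = pred.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2 * (pred & t).sum() / denom)


def train(model_cfg: ModelConfig, train_cfg: TrainConfig,
          train_data: Tuple[np.ndarray, np.ndarray],
          val_data: Optional[Tuple[np.ndarray, np.ndarray]] = None,
          steps: Optional[int] = None,
          use_augment: bool = True,
          log_path=None):
    """AdamW optimization of the compound loss; returns (model, history).

    ``steps`` caps total optimization steps (otherwise epochs x batches).
    The returned model carries the best-validation-DSC weights when
    validation data is given, else the final weights.  A NaN loss aborts
    with a diagnostic.
    """
    rng = np.random.default_rng(train_cfg.seed)
    model = ScaleFusionNet(model_cfg, rng=np.random.default_rng(model_cfg.seed))
    opt = AdamW(model.parameters(), lr=train_cfg.learning_rate,
                weight_decay=train_cfg.weight_decay)
    xs, ys = train_data
    n = len(xs)
    bs = min(train_cfg.batch_size, n)
    history: List[dict] = []
    best = {"val_dsc": -1.0, "state": None}
    step = 0
    log_fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(train_cfg.epochs):
            order = rng.permutation(n)
            epoch_loss, epoch_dsc, n_batches = 0.0, 0.0, 0
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb, yb = xs[idx], ys[idx]
                if use_augment:
                    aug_seeds = rng.integers(0, 2 ** 31, size=len(idx))
                    pairs = [
                        augment(x, y, int(s), train_cfg.rotation_degrees,
                                train_cfg.flip)
                        for x, y, s in zip(xb, yb, aug_seeds)
                    ]
                    xb = np.stack([p[0] for p in pairs])
                    yb = np.stack([p[1] for p in pairs])
                prob = model(Tensor(xb))
                loss = compound_loss(prob, Tensor(yb))
                lval = loss.item()
                if not np.isfinite(lval):
                    raise RuntimeError(
                        f"training diverged: loss={lval} at step {step} "
                        f"(epoch {epoch}); lower the learning rate"
                    )
                opt.zero_grad()
                loss.backward()
                if train_cfg.grad_clip > 0:
                    clip_grad_norm(model.parameters(), train_cfg.grad_clip)
                if train_cfg.warmup_steps > 0:
                    opt.lr = train_cfg.learning_rate * min(
                        1.0, (step + 1) / train_cfg.warmup_steps
                    )
                opt.step()
                epoch_loss += lval
                epoch_dsc += _batch_dsc(prob.data, yb)
                n_batches += 1
                step += 1
                if steps is not None and step >= steps:
                    break
            entry = {
                "epoch": epoch,
                "step": step,
                "train_loss": epoch_loss / max(n_batches, 1),
                "train_dsc": epoch_dsc / max(n_batches, 1),
            }
            if val_data is not None:
                entry["val_dsc"] = _eval_dsc(model, *val_data, bs=bs)
                if entry["val_dsc"] >= best["val_dsc"]:
                    best = {"val_dsc": entry["val_dsc"],
                            "state": model.state_dict()}
            history.append(entry)
            if log_fh:
                log_fh.write(json.dumps(entry) + "\n")
                log_fh.flush()
            if steps is not None and step >= steps:
                break
    finally:
        if log_fh:
            log_fh.close()
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    return model, history


def _eval_dsc(model, xs, ys, bs: int = 8) -> float:
    scores = []
    for start in range(0, len(xs), bs):
        prob, _ = model.predict(Tensor(xs[start:start + bs]))
        scores.append(_batch_dsc(prob, ys[start:start + bs]))
    return float(np.mean(scores))


def evaluate(model: ScaleFusionNet, images: np.ndarray, masks: np.ndarray,
             batch_size: int = 4, threshold: float = 0.5):
    """Full metric report on a dataset: per-image metrics, pooled AUC,
    and the aggregate mean +- std."""
    per_image, probs, truths = [], [], []
    for start in range(0, len(images), batch_size):
        prob, pred = model.predict(Tensor(images[start:start + batch_size]),
                                   threshold=threshold)
        for p, bm, t in zip(prob, pred, masks[start:start + batch_size]):
            per_image.append(M.evaluate_masks(bm[0], t[0].astype(int)))
            probs.append(p[0])
            truths.append(t[0].astype(int))
    pooled_auc = M.roc_auc(probs, truths)
    agg = M.aggregate(per_image)
    agg["auc"] = {"mean": pooled_auc, "std": 0.0, "n_excluded": 0}
    return {"per_image": per_image, "aggregate": agg, "auc": pooled_auc}


# ------------------------------------------------------------------ ablation
#: structural ablation rows: method id -> (catm, afb, shared_sa)
ABLATION_TABLE: Dict[str, Tuple[bool, bool, bool]] = {
    "0": (False, False, False),      # hybrid backbone only
    "1": (False, True, False),       # + AFB
    "2": (True, False, True),        # + CATM with SharedSA
    "3": (True, True, False),        # + AFB + CATM without SharedSA
    "full": (True, True, True),
}


@dataclass(frozen=True)
class AblationSpec:
    method_id: str = "full"
    qkv_routing: str = "decoder_all"

    def __post_init__(self):
        if self.method_id not in ABLATION_TABLE:
            raise ValueError(
                f"unknown method {self.method_id!r}; "
                f"valid: {sorted(ABLATION_TABLE)}"
            )
        if self.qkv_routing not in ROUTINGS:
            raise ValueError(
                f"unknown routing {self.qkv_routing!r}; "
                f"valid: {sorted(ROUTINGS)}"
            )


def build_ablation(spec: AblationSpec,
                   base: Optional[ModelConfig] = None) -> ModelConfig:
    """Model configuration for one structural-ablation or routing variant."""
    base = base or ModelConfig()
    catm, afb, shared = ABLATION_TABLE[spec.method_id]
    return dataclasses.replace(
        base,
        catm_enabled=catm,
        afb_enabled=afb,
        shared_sa_enabled=shared,
        qkv_routing=spec.qkv_routing,
    )
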