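"""Seeded training loop with Focal Tversky loss and validation-based selection.

The loop is deliberately plain: Adam at a constant learning rate, a fixed
batch size, per-epoch shuffling from one seeded generator, and a checkpoint
of the epoch with the best validation score.  Model selection uses the
validation set (never the test set).  Checkpoints are numpy ``.npz``
archives holding the parameter tensors plus the JSON-encoded network spec.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data as dio
from .architectures import NetworkSpec, build_network
from .metrics import TverskyParams, confusion_counts, dice, jaccard
from .nn import Adam, SGD, Tensor, focal_tversky, no_grad
from .synthetic import SynthConfig, generate_samples


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite; carries the log so far."""

    def __init__(self, message: str, log: pd.DataFrame):
        super().__init__(message)
        self.log = log


@dataclass
class TrainConfig:
    architecture: str = "attention_squeeze_unet"
    height: int = 384
    width: int = 512
    num_classes: int = 2
    seed: int = 0
    epochs: int = 100
    batch_size: int = 8
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    tversky: TverskyParams = field(default_factory=TverskyParams)
    selection_metric: str = "dice"          # dice | jaccard
    checkpoint_dir: str = "checkpoints"
    train_images: str | None = None
    train_masks: str | None = None
    val_images: str | None = None
    val_masks: str | None = None
    synth_train: SynthConfig | None = None
    synth_val: SynthConfig | None = None
    augment: bool = False
    max_steps: int | None = None            # cap on optimizer updates
    early_stop_train_dice: float | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.selection_metric not in ("dice", "jaccard"):
            raise ValueError("selection_metric must be 'dice' or 'jaccard'")

    def network_spec(self) -> NetworkSpec:
        return NetworkSpec(architecture=self.architecture, height=self.height,
                           width=self.width, num_classes=self.num_classes,
                           seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        def listify(v):
            if isinstance(v, dict):
                return {k: listify(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [listify(x) for x in v]
            return v

        d = listify(dataclasses.asdict(self))
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("tversky") is not None:
            d["tversky"] = TverskyParams(**d["tversky"])
        for key in ("synth_train", "synth_val"):
            if d.get(key) is not None:
                d[key] = SynthConfig.from_dict(d[key])
        return cls(**d)


@dataclass
class TrainResult:
    log: pd.DataFrame
    checkpoint: Path | None
    best_epoch: int
    best_score: float


def _stack_batch(samples) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.image for s in samples]).transpose(0, 3, 1, 2).astype(np.float32)
    y = np.stack([s.mask for s in samples]).astype(np.float32)
    return x, y


def _resolve_data(config: TrainConfig, train_data, val_data):
    target = (config.height, config.width)
    if train_data is None:
        if config.synth_train is not None:
            train_data = generate_samples(dataclasses.replace(
                config.synth_train, height=config.height, width=config.width))
        elif config.train_images:
            train_data = dio.load_dataset(config.train_images, config.train_masks,
                                          target=target)
        else:
            raise ValueError("no training data: set train_images or synth_train")
    if val_data is None:
        if config.synth_val is not None:
            val_data = generate_samples(dataclasses.replace(
                config.synth_val, height=config.height, width=config.width))
        elif config.val_images:
            val_data = dio.load_dataset(config.val_images, config.val_masks,
                                        target=target)
    train_data = [dio.resize_normalize(s, target) for s in train_data]
    if config.augment:
        train_data = dio.augment_flips(train_data)
    if val_data is not None:
        val_data = [dio.resize_normalize(s, target) for s in val_data]
    return train_data, val_data


def _mean_scores(model, samples, batch_size: int) -> tuple[float, float]:
    d_all, j_all = [], []
    for i in range(0, len(samples), batch_size):
        x, y = _stack_batch(samples[i:i + batch_size])
        with no_grad():
            probs = model(Tensor(x)).data
        preds = probs.argmax(axis=1).astype(np.uint8)
        for p, g in zip(preds, y.astype(np.uint8)):
            c = confusion_counts(p, g)
            d_all.append(dice(c))
            j_all.append(jaccard(c))
    return float(np.mean(d_all)), float(np.mean(j_all))


def train(config: TrainConfig, train_data=None, val_data=None) -> TrainResult:
    """Train per ``config``; returns the per-epoch log and best checkpoint.

    ``train_data`` / ``val_data`` may be passed directly as lists of
    :class:`~dermseg.data.ImageSample` (with masks); otherwise they are
    loaded from the configured directories or synthesized.
    """
    train_data, val_data = _resolve_data(config, train_data, val_data)
    spec = config.network_spec()
    model = build_network(spec)
    params = list(model.parameters())
    if config.optimizer == "adam":
        opt = Adam(params, lr=config.learning_rate)
    elif config.optimizer == "sgd":
        opt = SGD(params, lr=config.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    rng = np.random.default_rng(config.seed + 1)
    ckpt_dir = Path(config.checkpoint_dir)
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    ckpt_path = ckpt_dir / f"{config.architecture}_best.npz"

    rows = []
    best_score, best_epoch = -np.inf, -1
    steps = 0
    stop = False
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_data))
        losses, train_dices = [], []
        for i in range(0, len(order), config.batch_size):
            batch = [train_data[k] for k in order[i:i + config.batch_size]]
            x, y = _stack_batch(batch)
            opt.zero_grad()
            probs = model(Tensor(x))
            loss = focal_tversky(probs, y, config.tversky)
            lval = loss.item()
            if not np.isfinite(lval):
                log = pd.DataFrame(rows)
                last = rows[-1]["epoch"] if rows else None
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {steps}; "
                    f"last finite epoch: {last}", log)
            loss.backward()
            opt.step()
            steps += 1
            losses.append(lval)
            preds = probs.data.argmax(axis=1).astype(np.uint8)
            train_dices.append(np.mean([
                dice(confusion_counts(p, g))
                for p, g in zip(preds, y.astype(np.uint8))]))
            if config.max_steps is not None and steps >= config.max_steps:
                stop = True
            if (config.early_stop_train_dice is not None
                    and train_dices[-1] >= config.early_stop_train_dice):
                stop = True
            if stop:
                break

        row = {"epoch": epoch, "steps": steps,
               "train_loss": float(np.mean(losses)),
               "train_dice": float(np.mean(train_dices))}
        if val_data:
            vd, vj = _mean_scores(model, val_data, config.batch_size)
            row["val_dice"], row["val_jaccard"] = vd, vj
            score = vd if config.selection_metric == "dice" else vj
        else:
            score = row["train_dice"]
        if score > best_score:
            best_score, best_epoch = score, epoch
            save_checkpoint(model, spec, ckpt_path)
        rows.append(row)
        if stop:
            break

    log = pd.DataFrame(rows)
    log.to_csv(ckpt_dir / f"{config.architecture}_log.csv", index=False)
    return TrainResult(log=log, checkpoint=ckpt_path, best_epoch=best_epoch,
                       best_score=float(best_score))


def save_checkpoint(model, spec: NetworkSpec, path: str | Path) -> None:
    meta = dataclasses.asdict(spec)
    np.savez(Path(path), __spec__=json.dumps(meta), **model.state_dict())


def load_checkpoint(path: str | Path):
    """Rebuild the model stored at ``path``; returns (model, spec)."""
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["__spec__"]))
        state = {k: archive[k] for k in archive.files if k != "__spec__"}
    meta["schedule"] = dict(meta.get("schedule") or {}) or None
    spec = NetworkSpec(**{k: v for k, v in meta.items() if v is not None})
    model = build_network(spec)
    model.load_state_dict(state)
    return model, spec


def predict(model_or_checkpoint, images, batch_size: int = 4) -> list[np.ndarray]:
    """Segment images with a trained model.

    ``images`` is a sequence of (H, W, 3) float arrays in [0, 1] (arbitrary
    sizes) or :class:`ImageSample` objects.  Each image is resized to the
    network input, passed through the softmax head, binarized by per-pixel
    argmax and resized back to its original size (nearest-neighbour).
    """
    if isinstance(model_or_checkpoint, (str, Path)):
        model, spec = load_checkpoint(model_or_checkpoint)
    else:
        model = model_or_checkpoint
        spec = model.spec
    target = (spec.height, spec.width)
    arrays = [im.image if isinstance(im, dio.ImageSample) else np.asarray(im)
              for im in images]
    resized = np.stack([dio.resize_image(a, target) for a in arrays])
    out: list[np.ndarray] = []
    for i in range(0, len(resized), batch_size):
        x = resized[i:i + batch_size].transpose(0, 3, 1, 2).astype(np.float32)
        with no_grad():
            probs = model(Tensor(x)).data
        preds = probs.argmax(axis=1).astype(np.uint8)
        for p, original in zip(preds, arrays[i:i + batch_size]):
            out.append(dio.resize_mask(p, original.shape[:2]))
    return out
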