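"""The three-scale classifier bank and its training regimen.

One classifier per patch scale (400, 200, 100 px), trained independently
under weak, slide-level labels (each patch inherits its slide's class — the
multiple-instance, bag-labeling view). Training follows a fixed regimen:
mini-batches of 64, categorical cross-entropy, Adam at 1e-3, early stopping
on held-out validation accuracy, and learning-rate decay by 0.1 after two
epochs without validation improvement.

Each scale model block-averages its native patch to a small network input
(25x25 for the 100/200-px scales, 50x50 for the 400-px scale, keeping
per-scale compute balanced since coarse patches are ~4x fewer). The three
models therefore still see different fields of view (100/200/400 px of
tissue context) at different microns-per-input-pixel — the scale distinction
lives in the receptive field, not the tensor size — while keeping CPU
training tractable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import resize
from sklearn.model_selection import train_test_split

from .nn import Optimizer, SmallResNet, cross_entropy, softmax
from .tiling import Patch

__all__ = [
    "TrainingConfig",
    "ScaleModel",
    "PatchPrediction",
    "PlateauScheduler",
    "build_model",
    "default_input_size",
    "train",
    "predict_patch",
    "predict_batch",
    "save_model",
    "load_model",
]

DEFAULT_INPUT_SIZE = 25


def default_input_size(scale: int) -> int:
    """Network input side for a patch scale: at most 8x downsampling, >= 25."""
    return max(DEFAULT_INPUT_SIZE, scale // 8)


@dataclass(frozen=True)
class TrainingConfig:
    mini_batch_size: int = 64
    max_epochs: int = 10
    initial_learning_rate: float = 0.001
    optimizer: str = "adam"  # adam | sgdm | rmsprop
    lr_plateau_factor: float = 0.1
    lr_plateau_patience: int = 2
    early_stopping_patience: int = 6
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if not 0.0 < self.lr_plateau_factor < 1.0:
            raise ValueError("lr_plateau_factor must be in (0, 1)")
        if self.lr_plateau_patience < 1:
            raise ValueError("lr_plateau_patience must be >= 1")


@dataclass
class ScaleModel:
    """A trained (or fresh) classifier bound to one patch scale."""

    scale: int
    n_classes: int
    architecture: str
    class_order: tuple[str, ...]
    network: SmallResNet
    input_size: int = DEFAULT_INPUT_SIZE
    seed: int = 0


@dataclass(frozen=True, eq=False)
class PatchPrediction:
    label: str
    probabilities: np.ndarray  # ordered as class_order, sums to 1


class PlateauScheduler:
    """Reduce-LR-on-plateau + early stopping, monitoring validation accuracy.

    After ``plateau_patience`` epochs without improvement the learning rate
    is multiplied by ``factor``; after ``stop_patience`` epochs without
    improvement training stops. Improvement resets both counters.
    """

    def __init__(self, lr: float, factor: float, plateau_patience: int, stop_patience: int):
        self.lr = lr
        self.factor = factor
        self.plateau_patience = plateau_patience
        self.stop_patience = stop_patience
        self.best = -np.inf
        self.stale = 0
        self.since_decay = 0

    def update(self, val_accuracy: float) -> tuple[float, bool]:
        """Record one epoch's validation accuracy; return (next lr, stop?)."""
        if val_accuracy > self.best + 1e-12:
            self.best = val_accuracy
            self.stale = 0
            self.since_decay = 0
        else:
            self.stale += 1
            self.since_decay += 1
            if self.since_decay >= self.plateau_patience:
                self.lr *= self.factor
                self.since_decay = 0
        return self.lr, self.stale >= self.stop_patience


def _downsample(pixels: np.ndarray, input_size: int) -> np.ndarray:
    """Patch pixels (S,S,3 uint8) -> (input,input,3) floats in [0,1]."""
    s = pixels.shape[0]
    x = pixels.astype(np.float64) / 255.0
    if s == input_size:
        return x
    if s % input_size == 0:
        f = s // input_size
        return x.reshape(input_size, f, input_size, f, 3).mean(axis=(1, 3))
    return resize(x, (input_size, input_size, 3), anti_aliasing=True)


def patches_to_array(patches: list[Patch], input_size: int = DEFAULT_INPUT_SIZE) -> np.ndarray:
    return np.stack([_downsample(p.pixels, input_size) for p in patches])


def build_model(
    scale: int,
    n_classes: int,
    architecture: str = "small_resnet",
    seed: int = 0,
    class_order: tuple[str, ...] | None = None,
    input_size: int | None = None,
) -> ScaleModel:
    """Randomly initialized scale classifier (no pretrained weights)."""
    if architecture != "small_resnet":
        raise ValueError(
            f"unsupported architecture {architecture!r}; this build ships 'small_resnet'"
        )
    if scale % 4 != 0:
        raise ValueError("scale must be divisible by 4")
    if class_order is None:
        class_order = tuple(f"class_{i}" for i in range(n_classes))
    if len(class_order) != n_classes:
        raise ValueError("class_order length must equal n_classes")
    if input_size is None:
        input_size = default_input_size(scale)
    net = SmallResNet(input_size=input_size, n_classes=n_classes, seed=seed)
    return ScaleModel(
        scale=scale,
        n_classes=n_classes,
        architecture=architecture,
        class_order=tuple(class_order),
        network=net,
        input_size=input_size,
        seed=seed,
    )


def train(
    model: ScaleModel,
    patches: list[Patch],
    labels: list[str],
    config: TrainingConfig | None = None,
) -> tuple[ScaleModel, list[dict]]:
    """Train a scale model on weakly-labeled patches; return (model, history).

    Labels are the patches' slide-level classes. A stratified
    ``validation_fraction`` split is held out (seeded) to monitor validation
    accuracy for early stopping and LR-plateau decay. History records one
    dict per epoch: loss, val_accuracy, learning_rate. The parameters of the
    best-validation epoch are restored at the end.
    """
    config = config or TrainingConfig()
    if len(patches) != len(labels):
        raise ValueError("patches and labels must have equal length")
    for p in patches:
        if p.scale != model.scale:
            raise ValueError(f"patch scale {p.scale} does not match model scale {model.scale}")
    classes_present = set(labels)
    if len(classes_present) < 2:
        raise ValueError("training requires at least 2 classes present")
    unknown = classes_present - set(model.class_order)
    if unknown:
        raise ValueError(f"labels not in model class_order: {sorted(unknown)}")
    if config.max_epochs == 0:
        return model, []

    x = patches_to_array(patches, model.input_size)
    label_to_idx = {c: i for i, c in enumerate(model.class_order)}
    y = np.array([label_to_idx[l] for l in labels])

    # validation held-out: the configured fraction, but never fewer items
    # than classes (stratification needs one each) nor the whole set
    n_val = int(round(config.validation_fraction * len(x)))
    n_val = min(max(n_val, model.n_classes), len(x) - model.n_classes)
    if n_val < 1:
        raise ValueError("too few patches to hold out a validation split")
    counts = np.bincount(y, minlength=model.n_classes)
    stratify = y if counts[counts > 0].min() >= 2 else None
    x_tr, x_val, y_tr, y_val = train_test_split(
        x,
        y,
        test_size=n_val,
        random_state=config.seed,
        stratify=stratify,
    )
    onehot = np.eye(model.n_classes)[y_tr]

    net = model.network
    opt = Optimizer(net.parameters(), kind=config.optimizer, lr=config.initial_learning_rate)
    sched = PlateauScheduler(
        lr=config.initial_learning_rate,
        factor=config.lr_plateau_factor,
        plateau_patience=config.lr_plateau_patience,
        stop_patience=config.early_stopping_patience,
    )
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best_params: list[np.ndarray] | None = None
    best_acc = -np.inf

    for epoch in range(config.max_epochs):
        lr_this_epoch = sched.lr
        opt.lr = lr_this_epoch
        order = rng.permutation(len(x_tr))
        losses = []
        for i in range(0, len(order), config.mini_batch_size):
            idx = order[i : i + config.mini_batch_size]
            logits = net.forward(x_tr[idx], train=True)
            probs = softmax(logits)
            losses.append(cross_entropy(probs, onehot[idx]))
            net.backward((probs - onehot[idx]) / len(idx))
            opt.step(net.gradients())
        val_pred = net.predict_proba(x_val).argmax(axis=1)
        val_acc = float((val_pred == y_val).mean())
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "val_accuracy": val_acc,
                "learning_rate": lr_this_epoch,
            }
        )
        if val_acc > best_acc:
            best_acc = val_acc
            best_params = [a.copy() for a in net.state_arrays()]
        _, stop = sched.update(val_acc)
        if stop:
            break
    if best_params is not None:
        net.set_state(best_params)
    return model, history


def predict_batch(model: ScaleModel, patches: list[Patch]) -> list[PatchPrediction]:
    """Deterministic inference on a batch of same-scale patches."""
    for p in patches:
        if p.scale != model.scale:
            raise ValueError(f"patch scale {p.scale} does not match model scale {model.scale}")
    if not patches:
        return []
    x = patches_to_array(patches, model.input_size)
    probs = model.network.predict_proba(x)
    out = []
    for row in probs:
        out.append(PatchPrediction(label=model.class_order[int(row.argmax())], probabilities=row))
    return out


def predict_patch(model: ScaleModel, patch: Patch) -> PatchPrediction:
    return predict_batch(model, [patch])[0]


def save_model(model: ScaleModel, directory: str | Path) -> Path:
    """Write weights (npz) plus a JSON sidecar describing the model."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = model.network.state_arrays()
    np.savez(directory / "weights.npz", **{f"p{i}": a for i, a in enumerate(arrays)})
    sidecar = {
        "scale": model.scale,
        "n_classes": model.n_classes,
        "architecture": model.architecture,
        "class_order": list(model.class_order),
        "input_size": model.input_size,
        "seed": model.seed,
    }
    (directory / "model.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_model(directory: str | Path) -> ScaleModel:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    model = build_model(
        scale=sidecar["scale"],
        n_classes=sidecar["n_classes"],
        architecture=sidecar["architecture"],
        seed=sidecar["seed"],
        class_order=tuple(sidecar["class_order"]),
        input_size=sidecar["input_size"],
    )
    with np.load(directory / "weights.npz") as data:
        arrays = [data[f"p{i}"] for i in range(len(data.files))]
    model.network.set_state(arrays)
    return model
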