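"""The four-class CNN soft sensor over topographic-map images.

Architecture: four repeated blocks of convolution -> ReLU -> 2x2 max pool,
then flatten, one dense layer, dropout (rate 0.2), and a four-way softmax
output; trained with Adam on categorical cross-entropy.  Data is split at
the *subject-pair* level (default 10/2/2 pairs for train/validation/test),
so all images of a pair stay in one split and the network cannot pass the
test by recognising individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import CATEGORIES
from .nn import (Adam, Conv2D, Dense, Dropout, Flatten, MaxPool2D, ReLU,
                 Sequential, softmax, softmax_cross_entropy)
from .recording import Dataset


class LeakageError(RuntimeError):
    """Raised when images from a test pair reach a training stream."""


class SplitError(ValueError):
    """Raised for inconsistent split plans."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Hyperparameters of the soft sensor.

    The block structure, dropout rate, optimiser and output layer are fixed
    by the design; filter counts, kernel and pool sizes, dense width,
    learning rate, batch size and epoch budget are tunable.
    """

    input_size: int = 360
    channels: int = 3
    n_classes: int = 4
    conv_filters: tuple[int, int, int, int] = (16, 32, 64, 128)
    kernel: int = 3
    pool: int = 2
    dense_width: int = 128
    dropout: float = 0.2
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 30
    patience: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if len(self.conv_filters) != 4:
            raise ValueError("the architecture uses exactly four conv blocks")
        if self.n_classes != len(CATEGORIES):
            raise ValueError(f"output width must equal {len(CATEGORIES)} categories")
        if self.feature_size < 1:
            raise ValueError(
                f"input size {self.input_size} collapses to nothing after "
                f"four {self.pool}x{self.pool} pooling stages"
            )

    @property
    def feature_size(self) -> int:
        """Spatial edge length after the four pooling stages."""
        s = self.input_size
        for _ in range(4):
            s //= self.pool
        return s

    @property
    def flat_dim(self) -> int:
        return self.feature_size ** 2 * self.conv_filters[-1]

    @classmethod
    def desk_scale(cls) -> "ClassifierSpec":
        """Reduced configuration for single-CPU runs: 90 px images, halved
        filter counts, and a short epoch budget with early stopping."""
        return cls(input_size=90, conv_filters=(8, 16, 32, 64), dense_width=64,
                   batch_size=64, epochs=10, patience=3)


def build_classifier(spec: ClassifierSpec, seed: int = 0) -> Sequential:
    """Untrained network per the spec; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    layers = []
    in_ch = spec.channels
    for out_ch in spec.conv_filters:
        layers += [Conv2D(in_ch, out_ch, spec.kernel, rng), ReLU(), MaxPool2D(spec.pool)]
        in_ch = out_ch
    layers += [
        Flatten(),
        Dense(spec.flat_dim, spec.dense_width, rng),
        ReLU(),
        Dropout(spec.dropout, rng),
        Dense(spec.dense_width, spec.n_classes, rng),
    ]
    return Sequential(layers)


def predict_proba(model: Sequential, images: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    """Class probabilities (softmax of logits) for a stack of images."""
    x = _as_float(images)
    out = []
    for k in range(0, len(x), batch_size):
        out.append(softmax(model.forward(x[k:k + batch_size], train=False)))
    return np.vstack(out)


def _as_float(images: np.ndarray) -> np.ndarray:
    x = np.asarray(images)
    if x.dtype == np.uint8:
        x = x.astype(np.float32) / 255.0
    return x.astype(np.float32, copy=False)


@dataclass(frozen=True)
class SplitPlan:
    """Pair-level train/validation/test partition."""

    assignment: dict[int, str]  # pair_id -> "train" | "validation" | "test"

    def __post_init__(self) -> None:
        bad = set(self.assignment.values()) - {"train", "validation", "test"}
        if bad:
            raise SplitError(f"unknown split labels {sorted(bad)}")

    def pairs(self, split: str) -> list[int]:
        return sorted(p for p, s in self.assignment.items() if s == split)

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(self.pairs(s)) for s in ("train", "validation", "test")}


def plan_split(dataset: Dataset | list[int], n_train: int = 10, n_val: int = 2,
               n_test: int = 2, seed: int = 0) -> SplitPlan:
    """Random pair-level partition, deterministic for a fixed seed."""
    pair_ids = dataset.pair_ids if isinstance(dataset, Dataset) else sorted(dataset)
    if n_train + n_val + n_test != len(pair_ids):
        raise SplitError(
            f"{n_train}+{n_val}+{n_test} != {len(pair_ids)} pairs"
        )
    order = np.random.default_rng(seed).permutation(len(pair_ids))
    assignment = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            split = "train"
        elif rank < n_train + n_val:
            split = "validation"
        else:
            split = "test"
        assignment[pair_ids[idx]] = split
    return SplitPlan(assignment)


@dataclass
class ImageSet:
    """A stack of labelled images with their subject-pair provenance."""

    images: np.ndarray  # (n, h, w, 3) uint8
    labels: np.ndarray  # (n,) int, index into CATEGORIES
    pair_ids: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.labels) == len(self.pair_ids)):
            raise ValueError("images, labels and pair_ids must align")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, mask: np.ndarray) -> "ImageSet":
        return ImageSet(self.images[mask], self.labels[mask], self.pair_ids[mask])

    def for_split(self, plan: SplitPlan, split: str) -> "ImageSet":
        keep = set(plan.pairs(split))
        mask = np.array([p in keep for p in self.pair_ids])
        return self.subset(mask)


def stack_images(topomaps) -> ImageSet:
    """Collect rendered TopomapImage objects into training arrays."""
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    images = np.stack([t.pixels for t in topomaps])
    labels = np.array([cat_index[t.category] for t in topomaps])
    pairs = np.array([t.pair_id for t in topomaps])
    return ImageSet(images, labels, pairs)


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows are true categories, columns predictions."""

    counts: np.ndarray
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        n = len(self.categories)
        if c.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} count matrix")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_predictions(cls, true: np.ndarray, pred: np.ndarray) -> "ConfusionMatrix":
        n = len(CATEGORIES)
        c = np.zeros((n, n), dtype=int)
        np.add.at(c, (np.asarray(true, int), np.asarray(pred, int)), 1)
        return cls(c)


def accuracy(cm: ConfusionMatrix) -> float:
    """Sum of true (diagonal) cases over all cases."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def evaluate(model: Sequential, test: ImageSet, batch_size: int = 64) -> ConfusionMatrix:
    """Argmax predictions of the model tallied against the true labels."""
    if len(test) == 0:
        raise ValueError("test set is empty")
    probs = predict_proba(model, test.images, batch_size)
    return ConfusionMatrix.from_predictions(test.labels, probs.argmax(axis=1))


@dataclass
class TrainingHistory:
    """Per-epoch loss and accuracy on the training and validation streams."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


@dataclass
class SoftSensorResults:
    """Outcome of a fit: best weights are already loaded into ``model``."""

    spec: ClassifierSpec
    model: Sequential
    history: TrainingHistory
    best_epoch: int
    plan: SplitPlan | None = None
    confusion: ConfusionMatrix | None = None

    @property
    def test_accuracy(self) -> float | None:
        return accuracy(self.confusion) if self.confusion is not None else None

    def evaluate(self, test: ImageSet) -> ConfusionMatrix:
        self.confusion = evaluate(self.model, test)
        return self.confusion

    def summary(self) -> str:
        lines = [
            "Soft sensor fit",
            "=" * 46,
            f"input size        : {self.spec.input_size}x{self.spec.input_size}x{self.spec.channels}",
            f"conv filters      : {self.spec.conv_filters}",
            f"parameters        : {self.model.n_parameters():,}",
            f"epochs run        : {len(self.history)} (best: {self.best_epoch + 1})",
            f"final train acc   : {self.history.train_accuracy[-1]:.3f}",
            f"best val loss     : {self.history.val_loss[self.best_epoch]:.4f}",
            f"best val acc      : {self.history.val_accuracy[self.best_epoch]:.3f}",
        ]
        if self.confusion is not None:
            lines.append(f"test accuracy     : {accuracy(self.confusion):.3f}")
            lines.append("confusion matrix (rows true, cols predicted):")
            header = "            " + "  ".join(f"{c:>10s}" for c in self.confusion.categories)
            lines.append(header)
            for cat, row in zip(self.confusion.categories, self.confusion.counts):
                lines.append(f"{cat:>12s}" + "  ".join(f"{v:>10d}" for v in row))
        return "\n".join(lines)


class SoftSensor:
    """Model object wrapping the CNN; ``fit`` returns a results object."""

    def __init__(self, spec: ClassifierSpec | None = None) -> None:
        self.spec = spec or ClassifierSpec()

    def fit(self, images: ImageSet, plan: SplitPlan, seed: int = 0,
            verbose: bool = False) -> SoftSensorResults:
        """Train on the plan's train pairs, early-stopping on validation loss.

        Deterministic for a fixed seed.  The actual training entry point is
        :meth:`fit_streams`, whose leakage guard rejects any training or
        validation stream containing images of a test pair.
        """
        train = images.for_split(plan, "train")
        val = images.for_split(plan, "validation")
        return self.fit_streams(train, val, set(plan.pairs("test")),
                                seed=seed, verbose=verbose, plan=plan)

    def fit_streams(self, train: ImageSet, val: ImageSet, test_pairs: set[int],
                    seed: int = 0, verbose: bool = False,
                    plan: SplitPlan | None = None) -> SoftSensorResults:
        """Train on explicit streams.

        Raises :class:`LeakageError` if any image of a test pair appears in
        the training or validation stream.
        """
        spec = self.spec
        for name, stream in (("training", train), ("validation", val)):
            leaked = sorted(set(stream.pair_ids) & set(test_pairs))
            if leaked:
                raise LeakageError(
                    f"test pair(s) {leaked} found in the {name} stream"
                )
        if len(train) == 0 or len(val) == 0:
            raise SplitError("training and validation sets must be non-empty")
        expected = (spec.input_size, spec.input_size, spec.channels)
        if train.images.shape[1:] != expected:
            raise ValueError(
                f"images have shape {train.images.shape[1:]}, spec expects {expected}"
            )

        model = build_classifier(spec, seed=seed)
        opt = Adam(model.params, lr=spec.learning_rate)
        shuffle_rng = np.random.default_rng(seed + 1)
        history = TrainingHistory()
        best = {"epoch": -1, "loss": np.inf, "weights": model.get_weights()}

        for epoch in range(spec.epochs):
            order = shuffle_rng.permutation(len(train))
            losses, correct = [], 0
            for k in range(0, len(order), spec.batch_size):
                idx = order[k:k + spec.batch_size]
                xb = _as_float(train.images[idx])
                yb = train.labels[idx]
                logits = model.forward(xb, train=True)
                loss, dlogits = softmax_cross_entropy(logits, yb)
                model.backward(dlogits)
                opt.step(model.grads)
                losses.append(loss * len(idx))
                correct += int((logits.argmax(axis=1) == yb).sum())
            history.train_loss.append(sum(losses) / len(train))
            history.train_accuracy.append(correct / len(train))

            vloss, vacc = self._evaluate_stream(model, val, spec.batch_size)
            history.val_loss.append(vloss)
            history.val_accuracy.append(vacc)
            if verbose:
                print(f"epoch {epoch + 1:3d}  loss {history.train_loss[-1]:.4f}  "
                      f"acc {history.train_accuracy[-1]:.3f}  "
                      f"val_loss {vloss:.4f}  val_acc {vacc:.3f}")
            if vloss < best["loss"]:
                best = {"epoch": epoch, "loss": vloss, "weights": model.get_weights()}
            elif epoch - best["epoch"] >= spec.patience:
                break

        model.set_weights(best["weights"])
        return SoftSensorResults(spec, model, history, best["epoch"], plan)

    @staticmethod
    def _evaluate_stream(model: Sequential, data: ImageSet,
                         batch_size: int) -> tuple[float, float]:
        losses, correct = [], 0
        for k in range(0, len(data), batch_size):
            xb = _as_float(data.images[k:k + batch_size])
            yb = data.labels[k:k + batch_size]
            logits = model.forward(xb, train=False)
            loss, _ = softmax_cross_entropy(logits, yb)
            losses.append(loss * len(yb))
            correct += int((logits.argmax(axis=1) == yb).sum())
        return sum(losses) / len(data), correct / len(data)


def train(images: ImageSet, plan: SplitPlan, spec: ClassifierSpec | None = None,
          seed: int = 0, verbose: bool = False) -> SoftSensorResults:
    """Functional wrapper: build and fit a soft sensor in one call."""
    return SoftSensor(spec).fit(images, plan, seed=seed, verbose=verbose)


def shuffle_labels(images: ImageSet, seed: int = 0) -> ImageSet:
    """Permuted-label copy of an image set (negative-control training)."""
    rng = np.random.default_rng(seed)
    return ImageSet(images.images, rng.permutation(images.labels), images.pair_ids)
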