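"""Candidate evaluation: instantiate -> train -> score, and the metrics.

Fitness of a candidate architecture is its validation accuracy after brief
training.  Final models are additionally scored with macro one-vs-rest ROC
AUC and Cohen's kappa (unweighted by default; the quadratic-weighted
variant used by the APTOS competition is available), and their trainable
parameter count is reported.

Metric conventions
------------------
* accuracy = trace(confusion) / total;
* per-class AUC is the Mann–Whitney rank statistic (ties count 0.5),
  macro-averaged over classes that have both positives and negatives;
* kappa = (po - pe) / (1 - pe) with pe from the confusion-matrix marginals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .arch import Architecture, ConstraintSet, LayerKind, validate_architecture

__all__ = [
    "TrainerSpec",
    "EvalResult",
    "instantiate_network",
    "count_parameters",
    "train_and_score",
    "accuracy_from_confusion",
    "auc_ovr",
    "cohen_kappa",
    "confusion_matrix",
    "stratified_kfold",
    "TrainingEvaluator",
    "SurrogateEvaluator",
    "cross_validate",
]


@dataclass(frozen=True)
class TrainerSpec:
    """Training settings for one candidate evaluation."""

    epochs: int = 1
    batch_size: int = 16
    image_size: int = 32  # pixels, square
    optimizer: str = "adam"
    learning_rate: float = 3e-3
    rng_seed: int = 0
    patience: int = 0  # 0 disables early stopping

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.patience < 0:
            raise ValueError("epochs and patience must be >= 0")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")


@dataclass(frozen=True)
class EvalResult:
    accuracy: float
    auc: float
    kappa: float
    kappa_quadratic: float
    parameter_count: int
    per_class_auc: tuple[float, ...]


class InstantiationError(ValueError):
    """Architecture cannot be realized at the given input shape."""


def _walk(arch: Architecture, input_shape, rng=None, with_weights=False):
    """Walk layer shapes; optionally build backend layers along the way."""
    shape = tuple(input_shape)
    layers = []
    for idx, spec in enumerate(arch.layers):
        kw = dict(spec.params)
        try:
            if with_weights:
                layer, shape = nn.build_layer(rng, spec.kind.value, shape, **kw)
                layers.append(layer)
            else:
                layer, shape = _dry_layer(spec.kind.value, shape, **kw)
                layers.append(layer)
        except nn.ShapeError as e:
            raise InstantiationError(f"layer {idx} ({spec.kind.value}): {e}") from e
    return layers, shape


def _dry_layer(kind: str, in_shape, **kw):
    """Shape walk + exact trainable-parameter count, no weight allocation."""
    spatial = len(in_shape) == 3
    if kind == "C2D":
        if not spatial:
            raise nn.ShapeError("convolution requires a spatial input")
        h, w, c = in_shape
        k, f = kw["kernel_size"], kw["filter_count"]
        return k * k * c * f + f, (h, w, f)
    if kind in ("MP", "AP"):
        if not spatial:
            raise nn.ShapeError("pooling requires a spatial input")
        h, w, c = in_shape
        p = kw["pool_size"]
        if h // p < 1 or w // p < 1:
            raise nn.ShapeError(f"pooling size {p} underflows {h}x{w} input")
        return 0, (h // p, w // p, c)
    if kind == "BN":
        return 2 * in_shape[-1], in_shape  # gamma + beta per channel
    if kind == "DO":
        return 0, in_shape
    if kind == "F":
        if spatial:
            h, w, c = in_shape
            return 0, (h * w * c,)
        return 0, in_shape
    if kind == "DE":
        if spatial:
            raise nn.ShapeError("dense layer requires a flattened input")
        u = kw["unit_count"]
        return in_shape[0] * u + u, (u,)
    raise ValueError(kind)


def count_parameters(arch: Architecture, input_shape=None) -> int:
    """Exact trainable-parameter count of the listed layers.

    Conventions: same-padding stride-1 convolution (k*k*c_in*f + f), batch
    norm contributes 2 trainable terms per channel, pooling/flatten/dropout
    contribute none.
    """
    counts, _ = _walk(arch, input_shape or arch.input_shape)
    return int(sum(counts))


def instantiate_network(
    arch: Architecture,
    input_shape=None,
    n_classes: int = 5,
    seed: int = 0,
    rules: ConstraintSet = ConstraintSet(),
) -> nn.Network:
    """Build a trainable network: the architecture's layers in order plus a
    softmax classification head (a dense layer of ``n_classes`` units).

    Weight initialization is deterministic given ``seed``.  Raises
    :class:`InstantiationError` naming the offending layer on shape
    underflow or a dense/conv layer applied to an incompatible input.
    """
    violations = validate_architecture(arch, rules)
    if violations:
        raise InstantiationError(
            f"architecture violates structural rules: {[str(v) for v in violations]}"
        )
    rng = np.random.default_rng(seed)
    layers, shape = _walk(arch, input_shape or arch.input_shape, rng, with_weights=True)
    if len(shape) != 1:  # no flatten in arch tail (cannot happen post-repair)
        layers.append(nn.Flatten())
        shape = (int(np.prod(shape)),)
    head, _ = nn.build_layer(rng, "DE", shape, unit_count=n_classes, relu=False)
    layers.append(head)
    return nn.Network(layers, n_classes, seed=seed)


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    k = n_classes or int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy_from_confusion(cm: np.ndarray) -> float:
    cm = np.asarray(cm)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / total)


def auc_ovr(scores: np.ndarray, labels: np.ndarray) -> tuple[float, list[float]]:
    """Macro one-vs-rest ROC AUC via the rank (Mann–Whitney) statistic.

    ``scores`` is (n_samples, n_classes); ties count 0.5.  A class with no
    positives or no negatives is skipped with a warning and excluded from
    the macro average.  Returns ``(macro_auc, per_class_aucs)`` where a
    skipped class reports ``nan``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    per_class: list[float] = []
    used: list[float] = []
    for k in range(scores.shape[1]):
        pos = labels == k
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {k} has no positives or no negatives; skipped")
            per_class.append(float("nan"))
            continue
        ranks = rankdata(scores[:, k])  # average ranks handle ties as 0.5
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        per_class.append(float(auc))
        used.append(float(auc))
    if not used:
        raise ValueError("no class has both positives and negatives")
    return float(np.mean(used)), per_class


def cohen_kappa(cm: np.ndarray, weighting: str = "none") -> float:
    """Chance-corrected agreement (po - pe) / (1 - pe) from a confusion matrix.

    ``weighting="quadratic"`` applies standard quadratic disagreement
    weights (the APTOS competition metric).
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    expected = np.outer(row, col) / total
    k = cm.shape[0]
    if weighting == "none":
        w = 1.0 - np.eye(k)
    elif weighting == "quadratic":
        i, j = np.mgrid[0:k, 0:k]
        w = ((i - j) ** 2) / ((k - 1) ** 2) if k > 1 else np.zeros((1, 1))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    disagreement_e = float((w * expected).sum())
    if disagreement_e == 0:
        raise ValueError("degenerate marginals: chance agreement is 1")
    return float(1.0 - (w * cm).sum() / disagreement_e)


def stratified_kfold(labels, k: int, rng_seed: int = 0) -> list[np.ndarray]:
    """Class-stratified k-fold index lists (per-fold class counts differ <= 1).

    Raises if any class has fewer than ``k`` members, naming the class.
    """
    labels = np.asarray(labels)
    if k == 1:
        return [np.arange(len(labels))]
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < k:
            raise ValueError(f"class {cls} has {cnt} < k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


# ---------------------------------------------------------------------------
# train-and-score


def train_and_score(
    network: nn.Network,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    spec: TrainerSpec,
) -> tuple[EvalResult, float]:
    """Train a network and score it on the validation split.

    Returns ``(EvalResult, fitness)`` with fitness = validation accuracy.
    Training divergence (non-finite loss) yields fitness 0 with a warning.

    Inputs are standardized per channel with training-split statistics
    before training; validation data uses the same transform.
    """
    if len(np.unique(y_train)) < 2 or len(np.unique(y_val)) < 2:
        raise ValueError("both splits need at least 2 classes")
    axes = tuple(range(x_train.ndim - 1))
    mu = x_train.mean(axis=axes, dtype=np.float64).astype(np.float32)
    sd = np.maximum(x_train.std(axis=axes).astype(np.float32), 1e-6)
    x_train = (x_train - mu) / sd
    x_val = (x_val - mu) / sd
    hist = network.fit(
        x_train,
        y_train,
        x_val,
        y_val,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        lr=spec.learning_rate,
        patience=spec.patience,
    )
    if hist.diverged:
        warnings.warn("candidate diverged; fitness set to 0")
        nan = float("nan")
        result = EvalResult(0.0, nan, nan, nan, network.n_params(), ())
        return result, 0.0
    probs = network.predict_proba(x_val)
    preds = probs.argmax(axis=1)
    cm = confusion_matrix(y_val, preds, n_classes=network.n_classes)
    acc = accuracy_from_confusion(cm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        macro_auc, per_class = auc_ovr(probs, y_val)
    result = EvalResult(
        accuracy=acc,
        auc=macro_auc,
        kappa=cohen_kappa(cm, "none"),
        kappa_quadratic=cohen_kappa(cm, "quadratic"),
        parameter_count=network.n_params(),
        per_class_auc=tuple(per_class),
    )
    return result, acc


# ---------------------------------------------------------------------------
# fitness evaluators (the contract both searches consume)


class TrainingEvaluator:
    """Fitness = validation accuracy after ``spec.epochs`` of training.

    Holds a fixed stratified 80/20 train/validation split of the provided
    data so every candidate is scored on the same samples.  Counts calls.
    """

    def __init__(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        spec: TrainerSpec,
        n_classes: int | None = None,
        val_fraction: float = 0.2,
    ):
        idx_tr, idx_val = train_test_split(
            np.arange(len(labels)),
            test_size=val_fraction,
            stratify=labels,
            random_state=spec.rng_seed,
        )
        self.x_train, self.y_train = images[idx_tr], labels[idx_tr]
        self.x_val, self.y_val = images[idx_val], labels[idx_val]
        self.spec = spec
        self.n_classes = n_classes or int(labels.max()) + 1
        self.n_calls = 0
        self.input_shape = images.shape[1:]

    def __call__(self, arch: Architecture) -> float:
        self.n_calls += 1
        net = instantiate_network(
            arch, self.input_shape, self.n_classes, seed=self.spec.rng_seed
        )
        _, fitness = train_and_score(
            net, self.x_train, self.y_train, self.x_val, self.y_val, self.spec
        )
        return fitness

    def score(self, arch: Architecture, epochs: int, seed: int | None = None):
        """Full retrain + metric report (used for the final best model)."""
        spec = TrainerSpec(
            epochs=epochs,
            batch_size=self.spec.batch_size,
            image_size=self.spec.image_size,
            learning_rate=self.spec.learning_rate,
            rng_seed=self.spec.rng_seed if seed is None else seed,
            patience=self.spec.patience,
        )
        net = instantiate_network(
            arch, self.input_shape, self.n_classes, seed=spec.rng_seed
        )
        result, fitness = train_and_score(
            net, self.x_train, self.y_train, self.x_val, self.y_val, spec
        )
        return result, fitness


class SurrogateEvaluator:
    """Deterministic architecture-only fitness for search-mechanics tests.

    Scores in (0, 1) favour a moderate number of convolutions, the presence
    of pooling, and penalize very long architectures; a small seeded
    hash-based jitter makes distinct architectures distinguishable while
    keeping the map pure (same architecture -> same fitness).  No training
    is involved, so searches driven by it are fast and exactly repeatable.
    """

    def __init__(self, seed: int = 0, noise: float = 0.05):
        self.seed = seed
        self.noise = noise
        self.n_calls = 0

    def __call__(self, arch: Architecture) -> float:
        self.n_calls += 1
        kinds = arch.kinds
        n_conv = sum(1 for k in kinds if k is LayerKind.C2D)
        n_pool = sum(1 for k in kinds if k in (LayerKind.MP, LayerKind.AP))
        base = 0.4 + 0.1 * min(n_conv, 3) + 0.1 * min(n_pool, 1) - 0.01 * len(kinds)
        h = hash((self.seed,) + tuple((l.kind.value,) + l.params for l in arch.layers))
        jitter = (h % 10_000) / 10_000 * self.noise
        return float(min(max(base + jitter, 0.0), 1.0))


def cross_validate(
    arch: Architecture,
    images: np.ndarray,
    labels: np.ndarray,
    folds: int,
    spec: TrainerSpec,
) -> list[EvalResult]:
    """Stratified k-fold evaluation of one architecture.

    With ``folds=1`` a single stratified 80/20 split is scored instead.
    """
    n_classes = int(labels.max()) + 1
    if folds == 1:
        ev = TrainingEvaluator(images, labels, spec, n_classes)
        res, _ = ev.score(arch, epochs=spec.epochs)
        return [res]
    fold_idx = stratified_kfold(labels, folds, rng_seed=spec.rng_seed)
    results = []
    for i, test_idx in enumerate(fold_idx):
        mask = np.zeros(len(labels), dtype=bool)
        mask[test_idx] = True
        net = instantiate_network(
            arch, images.shape[1:], n_classes, seed=spec.rng_seed + i
        )
        res, _ = train_and_score(
            net, images[~mask], labels[~mask], images[mask], labels[mask], spec
        )
        results.append(res)
    return results
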