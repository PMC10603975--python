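"""Training, leave-one-out protocol, and the neural segmenter estimator.

The experiment protocol mirrors small-dataset segmentation practice: with
``n`` originals and a set of augmentation strategies, each (strategy,
held-out original) pair is one *launch* — the model trains on the other
``n - 1`` originals plus an augmentation group regenerated without the
held-out image, and is tested on the single held-out image.  With 40
originals and 11 strategies this yields the canonical 440 launches per
architecture, each training on 39 + 40 = 79 items.

:class:`NeuralSegmenter` wraps the numpy backend as a scikit-learn style
estimator (``fit`` / ``predict`` / ``score``), so the architectures compose
with sklearn model selection; :func:`train` and :func:`predict_mask` remain
as thin functional wrappers.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from .architectures import ModelSpec, PRESETS, build_variant
from .augment import AugmentedSample, build_group
from .imaging import BinaryMask, GrayscaleImage
from .metrics import ConfusionCounts, MetricSet, confusion, metrics
from .nn import Adam, Network, bce_with_logits, softmax_ce_with_logits

__all__ = [
    "TrainingConfig",
    "PlateauStopper",
    "TrainedModel",
    "NeuralSegmenter",
    "LooLaunch",
    "LooPlan",
    "FoldResult",
    "make_loo_plan",
    "train",
    "predict_mask",
    "run_loo",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer/loss settings: Adam + binary cross-entropy (two-class
    cross-entropy for softmax heads), with early stopping once the training
    loss plateaus ("train until just before the loss flattens")."""

    learning_rate: float = 1e-3
    batch_size: int = 4
    max_epochs: int = 200
    patience: int = 10
    min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class PlateauStopper:
    """Stop when the loss has not improved by more than ``min_delta`` over
    the best value for ``patience`` consecutive epochs."""

    def __init__(self, patience: int = 10, min_delta: float = 1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.stale = 0

    def update(self, loss: float) -> bool:
        """Record one epoch's loss; True means training should stop now."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


@dataclass
class TrainedModel:
    """A trained network plus the spec it realizes."""

    spec: ModelSpec
    network: Network
    loss_history: list[float]
    stopped_early: bool


def _as_arrays(train_set, side: int) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for item in train_set:
        if isinstance(item, tuple):
            img, mask = item
        else:
            img, mask = item.image, item.mask
        px = img.pixels if isinstance(img, GrayscaleImage) else np.asarray(img)
        lab = mask.labels if isinstance(mask, BinaryMask) else np.asarray(mask)
        if px.shape != (side, side) or lab.shape != (side, side):
            raise ValueError(
                f"training pair shape {px.shape}/{lab.shape} does not match spec side {side}"
            )
        xs.append(px)
        ys.append(lab)
    return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32)


def train(spec: ModelSpec, train_set, config: TrainingConfig | None = None) -> TrainedModel:
    """Fit a spec on aligned image/mask pairs with Adam + cross-entropy.

    Stops at the training-loss plateau (see :class:`PlateauStopper`) or at
    ``max_epochs``.  Deterministic under ``config.seed``.
    """
    config = config or TrainingConfig()
    if not train_set:
        raise ValueError("training set is empty")
    X, Y = _as_arrays(train_set, spec.side)
    rng = np.random.default_rng(config.seed)
    net = Network(spec, rng)
    opt = Adam(net.params, lr=config.learning_rate)
    stopper = PlateauStopper(config.patience, config.min_delta)
    softmax = spec.layers[-1].activation == "softmax"
    history: list[float] = []
    stopped = False
    n = X.shape[0]
    for _ in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx][..., None]
            z = net.forward(xb, training=True, rng=rng)
            if softmax:
                onehot = np.concatenate([1.0 - yb, yb], axis=-1)
                loss, gz = softmax_ce_with_logits(z, onehot)
            else:
                loss, gz = bce_with_logits(z, yb)
            if not np.isfinite(loss):
                raise RuntimeError("training diverged: non-finite loss")
            grads = net.backward(gz)
            if config.learning_rate > 0:
                opt.step(net.params, grads)
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / n)
        if stopper.update(history[-1]):
            stopped = True
            break
    return TrainedModel(spec=spec, network=net, loss_history=history, stopped_early=stopped)


def predict_mask(
    model: TrainedModel | Network, img: GrayscaleImage | np.ndarray, threshold: float = 0.5
) -> BinaryMask:
    """Binarize the model's probability map into a mask.

    Sigmoid heads threshold the foreground probability at ``threshold``;
    two-channel softmax heads take the foreground channel (equivalent to
    the channel argmax at threshold 0.5).
    """
    net = model.network if isinstance(model, TrainedModel) else model
    px = img.pixels if isinstance(img, GrayscaleImage) else np.asarray(img)
    if px.shape != (net.spec.side, net.spec.side):
        raise ValueError(f"image shape {px.shape} does not match model side {net.spec.side}")
    p = net.predict_proba(px[None, ...])[0]
    return BinaryMask(labels=(p >= threshold).astype(np.uint8))


class NeuralSegmenter(BaseEstimator):
    """Scikit-learn style wrapper around the encoder-decoder segmenters.

    Parameters
    ----------
    arch : str or AblationConfig, default "munet"
        A named preset ("unet", "munet", "unet-mini", or any ablation
        label such as "layer+filter") or an explicit config.
    side : int, default 64
        Input/output frame size.  64 is the desk-scale default; 250 is the
        full acquisition scale.
    learning_rate, batch_size, max_epochs, patience, min_delta :
        Training hyperparameters, see :class:`TrainingConfig`.
    threshold : float, default 0.5
        Binarization threshold on the foreground probability.
    random_state : int, default 0

    Attributes
    ----------
    spec_ : ModelSpec
    network_ : Network
    loss_history_ : list of float
    n_epochs_ : int
    """

    def __init__(self, arch="munet", side=64, learning_rate=1e-3, batch_size=4,
                 max_epochs=200, patience=10, min_delta=1e-4, threshold=0.5,
                 random_state=0):
        self.arch = arch
        self.side = side
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.min_delta = min_delta
        self.threshold = threshold
        self.random_state = random_state

    def _spec(self) -> ModelSpec:
        if isinstance(self.arch, str):
            if self.arch not in PRESETS:
                raise ValueError(f"unknown preset {self.arch!r}; known: {sorted(PRESETS)}")
            return build_variant(PRESETS[self.arch], self.side)
        return build_variant(self.arch, self.side)

    def fit(self, X, y):
        """Fit on images X (n, side, side) and binary masks y."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 3 or y.shape != X.shape:
            raise ValueError("X and y must both have shape (n_samples, side, side)")
        cfg = TrainingConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience,
            min_delta=self.min_delta, seed=self.random_state,
        )
        self.spec_ = self._spec()
        pairs = [(X[i], y[i]) for i in range(X.shape[0])]
        model = train(self.spec_, pairs, cfg)
        self.network_ = model.network
        self.loss_history_ = model.loss_history
        self.n_epochs_ = len(model.loss_history)
        self.stopped_early_ = model.stopped_early
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=np.float64)
        return self.network_.predict_proba(X)

    def predict(self, X):
        """Binary masks, shape (n, side, side), dtype uint8."""
        return (self.predict_proba(X) >= self.threshold).astype(np.uint8)

    def score(self, X, y):
        """Mean Dice over the samples."""
        pred = self.predict(X)
        y = np.asarray(y)
        dices = []
        for i in range(pred.shape[0]):
            m = metrics(confusion(BinaryMask(pred[i]), BinaryMask(y[i])))
            dices.append(m.dice)
        return float(np.nanmean(dices))


def save_model(model: TrainedModel, path: str | os.PathLike) -> None:
    """Persist a trained model as .npz (parameters + running stats + spec)."""
    arrays = {f"param/{k}": v for k, v in model.network.params.items()}
    arrays.update({f"state/{k}": v for k, v in model.network.state.items()})
    np.savez(
        path,
        spec_json=np.array(model.spec.to_json()),
        loss_history=np.array(model.loss_history),
        **arrays,
    )


def load_model(path: str | os.PathLike) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        spec = ModelSpec.from_json(str(data["spec_json"]))
        net = Network(spec, np.random.default_rng(0))
        for key in data.files:
            if key.startswith("param/"):
                net.params[key[len("param/"):]] = data[key]
            elif key.startswith("state/"):
                net.state[key[len("state/"):]] = data[key]
        history = [float(v) for v in data["loss_history"]]
    return TrainedModel(spec=spec, network=net, loss_history=history, stopped_early=False)


# ---------------------------------------------------------------------------
# leave-one-out protocol

@dataclass(frozen=True)
class LooLaunch:
    """One (architecture, strategy, held-out original) training launch."""

    architecture: str
    strategy: str
    held_out_id: str
    training_source_ids: tuple[str, ...]  # originals the fold may draw from
    group_size: int
    seed: int

    def manifest_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class LooPlan:
    launches: tuple[LooLaunch, ...]

    def __len__(self) -> int:
        return len(self.launches)


def make_loo_plan(
    n_originals: int,
    strategies: list[str],
    architecture: str = "munet",
    group_size: int = 40,
    seed: int = 0,
) -> LooPlan:
    """Enumerate every (strategy, held-out image) launch.

    ``len(plan) == n_originals * len(strategies)``; each launch trains on
    ``n_originals - 1`` originals plus ``group_size`` augmented items
    generated without the held-out image.
    """
    if n_originals < 2:
        raise ValueError("need at least 2 originals for leave-one-out")
    if not strategies:
        raise ValueError("need at least one augmentation strategy")
    ids = [f"{i:03d}" for i in range(n_originals)]
    launches = []
    for strat in strategies:
        for held in ids:
            launches.append(
                LooLaunch(
                    architecture=architecture,
                    strategy=strat,
                    held_out_id=held,
                    training_source_ids=tuple(i for i in ids if i != held),
                    group_size=group_size,
                    seed=seed,
                )
            )
    return LooPlan(launches=tuple(launches))


@dataclass
class FoldResult:
    """Per-launch outcome: held-out id, its prediction, counts, metrics."""

    launch: LooLaunch
    predicted: BinaryMask
    counts: ConfusionCounts
    scores: MetricSet
    manifest: tuple[tuple[str, str], ...]  # (item id, source original id)
    n_train: int


def _fold_train_set(originals, launch: LooLaunch):
    kept = [s for s in originals if s.id != launch.held_out_id]
    group = build_group(
        originals,
        launch.strategy,
        size=launch.group_size,
        exclude_id=launch.held_out_id,
        seed=launch.seed,
    )
    manifest = tuple(
        [(s.id, s.id) for s in kept] + [(a.id, a.source_id) for a in group]
    )
    return kept + group, manifest


def run_loo(
    plan: LooPlan,
    specs: dict[str, ModelSpec],
    config: TrainingConfig,
    originals,
    out_dir: str | os.PathLike | None = None,
) -> list[FoldResult]:
    """Execute a leave-one-out plan end to end.

    ``specs`` maps architecture ids to shape-checked ModelSpecs; the
    originals are the phantom (or real) samples the plan's ids refer to.
    With ``out_dir`` set, completed launches are skipped on re-run (keyed
    by manifest hash) and per-fold metrics are dumped as JSON.
    """
    by_id = {s.id: s for s in originals}
    results: list[FoldResult] = []
    for launch in plan.launches:
        if launch.architecture not in specs:
            raise KeyError(f"no ModelSpec for architecture {launch.architecture!r}")
        if launch.held_out_id not in by_id:
            raise KeyError(
                f"launch ({launch.architecture}, {launch.strategy}, {launch.held_out_id}): "
                "held-out id missing from data store"
            )
        done_path = None
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            done_path = os.path.join(out_dir, f"fold-{launch.manifest_hash()}.json")
        spec = specs[launch.architecture]
        train_set, manifest = _fold_train_set(originals, launch)
        assert all(src != launch.held_out_id for _, src in manifest), "leakage"
        if done_path is not None and os.path.exists(done_path):
            continue  # resumable: this fold is already on disk
        model = train(spec, train_set, config)
        held = by_id[launch.held_out_id]
        pred = predict_mask(model, held.image)
        counts = confusion(pred, held.mask)
        scores = metrics(counts)
        result = FoldResult(
            launch=launch, predicted=pred, counts=counts, scores=scores,
            manifest=manifest, n_train=len(train_set),
        )
        results.append(result)
        if done_path is not None:
            with open(done_path, "w") as fh:
                json.dump(
                    {
                        "launch": asdict(launch),
                        "counts": asdict(counts),
                        "metrics": scores.to_dict(),
                        "loss_history": model.loss_history,
                    },
                    fh,
                )
    return results
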