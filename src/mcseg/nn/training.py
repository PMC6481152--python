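"""Training loop: Adam on balanced minibatches, plateau-halved learning
rate, early stopping on validation loss.

The optimizer starts at learning rate 1e-3 and halves it whenever the
validation loss has not improved for ``plateau_patience`` consecutive
evaluations (the plateau rule); after ``early_stop_patience`` consecutive
non-improving evaluations training stops and the weights at the best
validation loss seen so far are restored.  All randomness (minibatch
draws, augmentations, dropout masks) derives from the schedule seed, so a
run is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..patches import Minibatch, PatchDatabase, Role, role_positive_classes, sample_minibatch
from .network import Network, NetworkConfig, TrainedModel, build_network, make_adam, softmax_posterior, CROSSENTROPY_EPS


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass(frozen=True)
class TrainSchedule:
    """Optimization hyperparameters (Adam throughout)."""

    initial_lr: float = 1e-3
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    batch_size: int = 256
    max_steps: int = 400
    early_stop_patience: int = 12
    eval_every: int = 20
    #: minimum decrease of validation loss that counts as an improvement
    min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.initial_lr, self.plateau_patience, self.batch_size, self.max_steps,
               self.early_stop_patience, self.eval_every) <= 0:
            raise ValueError("schedule values must be positive")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.batch_size % 2:
            raise ValueError("batch_size must be even (balanced halves)")


def evaluate_loss(network: Network, x: np.ndarray, y: np.ndarray, batch_size: int = 512) -> tuple[float, float]:
    """Mean cross-entropy and accuracy of a fixed set, inference mode."""
    probs = network.predict_proba(x, batch_size)
    loss = float(-(y * np.log(np.clip(probs, CROSSENTROPY_EPS, None))).sum() / len(y))
    acc = float((probs.argmax(axis=1) == np.asarray(y).argmax(axis=1)).mean())
    return loss, acc


def make_eval_set(
    db: PatchDatabase,
    role: Role,
    size: int,
    rng: np.random.Generator,
    split: str = "val",
    balance: str = "label",
) -> Minibatch:
    """A fixed label- or class-balanced patch set for validation/testing.

    ``balance='label'`` draws size/2 positives and size/2 negatives;
    ``balance='class'`` draws size/4 from each of C1..C4 (classes missing
    from the split are skipped).  No augmentation is applied.
    """
    pos = role_positive_classes(role)
    if balance == "label":
        groups = [frozenset(pos), frozenset({"C1", "C2", "C3", "C4"}) - pos]
    elif balance == "class":
        groups = [frozenset({k}) for k in ("C1", "C2", "C3", "C4")]
    else:
        raise ValueError("balance must be 'label' or 'class'")
    per = max(1, size // len(groups))
    picks: list[tuple[str, int, int, str]] = []
    for g in groups:
        pool = db._pool(split, g)
        if not pool:
            continue
        idx = rng.choice(len(pool), size=per, replace=len(pool) < per)
        picks.extend(pool[i] for i in idx)
    if not picks:
        raise ValueError(f"split {split!r} holds no records for role {role!r}")
    n = db.patch_side
    x = np.empty((len(picks), 1, n, n), dtype=np.float32)
    y = np.zeros((len(picks), 2), dtype=np.float32)
    classes = []
    for i, (image_id, row, col, klass) in enumerate(picks):
        x[i, 0] = db.patch_pixels(image_id, row, col)
        y[i, int(klass in pos)] = 1.0
        classes.append(klass)
    return Minibatch(pixels=x, labels=y, patch_classes=classes)


def train(
    model: Network | NetworkConfig,
    db: PatchDatabase,
    role: Role,
    schedule: TrainSchedule,
    val_set: Minibatch,
    split: str = "train",
) -> TrainedModel:
    """Train a patch classifier on balanced minibatches from the database.

    Returns the model with the weights that achieved the best validation
    loss before the early-stopping trigger, together with a step-indexed
    history (training loss/accuracy, validation evaluations, learning-rate
    halving events).
    """
    if isinstance(model, NetworkConfig):
        network = build_network(model, seed=schedule.seed)
    else:
        network = model
    if len(val_set) == 0:
        raise ValueError("validation set is empty")

    rng = np.random.default_rng(schedule.seed)
    adam = make_adam(network, schedule.initial_lr)
    history: dict[str, list] = {
        "step": [], "train_loss": [], "train_acc": [],
        "val_step": [], "val_loss": [], "val_acc": [],
        "lr_events": [],  # (step, new_lr)
    }
    best_loss = np.inf
    best_state = network.state_dict()
    best_step = 0
    bad_evals = 0
    stop_step = schedule.max_steps

    for step in range(1, schedule.max_steps + 1):
        batch = sample_minibatch(db, role, schedule.batch_size, rng, split)
        try:
            loss, acc = network.loss_and_grad(batch.pixels, batch.labels, rng)
        except ValueError as err:  # non-finite scores inside the softmax
            raise DivergenceError(f"diverged at step {step}: {err}") from err
        if not np.isfinite(loss):
            raise DivergenceError(f"non-finite training loss at step {step}")
        adam.step(network.gradients())
        history["step"].append(step)
        history["train_loss"].append(loss)
        history["train_acc"].append(acc)

        if step % schedule.eval_every == 0:
            val_loss, val_acc = evaluate_loss(network, val_set.pixels, val_set.labels)
            history["val_step"].append(step)
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
            if val_loss < best_loss - schedule.min_delta:
                best_loss = val_loss
                best_state = network.state_dict()
                best_step = step
                bad_evals = 0
            else:
                bad_evals += 1
                if bad_evals % schedule.plateau_patience == 0:
                    adam.lr *= schedule.plateau_factor
                    history["lr_events"].append((step, adam.lr))
                if bad_evals >= schedule.early_stop_patience:
                    stop_step = step
                    break

    network.load_state_dict(best_state)
    return TrainedModel(
        config=network.config,
        network=network,
        history=history,
        stopping_step=best_step if best_step else stop_step,
        role=role,
    )
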