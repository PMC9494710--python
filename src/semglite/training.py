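"""End-to-end training of the CNN/LSTM hybrids.

The CNN and LSTM blocks are trained jointly by default with Adam under a
step learning-rate schedule (0.01, cut to 20% every 20 epochs).  A
two-phase mode is available for fidelity experiments: an SGDM warm-up of
the whole stack followed by Adam fine-tuning.  Training stops early once
the train loss falls to its target and the validation loss to its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .dataset import GestureDataset
from .model import ArchitectureSpec, build_network

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings.

    ``lr_decay_factor`` is the multiplier applied after every
    ``lr_decay_every_epochs`` epochs — 0.2 corresponds to a reduction *by*
    80%.  ``batch_size`` defaults to 32 (128 is the setting used for the
    pure-CNN variant).  ``val_checks_per_epoch`` may be raised to 2 to
    validate twice per epoch.
    """

    optimizer: str = "ADAM"  # ADAM | SGDM
    lr_init: float = 0.01
    lr_decay_factor: float = 0.2
    lr_decay_every_epochs: int = 20
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    early_stop_train_loss: float = 0.01
    early_stop_val_loss: float = 0.1
    two_phase: bool = False
    warmup_epochs: int = 20
    val_checks_per_epoch: int = 1

    def __post_init__(self) -> None:
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must be in (0, 1]")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.optimizer not in ("ADAM", "SGDM"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch index."""
        return self.lr_init * self.lr_decay_factor ** (epoch // self.lr_decay_every_epochs)


@dataclass
class TrainedModel:
    """A trained network together with its declarative architecture."""

    spec: ArchitectureSpec
    network: nn.Network

    def save(self, path) -> int:
        """Serialize to an uncompressed .npz (+ architecture JSON inside);
        returns the artifact size in bytes."""
        path = Path(path)
        state = self.network.state_dict()
        state["__arch__"] = np.frombuffer(self.spec.to_json().encode(), dtype=np.uint8)
        np.savez(path, **state)
        actual = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
        return actual.stat().st_size

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as data:
            spec = ArchitectureSpec.from_json(bytes(data["__arch__"]).decode())
            net = build_network(spec, seed=0)
            net.load_state_dict({k: data[k] for k in data.files if k != "__arch__"})
        return cls(spec, net)


def train(
    spec: ArchitectureSpec,
    data: GestureDataset,
    cfg: TrainConfig | None = None,
) -> tuple[TrainedModel, dict[str, list[float]]]:
    """Train ``spec`` on the dataset's train split, validating on ``val``.

    Returns the trained model and a history dict with per-epoch
    ``train_loss``, ``train_acc``, ``val_loss``, ``val_acc`` and ``lr``.
    Reproducible for a fixed ``cfg.seed``; aborts on non-finite loss.
    """
    cfg = cfg or TrainConfig()
    data.assert_no_leakage()
    x_train, y_train = data.arrays("train")
    has_val = data.indices("val").size > 0
    x_val, y_val = data.arrays("val") if has_val else (None, None)
    if y_train.min() < 0 or y_train.max() >= spec.n_classes:
        raise ValueError("labels outside 1..n_classes")
    net = build_network(spec, seed=cfg.seed)
    params = net.params()
    shuffle_rng = np.random.default_rng(cfg.seed + 1)

    def make_opt(name: str):
        return nn.Adam(params) if name == "ADAM" else nn.SGDM(params)

    opt = make_opt("SGDM" if cfg.two_phase else cfg.optimizer)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [], "lr": [],
    }
    n = len(y_train)
    for epoch in range(cfg.epochs):
        if cfg.two_phase and epoch == min(cfg.warmup_epochs, cfg.epochs):
            opt = make_opt("ADAM")
        lr = cfg.lr_at(epoch)
        order = shuffle_rng.permutation(n)
        losses, accs = [], []
        n_batches = int(np.ceil(n / cfg.batch_size))
        val_every = max(1, n_batches // max(1, cfg.val_checks_per_epoch))
        for bi, lo in enumerate(range(0, n, cfg.batch_size)):
            idx = order[lo : lo + cfg.batch_size]
            loss, acc = net.train_step(x_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bi} "
                    f"(lr={lr}, batch_size={cfg.batch_size})"
                )
            opt.step(lr)
            losses.append(loss)
            accs.append(acc)
            if (
                has_val
                and cfg.val_checks_per_epoch > 1
                and (bi + 1) % val_every == 0
                and bi + 1 < n_batches
            ):
                net.evaluate(x_val, y_val)
        train_loss = float(np.mean(losses))
        val_loss, val_acc = net.evaluate(x_val, y_val) if has_val else (np.nan, np.nan)
        history["train_loss"].append(train_loss)
        history["train_acc"].append(float(np.mean(accs)))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["lr"].append(lr)
        log.info(
            "epoch %3d lr=%.4g train_loss=%.4f train_acc=%.3f val_loss=%.4f val_acc=%.3f",
            epoch, lr, train_loss, history["train_acc"][-1], val_loss, val_acc,
        )
        val_ok = val_loss <= cfg.early_stop_val_loss if has_val else True
        if train_loss <= cfg.early_stop_train_loss and val_ok:
            log.info("early stop at epoch %d (loss targets met)", epoch)
            break
    return TrainedModel(spec, net), history
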