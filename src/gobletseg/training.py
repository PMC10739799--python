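"""Training protocol: Adam + step-decay schedule, early stopping, grouped
k-fold cross-validation with case-level leakage control.

Datasets are sequences of :class:`Sample`; all tiles from one animal/case
share a ``case_id`` and are always assigned to the same fold, so validation
cases are never seen in training.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .losses import LossConfig, bce_loss, combined_loss
from .nn.autodiff import Tensor
from .nn.layers import Module
from .nn.optim import Adam
from .evaluation import confusion, metrics_from_counts

__all__ = ["Sample", "TrainConfig", "FoldAssignment", "make_group_folds",
           "train", "cross_validate", "predict_prob"]


@dataclass
class Sample:
    """One training example: normalized image in [0,1] and boolean mask."""

    image: np.ndarray
    mask: np.ndarray
    case_id: str = "case0"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask) > 0
        if self.image.shape != self.mask.shape:
            raise ValueError("image/mask shape mismatch")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    lr: float = 1e-4
    decay_every: int = 20
    decay_factor: float = 0.5
    early_stop_patience: int = 10
    batch_size: int = 2
    seed: int = 0
    k_folds: int = 5

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0 < self.decay_factor < 1):
            raise ValueError("decay_factor must be in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 1-based epoch under step decay."""
        return self.lr * self.decay_factor ** ((epoch - 1) // self.decay_every)


@dataclass
class FoldAssignment:
    """Case-level fold map plus the per-fold sample index lists."""

    case_to_fold: dict[str, int]
    fold_samples: list[list[int]] = field(default_factory=list)

    def fold_of(self, case_id: str) -> int:
        return self.case_to_fold[case_id]


def make_group_folds(case_ids: list[str], k: int, seed: int = 0) -> FoldAssignment:
    """Partition cases into k folds with sizes differing by at most one.

    ``case_ids`` is per-sample (repeats allowed); every sample of a case
    lands in its case's fold. Deterministic given ``seed``.
    """
    cases = sorted(set(case_ids))
    if k > len(cases):
        raise ValueError(f"k={k} exceeds number of cases ({len(cases)})")
    rng = np.random.default_rng(seed)
    order = [cases[i] for i in rng.permutation(len(cases))]
    case_to_fold = {c: i % k for i, c in enumerate(order)}
    fold_samples: list[list[int]] = [[] for _ in range(k)]
    for i, cid in enumerate(case_ids):
        fold_samples[case_to_fold[cid]].append(i)
    return FoldAssignment(case_to_fold, fold_samples)


def predict_prob(model: Module, image: np.ndarray) -> np.ndarray:
    """Probability map for one normalized 2-D image (eval mode)."""
    was_training = model.training
    model.eval()
    x = Tensor(np.asarray(image, dtype=np.float64)[None, None])
    prob = model(x).data[0, 0]
    model.train(was_training)
    return prob


def _val_dice(model: Module, val_set: list[Sample], threshold: float = 0.5) -> float:
    scores = []
    for s in val_set:
        pred = predict_prob(model, s.image) > threshold
        scores.append(metrics_from_counts(confusion(pred, s.mask)).dice)
    return float(np.mean(scores))


def train(model: Module, train_set: list[Sample], val_set: list[Sample],
          tcfg: TrainConfig | None = None, lcfg: LossConfig | None = None,
          loss: str = "combined", log=None):
    """Train a model with Adam, step-decayed lr and dice early stopping.

    ``loss`` is ``"combined"`` (dice+focal) or ``"bce"`` (baseline U-Net
    protocol). Returns ``(model, history)`` with the best-validation
    weights restored; ``history`` is a list of per-epoch records
    (epoch, lr, train_loss, val_dice).
    """
    tcfg = tcfg or TrainConfig()
    lcfg = lcfg or LossConfig()
    if not train_set or not val_set:
        raise ValueError("empty train or validation set")
    train_cases = {s.case_id for s in train_set}
    val_cases = {s.case_id for s in val_set}
    overlap = train_cases & val_cases
    if overlap and train_cases != val_cases:
        raise ValueError(f"case leakage between train and validation: {overlap}")

    def loss_fn(p, g):
        return combined_loss(p, g, lcfg) if loss == "combined" else bce_loss(p, g)

    rng = np.random.default_rng(tcfg.seed)
    opt = Adam(model.parameters(), lr=tcfg.lr)
    history: list[dict] = []
    best = {"dice": -np.inf, "state": None, "epoch": 0}
    bad_epochs = 0
    for epoch in range(1, tcfg.epochs + 1):
        opt.lr = tcfg.lr_at(epoch)
        model.train()
        order = rng.permutation(len(train_set))
        losses = []
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            x = np.stack([train_set[i].image for i in idx])[:, None]
            g = np.stack([train_set[i].mask for i in idx])[:, None]
            prob = model(Tensor(x))
            lval = loss_fn(prob, g)
            if not np.isfinite(lval.data):
                raise RuntimeError(
                    f"non-finite loss {lval.data} at epoch {epoch}; aborting"
                )
            opt.zero_grad()
            lval.backward()
            opt.step()
            losses.append(float(lval.data))
        vd = _val_dice(model, val_set)
        rec = {"epoch": epoch, "lr": opt.lr,
               "train_loss": float(np.mean(losses)), "val_dice": vd}
        history.append(rec)
        if log is not None:
            log(f"epoch {epoch:3d} lr {opt.lr:.2e} "
                f"loss {rec['train_loss']:.4f} val_dice {vd:.4f}")
        if vd > best["dice"] + 1e-6:
            best = {"dice": vd, "state": copy.deepcopy(model.state_dict()),
                    "epoch": epoch}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > tcfg.early_stop_patience:
                break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    return model, history


def cross_validate(dataset: list[Sample], model_builder,
                   tcfg: TrainConfig | None = None,
                   lcfg: LossConfig | None = None,
                   loss: str = "combined", log=None):
    """Grouped k-fold cross-validation.

    ``model_builder(fold_index)`` must return a fresh model. Returns a dict
    with per-fold validation dice, their mean and sample sd, the fold
    assignment, and the trained models.
    """
    tcfg = tcfg or TrainConfig()
    folds = make_group_folds([s.case_id for s in dataset], tcfg.k_folds,
                             tcfg.seed)
    fold_dice, models = [], []
    for f in range(tcfg.k_folds):
        val_idx = set(folds.fold_samples[f])
        train_set = [s for i, s in enumerate(dataset) if i not in val_idx]
        val_set = [dataset[i] for i in sorted(val_idx)]
        model = model_builder(f)
        model, history = train(model, train_set, val_set, tcfg, lcfg, loss, log)
        fold_dice.append(max(h["val_dice"] for h in history))
        models.append(model)
    arr = np.asarray(fold_dice)
    return {
        "fold_dice": fold_dice,
        "mean_dice": float(arr.mean()),
        "sd_dice": float(arr.std(ddof=1)) if len(arr) > 1 else float("nan"),
        "folds": folds,
        "models": models,
    }
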