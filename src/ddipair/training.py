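"""Training: BCE loss, step learning-rate schedule, AdamW, and the
epoch loop with validation-based checkpoint selection and replicate runs.

The optimizer is AdamW with decoupled weight decay (moments β₁ = 0.9,
β₂ = 0.999, ε = 1e-8; decay applied directly to the weights scaled by the
current learning rate).  The learning rate follows a step schedule,
``lr = base · γ^⌊epoch/step⌋``, stepped per epoch.  The best epoch is the
one maximizing validation ROC-AUC, and its parameter snapshot is returned.

Everything is seeded: initialization, per-epoch shuffling and replicate
seeds derive from ``TrainingConfig.seed``, so a full train → evaluate run
is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import evaluation
from .model import (
    ModelConfig,
    ModelParameters,
    backward_pairs,
    batchify,
    forward_pairs,
    init_parameters,
)
from .synthetic import LabeledPairDataset
from .tokenizer import TokenSequence, Vocabulary, encode

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "bce_loss",
    "step_lr",
    "AdamW",
    "train",
    "run_replicates",
]

EPS_PROB = 1e-7  # probability clamp before the log


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters.

    The defaults are the benchmark profile: AdamW at 2e-5 with weight decay
    2e-4, batch size 8, 30 epochs, step schedule γ = 0.8 every 10 epochs,
    three replicate runs.
    """

    learning_rate: float = 2e-5
    weight_decay: float = 2e-4
    batch_size: int = 8
    epochs: int = 30
    scheduler_gamma: float = 0.8
    scheduler_step: int = 10
    seed: int = 0
    n_runs: int = 3

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 < self.scheduler_gamma <= 1):
            raise ValueError("scheduler_gamma must be in (0, 1]")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.scheduler_step < 1:
            raise ValueError("scheduler_step must be at least 1")
        if self.batch_size < 1 or self.n_runs < 1:
            raise ValueError("batch_size and n_runs must be at least 1")


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    valid_loss: float
    valid_auc: float


@dataclass
class TrainingHistory:
    """Per-epoch losses and validation AUC; best_epoch maximizes the AUC."""

    epochs: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1

    def to_dict(self) -> dict:
        return {
            "best_epoch": self.best_epoch,
            "epochs": [vars(e) for e in self.epochs],
        }


def bce_loss(
    p: float | np.ndarray,
    t: float | np.ndarray,
    w: float | np.ndarray = 1.0,
) -> float:
    """Binary cross-entropy, mean over items.

    ``-w·[t·log p + (1 − t)·log(1 − p)]`` with probabilities clamped to
    ``[1e-7, 1 − 1e-7]`` so the 0·log 0 convention holds numerically.
    """
    p = np.clip(np.asarray(p, dtype=float), EPS_PROB, 1.0 - EPS_PROB)
    t = np.asarray(t, dtype=float)
    if not np.isin(t, (0.0, 1.0)).all():
        raise ValueError("labels must be 0 or 1")
    losses = -np.asarray(w, dtype=float) * (t * np.log(p) + (1.0 - t) * np.log(1.0 - p))
    return float(losses.mean())


def step_lr(epoch: int, base_lr: float, gamma: float, step_size: int) -> float:
    """Step schedule: ``base_lr · gamma^⌊epoch/step_size⌋``."""
    if step_size < 1:
        raise ValueError("step_size must be at least 1")
    return base_lr * gamma ** (epoch // step_size)


class AdamW:
    """Adam with decoupled weight decay on named parameter arrays.

    The decay term ``lr·λ·θ`` is subtracted directly from each weight,
    separate from the adaptive gradient step.
    """

    def __init__(
        self,
        named_params: Sequence[tuple[str, np.ndarray]],
        weight_decay: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(named_params)
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {name: np.zeros_like(a) for name, a in self.params}
        self.v = {name: np.zeros_like(a) for name, a in self.params}

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for name, arr in self.params:
            g = grads[name]
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            arr -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                arr -= lr * self.weight_decay * arr


def encode_pairs(
    dataset: LabeledPairDataset, vocab: Vocabulary, max_len: int
) -> tuple[list[TokenSequence], list[TokenSequence], np.ndarray]:
    """Tokenize both SMILES columns of a labeled dataset."""
    seqs_a = [encode(s, vocab, max_len) for s in dataset.smiles_a]
    seqs_b = [encode(s, vocab, max_len) for s in dataset.smiles_b]
    return seqs_a, seqs_b, dataset.labels.astype(float)


def _predict_scores(
    params: ModelParameters,
    seqs_a: Sequence[TokenSequence],
    seqs_b: Sequence[TokenSequence],
    batch_size: int = 256,
) -> np.ndarray:
    out = np.empty(len(seqs_a))
    for lo in range(0, len(seqs_a), batch_size):
        hi = min(lo + batch_size, len(seqs_a))
        ids_a, mask_a = batchify(seqs_a[lo:hi])
        ids_b, mask_b = batchify(seqs_b[lo:hi])
        p, _ = forward_pairs(params, ids_a, mask_a, ids_b, mask_b)
        out[lo:hi] = p
    return out


def train(
    dataset: LabeledPairDataset,
    vocab: Vocabulary,
    model_config: ModelConfig,
    train_config: TrainingConfig,
    log: Callable[[str], None] | None = None,
) -> tuple[ModelParameters, TrainingHistory]:
    """Mini-batch AdamW training with per-epoch validation.

    Requires a dataset with non-empty ``train`` and ``valid`` splits.
    Returns the parameter snapshot of the epoch with the best validation
    ROC-AUC (the initialization if ``epochs == 0``) and the history.
    """
    train_ds = dataset.subset("train")
    valid_ds = dataset.subset("valid")
    ta, tb, ty = encode_pairs(train_ds, vocab, model_config.max_len)
    va, vb, vy = encode_pairs(valid_ds, vocab, model_config.max_len)

    rng = np.random.default_rng(train_config.seed)
    params = init_parameters(model_config, rng)
    opt = AdamW(params.named_arrays(), weight_decay=train_config.weight_decay)
    history = TrainingHistory()
    best_params = params.copy()
    best_auc = -np.inf
    n = len(ta)
    bs = train_config.batch_size

    for epoch in range(train_config.epochs):
        lr = step_lr(epoch, train_config.learning_rate,
                     train_config.scheduler_gamma, train_config.scheduler_step)
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, bs):
            idx = perm[lo:lo + bs]
            ids_a, mask_a = batchify([ta[i] for i in idx])
            ids_b, mask_b = batchify([tb[i] for i in idx])
            t = ty[idx]
            p, cache = forward_pairs(params, ids_a, mask_a, ids_b, mask_b)
            loss = bce_loss(p, t)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {lo // bs}"
                )
            dlogit = (p - t) / len(idx)
            grads = backward_pairs(params, cache, dlogit)
            opt.step(grads, lr)
            epoch_loss += loss * len(idx)
        epoch_loss /= n

        valid_scores = _predict_scores(params, va, vb)
        valid_loss = bce_loss(valid_scores, vy)
        _, valid_auc = evaluation.roc_auc(valid_scores, vy.astype(int))
        history.epochs.append(EpochRecord(epoch, lr, epoch_loss, valid_loss, valid_auc))
        if log is not None:
            log(f"epoch {epoch:3d}  lr {lr:.3e}  train_loss {epoch_loss:.4f}  "
                f"valid_loss {valid_loss:.4f}  valid_auc {valid_auc:.4f}")
        if valid_auc > best_auc:
            best_auc = valid_auc
            best_params = params.copy()
            history.best_epoch = epoch

    return best_params, history


def run_replicates(
    dataset: LabeledPairDataset,
    vocab: Vocabulary,
    model_config: ModelConfig,
    train_config: TrainingConfig,
    log: Callable[[str], None] | None = None,
) -> tuple[list[tuple[ModelParameters, "evaluation.EvaluationReport"]], dict]:
    """n_runs independent trainings with seeds seed, seed+1, ...

    Each run is evaluated on the test split; the aggregate maps each metric
    to (mean, sample standard deviation), the across-run summary used for
    reporting "value (±std)" tables.
    """
    test_ds = dataset.subset("test")
    sa, sb, sy = encode_pairs(test_ds, vocab, model_config.max_len)
    runs = []
    metric_runs = []
    for k in range(train_config.n_runs):
        cfg_k = replace(train_config, seed=train_config.seed + k)
        params, _ = train(dataset, vocab, model_config, cfg_k, log=log)
        scores = _predict_scores(params, sa, sb)
        report = evaluation.evaluate(scores, sy.astype(int))
        runs.append((params, report))
        metric_runs.append(report.metrics())
    return runs, evaluation.aggregate(metric_runs)
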