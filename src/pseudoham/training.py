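"""Masked eigenvalue loss, eigenvalue gradients, optimizer and metrics.

The loss is the mean over masked-valid slots of the squared difference
between predicted and reference energies, matched index-wise after ascending
sort of both sides; padding slots contribute exactly zero loss and zero
gradient. Gradients flow through the eigendecomposition analytically
(∂ε_i/∂H = u_i u_iᵀ).

Reduction convention: per-molecule mean over valid slots, then mean over the
molecules of the batch — scale-free in n_max and batch size, and identical
whether accumulated molecule-by-molecule or evaluated on the full batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .autodiff import Tensor, tsum, sort_last
from .encoder import GraphBatch
from .heads import EigenvalueNet
from .molecular_io import DatasetSplit, EigenvalueRecord, split_dataset

__all__ = [
    "TrainingConfig",
    "MetricsReport",
    "TargetVector",
    "masked_l2_loss",
    "eigenvalue_gradient",
    "Adam",
    "fit_network",
    "evaluate_predictions",
    "evaluate",
    "train_model",
]


@dataclass
class TargetVector:
    """Slot-ordered masked regression targets without the ascending invariant.

    Used for Δ-ML targets, which are matched to prediction slots by index and
    need not be monotone. Duck-type-compatible with EigenvalueRecord where the
    training stack is concerned.
    """

    values: np.ndarray
    mask: np.ndarray
    n_occupied: int = 0
    level_tag: str = "delta"
    id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n_valid = int(self.mask.sum())
        if n_valid and not np.all(self.mask[:n_valid]):
            raise ValueError("padding slots must trail the valid slots")

    @property
    def n_max(self) -> int:
        return int(self.values.size)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; the seed is recorded in every checkpoint."""

    learning_rate: float = 0.01
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 25  # early stopping on validation loss
    lr_decay: float = 0.7  # plateau decay factor
    lr_patience: int = 8
    min_lr: float = 1e-4
    clip_norm: float = 5.0  # global gradient-norm clip; 0 disables
    seed: int = 0

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("rates, sizes and patience must be positive")


@dataclass
class MetricsReport:
    """Mask-aware error summary on one dataset split (all energies in eV)."""

    per_slot_mae: np.ndarray
    per_slot_rmse: np.ndarray
    mae: float
    rmse: float
    worst_molecule_error: float
    homo_mae: float
    lumo_mae: float
    n_molecules: int


def _check_record(ref: EigenvalueRecord) -> None:
    if ref.n_valid == 0:
        raise ValueError("record has an all-false mask; nothing to compare")


def masked_l2_loss(pred: np.ndarray, ref: EigenvalueRecord) -> float:
    """Mean squared error over valid slots (numpy, for analysis and tests).

    Both sides are sorted ascending over the valid slots before index-wise
    matching; masked-false slots contribute exactly zero.
    """
    _check_record(ref)
    pred = np.asarray(pred, dtype=float)
    k = ref.n_valid
    p = np.sort(pred[:k])
    r = ref.values[:k]
    return float(np.mean((p - r) ** 2))


def eigenvalue_gradient(H: np.ndarray, i: int) -> np.ndarray:
    """Analytic gradient ∂ε_i/∂H = u_i u_iᵀ of a symmetric eigenvalue.

    Exact for simple eigenvalues; at near-degeneracies (gap < 1e-8 eV) the
    eigensolver's tie-break selects a representative subgradient.
    """
    H = np.asarray(H, dtype=float)
    if not np.allclose(H, H.T, atol=1e-12):
        raise ValueError("H must be symmetric")
    _, U = np.linalg.eigh(H)
    u = U[:, i]
    return np.outer(u, u)


class Adam:
    """Adaptive-moment optimizer over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _batch_loss(
    net: EigenvalueNet,
    structures,
    records: Sequence[EigenvalueRecord],
    sort_pred: bool,
) -> Tensor:
    """Differentiable masked loss of one packed batch (mean convention)."""
    batch = GraphBatch(structures, net.encoder_config)
    pred = net.forward(batch)  # (B, n_out)
    if sort_pred:
        pred = sort_last(pred)
    n_out = pred.data.shape[1]
    mask = np.stack([r.mask[:n_out] for r in records]).astype(float)
    refs = np.stack([r.values[:n_out] for r in records])
    n_valid = mask.sum(axis=1)
    if np.any(n_valid == 0):
        raise ValueError("a record in the batch has an all-false mask")
    diff = (pred - refs) * mask
    per_mol = tsum(diff * diff, axis=1) * (1.0 / n_valid)
    return tsum(per_mol) / len(records)


def fit_network(
    net: EigenvalueNet,
    structures,
    records: Sequence[EigenvalueRecord],
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    config: TrainingConfig,
    slot: int | None = None,
) -> dict:
    """Minimize the masked loss; early-stop and return the best checkpoint.

    ``slot`` restricts training to one eigenvalue slot (1S models). Returns a
    history dict with per-epoch train/validation losses; the network is left
    at the best-validation parameters. Deterministic for a given seed.
    """
    if slot is not None:
        records = [_slot_record(r, slot) for r in records]
    for i in np.concatenate([train_idx, val_idx]):
        _check_record(records[int(i)])
    sort_pred = net.head_type == "hamiltonian"  # eigh output is sorted already;
    # sorting is a no-op forward but keeps the index-wise contract explicit.
    if net.head_type == "scalar" and records[0].n_max != 1:
        raise ValueError("scalar head needs single-slot records (use slot=...)")

    # bias initialization: mean spectrum of the training targets (valid slots)
    n_out = 1 if net.head_type == "scalar" else net.n_max
    vals = np.stack([records[i].values[:n_out] for i in train_idx])
    msk = np.stack([records[i].mask[:n_out] for i in train_idx])
    counts = np.maximum(msk.sum(axis=0), 1)
    mean_spectrum = (vals * msk).sum(axis=0) / counts
    net.head.set_output_bias(mean_spectrum)

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(net.parameters(), lr=config.learning_rate)
    best_val = np.inf
    best_state = [p.copy() for p in net.state_arrays()]
    history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    since_best = 0
    since_decay = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_idx))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            sel = train_idx[order[start : start + config.batch_size]]
            loss = _batch_loss(
                net, [structures[i] for i in sel], [records[i] for i in sel], sort_pred
            )
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged (loss={loss.data}) at epoch {epoch}, "
                    f"lr={optimizer.lr}"
                )
            optimizer.zero_grad()
            loss.backward()
            if config.clip_norm > 0:
                _clip_gradients(optimizer.params, config.clip_norm)
            optimizer.step()
            epoch_loss += loss.item() * len(sel)
        epoch_loss /= len(train_idx)
        val_loss = _dataset_loss(net, structures, records, val_idx, sort_pred)
        history["epoch"].append(epoch)
        history["train_loss"].append(epoch_loss)
        history["val_loss"].append(val_loss)
        history["lr"].append(optimizer.lr)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = [p.copy() for p in net.state_arrays()]
            since_best = 0
            since_decay = 0
        else:
            since_best += 1
            since_decay += 1
            if since_best >= config.patience:
                break
            if since_decay >= config.lr_patience and optimizer.lr > config.min_lr:
                optimizer.lr = max(config.min_lr, optimizer.lr * config.lr_decay)
                since_decay = 0
    net.load_state_arrays(best_state)
    history["best_val_loss"] = best_val
    history["seed"] = config.seed
    return history


def _clip_gradients(params, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / total
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def _dataset_loss(net, structures, records, idx, sort_pred, chunk: int = 256) -> float:
    total = 0.0
    for start in range(0, len(idx), chunk):
        sel = idx[start : start + chunk]
        loss = _batch_loss(
            net, [structures[i] for i in sel], [records[i] for i in sel], sort_pred
        )
        total += loss.item() * len(sel)
    return total / len(idx)


def _slot_record(r: EigenvalueRecord, slot: int) -> EigenvalueRecord:
    """Single-slot view of a record (for 1S training)."""
    valid = bool(r.mask[slot])
    return EigenvalueRecord(
        values=np.array([r.values[slot] if valid else 0.0]),
        mask=np.array([valid]),
        n_occupied=1 if (valid and slot < r.n_occupied) else 0,
        level_tag=r.level_tag,
        id=r.id,
    )


def evaluate_predictions(
    pred: np.ndarray, records: Sequence[EigenvalueRecord]
) -> MetricsReport:
    """Mask-aware MAE/RMSE per slot and aggregate, plus HOMO/LUMO slot errors."""
    if len(records) == 0:
        raise ValueError("empty split")
    pred = np.asarray(pred, dtype=float)
    n_max = records[0].n_max
    n_out = pred.shape[1]
    abs_err = np.full((len(records), n_max), np.nan)
    homo_err, lumo_err = [], []
    for k, r in enumerate(records):
        _check_record(r)
        nv = r.n_valid
        p = np.sort(pred[k][: min(nv, n_out)])
        e = np.abs(p - r.values[:nv])
        abs_err[k, :nv] = e
        if r.n_occupied >= 1:
            homo_err.append(e[r.n_occupied - 1])
        if r.n_occupied < nv:
            lumo_err.append(e[r.n_occupied])
    with np.errstate(invalid="ignore"):
        per_slot_mae = np.nanmean(abs_err, axis=0)
        per_slot_rmse = np.sqrt(np.nanmean(abs_err**2, axis=0))
    flat = abs_err[np.isfinite(abs_err)]
    return MetricsReport(
        per_slot_mae=per_slot_mae,
        per_slot_rmse=per_slot_rmse,
        mae=float(flat.mean()),
        rmse=float(np.sqrt((flat**2).mean())),
        worst_molecule_error=float(np.nanmax(abs_err)),
        homo_mae=float(np.mean(homo_err)) if homo_err else np.nan,
        lumo_mae=float(np.mean(lumo_err)) if lumo_err else np.nan,
        n_molecules=len(records),
    )


def evaluate(model, structures, records, idx=None) -> MetricsReport:
    """Evaluate a fitted model (anything with ``predict``) on a dataset split."""
    if idx is None:
        idx = np.arange(len(structures))
    if len(idx) == 0:
        raise ValueError("empty split")
    pred = model.predict([structures[i] for i in idx])
    return evaluate_predictions(pred, [records[i] for i in idx])


def train_model(structures, records, model_config: dict, training_config: TrainingConfig):
    """Thin functional wrapper over :class:`pseudoham.models.OrbitalEnergyRegressor`."""
    from .models import OrbitalEnergyRegressor

    model = OrbitalEnergyRegressor(**model_config, **_tc_kwargs(training_config))
    model.fit(structures, records)
    return model


def _tc_kwargs(tc: TrainingConfig) -> dict:
    return dict(
        learning_rate=tc.learning_rate,
        batch_size=tc.batch_size,
        max_epochs=tc.max_epochs,
        patience=tc.patience,
        seed=tc.seed,
    )
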