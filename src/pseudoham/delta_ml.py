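"""Δ-ML level-of-theory correction on top of a frozen base model.

A multi-state (MS) network is trained on the per-slot difference between
high-level reference energies and the base model's predictions,

    Δ_i = ε^ref_high,i − ε^ML_base,i ,

and corrected predictions are the exact sum ε^ML_high = ε^ML_base + Δ^ML.
The delta model consumes only the molecular structure; the two models are
trained separately and stacked at prediction time. By default the baseline is
the ML prediction (no reference calculation needed for new molecules); a
reference-data baseline is available behind ``baseline='reference'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .models import OrbitalEnergyRegressor
from .molecular_io import EigenvalueRecord
from .training import TargetVector

__all__ = ["DeltaRecord", "delta_targets", "combine", "DeltaCorrector", "train_delta"]


@dataclass
class DeltaRecord:
    """Per-slot energy differences between two levels of theory (eV)."""

    values: np.ndarray  # (n_max,), zero on padding slots
    mask: np.ndarray  # (n_max,) bool
    n_occupied: int
    base_tag: str = "base"
    high_tag: str = "high"
    id: str = ""

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


def delta_targets(
    high_ref: EigenvalueRecord, base_pred: np.ndarray, base_tag: str = "base"
) -> DeltaRecord:
    """Δ_i = ε^ref_high,i − ε^ML_base,i on valid slots (zero elsewhere)."""
    base_pred = np.asarray(base_pred, dtype=float)
    if base_pred.shape != high_ref.values.shape:
        raise ValueError("base prediction and high-level record length mismatch")
    values = np.where(high_ref.mask, high_ref.values - base_pred, 0.0)
    return DeltaRecord(
        values=values,
        mask=high_ref.mask.copy(),
        n_occupied=high_ref.n_occupied,
        base_tag=base_tag,
        high_tag=high_ref.level_tag,
        id=high_ref.id,
    )


def combine(base_pred: np.ndarray, delta_pred: np.ndarray) -> np.ndarray:
    """ε^ML(high) = ε^ML(base) + Δε^ML — exact element-wise addition."""
    base_pred = np.asarray(base_pred, dtype=float)
    delta_pred = np.asarray(delta_pred, dtype=float)
    if base_pred.shape != delta_pred.shape:
        raise ValueError("base and delta predictions must have the same shape")
    return base_pred + delta_pred


class DeltaCorrector(BaseEstimator, RegressorMixin):
    """MS-head corrector from a frozen base model to a higher level of theory.

    Parameters
    ----------
    base : fitted OrbitalEnergyRegressor
        The frozen baseline model (not refit here).
    baseline : {'ml', 'reference'}
        'ml' builds delta targets against base.predict(X) and needs no
        reference data at prediction time (the default); 'reference' builds
        them against base-level reference records passed to ``fit`` and
        requires the same at ``predict``.
    Remaining parameters configure the MS delta network (cold start).

    Attributes
    ----------
    delta_model_ : OrbitalEnergyRegressor
        The fitted MS network predicting per-slot deltas.
    """

    def __init__(
        self,
        base: OrbitalEnergyRegressor,
        baseline: str = "ml",
        n_features: int = 64,
        n_interactions: int = 2,
        n_rbf: int = 20,
        cutoff: float = 5.0,
        hidden: int | None = None,
        learning_rate: float = 0.01,
        batch_size: int = 32,
        max_epochs: int = 200,
        patience: int = 25,
        val_fraction: float = 0.1,
        seed: int = 0,
    ):
        self.base = base
        self.baseline = baseline
        self.n_features = n_features
        self.n_interactions = n_interactions
        self.n_rbf = n_rbf
        self.cutoff = cutoff
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    def _base_values(self, X, base_records=None) -> np.ndarray:
        if self.baseline == "ml":
            return self.base.predict(X)
        if self.baseline == "reference":
            if base_records is None:
                raise ValueError("baseline='reference' needs base-level records")
            return np.stack([r.values for r in base_records])
        raise ValueError(f"unknown baseline {self.baseline!r}")

    def fit(self, X, y, base_records=None):
        """Fit the delta network on structures X and high-level records y."""
        structures = list(X)
        high_records = list(y)
        base_values = self._base_values(structures, base_records)
        n_max = high_records[0].n_max
        # Deltas are matched to prediction slots by index (no sorting): the
        # delta network must learn the slot-wise correction directly.
        targets = []
        for k, hr in enumerate(high_records):
            d = delta_targets(hr, base_values[k])
            targets.append(
                TargetVector(
                    values=d.values,
                    mask=d.mask,
                    n_occupied=d.n_occupied,
                    level_tag=f"delta({d.high_tag}-{d.base_tag})",
                    id=d.id,
                )
            )
        self.delta_model_ = OrbitalEnergyRegressor(
            head="ms",
            sort_output=False,
            n_max=n_max,
            n_features=self.n_features,
            n_interactions=self.n_interactions,
            n_rbf=self.n_rbf,
            cutoff=self.cutoff,
            hidden=self.hidden,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
            seed=self.seed,
        )
        self.delta_model_.fit(structures, targets)
        self.n_parameters_ = self.delta_model_.n_parameters_
        return self

    def predict_delta(self, X) -> np.ndarray:
        return self.delta_model_.predict(list(X))

    def predict(self, X, base_records=None) -> np.ndarray:
        """Corrected high-level predictions: base + delta, slot-wise."""
        structures = list(X)
        base_values = self._base_values(structures, base_records)
        return combine(base_values, self.predict_delta(structures))


def train_delta(structures, high_records, base_model, **kwargs) -> DeltaCorrector:
    """Thin functional wrapper over :class:`DeltaCorrector`."""
    corrector = DeltaCorrector(base=base_model, **kwargs)
    corrector.fit(structures, high_records)
    return corrector
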