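"""Scikit-learn-style estimators wrapping the encoder/head/training stack.

``OrbitalEnergyRegressor`` is the user-facing model: fit on a list of
:class:`AtomicStructure` with :class:`EigenvalueRecord` targets, predict an
(n_samples, n_max) array of energies. ``head='hamiltonian'`` is the
pseudo-Hamiltonian model; ``'ms'`` the multi-state vector model; ``'1s'``
trains one scalar network per eigenvalue slot.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .encoder import EncoderConfig
from .heads import EigenvalueNet, matched_hidden_width
from .molecular_io import EigenvalueRecord, split_dataset
from .training import TrainingConfig, evaluate_predictions, fit_network

__all__ = ["OrbitalEnergyRegressor"]


def _as_records(y, n_max: int | None = None) -> list:
    """Accept records (or any masked target duck-type), or a plain array."""
    if isinstance(y, (list, tuple)) and y and hasattr(y[0], "mask"):
        return list(y)
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("targets must be records or a 2-D array")
    values = np.sort(y, axis=1)
    return [
        EigenvalueRecord(
            values=v, mask=np.ones(y.shape[1], dtype=bool), n_occupied=0
        )
        for v in values
    ]


class OrbitalEnergyRegressor(BaseEstimator, RegressorMixin):
    """Predict many molecular orbital/quasiparticle energies per molecule.

    Parameters
    ----------
    head : {'hamiltonian', 'ms', '1s'}
        Output head. ``'hamiltonian'`` predicts a symmetric n_max × n_max
        matrix and returns its ascending eigenvalues (gradients flow through
        the diagonalization); ``'ms'`` predicts the energy vector directly;
        ``'1s'`` trains ``n_max`` independent single-output networks.
    n_max : int
        Number of fitted eigenvalue slots (dimension of the pseudo-Hamiltonian).
    hidden : int or None
        Head hidden width. None picks a width whose parameter count matches a
        reference MS head of width ``n_features`` — the matched-budget setting
        used when comparing heads.
    val_fraction : float
        Fraction of the fit data held out for early stopping.

    Attributes
    ----------
    net_ : EigenvalueNet or list[EigenvalueNet]
        The trained network(s).
    history_ : dict or list[dict]
        Per-epoch train/validation losses.
    n_parameters_ : int
        Total trainable parameter count (summed over networks for '1s').
    """

    def __init__(
        self,
        head: str = "hamiltonian",
        n_max: int = 6,
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
        sort_output: bool = True,
        seed: int = 0,
    ):
        self.head = head
        self.n_max = n_max
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
        self.sort_output = sort_output
        self.seed = seed

    # ------------------------------------------------------------------
    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            n_features=self.n_features,
            n_interactions=self.n_interactions,
            n_rbf=self.n_rbf,
            cutoff=self.cutoff,
        )

    def _hidden_for(self, n_out: int) -> int:
        if self.hidden is not None:
            return self.hidden
        # reference budget: an MS head of hidden width n_features
        return matched_hidden_width(self.n_features, self.n_max, self.n_features, n_out)

    def _training_config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.seed,
        )

    # ------------------------------------------------------------------
    def fit(self, X, y):
        """Fit on structures X and eigenvalue records y."""
        if self.head not in ("hamiltonian", "ms", "1s"):
            raise ValueError(f"unknown head {self.head!r}")
        structures = list(X)
        records = _as_records(y, self.n_max)
        if len(structures) != len(records):
            raise ValueError("X and y length mismatch")
        if any(r.n_max != self.n_max for r in records):
            raise ValueError("record n_max does not match the model n_max")
        n = len(structures)
        n_val = max(1, int(round(self.val_fraction * n)))
        perm = np.random.default_rng(self.seed).permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        cfg = self._training_config()

        if self.head == "1s":
            self.net_, self.history_ = [], []
            for slot in range(self.n_max):
                net = EigenvalueNet(
                    "scalar",
                    1,
                    self._encoder_config(),
                    self._hidden_for(1),
                    seed=self.seed + 1000 * slot,
                )
                # restrict to molecules where this slot is valid
                valid = np.array([bool(r.mask[slot]) for r in records])
                tr = train_idx[valid[train_idx]]
                va = val_idx[valid[val_idx]]
                if len(tr) == 0 or len(va) == 0:
                    raise ValueError(f"slot {slot} has no valid training data")
                h = fit_network(net, structures, records, tr, va, cfg, slot=slot)
                self.net_.append(net)
                self.history_.append(h)
            self.n_parameters_ = sum(net.n_parameters for net in self.net_)
        else:
            head_type = "hamiltonian" if self.head == "hamiltonian" else "ms"
            n_out = (
                self.n_max * (self.n_max + 1) // 2
                if head_type == "hamiltonian"
                else self.n_max
            )
            net = EigenvalueNet(
                head_type,
                self.n_max,
                self._encoder_config(),
                self._hidden_for(n_out),
                seed=self.seed,
            )
            self.history_ = fit_network(net, structures, records, train_idx, val_idx, cfg)
            self.net_ = net
            self.n_parameters_ = net.n_parameters
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted energies, shape (n_samples, n_max), ascending per row.

        Predictions cover all slots; consumers apply reference masks.
        """
        structures = list(X)
        if self.head == "1s":
            cols = [net.predict(structures)[:, 0] for net in self.net_]
            return np.stack(cols, axis=1)
        pred = self.net_.predict(structures)
        if self.head == "ms" and self.sort_output:
            pred = np.sort(pred, axis=1)
        return pred

    def pseudo_hamiltonians(self, X) -> np.ndarray:
        """Predicted symmetric matrices (hamiltonian head only)."""
        if self.head != "hamiltonian":
            raise ValueError("only head='hamiltonian' produces matrices")
        return self.net_.pseudo_hamiltonians(list(X))

    def score(self, X, y) -> float:
        """Negative mask-aware MAE (eV); higher is better."""
        report = evaluate_predictions(self.predict(X), _as_records(y, self.n_max))
        return -report.mae
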