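"""Output heads: single-state (1S), multi-state (MS), and pseudo-Hamiltonian.

The pseudo-Hamiltonian head sum-pools per-atom contributions to the
n_max(n_max+1)/2 unique entries of a symmetric matrix H (eV) whose ascending
eigenvalues are the predicted energies:

    H_ij = Σ_a Σ_f w_ijf · x_af + b_ij ,   diag({ε_i}) = Uᵀ H U .

Only the upper triangle is predicted and mirrored, so H is symmetric bitwise
by construction; H's dimension is fixed by the user (number of fitted
eigenvalues) and independent of molecule size. Sorting happens only after
diagonalization — no ordering constraint is imposed on H itself.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, eigvalsh, segment_sum, symmetric_from_triu
from .encoder import Dense, EncoderConfig, GraphBatch, SchNetEncoder

__all__ = [
    "ScalarHead",
    "MultiStateHead",
    "HamiltonianHead",
    "eigenvalues_from_matrix",
    "matched_hidden_width",
    "EigenvalueNet",
]


def eigenvalues_from_matrix(H: np.ndarray) -> np.ndarray:
    """Ascending eigenvalues of a real symmetric matrix (eV).

    Raises if the input violates the symmetry contract.
    """
    H = np.asarray(H, dtype=float)
    if not np.allclose(H, np.swapaxes(H, -1, -2), atol=1e-10):
        raise ValueError("pseudo-Hamiltonian must be symmetric")
    return np.linalg.eigvalsh(H)


def matched_hidden_width(
    n_features: int, n_out_ref: int, hidden_ref: int, n_out: int
) -> int:
    """Hidden width giving a head ≈ the parameter count of a reference head.

    A two-layer head F→h→n_out has h(F + n_out) + h + n_out parameters; solve
    for h so different output widths (e.g. n_max vs n_max(n_max+1)/2) land on
    almost the same budget.
    """
    budget = hidden_ref * (n_features + n_out_ref) + hidden_ref + n_out_ref
    h = round((budget - n_out) / (n_features + n_out + 1))
    return max(1, h)


class _PooledHead:
    """Two atom-wise layers, sum-pooled per molecule, plus an output bias.

    The output bias is intended to be initialized to the training-set mean
    target (``set_output_bias``), centering the energy scale.
    """

    def __init__(self, n_features: int, n_out: int, hidden: int, rng):
        self.dense1 = Dense(n_features, hidden, rng, activation=True)
        self.dense2 = Dense(hidden, n_out, rng)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)
        self.n_out = n_out

    def pooled(self, features: Tensor, batch: GraphBatch) -> Tensor:
        per_atom = self.dense2(self.dense1(features))
        return segment_sum(per_atom, batch.mol_index, batch.n_molecules) + self.bias

    def set_output_bias(self, value: np.ndarray) -> None:
        self.bias.data = np.broadcast_to(
            np.asarray(value, dtype=float), self.bias.data.shape
        ).copy()

    def parameters(self) -> list[Tensor]:
        return self.dense1.parameters() + self.dense2.parameters() + [self.bias]

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class ScalarHead(_PooledHead):
    """One energy per molecule (the 1S model predicts one state per network)."""

    def __init__(self, n_features: int, hidden: int, rng):
        super().__init__(n_features, 1, hidden, rng)

    def __call__(self, features: Tensor, batch: GraphBatch) -> Tensor:
        return self.pooled(features, batch)  # (B, 1)


class MultiStateHead(_PooledHead):
    """A vector of n_max energies per molecule (MS model)."""

    def __init__(self, n_features: int, n_max: int, hidden: int, rng):
        super().__init__(n_features, n_max, hidden, rng)
        self.n_max = n_max

    def __call__(self, features: Tensor, batch: GraphBatch) -> Tensor:
        return self.pooled(features, batch)  # (B, n_max)


class HamiltonianHead(_PooledHead):
    """Pseudo-Hamiltonian head: pooled triangle → symmetric matrix → eigenvalues."""

    def __init__(self, n_features: int, n_max: int, hidden: int, rng):
        super().__init__(n_features, n_max * (n_max + 1) // 2, hidden, rng)
        self.n_max = n_max

    def matrix(self, features: Tensor, batch: GraphBatch) -> Tensor:
        """The symmetric pseudo-Hamiltonian, shape (B, n_max, n_max)."""
        return symmetric_from_triu(self.pooled(features, batch), self.n_max)

    def __call__(self, features: Tensor, batch: GraphBatch) -> Tensor:
        return eigvalsh(self.matrix(features, batch))  # ascending (B, n_max)

    def set_output_bias(self, value: np.ndarray) -> None:
        """Place the mean spectrum on the diagonal of the bias triangle."""
        value = np.asarray(value, dtype=float)
        iu, ju = np.triu_indices(self.n_max)
        bias = np.zeros(self.n_out)
        bias[iu == ju] = value
        self.bias.data = bias


class EigenvalueNet:
    """Encoder + head; the end-to-end network behind one trained model."""

    def __init__(
        self,
        head_type: str,
        n_max: int,
        encoder_config: EncoderConfig,
        hidden: int,
        seed: int = 0,
    ):
        if head_type not in ("scalar", "ms", "hamiltonian"):
            raise ValueError(f"unknown head type {head_type!r}")
        self.head_type = head_type
        self.n_max = n_max
        self.encoder_config = encoder_config
        self.encoder = SchNetEncoder(encoder_config, seed=seed)
        rng = np.random.default_rng(seed + 1)
        F = encoder_config.n_features
        if head_type == "scalar":
            self.head = ScalarHead(F, hidden, rng)
        elif head_type == "ms":
            self.head = MultiStateHead(F, n_max, hidden, rng)
        else:
            self.head = HamiltonianHead(F, n_max, hidden, rng)

    def forward(self, batch: GraphBatch) -> Tensor:
        return self.head(self.encoder(batch), batch)

    def predict(self, structures) -> np.ndarray:
        """Predicted energies, shape (B, n_out); ascending for the H head."""
        batch = GraphBatch(structures, self.encoder_config)
        return self.forward(batch).data

    def pseudo_hamiltonians(self, structures) -> np.ndarray:
        if self.head_type != "hamiltonian":
            raise ValueError("only the pseudo-Hamiltonian head exposes matrices")
        batch = GraphBatch(structures, self.encoder_config)
        return self.head.matrix(self.encoder(batch), batch).data

    def parameters(self) -> list[Tensor]:
        return self.encoder.parameters() + self.head.parameters()

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- checkpointing ----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint does not match the architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint array shape mismatch")
            p.data = np.array(a, dtype=float)
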