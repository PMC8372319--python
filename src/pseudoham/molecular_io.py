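"""Molecular geometries, eigenvalue records, neighbor lists and dataset splits.

Unit contract at every module boundary: coordinates in Å, energies in eV.
Geometries travel as (multi-frame) XYZ; eigenvalue labels travel as a flat
CSV table with one row per (molecule, level-of-theory) pair.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtomicStructure",
    "EigenvalueRecord",
    "NeighborList",
    "DatasetSplit",
    "read_xyz",
    "write_xyz",
    "build_neighbor_list",
    "split_dataset",
    "read_eigenvalue_table",
    "write_eigenvalue_table",
    "SYMBOL_TO_Z",
    "Z_TO_SYMBOL",
]

# Enough of the periodic table for organic molecules; extend as needed.
SYMBOL_TO_Z = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "Br": 35, "I": 53,
}
Z_TO_SYMBOL = {z: s for s, z in SYMBOL_TO_Z.items()}

MIN_INTERATOMIC_DISTANCE = 0.3  # Å; guards degenerate geometries


class XYZParseError(ValueError):
    """Raised for malformed XYZ input; message names the offending line."""


@dataclass
class AtomicStructure:
    """A molecule: atomic numbers plus Cartesian coordinates in Å."""

    elements: np.ndarray  # (N_a,) int
    positions: np.ndarray  # (N_a, 3) float, Å
    id: str = ""

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.elements.ndim != 1 or self.elements.size < 1:
            raise ValueError("structure needs at least one atom")
        if np.any(self.elements < 1):
            raise ValueError("atomic numbers must be >= 1")
        if self.positions.shape != (self.elements.size, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{self.elements.size} atoms"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.n_atoms > 1:
            d = pairwise_distances(self.positions)
            np.fill_diagonal(d, np.inf)
            if d.min() < MIN_INTERATOMIC_DISTANCE:
                raise ValueError(
                    f"atoms closer than {MIN_INTERATOMIC_DISTANCE} Å "
                    f"(min distance {d.min():.3f} Å)"
                )

    @property
    def n_atoms(self) -> int:
        return int(self.elements.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AtomicStructure):
            return NotImplemented
        return (
            np.array_equal(self.elements, other.elements)
            and np.array_equal(self.positions, other.positions)
            and self.id == other.id
        )


@dataclass
class EigenvalueRecord:
    """Fixed-length padded target energies with a validity mask.

    ``values[i]`` is meaningful only where ``mask[i]`` is True; valid slots
    are ascending and always precede the padding slots (padding value 0.0 is
    never read). ``n_occupied`` counts occupied levels among the valid slots,
    so the HOMO sits at slot ``n_occupied - 1`` and the LUMO at
    ``n_occupied`` when present.
    """

    values: np.ndarray  # (n_max,) float, eV
    mask: np.ndarray  # (n_max,) bool
    n_occupied: int
    level_tag: str = "base"
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 1:
            raise ValueError("values and mask must be 1-D and equally long")
        n_valid = int(self.mask.sum())
        if n_valid and not np.all(self.mask[:n_valid]):
            raise ValueError("padding slots must trail the valid slots")
        v = self.values[: n_valid]
        if n_valid > 1 and np.any(np.diff(v) < -1e-12):
            raise ValueError("valid eigenvalues must be ascending")
        if not (0 <= self.n_occupied <= n_valid):
            raise ValueError("n_occupied out of range")

    @property
    def n_max(self) -> int:
        return int(self.values.size)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def homo(self) -> float:
        if self.n_occupied < 1:
            raise ValueError("record has no occupied level in the window")
        return float(self.values[self.n_occupied - 1])

    def lumo(self) -> float:
        if self.n_occupied >= self.n_valid:
            raise ValueError("record has no virtual level in the window")
        return float(self.values[self.n_occupied])

    def gap(self) -> float:
        return self.lumo() - self.homo()


@dataclass
class NeighborList:
    """Symmetric ordered-pair list of atoms within a cutoff radius."""

    pairs: np.ndarray  # (n_pairs, 2) int, ordered (a, b), a != b
    distances: np.ndarray  # (n_pairs,) float, Å
    cutoff: float

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])


@dataclass
class DatasetSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int = 0

    def __iter__(self):
        return iter((self.train, self.validation, self.test))


def pairwise_distances(positions: np.ndarray) -> np.ndarray:
    diff = positions[:, None, :] - positions[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=-1))


# ---------------------------------------------------------------------------
# XYZ I/O

_COMMENT_KV = re.compile(r"(\w+)=(\S+)")


def _parse_comment(comment: str) -> dict:
    """Extract key=value pairs from an XYZ comment line (arbitrary text ok)."""
    return dict(_COMMENT_KV.findall(comment))


def read_xyz(path: str | Path) -> list[AtomicStructure]:
    """Read a (multi-frame) XYZ file into a list of structures.

    The comment line may carry ``key=value`` metadata; an ``id=...`` entry
    becomes the structure id. Raises :class:`XYZParseError` naming the line
    number for malformed input.
    """
    lines = Path(path).read_text().splitlines()
    structures: list[AtomicStructure] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate trailing blank lines
            i += 1
            continue
        try:
            n_atoms = int(lines[i].strip())
        except ValueError:
            raise XYZParseError(
                f"line {i + 1}: expected an atom count, got {lines[i]!r}"
            ) from None
        if i + 2 + n_atoms > len(lines):
            raise XYZParseError(
                f"line {i + 1}: frame declares {n_atoms} atoms but file ends early"
            )
        comment = lines[i + 1]
        meta = _parse_comment(comment)
        elements = np.empty(n_atoms, dtype=int)
        positions = np.empty((n_atoms, 3), dtype=float)
        for a in range(n_atoms):
            ln = i + 2 + a
            if ln >= len(lines):
                raise XYZParseError(f"line {ln + 1}: unexpected end of file")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise XYZParseError(f"line {ln + 1}: expected 'Symbol x y z'")
            sym = parts[0]
            if sym not in SYMBOL_TO_Z:
                raise XYZParseError(f"line {ln + 1}: unknown element symbol {sym!r}")
            elements[a] = SYMBOL_TO_Z[sym]
            try:
                positions[a] = [float(p) for p in parts[1:4]]
            except ValueError:
                raise XYZParseError(
                    f"line {ln + 1}: non-numeric coordinate in {lines[ln]!r}"
                ) from None
        structures.append(
            AtomicStructure(elements, positions, id=meta.get("id", str(frame)))
        )
        i += 2 + n_atoms
        frame += 1
    return structures


def write_xyz(
    structures: Sequence[AtomicStructure],
    path: str | Path,
    extra_comment: str = "",
) -> None:
    """Write structures as multi-frame XYZ with 8-decimal coordinates."""
    out = []
    for s in structures:
        out.append(str(s.n_atoms))
        comment = f"id={s.id}" if s.id else ""
        if extra_comment:
            comment = f"{comment} {extra_comment}".strip()
        out.append(comment)
        for z, (x, y, zz) in zip(s.elements, s.positions):
            sym = Z_TO_SYMBOL.get(int(z))
            if sym is None:
                raise ValueError(f"no symbol for atomic number {z}")
            out.append(f"{sym} {x:.8f} {y:.8f} {zz:.8f}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# Neighbor lists

def build_neighbor_list(structure: AtomicStructure, cutoff: float) -> NeighborList:
    """All ordered atom pairs (a, b), a ≠ b, with d_ab ≤ cutoff (open boundary)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = pairwise_distances(structure.positions)
    np.fill_diagonal(d, np.inf)
    a, b = np.nonzero(d <= cutoff)
    pairs = np.stack([a, b], axis=1) if a.size else np.empty((0, 2), dtype=int)
    return NeighborList(pairs=pairs, distances=d[a, b], cutoff=float(cutoff))


# ---------------------------------------------------------------------------
# Dataset splits

def split_dataset(
    n_items: int, fractions: tuple[float, float, float], seed: int
) -> DatasetSplit:
    """Deterministic disjoint train/validation/test split.

    Sizes are the rounded fractions; any remainder goes to train.
    """
    if n_items < 3:
        raise ValueError("need at least 3 items to populate all splits")
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be 3 positive reals")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n_val = max(1, round(fractions[1] * n_items))
    n_test = max(1, round(fractions[2] * n_items))
    n_train = n_items - n_val - n_test
    if n_train < 1:
        raise ValueError("fractions leave no training items")
    perm = np.random.default_rng(seed).permutation(n_items)
    return DatasetSplit(
        train=np.sort(perm[:n_train]),
        validation=np.sort(perm[n_train : n_train + n_val]),
        test=np.sort(perm[n_train + n_val :]),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Eigenvalue tables (CSV: id, level_tag, n_occupied, e_0..e_{n_max-1}, m_0..)

def write_eigenvalue_table(records: Sequence[EigenvalueRecord], path: str | Path) -> None:
    if not records:
        raise ValueError("no records to write")
    n_max = records[0].n_max
    rows = []
    for r in records:
        if r.n_max != n_max:
            raise ValueError("all records in one table must share n_max")
        row = {"id": r.id, "level_tag": r.level_tag, "n_occupied": r.n_occupied}
        row.update({f"e_{i}": r.values[i] for i in range(n_max)})
        row.update({f"m_{i}": int(r.mask[i]) for i in range(n_max)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_eigenvalue_table(path: str | Path) -> list[EigenvalueRecord]:
    df = pd.read_csv(path)
    e_cols = sorted(
        (c for c in df.columns if c.startswith("e_")), key=lambda c: int(c[2:])
    )
    m_cols = sorted(
        (c for c in df.columns if c.startswith("m_")), key=lambda c: int(c[2:])
    )
    records = []
    for _, row in df.iterrows():
        records.append(
            EigenvalueRecord(
                values=row[e_cols].to_numpy(dtype=float),
                mask=row[m_cols].to_numpy(dtype=float) > 0.5,
                n_occupied=int(row["n_occupied"]),
                level_tag=str(row["level_tag"]),
                id=str(row["id"]),
            )
        )
    return records
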