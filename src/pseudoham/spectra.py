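"""Broadened photoemission-style spectra from eigenvalue sets.

Stick spectra are convolved with a Pseudo-Voigt lineshape — a weighted sum of
a Lorentzian and a Gaussian sharing one full width at half maximum Γ, each
unit-area normalized before mixing:

    PV(x; c) = η·L(x; c, Γ) + (1 − η)·G(x; c, Γ)
    L(x; c)  = (Γ/2π) / ((x − c)² + (Γ/2)²)
    G(x; c)  = (2/Γ)·√(ln 2/π)·exp(−4 ln 2 (x − c)²/Γ²)

The photoemission default mixes 30% Lorentzian with 70% Gaussian. Intensities
are unit-weight per state (no photoionization cross sections), so the
integral of a spectrum equals the number of selected states. A plain Gaussian
envelope summed over many records visualizes dataset-level shifts between
levels of theory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .molecular_io import EigenvalueRecord

__all__ = [
    "SpectrumParams",
    "Spectrum",
    "pseudo_voigt",
    "make_spectrum",
    "gaussian_envelope",
    "spectrum_error",
]

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class SpectrumParams:
    eta: float = 0.3  # Lorentzian fraction
    fwhm: float = 0.5  # Γ, eV
    grid_low: float = -30.0  # eV
    grid_high: float = 5.0  # eV
    grid_step: float = 0.01  # eV
    mode: str = "occupied"  # 'occupied' | 'all' | 'markers'

    def __post_init__(self):
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.fwhm <= 0 or self.grid_step <= 0:
            raise ValueError("fwhm and grid step must be positive")
        if self.grid_high <= self.grid_low:
            raise ValueError("grid bounds must be ordered")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_high - self.grid_low) / self.grid_step)) + 1
        return self.grid_low + self.grid_step * np.arange(n)


@dataclass
class Spectrum:
    """Energy grid (eV) and intensity (states/eV) with provenance metadata."""

    energies: np.ndarray
    intensities: np.ndarray
    params: SpectrumParams | None = None
    level_tag: str = ""

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.energies.shape != self.intensities.shape:
            raise ValueError("grid and intensity shapes differ")
        steps = np.diff(self.energies)
        if steps.size and (np.any(steps <= 0) or np.ptp(steps) > 1e-9):
            raise ValueError("grid must be strictly increasing and uniform")

    def area(self) -> float:
        return float(np.trapezoid(self.intensities, self.energies))


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    hwhm = fwhm / 2.0
    return (hwhm / np.pi) / ((x - center) ** 2 + hwhm**2)


def _gaussian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    return (2.0 / fwhm) * np.sqrt(LN2 / np.pi) * np.exp(
        -4.0 * LN2 * (x - center) ** 2 / fwhm**2
    )


def pseudo_voigt(
    x: np.ndarray | float, center: float, params: SpectrumParams
) -> np.ndarray | float:
    """Unit-area Pseudo-Voigt profile η·L + (1−η)·G at position(s) ``x``."""
    x = np.asarray(x, dtype=float)
    out = params.eta * _lorentzian(x, center, params.fwhm) + (
        1.0 - params.eta
    ) * _gaussian(x, center, params.fwhm)
    return float(out) if out.ndim == 0 else out


def _selected_states(record: EigenvalueRecord, mode: str) -> np.ndarray:
    if mode == "occupied":
        return record.values[: record.n_occupied]
    if mode in ("all", "markers"):
        return record.valid_values
    raise ValueError(f"unknown spectrum mode {mode!r}")


def make_spectrum(
    record: EigenvalueRecord, params: SpectrumParams = SpectrumParams()
) -> Spectrum:
    """Sum of unit-weight Pseudo-Voigt lineshapes over the selected states.

    'occupied' mode (photoemission) uses the occupied levels only; 'all' uses
    every valid state. Errors if no state is selected or none lies within 5Γ
    of the grid.
    """
    centers = _selected_states(record, params.mode)
    if centers.size == 0:
        raise ValueError("no states selected for the spectrum")
    grid = params.grid()
    near = (centers >= grid[0] - 5 * params.fwhm) & (
        centers <= grid[-1] + 5 * params.fwhm
    )
    if not np.any(near):
        raise ValueError("no selected state lies within 5 FWHM of the grid")
    intensity = np.zeros_like(grid)
    for c in centers:
        intensity += pseudo_voigt(grid, float(c), params)
    return Spectrum(grid, intensity, params=params, level_tag=record.level_tag)


def gaussian_envelope(
    records: Sequence[EigenvalueRecord],
    width: float = 0.5,
    grid: np.ndarray | None = None,
    params: SpectrumParams | None = None,
) -> Spectrum:
    """Unit-area Gaussians of FWHM ``width`` over every valid eigenvalue, summed.

    The dataset-level density-of-states envelope used to visualize shifts
    between levels of theory.
    """
    if not records:
        raise ValueError("empty record collection")
    if params is None:
        all_vals = np.concatenate([r.valid_values for r in records])
        params = SpectrumParams(
            eta=0.0,
            fwhm=width,
            grid_low=float(all_vals.min() - 4 * width),
            grid_high=float(all_vals.max() + 4 * width),
        )
    else:
        params = replace(params, eta=0.0, fwhm=width)
    x = params.grid() if grid is None else np.asarray(grid, dtype=float)
    intensity = np.zeros_like(x)
    for r in records:
        for c in r.valid_values:
            intensity += _gaussian(x, float(c), width)
    return Spectrum(x, intensity, params=params, level_tag=records[0].level_tag)


def spectrum_error(
    pred: Spectrum, ref: Spectrum, peak_window: float | None = None
) -> tuple[float, float]:
    """MAE and RMSE of intensities near the reference spectrum's peaks.

    Only grid points within ``peak_window`` (default: the reference FWHM) of a
    local maximum of the reference intensity are compared.
    """
    if pred.energies.shape != ref.energies.shape or np.any(
        np.abs(pred.energies - ref.energies) > 1e-9
    ):
        raise ValueError("spectra must share one grid")
    if peak_window is None:
        peak_window = ref.params.fwhm if ref.params is not None else 0.5
    y = ref.intensities
    interior = np.zeros_like(y, dtype=bool)
    interior[1:-1] = (y[1:-1] >= y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] > 0)
    peaks = ref.energies[interior]
    if peaks.size == 0:
        raise ValueError("reference spectrum has no local maxima")
    near = np.any(
        np.abs(ref.energies[:, None] - peaks[None, :]) <= peak_window, axis=1
    )
    diff = pred.intensities[near] - ref.intensities[near]
    return float(np.mean(np.abs(diff))), float(np.sqrt(np.mean(diff**2)))
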