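# pseudoham

Molecular orbital and quasiparticle energies predicted as the **eigenvalues of a
learned symmetric pseudo-Hamiltonian**, with Δ-learning level-of-theory
correction and Pseudo-Voigt photoemission spectra. Pure NumPy (including a
small reverse-mode autodiff engine with an analytic backward pass through
symmetric eigendecomposition); runs on one CPU.

## The idea

A molecule's frontier orbital energies are the eigenvalues of an electronic
Hamiltonian. Instead of regressing each energy independently (one network per
state, "1S") or regressing the sorted vector of energies directly ("MS"), this
package's headline model predicts a small symmetric matrix **H**(molecule) —
a *pseudo-Hamiltonian* — and returns its eigenvalues as the orbital energies:

1. A SchNet-style message-passing encoder (element embeddings, Gaussian radial
   basis filters, cosine cutoff, shifted-softplus nonlinearities) produces
   atom-wise features that are invariant to rotation/translation and
   equivariant to atom permutation.
2. Sum pooling and a small MLP produce the upper triangle of an
   `n_max × n_max` matrix, which is symmetrized bitwise.
3. `eigvalsh` converts the matrix into `n_max` ascending energies; training
   backpropagates through the diagonalization with the analytic gradient
   ∂ε_i/∂H = u_i u_iᵀ.

Because the output is an eigenvalue spectrum by construction, the model
inherits the qualitative behavior of real spectra: levels are ordered, may
touch but not cross discontinuously along a geometry path, and respond
smoothly to deformations — properties a plain vector regressor has to learn
the hard way. Variable numbers of target states per molecule are handled by a
masked loss (padding slots contribute exactly zero loss and gradient).

Two companion components complete the workflow:

* **Δ-learning** (`DeltaCorrector`): given a base model trained on cheap
  labels, a small second network learns the per-state difference to an
  expensive level of theory from a fraction of the data; the correction is
  exact addition, so a perfect delta reproduces the high-level reference
  exactly.
* **Spectra** (`make_spectrum`, `gaussian_envelope`): unit-area Pseudo-Voigt
  broadening of predicted levels into photoemission-like spectra, plus
  Gaussian density-of-states envelopes over molecule ensembles.

Everything is testable end-to-end against a built-in **synthetic tight-binding
oracle**: an extended-Hückel-style Hamiltonian (distance-decaying couplings,
element-specific onsite energies) labels arbitrary H/C/N/O geometries, and a
synthetic "high level" applies a size-dependent gap-widening shift. Four
datasets are generated from one seed: a perturbed-water ensemble (A), an
interpolation path through eigenvalue crossings (B), random cross-compound
chains (C), and the same compounds at both levels of theory (D).

## Worked example

```python
import numpy as np
from pseudoham import (
    OrbitalEnergyRegressor, DeltaCorrector, make_benchmark_suite,
    make_spectrum, SpectrumParams,
)

suite = make_benchmark_suite(seed=0, n_ensemble=400, n_path=2, n_compounds=0)
data = suite["A"]                      # 400 perturbed water molecules
X, y = data.structures, data.records   # structures + masked eigenvalue records

model = OrbitalEnergyRegressor(head="hamiltonian", n_max=6, seed=0,
                               max_epochs=60)
model.fit(X[:300], y[:300])

pred = model.predict(X[300:])          # (100, 6) ascending energies in eV
print("test MAE:", -model.score(X[300:], y[300:]))

H = model.pseudo_hamiltonians(X[300:303])   # the learned matrices themselves
assert np.array_equal(H, np.swapaxes(H, 1, 2))

spec = make_spectrum(y[300], SpectrumParams(eta=0.3, fwhm=0.5,
                                            grid_low=-80, grid_high=5))
print("integrated states:", spec.area())
```

Δ-learning on the two-level dataset:

```python
d = make_benchmark_suite(seed=0, n_ensemble=0, n_path=2, n_compounds=300)["D"]
base = OrbitalEnergyRegressor(head="hamiltonian", n_max=12, seed=0,
                              max_epochs=60).fit(d.structures, d.base_records)
corr = DeltaCorrector(base=base, seed=0, max_epochs=60).fit(
    d.structures[:25], d.high_records[:25])     # 1/12 of the data
corrected = corr.predict(d.structures)          # base + learned delta
```

## Command-line workflow

```bash
pseudoham generate  --seed 0 --out runs/data            # XYZ + eigenvalue CSVs
pseudoham train     --structures runs/data/A.xyz --targets runs/data/A_base.csv \
                    --out runs/model --head hamiltonian --n-max 6
pseudoham predict   --model runs/model --structures runs/data/A.xyz --out runs/pred.csv
pseudoham evaluate  --pred runs/pred.csv --targets runs/data/A_base.csv --out runs/metrics.json
pseudoham spectrum  --targets runs/data/A_base.csv --id <molecule-id> --out runs/spec.csv
pseudoham delta-train --base runs/model --structures runs/data/D.xyz \
                    --targets runs/data/D_high.csv --out runs/delta
pseudoham benchmark --which fig1 --seed 0 --out runs/bench
```

Every command resolves its configuration as *defaults ← YAML config file ←
flags* (flags win), rejects unknown keys, and writes the resolved config, its
SHA-256 hash, and a checksum manifest next to its outputs, so any artifact is
regenerable from the files beside it. All commands are pure functions of
(resolved config, seed) in single-thread mode.

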