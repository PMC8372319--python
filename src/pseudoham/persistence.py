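"""Save and load fitted estimators as plain files.

A model directory contains ``params.json`` (estimator class and constructor
parameters) and ``weights.npz`` (the network parameter arrays); a
``DeltaCorrector`` directory nests its frozen base model under ``base/`` and
its delta network under ``delta/``. Loading reconstructs the estimator without
refitting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .delta_ml import DeltaCorrector
from .encoder import EncoderConfig
from .heads import EigenvalueNet
from .models import OrbitalEnergyRegressor

__all__ = ["save_model", "load_model"]


def _build_net(model: OrbitalEnergyRegressor, head_type: str, n_out: int, seed: int):
    cfg = EncoderConfig(
        n_features=model.n_features,
        n_interactions=model.n_interactions,
        n_rbf=model.n_rbf,
        cutoff=model.cutoff,
    )
    return EigenvalueNet(
        head_type, model.n_max, cfg, model._hidden_for(n_out), seed=seed
    )


def _save_regressor(model: OrbitalEnergyRegressor, directory: Path) -> None:
    directory.mkdir(parents=True, exist_ok=True)
    params = model.get_params(deep=False)
    meta = {"class": "OrbitalEnergyRegressor", "params": params}
    (directory / "params.json").write_text(json.dumps(meta, indent=1))
    if model.head == "1s":
        arrays = {
            f"net{k}_p{i}": arr
            for k, net in enumerate(model.net_)
            for i, arr in enumerate(net.state_arrays())
        }
    else:
        arrays = {f"net0_p{i}": arr for i, arr in enumerate(model.net_.state_arrays())}
    np.savez(directory / "weights.npz", **arrays)


def _load_regressor(directory: Path) -> OrbitalEnergyRegressor:
    meta = json.loads((directory / "params.json").read_text())
    model = OrbitalEnergyRegressor(**meta["params"])
    with np.load(directory / "weights.npz") as data:
        if model.head == "1s":
            nets = []
            for slot in range(model.n_max):
                net = _build_net(model, "scalar", 1, model.seed + 1000 * slot)
                net.load_state_arrays(
                    [data[f"net{slot}_p{i}"] for i in range(len(net.parameters()))]
                )
                nets.append(net)
            model.net_ = nets
            model.n_parameters_ = sum(n.n_parameters for n in nets)
        else:
            head_type = "hamiltonian" if model.head == "hamiltonian" else "ms"
            n_out = (
                model.n_max * (model.n_max + 1) // 2
                if head_type == "hamiltonian"
                else model.n_max
            )
            net = _build_net(model, head_type, n_out, model.seed)
            net.load_state_arrays(
                [data[f"net0_p{i}"] for i in range(len(net.parameters()))]
            )
            model.net_ = net
            model.n_parameters_ = net.n_parameters
    model.history_ = {}
    return model


def save_model(model, directory: str | Path) -> None:
    """Persist a fitted estimator to ``directory`` (created if needed)."""
    directory = Path(directory)
    if isinstance(model, OrbitalEnergyRegressor):
        if not hasattr(model, "net_"):
            raise ValueError("model is not fitted")
        _save_regressor(model, directory)
    elif isinstance(model, DeltaCorrector):
        if not hasattr(model, "delta_model_"):
            raise ValueError("corrector is not fitted")
        directory.mkdir(parents=True, exist_ok=True)
        params = {
            k: v for k, v in model.get_params(deep=False).items() if k != "base"
        }
        meta = {"class": "DeltaCorrector", "params": params}
        (directory / "params.json").write_text(json.dumps(meta, indent=1))
        _save_regressor(model.base, directory / "base")
        _save_regressor(model.delta_model_, directory / "delta")
    else:
        raise TypeError(f"cannot save objects of type {type(model).__name__}")


def load_model(directory: str | Path):
    """Load a model saved by :func:`save_model`."""
    directory = Path(directory)
    meta = json.loads((directory / "params.json").read_text())
    if meta["class"] == "OrbitalEnergyRegressor":
        return _load_regressor(directory)
    if meta["class"] == "DeltaCorrector":
        base = _load_regressor(directory / "base")
        corrector = DeltaCorrector(base=base, **meta["params"])
        corrector.delta_model_ = _load_regressor(directory / "delta")
        corrector.n_parameters_ = corrector.delta_model_.n_parameters_
        return corrector
    raise ValueError(f"unknown model class {meta['class']!r}")
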