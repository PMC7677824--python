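"""Serialize a fitted factor model as a directory of TSV matrices + manifest."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import FactorModel

__all__ = ["save_model", "load_model"]


def save_model(
    model: FactorModel,
    path,
    *,
    hyperparams: Optional[dict] = None,
    objective_trace: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, M in (("P", model.P), ("D", model.D), ("Q", model.Q)):
        np.savetxt(path / f"{name}.tsv", M, delimiter="\t")
    manifest = {
        "shapes": {"P": list(model.P.shape), "D": list(model.D.shape), "Q": list(model.Q.shape)},
        "hyperparams": hyperparams or {},
        "objective_trace": list(map(float, objective_trace or [])),
        "seed": seed,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(path) -> tuple[FactorModel, dict]:
    path = Path(path)
    mats = {
        name: np.atleast_2d(np.loadtxt(path / f"{name}.tsv", delimiter="\t"))
        for name in ("P", "D", "Q")
    }
    manifest = json.loads((path / "manifest.json").read_text())
    model = FactorModel(P=mats["P"], D=mats["D"], Q=mats["Q"])
    expect = manifest.get("shapes", {})
    for name in ("P", "D", "Q"):
        if expect.get(name) and list(getattr(model, name).shape) != expect[name]:
            raise ValueError(f"{name}.tsv shape does not match the manifest")
    return model, manifest
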