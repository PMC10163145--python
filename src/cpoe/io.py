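"""Dataset I/O, standardization, and text-based model persistence."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .kernels import build_kernel, spec_to_config
from .model import CPoEModel

__all__ = ["TabularData", "read_dataset", "write_dataset",
           "save_model", "load_model"]

SCHEMA_VERSION = 1


@dataclass
class TabularData:
    """Design matrix / response pair with optional z-score standardization."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list
    target: str
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None
    y_mean: float | None = None
    y_std: float | None = None

    @property
    def standardized(self) -> bool:
        return self.y_mean is not None

    def unstandardize_prediction(self, mean: np.ndarray, var: np.ndarray):
        """Map predictions on the standardized scale back to response units."""
        if not self.standardized:
            return mean, var
        return mean * self.y_std + self.y_mean, var * self.y_std ** 2


def read_dataset(path, target: str, standardize: bool = False) -> TabularData:
    """Read a numeric CSV with header; split the target column off."""
    df = pd.read_csv(path)
    if target not in df.columns:
        raise ValueError(f"target column {target!r} not in {list(df.columns)}")
    if df.isna().any().any():
        raise ValueError("dataset contains missing values")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in dataset: {exc}") from exc
    y = values[target].to_numpy()
    feats = [c for c in values.columns if c != target]
    if not feats:
        raise ValueError("no feature columns left after removing the target")
    X = values[feats].to_numpy()
    data = TabularData(X=X, y=y, feature_names=feats, target=target)
    if standardize:
        data.x_mean = X.mean(axis=0)
        data.x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        data.y_mean = float(y.mean())
        data.y_std = float(y.std()) or 1.0
        data.X = (X - data.x_mean) / data.x_std
        data.y = (y - data.y_mean) / data.y_std
    return data


def write_dataset(path, X: np.ndarray, y: np.ndarray,
                  feature_names: list | None = None, target: str = "y") -> None:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    feature_names = feature_names or [f"x{i + 1}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=feature_names)
    df[target] = np.asarray(y, dtype=float).ravel()
    df.to_csv(path, index=False)


def _sparse_to_triplets(A: sparse.spmatrix) -> dict:
    coo = A.tocoo()
    return {"shape": list(coo.shape), "row": coo.row.tolist(),
            "col": coo.col.tolist(), "data": coo.data.tolist()}


def save_model(path, model: CPoEModel) -> None:
    """Persist a fitted model as a JSON archive.

    The archive stores the kernel configuration, the approximation settings,
    the training data and the expert graph, plus the sparse posterior in
    coordinate-triplet form for auditability; loading rebuilds the
    factorization deterministically from these ingredients.
    """
    model._check_fitted()
    doc = {
        "schema": SCHEMA_VERSION,
        "kind": "cpoe",
        "kernel": spec_to_config(model.kernel),
        "settings": {"B": model.B, "C": model.C, "gamma": model.gamma,
                     "seed": model.seed, "mode": model.mode, "Z": model.Z},
        "graph": model.graph.to_dict(),
        "X": model._X.tolist(),
        "y": model._y.tolist(),
        "posterior": {
            "mu": model.post.mu.tolist(),
            "eta": model.post.eta.tolist(),
            "Lambda": _sparse_to_triplets(model.post.Lambda),
            "S": _sparse_to_triplets(model.post.S),
            "lml": model.post.lml,
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> CPoEModel:
    """Rebuild a fitted model from a JSON archive written by :func:`save_model`."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {doc.get('schema')!r}")
    kernel = build_kernel(doc["kernel"])
    s = doc["settings"]
    model = CPoEModel(kernel, B=s["B"], C=s["C"], gamma=s["gamma"],
                      seed=s["seed"], mode=s["mode"], Z=s["Z"])
    model.fit(np.asarray(doc["X"], dtype=float), np.asarray(doc["y"], dtype=float))
    stored = np.asarray(doc["posterior"]["mu"])
    if stored.size != model.post.mu.size or \
            not np.allclose(stored, model.post.mu, atol=1e-6, rtol=1e-6):
        raise ValueError("archive posterior does not match the rebuilt model")
    return model
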