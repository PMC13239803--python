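"""Model-bundle serialization.

A fitted fusion model is stored as a directory with ``meta.json`` (scalars,
hyperparameters, modality codes) and ``arrays.npz`` (documented layout:
``Z`` training loadings, ``S_<m>`` per-modality maps, ``W`` modality
weights, ``beta``/``b0`` prediction head, ``mu_<m>``/``sd_<m>`` feature
standardization, ``a`` modality scales).  Round-trips are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .fusion import FusionHyperparams, FusionResults, project_loadings


@dataclass
class PortableFusionModel:
    """Self-contained fitted model: enough to project and predict without the
    original dataset object."""

    Z: np.ndarray
    S: list[np.ndarray]
    W: np.ndarray
    beta: np.ndarray
    intercept: float
    feature_means: list[np.ndarray]
    feature_sds: list[np.ndarray]
    modality_scales: np.ndarray
    modalities: list[str]
    k: int
    hyperparams: FusionHyperparams

    def project(self, X_new: list[np.ndarray], standardized: bool = False) -> np.ndarray:
        Xs = X_new if standardized else [
            (x - mu) / sd for x, mu, sd in zip(X_new, self.feature_means, self.feature_sds)]
        return project_loadings(Xs, self.S, self.W, self.modality_scales,
                                self.hyperparams.ridge)

    def predict(self, Z: np.ndarray | None = None,
                X_new: list[np.ndarray] | None = None) -> np.ndarray:
        if Z is None:
            Z = self.project(X_new)
        return np.asarray(Z, dtype=float) @ self.beta + self.intercept


def save_model(results: FusionResults | PortableFusionModel, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(results, FusionResults):
        modalities = list(results.model.dataset.modalities)
        hp = results.model.hyperparams
        k = results.k
    else:
        modalities, hp, k = list(results.modalities), results.hyperparams, results.k
    arrays = {"Z": results.Z, "W": results.W, "beta": results.beta,
              "a": np.asarray(results.modality_scales)}
    for m, (s, mu, sd) in enumerate(zip(results.S, results.feature_means,
                                        results.feature_sds)):
        arrays[f"S_{m}"] = s
        arrays[f"mu_{m}"] = mu
        arrays[f"sd_{m}"] = sd
    np.savez(out / "arrays.npz", **arrays)
    meta = {"k": int(k), "modalities": modalities, "intercept": float(results.intercept),
            "hyperparams": asdict(hp), "format": "atnfuse-model-bundle-v1"}
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def load_model(in_dir: str | Path) -> PortableFusionModel:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    with np.load(src / "arrays.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    M = len(meta["modalities"])
    return PortableFusionModel(
        Z=arrays["Z"], S=[arrays[f"S_{m}"] for m in range(M)], W=arrays["W"],
        beta=arrays["beta"], intercept=float(meta["intercept"]),
        feature_means=[arrays[f"mu_{m}"] for m in range(M)],
        feature_sds=[arrays[f"sd_{m}"] for m in range(M)],
        modality_scales=arrays["a"], modalities=meta["modalities"],
        k=int(meta["k"]), hyperparams=FusionHyperparams(**meta["hyperparams"]))
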