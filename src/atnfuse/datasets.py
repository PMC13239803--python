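"""Containers for multimodal subject-by-feature datasets and their on-disk bundle format.

A dataset holds one matrix per imaging modality (subjects x features, shared
subject order), a phenotype table (clinical target, site, scanner, diagnosis
band, genetic-risk carrier flag, optional CSF biomarkers) and, for simulated
data, the generating ground truth.  The interchange format is plain TSV: one
matrix file per modality, one phenotype table, and a JSON ground-truth
sidecar, so every artifact stays auditable with standard tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical modality codes: gray matter density, cortical thickness,
#: pial surface area, amyloid PET Centiloid, tau PET SUVR
DEFAULT_MODALITIES = ("GM", "CT", "PSA", "AMY", "TAU")

PHENO_COLUMNS = [
    "subject_id", "target", "site", "scanner", "diagnosis", "carrier",
    "age", "sex", "csf_abeta42", "csf_ptau181", "csf_offset_days",
]


@dataclass
class GroundTruth:
    """Generating parameters of a simulated dataset.

    loadings_true : (N, K_true) latent subject loadings.
    maps_true : per-modality (P_m, K_true) sparse spatial maps.
    modality_weights_true : per-modality length-K_true nonnegative weights.
    beta_true : length-K_true target coefficients (sparse support).
    noise_sd_per_modality : feature-noise SD actually used per modality.
    batch_gamma / batch_delta : per-scanner additive / multiplicative
        feature-wise batch effects, keyed by scanner label, per modality.
    carrier_component_index : component whose loading drives the carrier label.
    """

    loadings_true: np.ndarray
    maps_true: list[np.ndarray]
    modality_weights_true: np.ndarray  # (M, K_true), >= 0
    beta_true: np.ndarray
    noise_sd_per_modality: np.ndarray
    batch_gamma: dict[str, list[np.ndarray]] = field(default_factory=dict)
    batch_delta: dict[str, list[np.ndarray]] = field(default_factory=dict)
    carrier_component_index: int = 0
    target_linear: np.ndarray | None = None  # pre-clip linear score (signal part)

    def to_json(self) -> str:
        def enc(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, list):
                return [enc(v) for v in x]
            if isinstance(x, dict):
                return {k: enc(v) for k, v in x.items()}
            return x

        payload = {
            "loadings_true": enc(self.loadings_true),
            "maps_true": enc(self.maps_true),
            "modality_weights_true": enc(self.modality_weights_true),
            "beta_true": enc(self.beta_true),
            "noise_sd_per_modality": enc(self.noise_sd_per_modality),
            "batch_gamma": enc(self.batch_gamma),
            "batch_delta": enc(self.batch_delta),
            "carrier_component_index": int(self.carrier_component_index),
            "target_linear": enc(self.target_linear),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            loadings_true=np.asarray(d["loadings_true"], dtype=float),
            maps_true=[np.asarray(m, dtype=float) for m in d["maps_true"]],
            modality_weights_true=np.asarray(d["modality_weights_true"], dtype=float),
            beta_true=np.asarray(d["beta_true"], dtype=float),
            noise_sd_per_modality=np.asarray(d["noise_sd_per_modality"], dtype=float),
            batch_gamma={k: [np.asarray(a, float) for a in v] for k, v in d["batch_gamma"].items()},
            batch_delta={k: [np.asarray(a, float) for a in v] for k, v in d["batch_delta"].items()},
            carrier_component_index=int(d["carrier_component_index"]),
            target_linear=None if d.get("target_linear") is None
            else np.asarray(d["target_linear"], dtype=float),
        )


@dataclass
class MultimodalDataset:
    """Per-subject multimodal feature matrices plus phenotype table.

    X : list of (N, P_m) float arrays, one per modality, shared subject order.
    pheno : DataFrame with columns target, site, scanner, diagnosis, carrier,
        age, sex and optional CSF columns; index = subject_id.
    truth : optional :class:`GroundTruth` for simulated data.
    """

    X: list[np.ndarray]
    pheno: pd.DataFrame
    modalities: list[str]
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        n = {x.shape[0] for x in self.X}
        if len(n) != 1:
            raise ValueError(f"modality matrices disagree on subject count: {sorted(n)}")
        if next(iter(n)) != len(self.pheno):
            raise ValueError("phenotype table and matrices disagree on subject count")
        for m, x in zip(self.modalities, self.X):
            if not np.all(np.isfinite(x)):
                raise ValueError(f"non-finite values in modality {m}")

    @property
    def n_subjects(self) -> int:
        return self.X[0].shape[0]

    @property
    def n_modalities(self) -> int:
        return len(self.X)

    @property
    def target(self) -> np.ndarray:
        return self.pheno["target"].to_numpy(dtype=float)

    @property
    def site(self) -> np.ndarray:
        return self.pheno["site"].to_numpy()

    @property
    def scanner(self) -> np.ndarray:
        return self.pheno["scanner"].to_numpy()


def save_bundle(dataset: MultimodalDataset, out_dir: str | Path) -> Path:
    """Write a dataset bundle: one TSV per modality, phenotype TSV, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = dataset.pheno.index.astype(str)
    for code, x in zip(dataset.modalities, dataset.X):
        cols = [f"f{j:05d}" for j in range(x.shape[1])]
        df = pd.DataFrame(x, columns=cols)
        df.insert(0, "subject_id", ids)
        df.to_csv(out / f"modality_{code}.tsv", sep="\t", index=False, float_format="%.10g")
    pheno = dataset.pheno.reset_index().rename(columns={"index": "subject_id"})
    if "subject_id" not in pheno.columns:
        pheno = pheno.rename(columns={pheno.columns[0]: "subject_id"})
    pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False)
    (out / "modalities.json").write_text(json.dumps(list(dataset.modalities)))
    if dataset.truth is not None:
        (out / "truth.json").write_text(dataset.truth.to_json())
    return out


def load_bundle(in_dir: str | Path) -> MultimodalDataset:
    """Read a dataset bundle written by :func:`save_bundle`."""
    src = Path(in_dir)
    modalities = json.loads((src / "modalities.json").read_text())
    pheno = pd.read_csv(src / "phenotype.tsv", sep="\t").set_index("subject_id")
    X = []
    for code in modalities:
        df = pd.read_csv(src / f"modality_{code}.tsv", sep="\t")
        ids = df["subject_id"].astype(str).to_numpy()
        if not np.array_equal(ids, pheno.index.astype(str).to_numpy()):
            raise ValueError(f"subject order mismatch in modality {code}")
        X.append(df.drop(columns="subject_id").to_numpy(dtype=float))
    truth = None
    tpath = src / "truth.json"
    if tpath.exists():
        truth = GroundTruth.from_json(tpath.read_text())
    return MultimodalDataset(X=X, pheno=pheno, modalities=list(modalities), truth=truth)


def write_matrix_tsv(path: str | Path, matrix: np.ndarray, index: list[str] | None = None,
                     columns: list[str] | None = None, index_name: str = "row") -> None:
    """Write a 2-D array as TSV with row and column labels."""
    m = np.atleast_2d(matrix)
    if columns is None:
        columns = [f"c{j:04d}" for j in range(m.shape[1])]
    if index is None:
        index = [f"r{i:05d}" for i in range(m.shape[0])]
    df = pd.DataFrame(m, columns=columns, index=pd.Index(index, name=index_name))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a TSV written by :func:`write_matrix_tsv`; returns (matrix, index, columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str))
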