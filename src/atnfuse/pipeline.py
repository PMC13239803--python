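"""End-to-end pipeline orchestration with validated configuration.

A :class:`RunConfig` (typically parsed from YAML) drives the full analysis
in order: simulate (or load) the dataset, site-grouped split, supervised
fusion fit, loading projection, harmonization of loadings, mixture
thresholding of spatial maps, transfer classification, and the
component-phenotype validation screen.  Every stage writes a plain-text
artifact plus a manifest line (inputs, outputs, seed, checksum); rerunning
an unchanged config reproduces the checksums of all deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .bundle import save_model
from .classify import FeatureSet, build_comparators, run_transfer_study
from .combat import fit_combat
from .datasets import load_bundle, save_bundle, write_matrix_tsv
from .fusion import FusionHyperparams, SupervisedFusion
from .mixture import fit_mixture
from .screen import correlation_screen, eligible_csf_mask, csf_association
from .simulate import SimulationConfig, generate_dataset, grouped_split

logger = logging.getLogger("atnfuse")


class SimulateStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int
    n_subjects: int = 300
    n_modalities: int = 5
    features_per_modality: int = 2000
    k_true: int = 6
    sparsity: float = 0.2
    snr: float = 5.0
    n_sites: int = 12
    n_scanners: int = 3
    beta_support: int = 3


class SplitStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)


class FitStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int
    k: int = 10
    gamma: float = 1.0
    l1: float = 0.0
    learning_rate: float = 0.01
    batch_size: int = 64
    max_epochs: int = 200
    patience: int = 25


class ThresholdStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mmthresh: float = 0.5


class ClassifyStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int
    n_components: int = 10
    boot_B: int = 200
    include_ica: bool = False


class ValidateStage(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected and every
    stochastic stage carries an explicit seed."""

    model_config = ConfigDict(extra="forbid")
    dataset_dir: str | None = None  # load instead of simulate when set
    simulate: SimulateStage | None = None
    split: SplitStage
    fit: FitStage
    threshold: ThresholdStage = Field(default_factory=ThresholdStage)
    classify: ClassifyStage
    validate_stage: ValidateStage = Field(default_factory=ValidateStage, alias="validate")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def record(self, stage: str, seed, outputs: list[Path]) -> None:
        line = {"stage": stage, "seed": seed, "time": time.time(),
                "outputs": {str(p.name): _sha256(p) for p in outputs}}
        with self.path.open("a") as fh:
            fh.write(json.dumps(line) + "\n")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage; returns a dict of in-memory artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    logger.addHandler(fh)
    logger.setLevel(logging.INFO)
    manifest = _Manifest(out / "manifest.jsonl")
    artifacts: dict = {}
    stage = "config"
    try:
        (out / "config.json").write_text(json.dumps(
            {"config": json.loads(config.model_dump_json()), "version": __version__},
            indent=2))
        manifest.record("config", None, [out / "config.json"])

        stage = "simulate"
        if config.dataset_dir:
            dataset = load_bundle(config.dataset_dir)
            logger.info("loaded dataset from %s", config.dataset_dir)
        else:
            if config.simulate is None:
                raise ValueError("config needs either dataset_dir or a simulate stage")
            sim = config.simulate
            cfg = SimulationConfig(**sim.model_dump())
            dataset = generate_dataset(cfg)
            logger.info("simulated dataset: N=%d M=%d (seed=%d)",
                        dataset.n_subjects, dataset.n_modalities, sim.seed)
        ds_dir = out / "dataset"
        save_bundle(dataset, ds_dir)
        manifest.record("simulate", getattr(config.simulate, "seed", None),
                        sorted(ds_dir.glob("*.tsv")))
        artifacts["dataset"] = dataset

        stage = "split"
        split = grouped_split(dataset.site, config.split.fractions, config.split.seed)
        split_path = out / "split.tsv"
        with split_path.open("w") as f:
            f.write("subject_id\tsplit\n")
            for sid, sp in zip(dataset.pheno.index, split.split):
                f.write(f"{sid}\t{sp}\n")
        manifest.record("split", config.split.seed, [split_path])
        artifacts["split"] = split
        logger.info("split sizes train/val/test = %d/%d/%d (seed=%d)",
                    split.train.size, split.val.size, split.test.size, config.split.seed)

        stage = "fit"
        fit_cfg = config.fit
        hp = FusionHyperparams(gamma=fit_cfg.gamma, l1=fit_cfg.l1,
                               learning_rate=fit_cfg.learning_rate,
                               batch_size=fit_cfg.batch_size,
                               max_epochs=fit_cfg.max_epochs,
                               patience=fit_cfg.patience, seed=fit_cfg.seed)
        results = SupervisedFusion(dataset, split, fit_cfg.k, hp).fit()
        model_dir = save_model(results, out / "model")
        Z_all = results.loadings_all()
        load_path = out / "loadings.tsv"
        write_matrix_tsv(load_path, Z_all, index=list(dataset.pheno.index.astype(str)),
                         columns=[f"comp{k:02d}" for k in range(results.k)],
                         index_name="subject_id")
        manifest.record("fit", fit_cfg.seed, [load_path, model_dir / "meta.json"])
        artifacts["fusion"] = results
        logger.info("fit done: K=%d best epoch %d (seed=%d)", results.k,
                    results.best_epoch, fit_cfg.seed)

        stage = "harmonize"
        combat = fit_combat(Z_all[split.train], dataset.scanner[split.train])
        Z_harm = np.empty_like(Z_all)
        for name in ("train", "val", "test"):
            idx = split.indices(name)
            if idx.size:
                Z_harm[idx] = combat.transform(Z_all[idx], dataset.scanner[idx])
        harm_path = out / "loadings_harmonized.tsv"
        write_matrix_tsv(harm_path, Z_harm, index=list(dataset.pheno.index.astype(str)),
                         columns=[f"comp{k:02d}" for k in range(results.k)],
                         index_name="subject_id")
        manifest.record("harmonize", None, [harm_path])
        artifacts["combat"] = combat
        artifacts["loadings_harmonized"] = Z_harm

        stage = "threshold"
        masks, mixtures = [], []
        for m, (code, S) in enumerate(zip(dataset.modalities, results.S)):
            for k in range(results.k):
                col = S[:, k]
                if np.ptp(col) == 0 or col.size < 100:
                    masks.append(np.zeros(col.size, dtype=bool))
                    mixtures.append({"modality": code, "component": k,
                                     "status": "skipped: degenerate or too few features"})
                    continue
                fit = fit_mixture(col)
                mask, _ = fit.threshold(config.threshold.mmthresh)
                masks.append(mask)
                mixtures.append({"modality": code, "component": k,
                                 "status": "ok", "converged": bool(fit.converged),
                                 "signal_proportion": fit.signal_proportion,
                                 "n_kept": int(mask.sum())})
        mix_path = out / "mixtures.json"
        mix_path.write_text(json.dumps(
            {"mmthresh": config.threshold.mmthresh, "fits": mixtures}, indent=2))
        manifest.record("threshold", None, [mix_path])
        artifacts["masks"] = masks
        artifacts["mixtures"] = mixtures

        stage = "classify"
        fused = FeatureSet("fused_loadings", Z_harm,
                           {"source": "harmonized fusion loadings", "k": results.k})
        comparators = build_comparators(dataset, split,
                                        n_components=config.classify.n_components,
                                        seed=config.classify.seed,
                                        include_ica=config.classify.include_ica)
        # harmonize decomposition-based comparators the same way as loadings
        harmonized_sets = [fused]
        for fs2 in comparators:
            if fs2.name == "demographics":
                harmonized_sets.append(fs2)
                continue
            cb = fit_combat(fs2.matrix[split.train], dataset.scanner[split.train])
            mat = fs2.matrix.copy()
            for name in ("train", "val", "test"):
                idx = split.indices(name)
                if idx.size:
                    mat[idx] = cb.transform(fs2.matrix[idx], dataset.scanner[idx])
            harmonized_sets.append(FeatureSet(fs2.name, mat,
                                              fs2.provenance | {"harmonized": True}))
        report = run_transfer_study(dataset, harmonized_sets, split,
                                    boot_B=config.classify.boot_B,
                                    seed=config.classify.seed)
        rep_path = out / "classification_report.json"
        rep_path.write_text(json.dumps(report.to_dict(), indent=2))
        manifest.record("classify", config.classify.seed, [rep_path])
        artifacts["classification"] = report

        stage = "validate"
        screen = correlation_screen(Z_harm, dataset.target,
                                    alpha=config.validate_stage.alpha)
        screen_path = out / "correlation_screen.tsv"
        screen.to_frame().to_csv(screen_path, sep="\t", index=False)
        csf_out = {}
        csf_mask = eligible_csf_mask(dataset.pheno)
        if csf_mask.sum() >= 3:
            strongest = int(np.argmax(np.abs(screen.r)))
            for marker in ("csf_abeta42", "csf_ptau181"):
                vals = np.where(csf_mask, dataset.pheno[marker].to_numpy(dtype=float),
                                np.nan)
                r, p, n = csf_association(Z_harm, strongest, vals)
                csf_out[marker] = {"component": strongest, "r": r, "p": p, "n": n}
        csf_path = out / "csf_associations.json"
        csf_path.write_text(json.dumps(csf_out, indent=2))
        manifest.record("validate", None, [screen_path, csf_path])
        artifacts["screen"] = screen
        artifacts["csf"] = csf_out
        return artifacts
    except Exception as exc:
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(fh)
        fh.close()
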