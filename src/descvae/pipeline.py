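"""End-to-end workflow orchestration.

Stages: preprocess -> compute descriptors -> select descriptors ->
pretrain VAE (with and/or without the descriptor predictor) -> embed
-> train QSAR models -> compare/diagnose.  Each stage writes its
artifact and a manifest entry (stage name, input content hashes,
derived seed, wall time).  Per-stage seeds are derived
deterministically from the global seed and the stage name, so stages
re-run independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import chem_data, descriptor_selection, qsar_models, synthetic_fixtures, vae_core
from .chem_data import TaskType
from .evaluation import (bootstrap_compare, cluster_error_analysis,
                         dataset_prior_distance, linear_probe)

__all__ = ["RunConfig", "run_workflow", "experiment_variance", "derive_seed"]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Single-file description of a full experiment."""

    output_dir: str = "runs/run"
    seed: int = 0
    task_type: str = "regression"
    # data: either explicit CSV paths or a generated fixture
    target_csv: str | None = None
    smiles_column: str = "smiles"
    label_column: str | None = "y"
    fixture: dict[str, Any] | None = None     # FixtureSpec kwargs
    # descriptor selection
    n_descriptors: int = 3
    variance_threshold: float = 0.5
    r_max: float = 0.9
    candidate_descriptors: list[str] = field(default_factory=lambda: [
        "MolLogP", "MolWt", "TPSA", "NumHAcceptors", "NumHDonors",
        "NumRotatableBonds", "HeavyAtomCount", "NumHeteroatoms",
        "FractionCSP3", "NOCount", "NHOHCount", "LabuteASA",
    ])
    # VAE
    vae: dict[str, Any] = field(default_factory=dict)     # VAEConfig kwargs
    train_plain: bool = True                              # also train lambda_pred=0
    embed_mode: str = "mean"
    # QSAR
    models: list[dict[str, Any]] = field(default_factory=lambda: [
        {"family": "linear"}])
    n_folds: int = 10
    # diagnostics
    n_clusters: int = 5
    bootstrap_trials: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


class _Manifest:
    def __init__(self, out_dir: Path) -> None:
        self.out_dir = out_dir
        self.entries: list[dict[str, Any]] = []

    def record(self, stage: str, seed: int, t0: float,
               artifacts: list[Path], inputs: list[Path] = ()) -> None:
        self.entries.append({
            "stage": stage,
            "seed": seed,
            "wall_time_s": round(time.time() - t0, 3),
            "inputs": {str(p.relative_to(self.out_dir)): _hash_file(p)
                       for p in inputs},
            "artifacts": {str(p.relative_to(self.out_dir)): _hash_file(p)
                          for p in artifacts},
        })

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps({"stages": self.entries}, indent=2))
        return path


def _prepare_dataset(config: RunConfig, out: Path, seed: int
                     ) -> tuple[chem_data.MoleculeDataset, Path]:
    task = TaskType(config.task_type)
    if config.fixture is not None:
        spec = synthetic_fixtures.FixtureSpec(**{**config.fixture, "seed": seed})
        corpus = synthetic_fixtures.generate_corpus(spec)
        dataset = chem_data.MoleculeDataset(
            records=[chem_data.make_record(s) for s in corpus],
            task_type=task, name="fixture")
        table = chem_data.compute_descriptors(dataset, config.candidate_descriptors)
        weights = dict(spec.planted_descriptors) or {"MolLogP": 1.0}
        y = synthetic_fixtures.plant_property(table, weights, spec.noise_sd, seed + 1)
        if task is TaskType.CLASSIFICATION:
            y = (y >= np.median(y)).astype(float)
        dataset = chem_data.MoleculeDataset(
            records=[chem_data.MoleculeRecord(r.raw_smiles, r.canonical_smiles,
                                              r.structure_key, float(v))
                     for r, v in zip(dataset.records, y)],
            task_type=task, name="fixture")
        csv_path = out / "clean.csv"
        pd.DataFrame({"smiles": dataset.smiles, "y": y}).to_csv(csv_path, index=False)
        return dataset, csv_path

    report = chem_data.CurationReport()
    dataset = chem_data.load_dataset(config.target_csv, config.smiles_column,
                                     config.label_column, task, report=report)
    dataset = chem_data.deduplicate(dataset, report=report)
    dataset = chem_data.remove_salts_and_mixtures(dataset, report=report)
    csv_path = out / "clean.csv"
    pd.DataFrame({"smiles": dataset.smiles, "y": dataset.labels}).to_csv(
        csv_path, index=False)
    report.to_json(out / "curation_report.json")
    return dataset, csv_path


def run_workflow(config: RunConfig) -> dict[str, Any]:
    """Execute every stage in order; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out)
    task = TaskType(config.task_type)

    # 1. preprocess ------------------------------------------------------
    t0 = time.time()
    seed = derive_seed(config.seed, "preprocess")
    dataset, csv_path = _prepare_dataset(config, out, seed)
    manifest.record("preprocess", seed, t0, [csv_path])

    # 2. descriptors -----------------------------------------------------
    t0 = time.time()
    seed = derive_seed(config.seed, "descriptors")
    table = chem_data.compute_descriptors(dataset, config.candidate_descriptors)
    desc_path = out / "descriptors.csv"
    table.data.to_csv(desc_path)
    manifest.record("descriptors", seed, t0, [desc_path], [csv_path])

    # 3. selection -------------------------------------------------------
    t0 = time.time()
    seed = derive_seed(config.seed, "select")
    y = dataset.labels
    mask = None
    if task is TaskType.CLASSIFICATION:
        mask = np.isfinite(y)
    result = descriptor_selection.select_descriptors(
        table, y[mask] if mask is not None else y,
        k=config.n_descriptors, variance_threshold=config.variance_threshold,
        r_max=config.r_max, mask=mask)
    sel_path = out / "selection.json"
    sel_path.write_text(json.dumps({
        "selected": result.selected,
        "ranking": result.ranking.entries,
        "removed_low_variance": result.removed_low_variance,
        "removed_intercorrelated": result.removed_intercorrelated,
    }, indent=2))
    manifest.record("select", seed, t0, [sel_path], [desc_path])

    # 4. pretrain --------------------------------------------------------
    t0 = time.time()
    seed = derive_seed(config.seed, "pretrain")
    vae_cfg = vae_core.VAEConfig(**{**config.vae, "seed": seed})
    corpus = dataset.smiles
    sel_table = table.subset(result.selected) if result.selected else None
    model_joint = vae_core.train_vae(vae_cfg, corpus, sel_table,
                                     descriptor_names=result.selected or None)
    joint_dir = out / "model_joint"
    vae_core.save_model(model_joint, joint_dir)
    artifacts = [p for p in joint_dir.iterdir()]
    models = {"joint": model_joint}
    if config.train_plain:
        plain_cfg = vae_core.VAEConfig(**{**config.vae, "seed": seed,
                                          "lambda_pred": 0.0})
        model_plain = vae_core.train_vae(plain_cfg, corpus)
        plain_dir = out / "model_plain"
        vae_core.save_model(model_plain, plain_dir)
        artifacts += list(plain_dir.iterdir())
        models["plain"] = model_plain
    manifest.record("pretrain", seed, t0, artifacts, [csv_path, sel_path])

    # 5. embed -----------------------------------------------------------
    t0 = time.time()
    seed = derive_seed(config.seed, "embed")
    emb_paths = []
    embeddings = {}
    for tag, model in models.items():
        emb = vae_core.embed(model, corpus, mode=config.embed_mode, seed=seed)
        p = out / f"embeddings_{tag}.npz"
        np.savez(p, vectors=emb.vectors, posterior_means=emb.posterior_means,
                 posterior_logvars=emb.posterior_logvars)
        emb_paths.append(p)
        embeddings[tag] = emb
    manifest.record("embed", seed, t0, emb_paths)

    # 6. qsar ------------------------------------------------------------
    t0 = time.time()
    seed = derive_seed(config.seed, "qsar")
    cv_paths = []
    cv_results: dict[str, qsar_models.CVResult] = {}
    y_task = dataset.labels
    for tag, emb in embeddings.items():
        for mspec in config.models:
            spec = qsar_models.ModelSpec(task_type=task, **mspec)
            cv = qsar_models.run_cv(spec, emb.vectors, y_task,
                                    n_folds=config.n_folds, seed=seed)
            key = f"{tag}_{spec.family}"
            cv_results[key] = cv
            p = out / f"cv_{key}.json"
            p.write_text(json.dumps({
                "fold_assignment": cv.fold_assignment.tolist(),
                "predictions": cv.predictions.tolist(),
                "per_fold_metrics": cv.per_fold_metrics,
                "aggregate": {k: list(v) for k, v in cv.aggregate.items()},
            }, indent=2))
            cv_paths.append(p)
    manifest.record("qsar", seed, t0, cv_paths, emb_paths)

    # 7. diagnose --------------------------------------------------------
    t0 = time.time()
    seed = derive_seed(config.seed, "diagnose")
    diag: dict[str, Any] = {}
    first_family = qsar_models.ModelSpec(
        task_type=task, **config.models[0]).family
    if "joint" in models and "plain" in models:
        key_a, key_b = f"joint_{first_family}", f"plain_{first_family}"
        cv_a, cv_b = cv_results[key_a], cv_results[key_b]
        metric = "r2" if task is TaskType.REGRESSION else "accuracy"
        comp = bootstrap_compare(cv_a.predictions, cv_b.predictions, y_task,
                                 cv_a.fold_assignment, metric=metric,
                                 n_trials=config.bootstrap_trials, seed=seed)
        diag["bootstrap"] = {
            "metric": metric, "proportion": comp.proportion,
            "significant": comp.significant, "direction": comp.direction,
        }
    if task is TaskType.REGRESSION:
        emb = embeddings["joint"]
        cv = cv_results[f"joint_{first_family}"]
        cd = cluster_error_analysis(emb, cv.predictions, y_task,
                                    k=min(config.n_clusters, len(y_task)),
                                    seed=seed)
        diag["clusters"] = {"sizes": cd.sizes, "distances": cd.distances,
                            "rmses": cd.rmses}
        if result.selected:
            rm, rs = linear_probe(emb, table.column(result.selected[0]),
                                  n_folds=config.n_folds, seed=seed)
            diag["probe_top_descriptor"] = {"name": result.selected[0],
                                            "rmse_mean": rm, "rmse_sd": rs}
    diag["dataset_prior_distance"] = {
        tag: dataset_prior_distance(model, corpus) for tag, model in models.items()}
    diag_path = out / "diagnostics.json"
    diag_path.write_text(json.dumps(diag, indent=2))
    manifest.record("diagnose", seed, t0, [diag_path], cv_paths)

    path = manifest.write()
    return json.loads(path.read_text())


def experiment_variance(config: RunConfig, n_pretrainings: int = 3,
                        n_embeddings: int = 2) -> dict[str, Any]:
    """Two-level variance decomposition of the aggregate CV metric.

    Level 1 (embedding noise): one pre-trained VAE, the dataset passed
    through its encoder ``n_embeddings`` times with sampled posteriors.
    Level 2 (pre-training noise): ``n_pretrainings`` fresh VAEs, one
    embedding each.  Reports mean and SD of the aggregate metric at
    each level.
    """
    if n_pretrainings < 1 or n_embeddings < 1:
        raise ValueError("repeat counts must be >= 1")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    task = TaskType(config.task_type)
    seed = derive_seed(config.seed, "variance")
    dataset, _ = _prepare_dataset(config, out, seed)
    corpus = dataset.smiles
    y = dataset.labels
    metric = "r2" if task is TaskType.REGRESSION else "accuracy"
    spec = qsar_models.ModelSpec(task_type=task, **config.models[0])

    def agg_score(emb_vectors: np.ndarray, cv_seed: int) -> float:
        cv = qsar_models.run_cv(spec, emb_vectors, y,
                                n_folds=config.n_folds, seed=cv_seed)
        return cv.aggregate[metric][0]

    # level 1: fixed model, repeated sampled embeddings
    base_cfg = vae_core.VAEConfig(**{**config.vae, "seed": seed})
    base_model = vae_core.train_vae(base_cfg, corpus)
    emb_scores = []
    for j in range(n_embeddings):
        emb = vae_core.embed(base_model, corpus, mode="sample", seed=seed + j)
        emb_scores.append(agg_score(emb.vectors, seed))

    # level 2: repeated pre-trainings, one (mean) embedding each
    pre_scores = []
    for i in range(n_pretrainings):
        cfg = vae_core.VAEConfig(**{**config.vae, "seed": seed + 1000 + i})
        model = vae_core.train_vae(cfg, corpus)
        emb = vae_core.embed(model, corpus, mode="mean")
        pre_scores.append(agg_score(emb.vectors, seed))

    def mean_sd(xs):
        return (float(np.mean(xs)),
                float(np.std(xs, ddof=1)) if len(xs) > 1 else 0.0)

    report = {
        "metric": metric,
        "embedding_level": {"scores": emb_scores,
                            "mean": mean_sd(emb_scores)[0],
                            "sd": mean_sd(emb_scores)[1]},
        "pretraining_level": {"scores": pre_scores,
                              "mean": mean_sd(pre_scores)[0],
                              "sd": mean_sd(pre_scores)[1]},
        "n_cv_runs": n_embeddings + n_pretrainings,
    }
    (out / "variance_report.json").write_text(json.dumps(report, indent=2))
    return report
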