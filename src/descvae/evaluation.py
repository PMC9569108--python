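"""Model comparison and latent-space diagnostics.

* Bootstrap model comparison: resample within each CV fold, recompute
  the metric per fold for both candidates, average over folds, and
  count how often each candidate strictly exceeds the other; a pair is
  significantly different when one direction's exceedance proportion
  passes the level (default 95%).
* Expected-KL dataset distance: the mean, over a dataset, of the KL
  divergence between each molecule's encoder posterior and the latent
  prior — how far the dataset sits from the modeled chemical space.
* Linear probe: cross-validated linear regression from frozen
  embeddings to a target, quantifying how much information about the
  target the embeddings retain.
* Cluster diagnostics: K-means over embeddings with per-cluster
  distance-to-prior and held-out prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression

from .qsar_models import metric_accuracy_f1, metric_r2, metric_rmse, make_folds
from .vae_core import EmbeddingMatrix, TrainedVAE, _kl_rows, embed

__all__ = [
    "BootstrapComparison",
    "ClusterDiagnostics",
    "bootstrap_compare",
    "dataset_prior_distance",
    "linear_probe",
    "cluster_error_analysis",
    "pca_project",
]


@dataclass
class BootstrapComparison:
    proportion: float
    n_trials: int
    significant: bool
    metric_name: str
    direction: str           # "a" | "b" | "tie"
    proportion_a: float = 0.0
    proportion_b: float = 0.0


@dataclass
class ClusterDiagnostics:
    cluster_ids: np.ndarray
    sizes: list[int]
    distances: list[float]          # mean KL-to-prior per cluster
    rmses: list[float]              # held-out prediction RMSE per cluster
    member_indices: list[np.ndarray] = field(default_factory=list)
    source_distance: float | None = None


def _metric_fn(metric: str):
    if metric == "r2":
        return metric_r2
    if metric == "rmse":
        return metric_rmse
    if metric == "accuracy":
        return lambda y, p: metric_accuracy_f1(y.astype(int), p.astype(int))[0]
    if metric == "f1":
        return lambda y, p: metric_accuracy_f1(y.astype(int), p.astype(int))[1]
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_compare(pred_a: np.ndarray, pred_b: np.ndarray, y: np.ndarray,
                      fold_assignment: np.ndarray, metric: str = "r2",
                      n_trials: int = 1000, level: float = 0.95,
                      seed: int = 0) -> BootstrapComparison:
    """Pairwise bootstrap comparison of two prediction vectors.

    Per trial, indices are resampled with replacement within each fold;
    the metric is recomputed per fold for both candidates and averaged
    over folds.  Ties count for neither direction, so identical
    candidates give proportion 0.
    """
    pred_a, pred_b, y = map(np.asarray, (pred_a, pred_b, y))
    fold_assignment = np.asarray(fold_assignment)
    if not (len(pred_a) == len(pred_b) == len(y) == len(fold_assignment)):
        raise ValueError("inputs must be aligned")
    fn = _metric_fn(metric)
    folds = [np.flatnonzero(fold_assignment == f)
             for f in np.unique(fold_assignment)]
    rng = np.random.default_rng(seed)
    wins_a = wins_b = 0
    for _ in range(n_trials):
        scores_a, scores_b = [], []
        for idx in folds:
            take = idx[rng.integers(0, len(idx), size=len(idx))]
            try:
                scores_a.append(fn(y[take], pred_a[take]))
                scores_b.append(fn(y[take], pred_b[take]))
            except ValueError:
                continue          # e.g. constant y in a resample for R^2
        if not scores_a:
            continue
        ma, mb = np.mean(scores_a), np.mean(scores_b)
        if ma > mb:
            wins_a += 1
        elif mb > ma:
            wins_b += 1
    pa, pb = wins_a / n_trials, wins_b / n_trials
    proportion = max(pa, pb)
    direction = "tie" if pa == pb else ("a" if pa > pb else "b")
    return BootstrapComparison(
        proportion=proportion, n_trials=n_trials,
        significant=proportion > level, metric_name=metric,
        direction=direction, proportion_a=pa, proportion_b=pb)


def dataset_prior_distance(model: TrainedVAE, smiles: list[str]) -> float:
    """Mean per-molecule KL divergence from the encoder posterior to
    the latent prior N(0, I)."""
    if not smiles:
        raise ValueError("no molecules given")
    emb = embed(model, smiles, mode="mean")
    return float(np.mean(_kl_rows(emb.posterior_means, emb.posterior_logvars)))


def linear_probe(embeddings: EmbeddingMatrix | np.ndarray, target: np.ndarray,
                 n_folds: int = 10, seed: int = 0,
                 standardize_target: bool = True
                 ) -> tuple[float, float]:
    """Cross-validated linear regression of a target on embeddings.

    Returns held-out RMSE mean and SD over folds.  Targets are
    standardized by default so probe errors are comparable across
    descriptors (an uninformative embedding then probes at RMSE ~ 1).
    """
    X = embeddings.vectors if isinstance(embeddings, EmbeddingMatrix) else np.asarray(embeddings)
    target = np.asarray(target, dtype=float)
    if len(X) != len(target):
        raise ValueError("embeddings and target misaligned")
    if target.std() == 0:
        raise ValueError("constant probe target")
    if standardize_target:
        target = (target - target.mean()) / target.std()
    assignment = make_folds(len(target), n_folds, seed)
    rmses = []
    for f in range(n_folds):
        test = assignment == f
        model = LinearRegression()
        model.fit(X[~test], target[~test])
        rmses.append(metric_rmse(target[test], model.predict(X[test])))
    return float(np.mean(rmses)), float(np.std(rmses, ddof=1))


def cluster_error_analysis(embeddings: EmbeddingMatrix,
                           held_out_predictions: np.ndarray, y: np.ndarray,
                           k: int = 10, seed: int = 0,
                           model: TrainedVAE | None = None,
                           source_smiles: list[str] | None = None
                           ) -> ClusterDiagnostics:
    """Seeded K-means over embedding vectors with per-cluster
    expected-KL distance and held-out RMSE."""
    X = embeddings.vectors
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    held_out_predictions = np.asarray(held_out_predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    ids = km.fit_predict(X)
    kl = _kl_rows(embeddings.posterior_means, embeddings.posterior_logvars)
    sizes, distances, rmses, members = [], [], [], []
    for c in range(k):
        idx = np.flatnonzero(ids == c)
        sizes.append(len(idx))
        distances.append(float(kl[idx].mean()))
        rmses.append(metric_rmse(y[idx], held_out_predictions[idx]))
        members.append(idx)
    source_distance = None
    if model is not None and source_smiles:
        source_distance = dataset_prior_distance(model, source_smiles)
    return ClusterDiagnostics(cluster_ids=ids, sizes=sizes, distances=distances,
                              rmses=rmses, member_indices=members,
                              source_distance=source_distance)


def pca_project(embeddings: EmbeddingMatrix | np.ndarray,
                n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA scores and explained-variance fractions."""
    X = embeddings.vectors if isinstance(embeddings, EmbeddingMatrix) else np.asarray(embeddings)
    if len(X) <= n_components:
        raise ValueError("need more samples than components")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate embeddings: all rows identical")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
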