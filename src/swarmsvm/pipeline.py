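"""End-to-end training, cross-validation, delta grid search and ablations.

The full method: (1) mRMR preselects the top-k genes (k = 50 by default);
(2) a particle swarm searches jointly over per-gene weights and the SVM
hyperparameters (C, gamma), scoring candidate positions by classification
accuracy; (3) the global best's raw weights pass the U_delta threshold gate
and are renormalized, discarding low-weight genes; (4) a final weighted SVM
is trained with the surviving weights.

Cross-validation is leave-one-out by default (stratified 10-fold available),
repeated ``n_repeats`` times with derived seeds and averaged.  By default
gene preselection sees the whole dataset before folds are formed -- the
protocol this reproduces carries selection bias; the nested ``per-fold``
scope re-runs mRMR inside every training fold and is the honest estimate.

Ablation variants:

====================  ============================================================
svm                   all genes, uniform weights, fixed C and gamma
mrmr-svm              top-k genes, uniform weights, fixed C and gamma
mrmr-pso-svm          top-k genes, uniform weights, PSO over (C, gamma) only
mrmr-pso-wsvm         the full method (weights + hyperparameters + threshold)
====================  ============================================================
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset
from .mrmr import GeneRanking, mrmr_select
from .pso import AllWeightsZeroError, PsoConfig, PsoResult, optimize
from .wsvm import KernelParams, TrainedModel, WeightVector, train_wsvm

__all__ = [
    "ABLATION_VARIANTS",
    "PipelineConfig",
    "FittedPipeline",
    "RepeatResult",
    "CVResult",
    "DeltaSearchResult",
    "fit",
    "cross_validate",
    "delta_search",
    "run_ablation",
    "ablation_table",
    "config_from_mapping",
]

ABLATION_VARIANTS = ("svm", "mrmr-svm", "mrmr-pso-svm", "mrmr-pso-wsvm")
_CV_SCHEMES = ("loocv", "kfold-10")


@dataclass
class PipelineConfig:
    """Everything needed to train and evaluate one pipeline variant.

    ``baseline_C`` / ``baseline_gamma`` parameterize the fixed-parameter
    ablations; with uniform weights a weighted-kernel gamma of 1 equals a
    standard RBF at width 1/n_features.
    """

    preselect_k: int = 50
    delta: float = 0.3
    pso: PsoConfig = field(default_factory=PsoConfig)
    cv_scheme: str = "loocv"
    n_repeats: int = 10
    ablation: str = "mrmr-pso-wsvm"
    selection_scope: str = "whole-dataset"
    scheme: str = "sigma-3bin"
    fitness_evaluation: str = "internal-kfold"
    fitness_n_folds: int = 5
    threshold_in_fitness: bool = True
    baseline_C: float = 1.0
    baseline_gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.preselect_k < 1:
            raise ValueError("preselect_k must be >= 1")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.cv_scheme not in _CV_SCHEMES:
            raise ValueError(f"cv_scheme must be one of {_CV_SCHEMES}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.ablation not in ABLATION_VARIANTS:
            raise ValueError(f"ablation must be one of {ABLATION_VARIANTS}")
        if self.selection_scope not in ("whole-dataset", "per-fold"):
            raise ValueError("selection_scope must be 'whole-dataset' or 'per-fold'")


@dataclass
class FittedPipeline:
    """Result of :func:`fit`: ranking, weights, hyperparameters, final model."""

    ranking: GeneRanking
    weights: WeightVector
    params: KernelParams
    model: TrainedModel
    surviving_gene_ids: list
    selected_gene_indices: list
    pso_result: PsoResult

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_gene_ids)

    def predict(self, matrix) -> np.ndarray:
        """Predict labels for samples over the *original* gene columns."""
        X = np.atleast_2d(np.asarray(matrix, dtype=float))
        return self.model.predict(X[:, self.selected_gene_indices])


@dataclass
class RepeatResult:
    accuracy: float
    n_genes: float
    seed: int


@dataclass
class CVResult:
    """Cross-validated accuracy and mean surviving-gene count."""

    accuracy: float
    n_selected_genes: float
    per_repeat: list
    scheme: str
    degenerate: bool = False


@dataclass
class DeltaSearchResult:
    best_delta: float | None
    rows: list  # (delta, accuracy, n_selected_genes, degenerate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["delta", "accuracy", "mean_selected_genes", "degenerate"]
        )


def _derive_seed(*parts) -> int:
    """Deterministic sub-seed from mixed parts, kept below 2**31."""
    text = "|".join(str(p) for p in parts)
    return zlib.crc32(text.encode()) % (2**31)


def fit(dataset: ExpressionDataset, config: PipelineConfig, seed: int = 0) -> FittedPipeline:
    """Train the full method on one dataset; deterministic given the seed."""
    if config.preselect_k > dataset.n_genes:
        raise ValueError(
            f"preselect_k={config.preselect_k} exceeds the {dataset.n_genes} genes available"
        )
    ranking = mrmr_select(dataset, config.preselect_k, scheme=config.scheme)
    sub = dataset.subset_genes(ranking.order)
    pso_cfg = replace(config.pso, seed=int(seed) % (2**31))
    try:
        result = optimize(
            sub, pso_cfg, config.delta,
            evaluation=config.fitness_evaluation,
            threshold_in_fitness=config.threshold_in_fitness,
            n_folds=config.fitness_n_folds,
        )
    except AllWeightsZeroError as exc:
        raise AllWeightsZeroError(
            f"threshold delta={config.delta} zeroed every gene weight of the best "
            "particle; reduce delta (delta_search scans a grid automatically)"
        ) from exc
    model = train_wsvm(sub, result.weights, result.params)
    surviving = result.weights.surviving_indices()
    return FittedPipeline(
        ranking=ranking,
        weights=result.weights,
        params=result.params,
        model=model,
        surviving_gene_ids=[sub.gene_ids[i] for i in surviving],
        selected_gene_indices=list(ranking.order),
        pso_result=result,
    )


def _make_folds(dataset: ExpressionDataset, scheme: str, seed: int) -> list:
    """(train_idx, test_idx) pairs; assignment is sample-order invariant."""
    n = dataset.n_samples
    if scheme == "loocv":
        if n < 3:
            raise ValueError("LOOCV needs at least 3 samples")
        return [
            (np.delete(np.arange(n), i), np.array([i]))
            for i in range(n)
        ]
    if n < 10:
        raise ValueError("10-fold CV needs at least 10 samples")
    # stratified, keyed on sorted sample ids so row permutations do not matter
    order = sorted(range(n), key=lambda i: dataset.sample_ids[i])
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    slot = 0
    for cls in (1, -1):
        members = [i for i in order if dataset.labels[i] == cls]
        members = list(np.asarray(members)[rng.permutation(len(members))])
        for i in members:
            assignment[i] = slot % 10
            slot += 1
    folds = []
    for f in range(10):
        test = np.flatnonzero(assignment == f)
        if test.size:
            folds.append((np.flatnonzero(assignment != f), test))
    return folds


def _fit_predict_fold(
    dataset: ExpressionDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: PipelineConfig,
    ranking: GeneRanking | None,
    fold_seed: int,
):
    """Train one fold's model, predict the held-out samples.

    Returns ``(predictions, n_genes_used)``; predictions are ``None`` when the
    threshold zeroed every weight (degenerate delta).
    """
    trainset = dataset.subset_samples(train_idx)
    variant = config.ablation

    if variant == "svm":
        gene_idx = np.arange(dataset.n_genes)
        model = train_wsvm(
            trainset,
            WeightVector.uniform(dataset.n_genes),
            KernelParams(C=config.baseline_C, gamma=config.baseline_gamma),
        )
        n_used = dataset.n_genes
    else:
        if config.selection_scope == "per-fold" or ranking is None:
            ranking = mrmr_select(trainset, config.preselect_k, scheme=config.scheme)
        gene_idx = np.asarray(ranking.order)
        sub = trainset.subset_genes(gene_idx)
        if variant == "mrmr-svm":
            model = train_wsvm(
                sub,
                WeightVector.uniform(config.preselect_k),
                KernelParams(C=config.baseline_C, gamma=config.baseline_gamma),
            )
            n_used = config.preselect_k
        elif variant == "mrmr-pso-svm":
            result = optimize(
                sub, replace(config.pso, seed=fold_seed), config.delta,
                evaluation=config.fitness_evaluation, optimize_weights=False,
                n_folds=config.fitness_n_folds,
            )
            model = train_wsvm(sub, result.weights, result.params)
            n_used = config.preselect_k
        else:  # mrmr-pso-wsvm
            try:
                result = optimize(
                    sub, replace(config.pso, seed=fold_seed), config.delta,
                    evaluation=config.fitness_evaluation,
                    threshold_in_fitness=config.threshold_in_fitness,
                    n_folds=config.fitness_n_folds,
                )
            except AllWeightsZeroError:
                return None, 0
            model = train_wsvm(sub, result.weights, result.params)
            n_used = int(result.weights.surviving_indices().size)

    X_test = dataset.matrix[np.ix_(test_idx, gene_idx)]
    return model.predict(X_test), n_used


def cross_validate(dataset: ExpressionDataset, config: PipelineConfig, seed: int = 0) -> CVResult:
    """Repeated cross-validation of the configured variant.

    Accuracy is total correct held-out predictions over total samples, averaged
    over ``n_repeats`` repeats whose seeds derive from the master seed.
    """
    if config.ablation != "svm" and config.preselect_k > dataset.n_genes:
        raise ValueError("preselect_k exceeds the number of genes")
    needs_ranking = (
        config.ablation != "svm" and config.selection_scope == "whole-dataset"
    )
    ranking = (
        mrmr_select(dataset, config.preselect_k, scheme=config.scheme)
        if needs_ranking
        else None
    )
    per_repeat = []
    any_fold_ok = False
    for r in range(config.n_repeats):
        rseed = (int(seed) + r) % (2**31)
        folds = _make_folds(dataset, config.cv_scheme, rseed)
        correct = 0
        counts = []
        for train_idx, test_idx in folds:
            fseed = _derive_seed(rseed, *sorted(dataset.sample_ids[i] for i in test_idx))
            pred, n_used = _fit_predict_fold(
                dataset, train_idx, test_idx, config, ranking, fseed
            )
            if pred is None:
                counts.append(0)
                continue  # every held-out sample counts as misclassified
            any_fold_ok = True
            correct += int((pred == dataset.labels[test_idx]).sum())
            counts.append(n_used)
        per_repeat.append(
            RepeatResult(correct / dataset.n_samples, float(np.mean(counts)), rseed)
        )
    return CVResult(
        accuracy=float(np.mean([r.accuracy for r in per_repeat])),
        n_selected_genes=float(np.mean([r.n_genes for r in per_repeat])),
        per_repeat=per_repeat,
        scheme=config.cv_scheme,
        degenerate=not any_fold_ok,
    )


def delta_search(
    dataset: ExpressionDataset,
    config: PipelineConfig,
    grid_start: float = 0.2,
    grid_step: float = 0.1,
    seed: int = 0,
) -> DeltaSearchResult:
    """Scan threshold values delta = grid_start, +step, ... and cross-validate.

    Stops once a delta zeroes all weights in every fold (recorded as a
    degenerate row with accuracy 0).  The best delta maximizes accuracy; ties
    break toward the smaller delta, which keeps more genes.
    """
    if not 0.0 <= grid_start <= 1.0 or grid_step <= 0:
        raise ValueError("grid must start in [0, 1] with a positive step")
    deltas = []
    x = grid_start
    while x <= 1.0 + 1e-12:
        deltas.append(round(x, 10))
        x += grid_step
    rows = []
    best_delta, best_acc = None, -np.inf
    for d in deltas:
        cfg = replace(config, delta=min(d, 1.0), ablation="mrmr-pso-wsvm")
        res = cross_validate(dataset, cfg, seed)
        acc = 0.0 if res.degenerate else res.accuracy
        rows.append((cfg.delta, acc, res.n_selected_genes, res.degenerate))
        if not res.degenerate and acc > best_acc:
            best_acc, best_delta = acc, cfg.delta
        if res.degenerate:
            break
    return DeltaSearchResult(best_delta=best_delta, rows=rows)


def run_ablation(dataset: ExpressionDataset, config: PipelineConfig, seed: int = 0) -> dict:
    """Cross-validate all four variants under shared seeds and folds."""
    results = {}
    for variant in ABLATION_VARIANTS:
        cfg = replace(config, ablation=variant)
        results[variant] = cross_validate(dataset, cfg, seed)
    return results


def ablation_table(results: dict) -> pd.DataFrame:
    """Variant / accuracy / mean selected genes summary of an ablation run."""
    return pd.DataFrame(
        {
            "variant": list(results),
            "accuracy": [r.accuracy for r in results.values()],
            "mean_selected_genes": [r.n_selected_genes for r in results.values()],
        }
    )


def config_from_mapping(mapping: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a (YAML-style) nested mapping."""
    mapping = dict(mapping or {})
    pso_map = mapping.pop("pso", {}) or {}
    pso = PsoConfig(**pso_map)
    return PipelineConfig(pso=pso, **mapping)
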