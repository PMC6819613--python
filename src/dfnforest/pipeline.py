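"""End-to-end pipeline: preprocessing -> per-omics SAEs -> integration -> cascade.

The pipeline wires the stages together the way the framework is meant to be
used on aligned multi-omics matrices: each block is filtered for overly
missing samples (a sample dropped in any block is dropped from all, to keep
alignment), KNN-imputed and z-scored; a stacked autoencoder per block
compresses it to a code; the concatenated codes pass through one
integrating autoencoder layer; and the final representation feeds the
cascade forest classifier. A fitted pipeline freezes every per-stage
statistic (imputation donor pool, feature means/variances, all weights,
all trees) so new samples are transformed without touching the training
data again.

Evaluation is stratified k-fold cross-validation with every stage fitted
inside the training folds only, plus a permuted-input control that compares
the model against the 1/C random-guess level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from . import preprocess as pp
from .autoencoder import (
    AEParameters,
    SAEModel,
    TrainConfig,
    encode,
    integrate_representations,
    sae_encode,
    train_sae,
)
from .cascade import CascadeConfig, CascadeModel, predict as cascade_predict, train_cascade
from .preprocess import OmicsMatrix


class PipelineError(ValueError):
    """Raised on alignment or configuration failures, naming the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the full framework.

    sae_dims gives the hidden sizes of the per-block stacked autoencoders;
    None selects the standard structures by block width (500-200-50 for
    wide, expression-like blocks, 100-50 for narrow, miRNA-like ones). The
    integrator compresses the concatenated codes to ``integrator_dim``.
    The master seed fans out to per-stage seeds through a spawned seed
    sequence, so stages are independently reproducible.
    """

    sae_dims: tuple[tuple[int, ...], ...] | None = None
    integrator_dim: int = 50
    train: TrainConfig = field(default_factory=TrainConfig)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    missing_threshold: float = 0.2
    knn_k: int = 5
    winsorize_z: float | None = None
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise PipelineError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.integrator_dim < 1:
            raise PipelineError(f"integrator_dim must be >= 1, got {self.integrator_dim}")

    def dims_for(self, n_blocks: int, widths: list[int]) -> list[list[int]]:
        if self.sae_dims is not None:
            if len(self.sae_dims) != n_blocks:
                raise PipelineError(
                    f"config lists {len(self.sae_dims)} SAE structures for "
                    f"{n_blocks} omics blocks"
                )
            return [list(d) for d in self.sae_dims]
        return [[500, 200, 50] if w >= 500 else [100, 50] for w in widths]


@dataclass
class _BlockState:
    """Frozen preprocessing + representation state for one omics block."""

    feature_ids: list[str]
    mean: np.ndarray
    var: np.ndarray
    donor_pool: OmicsMatrix  # imputed, un-normalised training matrix
    sae: SAEModel


@dataclass
class FittedPipeline:
    blocks: list[_BlockState]
    integrator: AEParameters
    cascade_model: CascadeModel
    config: PipelineConfig
    sample_ids: list[str]

    def transform(self, omics: list[OmicsMatrix]) -> np.ndarray:
        """Map new aligned omics blocks to the integrated representation."""
        if len(omics) != len(self.blocks):
            raise PipelineError(
                f"pipeline was fitted on {len(self.blocks)} blocks, got {len(omics)}"
            )
        _check_alignment(omics)
        codes = []
        for matrix, state in zip(omics, self.blocks):
            matrix = _restrict_features(matrix, state.feature_ids)
            matrix = pp.impute_against_reference(
                matrix, state.donor_pool, k=self.config.knn_k
            )
            matrix = pp.apply_normalization(matrix, state.mean, state.var)
            codes.append(sae_encode(state.sae, matrix.values))
        stacked = np.concatenate(codes, axis=1)
        return encode(self.integrator, stacked, self.config.train.activation)

    def predict(self, omics: list[OmicsMatrix]) -> np.ndarray:
        return cascade_predict(self.cascade_model, self.transform(omics))


def _check_alignment(omics: list[OmicsMatrix]) -> None:
    if not omics:
        raise PipelineError("no omics blocks given")
    ids = omics[0].sample_ids
    for i, matrix in enumerate(omics[1:], start=2):
        if matrix.sample_ids != ids:
            raise PipelineError(
                f"alignment: omics block {i} sample identifiers differ from block 1"
            )


def _restrict_features(matrix: OmicsMatrix, feature_ids: list[str]) -> OmicsMatrix:
    if matrix.feature_ids == feature_ids:
        return matrix
    index = {f: j for j, f in enumerate(matrix.feature_ids)}
    try:
        cols = [index[f] for f in feature_ids]
    except KeyError as err:
        raise PipelineError(f"feature {err.args[0]!r} absent from new data") from err
    return OmicsMatrix(
        values=matrix.values[:, cols],
        sample_ids=list(matrix.sample_ids),
        feature_ids=list(feature_ids),
        missing_mask=matrix.missing_mask[:, cols],
    )


def fit_pipeline(
    omics: list[OmicsMatrix], labels: np.ndarray, config: PipelineConfig
) -> FittedPipeline:
    """Fit preprocessing, representation learning and the cascade jointly."""
    _check_alignment(omics)
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != omics[0].n_samples:
        raise PipelineError(
            f"alignment: {labels.shape[0]} labels for {omics[0].n_samples} samples"
        )

    # Missingness filter per block; keep only samples surviving in all blocks.
    keep = np.ones(omics[0].n_samples, dtype=bool)
    for b, matrix in enumerate(omics):
        frac = matrix.missing_mask.mean(axis=1)
        keep &= frac <= config.missing_threshold
    if not keep.any():
        raise PipelineError(
            "preprocessing: every sample exceeds the missing-value threshold "
            "in at least one block"
        )
    keep_idx = np.flatnonzero(keep)
    omics = [m.take_samples(keep_idx) for m in omics]
    labels = labels[keep_idx]

    widths = [m.n_features for m in omics]
    dims = config.dims_for(len(omics), widths)
    seeds = np.random.SeedSequence(config.seed).spawn(len(omics) + 2)

    blocks: list[_BlockState] = []
    codes: list[np.ndarray] = []
    for b, matrix in enumerate(omics):
        try:
            if config.winsorize_z is not None:
                matrix = pp.winsorize(matrix, config.winsorize_z)
            imputed = pp.knn_impute(matrix, k=config.knn_k)
            normalized = pp.normalize_features(imputed, drop_constant=True)
        except pp.PreprocessingError as err:
            raise PipelineError(f"preprocessing block {b + 1}: {err}") from err
        kept = [imputed.feature_ids.index(f) for f in normalized.feature_ids]
        mean, var = pp.column_stats(imputed.values[:, kept])
        donor = OmicsMatrix(
            values=imputed.values[:, kept],
            sample_ids=list(imputed.sample_ids),
            feature_ids=list(normalized.feature_ids),
        )
        train_cfg = replace(
            config.train, seed=int(seeds[b].generate_state(1)[0] % 2**31)
        )
        sae = train_sae(normalized.values, dims[b], train_cfg)
        blocks.append(
            _BlockState(
                feature_ids=list(normalized.feature_ids),
                mean=mean,
                var=var,
                donor_pool=donor,
                sae=sae,
            )
        )
        codes.append(sae_encode(sae, normalized.values))

    integrator_cfg = replace(
        config.train, seed=int(seeds[-2].generate_state(1)[0] % 2**31)
    )
    integrator, integrated = integrate_representations(
        codes, config.integrator_dim, integrator_cfg
    )
    cascade_cfg = replace(
        config.cascade, seed=int(seeds[-1].generate_state(1)[0] % 2**31)
    )
    model = train_cascade(integrated, labels, cascade_cfg)
    return FittedPipeline(
        blocks=blocks,
        integrator=integrator,
        cascade_model=model,
        config=config,
        sample_ids=list(omics[0].sample_ids),
    )


# ---------------------------------------------------------------------------
# Metrics and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class Metrics:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def compute_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> Metrics:
    """Accuracy plus macro precision/recall/F1 with 0/0 counted as 0."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise PipelineError(
            f"y_true has {y_true.shape[0]} entries, y_pred has {y_pred.shape[0]}"
        )
    if y_true.size and (max(y_true.max(), y_pred.max()) >= n_classes):
        raise PipelineError("labels exceed n_classes")
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=np.arange(n_classes), zero_division=0
    )
    return Metrics(
        accuracy=float(np.mean(y_true == y_pred)),
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
    )


@dataclass
class EvalReport:
    """Per-fold and mean classification metrics from cross-validation."""

    fold_metrics: list[Metrics]
    mean: Metrics
    n_classes: int

    def as_dict(self) -> dict:
        return {
            "n_folds": len(self.fold_metrics),
            "folds": [m.as_dict() for m in self.fold_metrics],
            "mean": self.mean.as_dict(),
        }


def _mean_metrics(folds: list[Metrics]) -> Metrics:
    return Metrics(
        accuracy=float(np.mean([m.accuracy for m in folds])),
        macro_precision=float(np.mean([m.macro_precision for m in folds])),
        macro_recall=float(np.mean([m.macro_recall for m in folds])),
        macro_f1=float(np.mean([m.macro_f1 for m in folds])),
    )


def cross_validate(
    omics: list[OmicsMatrix], labels: np.ndarray, config: PipelineConfig
) -> EvalReport:
    """Stratified k-fold evaluation with all fitting inside training folds."""
    _check_alignment(omics)
    labels = np.asarray(labels, dtype=int)
    n_classes = int(labels.max()) + 1
    counts = np.bincount(labels, minlength=n_classes)
    if counts.min() < config.cv_folds:
        small = int(np.argmin(counts))
        raise PipelineError(
            f"class {small} has {counts.min()} members, fewer than "
            f"cv_folds={config.cv_folds}"
        )
    splitter = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed % 2**31
    )
    fold_seeds = np.random.SeedSequence(config.seed).spawn(config.cv_folds)
    folds: list[Metrics] = []
    for f, (train_idx, test_idx) in enumerate(splitter.split(labels[:, None], labels)):
        train_blocks = [m.take_samples(train_idx) for m in omics]
        test_blocks = [m.take_samples(test_idx) for m in omics]
        fold_config = replace(
            config, seed=int(fold_seeds[f].generate_state(1)[0] % 2**31)
        )
        fitted = fit_pipeline(train_blocks, labels[train_idx], fold_config)
        y_pred = fitted.predict(test_blocks)
        folds.append(compute_metrics(labels[test_idx], y_pred, n_classes))
    return EvalReport(fold_metrics=folds, mean=_mean_metrics(folds), n_classes=n_classes)


# ---------------------------------------------------------------------------
# Canonical configurations for the desk-scale synthetic study
# ---------------------------------------------------------------------------

def synthetic_study_config(seed: int) -> PipelineConfig:
    """Pipeline settings for the bundled synthetic study.

    Code widths are chosen commensurate with the generator's latent
    dimensionality (eight shared factors): 50-12 stacks per block and a
    10-unit integrating layer, the role the 500-200-50 / 100-50 / 50
    structures play at TCGA scale. Search budgets are desk-scale:
    10 GGGP generations and a 10-particle swarm per tree.
    """
    from .cascade import CascadeConfig
    from .fnt import GPConfig, PSOConfig

    return PipelineConfig(
        sae_dims=((50, 12), (50, 12), (50, 12)),
        integrator_dim=10,
        train=TrainConfig(epochs=500, learning_rate=2e-2),
        cascade=CascadeConfig(
            gp=GPConfig(population_size=50, generations=10, final_candidates=10),
            pso=PSOConfig(swarm_size=10, iterations=150),
            max_depth=3,
            max_levels=3,
        ),
        seed=seed,
    )


def null_control_config(seed: int, n_blocks: int = 3) -> PipelineConfig:
    """Compact settings for the repeated permuted-input control.

    Chance-level behaviour does not depend on training effort, so the
    control uses shorter autoencoder training, a single-growth cascade and
    2-fold cross-validation to keep ten repeats affordable; search budgets
    per tree (generations, swarm) match the main study.
    """
    from .cascade import CascadeConfig
    from .fnt import GPConfig, PSOConfig

    return PipelineConfig(
        sae_dims=((50, 12),) * n_blocks,
        integrator_dim=10,
        train=TrainConfig(epochs=100, learning_rate=2e-2),
        cascade=CascadeConfig(
            gp=GPConfig(population_size=50, generations=10),
            pso=PSOConfig(swarm_size=10, iterations=150),
            max_depth=3,
            max_levels=1,
        ),
        cv_folds=2,
        seed=seed,
    )


@dataclass
class PermutationReport:
    """Permuted-input control: accuracy should sit at the 1/C chance level."""

    per_repeat_accuracy: list[float]
    mean_accuracy: float
    chance_level: float
    empirical_chance_level: float


def permutation_control(
    omics: list[OmicsMatrix],
    labels: np.ndarray,
    config: PipelineConfig,
    repeats: int = 10,
    mode: str = "labels",
) -> PermutationReport:
    """Cross-validate on permuted data ``repeats`` times with fresh seeds.

    Reports the mean accuracy next to the 1/n_classes chance level (and the
    empirical majority-class frequency, for unbalanced data).
    """
    from .synthetic import permute_dataset

    if repeats < 1:
        raise PipelineError(f"repeats must be >= 1, got {repeats}")
    labels = np.asarray(labels, dtype=int)
    n_classes = int(labels.max()) + 1
    seeds = np.random.SeedSequence(config.seed).spawn(repeats)
    accs = []
    for r in range(repeats):
        s1, s2 = (int(v % 2**31) for v in seeds[r].generate_state(2))
        perm_omics, perm_labels = permute_dataset(omics, labels, mode=mode, seed=s1)
        report = cross_validate(perm_omics, perm_labels, replace(config, seed=s2))
        accs.append(report.mean.accuracy)
    counts = np.bincount(labels, minlength=n_classes)
    return PermutationReport(
        per_repeat_accuracy=accs,
        mean_accuracy=float(np.mean(accs)),
        chance_level=1.0 / n_classes,
        empirical_chance_level=float(counts.max() / counts.sum()),
    )
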