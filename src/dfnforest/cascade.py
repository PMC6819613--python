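"""The deep flexible neural forest: M-ary coding, forests of FNTs, cascade levels.

A C-class problem is decomposed into ceil(log2 C) binary tasks (M-ary
output coding): class c's codeword is the binary representation of c,
least-significant bit first. Each forest holds one FNT per code bit; the
concatenated tree outputs form the forest's class vector. A cascade level
holds several forests with pairwise distinct function sets (diversity), and
every level after the first sees the raw features concatenated with the
previous level's class vectors. Levels are added until the validation
accuracy stops improving; prediction decodes each forest's class vector to
the nearest codeword (Euclidean) and majority-votes across forests, with
ties broken toward the lowest class index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import train_test_split

from .fnt import FNTree, GPConfig, PSOConfig, evaluate_tree_batch, gggp_search

DEFAULT_FUNCTION_SETS: tuple[frozenset[int], ...] = (
    frozenset({2, 3, 4}),
    frozenset({2, 4, 5}),
    frozenset({3, 4, 5}),
)


class CascadeError(ValueError):
    """Raised on cascade contract violations."""


# ---------------------------------------------------------------------------
# M-ary output coding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaryCode:
    """Binary output code: class c -> bits of c, least-significant first."""

    n_classes: int
    code_length: int
    codewords: tuple[tuple[int, ...], ...]

    def encode(self, label: int) -> tuple[int, ...]:
        if not 0 <= label < self.n_classes:
            raise CascadeError(f"label {label} outside [0, {self.n_classes})")
        return self.codewords[label]

    def decode(self, vector: np.ndarray) -> int:
        """Nearest codeword by Euclidean distance; ties -> lowest class."""
        vector = np.asarray(vector, dtype=float)
        words = np.asarray(self.codewords, dtype=float)
        d2 = ((words - vector[None, :]) ** 2).sum(axis=1)
        return int(np.argmin(d2))

    def bit_targets(self, labels: np.ndarray) -> np.ndarray:
        """(n_samples, code_length) 0/1 matrix of per-bit targets."""
        words = np.asarray(self.codewords, dtype=float)
        return words[np.asarray(labels, dtype=int)]


def build_mary_code(n_classes: int) -> MaryCode:
    if n_classes < 2:
        raise CascadeError(f"n_classes must be >= 2, got {n_classes}")
    code_length = max(1, math.ceil(math.log2(n_classes)))
    codewords = tuple(
        tuple((c >> bit) & 1 for bit in range(code_length)) for c in range(n_classes)
    )
    return MaryCode(n_classes=n_classes, code_length=code_length, codewords=codewords)


# ---------------------------------------------------------------------------
# Forests and levels
# ---------------------------------------------------------------------------

@dataclass
class Forest:
    """One FNT per code bit, all sharing a function set."""

    trees: list[FNTree]
    function_set: frozenset[int]

    def __post_init__(self) -> None:
        for tree in self.trees:
            if tree.function_set != self.function_set:
                raise CascadeError("tree function set differs from the forest's")


def forest_class_vector(forest: Forest, x: np.ndarray) -> np.ndarray:
    """Concatenated estimated values of the forest's trees for one sample."""
    return forest_class_matrix(forest, np.atleast_2d(np.asarray(x, dtype=float)))[0]


def forest_class_matrix(forest: Forest, X: np.ndarray) -> np.ndarray:
    """(n_samples, code_length) matrix of tree outputs."""
    return np.column_stack([evaluate_tree_batch(t, X) for t in forest.trees])


@dataclass
class CascadeLevel:
    forests: list[Forest]
    input_dim: int

    def __post_init__(self) -> None:
        sets = [f.function_set for f in self.forests]
        if len(set(sets)) != len(sets):
            raise CascadeError("forests within a level must have distinct function sets")


@dataclass
class CascadeModel:
    levels: list[CascadeLevel]
    code: MaryCode
    raw_dim: int
    best_level: int
    validation_accuracy_trace: list[float]

    def __post_init__(self) -> None:
        if not 0 <= self.best_level < len(self.levels):
            raise CascadeError("best_level outside the trained levels")
        extra = len(self.levels[0].forests) * self.code.code_length
        for i, level in enumerate(self.levels):
            expected = self.raw_dim + (extra if i > 0 else 0)
            if level.input_dim != expected:
                raise CascadeError(
                    f"level {i} input_dim {level.input_dim} != expected {expected}"
                )


def augment_features(raw: np.ndarray, class_vectors: list[np.ndarray]) -> np.ndarray:
    """[raw | cv_1 | ... | cv_F]: raw columns first, forests in fixed order."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    mats = [raw]
    for cv in class_vectors:
        cv = np.atleast_2d(np.asarray(cv, dtype=float))
        if cv.shape[0] != raw.shape[0]:
            raise CascadeError(
                f"class-vector block has {cv.shape[0]} samples, raw has {raw.shape[0]}"
            )
        mats.append(cv)
    return np.concatenate(mats, axis=1)


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CascadeConfig:
    """Cascade growth settings.

    Three forests per level with the standard function-set triple; growth
    stops when validation accuracy fails to improve by more than ``tol``
    for ``patience`` consecutive levels, or at ``max_levels``.
    """

    function_sets: tuple[frozenset[int], ...] = DEFAULT_FUNCTION_SETS
    gp: GPConfig = field(default_factory=GPConfig)
    pso: PSOConfig = field(default_factory=PSOConfig)
    max_depth: int = 4
    max_levels: int = 10
    tol: float = 1e-6
    patience: int = 1
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.function_sets)) != len(self.function_sets):
            raise CascadeError("function_sets must be pairwise distinct")
        if self.max_levels < 1:
            raise CascadeError(f"max_levels must be >= 1, got {self.max_levels}")
        if not 0.0 < self.val_fraction < 1.0:
            raise CascadeError(f"val_fraction must be in (0, 1), got {self.val_fraction}")


def _level_class_matrices(
    level: CascadeLevel, X: np.ndarray
) -> list[np.ndarray]:
    return [forest_class_matrix(f, X) for f in level.forests]


def _train_level(
    X: np.ndarray,
    bit_targets: np.ndarray,
    config: CascadeConfig,
    rng: np.random.Generator,
) -> CascadeLevel:
    forests = []
    for fset in config.function_sets:
        trees = []
        for bit in range(bit_targets.shape[1]):
            gp = replace(config.gp, seed=int(rng.integers(2**31)))
            pso = replace(config.pso, seed=int(rng.integers(2**31)))
            trees.append(
                gggp_search(
                    X, bit_targets[:, bit], fset, gp, pso, max_depth=config.max_depth
                )
            )
        forests.append(Forest(trees=trees, function_set=frozenset(fset)))
    return CascadeLevel(forests=forests, input_dim=X.shape[1])


def _decode_votes(code: MaryCode, class_matrices: list[np.ndarray]) -> np.ndarray:
    """Nearest-codeword decode per forest, then majority vote across forests."""
    n = class_matrices[0].shape[0]
    words = np.asarray(code.codewords, dtype=float)
    votes = np.empty((len(class_matrices), n), dtype=int)
    for f, cm in enumerate(class_matrices):
        d2 = ((cm[:, None, :] - words[None, :, :]) ** 2).sum(axis=2)
        votes[f] = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
    counts = np.zeros((n, code.n_classes), dtype=int)
    for f in range(votes.shape[0]):
        counts[np.arange(n), votes[f]] += 1
    return counts.argmax(axis=1)  # ties -> lowest class index


def train_cascade(
    X: np.ndarray, y: np.ndarray, config: CascadeConfig
) -> CascadeModel:
    """Grow cascade levels until validation accuracy stops improving.

    An internal stratified 80/20 train/validation split (seeded) monitors
    each level; ``best_level`` is the earliest level attaining the maximum
    of the validation-accuracy trace, and prediction uses levels up to it.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise CascadeError("need at least 2 classes present in y")
    if not np.all(np.isfinite(X)):
        raise CascadeError("X contains non-finite entries")
    code = build_mary_code(int(classes.max()) + 1)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    try:
        X_tr, X_val, y_tr, y_val = train_test_split(
            X,
            y,
            test_size=config.val_fraction,
            stratify=y,
            random_state=int(rng.integers(2**31)),
        )
    except ValueError as err:
        raise CascadeError(f"stratified train/validation split failed: {err}") from err
    if np.unique(y_tr).size < classes.size:
        raise CascadeError("a class is absent from the training split")

    bits_tr = code.bit_targets(y_tr)
    levels: list[CascadeLevel] = []
    trace: list[float] = []
    feats_tr, feats_val = X_tr, X_val
    best_acc, stall = -np.inf, 0
    while len(levels) < config.max_levels:
        level = _train_level(feats_tr, bits_tr, config, rng)
        levels.append(level)
        cm_tr = _level_class_matrices(level, feats_tr)
        cm_val = _level_class_matrices(level, feats_val)
        acc = float(np.mean(_decode_votes(code, cm_val) == y_val))
        trace.append(acc)
        if acc > best_acc + config.tol:
            best_acc, stall = acc, 0
        else:
            stall += 1
            if stall >= config.patience:
                break
        feats_tr = augment_features(X_tr, cm_tr)
        feats_val = augment_features(X_val, cm_val)

    best_level = int(np.argmax(trace))
    return CascadeModel(
        levels=levels,
        code=code,
        raw_dim=X.shape[1],
        best_level=best_level,
        validation_accuracy_trace=trace,
    )


def predict(model: CascadeModel, X: np.ndarray) -> np.ndarray:
    """Propagate class vectors through the cascade and decode at best_level."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.raw_dim:
        raise CascadeError(
            f"X has {X.shape[1]} features, model expects {model.raw_dim}"
        )
    feats = X
    for i in range(model.best_level + 1):
        class_matrices = _level_class_matrices(model.levels[i], feats)
        if i < model.best_level:
            feats = augment_features(X, class_matrices)
    return _decode_votes(model.code, class_matrices)
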