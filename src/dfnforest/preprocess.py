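"""Preprocessing of omics matrices: missingness filtering, KNN imputation, z-scoring.

The preprocessing contract mirrors the usual treatment of TCGA-style Level-3
matrices: samples with too many missing measurements are dropped, remaining
gaps are filled by K-nearest-neighbour imputation over samples, and every
feature is standardised to zero mean and unit (population) variance,

    f~ = (f - E(f)) / sqrt(Var(f)).

All operations are pure: they return new :class:`OmicsMatrix` objects and
never mutate their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class PreprocessingError(ValueError):
    """Raised when a preprocessing contract is violated."""


class EmptyDatasetError(PreprocessingError):
    """Raised when a filtering step removes every sample."""


@dataclass
class OmicsMatrix:
    """One omics layer: a samples x features matrix with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Measurements. Entries flagged in ``missing_mask`` carry no
        information and are ignored by every statistic.
    sample_ids, feature_ids : list of str
        Unique row / column identifiers.
    missing_mask : bool ndarray, same shape as ``values``
        True where the entry is missing. Defaults to all-observed.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise PreprocessingError("values must be a 2-D samples x features matrix")
        n, p = self.values.shape
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.sample_ids) != n:
            raise PreprocessingError(
                f"sample_ids has {len(self.sample_ids)} entries for {n} rows"
            )
        if len(self.feature_ids) != p:
            raise PreprocessingError(
                f"feature_ids has {len(self.feature_ids)} entries for {p} columns"
            )
        if len(set(self.sample_ids)) != n:
            raise PreprocessingError("sample_ids are not unique")
        if len(set(self.feature_ids)) != p:
            raise PreprocessingError("feature_ids are not unique")
        if self.missing_mask is None:
            self.missing_mask = np.zeros_like(self.values, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise PreprocessingError("missing_mask shape differs from values shape")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take_samples(self, indices: np.ndarray) -> "OmicsMatrix":
        """Return the matrix restricted to the given sample rows (order kept)."""
        idx = np.asarray(indices)
        return OmicsMatrix(
            values=self.values[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_ids=list(self.feature_ids),
            missing_mask=self.missing_mask[idx].copy(),
        )


def filter_samples(matrix: OmicsMatrix, threshold: float = 0.2) -> OmicsMatrix:
    """Drop samples whose fraction of missing features exceeds ``threshold``.

    The removal criterion is strictly greater-than: a sample missing exactly
    ``threshold`` of its features is retained. Survivor order is preserved.
    """
    if not 0.0 <= threshold < 1.0:
        raise PreprocessingError(f"threshold must be in [0, 1), got {threshold}")
    frac = matrix.missing_mask.mean(axis=1)
    keep = np.flatnonzero(frac <= threshold)
    if keep.size == 0:
        raise EmptyDatasetError(
            f"empty dataset: all {matrix.n_samples} samples exceed the "
            f"{threshold:.0%} missing-value threshold"
        )
    if keep.size == matrix.n_samples:
        return matrix
    return matrix.take_samples(keep)


def _knn_impute_rows(
    target_values: np.ndarray,
    target_mask: np.ndarray,
    pool_values: np.ndarray,
    pool_mask: np.ndarray,
    k: int,
    exclude_self: bool,
) -> np.ndarray:
    """Impute missing entries of target rows from the k nearest pool rows.

    Distances are plain Euclidean over features observed in both rows
    (no rescaling by the number of shared features); ties are broken by
    pool row order. For a missing (s, f), only neighbours observing f
    contribute; if none of the k nearest observe f, the feature's global
    observed mean over the pool is used.
    """
    out = target_values.copy()
    observed_pool = ~pool_mask
    with np.errstate(invalid="ignore"):
        global_mean = np.where(
            observed_pool.any(axis=0),
            np.nansum(np.where(observed_pool, pool_values, np.nan), axis=0)
            / observed_pool.sum(axis=0).clip(min=1),
            np.nan,
        )
    for s in range(target_values.shape[0]):
        miss = np.flatnonzero(target_mask[s])
        if miss.size == 0:
            continue
        shared = (~target_mask[s])[None, :] & observed_pool
        diff = np.where(shared, pool_values - target_values[s], 0.0)
        d2 = np.einsum("ij,ij->i", diff, diff)
        if exclude_self:
            d2 = d2.copy()
            d2[s] = np.inf
        order = np.argsort(d2, kind="stable")
        if exclude_self:
            order = order[: pool_values.shape[0] - 1]
        neighbours = order[:k]
        for f in miss:
            donors = neighbours[observed_pool[neighbours, f]]
            if donors.size:
                out[s, f] = pool_values[donors, f].mean()
            else:
                out[s, f] = global_mean[f]
    return out


def knn_impute(matrix: OmicsMatrix, k: int = 5) -> OmicsMatrix:
    """Fill missing entries with the mean of the k nearest samples.

    Nearness is Euclidean distance over features observed in both samples;
    distance ties are broken by sample order. The returned matrix has an
    empty missing mask.
    """
    if k < 1:
        raise PreprocessingError(f"k must be >= 1, got {k}")
    if matrix.n_samples < k + 1:
        raise PreprocessingError(
            f"knn_impute needs at least k+1={k + 1} samples, got {matrix.n_samples}"
        )
    never_observed = matrix.missing_mask.all(axis=0)
    if never_observed.any():
        bad = matrix.feature_ids[int(np.flatnonzero(never_observed)[0])]
        raise PreprocessingError(f"feature {bad!r} is missing in every sample")
    if not matrix.missing_mask.any():
        return matrix
    filled = _knn_impute_rows(
        matrix.values, matrix.missing_mask, matrix.values, matrix.missing_mask,
        k=k, exclude_self=True,
    )
    return replace(
        matrix, values=filled, missing_mask=np.zeros_like(matrix.missing_mask)
    )


def impute_against_reference(
    matrix: OmicsMatrix, reference: OmicsMatrix, k: int = 5
) -> OmicsMatrix:
    """Impute missing entries of ``matrix`` using rows of ``reference`` as donors.

    Used at prediction time so that new samples are filled from the training
    pool with frozen statistics, never from each other.
    """
    if matrix.feature_ids != reference.feature_ids:
        raise PreprocessingError("feature identifiers differ from the reference")
    if not matrix.missing_mask.any():
        return matrix
    filled = _knn_impute_rows(
        matrix.values, matrix.missing_mask,
        reference.values, reference.missing_mask,
        k=min(k, reference.n_samples), exclude_self=False,
    )
    return replace(
        matrix, values=filled, missing_mask=np.zeros_like(matrix.missing_mask)
    )


def column_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mean and population variance (divide by N)."""
    return values.mean(axis=0), values.var(axis=0, ddof=0)


def normalize_features(
    matrix: OmicsMatrix, drop_constant: bool = False
) -> OmicsMatrix:
    """Standardise each feature to mean 0 and population variance 1.

    Must run after imputation (no missing entries allowed). Zero-variance
    columns are an error unless ``drop_constant`` is set, in which case they
    are removed.
    """
    if matrix.missing_mask.any():
        raise PreprocessingError("normalize_features requires a fully observed matrix")
    mean, var = column_stats(matrix.values)
    constant = var == 0.0
    if constant.any():
        if not drop_constant:
            bad = matrix.feature_ids[int(np.flatnonzero(constant)[0])]
            raise PreprocessingError(f"feature {bad!r} has zero variance")
        keep = np.flatnonzero(~constant)
        matrix = OmicsMatrix(
            values=matrix.values[:, keep],
            sample_ids=list(matrix.sample_ids),
            feature_ids=[matrix.feature_ids[i] for i in keep],
        )
        mean, var = mean[keep], var[keep]
    values = (matrix.values - mean) / np.sqrt(var)
    return replace(matrix, values=values, missing_mask=np.zeros_like(matrix.missing_mask))


def apply_normalization(
    matrix: OmicsMatrix, mean: np.ndarray, var: np.ndarray
) -> OmicsMatrix:
    """Standardise with frozen statistics (prediction-time counterpart)."""
    if matrix.missing_mask.any():
        raise PreprocessingError("apply_normalization requires a fully observed matrix")
    values = (matrix.values - mean) / np.sqrt(var)
    return replace(matrix, values=values, missing_mask=np.zeros_like(matrix.missing_mask))


def winsorize(matrix: OmicsMatrix, z_limit: float = 6.0) -> OmicsMatrix:
    """Optional outlier control: clip entries beyond ``z_limit`` column z-scores.

    Off by default in the pipeline; the clipping threshold is a package
    choice, as no principled criterion exists for these data.
    """
    mean, var = column_stats(matrix.values)
    sd = np.sqrt(var)
    sd = np.where(sd == 0.0, 1.0, sd)
    lo, hi = mean - z_limit * sd, mean + z_limit * sd
    return replace(matrix, values=np.clip(matrix.values, lo, hi))
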