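"""Synthetic multi-omics data with known subtype structure.

Real multi-omics layers measured on the same patients are not independent:
a tumour's subtype shapes its transcriptome, miRNA profile and methylome
jointly. The generator emulates this with a shared latent factor model.
Each sample draws a latent vector from a class-specific Gaussian; each
omics block is an independent random linear read-out of those latents plus
Gaussian noise, so cross-omics correlation arises only through the shared
factors. Class separation is controlled by a single effect size (the
Euclidean distance between class means in latent space), and a configurable
fraction of entries is masked missing uniformly at random.

All randomness flows from the spec's single seed through named generators;
an identical spec reproduces identical output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import OmicsMatrix


class SyntheticSpecError(ValueError):
    """Raised when a generator specification is inconsistent."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions for one simulated multi-omics study.

    Defaults describe a desk-scale study: 200 samples, four subtypes,
    three blocks of differing width (gene-expression-, methylation- and
    miRNA-like), strong class separation (effect_size 5 vs latent sd 1 and
    read-out noise sd 0.1) and 5% missing entries.
    """

    n_samples: int = 200
    n_classes: int = 4
    features_per_omics: tuple[int, ...] = (300, 150, 80)
    n_latent: int = 8
    effect_size: float = 5.0
    noise_sd: float = 0.1
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "features_per_omics", tuple(int(p) for p in self.features_per_omics)
        )
        if self.n_samples < 1:
            raise SyntheticSpecError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.n_classes < 2:
            raise SyntheticSpecError(f"n_classes must be >= 2, got {self.n_classes}")
        if not self.features_per_omics or any(p < 1 for p in self.features_per_omics):
            raise SyntheticSpecError(
                f"features_per_omics must be positive counts, got {self.features_per_omics}"
            )
        if self.n_latent < 1:
            raise SyntheticSpecError(f"n_latent must be >= 1, got {self.n_latent}")
        if self.effect_size < 0:
            raise SyntheticSpecError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise SyntheticSpecError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise SyntheticSpecError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}"
            )


def _class_means(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Class means in latent space with pairwise distance == effect_size.

    Scaled standard-basis vectors give an exact regular simplex when the
    latent dimension allows it; otherwise random unit directions are used
    (pairwise distances then only approximate the effect size).
    """
    if spec.n_classes <= spec.n_latent:
        means = np.zeros((spec.n_classes, spec.n_latent))
        scale = spec.effect_size / np.sqrt(2.0)
        means[np.arange(spec.n_classes), np.arange(spec.n_classes)] = scale
        return means
    directions = rng.standard_normal((spec.n_classes, spec.n_latent))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    return directions * spec.effect_size / np.sqrt(2.0)


def generate_multiomics(
    spec: SyntheticSpec,
) -> tuple[list[OmicsMatrix], np.ndarray]:
    """Simulate aligned omics blocks and subtype labels.

    Returns one :class:`OmicsMatrix` per entry of ``features_per_omics``,
    all sharing the same sample identifiers in the same order, and an
    integer label vector with every class nonempty (labels are balanced up
    to remainder and shuffled).
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    labels = np.arange(spec.n_samples) % spec.n_classes
    labels = rng.permutation(labels)

    means = _class_means(spec, rng)
    latents = means[labels] + rng.standard_normal((spec.n_samples, spec.n_latent))
    sample_ids = [f"S{i:04d}" for i in range(spec.n_samples)]

    blocks: list[OmicsMatrix] = []
    for b, p in enumerate(spec.features_per_omics):
        loading = rng.standard_normal((spec.n_latent, p)) / np.sqrt(spec.n_latent)
        values = latents @ loading + spec.noise_sd * rng.standard_normal(
            (spec.n_samples, p)
        )
        mask = rng.random((spec.n_samples, p)) < spec.missing_rate
        blocks.append(
            OmicsMatrix(
                values=values,
                sample_ids=sample_ids,
                feature_ids=[f"omics{b + 1}_f{j:05d}" for j in range(p)],
                missing_mask=mask,
            )
        )
    return blocks, labels


def permute_dataset(
    omics: list[OmicsMatrix],
    labels: np.ndarray,
    mode: str = "labels",
    seed: int = 0,
) -> tuple[list[OmicsMatrix], np.ndarray]:
    """Destroy the feature-label association for overfitting controls.

    mode="labels" shuffles the label vector only (the standard permutation
    control); mode="rows" shuffles sample order independently within each
    omics block, destroying cross-omics sample alignment while leaving
    identifiers and the label vector in place. Either way the multiset of
    labels is unchanged.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if mode == "labels":
        return [m for m in omics], rng.permutation(labels)
    if mode == "rows":
        permuted = []
        for matrix in omics:
            order = rng.permutation(matrix.n_samples)
            permuted.append(
                OmicsMatrix(
                    values=matrix.values[order],
                    sample_ids=list(matrix.sample_ids),
                    feature_ids=list(matrix.feature_ids),
                    missing_mask=matrix.missing_mask[order],
                )
            )
        return permuted, labels.copy()
    raise ValueError(f"unknown permutation mode {mode!r}; expected 'labels' or 'rows'")
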