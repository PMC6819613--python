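"""Autoencoders: single layers, greedy stacking, and hierarchical integration.

A single autoencoder maps x in R^n to a code h = f(W x + b_x) in R^m and
reconstructs x' = W' h + b_h. Training minimises

    J(theta, theta') = (1/N) sum_i ||x(i) - d(e(x(i)))||^2  +  lambda ||W||_2^2

by plain (mini-)batch gradient descent; ||W||_2^2 is the sum of squared
encoder weights and the decoder is affine (identity output) because the
inputs are z-scored and therefore signed and unbounded. A stacked
autoencoder trains layers greedily, each on the previous layer's codes,
without end-to-end fine-tuning. Hierarchical integration trains one stacked
autoencoder per omics block and compresses the concatenated per-block codes
through one further autoencoder layer, so the final representation reflects
both within-block structure and cross-block correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np


class AutoencoderError(ValueError):
    """Raised on shape mismatches or invalid training configuration."""


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # name -> (f, f' as a function of the activation value)
    "tanh": (np.tanh, lambda h: 1.0 - h * h),
    "sigmoid": (lambda z: 1.0 / (1.0 + np.exp(-z)), lambda h: h * (1.0 - h)),
}


@dataclass
class AEParameters:
    """Weights of one autoencoder layer.

    W (m x n) and b_x (m,) parameterise the encoder; W_prime (n x m) and
    b_h (n,) the affine decoder. ``loss_trace`` records the training loss
    after each epoch when the parameters come out of :func:`train_ae`.
    """

    W: np.ndarray
    b_x: np.ndarray
    W_prime: np.ndarray
    b_h: np.ndarray
    loss_trace: list[float] = field(default_factory=list, compare=False)
    initial_loss: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b_x = np.asarray(self.b_x, dtype=float)
        self.W_prime = np.asarray(self.W_prime, dtype=float)
        self.b_h = np.asarray(self.b_h, dtype=float)
        m, n = self.W.shape
        if self.b_x.shape != (m,):
            raise AutoencoderError(f"b_x must have shape ({m},), got {self.b_x.shape}")
        if self.W_prime.shape != (n, m):
            raise AutoencoderError(
                f"W_prime must have shape ({n}, {m}), got {self.W_prime.shape}"
            )
        if self.b_h.shape != (n,):
            raise AutoencoderError(f"b_h must have shape ({n},), got {self.b_h.shape}")
        for name in ("W", "b_x", "W_prime", "b_h"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise AutoencoderError(f"{name} contains non-finite entries")

    @property
    def input_dim(self) -> int:
        return self.W.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent settings for one autoencoder layer.

    lambda_ is the L2 coefficient on the encoder weights; batch_size "full"
    means one gradient step per epoch on the whole sample.
    """

    lambda_: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int | str = "full"
    seed: int = 0
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise AutoencoderError(f"lambda_ must be >= 0, got {self.lambda_}")
        if self.learning_rate <= 0:
            raise AutoencoderError(
                f"learning_rate must be > 0, got {self.learning_rate}"
            )
        if self.epochs < 1:
            raise AutoencoderError(f"epochs must be >= 1, got {self.epochs}")
        if self.activation not in _ACTIVATIONS:
            raise AutoencoderError(
                f"activation must be one of {sorted(_ACTIVATIONS)}, got {self.activation!r}"
            )
        if self.batch_size != "full" and (
            not isinstance(self.batch_size, int) or self.batch_size < 1
        ):
            raise AutoencoderError(f"invalid batch_size {self.batch_size!r}")


@dataclass
class SAEModel:
    """Greedily trained stack of autoencoder layers."""

    layers: list[AEParameters]
    dims: list[int]
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if [l.hidden_dim for l in self.layers] != list(self.dims):
            raise AutoencoderError("layer hidden sizes disagree with dims")
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if nxt.input_dim != prev.hidden_dim:
                raise AutoencoderError(
                    f"layer input size {nxt.input_dim} != previous hidden size {prev.hidden_dim}"
                )

    @property
    def code_dim(self) -> int:
        return self.dims[-1]


@dataclass
class IntegrationModel:
    """Per-omics stacked autoencoders plus the integrating layer."""

    per_omics: list[SAEModel]
    integrator: AEParameters
    activation: str = "tanh"

    def __post_init__(self) -> None:
        total = sum(m.code_dim for m in self.per_omics)
        if self.integrator.input_dim != total:
            raise AutoencoderError(
                f"integrator input size {self.integrator.input_dim} != "
                f"sum of per-omics code sizes {total}"
            )


def encode(params: AEParameters, X: np.ndarray, activation: str = "tanh") -> np.ndarray:
    """Row-wise code f(X W^T + b_x)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.input_dim:
        raise AutoencoderError(
            f"X has {X.shape[1]} features, encoder expects {params.input_dim}"
        )
    f, _ = _ACTIVATIONS[activation]
    return f(X @ params.W.T + params.b_x)


def reconstruct(params: AEParameters, X: np.ndarray, activation: str = "tanh") -> np.ndarray:
    return encode(params, X, activation) @ params.W_prime.T + params.b_h


def ae_loss(
    params: AEParameters, X: np.ndarray, lambda_: float = 0.0, activation: str = "tanh"
) -> float:
    """Mean squared reconstruction error plus lambda * sum(W**2)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    resid = X - reconstruct(params, X, activation)
    mse = float(np.einsum("ij,ij->", resid, resid)) / X.shape[0]
    return mse + lambda_ * float(np.sum(params.W * params.W))


def _ae_gradients(
    params: AEParameters, X: np.ndarray, lambda_: float, activation: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the cost with respect to (W, b_x, W', b_h)."""
    f, fprime = _ACTIVATIONS[activation]
    N = X.shape[0]
    H = f(X @ params.W.T + params.b_x)
    Xhat = H @ params.W_prime.T + params.b_h
    dXhat = (2.0 / N) * (Xhat - X)
    dWp = dXhat.T @ H
    dbh = dXhat.sum(axis=0)
    dH = dXhat @ params.W_prime
    dZ = dH * fprime(H)
    dW = dZ.T @ X + 2.0 * lambda_ * params.W
    dbx = dZ.sum(axis=0)
    return dW, dbx, dWp, dbh


def initialize_parameters(
    n_features: int, hidden_dim: int, rng: np.random.Generator
) -> AEParameters:
    """Symmetric uniform init on +/- sqrt(6/(n+m)); biases start at zero."""
    limit = np.sqrt(6.0 / (n_features + hidden_dim))
    return AEParameters(
        W=rng.uniform(-limit, limit, size=(hidden_dim, n_features)),
        b_x=np.zeros(hidden_dim),
        W_prime=rng.uniform(-limit, limit, size=(n_features, hidden_dim)),
        b_h=np.zeros(n_features),
    )


def train_ae(X: np.ndarray, hidden_dim: int, config: TrainConfig) -> AEParameters:
    """Gradient-descent training of a single autoencoder layer.

    Parameters are initialised from the seeded generator, updated for
    ``config.epochs`` epochs, and the snapshot with the lowest recorded
    training loss is returned (its ``loss_trace`` holds the post-epoch
    losses; ``initial_loss`` the loss at initialisation).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if hidden_dim < 1:
        raise AutoencoderError(f"hidden_dim must be >= 1, got {hidden_dim}")
    if not np.all(np.isfinite(X)):
        raise AutoencoderError("X contains non-finite entries")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    params = initialize_parameters(X.shape[1], hidden_dim, rng)
    initial = ae_loss(params, X, config.lambda_, config.activation)

    n = X.shape[0]
    batch = n if config.batch_size == "full" else min(int(config.batch_size), n)
    trace: list[float] = []
    best: tuple[float, AEParameters] | None = None
    current = params
    for epoch in range(config.epochs):
        order = np.arange(n) if batch == n else rng.permutation(n)
        for start in range(0, n, batch):
            rows = X[order[start : start + batch]]
            dW, dbx, dWp, dbh = _ae_gradients(
                current, rows, config.lambda_, config.activation
            )
            current = AEParameters(
                W=current.W - config.learning_rate * dW,
                b_x=current.b_x - config.learning_rate * dbx,
                W_prime=current.W_prime - config.learning_rate * dWp,
                b_h=current.b_h - config.learning_rate * dbh,
            )
        loss = ae_loss(current, X, config.lambda_, config.activation)
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"training loss became non-finite at epoch {epoch + 1}"
            )
        trace.append(loss)
        if best is None or loss < best[0]:
            best = (loss, current)
    assert best is not None
    result = replace(best[1])
    result.loss_trace = trace
    result.initial_loss = initial
    return result


def train_sae(X: np.ndarray, dims: list[int], config: TrainConfig) -> SAEModel:
    """Greedy layer-wise stacking: layer i trains on layer i-1's codes."""
    if not dims or any(d < 1 for d in dims):
        raise AutoencoderError(f"dims must be nonempty positive counts, got {dims}")
    layers: list[AEParameters] = []
    current = np.atleast_2d(np.asarray(X, dtype=float))
    for i, d in enumerate(dims):
        layer_cfg = replace(config, seed=config.seed + i)
        try:
            layer = train_ae(current, d, layer_cfg)
        except (AutoencoderError, TrainingDivergedError) as err:
            raise type(err)(f"layer {i + 1}: {err}") from err
        layers.append(layer)
        current = encode(layer, current, config.activation)
    return SAEModel(layers=layers, dims=list(dims), activation=config.activation)


def sae_encode(model: SAEModel, X: np.ndarray) -> np.ndarray:
    code = np.atleast_2d(np.asarray(X, dtype=float))
    for layer in model.layers:
        code = encode(layer, code, model.activation)
    return code


def save_sae(model: SAEModel, path) -> None:
    """Write a stacked autoencoder to a single .npz archive.

    Layout: ``dims`` (int array), ``activation`` (str array of length 1),
    and per layer i the arrays ``layer{i}_W``, ``layer{i}_b_x``,
    ``layer{i}_W_prime``, ``layer{i}_b_h``. Floats round-trip exactly.
    """
    payload: dict[str, np.ndarray] = {
        "dims": np.asarray(model.dims, dtype=np.int64),
        "activation": np.asarray([model.activation]),
    }
    for i, layer in enumerate(model.layers):
        payload[f"layer{i}_W"] = layer.W
        payload[f"layer{i}_b_x"] = layer.b_x
        payload[f"layer{i}_W_prime"] = layer.W_prime
        payload[f"layer{i}_b_h"] = layer.b_h
    np.savez(path, **payload)


def load_sae(path) -> SAEModel:
    with np.load(path, allow_pickle=False) as archive:
        dims = [int(d) for d in archive["dims"]]
        activation = str(archive["activation"][0])
        layers = [
            AEParameters(
                W=archive[f"layer{i}_W"],
                b_x=archive[f"layer{i}_b_x"],
                W_prime=archive[f"layer{i}_W_prime"],
                b_h=archive[f"layer{i}_b_h"],
            )
            for i in range(len(dims))
        ]
    return SAEModel(layers=layers, dims=dims, activation=activation)


def integrate_representations(
    omics_codes: list[np.ndarray], integrator_dim: int, config: TrainConfig
) -> tuple[AEParameters, np.ndarray]:
    """Concatenate per-omics codes and compress through one trained layer."""
    codes = [np.atleast_2d(np.asarray(c, dtype=float)) for c in omics_codes]
    counts = {c.shape[0] for c in codes}
    if len(counts) != 1:
        raise AutoencoderError(
            f"omics code blocks disagree on sample count: {sorted(counts)}"
        )
    stacked = np.concatenate(codes, axis=1)
    layer = train_ae(stacked, integrator_dim, config)
    return layer, encode(layer, stacked, config.activation)
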