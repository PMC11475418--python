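"""Parametric t-SNE: a feed-forward projector from fingerprints to 2D.

Classic t-SNE places low-dimensional points directly by gradient descent
on the Kullback-Leibler divergence between a high-dimensional neighbor
distribution P (Gaussian kernels, per-point bandwidths calibrated to a
target perplexity) and a low-dimensional distribution Q (Student-t kernel
with one degree of freedom). The parametric variant instead trains the
weights of a neural network y = f(x) under the same loss, so that unseen
compounds can be projected onto an existing map (out-of-sample property).

The network is a plain multilayer perceptron — rectifier hidden layers,
linear 2D output — trained with Adam on minibatches; P is computed per
batch for scalability. Everything is seeded and deterministic: the same
config and seed reproduce the same weights bit for bit on one platform.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

DEFAULT_LAYERS = (2048, 500, 500, 2000, 2)

_EPS = 1e-12


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class TsneConfig:
    perplexity: float = 30.0
    layer_sizes: tuple[int, ...] = DEFAULT_LAYERS
    epochs: int = 300
    batch_size: int = 500
    learning_rate: float = 1e-3
    seed: int = 0
    input_metric: str = "euclidean"  # or "jaccard"
    exaggeration: float = 4.0  # early-exaggeration factor on P
    exaggeration_fraction: float = 0.25  # fraction of epochs exaggerated

    def __post_init__(self) -> None:
        if self.perplexity <= 0:
            raise ConfigurationError("perplexity must be positive")
        if self.layer_sizes[-1] != 2:
            raise ConfigurationError("last layer size must be 2")
        if self.input_metric not in ("euclidean", "jaccard"):
            raise ConfigurationError(f"unknown input_metric: {self.input_metric}")


@dataclass
class NeighborDistribution:
    """Symmetrized pairwise affinities P with per-point bandwidths."""

    p: np.ndarray  # (n, n), symmetric, zero diagonal, sums to 1
    sigmas: np.ndarray  # (n,) Gaussian bandwidths
    conditional: np.ndarray  # (n, n) row-stochastic p_{j|i}


@dataclass
class EmbeddingModel:
    """Trained projector: per-layer (W, b) arrays plus the training config."""

    weights: list[tuple[np.ndarray, np.ndarray]]
    config: TsneConfig
    training_loss_trace: list[float] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.weights[0][0].shape[0]


@dataclass(frozen=True)
class ProjectedPoint:
    x: float
    y: float
    inchi_key: str = ""
    family: str = ""
    aggregated_pchembl: Optional[float] = None


def _pairwise_sq_dists(X: np.ndarray, metric: str) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if metric == "euclidean":
        sq = np.sum(X * X, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        np.fill_diagonal(d2, 0.0)
        return np.maximum(d2, 0.0)
    # Jaccard distance on binary vectors, squared to mirror the
    # squared-Euclidean convention of the Gaussian kernel.
    inter = X @ X.T
    counts = X.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = 1.0 - np.where(union > 0, inter / union, 1.0)
    np.fill_diagonal(jac, 0.0)
    return jac**2


def _row_affinity(d2_row: np.ndarray, beta: float) -> tuple[np.ndarray, float]:
    """Gaussian affinities and Shannon entropy (nats) for one point at precision beta."""
    p = np.exp(-d2_row * beta)
    s = p.sum()
    if s <= 0:
        return np.zeros_like(p), 0.0
    p /= s
    nz = p > 0
    h = -np.sum(p[nz] * np.log(p[nz]))
    return p, h


def conditional_p(
    fingerprints: np.ndarray,
    perplexity: float,
    metric: str = "euclidean",
    max_iter: int = 200,
    tol: float = 1e-7,
) -> NeighborDistribution:
    """Calibrate per-point bandwidths and build the symmetrized P matrix.

    For each point i, a binary search on the Gaussian precision finds the
    bandwidth sigma_i such that the conditional distribution p_{.|i} has
    2**H equal to the target perplexity. The symmetrized affinities are
    p_ij = (p_{j|i} + p_{i|j}) / (2n), which sum to one over all pairs.
    """
    X = np.asarray(fingerprints, dtype=np.float64)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if perplexity >= n:
        raise ValueError(f"perplexity {perplexity} must be < n = {n}")
    d2 = _pairwise_sq_dists(X, metric)
    target_h = math.log(perplexity)  # entropy target in nats
    cond = np.zeros((n, n))
    sigmas = np.zeros(n)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        row = d2[i][mask[i]]
        beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
        p = None
        for _ in range(max_iter):
            p, h = _row_affinity(row, beta)
            diff = h - target_h
            if abs(diff) < tol:
                break
            if diff > 0:  # entropy too high -> sharpen
                beta_lo = beta
                beta = beta * 2.0 if not np.isfinite(beta_hi) else (beta + beta_hi) / 2.0
            else:
                beta_hi = beta
                beta = beta / 2.0 if beta_lo == 0.0 else (beta + beta_lo) / 2.0
        else:
            raise RuntimeError(
                f"perplexity calibration did not converge for point {i}"
            )
        cond[i][mask[i]] = p
        sigmas[i] = math.sqrt(1.0 / (2.0 * beta))
    p_sym = (cond + cond.T) / (2.0 * n)
    np.fill_diagonal(p_sym, 0.0)
    return NeighborDistribution(p=p_sym, sigmas=sigmas, conditional=cond)


def map_q(coordinates: np.ndarray) -> np.ndarray:
    """Student-t (1 d.o.f.) neighbor distribution over 2D map positions."""
    Y = np.asarray(coordinates, dtype=np.float64)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 points")
    sq = np.sum(Y * Y, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
    num = 1.0 / (1.0 + np.maximum(d2, 0.0))
    np.fill_diagonal(num, 0.0)
    return num / num.sum()


def kl_loss(p: np.ndarray, q: np.ndarray) -> float:
    """KL(P || Q) over off-diagonal pairs, with 0 * log 0 = 0."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("shape mismatch")
    nz = p > 0
    if np.any(q[nz] <= 0):
        raise ValueError("q is zero where p is positive")
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


# ---------------------------------------------------------------------------
# Feed-forward projector


def _init_weights(
    layer_sizes: Sequence[int], rng: np.random.Generator
) -> list[tuple[np.ndarray, np.ndarray]]:
    weights = []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        scale = math.sqrt(2.0 / fan_in)  # He init for rectifier layers
        W = rng.normal(0.0, scale, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((W, b))
    return weights


def _forward(
    weights: Sequence[tuple[np.ndarray, np.ndarray]], X: np.ndarray
) -> list[np.ndarray]:
    """Activations per layer; rectifiers on hidden layers, linear output."""
    acts = [X]
    a = X
    last = len(weights) - 1
    for i, (W, b) in enumerate(weights):
        z = a @ W + b
        a = z if i == last else np.maximum(z, 0.0)
        acts.append(a)
    return acts


def _backward(
    weights: Sequence[tuple[np.ndarray, np.ndarray]],
    acts: Sequence[np.ndarray],
    d_out: np.ndarray,
) -> list[tuple[np.ndarray, np.ndarray]]:
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(weights)  # type: ignore
    delta = d_out
    for i in range(len(weights) - 1, -1, -1):
        W, _ = weights[i]
        grads[i] = (acts[i].T @ delta, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ W.T) * (acts[i] > 0)
    return grads


def _tsne_grad_y(Y: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, float]:
    """Gradient of KL(P||Q) w.r.t. map coordinates, plus the loss value."""
    sq = np.sum(Y * Y, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Y @ Y.T)
    num = 1.0 / (1.0 + np.maximum(d2, 0.0))
    np.fill_diagonal(num, 0.0)
    Q = num / max(num.sum(), _EPS)
    PQ = (P - Q) * num
    dY = 4.0 * (np.diag(PQ.sum(axis=1)) @ Y - PQ @ Y)
    nz = P > 0
    loss = float(np.sum(P[nz] * np.log(P[nz] / np.maximum(Q[nz], _EPS))))
    return dY, loss


def train(fingerprints: np.ndarray, config: TsneConfig) -> EmbeddingModel:
    """Train the projector by minibatch Adam on the t-SNE KL loss.

    P is computed per batch from the batch's own pairwise distances. An
    early-exaggeration phase multiplies P for the first fraction of the
    epochs, which helps clusters separate before fine-tuning. Raises on a
    non-finite loss, reporting the last finite epoch.
    """
    X = np.asarray(fingerprints, dtype=np.float64)
    n, dim = X.shape
    if dim != config.layer_sizes[0]:
        raise ConfigurationError(
            f"fingerprint length {dim} != input layer {config.layer_sizes[0]}"
        )
    if config.perplexity >= n:
        raise ConfigurationError("perplexity must be < number of training points")
    rng = np.random.default_rng(config.seed)
    weights = _init_weights(config.layer_sizes, rng)
    batch = min(config.batch_size, n)

    # Adam state
    m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    n_exagg = int(config.epochs * config.exaggeration_fraction)
    trace: list[float] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            idx = perm[start : start + batch]
            if len(idx) <= config.perplexity or len(idx) < 3:
                continue  # remainder too small to calibrate; skipped
            Xb = X[idx]
            P = conditional_p(Xb, config.perplexity, metric=config.input_metric).p
            if epoch < n_exagg:
                P = P * config.exaggeration
            acts = _forward(weights, Xb)
            dY, loss = _tsne_grad_y(acts[-1], P)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"loss diverged at epoch {epoch}; last finite epoch "
                    f"{len(trace) - 1}"
                )
            losses.append(loss)
            grads = _backward(weights, acts, dY)
            step += 1
            lr_t = config.learning_rate * math.sqrt(1 - beta2**step) / (1 - beta1**step)
            for li, ((W, b), (gW, gb)) in enumerate(zip(weights, grads)):
                mW, mb = m[li]
                vW, vb = v[li]
                mW = beta1 * mW + (1 - beta1) * gW
                mb = beta1 * mb + (1 - beta1) * gb
                vW = beta2 * vW + (1 - beta2) * gW**2
                vb = beta2 * vb + (1 - beta2) * gb**2
                m[li] = (mW, mb)
                v[li] = (vW, vb)
                weights[li] = (
                    W - lr_t * mW / (np.sqrt(vW) + eps),
                    b - lr_t * mb / (np.sqrt(vb) + eps),
                )
        trace.append(float(np.mean(losses)) if losses else float("nan"))
    return EmbeddingModel(weights=weights, config=config, training_loss_trace=trace)


def transform(model: EmbeddingModel, fingerprints: np.ndarray) -> np.ndarray:
    """Deterministic forward pass: (n, 2) map coordinates."""
    X = np.asarray(fingerprints, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.input_dim:
        raise ValueError(
            f"fingerprint length {X.shape[1]} != model input {model.input_dim}"
        )
    return _forward(model.weights, X)[-1]


def project(
    model: EmbeddingModel,
    fingerprints: np.ndarray,
    inchi_keys: Optional[Sequence[str]] = None,
    families: Optional[Sequence[str]] = None,
    aggregated_pchembl: Optional[Sequence[Optional[float]]] = None,
) -> list[ProjectedPoint]:
    """Project points (training or out-of-sample) with optional metadata."""
    Y = transform(model, fingerprints)
    n = Y.shape[0]
    keys = list(inchi_keys) if inchi_keys is not None else [""] * n
    fams = list(families) if families is not None else [""] * n
    pchs = list(aggregated_pchembl) if aggregated_pchembl is not None else [None] * n
    if not (len(keys) == len(fams) == len(pchs) == n):
        raise ValueError("metadata length mismatch")
    return [
        ProjectedPoint(
            x=float(Y[i, 0]),
            y=float(Y[i, 1]),
            inchi_key=keys[i],
            family=fams[i],
            aggregated_pchembl=pchs[i],
        )
        for i in range(n)
    ]


def trustworthiness(
    high_dim: np.ndarray, low_dim: np.ndarray, k: int = 12, metric: str = "euclidean"
) -> float:
    """Fraction-of-preserved-neighborhood statistic in [0, 1].

    Penalizes points that enter a map neighborhood without being close in
    the original space (the standard rank-based definition).
    """
    from sklearn.manifold import trustworthiness as _tw

    X = np.asarray(high_dim, dtype=np.float64)
    if k >= X.shape[0] / 2:
        raise ValueError("k must be < n/2")
    return float(_tw(X, np.asarray(low_dim, dtype=np.float64), n_neighbors=k, metric=metric))


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: EmbeddingModel, directory: str | Path) -> Path:
    """Write weights (.npz) plus a JSON sidecar with the training config."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, (W, b) in enumerate(model.weights):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    np.savez(directory / "weights.npz", **arrays)
    sidecar = {
        "config": asdict(model.config),
        "n_layers": len(model.weights),
        "training_loss_trace": model.training_loss_trace,
    }
    (directory / "model.json").write_text(json.dumps(sidecar, indent=2))
    return directory


def load_model(directory: str | Path) -> EmbeddingModel:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    cfg_dict = sidecar["config"]
    cfg_dict["layer_sizes"] = tuple(cfg_dict["layer_sizes"])
    config = TsneConfig(**cfg_dict)
    data = np.load(directory / "weights.npz")
    weights = [
        (data[f"W{i}"], data[f"b{i}"]) for i in range(sidecar["n_layers"])
    ]
    return EmbeddingModel(
        weights=weights,
        config=config,
        training_loss_trace=list(sidecar["training_loss_trace"]),
    )
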