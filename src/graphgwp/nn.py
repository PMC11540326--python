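"""Graph-convolution building blocks for phenotype regression.

The network is fixed at two graph-convolution layers followed by a linear
head mapping each vertex's embedding to a scalar phenotype, with ReLU and
dropout between the two convolutions. Three propagation modes are
supported:

``normalized_gcn``
    H' = sigma( D̃^{-1/2} Ã D̃^{-1/2} H W ), the symmetric-normalized
    convolution used by the whole-graph model.
``mean_aggregator``
    h_v = sigma( W · mean{h_u : u in N(v)} + B · h_v ), the neighborhood
    mean aggregation with a separate self-weight.
``sample_aggregate``
    h_v = sigma( W · [AGG{h_u : u in S(v)}, h_v] ), aggregation over a
    sampled neighbor subset concatenated with the vertex's own embedding.

Autograd is not used anywhere: gradients are computed in closed form by
:func:`backward_full`, which keeps the package dependency-light and every
update inspectable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .graph import NeighborGraph

logger = logging.getLogger(__name__)

__all__ = [
    "LayerWeights",
    "GCNModel",
    "PredictionVector",
    "PROPAGATION_MODES",
    "gcn_layer_forward",
    "mean_aggregate_forward",
    "sample_aggregate_forward",
    "row_normalized_adjacency",
    "init_gcn_model",
    "forward",
    "forward_full",
    "backward_full",
    "mse_loss",
    "save_model",
    "load_model",
]

PROPAGATION_MODES = ("normalized_gcn", "mean_aggregator", "sample_aggregate")

_ACTIVATIONS = {
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(z.dtype)),
}


def _act(name: str):
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; options: {sorted(_ACTIVATIONS)}")


@dataclass
class LayerWeights:
    """Weights of one graph-convolution layer.

    ``W`` multiplies the aggregated neighborhood signal; ``B`` (optional)
    multiplies the vertex's own previous embedding; ``b`` is an optional
    bias; ``activation`` names the nonlinearity.
    """

    W: np.ndarray
    b: np.ndarray | None = None
    B: np.ndarray | None = None
    activation: str = "identity"

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if self.b is not None:
            self.b = np.asarray(self.b, dtype=float)
        if self.B is not None:
            self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        for name, arr in (("W", self.W), ("b", self.b), ("B", self.B)):
            if arr is not None and not np.all(np.isfinite(arr)):
                raise ValueError(f"layer weight {name} has non-finite entries")
        _act(self.activation)


@dataclass
class PredictionVector:
    """Per-vertex predicted phenotypes."""

    vertex_indices: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.vertex_indices = np.asarray(self.vertex_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.vertex_indices.shape != self.values.shape:
            raise ValueError("one prediction per requested vertex required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite predictions")


@dataclass
class GCNModel:
    """Two-convolution-layer regression network.

    ``params`` maps names (W1, b1, [B1], W2, b2, [B2], head_w, head_b) to
    arrays. ``x_center``/``x_scale``/``y_center``/``y_scale`` hold the
    feature and label standardization fitted on the training vertices so
    predictions come back on the original phenotype scale.
    """

    params: dict[str, np.ndarray]
    propagation_mode: str = "normalized_gcn"
    dropout_p: float = 0.5
    activations: tuple[str, str] = ("relu", "identity")
    rng_seed: int = 0
    x_center: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_center: float = 0.0
    y_scale: float = 1.0
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.propagation_mode not in PROPAGATION_MODES:
            raise ValueError(f"unknown propagation mode {self.propagation_mode!r}")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


# ---------------------------------------------------------------------------
# standalone layer operations


def gcn_layer_forward(
    H: np.ndarray, A_norm: np.ndarray | sp.spmatrix, layer: LayerWeights
) -> np.ndarray:
    """One normalized graph convolution: sigma(A_norm @ H @ W [+ b])."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    if A_norm.shape[1] != H.shape[0] or H.shape[1] != layer.W.shape[0]:
        raise ValueError(
            f"shape mismatch: A_norm {A_norm.shape}, H {H.shape}, W {layer.W.shape}"
        )
    Z = A_norm @ H @ layer.W
    if layer.b is not None:
        Z = Z + layer.b
    return _act(layer.activation)[0](Z)


def mean_aggregate_forward(
    h_prev: np.ndarray, neighbors: list, layer: LayerWeights
) -> np.ndarray:
    """Neighborhood-mean aggregation with a self-weight path.

    h_v = sigma( W·mean{h_u : u in N(v)} + B·h_v [+ b] ), computed for all
    vertices synchronously from the previous-layer snapshot. ``neighbors``
    excludes the vertex itself (the self path is the B term).
    """
    H = np.atleast_2d(np.asarray(h_prev, dtype=float))
    n = H.shape[0]
    if len(neighbors) != n:
        raise ValueError("one neighbor set per vertex required")
    agg = np.empty_like(H)
    for v, nbrs in enumerate(neighbors):
        nbrs = np.asarray(sorted(nbrs), dtype=int)
        if nbrs.size == 0:
            raise ValueError(f"vertex {v} has an empty neighborhood and no self-loop")
        agg[v] = H[nbrs].mean(axis=0)
    Z = agg @ layer.W
    if layer.B is not None:
        Z = Z + H @ layer.B
    if layer.b is not None:
        Z = Z + layer.b
    return _act(layer.activation)[0](Z)


def sample_aggregate_forward(
    h_prev: np.ndarray,
    sampled_neighbors: list,
    layer: LayerWeights,
    agg: str = "mean",
) -> np.ndarray:
    """Sampled-neighborhood aggregation with concatenation.

    h_v = sigma( W · [AGG{h_u : u in S(v)}, h_v] [+ b] ); AGG is ``mean``
    or ``max`` over the sampled subset. An empty sample falls back to the
    vertex's own embedding for the AGG slot (logged).
    """
    if agg not in ("mean", "max"):
        raise ValueError(f"aggregator must be 'mean' or 'max', got {agg!r}")
    H = np.atleast_2d(np.asarray(h_prev, dtype=float))
    n = H.shape[0]
    if len(sampled_neighbors) != n:
        raise ValueError("one sampled-neighbor set per vertex required")
    slot = np.empty_like(H)
    for v, nbrs in enumerate(sampled_neighbors):
        nbrs = np.asarray(sorted(nbrs), dtype=int)
        if nbrs.size == 0:
            logger.info("vertex %d sampled no neighbors; using self embedding", v)
            slot[v] = H[v]
        elif agg == "mean":
            slot[v] = H[nbrs].mean(axis=0)
        else:
            slot[v] = H[nbrs].max(axis=0)
    Z = np.hstack([slot, H]) @ layer.W
    if layer.b is not None:
        Z = Z + layer.b
    return _act(layer.activation)[0](Z)


def mse_loss(pred, truth) -> float:
    """Mean squared error between aligned prediction and truth vectors."""
    p = pred.values if isinstance(pred, PredictionVector) else np.asarray(pred, float)
    t = getattr(truth, "values", truth)
    t = np.asarray(t, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: pred {p.shape} vs truth {t.shape}")
    if p.size < 1:
        raise ValueError("need at least one value")
    return float(np.mean((p - t) ** 2))


# ---------------------------------------------------------------------------
# whole-network forward / backward


def row_normalized_adjacency(g: NeighborGraph) -> sp.csr_matrix:
    """Row-stochastic neighbor-mean operator M (self excluded).

    M[v] averages v's neighbors; a vertex without neighbors falls back to
    a self-loop so the mean slot degrades to the vertex's own embedding.
    """
    A = g.adjacency.tocsr().astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    isolated = np.flatnonzero(deg == 0)
    if isolated.size:
        A = A.tolil()
        for v in isolated:
            A[v, v] = 1.0
        A = A.tocsr()
        deg = np.asarray(A.sum(axis=1)).ravel()
    return (sp.diags(1.0 / deg) @ A).tocsr()


def propagation_operator(g: NeighborGraph, mode: str) -> sp.csr_matrix:
    from .graph import normalize_adjacency

    if mode == "normalized_gcn":
        return normalize_adjacency(g)
    if mode in ("mean_aggregator", "sample_aggregate"):
        return row_normalized_adjacency(g)
    raise ValueError(f"unknown propagation mode {mode!r}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_gcn_model(
    n_features: int,
    hidden_widths: tuple[int, int] = (64, 32),
    propagation_mode: str = "normalized_gcn",
    dropout_p: float = 0.5,
    rng: np.random.Generator | int = 0,
) -> GCNModel:
    """Glorot-uniform initialization of a two-layer network.

    The RNG draw order (W1, [B1], W2, [B2], head) is fixed so runs are
    reproducible given the generator state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    h1, h2 = hidden_widths
    p: dict[str, np.ndarray] = {}
    if propagation_mode == "sample_aggregate":
        p["W1"] = _glorot(rng, 2 * n_features, h1)
        p["b1"] = np.zeros(h1)
        p["W2"] = _glorot(rng, 2 * h1, h2)
        p["b2"] = np.zeros(h2)
    elif propagation_mode == "mean_aggregator":
        p["W1"] = _glorot(rng, n_features, h1)
        p["B1"] = _glorot(rng, n_features, h1)
        p["b1"] = np.zeros(h1)
        p["W2"] = _glorot(rng, h1, h2)
        p["B2"] = _glorot(rng, h1, h2)
        p["b2"] = np.zeros(h2)
    else:
        p["W1"] = _glorot(rng, n_features, h1)
        p["b1"] = np.zeros(h1)
        p["W2"] = _glorot(rng, h1, h2)
        p["b2"] = np.zeros(h2)
    p["head_w"] = _glorot(rng, h2, 1)
    p["head_b"] = np.zeros(1)
    return GCNModel(params=p, propagation_mode=propagation_mode, dropout_p=dropout_p)


def _conv(mode: str, P: sp.spmatrix, H: np.ndarray, W, B, b):
    """Pre-activation of one convolution layer; returns (C, cache)."""
    if mode == "sample_aggregate":
        F = np.hstack([P @ H, H])
        C = F @ W
        cache = {"F": F}
    elif mode == "mean_aggregator":
        PH = P @ H
        C = PH @ W + H @ B
        cache = {"PH": PH, "H": H}
    else:
        PH = P @ H
        C = PH @ W
        cache = {"PH": PH}
    if b is not None:
        C = C + b
    return C, cache


def _conv_backward(mode: str, P: sp.spmatrix, dC: np.ndarray, W, cache, B=None):
    """Gradients of one convolution layer w.r.t. weights and input."""
    grads = {}
    if mode == "sample_aggregate":
        grads["W"] = cache["F"].T @ dC
        dF = dC @ W.T
        d = W.shape[0] // 2
        dH = P.T @ dF[:, :d] + dF[:, d:]
    elif mode == "mean_aggregator":
        grads["W"] = cache["PH"].T @ dC
        grads["B"] = cache["H"].T @ dC
        dH = P.T @ (dC @ W.T) + dC @ B.T
    else:
        grads["W"] = cache["PH"].T @ dC
        dH = P.T @ (dC @ W.T)
    grads["b"] = dC.sum(axis=0)
    return grads, dH


def forward_full(
    model: GCNModel,
    P: sp.spmatrix,
    X: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
):
    """Full forward pass; returns (predictions, caches for backward).

    Stages: conv1 -> ReLU -> dropout (train mode only) -> conv2 ->
    linear head -> one scalar per vertex.
    """
    p = model.params
    mode = model.propagation_mode
    act1, dact1 = _act(model.activations[0])
    act2, _ = _act(model.activations[1])

    C1, cache1 = _conv(mode, P, X, p["W1"], p.get("B1"), p["b1"])
    H1 = act1(C1)
    if train_mode and model.dropout_p > 0.0:
        if rng is None:
            rng = np.random.default_rng(model.rng_seed)
        keep = 1.0 - model.dropout_p
        mask = (rng.random(H1.shape) < keep).astype(float) / keep
    else:
        mask = None
    H1d = H1 * mask if mask is not None else H1
    C2, cache2 = _conv(mode, P, H1d, p["W2"], p.get("B2"), p["b2"])
    H2 = act2(C2)
    pred = (H2 @ p["head_w"]).ravel() + p["head_b"][0]
    for name, arr in (("conv1", C1), ("conv2", C2), ("head", pred)):
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(f"non-finite activations at stage {name}")
    caches = {
        "P": P,
        "X": X,
        "C1": C1,
        "H1": H1,
        "mask": mask,
        "H1d": H1d,
        "C2": C2,
        "H2": H2,
        "cache1": cache1,
        "cache2": cache2,
    }
    return pred, caches


def backward_full(model: GCNModel, caches: dict, dpred: np.ndarray) -> dict:
    """Closed-form gradients of the network for a given output gradient."""
    p = model.params
    mode = model.propagation_mode
    P = caches["P"]
    _, dact1 = _act(model.activations[0])
    _, dact2 = _act(model.activations[1])

    dpred = np.asarray(dpred, dtype=float).reshape(-1, 1)
    grads: dict[str, np.ndarray] = {}
    grads["head_w"] = caches["H2"].T @ dpred
    grads["head_b"] = dpred.sum(axis=0)
    dH2 = dpred @ p["head_w"].T
    dC2 = dH2 * dact2(caches["C2"])
    g2, dH1d = _conv_backward(mode, P, dC2, p["W2"], caches["cache2"], p.get("B2"))
    grads["W2"] = g2["W"]
    grads["b2"] = g2["b"]
    if "B" in g2:
        grads["B2"] = g2["B"]
    dH1 = dH1d * caches["mask"] if caches["mask"] is not None else dH1d
    dC1 = dH1 * dact1(caches["C1"])
    g1, _ = _conv_backward(mode, P, dC1, p["W1"], caches["cache1"], p.get("B1"))
    grads["W1"] = g1["W"]
    grads["b1"] = g1["b"]
    if "B" in g1:
        grads["B1"] = g1["B"]
    return grads


def forward(
    model: GCNModel,
    graph_or_operator,
    X: np.ndarray,
    train_mode: bool = False,
    seed: int | None = None,
    vertices: np.ndarray | None = None,
) -> PredictionVector:
    """Evaluate the network on a graph and return per-vertex predictions.

    Features and output are (de)standardized with the scalers stored on
    the model. Dropout is active only in ``train_mode`` and is drawn
    reproducibly from ``seed``.
    """
    P = (
        propagation_operator(graph_or_operator, model.propagation_mode)
        if isinstance(graph_or_operator, NeighborGraph)
        else graph_or_operator
    )
    X = np.asarray(X, dtype=float)
    if model.x_center is not None:
        X = (X - model.x_center) / model.x_scale
    rng = np.random.default_rng(model.rng_seed if seed is None else seed)
    pred, _ = forward_full(model, P, X, train_mode=train_mode, rng=rng)
    pred = pred * model.y_scale + model.y_center
    if vertices is None:
        vertices = np.arange(len(pred))
    vertices = np.asarray(vertices, dtype=int)
    return PredictionVector(vertex_indices=vertices, values=pred[vertices])


# ---------------------------------------------------------------------------
# checkpointing


_CHECKPOINT_VERSION = 1


def save_model(model: GCNModel, path) -> None:
    """Single-file checkpoint: named weight arrays + JSON-encoded config."""
    meta = {
        "version": _CHECKPOINT_VERSION,
        "propagation_mode": model.propagation_mode,
        "dropout_p": model.dropout_p,
        "activations": list(model.activations),
        "rng_seed": model.rng_seed,
        "y_center": model.y_center,
        "y_scale": model.y_scale,
        "config": model.config,
    }
    arrays = dict(model.params)
    if model.x_center is not None:
        arrays["_x_center"] = model.x_center
        arrays["_x_scale"] = model.x_scale
    np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> GCNModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta["version"] != _CHECKPOINT_VERSION:
            warnings.warn(f"checkpoint version {meta['version']} != {_CHECKPOINT_VERSION}")
        params = {
            k: data[k] for k in data.files if not k.startswith("_")
        }
        x_center = data["_x_center"] if "_x_center" in data.files else None
        x_scale = data["_x_scale"] if "_x_scale" in data.files else None
    return GCNModel(
        params=params,
        propagation_mode=meta["propagation_mode"],
        dropout_p=meta["dropout_p"],
        activations=tuple(meta["activations"]),
        rng_seed=meta["rng_seed"],
        x_center=x_center,
        x_scale=x_scale,
        y_center=meta["y_center"],
        y_scale=meta["y_scale"],
        config=meta.get("config", {}),
    )
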