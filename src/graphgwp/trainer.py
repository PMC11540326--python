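"""Training loops for the whole-graph GCN and the sub-sampling ensemble.

Two procedures are provided. ``train_gcn`` fits a single network on the
full training partition, with per-epoch validation MSE driving early
stopping. ``train_gcn_rs`` randomly partitions the training vertices into
sub-graphs, fits one network per sub-graph (each early-stopped on the
shared validation set), and combines the members by averaging their
predictions.

Because cross-partition edges are zeroed before training, the graph is
block-diagonal over train/validation/test: propagation restricted to one
partition block is exactly propagation on the whole graph. The loops
therefore operate on induced blocks, which also makes the ensemble with a
single sub-graph reproduce the whole-graph procedure bit-for-bit under a
shared seed.

Optimization is plain Adam with bias correction; no learning-rate
schedule beyond Adam's own adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from . import nn
from .graph import (
    DataSplit,
    NeighborGraph,
    induced_subgraph,
    sample_subgraphs,
)
from .nn import GCNModel, PredictionVector
from .snp_data import MarkerMatrix, PhenotypeVector

__all__ = [
    "GCNConfig",
    "TrainHistory",
    "EnsembleModel",
    "train_gcn",
    "train_gcn_rs",
    "predict",
    "adam_step",
    "tune",
    "TrialPruned",
    "TuneResult",
]

# seed-sequence key for the sub-graph sampler, outside the member-key range
_SAMPLER_KEY = 2**20


@dataclass
class GCNConfig:
    """Hyper-parameters of the graph regression models.

    Defaults are the tuned operating point: learning rate 0.0025, 250
    epochs, K = 3 graph neighbors and 10 sub-graphs for the ensemble.
    ``propagation_mode`` None selects the symmetric-normalized convolution
    for the whole-graph model and the mean aggregator for ensemble
    members; set it explicitly to force one mode everywhere.
    """

    learning_rate: float = 0.0025
    epochs: int = 250
    k_neighbors: int = 3
    n_subgraphs: int = 10
    hidden_widths: tuple[int, int] = (64, 32)
    dropout_p: float = 0.5
    patience: int = 10
    seed: int = 0
    propagation_mode: str | None = None
    aggregation: str = "mean_prediction"
    subgraph_policy: str = "disjoint_partition"
    standardize: bool = True
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.k_neighbors < 1 or self.n_subgraphs < 1:
            raise ValueError("epochs, k_neighbors and n_subgraphs must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")
        if len(self.hidden_widths) != 2 or min(self.hidden_widths) < 1:
            raise ValueError("hidden_widths must be two positive layer widths")
        if self.aggregation not in ("mean_prediction", "mean_embedding_then_linear"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.propagation_mode is not None and self.propagation_mode not in nn.PROPAGATION_MODES:
            raise ValueError(f"unknown propagation mode {self.propagation_mode!r}")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["hidden_widths"] = list(self.hidden_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GCNConfig":
        d = dict(d)
        if "hidden_widths" in d:
            d["hidden_widths"] = tuple(d["hidden_widths"])
        return cls(**d)


@dataclass
class TrainHistory:
    """Per-epoch losses (original phenotype scale) and stopping bookkeeping."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch]


@dataclass
class EnsembleModel:
    """Collection of sub-graph-trained networks with an aggregation rule."""

    members: list[GCNModel]
    aggregation: str = "mean_prediction"
    config: GCNConfig | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        modes = {m.propagation_mode for m in self.members}
        shapes = {tuple(sorted((k, v.shape) for k, v in m.params.items())) for m in self.members}
        if len(modes) > 1 or len(shapes) > 1:
            raise ValueError("ensemble members must share one architecture")

    @property
    def n_members(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# Adam


def adam_step(
    weights: dict[str, np.ndarray],
    gradients: dict[str, np.ndarray],
    state: dict | None,
    learning_rate: float,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> tuple[dict[str, np.ndarray], dict]:
    """One bias-corrected Adam update; returns (new weights, new state).

    ``state`` holds first/second moment accumulators and the step count;
    pass None to start from zeroed moments.
    """
    if state is None:
        state = {
            "m": {k: np.zeros_like(v) for k, v in weights.items()},
            "v": {k: np.zeros_like(v) for k, v in weights.items()},
            "t": 0,
        }
    t = state["t"] + 1
    new_w, new_m, new_v = {}, {}, {}
    for k, w in weights.items():
        g = np.asarray(gradients[k], dtype=float).reshape(w.shape)
        m = beta1 * state["m"][k] + (1.0 - beta1) * g
        v = beta2 * state["v"][k] + (1.0 - beta2) * g * g
        m_hat = m / (1.0 - beta1**t)
        v_hat = v / (1.0 - beta2**t)
        new_w[k] = w - learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        new_m[k], new_v[k] = m, v
    return new_w, {"m": new_m, "v": new_v, "t": t}


# ---------------------------------------------------------------------------
# shared single-network loop


def _as_array(X) -> np.ndarray:
    if isinstance(X, MarkerMatrix):
        return np.asarray(X.dosages, dtype=float)
    return np.asarray(X, dtype=float)


def _as_phenotypes(Y) -> np.ndarray:
    if isinstance(Y, PhenotypeVector):
        return np.asarray(Y.values, dtype=float)
    return np.asarray(Y, dtype=float)


def _check_zeroed(graph: NeighborGraph, split: DataSplit) -> None:
    lab = split.labels(graph.n_vertices)
    A = graph.adjacency.tocoo()
    li, lj = lab[A.row], lab[A.col]
    if np.any((li >= 0) & (lj >= 0) & (li != lj)):
        raise ValueError(
            "graph still has cross-partition edges; call zero_cross_partition_edges first"
        )


def _train_single(
    train_graph: NeighborGraph,
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    val_graph: NeighborGraph,
    X_va: np.ndarray,
    y_va: np.ndarray,
    config: GCNConfig,
    mode: str,
    member_key: int,
) -> tuple[GCNModel, TrainHistory]:
    """Fit one network on a training block, early-stopping on a validation block."""
    if X_tr.shape[0] < 2:
        raise ValueError(
            "training block has fewer than 2 vertices; use fewer sub-graphs"
        )
    rng = np.random.default_rng([config.seed, member_key])

    if config.standardize:
        x_center = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        x_scale = np.where(sd > 0, sd, 1.0)
        y_center = float(y_tr.mean())
        y_sd = float(y_tr.std())
        y_scale = y_sd if y_sd > 0 else 1.0
    else:
        x_center = np.zeros(X_tr.shape[1])
        x_scale = np.ones(X_tr.shape[1])
        y_center, y_scale = 0.0, 1.0

    Xt = (X_tr - x_center) / x_scale
    Xv = (X_va - x_center) / x_scale
    yt = (y_tr - y_center) / y_scale

    model = nn.init_gcn_model(
        n_features=X_tr.shape[1],
        hidden_widths=config.hidden_widths,
        propagation_mode=mode,
        dropout_p=config.dropout_p,
        rng=rng,
    )
    model.x_center, model.x_scale = x_center, x_scale
    model.y_center, model.y_scale = y_center, y_scale
    model.rng_seed = config.seed
    model.config = config.to_dict()

    P_tr = nn.propagation_operator(train_graph, mode)
    P_va = nn.propagation_operator(val_graph, mode)

    history = TrainHistory()
    state = None
    best_val = np.inf
    best_params = model.copy_params()
    since_best = 0
    n_tr = len(yt)

    for epoch in range(config.epochs):
        try:
            pred, caches = nn.forward_full(model, P_tr, Xt, train_mode=True, rng=rng)
        except FloatingPointError as exc:
            raise RuntimeError(
                f"training diverged at epoch {epoch}: {exc}; "
                f"last train loss {history.train_loss[-1] if history.train_loss else 'n/a'}"
            ) from exc
        resid = pred - yt
        loss_std = float(np.mean(resid**2))
        grads = nn.backward_full(model, caches, 2.0 * resid / n_tr)
        model.params, state = adam_step(
            model.params, grads, state, config.learning_rate,
            config.beta1, config.beta2, config.eps,
        )

        val_pred, _ = nn.forward_full(model, P_va, Xv, train_mode=False)
        val_mse = float(np.mean((val_pred * y_scale + y_center - y_va) ** 2))
        history.train_loss.append(loss_std * y_scale**2)
        history.val_loss.append(val_mse)

        if val_mse < best_val:
            best_val = val_mse
            best_params = model.copy_params()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break
    history.stopped_epoch = len(history.val_loss) - 1
    model.params = best_params
    return model, history


def train_gcn(
    graph: NeighborGraph,
    split: DataSplit,
    X,
    Y,
    config: GCNConfig | None = None,
) -> tuple[GCNModel, TrainHistory]:
    """Whole-graph training: Adam on training-vertex MSE, validation early stop.

    The graph must already have cross-partition edges zeroed; validation
    and test labels are never touched by the gradient (only Y over the
    training vertices enters the loss, and only Y over the validation
    vertices drives early stopping). Returns the weights of the best
    validation epoch.
    """
    config = config or GCNConfig()
    X, Y = _as_array(X), _as_phenotypes(Y)
    _check_zeroed(graph, split)
    for name, idx in (("train", split.train_idx), ("val", split.val_idx)):
        if idx.size == 0:
            raise ValueError(f"{name} partition is empty")
    mode = config.propagation_mode or "normalized_gcn"
    return _train_single(
        induced_subgraph(graph, split.train_idx),
        X[split.train_idx],
        Y[split.train_idx],
        induced_subgraph(graph, split.val_idx),
        X[split.val_idx],
        Y[split.val_idx],
        config,
        mode,
        member_key=0,
    )


def train_gcn_rs(
    graph: NeighborGraph,
    split: DataSplit,
    X,
    Y,
    config: GCNConfig | None = None,
) -> tuple[EnsembleModel, list[TrainHistory]]:
    """Sub-sampling ensemble: one network per random training sub-graph.

    The training vertices are shuffled and partitioned into
    ``config.n_subgraphs`` near-equal units; each member trains on its
    unit's induced sub-graph and labels and early-stops independently on
    the shared validation set. Member i draws its weights and dropout from
    seed key (config.seed, i), so a single-member ensemble reproduces
    ``train_gcn`` on the induced training graph exactly (when the same
    propagation mode is forced).
    """
    config = config or GCNConfig()
    X, Y = _as_array(X), _as_phenotypes(Y)
    _check_zeroed(graph, split)
    if split.val_idx.size == 0:
        raise ValueError("validation partition is empty")
    mode = config.propagation_mode or "mean_aggregator"

    batch = sample_subgraphs(
        graph,
        split,
        n_subgraphs=config.n_subgraphs,
        policy=config.subgraph_policy,
        seed=np.random.default_rng([config.seed, _SAMPLER_KEY]).integers(2**31),
    )
    val_graph = induced_subgraph(graph, split.val_idx)
    X_va, y_va = X[split.val_idx], Y[split.val_idx]

    members: list[GCNModel] = []
    histories: list[TrainHistory] = []
    for i, sub in enumerate(batch.subgraphs):
        if sub.vertex_indices.size < 2:
            raise ValueError(
                f"sub-graph {i} has {sub.vertex_indices.size} vertices; "
                "reduce n_subgraphs"
            )
        model, hist = _train_single(
            sub.graph,
            X[sub.vertex_indices],
            Y[sub.vertex_indices],
            val_graph,
            X_va,
            y_va,
            config,
            mode,
            member_key=i,
        )
        members.append(model)
        histories.append(hist)
    return EnsembleModel(members=members, aggregation=config.aggregation, config=config), histories


# ---------------------------------------------------------------------------
# prediction


def _predict_single(model: GCNModel, graph: NeighborGraph, X, vertices) -> PredictionVector:
    return nn.forward(model, graph, _as_array(X), train_mode=False, vertices=vertices)


def predict(
    model_or_ensemble: GCNModel | EnsembleModel,
    graph: NeighborGraph,
    X,
    vertices=None,
) -> PredictionVector:
    """Deterministic evaluation-mode predictions for the requested vertices.

    A single model runs one forward pass; an ensemble aggregates member
    outputs (mean of predictions, or mean of second-layer embeddings
    through the averaged linear head for ``mean_embedding_then_linear``).
    """
    n = graph.n_vertices
    if vertices is None:
        vertices = np.arange(n)
    vertices = np.asarray(vertices, dtype=int)
    if vertices.size and (vertices.min() < 0 or vertices.max() >= n):
        raise ValueError(f"unknown vertex index (graph has {n} vertices)")

    if isinstance(model_or_ensemble, GCNModel):
        return _predict_single(model_or_ensemble, graph, X, vertices)

    ens = model_or_ensemble
    Xa = _as_array(X)
    if ens.aggregation == "mean_prediction":
        stacked = np.stack(
            [_predict_single(m, graph, Xa, vertices).values for m in ens.members]
        )
        return PredictionVector(vertices, stacked.mean(axis=0))

    # mean_embedding_then_linear: average members' final embeddings, then the
    # averaged linear head, de-standardized with the averaged label scalers.
    P_cache: dict[str, object] = {}
    H_sum = None
    for m in ens.members:
        P = P_cache.setdefault(
            m.propagation_mode, nn.propagation_operator(graph, m.propagation_mode)
        )
        Xs = (Xa - m.x_center) / m.x_scale if m.x_center is not None else Xa
        _, caches = nn.forward_full(m, P, Xs, train_mode=False)
        H_sum = caches["H2"] if H_sum is None else H_sum + caches["H2"]
    H_bar = H_sum / ens.n_members
    head_w = np.mean([m.params["head_w"] for m in ens.members], axis=0)
    head_b = float(np.mean([m.params["head_b"] for m in ens.members]))
    y_scale = float(np.mean([m.y_scale for m in ens.members]))
    y_center = float(np.mean([m.y_center for m in ens.members]))
    pred = ((H_bar @ head_w).ravel() + head_b) * y_scale + y_center
    return PredictionVector(vertices, pred[vertices])


# ---------------------------------------------------------------------------
# hyper-parameter search


class TrialPruned(Exception):
    """Raised inside an objective to abandon a dominated trial."""


@dataclass
class TuneResult:
    best_params: dict
    best_value: float
    trials: list  # (params, value or None, pruned flag)

    def best_config(self, base: GCNConfig) -> GCNConfig:
        return replace(base, **self.best_params)


def _sample_space(space: dict, rng: np.random.Generator) -> dict:
    params = {}
    for name, spec in space.items():
        kind = spec[0]
        if kind == "float":
            params[name] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "logfloat":
            params[name] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        elif kind == "int":
            params[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif kind == "categorical":
            params[name] = spec[1][rng.integers(len(spec[1]))]
        else:
            raise ValueError(f"unknown search-space kind {kind!r} for {name!r}")
    return params


def _parzen_logpdf(x: float, values: np.ndarray, lo: float, hi: float) -> float:
    bw = max(values.std() * values.size ** (-0.2), 1e-3 * (hi - lo), 1e-12)
    z = (x - values) / bw
    return float(np.log(np.mean(np.exp(-0.5 * z**2)) / (bw * np.sqrt(2 * np.pi)) + 1e-300))


def _tpe_propose(space: dict, trials: list, rng: np.random.Generator, n_candidates: int = 24) -> dict:
    """Density-ratio (TPE-style) proposal: sample near good trials, score l(x)/g(x)."""
    done = [(p, v) for p, v, pruned in trials if not pruned and np.isfinite(v)]
    done.sort(key=lambda t: t[1])
    n_good = max(2, int(np.ceil(0.25 * len(done))))
    good, bad = done[:n_good], done[n_good:] or done[n_good - 1:]

    best_score, best_params = -np.inf, None
    for _ in range(n_candidates):
        cand: dict = {}
        score = 0.0
        for name, spec in space.items():
            kind = spec[0]
            if kind == "categorical":
                choices = spec[1]
                counts = np.ones(len(choices))
                for p, _ in good:
                    counts[choices.index(p[name])] += 1
                probs = counts / counts.sum()
                idx = rng.choice(len(choices), p=probs)
                cand[name] = choices[idx]
                score += np.log(probs[idx])
                continue
            log = kind == "logfloat"
            lo, hi = (np.log(spec[1]), np.log(spec[2])) if log else (spec[1], spec[2])
            gvals = np.array([np.log(p[name]) if log else p[name] for p, _ in good], float)
            bvals = np.array([np.log(p[name]) if log else p[name] for p, _ in bad], float)
            bw = max(gvals.std() * gvals.size ** (-0.2), 1e-3 * (hi - lo), 1e-12)
            x = float(np.clip(rng.choice(gvals) + bw * rng.standard_normal(), lo, hi))
            score += _parzen_logpdf(x, gvals, lo, hi) - _parzen_logpdf(x, bvals, lo, hi)
            if log:
                x = float(np.exp(x))
            cand[name] = int(round(x)) if kind == "int" else x
        if score > best_score:
            best_score, best_params = score, cand
    return best_params


def tune(
    objective: Callable[[dict, Callable[[int, float], None]], float],
    search_space: dict,
    n_trials: int = 50,
    seed: int = 0,
    method: str = "bayesian",
    base_config: GCNConfig | None = None,
):
    """Minimize a validation-MSE objective over a hyper-parameter space.

    ``search_space`` maps parameter names to specs: ``("float", lo, hi)``,
    ``("logfloat", lo, hi)``, ``("int", lo, hi)`` or
    ``("categorical", [choices])``. The objective receives sampled params
    and a ``report(step, value)`` callback; a median pruning rule abandons
    trials whose intermediate value is worse than the running median at
    the same step. ``method="bayesian"`` uses a TPE-style density-ratio
    sampler after a random warm-up; ``method="random"`` samples uniformly.
    Per-trial seeds are derived from ``seed`` by trial index.

    Returns a :class:`TuneResult`, or the best :class:`GCNConfig` when
    ``base_config`` is given.
    """
    if not search_space:
        raise ValueError("search space is empty")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if method not in ("bayesian", "random"):
        raise ValueError(f"unknown tuning method {method!r}")

    trials: list = []  # (params, value, pruned)
    step_reports: dict[int, list[float]] = {}
    n_warmup = max(5, n_trials // 5)

    for trial_idx in range(n_trials):
        rng = np.random.default_rng([seed, trial_idx])
        if method == "random" or trial_idx < n_warmup or sum(
            1 for _, v, pr in trials if not pr and np.isfinite(v)
        ) < 4:
            params = _sample_space(search_space, rng)
        else:
            params = _tpe_propose(search_space, trials, rng)

        reported: list[tuple[int, float]] = []

        def report(step: int, value: float) -> None:
            reported.append((step, value))
            history = step_reports.get(step, [])
            if len(history) >= 5 and value > float(np.median(history)):
                raise TrialPruned(f"step {step}: {value:.4g} above median")

        try:
            value = float(objective(params, report))
            pruned = False
        except TrialPruned:
            value, pruned = np.inf, True
        for step, v in reported:
            step_reports.setdefault(step, []).append(v)
        trials.append((params, value, pruned))

    finished = [(p, v) for p, v, pr in trials if not pr and np.isfinite(v)]
    if not finished:
        raise RuntimeError("all trials were pruned or failed")
    best_params, best_value = min(finished, key=lambda t: t[1])
    result = TuneResult(best_params=best_params, best_value=best_value, trials=trials)
    if base_config is not None:
        return result.best_config(base_config)
    return result
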