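"""Model/Results interface for graph-based genome-wide prediction.

Three model classes share one workflow: construct from a marker matrix
and a phenotype vector, call :meth:`fit`, and read estimates, history and
evaluation metrics off the returned results object.

* :class:`GCN` — whole-graph graph-convolutional regression.
* :class:`GCNEnsemble` — the sub-sampling ensemble (one network per
  random training sub-graph, predictions averaged).
* :class:`GBLUP` — the ridge-type genomic BLUP comparator.

All three share the split convention: a test set of fixed size (default
100 individuals) or fraction is held out first, and the remainder is
divided 80/20 into training and validation. The graph models zero every
edge crossing a partition boundary before training, so no information
flows between partitions during propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import gblup as _gblup
from . import metrics as _metrics
from . import trainer as _trainer
from .graph import DataSplit, NeighborGraph, knn_graph, split_vertices, zero_cross_partition_edges
from .nn import GCNModel, PredictionVector
from .snp_data import MarkerMatrix, PhenotypeVector, align
from .trainer import EnsembleModel, GCNConfig, TrainHistory

__all__ = ["GCN", "GCNEnsemble", "GBLUP", "GCNResults", "EnsembleResults", "GBLUPResults"]


def _coerce_data(markers, phenotypes) -> tuple[MarkerMatrix, PhenotypeVector]:
    if not isinstance(markers, MarkerMatrix):
        markers = MarkerMatrix(
            [str(i) for i in range(np.asarray(markers).shape[0])],
            [f"m{j}" for j in range(np.asarray(markers).shape[1])],
            np.asarray(markers),
        )
    if not isinstance(phenotypes, PhenotypeVector):
        phenotypes = PhenotypeVector(list(markers.individual_ids), np.asarray(phenotypes))
    return align(markers, phenotypes)


class _BaseModel:
    """Data container shared by the three model families."""

    def __init__(self, markers, phenotypes):
        self.markers, self.phenotypes = _coerce_data(markers, phenotypes)
        if self.markers.has_missing:
            raise ValueError("impute missing dosages before modeling")
        self.X = np.asarray(self.markers.dosages, dtype=float)
        self.y = np.asarray(self.phenotypes.values, dtype=float)

    @property
    def nobs(self) -> int:
        return self.markers.n_individuals

    @classmethod
    def from_files(cls, genotypes_path, phenotypes_path, **kwargs):
        from .snp_data import load_genotypes, load_phenotypes

        return cls(load_genotypes(genotypes_path), load_phenotypes(phenotypes_path), **kwargs)

    def make_split(
        self,
        split: DataSplit | None = None,
        test_n: int | None = None,
        test_fraction: float | None = None,
        train_fraction: float = 0.8,
        seed: int | None = None,
    ) -> DataSplit:
        if split is not None:
            return split
        if test_fraction is not None:
            test_n = max(1, int(round(test_fraction * self.nobs)))
        if test_n is None:
            test_n = 100
        if seed is None:
            seed = getattr(getattr(self, "config", None), "seed", 0)
        return split_vertices(self.nobs, test_n=test_n, train_fraction=train_fraction, seed=seed)


@dataclass
class _ResultsBase:
    split: DataSplit
    config: GCNConfig | None = None

    def _truth(self, idx) -> np.ndarray:
        raise NotImplementedError

    def metrics(self, partition: str = "test") -> _metrics.MetricsReport:
        idx = getattr(self.split, f"{partition}_idx")
        pred = self.predict(idx)
        return _metrics.evaluate(pred.values, self._y[idx])

    def summary(self) -> str:
        lines = [self._title, "=" * len(self._title)]
        lines += [f"{k:<28}{v}" for k, v in self._info()]
        lines.append("-" * 44)
        lines.append(f"{'partition':<12}{'n':>6}{'MSE':>10}{'r':>8}{'dcor':>8}")
        for part in ("train", "val", "test"):
            rep = self.metrics(part)
            lines.append(
                f"{part:<12}{rep.n:>6}{rep.mse:>10.4f}{rep.pearson:>8.3f}{rep.dcor:>8.3f}"
            )
        return "\n".join(lines)


@dataclass
class GCNResults(_ResultsBase):
    """Fitted whole-graph GCN: best-validation-epoch weights and history."""

    network: GCNModel = None
    history: TrainHistory = None
    graph: NeighborGraph = None
    _X: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)
    _title = "Whole-graph GCN regression"

    def predict(self, vertices=None) -> PredictionVector:
        return _trainer.predict(self.network, self.graph, self._X, vertices)

    def _info(self):
        return [
            ("No. individuals:", len(self._y)),
            ("No. markers:", self._X.shape[1]),
            ("Neighbors K:", self.config.k_neighbors),
            ("Propagation:", self.network.propagation_mode),
            ("Epochs run / best:", f"{self.history.stopped_epoch + 1} / {self.history.best_epoch + 1}"),
            ("Best val MSE:", f"{self.history.best_val_loss:.4f}"),
        ]


@dataclass
class EnsembleResults(_ResultsBase):
    """Fitted sub-sampling ensemble and the per-member training histories."""

    ensemble: EnsembleModel = None
    histories: list[TrainHistory] = None
    graph: NeighborGraph = None
    _X: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)
    _title = "Sub-sampling GCN ensemble (GCN-RS) regression"

    def predict(self, vertices=None) -> PredictionVector:
        return _trainer.predict(self.ensemble, self.graph, self._X, vertices)

    def _info(self):
        best = min(h.best_val_loss for h in self.histories)
        return [
            ("No. individuals:", len(self._y)),
            ("No. markers:", self._X.shape[1]),
            ("Neighbors K:", self.config.k_neighbors),
            ("Sub-graphs:", self.ensemble.n_members),
            ("Propagation:", self.ensemble.members[0].propagation_mode),
            ("Aggregation:", self.ensemble.aggregation),
            ("Best member val MSE:", f"{best:.4f}"),
        ]


@dataclass
class GBLUPResults(_ResultsBase):
    """Fitted GBLUP: breeding-value solutions on the training block."""

    u_hat: np.ndarray = None
    mu_hat: float = 0.0
    lam: float = 1.0
    _grm: _gblup.GRM = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)
    _title = "GBLUP (VanRaden G, ridge-type) regression"

    def predict(self, vertices=None) -> PredictionVector:
        if vertices is None:
            vertices = np.arange(self._grm.n)
        vertices = np.asarray(vertices, dtype=int)
        G_vt = self._grm.matrix[np.ix_(vertices, self.split.train_idx)]
        return PredictionVector(vertices, self.mu_hat + G_vt @ self.u_hat)

    def _info(self):
        return [
            ("No. individuals:", len(self._y)),
            ("Lambda (sigma_e^2/sigma_g^2):", f"{self.lam:.4f}"),
            ("Mean diag(G):", f"{np.mean(np.diag(self._grm.matrix)):.4f}"),
        ]


class GCN(_BaseModel):
    """Whole-graph graph-convolutional phenotype regression.

    Parameters
    ----------
    markers, phenotypes
        A :class:`MarkerMatrix` and aligned :class:`PhenotypeVector`
        (plain arrays also accepted).
    config
        :class:`GCNConfig`; defaults are the tuned operating point
        (learning rate 0.0025, 250 epochs, K = 3).
    graph
        Optional pre-built :class:`NeighborGraph`; otherwise the K-NN
        graph is constructed from the markers at fit time.
    """

    results_class = GCNResults

    def __init__(self, markers, phenotypes, config: GCNConfig | None = None,
                 graph: NeighborGraph | None = None):
        super().__init__(markers, phenotypes)
        self.config = config or GCNConfig()
        self.graph = graph

    def build_graph(self) -> NeighborGraph:
        if self.graph is None:
            self.graph = knn_graph(self.markers, K=self.config.k_neighbors)
        return self.graph

    def _fit_networks(self, graph, split):
        network, history = _trainer.train_gcn(graph, split, self.X, self.y, self.config)
        return {"network": network, "history": history}

    def fit(self, split: DataSplit | None = None, **split_kw):
        """Build the graph, zero cross-partition edges, train, and return results."""
        split = self.make_split(split, **split_kw)
        graph = zero_cross_partition_edges(self.build_graph(), split)
        parts = self._fit_networks(graph, split)
        return self.results_class(
            split=split, config=self.config, graph=graph,
            _X=self.X, _y=self.y, **parts,
        )


class GCNEnsemble(GCN):
    """Sub-sampling GCN ensemble (GCN-RS).

    The training partition is randomly split into ``config.n_subgraphs``
    sub-graphs; one network is trained per sub-graph and the member
    predictions are averaged.
    """

    results_class = EnsembleResults

    def _fit_networks(self, graph, split):
        ensemble, histories = _trainer.train_gcn_rs(graph, split, self.X, self.y, self.config)
        return {"ensemble": ensemble, "histories": histories}


class GBLUP(_BaseModel):
    """Genomic BLUP with the VanRaden method-1 relationship matrix.

    ``lam`` is the variance ratio sigma_e^2 / sigma_g^2; alternatively
    pass ``h2`` and lam = (1 - h2) / h2 is used. No variance components
    are estimated.
    """

    def __init__(self, markers, phenotypes, h2: float | None = None, lam: float | None = None):
        super().__init__(markers, phenotypes)
        if lam is None:
            lam = _gblup.lambda_from_h2(0.35 if h2 is None else h2)
        self.lam = float(lam)
        self.config = None
        self._grm: _gblup.GRM | None = None

    @property
    def grm(self) -> _gblup.GRM:
        if self._grm is None:
            self._grm = _gblup.compute_grm(self.markers)
        return self._grm

    def fit(self, split: DataSplit | None = None, **split_kw) -> GBLUPResults:
        split = self.make_split(split, **split_kw)
        G = self.grm
        y_tr = self.y[split.train_idx]
        mu = float(y_tr.mean())
        G_tt = G.matrix[np.ix_(split.train_idx, split.train_idx)]
        u_hat = np.linalg.solve(G_tt + self.lam * np.eye(split.train_idx.size), y_tr - mu)
        return GBLUPResults(
            split=split, config=None, u_hat=u_hat, mu_hat=mu, lam=self.lam,
            _grm=G, _y=self.y,
        )
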