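"""Evaluation statistics: test MSE, Pearson correlation, distance correlation.

Distance correlation is implemented from the double-centering definition
(the biased V-statistic sample version, matching the R ``energy``
package's default), so cross-checks against that reference are exact:
pairwise absolute-distance matrices are double-centered, dCov^2 is the
mean of their elementwise product, and dCor = dCov / sqrt(dVar_x dVar_y).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn import PredictionVector, mse_loss
from .snp_data import PhenotypeVector

__all__ = ["MetricsReport", "pearson", "distance_correlation", "evaluate"]


@dataclass
class MetricsReport:
    """MSE, Pearson r and distance correlation over an evaluation set."""

    mse: float
    pearson: float
    dcor: float
    n: int

    def to_dict(self) -> dict:
        return {"mse": self.mse, "pearson": self.pearson, "dcor": self.dcor, "n": self.n}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _as_vector(x, name: str) -> np.ndarray:
    if isinstance(x, (PredictionVector, PhenotypeVector)):
        x = x.values
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson(y, y_hat) -> float:
    """Sample Pearson correlation coefficient; errors on constant input."""
    a = _as_vector(y, "y")
    b = _as_vector(y_hat, "y_hat")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(a) == 0:
        raise ValueError("first vector (y) is constant; Pearson undefined")
    if np.ptp(b) == 0:
        raise ValueError("second vector (y_hat) is constant; Pearson undefined")
    return float(np.corrcoef(a, b)[0, 1])


def _double_centered(x: np.ndarray) -> np.ndarray:
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(y, y_hat) -> float:
    """Sample distance correlation in [0, 1] (V-statistic definition).

    Returns 0 by convention when either argument has zero distance
    variance (e.g. a constant vector).
    """
    a = _as_vector(y, "y")
    b = _as_vector(y_hat, "y_hat")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    A = _double_centered(a)
    B = _double_centered(b)
    dcov2 = float(np.mean(A * B))
    dvar_a = float(np.mean(A * A))
    dvar_b = float(np.mean(B * B))
    if dvar_a <= 0.0 or dvar_b <= 0.0:
        return 0.0
    dcor2 = dcov2 / np.sqrt(dvar_a * dvar_b)
    return float(np.sqrt(max(dcor2, 0.0)))


def evaluate(pred, truth) -> MetricsReport:
    """Bundle MSE, Pearson and distance correlation over aligned vectors.

    When both arguments carry indices/IDs, alignment is checked; plain
    arrays are taken as already aligned.
    """
    if isinstance(pred, PredictionVector) and isinstance(truth, PhenotypeVector):
        if len(pred.values) != len(truth.values):
            raise ValueError(
                f"alignment failure: {len(pred.values)} predictions vs "
                f"{len(truth.values)} phenotypes"
            )
    p = _as_vector(pred, "pred")
    t = _as_vector(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"alignment failure: {p.shape} vs {t.shape}")
    if p.size < 2:
        raise ValueError("need at least 2 evaluated individuals")
    return MetricsReport(
        mse=mse_loss(p, t),
        pearson=pearson(t, p),
        dcor=distance_correlation(t, p),
        n=int(p.size),
    )
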