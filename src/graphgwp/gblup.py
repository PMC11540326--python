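"""Ridge-type GBLUP comparator.

Genomic best linear unbiased prediction with the VanRaden method-1
genomic relationship matrix: G = Z Z' / (2 * sum_j p_j (1 - p_j)) with Z
the allele-frequency-centered dosage matrix. Prediction solves the mixed
model equations on the training block,

    u_hat = (G_tt + lambda I)^{-1} (y_train - mu_hat),
    y_hat_test = mu_hat + G_st u_hat,

with mu_hat the training mean and lambda = sigma_e^2 / sigma_g^2 either
supplied directly or derived from a target heritability as (1 - h2) / h2.
No variance-component estimation is performed; the comparator is
deterministic and closed-form. By RR-BLUP duality it coincides with ridge
regression on the centered markers at penalty lambda * 2 sum p(1-p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import PredictionVector
from .snp_data import MarkerMatrix

__all__ = ["GRM", "compute_grm", "gblup_fit_predict", "lambda_from_h2"]


@dataclass
class GRM:
    """Genomic relationship matrix with the allele frequencies used to center."""

    matrix: np.ndarray
    allele_frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.allele_frequencies = np.asarray(self.allele_frequencies, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("GRM has non-finite entries")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def compute_grm(m: MarkerMatrix | np.ndarray) -> GRM:
    """VanRaden method-1 GRM from an allele-dosage matrix.

    Requires complete data and at least one polymorphic marker (the
    denominator 2 sum p(1-p) is zero otherwise).
    """
    X = np.asarray(m.dosages if isinstance(m, MarkerMatrix) else m, dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute missing dosages before computing the GRM")
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers are monomorphic; GRM denominator is zero")
    Z = X - 2.0 * p
    G = (Z @ Z.T) / denom
    return GRM(matrix=G, allele_frequencies=p)


def lambda_from_h2(h2: float) -> float:
    """Variance ratio sigma_e^2 / sigma_g^2 implied by a heritability target."""
    if not 0.0 < h2 < 1.0:
        raise ValueError(f"h2 must be in (0, 1), got {h2}")
    return (1.0 - h2) / h2


def gblup_fit_predict(
    G: GRM,
    y_train: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    lam: float,
) -> PredictionVector:
    """Solve the training-block mixed-model equations and predict the test block."""
    if lam <= 0.0:
        raise ValueError(f"lambda must be positive, got {lam}")
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices must be disjoint")
    y_train = np.asarray(y_train, dtype=float)
    if y_train.shape != train_idx.shape:
        raise ValueError("y_train must align with train_idx")

    G_tt = G.matrix[np.ix_(train_idx, train_idx)]
    G_st = G.matrix[np.ix_(test_idx, train_idx)]
    mu = float(y_train.mean())
    lhs = G_tt + lam * np.eye(train_idx.size)
    try:
        u_hat = np.linalg.solve(lhs, y_train - mu)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular mixed-model system (lambda={lam}); try a larger lambda"
        ) from exc
    return PredictionVector(vertex_indices=test_idx, values=mu + G_st @ u_hat)
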