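"""Locally supervised metric learning (LSML).

Learns a disease-specific distance

    d(a, b) = sqrt((a - b)^T W W^T (a - b))

— a generalization of the Mahalanobis distance — where W is fit by
average neighborhood margin maximization: for every training point, pull
its nearest same-outcome neighbors closer and push its nearest
different-outcome neighbors away.  Concretely, with hom(i) the k_hom
nearest same-label rows of i and het(i) the k_het nearest different-label
rows (Euclidean, ties broken by row index),

    C = sum_i (1/k_hom) sum_{j in hom(i)} (x_i - x_j)(x_i - x_j)^T
    S = sum_i (1/k_het) sum_{j in het(i)} (x_i - x_j)(x_i - x_j)^T

and W collects the top-d eigenvectors of S - C.  The per-variable
similarity weights are 1^T W W^T.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VectorLike = Union[Mapping[str, float], Sequence[float], np.ndarray]


@dataclass
class SimilarityModel:
    """Standardization parameters plus the learned transformation W."""

    variable_names: list[str]
    mean: np.ndarray  # (p,)
    sd: np.ndarray  # (p,), strictly positive
    W: np.ndarray  # (p, d), orthonormal columns
    k_hom: int = 10
    k_het: int = 10

    def __post_init__(self) -> None:
        p = len(self.variable_names)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.mean.shape != (p,) or self.sd.shape != (p,):
            raise ValueError("standardization parameter shapes must match variable count")
        if self.W.ndim != 2 or self.W.shape[0] != p or self.W.shape[1] < 1:
            raise ValueError("W must be p x d with d >= 1")
        if np.any(self.sd <= 0):
            raise ValueError("standardization sds must be positive")
        gram = self.W.T @ self.W
        if not np.allclose(gram, np.eye(self.W.shape[1]), atol=1e-8):
            raise ValueError("columns of W must be orthonormal")

    @property
    def p(self) -> int:
        return len(self.variable_names)

    @property
    def d(self) -> int:
        return self.W.shape[1]

    def _coerce(self, x: VectorLike) -> np.ndarray:
        if isinstance(x, Mapping):
            missing = [n for n in self.variable_names if n not in x]
            if missing:
                raise KeyError(f"vector missing variables: {missing}")
            return np.array([float(x[n]) for n in self.variable_names])
        arr = np.asarray(x, dtype=float)
        if arr.shape != (self.p,):
            raise ValueError(f"expected vector of length {self.p}, got shape {arr.shape}")
        return arr

    def standardize(self, X: VectorLike | np.ndarray) -> np.ndarray:
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return (X - self.mean) / self.sd
        return (self._coerce(X) - self.mean) / self.sd

    def project(self, X: np.ndarray) -> np.ndarray:
        """Standardize rows of X and map into the learned subspace; plain
        Euclidean distance there equals the learned metric."""
        return self.standardize(np.asarray(X, dtype=float)) @ self.W

    # -- serialization (text-only; floats round-trip exactly via repr) ------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variable_names": self.variable_names,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "W": self.W.tolist(),
            "k_hom": self.k_hom,
            "k_het": self.k_het,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimilarityModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            variable_names=list(payload["variable_names"]),
            mean=np.array(payload["mean"], dtype=float),
            sd=np.array(payload["sd"], dtype=float),
            W=np.array(payload["W"], dtype=float),
            k_hom=int(payload["k_hom"]),
            k_het=int(payload["k_het"]),
        )


def _neighbor_indices(order_dist: np.ndarray, candidates: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k candidates with smallest distance, ties broken by
    row index (stable lexicographic sort)."""
    order = np.lexsort((candidates, order_dist[candidates]))
    return candidates[order[:k]]


def train_lsml(
    X: Union[pd.DataFrame, np.ndarray],
    y: Sequence[int],
    k_hom: int = 10,
    k_het: int = 10,
    d: Union[int, str] = "auto",
    variable_names: Optional[Sequence[str]] = None,
) -> SimilarityModel:
    """Fit the LSML transformation on a training matrix.

    Rows are z-scored with training means/sds (stored on the model;
    zero-variance columns get sd 1).  ``d="auto"`` keeps every strictly
    positive eigenvalue of S - C (at least 1 direction).
    """
    if isinstance(X, pd.DataFrame):
        variable_names = list(X.columns)
        A = X.to_numpy(dtype=float)
    else:
        A = np.asarray(X, dtype=float)
        if variable_names is None:
            variable_names = [f"x{i}" for i in range(A.shape[1])]
    y = np.asarray(y, dtype=int)
    n, p = A.shape
    if n != len(y):
        raise ValueError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two outcome classes required")
    smallest = counts.min()
    if smallest < k_hom + 1:
        raise ValueError(
            f"class with {smallest} members cannot supply k_hom={k_hom} same-label "
            "neighbors; reduce k_hom"
        )
    if smallest < k_het:
        raise ValueError(
            f"class with {smallest} members cannot supply k_het={k_het} neighbors; reduce k_het"
        )

    mean = A.mean(axis=0)
    sd = A.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (A - mean) / sd

    # pairwise squared Euclidean distances (n is training-set sized)
    sq = np.einsum("ij,ij->i", Z, Z)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    np.fill_diagonal(D2, np.inf)

    C = np.zeros((p, p))
    S = np.zeros((p, p))
    idx_all = np.arange(n)
    for i in range(n):
        same = idx_all[(y == y[i]) & (idx_all != i)]
        diff = idx_all[y != y[i]]
        hom = _neighbor_indices(D2[i], same, k_hom)
        het = _neighbor_indices(D2[i], diff, k_het)
        dh = Z[i] - Z[hom]
        ds = Z[i] - Z[het]
        C += (dh.T @ dh) / k_hom
        S += (ds.T @ ds) / k_het

    M = S - C
    M = (M + M.T) / 2.0  # guard numerical asymmetry
    eigvals, eigvecs = np.linalg.eigh(M)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    if d == "auto":
        n_keep = max(1, int(np.sum(eigvals > 1e-10)))
    else:
        n_keep = int(d)
        if not 1 <= n_keep <= p:
            raise ValueError(f"d must be in [1, {p}]")
    W = eigvecs[:, :n_keep].copy()

    # deterministic sign: largest-|entry| of each column positive
    for j in range(W.shape[1]):
        k = int(np.argmax(np.abs(W[:, j])))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]

    return SimilarityModel(
        variable_names=list(variable_names),
        mean=mean,
        sd=sd,
        W=W,
        k_hom=k_hom,
        k_het=k_het,
    )


def distance(model: SimilarityModel, a: VectorLike, b: VectorLike) -> float:
    """Learned distance between two raw variable vectors."""
    za = model.standardize(a)
    zb = model.standardize(b)
    v = (za - zb) @ model.W
    return float(np.sqrt(v @ v))


def pairwise_distances(model: SimilarityModel, X_index: np.ndarray, X_others: np.ndarray) -> np.ndarray:
    """Learned distances from one raw vector to each row of a raw matrix."""
    zi = model.project(np.atleast_2d(X_index))[0]
    Zo = model.project(np.asarray(X_others, dtype=float))
    return np.sqrt(np.maximum(np.einsum("ij,ij->i", Zo - zi, Zo - zi), 0.0))


def variable_weights(model: SimilarityModel) -> pd.DataFrame:
    """Per-variable similarity weights.

    ``weight`` is 1^T W W^T (the column sums of W W^T, the primary
    published form); ``diag_weight`` is diag(W W^T), a non-negative
    secondary diagnostic.
    """
    col_sums = model.W @ model.W.sum(axis=0)
    diag = np.einsum("ij,ij->i", model.W, model.W)
    return pd.DataFrame(
        {"weight": col_sums, "diag_weight": diag},
        index=pd.Index(model.variable_names, name="variable"),
    )


def average_neighborhood_margin(Z: np.ndarray, y: Sequence[int], W: Optional[np.ndarray], k_hom: int, k_het: int) -> float:
    """Mean (scatterness - compactness) in the (optionally) projected
    space; a diagnostic for permutation checks."""
    y = np.asarray(y, dtype=int)
    P = Z if W is None else Z @ W
    n = len(P)
    sq = np.einsum("ij,ij->i", P, P)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (P @ P.T)
    np.fill_diagonal(D2, np.inf)
    idx_all = np.arange(n)
    total = 0.0
    for i in range(n):
        same = idx_all[(y == y[i]) & (idx_all != i)]
        diff = idx_all[y != y[i]]
        hom = _neighbor_indices(D2[i], same, k_hom)
        het = _neighbor_indices(D2[i], diff, k_het)
        total += D2[i, het].mean() - D2[i, hom].mean()
    return total / n
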