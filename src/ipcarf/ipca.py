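"""One-shot randomized-flavoured PCA via covariance column selection.

The reduction compresses the feature covariance before eigendecomposition:

1. centre the sample matrix (rows = samples, columns = features);
2. form the p x p covariance C (normalization 1/(rows-1));
3. keep the k covariance columns of largest l2 norm as B (p x k);
4. orthonormalise B by QR, giving Q;
5. compress: C1 = Q^T C Q (k x k), then SVD of C1;
6. basis = Q @ (top n_components left singular vectors of C1).

High-norm covariance columns are the features most entangled with the rest,
so their span approximates the dominant eigenspace; at k = p the procedure
is exact PCA.  The stored model projects new samples by (X - mean) @ basis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger("ipcarf")


@dataclass
class IPCAModel:
    """Fitted reduction: centring mean, selected columns, orthonormal basis."""

    mean: np.ndarray               # length p
    selected_columns: np.ndarray   # k indices into the covariance columns
    basis: np.ndarray              # p x n_components, orthonormal columns
    n_components: int
    explained_variance: np.ndarray  # top singular values of the compressed covariance

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.selected_columns = np.asarray(self.selected_columns, dtype=int)
        self.basis = np.asarray(self.basis, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.basis.shape[1]), atol=1e-10):
            raise ValueError("basis columns are not orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained_variance must be nonincreasing")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "selected_columns": self.selected_columns.tolist(),
            "basis": self.basis.tolist(),
            "n_components": self.n_components,
            "explained_variance": self.explained_variance.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "IPCAModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            mean=np.array(payload["mean"]),
            selected_columns=np.array(payload["selected_columns"]),
            basis=np.array(payload["basis"]),
            n_components=int(payload["n_components"]),
            explained_variance=np.array(payload["explained_variance"]),
        )


def center(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract column means; returns (centred matrix, mean vector)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = X.mean(axis=0)
    return X - mean, mean


def covariance(Xc: np.ndarray) -> np.ndarray:
    """Sample covariance of a centred matrix, 1/(rows-1) normalization."""
    Xc = np.asarray(Xc, dtype=float)
    if Xc.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    return (Xc.T @ Xc) / (Xc.shape[0] - 1)


def select_columns(C: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k covariance columns with largest l2 norm.

    Ties break toward the smaller index; the returned indices are in
    ascending order so the selection is reproducible.
    """
    C = np.asarray(C, dtype=float)
    p = C.shape[1]
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    norms = np.linalg.norm(C, axis=0)
    # stable sort on negated norms keeps the lower index first among ties
    order = np.argsort(-norms, kind="stable")
    return np.sort(order[:k])


def ipca_fit(X: np.ndarray, k: int | None = None, n_components: int | None = None) -> IPCAModel:
    """Fit the reduction: centre -> covariance -> column selection -> QR -> SVD."""
    X = np.asarray(X, dtype=float)
    Xc, mean = center(X)
    C = covariance(Xc)
    p = C.shape[0]
    if n_components is None:
        n_components = min(64, p)
    if k is None:
        k = min(2 * n_components, p)
    if not (1 <= n_components <= k <= p):
        raise ValueError(f"need 1 <= n_components <= k <= p; got n_components={n_components}, k={k}, p={p}")

    cols = select_columns(C, k)
    B = C[:, cols]
    Q, _ = np.linalg.qr(B)          # p x k, orthonormal columns
    C1 = Q.T @ C @ Q                # compressed covariance, k x k
    U, s, _ = np.linalg.svd(C1, hermitian=True)

    rank = int(np.sum(s > max(s[0], 1.0) * 1e-12)) if s.size else 0
    n_out = n_components
    if rank < n_components:
        # degenerate data: keep the requested width but flag that the trailing
        # directions carry (numerically) zero variance
        logger.warning("requested %d components but compressed covariance has rank %d",
                       n_components, rank)
    basis = Q @ U[:, :n_out]
    # sign convention: largest-magnitude entry of each basis column positive
    flip = np.sign(basis[np.abs(basis).argmax(axis=0), np.arange(n_out)])
    flip[flip == 0] = 1.0
    basis = basis * flip
    return IPCAModel(mean, cols, basis, n_out, s[:n_out])


def ipca_transform(model: IPCAModel, X: np.ndarray) -> np.ndarray:
    """Project samples onto the fitted basis: (X - mean) @ basis."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(f"expected width {model.mean.shape[0]}, got {X.shape[1]}")
    return (X - model.mean) @ model.basis
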