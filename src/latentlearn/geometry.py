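"""Low-dimensional embeddings of condition geometries and module separability.

Neural RDMs are genuine (cross-validated) Euclidean distance matrices, so
classical MDS is the right embedding; estimated latent spaces A_hat are
similarity matrices, for which PCA of the (centred, scaled) matrix rows is
used instead.  Module separability is summarised as the resubstitution loss
of a two-class linear discriminant on the 2-D coordinates: 0 means the two
five-node modules are perfectly linearly separable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .rsa import DissimilarityMatrix

__all__ = ["Embedding", "classical_mds", "pca_embed", "lda_module_loss"]


@dataclass
class Embedding:
    coords: np.ndarray  # n_nodes x dims, column-centred
    method: str  # classical_mds | pca


def classical_mds(d: DissimilarityMatrix, dims: int = 2) -> Embedding:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centres the squared distances, eigendecomposes, and projects on
    the top ``dims`` nonnegative eigenpairs scaled by sqrt(eigenvalue).
    Cross-validated RDMs may have slightly negative eigenvalues; if fewer
    than ``dims`` nonnegative eigenvalues exist the remaining coordinates
    are zero-padded with a warning.
    """
    if d.polarity != "dissimilarity":
        raise ValueError("classical MDS requires a dissimilarity matrix")
    D = np.asarray(d.values, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, dims))
    tol = max(evals.max(), 0.0) * 1e-10
    usable = min(dims, int(np.sum(evals > tol)))
    if usable < dims:
        warnings.warn(
            f"only {usable} nonnegative eigenvalues; padding remaining coordinates with 0"
        )
    for k in range(usable):
        coords[:, k] = evecs[:, k] * np.sqrt(evals[k])
    return Embedding(coords=coords, method="classical_mds")


def pca_embed(s: np.ndarray, dims: int = 2) -> Embedding:
    """Project the rows of a (similarity) matrix onto its principal axes.

    The diagonal is zeroed first: self-transitions never occur in the task,
    so self-similarity carries no information about the node geometry (for
    a neural RDM, whose diagonal is already zero, this is a no-op).  Columns
    are then centred and scaled to unit variance and the rows (one
    observation per node) are projected onto the first two principal axes.
    Zero-variance columns are dropped with a warning.
    """
    S = np.asarray(s, dtype=float).copy()
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("input must be a square matrix")
    np.fill_diagonal(S, 0.0)
    sd = S.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn("dropping zero-variance columns before PCA")
    Z = (S[:, keep] - S[:, keep].mean(axis=0)) / sd[keep]
    # principal axes via SVD of the centred, scaled matrix
    U, sv, _ = np.linalg.svd(Z, full_matrices=False)
    coords = np.zeros((S.shape[0], dims))
    k = min(dims, len(sv))
    coords[:, :k] = U[:, :k] * sv[:k]
    return Embedding(coords=coords, method="pca")


def lda_module_loss(emb: Embedding, modules: np.ndarray) -> float:
    """Fraction of nodes misclassified by the best linear module boundary.

    Fits a two-class linear discriminant to the embedding coordinates and
    reports the resubstitution misclassification rate (with only 10 points
    a held-out estimate is not meaningful).  Degenerate within-class
    covariance falls back to a small-ridge (shrinkage) discriminant.
    """
    modules = np.asarray(modules)
    if len(np.unique(modules)) != 2:
        raise ValueError("exactly two module labels required")
    X = emb.coords
    lda = LinearDiscriminantAnalysis(solver="svd")
    try:
        lda.fit(X, modules)
    except Exception:
        warnings.warn("degenerate within-class covariance; using ridge-regularised LDA")
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-8)
        lda.fit(X, modules)
    pred = lda.predict(X)
    return float(np.mean(pred != modules))
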