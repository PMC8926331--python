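"""Latent semantic analysis of the tf-idf matrix.

A truncated singular decomposition M ~= T R W^T factors the testimonial x
word matrix into orthonormal testimonial weights T (documents x k),
positive nonincreasing component relevances R (the singular values) and
orthonormal word weights W (words x k). Each testimonial is then
re-represented by its k component projections X = T diag(R), which feed
the canonical correlation stage.

No mean-centering is applied before the decomposition (classical LSA on
tf-idf); the explained-variance denominator is accordingly the raw squared
Frobenius norm. Both choices only rescale/shift the inputs of the CCA
stage in ways its correlations are invariant to.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.utils.extmath import randomized_svd

#: below this size the exact dense LAPACK path is used
_DENSE_MAX_ENTRIES = 4_000_000


@dataclass
class LsaModel:
    """Fitted decomposition: W words x k, R relevances (k,), T docs x k."""

    W: np.ndarray
    R: np.ndarray
    T: np.ndarray
    k: int
    total_sq_norm: float
    solver: str
    seed: int | None = None

    def document_coordinates(self) -> np.ndarray:
        """Relevance-scaled testimonial embedding X = T diag(R) (docs x k)."""
        return self.T * self.R

    def explained_variance_fraction(self) -> float:
        """Fraction of the matrix's squared norm captured by the k kept
        components (Eckart-Young: the discarded squared relevances are the
        best-rank-k reconstruction error)."""
        if self.total_sq_norm == 0:
            return 1.0
        return float(np.sum(self.R**2) / self.total_sq_norm)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        mmwrite(d / "W.mtx", sp.csr_matrix(self.W))
        mmwrite(d / "T.mtx", sp.csr_matrix(self.T))
        np.savetxt(d / "R.tsv", self.R, delimiter="\t")
        meta = {
            "k": self.k,
            "total_sq_norm": self.total_sq_norm,
            "solver": self.solver,
            "seed": self.seed,
            "centering": "none",
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "LsaModel":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        return cls(
            W=np.asarray(mmread(d / "W.mtx").todense()),
            T=np.asarray(mmread(d / "T.mtx").todense()),
            R=np.atleast_1d(np.loadtxt(d / "R.tsv", delimiter="\t")),
            k=meta["k"],
            total_sq_norm=meta["total_sq_norm"],
            solver=meta["solver"],
            seed=meta["seed"],
        )


def _fix_signs(W: np.ndarray, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic orientation: largest-|weight| word positive per component
    flip = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(W.shape[1])])
    flip[flip == 0] = 1.0
    return W * flip, T * flip


def fit_lsa(
    tfidf: sp.spmatrix | np.ndarray, k: int, seed: int | None = 0
) -> LsaModel:
    """Truncated SVD of the (documents x words) tf-idf matrix.

    k is capped at min(n_docs, n_words) with a warning. Small matrices take
    an exact dense LAPACK decomposition; larger ones a randomized solver
    whose oversampled iterations make the kept components accurate, with
    `seed` fixing the sketch.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_docs, n_words = tfidf.shape
    max_k = min(n_docs, n_words)
    if k > max_k:
        warnings.warn(f"k={k} exceeds min(matrix dims)={max_k}; capping", stacklevel=2)
        k = max_k
    if sp.issparse(tfidf):
        total_sq = float(tfidf.power(2).sum())
    else:
        total_sq = float(np.sum(np.asarray(tfidf, dtype=float) ** 2))

    if n_docs * n_words <= _DENSE_MAX_ENTRIES:
        dense = np.asarray(
            tfidf.todense() if sp.issparse(tfidf) else tfidf, dtype=float
        )
        U, s, Vt = scipy.linalg.svd(dense, full_matrices=False)
        T, R, W = U[:, :k], s[:k], Vt[:k].T
        solver = "dense"
    else:
        U, s, Vt = randomized_svd(
            tfidf, n_components=k, n_iter=7, random_state=seed
        )
        T, R, W = U, s, Vt.T
        solver = "randomized"
    W, T = _fix_signs(W, T)
    return LsaModel(
        W=W, R=R, T=T, k=k, total_sq_norm=total_sq, solver=solver, seed=seed
    )


def document_coordinates(model: LsaModel) -> np.ndarray:
    """Functional alias for :meth:`LsaModel.document_coordinates`."""
    return model.document_coordinates()


def explained_variance_fraction(model: LsaModel) -> float:
    """Functional alias for :meth:`LsaModel.explained_variance_fraction`."""
    return model.explained_variance_fraction()
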