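"""Canonical correlation analysis between semantic and receptor blocks.

Given testimonial-level semantic coordinates X (n x p, from LSA) and the
per-testimonial receptor fingerprint matrix Y (n x q), CCA finds paired
projection vectors (a_i, b_i) maximizing the Pearson correlation between
the canonical variates U_i = X a_i and V_i = Y b_i, with successive
factors uncorrelated with the earlier ones within each block. The
canonical correlations rho_i = corr(U_i, V_i) come out ordered
nonincreasing.

The solver centers both blocks, pseudo-whitens each by an SVD with
eigenvalue truncation (rank-deficiency is the norm here: Y has one
distinct row per drug, so its centered rank is at most n_drugs - 1), and
takes the SVD of the whitened cross-covariance. An optional ridge term
inflates each block's covariance by eps*I; the default is 0
(unregularized).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

#: relative eigenvalue cutoff for rank truncation during whitening
WHITEN_RTOL = 1e-10


@dataclass
class CcaModel:
    """Fitted factors: canonical vectors a (p x h), b (q x h), variates
    U = (X - mean_X) a and V = (Y - mean_Y) b (n x h), correlations rho."""

    a: np.ndarray
    b: np.ndarray
    U: np.ndarray
    V: np.ndarray
    rho: np.ndarray
    h: int
    mean_x: np.ndarray
    mean_y: np.ndarray
    ridge: float = 0.0
    receptor_names: list[str] | None = None

    def transform(
        self, X_new: np.ndarray, Y_new: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Project new rows into the canonical space using the stored
        training means for centering."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        Y_new = np.atleast_2d(np.asarray(Y_new, dtype=float))
        if X_new.shape[1] != self.mean_x.size or Y_new.shape[1] != self.mean_y.size:
            raise ValueError(
                f"dimension mismatch: expected {self.mean_x.size} semantic and "
                f"{self.mean_y.size} receptor columns, "
                f"got {X_new.shape[1]} and {Y_new.shape[1]}"
            )
        return (X_new - self.mean_x) @ self.a, (Y_new - self.mean_y) @ self.b

    def truncated(self, n_keep: int) -> "CcaModel":
        """Copy keeping only the first `n_keep` factors (order preserved)."""
        return CcaModel(
            a=self.a[:, :n_keep].copy(),
            b=self.b[:, :n_keep].copy(),
            U=self.U[:, :n_keep].copy(),
            V=self.V[:, :n_keep].copy(),
            rho=self.rho[:n_keep].copy(),
            h=n_keep,
            mean_x=self.mean_x,
            mean_y=self.mean_y,
            ridge=self.ridge,
            receptor_names=self.receptor_names,
        )

    def flip_factor(self, i: int) -> None:
        """Jointly negate factor i on both sides; rho is unaffected."""
        for arr in (self.a, self.b, self.U, self.V):
            arr[:, i] *= -1.0

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savetxt(d / "a.tsv", self.a, delimiter="\t")
        if self.receptor_names is not None:
            header = "receptor\t" + "\t".join(
                f"factor_{i + 1}" for i in range(self.h)
            )
            rows = [
                name + "\t" + "\t".join(f"{v:.12g}" for v in self.b[r])
                for r, name in enumerate(self.receptor_names)
            ]
            (d / "b.tsv").write_text(header + "\n" + "\n".join(rows) + "\n")
        else:
            np.savetxt(d / "b.tsv", self.b, delimiter="\t")
        np.savetxt(d / "rho.tsv", self.rho, delimiter="\t")
        meta = {
            "h": self.h,
            "ridge": self.ridge,
            "mean_x": self.mean_x.tolist(),
            "mean_y": self.mean_y.tolist(),
            "receptor_names": self.receptor_names,
            "U": self.U.tolist(),
            "V": self.V.tolist(),
        }
        (d / "metadata.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "CcaModel":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        a = np.atleast_2d(np.loadtxt(d / "a.tsv", delimiter="\t"))
        rho = np.atleast_1d(np.loadtxt(d / "rho.tsv", delimiter="\t"))
        if meta["receptor_names"] is not None:
            lines = (d / "b.tsv").read_text().splitlines()[1:]
            b = np.array(
                [[float(v) for v in ln.split("\t")[1:]] for ln in lines]
            )
        else:
            b = np.atleast_2d(np.loadtxt(d / "b.tsv", delimiter="\t"))
        return cls(
            a=a,
            b=b,
            U=np.array(meta["U"]),
            V=np.array(meta["V"]),
            rho=rho,
            h=meta["h"],
            mean_x=np.array(meta["mean_x"]),
            mean_y=np.array(meta["mean_y"]),
            ridge=meta["ridge"],
            receptor_names=meta["receptor_names"],
        )


def _whiten_basis(
    Zc: np.ndarray, ridge: float
) -> tuple[np.ndarray, np.ndarray]:
    """Return (orthonormal variate basis Q, coefficient map K) such that
    Zc @ K = Q with Q^T Q = I on the retained rank; ridge > 0 swaps exact
    whitening for the regularized inverse of (Z^T Z + ridge*I)."""
    U, s, Vt = scipy.linalg.svd(Zc, full_matrices=False)
    keep = s > WHITEN_RTOL * (s[0] if s.size else 0.0)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    if not s.size:
        raise ValueError("degenerate input: block has zero variance everywhere")
    if ridge > 0:
        scale = 1.0 / np.sqrt(s**2 + ridge)
        K = Vt.T * scale
        Q = Zc @ K
    else:
        K = Vt.T / s
        Q = U
    return Q, K


def fit_cca(
    X: np.ndarray,
    Y: np.ndarray,
    h: int | None = None,
    ridge: float = 0.0,
    receptor_names: list[str] | None = None,
) -> CcaModel:
    """Fit CCA between blocks X (n x p) and Y (n x q).

    `h` caps the number of returned factors; it is further capped at the
    effective (truncated) rank of each centered block. Canonical vectors
    are scaled so each variate has unit sample variance, and each factor
    is signed so that its largest-|weight| receptor coefficient in b is
    positive (an anatomical anchor rule may re-orient signs later).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with equal row counts")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    if h is not None and h < 1:
        raise ValueError("h must be >= 1")
    mean_x = X.mean(axis=0)
    mean_y = Y.mean(axis=0)
    Xc = X - mean_x
    Yc = Y - mean_y
    Qx, Kx = _whiten_basis(Xc, ridge)
    Qy, Ky = _whiten_basis(Yc, ridge)
    max_h = min(Qx.shape[1], Qy.shape[1])
    h_eff = max_h if h is None else min(h, max_h)
    L, d, Rt = scipy.linalg.svd(Qx.T @ Qy, full_matrices=False)
    rho = np.clip(d[:h_eff], 0.0, 1.0)
    a = Kx @ L[:, :h_eff]
    b = Ky @ Rt.T[:, :h_eff]
    U = Xc @ a
    V = Yc @ b
    # unit-variance variates
    for Z, coef in ((U, a), (V, b)):
        sd = Z.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Z /= sd
        coef /= sd
    model = CcaModel(
        a=a,
        b=b,
        U=U,
        V=V,
        rho=rho,
        h=h_eff,
        mean_x=mean_x,
        mean_y=mean_y,
        ridge=ridge,
        receptor_names=receptor_names,
    )
    for i in range(h_eff):
        lead = np.argmax(np.abs(model.b[:, i]))
        if model.b[lead, i] < 0:
            model.flip_factor(i)
    return model


def compare_models(
    model1: CcaModel, model2: CcaModel
) -> dict[str, np.ndarray]:
    """Similarity of two fits sharing a receptor panel.

    Receptor-side canonical vectors are compared by Pearson correlation
    after greedy matching: factors are paired by maximal |r|, and each
    pair's sign is aligned (the larger-|r| orientation is kept). Returns
    the per-pair similarities, the matched factor indices, and the full
    |r| matrix.
    """
    if model1.b.shape[0] != model2.b.shape[0]:
        raise ValueError("receptor panels differ between models")
    if (
        model1.receptor_names is not None
        and model2.receptor_names is not None
        and model1.receptor_names != model2.receptor_names
    ):
        raise ValueError("receptor panels differ between models")
    r_full = np.zeros((model1.h, model2.h))
    for i in range(model1.h):
        for j in range(model2.h):
            r_full[i, j] = np.corrcoef(model1.b[:, i], model2.b[:, j])[0, 1]
    abs_r = np.abs(r_full)
    n_pairs = min(model1.h, model2.h)
    pairs: list[tuple[int, int]] = []
    sims: list[float] = []
    avail1, avail2 = set(range(model1.h)), set(range(model2.h))
    for _ in range(n_pairs):
        best = max(
            ((i, j) for i in avail1 for j in avail2),
            key=lambda ij: abs_r[ij],
        )
        pairs.append(best)
        sims.append(abs_r[best])
        avail1.discard(best[0])
        avail2.discard(best[1])
    order = np.argsort([p[0] for p in pairs])
    return {
        "similarity": np.array(sims)[order],
        "pairs": np.array(pairs)[order],
        "r_matrix": r_full,
    }
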