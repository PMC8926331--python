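"""Nonparametric significance of canonical factors.

The null hypothesis — no association between semantic coordinates X and
receptor fingerprints Y across testimonials — is simulated by holding X
fixed and shuffling the rows of Y testimonial-wise. Each shuffle destroys
the report-to-drug pairing while preserving both blocks' marginal
structure. The maximum canonical correlation of every shuffled refit
forms a single null distribution against which *all* observed factors are
compared (a max-statistic test), which controls the family-wise error of
searching through every estimated factor.

P-values use the add-one estimator p_i = (1 + #{null_max >= rho_i}) /
(n_perm + 1), which is valid (never anti-conservative) and has floor
1/(n_perm + 1); ties count as exceedances. Because every factor is
compared with the same null maxima, p-values are automatically
nondecreasing across the rho-ordered factors.

Shuffles are driven by per-iteration child seeds spawned from the master
seed, so results do not depend on execution order and a fixed seed
reproduces the null distribution exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .cca import CcaModel, _whiten_basis, fit_cca


@dataclass
class PermutationResult:
    null_max_rho: np.ndarray
    p_values: np.ndarray
    n_perm: int
    seed: int
    alpha: float

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.p_values < self.alpha))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "null_max_rho": self.null_max_rho.tolist(),
                    "p_values": self.p_values.tolist(),
                    "n_perm": self.n_perm,
                    "seed": self.seed,
                    "alpha": self.alpha,
                },
                indent=2,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "PermutationResult":
        d = json.loads(Path(path).read_text())
        return cls(
            null_max_rho=np.array(d["null_max_rho"]),
            p_values=np.array(d["p_values"]),
            n_perm=d["n_perm"],
            seed=d["seed"],
            alpha=d["alpha"],
        )


def _iteration_rngs(seed: int, n_perm: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n_perm)
    return [np.random.default_rng(c) for c in children]


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    h: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    ridge: float = 0.0,
    permute_drug_labels: np.ndarray | None = None,
) -> tuple[CcaModel, PermutationResult]:
    """Fit the observed CCA and derive max-statistic permutation p-values.

    With the default unregularized fit, shuffled refits reuse the observed
    blocks' whitening (a row permutation of Y permutes its orthonormal
    variate basis identically and leaves column means and singular values
    unchanged), so each iteration reduces to one small SVD. With ridge > 0
    the model is refitted from scratch per iteration.

    `permute_drug_labels` switches to block shuffling: instead of
    permuting testimonial rows, the drug label attached to each distinct
    fingerprint row is reassigned at random (an off-by-default variant for
    drug-level exchangeability; the default testimonial-wise shuffle is
    the procedure of record).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    model = fit_cca(X, Y, h=h, ridge=ridge)
    n = X.shape[0]
    rngs = _iteration_rngs(seed, n_perm)
    null_max = np.empty(n_perm)

    if ridge == 0 and permute_drug_labels is None:
        Qx, _ = _whiten_basis(X - X.mean(axis=0), 0.0)
        Qy, _ = _whiten_basis(Y - Y.mean(axis=0), 0.0)
        for it, rng in enumerate(rngs):
            perm = rng.permutation(n)
            s = scipy.linalg.svd(
                Qx.T @ Qy[perm], full_matrices=False, compute_uv=False
            )
            null_max[it] = min(s[0], 1.0)
    else:
        for it, rng in enumerate(rngs):
            if permute_drug_labels is not None:
                labels = np.asarray(permute_drug_labels)
                uniq = np.unique(labels)
                relabel = dict(zip(uniq, rng.permutation(uniq)))
                row_of = {d: np.flatnonzero(labels == d)[0] for d in uniq}
                Y_perm = Y[[row_of[relabel[d]] for d in labels]]
            else:
                Y_perm = Y[rng.permutation(n)]
            null_max[it] = fit_cca(X, Y_perm, h=1, ridge=ridge).rho[0]

    # ties count as exceedances (conservative)
    exceed = (null_max[None, :] >= model.rho[:, None] - 1e-12).sum(axis=1)
    p_values = (1.0 + exceed) / (n_perm + 1.0)
    result = PermutationResult(
        null_max_rho=null_max,
        p_values=p_values,
        n_perm=n_perm,
        seed=seed,
        alpha=alpha,
    )
    return model, result


def select_significant(
    result: PermutationResult, model: CcaModel
) -> CcaModel:
    """Truncate the model to the factors with p < alpha (order preserved).
    Zero significant factors is a valid outcome: an empty model is
    returned with a warning."""
    n_sig = result.n_significant
    if n_sig == 0:
        import warnings

        warnings.warn(
            "no canonical factor is significant at "
            f"alpha={result.alpha}; returning an empty model",
            stacklevel=2,
        )
    return model.truncated(n_sig)
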