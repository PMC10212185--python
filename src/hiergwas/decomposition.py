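"""Principal genetic components of system dosage matrices.

For a centred N x S system matrix G the decomposition keeps the first k
principal components, where k is the smallest number explaining 95% of the
variance, capped at 50 (and at the numerical rank).  Scores are T = G W with
W the right singular vectors of G.  A randomized SVD path trades a little
accuracy for speed on large matrices.  Genome-wide population-structure
components reuse the same machinery on the full variant set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.utils.extmath import randomized_svd

from ._util import DegenerateInputError
from .genotypes import GenotypeMatrix

__all__ = [
    "SystemComponents",
    "principal_components",
    "randomized_components",
    "population_pcs",
]


@dataclass
class SystemComponents:
    scores: np.ndarray  # T, N x k
    loadings: np.ndarray  # W, S x k
    explained_variance_ratio: np.ndarray  # length k
    k: int
    method: str  # "exact" | "randomized"
    singular_values: np.ndarray


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| entry is positive."""
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return signs


def _select_k(ratios: np.ndarray, var_target: float, k_max: int, rank: int) -> int:
    cum = np.cumsum(ratios[:rank])
    reached = np.nonzero(cum >= var_target - 1e-12)[0]
    k_needed = int(reached[0]) + 1 if reached.size else rank
    return max(1, min(k_max, rank, k_needed))


def principal_components(
    G: np.ndarray,
    var_target: float = 0.95,
    k_max: int = 50,
    method: str = "exact",
    seed=None,
    **randomized_kwargs,
) -> SystemComponents:
    """Decompose a centred system matrix, keeping k components by the 95%/50 rule.

    ``method='randomized'`` delegates to :func:`randomized_components`.
    """
    G = np.asarray(G, dtype=float)
    if method == "randomized":
        return randomized_components(
            G, var_target=var_target, k_max=k_max, seed=seed, **randomized_kwargs
        )
    total_var = float((G ** 2).sum())
    if total_var == 0.0:
        raise DegenerateInputError("all-zero system matrix has no components")
    U, s, Vt = np.linalg.svd(G, full_matrices=False)
    tol = s[0] * max(G.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    ratios = s ** 2 / total_var
    k = _select_k(ratios, var_target, k_max, rank)
    W = Vt[:k].T
    signs = _fix_signs(W)
    W = W * signs
    T = G @ W
    return SystemComponents(
        scores=T,
        loadings=W,
        explained_variance_ratio=ratios[:k],
        k=k,
        method="exact",
        singular_values=s[:k],
    )


def randomized_components(
    G: np.ndarray,
    var_target: float = 0.95,
    k_max: int = 50,
    k_probe: int | None = None,
    oversampling: int = 10,
    n_iter: int = 7,
    seed=None,
) -> SystemComponents:
    """Approximate decomposition via randomized SVD (reproducible per seed).

    ``k_probe`` components are estimated (default: the k_max cap); the k rule
    is then applied using the exact total variance of G, so the cumulative
    ratios are comparable with the exact path.
    """
    G = np.asarray(G, dtype=float)
    total_var = float((G ** 2).sum())
    if total_var == 0.0:
        raise DegenerateInputError("all-zero system matrix has no components")
    max_rank = min(G.shape)
    if k_probe is None:
        k_probe = min(k_max, max_rank)
    if k_probe > max_rank:
        raise ValueError(f"k_probe={k_probe} exceeds min(N, S)={max_rank}")
    rng = np.random.RandomState(
        None if seed is None else np.random.SeedSequence(seed).generate_state(1)[0]
    )
    U, s, Vt = randomized_svd(
        G, n_components=k_probe, n_oversamples=oversampling,
        n_iter=n_iter, random_state=rng,
    )
    tol = (s[0] if s.size else 0.0) * max(G.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    ratios = s ** 2 / total_var
    k = _select_k(ratios, var_target, k_max, max(rank, 1))
    W = Vt[:k].T
    signs = _fix_signs(W)
    W = W * signs
    T = G @ W
    return SystemComponents(
        scores=T,
        loadings=W,
        explained_variance_ratio=ratios[:k],
        k=k,
        method="randomized",
        singular_values=s[:k],
    )


def population_pcs(
    full_gm: GenotypeMatrix | np.ndarray,
    n_components: int = 10,
    method: str = "auto",
    seed=None,
) -> np.ndarray:
    """Top population-structure principal-component scores (N x n_components).

    Computed on the centred genome-wide dosage matrix (missing values
    mean-imputed) with the deterministic sign convention.  ``method='auto'``
    uses randomized SVD when the variant count is large.
    """
    if isinstance(full_gm, GenotypeMatrix):
        X = full_gm.dosages.copy()
        means = np.nanmean(X, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = means[nan_c]
        X = X - means
    else:
        X = np.asarray(full_gm, dtype=float)
        X = X - X.mean(axis=0)
    max_rank = min(X.shape)
    if method == "auto":
        method = "randomized" if X.shape[1] > 2000 else "exact"
    if method == "exact":
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
    else:
        rng = np.random.RandomState(
            0 if seed is None else np.random.SeedSequence(seed).generate_state(1)[0]
        )
        U, s, Vt = randomized_svd(
            X, n_components=min(n_components, max_rank), n_oversamples=10,
            n_iter=4, random_state=rng,
        )
    tol = (s[0] if s.size else 0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    n_avail = min(n_components, rank)
    if n_avail < n_components:
        warnings.warn(
            f"only {n_avail} non-degenerate population components available "
            f"({n_components} requested)"
        )
    W = Vt[:n_avail].T
    W = W * _fix_signs(W)
    return X @ W
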