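"""Per-system association: logistic likelihood-ratio tests and effect vectors.

Each system is tested by comparing the full logistic model

    f1:  logit P(y=1) = T a + C b + intercept

against the covariate-only null

    f0:  logit P(y=1) = C b + intercept

with a chi-squared likelihood-ratio test on k = ncol(T) degrees of freedom,
where T holds the system's principal genetic component scores and C the
clinical covariates plus population PCs.  The fitted component coefficients
``a`` map back to per-SNP log-odds contributions through e = W a.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import chi2, hypergeom

from ._util import DataError
from .decomposition import SystemComponents, principal_components
from .genotypes import GenotypeMatrix, build_system_matrix

__all__ = [
    "LogisticFit",
    "AssociationResult",
    "fit_logistic",
    "drop_collinear",
    "lrt_system",
    "bonferroni",
    "snp_effects",
    "associate_system",
    "gene_association",
    "replication_overlap_test",
]

_ETA_CLIP = 35.0  # logits beyond this are numerically 0/1
_SEPARATION_BOUND = 30.0  # |coef| beyond this flags (quasi-)separation


@dataclass
class LogisticFit:
    params: np.ndarray
    llf: float
    converged: bool
    n_iter: int
    separated: bool = False


@dataclass
class AssociationResult:
    system_id: str
    n_genes: int
    n_snps: int
    k: int
    chi2: float
    df: int
    p: float
    p_adj: float = float("nan")
    alpha_hat: np.ndarray | None = None
    snp_effects: np.ndarray | None = None
    snp_ids: list[str] = field(default_factory=list)
    name: str = ""
    namespace: str = ""


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: -log(1 + e^-eta) etc.
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS with step halving.

    Convergence when the largest coefficient change is below ``tol``.
    (Quasi-)separation is flagged when coefficients diverge; callers report
    such systems with a missing p-value rather than aborting.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    # column scales make the convergence and separation criteria invariant to
    # predictor rescaling (PC score columns can have arbitrarily small scale)
    col_scale = X.std(axis=0)
    col_scale[col_scale == 0] = np.maximum(np.abs(X[:, col_scale == 0]).max(axis=0), 1.0)
    beta = np.zeros(d)
    eta = X @ beta
    ll = _loglik(y, eta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, grad, rcond=None)[0]
        # damped Newton: halve the step until the likelihood does not decrease
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new = _loglik(y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = beta + step * delta
        eta = X @ beta
        ll = _loglik(y, eta)
        scaled_step = np.abs(step * delta) * col_scale / (1.0 + np.abs(beta) * col_scale)
        if scaled_step.max() < tol:
            converged = True
            break
    separated = bool((np.abs(beta) * col_scale).max() > _SEPARATION_BOUND) or not converged
    return LogisticFit(params=beta, llf=ll, converged=converged, n_iter=it,
                       separated=separated)


def drop_collinear(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal linearly independent subset of columns (QR with pivoting)."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    ref = diag[0] if diag.size and diag[0] > 0 else 1.0
    rank = int((diag > tol * ref).sum())
    return np.sort(piv[:rank])


def lrt_system(
    y: np.ndarray,
    T: np.ndarray,
    C: np.ndarray | None,
    fit0: LogisticFit | None = None,
) -> tuple[float, int, float]:
    """Likelihood-ratio test of the system components T given covariates C.

    Returns (chi2 statistic, df, p).  Zero-variance or collinear component
    columns are dropped (df counts the columns actually tested); if both
    fits fail to converge the p-value is NaN.  A precomputed null fit may be
    passed to avoid refitting f0 across systems sharing y and C.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    base = [np.ones((n, 1))]
    if C is not None and np.asarray(C).size:
        base.append(np.asarray(C, dtype=float))
    X0 = np.column_stack(base)
    T = np.atleast_2d(np.asarray(T, dtype=float))
    if T.shape[0] != n:
        T = T.T
    # keep component columns independent of the null design and of each other
    keep = drop_collinear(np.column_stack([X0, T]))
    t_cols = keep[keep >= X0.shape[1]] - X0.shape[1]
    df = int(t_cols.size)
    if df == 0:
        return 0.0, 0, 1.0
    if fit0 is None:
        fit0 = fit_logistic(y, X0)
    X1 = np.column_stack([X0, T[:, t_cols]])
    fit1 = fit_logistic(y, X1)
    if fit0.separated or fit1.separated:
        return float("nan"), df, float("nan")
    stat = max(0.0, 2.0 * (fit1.llf - fit0.llf))
    return stat, df, float(chi2.sf(stat, df))


def bonferroni(p: float, m: int) -> float:
    """Family-wise error control: min(1, p * m) over m tested systems."""
    if not 0.0 <= p <= 1.0:
        raise DataError(f"p-value {p} outside [0, 1]")
    if m < 1:
        raise DataError("m must be >= 1")
    return min(1.0, p * m)


def snp_effects(W: np.ndarray, alpha_hat: np.ndarray) -> np.ndarray:
    """Per-SNP log-odds contribution per minor-allele copy: e = W a."""
    W = np.asarray(W, dtype=float)
    alpha_hat = np.asarray(alpha_hat, dtype=float).ravel()
    if W.shape[1] != alpha_hat.shape[0]:
        raise DataError(
            f"loadings have {W.shape[1]} components but alpha has {alpha_hat.shape[0]}"
        )
    return W @ alpha_hat


def associate_system(
    y: np.ndarray,
    gm: GenotypeMatrix,
    snp_ids,
    C: np.ndarray | None,
    system_id: str = "",
    n_genes: int = 0,
    var_target: float = 0.95,
    k_max: int = 50,
    method: str = "exact",
    seed=None,
    fit0: LogisticFit | None = None,
    components: SystemComponents | None = None,
) -> tuple[AssociationResult, SystemComponents]:
    """Full single-system pipeline: dosage matrix -> PCs -> LRT -> effect vector."""
    X, _, ids = build_system_matrix(gm, snp_ids)
    if components is None:
        components = principal_components(
            X, var_target=var_target, k_max=k_max, method=method, seed=seed
        )
    T = components.scores
    stat, df, p = lrt_system(y, T, C, fit0=fit0)
    alpha_hat = None
    effects = None
    if np.isfinite(p):
        # refit f1 once to extract the component coefficients for e = W a
        n = y.shape[0]
        base = [np.ones((n, 1))]
        if C is not None and np.asarray(C).size:
            base.append(np.asarray(C, dtype=float))
        X0 = np.column_stack(base)
        keep = drop_collinear(np.column_stack([X0, T]))
        t_cols = keep[keep >= X0.shape[1]] - X0.shape[1]
        if t_cols.size:
            fit1 = fit_logistic(y, np.column_stack([X0, T[:, t_cols]]))
            alpha_full = np.zeros(T.shape[1])
            alpha_full[t_cols] = fit1.params[X0.shape[1]:]
            alpha_hat = alpha_full
            effects = snp_effects(components.loadings, alpha_full)
    result = AssociationResult(
        system_id=system_id,
        n_genes=n_genes,
        n_snps=len(ids),
        k=components.k,
        chi2=stat,
        df=df,
        p=p,
        alpha_hat=alpha_hat,
        snp_effects=effects,
        snp_ids=ids,
    )
    return result, components


def gene_association(
    y: np.ndarray,
    gene: str,
    snp_ids,
    gm: GenotypeMatrix,
    C: np.ndarray | None,
    fit0: LogisticFit | None = None,
    **pca_params,
) -> AssociationResult | None:
    """Association of a single gene (the system is the singleton gene set)."""
    if not snp_ids:
        warnings.warn(f"gene {gene} has no assigned SNPs; skipped")
        return None
    result, _ = associate_system(
        y, gm, snp_ids, C, system_id=gene, n_genes=1, fit0=fit0, **pca_params
    )
    return result


def replication_overlap_test(nA: int, nB: int, k_overlap: int, N_universe: int) -> float:
    """Hypergeometric upper-tail probability of >= k_overlap shared hits.

    Used to ask whether two cohorts' borderline-significant system lists
    overlap more than chance given a universe of tested systems.
    """
    if not (0 <= k_overlap <= min(nA, nB) <= N_universe):
        raise DataError(
            f"inconsistent counts: nA={nA}, nB={nB}, k={k_overlap}, N={N_universe}"
        )
    return float(hypergeom.sf(k_overlap - 1, N_universe, nA, nB))
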