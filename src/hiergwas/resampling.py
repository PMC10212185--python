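"""Permutation machinery: type-I calibration and competitive recalibration.

Outcome labels are permuted while *balancing* the clinical covariates:
samples are stratified into deciles of a covariate-only logistic propensity
score and labels are shuffled within strata, which preserves the
covariate-outcome association structure while breaking any genotype link.
The type-I error rate of the per-system test is the mean fraction of systems
with p < 0.05 across permutations.  Competitive recalibration compares a
system's observed p-value against p-values of the same structural position
in label-permuted ontologies, via the add-one empirical estimator
(r + 1) / (n + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import fit_logistic

__all__ = [
    "PermutationRun",
    "balanced_permutation",
    "type1_error",
    "ontology_permutation_pvalue",
    "qq_table",
]


@dataclass
class PermutationRun:
    n_perm: int
    seed: object
    fractions: np.ndarray  # per-permutation fraction of systems with p < alpha
    alpha: float = 0.05

    @property
    def mean_fraction(self) -> float:
        return float(self.fractions.mean())

    @property
    def sd_fraction(self) -> float:
        return float(self.fractions.std(ddof=1)) if self.fractions.size > 1 else 0.0


def _propensity_strata(y, C, n_strata: int) -> np.ndarray:
    """Stratum label per sample from deciles of the covariate-only propensity."""
    n = len(y)
    if C is None or np.asarray(C).size == 0 or n_strata <= 1:
        return np.zeros(n, dtype=int)
    C = np.asarray(C, dtype=float)
    fit = fit_logistic(np.asarray(y, float), np.column_stack([np.ones(n), C]))
    score = np.column_stack([np.ones(n), C]) @ fit.params
    edges = np.quantile(score, np.linspace(0, 1, n_strata + 1)[1:-1])
    strata = np.searchsorted(edges, score, side="right")
    # merge undersized strata into their left neighbour
    labels, counts = np.unique(strata, return_counts=True)
    for lab, cnt in zip(labels, counts):
        if cnt < 2:
            warnings.warn(f"propensity stratum {lab} has {cnt} member(s); merged")
            target = labels[labels < lab][-1] if (labels < lab).any() else labels[labels > lab][0]
            strata[strata == lab] = target
    return strata


def balanced_permutation(
    y: np.ndarray,
    C: np.ndarray | None,
    n_perm: int,
    seed,
    n_strata: int = 10,
) -> np.ndarray:
    """Covariate-balanced permutations of the outcome: (n_perm, N) array.

    Case counts are preserved exactly within every propensity stratum (hence
    globally).  With no covariates this reduces to a plain permutation.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    strata = _propensity_strata(y, C, n_strata)
    groups = [np.nonzero(strata == s)[0] for s in np.unique(strata)]
    out = np.empty((n_perm, y.shape[0]), dtype=y.dtype)
    for i in range(n_perm):
        perm = y.copy()
        for idx in groups:
            perm[idx] = perm[idx[rng.permutation(idx.size)]]
        out[i] = perm
    return out


def type1_error(per_perm_system_pvalues: np.ndarray, alpha: float = 0.05):
    """Mean and sd of the per-permutation fraction of systems below ``alpha``.

    ``per_perm_system_pvalues`` is (n_perm, n_systems); NaN p-values (failed
    fits) are excluded from each permutation's denominator.
    """
    P = np.asarray(per_perm_system_pvalues, dtype=float)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValueError("expected a (n_perm, n_systems) array")
    finite = np.isfinite(P)
    denom = np.maximum(finite.sum(axis=1), 1)
    fractions = (finite & (P < alpha)).sum(axis=1) / denom
    mean = float(np.mean(fractions))
    sd = float(np.std(fractions, ddof=1)) if P.shape[0] > 1 else 0.0
    return mean, sd, fractions


def ontology_permutation_pvalue(p_obs: float, null_pvalues) -> float:
    """Competitive (add-one) empirical p: (r + 1) / (n + 1).

    r counts permuted-ontology p-values at or below the observed one; with
    100 permutations and no exceedances this is 1/101, printed as 0.01.
    """
    null = np.asarray(null_pvalues, dtype=float)
    null = null[np.isfinite(null)]
    r = int((null <= p_obs).sum())
    return (r + 1) / (null.size + 1)


def qq_table(pvalues) -> pd.DataFrame:
    """Sorted observed vs expected -log10 p pairs for QQ plotting."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if (p == 0).any():
        warnings.warn("p-values of 0 clamped to the smallest positive float")
        p = np.maximum(p, np.finfo(float).tiny)
    obs = np.sort(p)
    n = obs.size
    expected = np.arange(1, n + 1) / (n + 1)
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(obs),
        }
    )
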