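"""Controlled one-step vs two-step power comparison.

Simulates a 10-SNP system for 1000 cases and 1000 controls under two
genotype schemas — independent Bernoulli SNPs (case probability 0.02 vs
control 0.01) and an Ising model with pairwise couplings (random 0/1
coupling graph with edge probability 0.5; activation thresholds -3.5 for
cases, -5 for controls) — then compares

* one-step: PCA of the pooled matrix (95%/50-PC rule) followed by a logistic
  likelihood-ratio chi-squared test of case/control status, and
* two-step: per-SNP univariate logistic tests combined by Fisher's method
  (chi-squared with 2m degrees of freedom).

Additive noise shrinks the case/control contrast; power at each noise level
is 1 minus the fraction of repetitions failing to reject at p = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from ._util import DataError, spawn_rngs
from .association import fit_logistic, lrt_system
from .decomposition import principal_components

__all__ = [
    "SimulationConfig",
    "PowerResult",
    "simulate_independent",
    "ising_distribution",
    "simulate_ising",
    "one_step_test",
    "fisher_combine",
    "two_step_test",
    "power_sweep",
]

DEFAULT_NOISE_GRID = (0.0, 0.025, 0.05, 0.075, 0.1)


@dataclass
class SimulationConfig:
    schema: str = "independent"  # "independent" | "ising"
    m_snps: int = 10
    n_case: int = 1000
    n_ctrl: int = 1000
    p_case: float = 0.02
    p_ctrl: float = 0.01
    tau_case: float = -3.5
    tau_ctrl: float = -5.0
    connectivity: float = 0.5
    noise_grid: tuple = DEFAULT_NOISE_GRID
    reps: int = 100
    alpha: float = 0.05
    seed: int = 0


@dataclass
class PowerResult:
    schema: str
    table: pd.DataFrame  # columns: schema, noise, method, power, reps, seed
    reps: int
    seed: int = 0


def simulate_independent(cfg: SimulationConfig, noise: float, seed):
    """Independent binary SNPs: Bernoulli(p_group + noise) entries."""
    pc, pk = cfg.p_case + noise, cfg.p_ctrl + noise
    if not (0.0 <= pc <= 1.0 and 0.0 <= pk <= 1.0):
        raise DataError(f"noise {noise} pushes a probability outside [0, 1]")
    rng = np.random.default_rng(seed)
    case = (rng.random((cfg.n_case, cfg.m_snps)) < pc).astype(np.int8)
    ctrl = (rng.random((cfg.n_ctrl, cfg.m_snps)) < pk).astype(np.int8)
    return case, ctrl


def ising_distribution(tau, W):
    """Exact probability table over all 2^m binary states.

    P(x) is proportional to exp(sum_i tau_i x_i + sum_{i<j} w_ij x_i x_j) for
    x in {0, 1}^m.  Returns (states array of shape (2^m, m), probabilities).
    """
    tau = np.asarray(tau, dtype=float).ravel()
    W = np.asarray(W, dtype=float)
    m = tau.size
    if W.shape != (m, m) or not np.allclose(W, W.T):
        raise DataError("coupling matrix must be symmetric m x m")
    if m > 20:
        raise DataError("exact enumeration limited to m <= 20")
    states = ((np.arange(2 ** m)[:, None] >> np.arange(m)) & 1).astype(np.int8)
    energy = states @ tau + 0.5 * np.einsum("si,ij,sj->s", states, W, states)
    energy -= energy.max()
    p = np.exp(energy)
    p /= p.sum()
    return states, p


def simulate_ising(cfg: SimulationConfig, noise: float, seed):
    """Ising-coupled binary SNPs for case and control groups.

    One coupling graph is drawn per call (edge probability ``connectivity``,
    weight 1); rows are sampled exactly from the enumerated distribution with
    group-specific thresholds.  Noise then flips each entry to 1 with
    probability ``noise``, keeping entries binary.
    """
    if not 0.0 <= noise <= 1.0:
        raise DataError(f"noise {noise} outside [0, 1]")
    rng = np.random.default_rng(seed)
    m = cfg.m_snps
    W = np.zeros((m, m))
    iu = np.triu_indices(m, k=1)
    edges = rng.random(iu[0].size) < cfg.connectivity
    W[iu] = edges.astype(float)
    W += W.T

    def draw(tau_scalar, n):
        states, p = ising_distribution(np.full(m, tau_scalar), W)
        idx = rng.choice(states.shape[0], size=n, p=p)
        return states[idx].copy()

    case = draw(cfg.tau_case, cfg.n_case)
    ctrl = draw(cfg.tau_ctrl, cfg.n_ctrl)
    if noise > 0:
        case[rng.random(case.shape) < noise] = 1
        ctrl[rng.random(ctrl.shape) < noise] = 1
    return case, ctrl


def _stack(case, ctrl):
    X = np.vstack([case, ctrl]).astype(float)
    y = np.concatenate([np.ones(len(case)), np.zeros(len(ctrl))])
    return X, y


def one_step_test(case, ctrl, var_target: float = 0.95, k_max: int = 50) -> float:
    """Pooled PCA (95%/50-PC rule) followed by a logistic LRT on the label."""
    X, y = _stack(case, ctrl)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        return float("nan")
    comps = principal_components(Xc, var_target=var_target, k_max=k_max)
    _, _, p = lrt_system(y, comps.scores, C=None)
    return p


def _univariate_logistic_p(y, x) -> float:
    n = y.shape[0]
    if np.ptp(x) == 0:
        return 1.0
    X0 = np.ones((n, 1))
    fit0 = fit_logistic(y, X0)
    fit1 = fit_logistic(y, np.column_stack([X0, x]))
    if fit1.separated:
        return float("nan")
    stat = max(0.0, 2.0 * (fit1.llf - fit0.llf))
    return float(chi2.sf(stat, 1))


def fisher_combine(pvalues) -> float:
    """Fisher's method: X = -2 sum ln p_i referred to chi2 with 2m df."""
    pvals = np.asarray(pvalues, dtype=float)
    pvals = pvals[np.isfinite(pvals)]
    if pvals.size == 0:
        return float("nan")
    if (pvals == 0).any():
        warnings.warn("p of 0 clamped to the smallest positive float")
        pvals = np.maximum(pvals, np.finfo(float).tiny)
    stat = -2.0 * np.log(pvals).sum()
    return float(chi2.sf(stat, 2 * pvals.size))


def two_step_test(case, ctrl) -> float:
    """Per-SNP logistic p-values combined by Fisher's method, chi2(2m)."""
    X, y = _stack(case, ctrl)
    m = X.shape[1]
    pvals = [_univariate_logistic_p(y, X[:, j]) for j in range(m)]
    return fisher_combine(pvals)


def _simulate(cfg: SimulationConfig, noise: float, seed):
    if cfg.schema == "independent":
        return simulate_independent(cfg, noise, seed)
    if cfg.schema == "ising":
        return simulate_ising(cfg, noise, seed)
    raise DataError(f"unknown simulation schema {cfg.schema!r}")


def power_sweep(cfg: SimulationConfig) -> PowerResult:
    """Power of both tests at each noise level over ``cfg.reps`` repetitions.

    Each repetition draws one dataset per noise level and applies both tests
    to the same draw (paired comparison).  Power = 1 - fraction of reps with
    p >= alpha.
    """
    rngs = spawn_rngs(cfg.seed, len(cfg.noise_grid) * cfg.reps)
    rows = []
    idx = 0
    for noise in cfg.noise_grid:
        rejections = {"one_step": 0, "two_step": 0}
        valid = {"one_step": 0, "two_step": 0}
        for _ in range(cfg.reps):
            case, ctrl = _simulate(cfg, noise, rngs[idx])
            idx += 1
            for method, test in (("one_step", one_step_test), ("two_step", two_step_test)):
                p = test(case, ctrl)
                if np.isfinite(p):
                    valid[method] += 1
                    if p < cfg.alpha:
                        rejections[method] += 1
        for method in ("one_step", "two_step"):
            power = rejections[method] / valid[method] if valid[method] else float("nan")
            rows.append(
                {
                    "schema": cfg.schema,
                    "noise": noise,
                    "method": method,
                    "power": power,
                    "reps": cfg.reps,
                    "seed": cfg.seed,
                }
            )
    return PowerResult(schema=cfg.schema, table=pd.DataFrame(rows), reps=cfg.reps,
                       seed=cfg.seed)
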