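"""Conditional localisation of association signal within the hierarchy.

Nested gene sets often light up together; the top-child and top-gene tests
ask whether a system's association survives after removing the SNPs
attributable to its most associated child system or single gene.  SNP removal
is strict: a SNP near both a removed gene and a kept gene is removed anyway.
PCs are recomputed from scratch on the reduced matrix and the LRT re-run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import AssociationResult, LogisticFit, associate_system
from .genotypes import GenotypeMatrix
from .ontology import OntologyGraph

__all__ = ["ConditionalResult", "top_child_test", "top_gene_test"]


@dataclass
class ConditionalResult:
    system_id: str
    original_p: float = float("nan")
    top_child_id: str | None = None
    p_without_top_child: float = float("nan")
    n_snps_removed_child: int = 0
    child_applicable: bool = True
    top_gene_id: str | None = None
    p_without_top_gene: float = float("nan")
    n_snps_removed_gene: int = 0


def _most_significant(candidates: list[AssociationResult]) -> AssociationResult:
    """Deterministic 'most significant': smallest p, then more SNPs, then id."""
    finite = [c for c in candidates if np.isfinite(c.p)]
    pool = finite or candidates
    return min(pool, key=lambda c: (c.p if np.isfinite(c.p) else np.inf,
                                    -c.n_snps, c.system_id))


def _reduced_test(
    y, gm: GenotypeMatrix, kept_snps: set[str], C, fit0, pca_params
) -> float:
    if not kept_snps:
        return float("nan")
    result, _ = associate_system(y, gm, kept_snps, C, fit0=fit0, **pca_params)
    return result.p


def top_child_test(
    system_id: str,
    graph: OntologyGraph,
    results: dict[str, AssociationResult],
    system_snps: dict[str, set[str]],
    gene_snps: dict[str, set[str]],
    y: np.ndarray,
    gm: GenotypeMatrix,
    C: np.ndarray | None,
    fit0: LogisticFit | None = None,
    **pca_params,
) -> ConditionalResult:
    """Re-test a system after removing all SNPs near its top child's genes.

    Childless systems are marked not applicable; if removal empties the SNP
    set the conditional p is missing (the child fully accounts for the
    system's genetic context).
    """
    out = ConditionalResult(system_id=system_id,
                            original_p=results[system_id].p)
    children = [cid for cid in graph.nodes[system_id].children if cid in results]
    if not children:
        out.child_applicable = False
        return out
    top = _most_significant([results[c] for c in children])
    out.top_child_id = top.system_id
    removed: set[str] = set()
    for gene in graph.nodes[top.system_id].genes:
        removed |= gene_snps.get(gene, set())
    snps = system_snps[system_id]
    kept = snps - removed
    out.n_snps_removed_child = len(snps) - len(kept)
    out.p_without_top_child = _reduced_test(y, gm, kept, C, fit0, pca_params)
    return out


def top_gene_test(
    system_id: str,
    graph: OntologyGraph,
    gene_results: dict[str, AssociationResult],
    system_snps: dict[str, set[str]],
    gene_snps: dict[str, set[str]],
    y: np.ndarray,
    gm: GenotypeMatrix,
    C: np.ndarray | None,
    original_p: float = float("nan"),
    fit0: LogisticFit | None = None,
    **pca_params,
) -> ConditionalResult:
    """Re-test a system after removing all SNPs near its most associated gene."""
    out = ConditionalResult(system_id=system_id, original_p=original_p)
    genes = [g for g in graph.nodes[system_id].genes if g in gene_results]
    if not genes:
        return out
    top = _most_significant([gene_results[g] for g in genes])
    out.top_gene_id = top.system_id
    snps = system_snps[system_id]
    kept = snps - gene_snps.get(top.system_id, set())
    out.n_snps_removed_gene = len(snps) - len(kept)
    out.p_without_top_gene = _reduced_test(y, gm, kept, C, fit0, pca_params)
    return out
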