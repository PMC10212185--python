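"""Model/Results interface for the hierarchical association scan.

:class:`SystemAssociationScan` bundles genotypes, gene loci, the filtered
ontology, covariates and the case/control phenotype; ``fit()`` runs the
per-system pipeline (SNP window assignment, PCA of the system dosage matrix,
logistic likelihood-ratio test against the covariate-only null, Bonferroni
adjustment) and returns a :class:`SystemAssociationResults` carrying the
per-system table plus methods for conditional localisation tests,
covariate-balanced permutation calibration and competitive ontology-
permutation recalibration.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._util import DataError, spawn_rngs
from .association import (
    associate_system,
    bonferroni,
    fit_logistic,
    gene_association,
)
from .decomposition import population_pcs
from .genotypes import GenotypeMatrix, assign_snps_to_genes, qc_filter
from .hierarchy_tests import top_child_test, top_gene_test
from .ontology import OntologyGraph, permute_gene_labels
from .resampling import balanced_permutation, qq_table, type1_error, PermutationRun
from .association import lrt_system

__all__ = ["SystemAssociationScan", "SystemAssociationResults"]

COVARIATE_COLUMNS = ("age", "sex", "smoking", "pack_years")


class SystemAssociationScan:
    """Scan every system in an ontology for phenotype association.

    Parameters
    ----------
    genotypes
        QC'd or raw :class:`GenotypeMatrix` (set ``apply_qc=True`` to filter
        on MAF and control-sample HWE here).
    loci
        Gene loci (1-based inclusive) used for the SNP window assignment.
    ontology
        Filtered, propagated :class:`OntologyGraph`; every non-root node with
        assigned SNPs is tested.
    covariates
        DataFrame of clinical covariates aligned with the genotype samples
        (or ``None`` for an intercept-only null).
    phenotype
        Binary 0/1 outcome vector.
    window_bp, var_target, k_max, svd_method, n_population_pcs
        Pipeline parameters: SNP window around gene bodies (10 kb), the
        cumulative-variance target (0.95) and component cap (50) of the PCA,
        the SVD flavour, and how many genome-wide population PCs join the
        covariates (10).
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        loci,
        ontology: OntologyGraph,
        covariates: pd.DataFrame | None,
        phenotype,
        *,
        window_bp: int = 10_000,
        var_target: float = 0.95,
        k_max: int = 50,
        svd_method: str = "exact",
        n_population_pcs: int = 10,
        apply_qc: bool = False,
        maf_min: float = 0.01,
        hwe_alpha: float = 1e-6,
        seed: int | None = None,
    ):
        y = np.asarray(phenotype, dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise DataError("phenotype must be binary 0/1")
        if covariates is not None:
            if len(covariates) != genotypes.n_samples:
                raise DataError("covariate rows do not match genotype samples")
            if covariates.isna().any().any():
                raise DataError("missing covariate values are not allowed")
        if apply_qc:
            genotypes = qc_filter(genotypes, maf_min=maf_min, hwe_alpha=hwe_alpha,
                                  control_mask=y == 0)
        self.genotypes = genotypes
        self.loci = list(loci)
        self.ontology = ontology
        self.covariates = covariates
        self.y = y
        self.window_bp = window_bp
        self.var_target = var_target
        self.k_max = k_max
        self.svd_method = svd_method
        self.n_population_pcs = n_population_pcs
        self.seed = seed

        self.gene_snps = assign_snps_to_genes(genotypes.variants, self.loci, window_bp)
        self._pop_pcs: np.ndarray | None = None

    @classmethod
    def from_files(
        cls,
        genotype_path,
        genotype_dialect: str,
        loci_path,
        obo_path,
        annotation_path,
        covariate_path=None,
        phenotype_path=None,
        loci_dialect: str = "tsv",
        min_genes: int = 3,
        max_genes: int = 75,
        similarity_threshold: float = 0.9,
        apply_qc: bool = True,
        **kwargs,
    ) -> "SystemAssociationScan":
        """Build the model from on-disk inputs (VCF/PLINK, TSV, OBO + GAF/TSV)."""
        from .genotypes import read_gene_loci, read_genotypes
        from .ontology import build_hierarchy

        gm = read_genotypes(genotype_path, genotype_dialect)
        loci = read_gene_loci(loci_path, loci_dialect)
        with open(obo_path) as fo, open(annotation_path) as fa:
            graph = build_hierarchy(
                fo, fa, min_genes=min_genes, max_genes=max_genes,
                similarity_threshold=similarity_threshold,
            )
        covariates = None
        if covariate_path is not None:
            covariates = pd.read_csv(covariate_path, sep="\t").drop(
                columns=["sample_id"], errors="ignore"
            )
        pheno = pd.read_csv(phenotype_path, sep="\t")["phenotype"].to_numpy()
        return cls(gm, loci, graph, covariates, pheno, apply_qc=apply_qc, **kwargs)

    # -- design helpers ----------------------------------------------------

    @property
    def population_pcs_(self) -> np.ndarray:
        if self._pop_pcs is None:
            if self.n_population_pcs > 0:
                self._pop_pcs = population_pcs(
                    self.genotypes, n_components=self.n_population_pcs, seed=self.seed
                )
            else:
                self._pop_pcs = np.empty((self.genotypes.n_samples, 0))
        return self._pop_pcs

    def covariate_matrix(self) -> np.ndarray | None:
        blocks = []
        if self.covariates is not None and self.covariates.shape[1]:
            blocks.append(self.covariates.to_numpy(dtype=float))
        if self.n_population_pcs > 0:
            blocks.append(self.population_pcs_)
        if not blocks:
            return None
        return np.column_stack(blocks)

    def system_snp_sets(self) -> dict[str, set[str]]:
        out = {}
        for sid in self.ontology.systems():
            snps: set[str] = set()
            for gene in self.ontology.nodes[sid].genes:
                snps |= self.gene_snps.get(gene, set())
            if snps:
                out[sid] = snps
        return out

    # -- fitting -----------------------------------------------------------

    def fit(self, systems=None) -> "SystemAssociationResults":
        """Run the scan; returns results ordered by unadjusted p-value."""
        C = self.covariate_matrix()
        fit0 = fit_logistic(self.y, _design(self.y, C))
        snp_sets = self.system_snp_sets()
        if systems is not None:
            snp_sets = {s: snp_sets[s] for s in systems if s in snp_sets}
        results = {}
        components = {}
        for sid, snps in snp_sets.items():
            node = self.ontology.nodes[sid]
            try:
                res, comp = associate_system(
                    self.y, self.genotypes, snps, C,
                    system_id=sid, n_genes=len(node.genes),
                    var_target=self.var_target, k_max=self.k_max,
                    method=self.svd_method, seed=self.seed, fit0=fit0,
                )
            except DataError as exc:
                warnings.warn(f"system {sid} skipped: {exc}")
                continue
            res.name = node.name
            res.namespace = node.namespace
            results[sid] = res
            components[sid] = comp
        m = len(results)
        for res in results.values():
            res.p_adj = bonferroni(res.p, m) if np.isfinite(res.p) else float("nan")
        return SystemAssociationResults(self, results, components, fit0)


def _design(y, C):
    n = len(y)
    if C is None or np.asarray(C).size == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones((n, 1)), np.asarray(C, dtype=float)])


class SystemAssociationResults:
    """Fitted scan: per-system table, diagnostics, and follow-up tests."""

    def __init__(self, model: SystemAssociationScan, results, components, fit0):
        self.model = model
        self.results = results
        self.components = components
        self.fit0 = fit0
        self._gene_results: dict | None = None

    # -- tabular views -----------------------------------------------------

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "system_id": r.system_id,
                "name": r.name,
                "namespace": r.namespace,
                "n_genes": r.n_genes,
                "n_snps": r.n_snps,
                "k": r.k,
                "chi2": r.chi2,
                "df": r.df,
                "p": r.p,
                "p_adj": r.p_adj,
            }
            for r in self.results.values()
        ]
        df = pd.DataFrame(rows)
        if len(df):
            df = df.sort_values(["p", "system_id"], na_position="last").reset_index(drop=True)
        return df

    def summary(self, top: int = 10) -> str:
        df = self.table.head(top)
        lines = [
            "System association scan",
            "=" * 72,
            f"samples: {self.model.genotypes.n_samples} "
            f"(cases {int(self.model.y.sum())} / controls {int((1 - self.model.y).sum())})",
            f"variants: {self.model.genotypes.n_variants}   "
            f"systems tested: {len(self.results)}",
            f"window: {self.model.window_bp} bp   variance target: "
            f"{self.model.var_target}   component cap: {self.model.k_max}",
            "-" * 72,
            df.to_string(index=False,
                         float_format=lambda v: f"{v:.3g}") if len(df) else "(no systems)",
        ]
        return "\n".join(lines)

    def snp_effects(self, system_id: str) -> pd.Series:
        """Per-SNP log-odds contribution per minor-allele copy (e = W a)."""
        r = self.results[system_id]
        if r.snp_effects is None:
            raise DataError(f"system {system_id} has no fitted effect vector")
        return pd.Series(r.snp_effects, index=r.snp_ids, name="snp_effect")

    def qq_table(self) -> pd.DataFrame:
        return qq_table(self.table["p"].to_numpy())

    # -- per-gene scan -----------------------------------------------------

    def gene_scan(self) -> pd.DataFrame:
        """Single-gene associations for every gene in any tested system."""
        if self._gene_results is None:
            C = self.model.covariate_matrix()
            genes: set[str] = set()
            for sid in self.results:
                genes |= self.model.ontology.nodes[sid].genes
            out = {}
            for gene in sorted(genes):
                snps = self.model.gene_snps.get(gene, set())
                res = gene_association(
                    self.model.y, gene, snps, self.model.genotypes, C,
                    fit0=self.fit0, var_target=self.model.var_target,
                    k_max=self.model.k_max,
                )
                if res is not None:
                    out[gene] = res
            self._gene_results = out
        rows = [
            {"gene": g, "n_snps": r.n_snps, "k": r.k, "chi2": r.chi2,
             "df": r.df, "p": r.p}
            for g, r in self._gene_results.items()
        ]
        return pd.DataFrame(rows).sort_values(["p", "gene"]).reset_index(drop=True)

    # -- conditional tests ---------------------------------------------------

    def conditional_tests(self, top_n: int = 10) -> pd.DataFrame:
        """Top-child and top-gene tests on the ``top_n`` most associated systems."""
        self.gene_scan()
        C = self.model.covariate_matrix()
        snp_sets = self.model.system_snp_sets()
        order = self.table["system_id"].tolist()[:top_n]
        pca = dict(var_target=self.model.var_target, k_max=self.model.k_max)
        rows = []
        for sid in order:
            child = top_child_test(
                sid, self.model.ontology, self.results, snp_sets,
                self.model.gene_snps, self.model.y, self.model.genotypes, C,
                fit0=self.fit0, **pca,
            )
            gene = top_gene_test(
                sid, self.model.ontology, self._gene_results, snp_sets,
                self.model.gene_snps, self.model.y, self.model.genotypes, C,
                original_p=self.results[sid].p, fit0=self.fit0, **pca,
            )
            rows.append(
                {
                    "system_id": sid,
                    "original_p": self.results[sid].p,
                    "top_child_id": child.top_child_id if child.child_applicable else None,
                    "child_applicable": child.child_applicable,
                    "p_without_top_child": child.p_without_top_child,
                    "n_snps_removed_child": child.n_snps_removed_child,
                    "top_gene_id": gene.top_gene_id,
                    "p_without_top_gene": gene.p_without_top_gene,
                    "n_snps_removed_gene": gene.n_snps_removed_gene,
                }
            )
        return pd.DataFrame(rows)

    # -- permutation calibration -------------------------------------------

    def type1_calibration(
        self, n_perm: int = 1000, seed=0, alpha: float = 0.05, n_strata: int = 10
    ) -> PermutationRun:
        """Type-I error of the per-system test under balanced label permutations.

        System component scores are fixed (they do not depend on the
        outcome), so each permutation refits only the logistic models.
        Returns the per-permutation fractions of systems with p < alpha.
        """
        C = self.model.covariate_matrix()
        perms = balanced_permutation(self.model.y, C, n_perm, seed, n_strata)
        pmat = self.pvalues_under_permutations(perms)
        mean, sd, fractions = type1_error(pmat, alpha)
        return PermutationRun(n_perm=n_perm, seed=seed, fractions=fractions, alpha=alpha)

    def pvalues_under_permutations(self, permuted_outcomes: np.ndarray) -> np.ndarray:
        """(n_perm, n_systems) p-value matrix for given outcome vectors."""
        C = self.model.covariate_matrix()
        scores = [self.components[sid].scores for sid in self.results]
        pmat = np.empty((permuted_outcomes.shape[0], len(scores)))
        X0 = _design(self.model.y, C)
        for i, yp in enumerate(permuted_outcomes):
            yp = np.asarray(yp, dtype=float)
            fit0 = fit_logistic(yp, X0)
            for j, T in enumerate(scores):
                _, _, p = lrt_system(yp, T, C, fit0=fit0)
                pmat[i, j] = p
        return pmat

    # -- competitive recalibration -------------------------------------------

    def competitive_recalibration(
        self, system_ids=None, n_ontology_perm: int = 100, seed=0
    ) -> pd.DataFrame:
        """Recalibrate p-values against structure-preserving permuted ontologies.

        For each selected system, its association is recomputed under
        ``n_ontology_perm`` random gene-label bijections of the whole
        ontology; the recalibrated p is the add-one empirical tail
        probability of the observed p within that null set.
        """
        from .resampling import ontology_permutation_pvalue

        if system_ids is None:
            df = self.table
            system_ids = df[df["p_adj"] < 0.05]["system_id"].tolist() or \
                df["system_id"].tolist()[:1]
        C = self.model.covariate_matrix()
        rngs = spawn_rngs(seed, n_ontology_perm)
        null_ps: dict[str, list] = {sid: [] for sid in system_ids}
        for rng in rngs:
            permuted = permute_gene_labels(self.model.ontology, rng)
            for sid in system_ids:
                snps: set[str] = set()
                for gene in permuted.nodes[sid].genes:
                    snps |= self.model.gene_snps.get(gene, set())
                if not snps:
                    null_ps[sid].append(np.nan)
                    continue
                res, _ = associate_system(
                    self.model.y, self.model.genotypes, snps, C,
                    system_id=sid, fit0=self.fit0,
                    var_target=self.model.var_target, k_max=self.model.k_max,
                )
                null_ps[sid].append(res.p)
        rows = []
        for sid in system_ids:
            p_obs = self.results[sid].p
            rows.append(
                {
                    "system_id": sid,
                    "p": p_obs,
                    "p_competitive": ontology_permutation_pvalue(p_obs, null_ps[sid]),
                    "n_ontology_perm": n_ontology_perm,
                }
            )
        return pd.DataFrame(rows)
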