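"""Synthetic cohorts and toy ontologies with the structure the method assumes.

The generator emulates a genotyped case/control cohort: genes carrying small
LD blocks of biallelic SNPs (within-gene dosage correlation via a Gaussian
copula), two subpopulations with divergent allele frequencies, clinical
covariates (age, sex, current smoking, pack-years) with configurable effect
sizes, and a logistic phenotype model into which multi-locus system effects
can be planted.  Everything is reproducible from a single seed and can be
written out as VCF + PLINK + TSV files, so every pipeline stage is testable
without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from ._util import DataError, spawn_rngs
from .genotypes import GeneLocus, GenotypeMatrix, VariantRecord, write_plink, write_vcf
from .ontology import (
    ROOT_ID,
    OntologyGraph,
    SystemNode,
    propagate_annotations,
    unify_roots,
)

__all__ = [
    "CohortSpec",
    "Cohort",
    "DEFAULT_COVARIATE_EFFECTS",
    "generate_toy_ontology",
    "generate_cohort",
    "write_cohort",
    "ontology_from_systems",
    "plant_child_vs_parent_scenarios",
]

DEFAULT_COVARIATE_EFFECTS = {
    "age": 0.02,  # per year, centred at 60
    "sex": 0.2,
    "smoking": 0.4,
    "pack_years": 0.01,  # per pack-year, centred at 40
}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``planted_systems`` entries are (system_id, per-SNP log-odds effect,
    fraction of the system's genes carrying signal); entries may instead be
    (tuple of gene ids, effect) to plant on explicit genes.
    """

    n_case: int = 400
    n_ctrl: int = 400
    n_genes: int = 600
    genes_per_system: int = 3
    snps_per_gene: int = 4
    ld_block_rho: float = 0.3
    maf_range: tuple = (0.1, 0.4)
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    pop_divergence: float = 0.05  # allele-frequency shift between subpopulations
    pop_effect: float = 0.3  # phenotype log-odds offset of subpopulation 2
    planted_systems: tuple = ()
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_case + self.n_ctrl

    @property
    def n_systems(self) -> int:
        return self.n_genes // self.genes_per_system


@dataclass
class Cohort:
    gm: GenotypeMatrix
    loci: list[GeneLocus]
    covariates: pd.DataFrame  # age, sex, smoking, pack_years
    phenotype: np.ndarray  # 0/1 per sample
    systems: dict[str, tuple]  # system id -> ordered gene ids
    population: np.ndarray  # subpopulation label per sample
    obo_text: str
    annotation_text: str
    spec: CohortSpec


# ---------------------------------------------------------------------------
# toy ontology generator


def generate_toy_ontology(
    n_systems: int,
    max_depth: int = 4,
    gene_universe_size: int = 300,
    seed: int = 0,
    frac_high_overlap: float = 0.0,
    size_range: tuple = (1, 90),
):
    """Random DAG as OBO + annotation TSV text, for parser/filter exercise.

    Term sizes span below 3 and above 75 so the size filter has work to do;
    ``frac_high_overlap`` inserts that fraction of near-duplicate parents
    (child covering >= 90% of the parent) to exercise the similarity
    collapse.  Returns (obo_text, annotation_text, info) where ``info``
    records the planted near-duplicate parent ids.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(gene_universe_size)]
    terms: dict[str, dict] = {}
    levels: list[list[str]] = [["TOY:ROOT"]]
    terms["TOY:ROOT"] = {"name": "toy root", "parents": [], "genes": []}
    tid = 0
    for depth in range(1, max_depth + 1):
        width = max(1, math.ceil(n_systems / max_depth))
        level = []
        for _ in range(width):
            if tid >= n_systems:
                break
            name = f"TOY:{tid:05d}"
            tid += 1
            n_parents = 1 + int(rng.random() < 0.3)
            parents = list(
                rng.choice(levels[depth - 1], size=min(n_parents, len(levels[depth - 1])),
                           replace=False)
            )
            # mixture spanning below-3 and above-75 sizes so both ends of the
            # size filter are exercised
            lo, hi = size_range
            u = rng.random()
            if u < 0.2 and lo < 3:
                size = int(rng.integers(lo, 3))
            elif u > 0.9 and hi > 75:
                size = int(rng.integers(76, hi + 1))
            else:
                size = int(rng.integers(max(lo, 3), min(hi, 75) + 1))
            annot = list(rng.choice(genes, size=min(size, len(genes)), replace=False))
            terms[name] = {"name": f"toy term {name}", "parents": parents, "genes": annot}
            level.append(name)
        if level:
            levels.append(level)
    # planted near-duplicate parents: wrap an existing term with a parent whose
    # gene set barely exceeds the child's
    planted = []
    candidates = [t for t in terms if t != "TOY:ROOT" and len(terms[t]["genes"]) >= 9]
    n_plant = int(round(frac_high_overlap * len(candidates)))
    for child in list(rng.choice(candidates, size=min(n_plant, len(candidates)),
                                 replace=False)):
        wrapper = f"TOY:W{len(planted):04d}"
        terms[wrapper] = {
            "name": f"near-duplicate of {child}",
            "parents": list(terms[child]["parents"]),
            "genes": [],
        }
        terms[child]["parents"] = [wrapper]
        planted.append(wrapper)

    obo = ["format-version: 1.2", "ontology: toy", ""]
    for name, info in terms.items():
        obo.append("[Term]")
        obo.append(f"id: {name}")
        obo.append(f"name: {info['name']}")
        obo.append("namespace: biological_process")
        for p in info["parents"]:
            obo.append(f"is_a: {p}")
        obo.append("")
    annot_lines = []
    for name, info in terms.items():
        for g in info["genes"]:
            annot_lines.append(f"{g}\t{name}\tEXP")
    return "\n".join(obo) + "\n", "\n".join(annot_lines) + "\n", {"planted_wrappers": planted}


# ---------------------------------------------------------------------------
# cohort generator

_GENE_SPAN = 2_000  # bp of each synthetic gene body
_GENE_SPACING = 100_000  # bp between gene starts; keeps 10 kb windows disjoint
_GENES_PER_CHROM = 50


def _gene_layout(n_genes: int):
    loci = []
    for i in range(n_genes):
        chrom = str(1 + i // _GENES_PER_CHROM)
        offset = (i % _GENES_PER_CHROM) * _GENE_SPACING + 50_000
        loci.append(GeneLocus(f"GENE{i:05d}", chrom, offset, offset + _GENE_SPAN - 1))
    return loci


def _latent_rho(target_rho: float, maf: float) -> float:
    """Latent Gaussian correlation yielding ~``target_rho`` between binary alleles.

    Thresholding attenuates correlation; the threshold-model linearisation
    corr_binary ~= rho_latent * phi(z)^2 / (p(1-p)) is inverted and clipped.
    """
    if target_rho <= 0:
        return 0.0
    z = norm.ppf(maf)
    atten = norm.pdf(z) ** 2 / (maf * (1.0 - maf))
    return float(np.clip(target_rho / atten, 0.0, 0.97))


def _resolve_planted(spec: CohortSpec, systems: dict[str, tuple]) -> list[tuple[str, float]]:
    """Flatten planted specs into (gene, per-SNP beta) pairs."""
    out: list[tuple[str, float]] = []
    for entry in spec.planted_systems:
        if isinstance(entry[0], str):
            sys_id, beta, fraction = entry
            if sys_id not in systems:
                raise DataError(f"planted system {sys_id!r} not in generated systems")
            genes = systems[sys_id]
            n_carry = max(1, math.ceil(fraction * len(genes)))
            out.extend((g, float(beta)) for g in genes[:n_carry])
        else:
            genes, beta = entry
            out.extend((g, float(beta)) for g in genes)
    return out


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one cohort under ``spec``; fully deterministic per seed.

    Genotypes: per gene, ``snps_per_gene`` SNPs whose two allele draws share a
    Gaussian copula factor (within-gene correlation ``ld_block_rho``); MAFs
    uniform in ``maf_range`` with a +/- ``pop_divergence``/2 shift between
    two equal subpopulations.  Phenotype: Bernoulli through a logit linear in
    centred planted dosages, centred covariates and the subpopulation offset,
    with the intercept set to the target case fraction.
    """
    rng_geno, rng_cov, rng_pheno = spawn_rngs(spec.seed, 3)
    n = spec.n_samples
    loci = _gene_layout(spec.n_genes)
    pop = (np.arange(n) >= n // 2).astype(int)

    # systems: consecutive disjoint gene blocks
    systems: dict[str, tuple] = {}
    for s in range(spec.n_systems):
        genes = tuple(
            loci[g].gene
            for g in range(s * spec.genes_per_system, (s + 1) * spec.genes_per_system)
        )
        systems[f"SYS:{s:04d}"] = genes

    variants: list[VariantRecord] = []
    dosage_cols = []
    mafs_all = []
    for gi, locus in enumerate(loci):
        s = spec.snps_per_gene
        mafs = rng_geno.uniform(*spec.maf_range, size=s)
        shift_sign = rng_geno.choice([-1.0, 1.0], size=s)
        d = spec.pop_divergence / 2.0
        maf_pop = np.clip(
            mafs[None, :] + shift_sign[None, :] * d * np.array([[-1.0], [1.0]]),
            0.01, 0.99,
        )  # 2 x s
        thresh = norm.ppf(maf_pop)  # copula threshold per pop per SNP
        rho_lat = _latent_rho(spec.ld_block_rho, float(mafs.mean()))
        dos = np.zeros((n, s))
        for _hap in range(2):
            shared = rng_geno.standard_normal(n)
            eps = rng_geno.standard_normal((n, s))
            z = np.sqrt(rho_lat) * shared[:, None] + np.sqrt(1.0 - rho_lat) * eps
            dos += (z < thresh[pop]).astype(float)
        dosage_cols.append(dos)
        mafs_all.append(mafs)
        positions = np.sort(
            rng_geno.choice(np.arange(locus.start, locus.end + 1), size=s, replace=False)
        )
        for k, pos_k in enumerate(positions):
            variants.append(
                VariantRecord(
                    id=f"rs{gi:05d}_{k}", chrom=locus.chrom, pos=int(pos_k),
                    ref="A", alt="C", maf=float(mafs[k]),
                )
            )
    dosages = np.concatenate(dosage_cols, axis=1)

    covariates = pd.DataFrame(
        {
            "age": np.round(rng_cov.normal(60.0, 8.0, size=n), 1),
            "sex": rng_cov.integers(0, 2, size=n).astype(float),
            "smoking": (rng_cov.random(n) < 0.45).astype(float),
            "pack_years": np.round(np.maximum(10.0, rng_cov.normal(40.0, 15.0, size=n)), 1),
        }
    )

    eff = spec.covariate_effects
    eta = np.zeros(n)
    eta += eff.get("age", 0.0) * (covariates["age"].to_numpy() - 60.0)
    eta += eff.get("sex", 0.0) * covariates["sex"].to_numpy()
    eta += eff.get("smoking", 0.0) * covariates["smoking"].to_numpy()
    eta += eff.get("pack_years", 0.0) * (covariates["pack_years"].to_numpy() - 40.0)
    eta += spec.pop_effect * (pop - pop.mean())

    gene_cols = {
        locus.gene: slice(gi * spec.snps_per_gene, (gi + 1) * spec.snps_per_gene)
        for gi, locus in enumerate(loci)
    }
    for gene, beta in _resolve_planted(spec, systems):
        block = dosages[:, gene_cols[gene]]
        eta += beta * (block - block.mean(axis=0)).sum(axis=1)

    eta -= eta.mean()  # centre so the intercept sets the case fraction
    eta += logit(spec.n_case / n)
    prob = expit(eta)
    y = None
    for _attempt in range(10):
        draw = (rng_pheno.random(n) < prob).astype(int)
        if 0 < draw.sum() < n:
            y = draw
            break
    if y is None:
        raise DataError("phenotype model produced a single-class cohort 10 times")

    gm = GenotypeMatrix(
        sample_ids=[f"IND{i:05d}" for i in range(n)], variants=variants, dosages=dosages
    )

    obo, annot = _systems_obo(systems)
    return Cohort(
        gm=gm, loci=loci, covariates=covariates, phenotype=y, systems=systems,
        population=pop, obo_text=obo, annotation_text=annot, spec=spec,
    )


def _systems_obo(systems: dict[str, tuple]) -> tuple[str, str]:
    """Flat ontology text: every system a child of one namespace root."""
    obo = ["format-version: 1.2", "ontology: synthetic", "", "[Term]",
           "id: SYN:0000", "name: synthetic root",
           "namespace: biological_process", ""]
    annot = []
    for sid, genes in systems.items():
        obo += ["[Term]", f"id: {sid}", f"name: synthetic system {sid}",
                "namespace: biological_process", "is_a: SYN:0000", ""]
        annot += [f"{g}\t{sid}\tEXP" for g in genes]
    return "\n".join(obo) + "\n", "\n".join(annot) + "\n"


def ontology_from_systems(
    direct: dict[str, tuple], edges: list[tuple[str, str]]
) -> OntologyGraph:
    """Build a propagated, unified graph from direct gene sets and child->parent edges."""
    graph = OntologyGraph()
    for sid, genes in direct.items():
        graph.nodes[sid] = SystemNode(id=sid, name=sid, namespace="BP",
                                      direct_genes=set(genes))
    for child, parent in edges:
        graph.nodes[child].parents.add(parent)
        graph.nodes[parent].children.add(child)
    graph = unify_roots(graph)
    return propagate_annotations(graph)


def write_cohort(cohort: Cohort, outdir) -> dict[str, Path]:
    """Write the cohort as VCF + PLINK + TSV + OBO files; deterministic bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "plink": outdir / "genotypes",
        "loci": outdir / "gene_loci.tsv",
        "covariates": outdir / "covariates.tsv",
        "phenotype": outdir / "phenotype.tsv",
        "obo": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
    }
    write_vcf(cohort.gm, paths["vcf"])
    write_plink(cohort.gm, paths["plink"])
    with open(paths["loci"], "w") as fh:
        fh.write("gene\tchrom\tstart\tend\n")
        for locus in cohort.loci:
            fh.write(f"{locus.gene}\t{locus.chrom}\t{locus.start}\t{locus.end}\n")
    cov = cohort.covariates.copy()
    cov.insert(0, "sample_id", cohort.gm.sample_ids)
    cov.to_csv(paths["covariates"], sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": cohort.gm.sample_ids, "phenotype": cohort.phenotype}
    ).to_csv(paths["phenotype"], sep="\t", index=False)
    paths["obo"].write_text(cohort.obo_text)
    paths["annotations"].write_text(cohort.annotation_text)
    return paths


# ---------------------------------------------------------------------------
# conditional-test scenarios


@dataclass
class Scenario:
    name: str
    cohort: Cohort
    graph: OntologyGraph
    parent_id: str
    signal_child_id: str | None = None
    dominant_gene: str | None = None


def plant_child_vs_parent_scenarios(
    spec: CohortSpec | None = None, n_null_systems: int = 30, seed: int = 0
) -> dict[str, Scenario]:
    """Three cohorts exercising the conditional tests.

    A: all signal in one child of a nested parent (top-child removal should
    erase the parent's association).  B: signal spread over the parent's own
    genes outside its children (top-child removal should leave it).  C: a
    system driven by one dominant gene (top-gene removal should erase it).
    """
    base = spec or CohortSpec(n_case=500, n_ctrl=500)
    genes_per = base.genes_per_system
    n_genes = max(base.n_genes, (n_null_systems + 6) * genes_per + 30)

    def make(name, planted, seed_offset):
        sp = CohortSpec(
            n_case=base.n_case, n_ctrl=base.n_ctrl, n_genes=n_genes,
            genes_per_system=genes_per, snps_per_gene=base.snps_per_gene,
            ld_block_rho=base.ld_block_rho, maf_range=base.maf_range,
            covariate_effects=base.covariate_effects,
            pop_divergence=base.pop_divergence, pop_effect=base.pop_effect,
            planted_systems=(), seed=seed + seed_offset,
        )
        all_genes = [locus.gene for locus in _gene_layout(n_genes)]
        # nested block at the front: P_direct (5), C1 (5), C2 (5), D (3)
        p_direct = tuple(all_genes[0:5])
        c1 = tuple(all_genes[5:10])
        c2 = tuple(all_genes[10:15])
        d = tuple(all_genes[15:18])
        direct = {"P": p_direct, "C1": c1, "C2": c2, "D": d}
        offset = 18 // genes_per + 1
        for i in range(n_null_systems):
            sid = f"NULL:{i:03d}"
            start = (offset + i) * genes_per
            direct[sid] = tuple(all_genes[start:start + genes_per])
        graph = ontology_from_systems(direct, [("C1", "P"), ("C2", "P")])
        planted_genes = {
            "A": [(c1, 0.35)],
            "B": [(p_direct, 0.35)],
            "C": [((d[0],), 0.8)],
        }[planted]
        sp2 = CohortSpec(**{**sp.__dict__, "planted_systems": tuple(planted_genes)})
        cohort = generate_cohort(sp2)
        return Scenario(
            name=name, cohort=cohort, graph=graph, parent_id="P" if planted != "C" else "D",
            signal_child_id="C1" if planted == "A" else None,
            dominant_gene=d[0] if planted == "C" else None,
        )

    return {
        "child_concentrated": make("child_concentrated", "A", 11),
        "spread_outside_child": make("spread_outside_child", "B", 22),
        "dominant_gene": make("dominant_gene", "C", 33),
    }
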