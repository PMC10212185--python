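import numpy as np
import pytest

from hiergwas.ontology import build_hierarchy
from hiergwas.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no planted genotype-phenotype association."""
    return generate_cohort(
        CohortSpec(n_case=200, n_ctrl=200, n_genes=60, genes_per_system=3, seed=101)
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with one multi-gene system carrying signal (SYS:0004)."""
    return generate_cohort(
        CohortSpec(
            n_case=300, n_ctrl=300, n_genes=60, genes_per_system=3, seed=202,
            planted_systems=(("SYS:0004", 0.35, 1.0),),
        )
    )


@pytest.fixture(scope="session")
def planted_scan(planted_cohort):
    from hiergwas.model import SystemAssociationScan

    graph = build_hierarchy(planted_cohort.obo_text, planted_cohort.annotation_text)
    model = SystemAssociationScan(
        planted_cohort.gm, planted_cohort.loci, graph,
        planted_cohort.covariates, planted_cohort.phenotype, seed=7,
    )
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
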