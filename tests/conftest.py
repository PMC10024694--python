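"""Shared fixtures: simulated pair datasets and the null LRT replicate study."""

from __future__ import annotations

import numpy as np
import pytest

import famgreml as fg
from famgreml.pheno import build_covariate_table, residualize


def simulate_pair_dataset(
    n_families: int,
    n_snps: int,
    v_o: float = 0.3,
    v_m: float = 0.15,
    rho_m: float = 0.5,
    seed: int = 0,
    parent: str = "maternal",
):
    """Simulate one mother-child (or father-child) dataset ready for REML.

    Returns (y, grm_set, truth) where y is the covariate-residualized,
    standardized phenotype aligned with the GRM set.
    """
    kwargs = dict(v_o=v_o, seed=seed)
    if parent == "maternal":
        kwargs.update(v_m=v_m, rho_m=rho_m, v_f=0.0, rho_f=0.0)
    else:
        kwargs.update(v_f=v_m, rho_f=rho_m, v_m=0.0, rho_m=0.0)
    config = fg.SimulationConfig(n_families=n_families, n_snps=n_snps,
                                 n_causal=n_snps, **kwargs)
    cohort = fg.simulate_trio_genotypes(config)
    pheno = fg.simulate_phenotypes(cohort, config)
    cov = build_covariate_table(
        cohort.member_iids("child"), sex=cohort.child_sex, batch=cohort.batch,
        fids=cohort.family_ids,
    )
    pheno = residualize(pheno, cov)
    y = pheno.standardized_score
    parent_geno = (cohort.mother_genotypes if parent == "maternal"
                   else cohort.father_genotypes)
    grm_set = fg.build_grm_set(cohort.family_ids, cohort.child_genotypes, parent_geno)
    truth = fg.expected_components(config)
    return y, grm_set, truth


@pytest.fixture(scope="session")
def null_lrt_study():
    """200 replicate fits under the null of no nurture (v_m = v_om = 0).

    Used for the LRT type-I error rate and for the boundary-zero behaviour
    of the nurture variance estimate.  n = 800 pairs, 1000 SNPs per
    replicate.
    """
    pvals = []
    vm_boundary = []
    for rep in range(200):
        y, grm_set, _ = simulate_pair_dataset(
            800, 1000, v_o=0.3, v_m=0.0, rho_m=0.0, seed=40_000 + rep
        )
        res = fg.fit_parent_model(y, grm_set, "maternal")
        pvals.append(res.lrt_p)
        vm_boundary.append(bool(res.boundary[1]))
    return {"pvals": np.array(pvals), "vm_boundary": np.array(vm_boundary)}


def pytest_configure(config):
    try:
        from hypothesis import settings

        settings.register_profile("ci", deadline=None, derandomize=True,
                                  max_examples=50)
        settings.load_profile("ci")
    except ImportError:  # pragma: no cover
        pass
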