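import numpy as np
import pytest

import wgreg


@pytest.fixture(scope="session")
def small_cohort():
    """60-family, 300-marker cohort with h2 = 0.5, shared across read-only tests."""
    cfg = wgreg.SimulationConfig(
        n_families=60, family_size_range=(4, 5), p_markers=300, h2_target=0.5, seed=42
    )
    ped, geno, cov, pheno, truth = wgreg.simulate_cohort(cfg)
    return {
        "config": cfg,
        "pedigree": ped,
        "genotypes": geno,
        "covariates": cov,
        "phenotypes": pheno,
        "truth": truth,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_design(cohort):
    """Intercept + sex + cohort + centered age design aligned to the genotype rows."""
    cov = cohort["covariates"].set_index("individual_id")
    cov = cov.loc[list(cohort["genotypes"].subject_ids)]
    age = cov["age"].to_numpy()
    W = np.column_stack(
        [
            np.ones(len(cov)),
            cov["sex"].to_numpy(dtype=float),
            cov["cohort"].to_numpy(dtype=float),
            age - age.mean(),
        ]
    )
    return W, ["intercept", "sex", "cohort", "age"]
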