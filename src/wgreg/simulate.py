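"""Synthetic family cohorts with a liability-threshold binary trait.

The generator emulates a two-generation family study of a common disease:
nuclear families (two founder parents plus full-sib offspring), SNP dosages
produced by gene dropping (founder alleles drawn at marker-specific
frequencies, offspring inheriting one allele per parent), non-genetic
covariates (sex, cohort/generation, age at last contact), and a binary
outcome generated from a probit liability model

    z_i = a + covariates_i' alpha + g_i + e_i,   e_i ~ N(0, 1),
    y_i = 1(z_i > 0),

where g_i = sum_j (x_ij - 2 q_j) beta_j is an additive genetic value with
Var(g) = sigma_u^2 = h^2 / (1 - h^2) so that the liability-scale heritability
sigma_u^2 / (sigma_u^2 + 1) equals the configured target. The intercept ``a``
is solved by bisection so the expected prevalence matches the target.

Markers are simulated in linkage equilibrium among founders; within-family
LD arises solely from co-inheritance of parental haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .containers import GenotypeMatrix, validate_pedigree

#: Case prevalence of the emulated cohort (939 cases among 5,245 subjects).
DEFAULT_PREVALENCE = 939 / 5245

#: Liability-scale covariate effects of the emulated cohort: sex (female),
#: cohort (offspring generation), and age at last contact per year.
DEFAULT_COVARIATE_EFFECTS = {"sex": -0.26, "cohort": -0.40, "age": 0.016}

DEFAULT_AGE_RANGE = (34.0, 104.0)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    ``prevalence_target`` and ``covariate_effects`` default to the emulated
    cohort's values; ``sigma_u2`` implied by ``h2_target`` is
    ``h2/(1-h2)`` because the liability residual variance is fixed at one.
    """

    n_families: int = 250
    family_size_range: tuple[int, int] = (4, 6)
    p_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_target: float = 0.5
    pi_nonnull: float = 1.0
    prevalence_target: float = DEFAULT_PREVALENCE
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.family_size_range
        if not (1 <= lo <= hi):
            raise ValueError("family_size_range must be a well-ordered pair of sizes >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5] and be well-ordered")
        if not (0.0 <= self.h2_target < 1.0):
            raise ValueError("h2_target must be in [0, 1)")
        if not (0.0 < self.pi_nonnull <= 1.0):
            raise ValueError("pi_nonnull must be in (0, 1]")
        if not (0.0 < self.prevalence_target < 1.0):
            raise ValueError("prevalence_target must be in (0, 1)")
        if self.n_families < 1 or self.p_markers < 1:
            raise ValueError("n_families and p_markers must be positive")

    @property
    def sigma_u2(self) -> float:
        return self.h2_target / (1.0 - self.h2_target)


@dataclass
class TrueArchitecture:
    """Ground truth of a simulated cohort, kept for parameter-recovery tests."""

    beta_true: np.ndarray          # per-marker liability effects (0 where null)
    nonnull_mask: np.ndarray       # boolean per marker
    sigma_u2_true: float           # Var(genetic value) on the liability scale
    alpha_true: dict               # covariate name -> liability effect
    intercept_true: float = 0.0
    genetic_values: np.ndarray | None = None
    liabilities: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta_true": self.beta_true, "nonnull": self.nonnull_mask.astype(int)}
        )


def simulate_pedigree(
    n_families: int,
    family_size_range: tuple[int, int] = (4, 6),
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate two-generation nuclear families.

    Each family of size ``s >= 3`` has two founder parents (generation 0) and
    ``s - 2`` offspring (generation 1); families of size 1 or 2 consist of
    founders only. Family sizes are drawn uniformly from the inclusive range.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    lo, hi = family_size_range
    if lo < 1 or hi < lo:
        raise ValueError("family_size_range must satisfy 1 <= lo <= hi")
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_families):
        fam = f"F{f:04d}"
        size = int(rng.integers(lo, hi + 1))
        n_founders = min(size, 2)
        founder_ids = [f"{fam}_G0_{k}" for k in range(n_founders)]
        for iid in founder_ids:
            rows.append((iid, None, None, fam, 0))
        if size >= 3:
            father, mother = founder_ids
            for k in range(size - 2):
                rows.append((f"{fam}_G1_{k}", father, mother, fam, 1))
    ped = pd.DataFrame(
        rows, columns=["individual_id", "father_id", "mother_id", "family_id", "generation"]
    )
    return validate_pedigree(ped)


def simulate_genotypes(
    pedigree: pd.DataFrame,
    p_markers: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop SNP genotypes down a pedigree.

    Founder haplotypes carry independent Bernoulli(q_j) alleles with
    q_j ~ Uniform(maf_range); each offspring receives one allele per marker
    from each parent, chosen uniformly between the parent's two haplotypes.
    Dosages count the q_j allele, so they lie in {0, 1, 2} with founder mean
    2 q_j.
    """
    validate_pedigree(pedigree)
    if p_markers < 1:
        raise ValueError("p_markers must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    q = rng.uniform(lo, hi, size=p_markers)
    # haplotypes[i, j, k]: allele k of subject i at marker j
    hap = np.zeros((n, p_markers, 2), dtype=np.int8)
    row_of = {iid: i for i, iid in enumerate(pedigree["individual_id"])}
    order = np.argsort(pedigree["generation"].to_numpy(), kind="stable")
    for idx in order:
        row = pedigree.iloc[idx]
        i = row_of[row["individual_id"]]
        if row["father_id"] is None or pd.isna(row["father_id"]):
            hap[i] = rng.random((p_markers, 2)) < q[:, None]
        else:
            for k, par in enumerate((row["father_id"], row["mother_id"])):
                j = row_of[par]
                pick = rng.integers(0, 2, size=p_markers)
                hap[i, :, k] = hap[j, np.arange(p_markers), pick]
    dosages = hap.sum(axis=2).astype(np.float64)
    return GenotypeMatrix(
        dosages=dosages,
        subject_ids=pedigree["individual_id"].to_numpy(),
        marker_ids=np.array([f"snp{j:06d}" for j in range(p_markers)], dtype=object),
        chrom=np.ones(p_markers, dtype=np.int64),
        pos=np.arange(1, p_markers + 1, dtype=np.int64),
        a1=np.full(p_markers, "A", dtype=object),
        a2=np.full(p_markers, "B", dtype=object),
    )


def simulate_covariates(
    pedigree: pd.DataFrame,
    seed: int = 0,
    p_female: float = 0.55,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
) -> pd.DataFrame:
    """Simulate sex, cohort and exposure-age covariates.

    ``sex`` is a female dummy (P(female) defaults to 0.55), ``cohort`` is the
    generation dummy (0 = original/parental cohort, 1 = offspring), and
    ``age`` is age at last contact, uniform over ``age_range``.
    """
    validate_pedigree(pedigree)
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    return pd.DataFrame(
        {
            "individual_id": pedigree["individual_id"].to_numpy(),
            "sex": (rng.random(n) < p_female).astype(int),
            "cohort": pedigree["generation"].to_numpy().astype(int),
            "age": rng.uniform(age_range[0], age_range[1], size=n),
        }
    )


def _solve_intercept(fixed_part: np.ndarray, target: float, tol: float = 1e-6) -> float:
    """Bisection for the intercept a with mean(Phi(a + m_i)) = target."""
    lo, hi = -20.0, 20.0
    f = lambda a: float(np.mean(ndtr(a + fixed_part))) - target
    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:  # pragma: no cover - target in (0,1) makes this unreachable
        raise RuntimeError("intercept bracketing failed")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TrueArchitecture]:
    """Draw a binary outcome from the liability-threshold model.

    A fraction ``pi_nonnull`` of markers receives a Gaussian effect; effects
    are rescaled so the *realized* sample variance of the genetic value
    equals sigma_u^2 = h2/(1-h2) exactly (moment matching against the
    realized genotypes, which gives exact control of the simulated
    heritability). The liability threshold is fixed at 0 and the intercept is
    solved so the expected prevalence matches ``prevalence_target``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    X = genotypes.dosages
    if np.isnan(X).any():
        raise ValueError("phenotype simulation requires complete genotypes")
    n, p = X.shape
    q = X.mean(axis=0) / 2.0
    Xc = X - 2.0 * q

    nonnull = rng.random(p) < cfg.pi_nonnull
    beta = np.zeros(p)
    sigma_u2 = cfg.sigma_u2
    if cfg.h2_target > 0.0 and nonnull.any():
        sum2pq = float(np.sum(2.0 * q[nonnull] * (1.0 - q[nonnull])))
        beta[nonnull] = rng.normal(0.0, np.sqrt(sigma_u2 / max(sum2pq, 1e-12)), nonnull.sum())
        g = Xc @ beta
        sd = g.std()
        if sd > 0:
            scale = np.sqrt(sigma_u2) / sd
            beta *= scale
        g = Xc @ beta
    else:
        nonnull = np.zeros(p, dtype=bool)
        g = np.zeros(n)

    alpha = dict(cfg.covariate_effects)
    cov = covariates.set_index("individual_id").loc[list(genotypes.subject_ids)]
    age_c = cov["age"].to_numpy() - cov["age"].to_numpy().mean()
    fixed = (
        alpha.get("sex", 0.0) * cov["sex"].to_numpy()
        + alpha.get("cohort", 0.0) * cov["cohort"].to_numpy()
        + alpha.get("age", 0.0) * age_c
    )
    m = fixed + g
    intercept = _solve_intercept(m, cfg.prevalence_target)
    z = intercept + m + rng.standard_normal(n)
    y = (z > 0.0).astype(int)

    pheno = pd.DataFrame(
        {
            "individual_id": genotypes.subject_ids,
            "y": y,
            "liability": z,
            "genetic_value": g,
        }
    )
    truth = TrueArchitecture(
        beta_true=beta,
        nonnull_mask=nonnull,
        sigma_u2_true=sigma_u2,
        alpha_true=alpha,
        intercept_true=intercept,
        genetic_values=g,
        liabilities=z,
    )
    return pheno, truth


def simulate_cohort(config: SimulationConfig):
    """Convenience wrapper: pedigree + genotypes + covariates + phenotypes.

    Sub-seeds for the four stages are derived deterministically from
    ``config.seed`` so the whole cohort is reproducible from one integer.
    """
    ss = np.random.SeedSequence(config.seed).spawn(4)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    ped = simulate_pedigree(config.n_families, config.family_size_range, seed=seeds[0])
    geno = simulate_genotypes(ped, config.p_markers, config.maf_range, seed=seeds[1])
    cov = simulate_covariates(ped, seed=seeds[2], age_range=config.age_range)
    cfg = SimulationConfig(**{**config.__dict__, "seed": seeds[3]})
    pheno, truth = simulate_phenotypes(geno, cov, cfg)
    return ped, geno, cov, pheno, truth
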