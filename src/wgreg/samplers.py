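"""Gibbs samplers for probit-link whole-genome regression.

The observation model is a liability-threshold probit: P(y_i = 1) =
Phi(eta_i) with linear predictor

    eta_i = w_i' alpha + u_i,

flat prior on the fixed effects alpha, residual variance fixed at 1 for
identification, and the genomic term u_i modeled under one of several prior
families:

``bayes-a``
    u_i = sum_j x_cij beta_j with per-marker variances
    sigma2_{beta j} ~ scaled-inv-chi2(df, S), marginally a scaled-t prior.
``bayes-c-pi``
    spike-and-slab mixture: mass pi at beta_j = 0, slab N(0, sigma2_beta);
    pi itself carries a Beta prior and is updated each iteration.
``b-lasso``
    double-exponential prior as a scale mixture of normals, beta_j ~
    N(0, tau2_j), tau2_j ~ Exp(lambda2/2), lambda2 ~ Gamma(shape, rate).
``gblup-brr``
    Bayesian ridge: common variance sigma2_beta for all markers, so u has
    covariance proportional to the genomic relationship matrix (the marker
    parameterization of G-BLUP).
``gblup-grm``
    u ~ N(0, G sigma2_u) sampled in the eigenbasis of the GRM.
``fixed-only``
    covariates-only baseline (no genomic term).

Binary outcomes are handled by truncated-normal data augmentation: latent
liabilities z_i ~ N(eta_i, 1) truncated to (0, inf) when y_i = 1 and
(-inf, 0] otherwise, which makes every conditional conjugate. The identity
link (z = y observed, no augmentation) is available for validation runs
against closed-form ridge solutions.

Default inverse-chi-square hyperparameters follow the common treatment-of-
variance rule: df = 5, scale solved so the prior mean of the genomic
variance equals R2/(1 - R2) of the liability variance (R2 = 0.5), divided
by 2*sum q(1-q) for marker-level priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtr

from ._kernels import sweep_gaussian, sweep_mixture
from .containers import GenotypeMatrix
from .grm import GRM, heritability

_PRIOR_FAMILIES = ("fixed-only", "bayes-a", "bayes-c-pi", "b-lasso", "gblup-brr", "gblup-grm")


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Prior family, link and hyperparameters of one regression model."""

    prior_family: str = "gblup-brr"
    link: str = "probit"
    #: target model R2 used to solve default variance-prior scales
    r2_prior: float = 0.5
    df_beta: float = 5.0
    scale_beta: float | None = None     # solved from r2_prior when None
    df_u: float = 5.0
    scale_u: float | None = None
    #: Bayes C-pi Beta prior on the null mass pi: (prior probability, prior counts)
    pi_prior_prob: float = 0.5
    pi_prior_counts: float = 10.0
    pi_fixed: float | None = None       # fix pi (0 -> Bayesian ridge limit)
    #: Bayesian LASSO gamma hyper-prior on lambda2
    lasso_shape: float = 0.55
    lasso_rate: float = 1e-4
    #: validation hooks: freeze variances at these values (skip their updates)
    sigma2_beta_fixed: float | None = None
    sigma2_u_fixed: float | None = None
    #: center marker columns at 2*q_hat inside the sampler
    center: bool = True
    #: divergence guard for fixed effects under quasi-separation
    alpha_bound: float = 25.0
    #: Bayes A stability guard: df below this is raised with a warning
    min_df_bayes_a: float = 4.0

    def __post_init__(self) -> None:
        if self.prior_family not in _PRIOR_FAMILIES:
            raise ValueError(
                f"unknown prior family {self.prior_family!r}; choose from {_PRIOR_FAMILIES}"
            )
        if self.link not in ("probit", "identity"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.df_beta <= 0 or self.df_u <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        if not (0.0 < self.r2_prior < 1.0):
            raise ValueError("r2_prior must be in (0, 1)")
        if self.prior_family == "bayes-a" and self.df_beta < self.min_df_bayes_a:
            warnings.warn(
                f"Bayes A with df_beta={self.df_beta} is prone to poor mixing; "
                f"raising to {self.min_df_bayes_a} (set min_df_bayes_a to override)",
                UserWarning,
                stacklevel=2,
            )
            self.df_beta = self.min_df_bayes_a


@dataclass
class MCMCConfig:
    """Chain length controls (defaults sized for a production run)."""

    n_iter: int = 40_000
    burn_in: int = 15_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class ChainState:
    """All sampler unknowns at one iteration (exposed for unit-level updates)."""

    z: np.ndarray                       # latent liabilities
    alpha: np.ndarray                   # fixed effects
    beta: np.ndarray | None = None      # marker effects
    sigma2_beta_j: np.ndarray | None = None   # per-marker variances (bayes-a)
    delta: np.ndarray | None = None     # inclusion indicators (bayes-c-pi)
    pi: float | None = None             # null-mass probability
    sigma2_beta: float | None = None    # common slab/ridge variance
    tau2: np.ndarray | None = None      # b-lasso per-marker scales
    lambda2: float | None = None        # b-lasso shrinkage
    u: np.ndarray | None = None         # genomic values
    sigma2_u: float | None = None       # genomic variance


@dataclass
class PosteriorSummary:
    """Post-burn-in, thinned posterior summaries of one chain."""

    model: ModelSpec
    mcmc: MCMCConfig
    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    alpha_names: list
    beta_mean: np.ndarray | None
    beta_sd: np.ndarray | None
    eta_mean: np.ndarray
    prob: np.ndarray                    # Phi(eta_mean)
    u_mean: np.ndarray                  # posterior mean genomic values
    samples: dict                       # thinned scalar chains by name
    traces: dict                        # full-length chains for trace plots
    geweke_z: dict                      # stationarity z-score per variance parameter
    h2: object | None = None            # HeritabilityEstimate when a genomic term exists

    def summary_table(self):
        import pandas as pd

        rows = [
            {"parameter": n, "mean": m, "sd": s}
            for n, m, s in zip(self.alpha_names, self.alpha_mean, self.alpha_sd)
        ]
        for name, chain in self.samples.items():
            chain = np.asarray(chain)
            rows.append(
                {
                    "parameter": name,
                    "mean": float(chain.mean()),
                    "sd": float(chain.std(ddof=1)) if chain.size > 1 else 0.0,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# conditional-update building blocks
# ---------------------------------------------------------------------------

def update_latent_liability(eta: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw liabilities z_i ~ N(eta_i, 1) truncated by the observed class.

    y_i = 1 constrains z_i to (0, inf); y_i = 0 to (-inf, 0]. Tail draws at
    |eta| > 6 are delegated to scipy's truncated-normal sampler, which is
    robust far into the tails.
    """
    eta = np.asarray(eta, dtype=np.float64)
    y = np.asarray(y)
    a = np.where(y == 1, -eta, -np.inf)
    b = np.where(y == 1, np.inf, -eta)
    return eta + stats.truncnorm.rvs(a, b, size=eta.shape, random_state=rng)


def sample_fixed_effects(
    W: np.ndarray,
    target: np.ndarray,
    rng: np.random.Generator,
    chol_WtW: np.ndarray | None = None,
    alpha_bound: float | None = None,
) -> np.ndarray:
    """Joint flat-prior draw: alpha ~ N((W'W)^-1 W'target, (W'W)^-1).

    With the residual variance fixed at 1 this is the Bayesian analogue of
    least squares on the current partial residual; posterior means match
    maximum likelihood on the liability scale.
    """
    if chol_WtW is None:
        WtW = W.T @ W
        try:
            chol_WtW = np.linalg.cholesky(WtW)
        except np.linalg.LinAlgError:
            raise ValueError("singular W'W: fixed-effect design is rank deficient") from None
    m = np.linalg.solve(chol_WtW.T, np.linalg.solve(chol_WtW, W.T @ target))
    draw = m + np.linalg.solve(chol_WtW.T, rng.standard_normal(W.shape[1]))
    if alpha_bound is not None and np.abs(draw).max() > alpha_bound:
        warnings.warn(
            f"fixed-effect draw exceeded |alpha| = {alpha_bound}; "
            "possible quasi-separation in the design",
            UserWarning,
            stacklevel=2,
        )
    return draw


def sample_marker_effect(
    x_j: np.ndarray,
    resid: np.ndarray,
    beta_j: float,
    prior_var: float,
    rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Single conjugate marker draw; returns (new beta_j, updated partial residual).

    beta_j ~ N(c_j/C_j, 1/C_j) with C_j = x_j'x_j + 1/prior_var and c_j the
    correlation of x_j with the partial residual (beta_j added back). A zero
    prior variance sets the effect to 0 deterministically.
    """
    xtx = float(x_j @ x_j)
    cj = float(x_j @ resid) + xtx * beta_j
    if prior_var <= 1e-300:
        bnew = 0.0
    else:
        Cj = xtx + 1.0 / prior_var
        bnew = cj / Cj + rng.standard_normal() / np.sqrt(Cj)
    return bnew, resid - x_j * (bnew - beta_j)


def sample_scaled_inv_chi2(
    rng: np.random.Generator, df: float, scale: float, size=None
) -> np.ndarray | float:
    """scaled-inv-chi2(df, scale) = df*scale / chi2(df)."""
    return df * scale / rng.chisquare(df, size=size)


def update_variance_bayes_a(
    beta: np.ndarray, df: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-marker conjugate update: sigma2_j ~ scaled-inv-chi2(df+1, (df*S + beta_j^2)/(df+1))."""
    dfn = df + 1.0
    return (df * scale + beta**2) / rng.chisquare(dfn, size=beta.shape)


def update_pi(
    n_null: int, n_nonnull: int, prior_prob: float, prior_counts: float, rng: np.random.Generator
) -> float:
    """Beta posterior draw of the null mass pi given inclusion counts."""
    a = prior_prob * prior_counts + n_null
    b = (1.0 - prior_prob) * prior_counts + n_nonnull
    return float(rng.beta(a, b))


def update_mixture_bayes_c(
    Xc: np.ndarray,
    xtx: np.ndarray,
    resid: np.ndarray,
    beta: np.ndarray,
    delta: np.ndarray,
    sigma2_beta: float,
    pi: float,
    spec: "ModelSpec",
    scale_beta: float,
    rng: np.random.Generator,
) -> tuple[int, float, float]:
    """One full spike-and-slab cycle: inclusion + effects, then pi, then slab variance.

    Per marker, the inclusion indicator is drawn from the marginal odds of
    spike vs slab (the effect integrated out) and beta_j from its conditional
    (0 when excluded); pi from its Beta posterior given the inclusion counts;
    the slab variance from a scaled-inv-chi2 over the included effects.
    ``beta``, ``delta`` and ``resid`` are updated in place; returns
    (n_included, pi, sigma2_beta).
    """
    p = beta.size
    normals = rng.standard_normal(p)
    uniforms = rng.random(p)
    n_incl = sweep_mixture(
        Xc, xtx, resid, beta, delta, float(sigma2_beta), float(pi), normals, uniforms
    )
    if spec.pi_fixed is None:
        pi = update_pi(p - n_incl, n_incl, spec.pi_prior_prob, spec.pi_prior_counts, rng)
    if spec.sigma2_beta_fixed is None:
        dfn = spec.df_beta + n_incl
        ss = float(np.sum(beta[delta == 1] ** 2)) if n_incl else 0.0
        sigma2_beta = float(
            sample_scaled_inv_chi2(rng, dfn, (spec.df_beta * scale_beta + ss) / dfn)
        )
    return n_incl, pi, sigma2_beta


def update_lasso_scales(
    beta: np.ndarray,
    lambda2: float,
    shape0: float,
    rate0: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Bayesian LASSO scale updates.

    1/tau2_j ~ inverse-Gaussian(sqrt(lambda2/beta_j^2), lambda2); markers with
    beta_j numerically zero draw tau2_j from its Exp(lambda2/2) prior.
    Then lambda2 ~ Gamma(shape0 + p, rate0 + sum tau2 / 2).
    """
    p = beta.size
    tau2 = np.empty(p)
    b2 = beta**2
    tiny = b2 < 1e-300
    if (~tiny).any():
        mu = np.sqrt(lambda2 / b2[~tiny])
        inv_tau2 = rng.wald(mu, lambda2)
        tau2[~tiny] = 1.0 / np.maximum(inv_tau2, 1e-300)
    if tiny.any():
        tau2[tiny] = rng.exponential(2.0 / lambda2, size=int(tiny.sum()))
    lambda2_new = float(rng.gamma(shape0 + p, 1.0 / (rate0 + tau2.sum() / 2.0)))
    return tau2, lambda2_new


def update_sigma_u(
    d: np.ndarray,
    eigvals: np.ndarray,
    df: float,
    scale: float,
    rng: np.random.Generator,
    eig_tol: float = 1e-8,
) -> float:
    """Genomic-variance update in the GRM eigenbasis.

    ``d`` holds the coordinates of u in the eigenbasis; u'G^- u = sum d_k^2 /
    lambda_k over non-null eigenvalues, and sigma2_u ~ scaled-inv-chi2 with
    df + n_eff degrees of freedom.
    """
    keep = eigvals > eig_tol
    n_eff = int(keep.sum())
    ss = float(np.sum(d[keep] ** 2 / eigvals[keep]))
    dfn = df + n_eff
    return float(sample_scaled_inv_chi2(rng, dfn, (ss + df * scale) / dfn))


def geweke_zscore(chain: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke-style stationarity diagnostic: z-score comparing early vs late means.

    Segment variances use a Bartlett-windowed spectral estimate so
    autocorrelation does not understate the standard error. An automated
    stand-in for visual trace inspection; |z| > 2 flags non-stationarity.
    """
    x = np.asarray(chain, dtype=np.float64)
    n = x.size
    if n < 20:
        return float("nan")
    a = x[: max(2, int(first * n))]
    b = x[n - max(2, int(last * n)):]

    def spectral_var(seg: np.ndarray) -> float:
        seg = seg - seg.mean()
        m = seg.size
        max_lag = max(1, int(0.04 * m))
        s = float(seg @ seg) / m
        for lag in range(1, max_lag):
            c = float(seg[:-lag] @ seg[lag:]) / m
            s += 2.0 * (1.0 - lag / max_lag) * c
        return max(s, 1e-300)

    se = np.sqrt(spectral_var(a) / a.size + spectral_var(b) / b.size)
    return float((a.mean() - b.mean()) / se)


def summarize_chain(chain: np.ndarray, mcmc: MCMCConfig) -> np.ndarray:
    """Discard burn-in and thin one full-length chain."""
    chain = np.asarray(chain)
    return chain[mcmc.burn_in:: mcmc.thin]


def posterior_summary(traces: dict, mcmc: MCMCConfig, min_retained: int = 100) -> dict:
    """Burn-in/thin raw chains into mean, SD and a Geweke z per parameter.

    ``traces`` maps parameter name -> full-length chain. Warns when fewer
    than ``min_retained`` samples remain after thinning.
    """
    out = {}
    for name, chain in traces.items():
        kept = summarize_chain(chain, mcmc)
        if kept.size < min_retained:
            warnings.warn(
                f"only {kept.size} retained samples for {name!r}; "
                "summaries will be noisy",
                UserWarning,
                stacklevel=2,
            )
        out[name] = {
            "samples": kept,
            "mean": float(kept.mean()),
            "sd": float(kept.std(ddof=1)) if kept.size > 1 else 0.0,
            "geweke_z": geweke_zscore(kept),
        }
    return out


# ---------------------------------------------------------------------------
# design-matrix plumbing
# ---------------------------------------------------------------------------

def _check_full_rank(W: np.ndarray, names: list) -> None:
    _, R = np.linalg.qr(W)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    if bad.any():
        cols = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"fixed-effect design is rank deficient; collinear columns: {cols}")


def _prepare_markers(genetic_part, center: bool):
    """Return (Xc Fortran-ordered, sum2pq, marker_ids)."""
    if isinstance(genetic_part, GenotypeMatrix):
        X = genetic_part.dosages
        ids = genetic_part.marker_ids
    else:
        X = np.asarray(genetic_part, dtype=np.float64)
        ids = np.array([f"m{j}" for j in range(X.shape[1])], dtype=object)
    if np.isnan(X).any():
        raise ValueError("marker matrix contains missing values; impute first")
    q = X.mean(axis=0) / 2.0
    sum2pq = float(np.sum(2.0 * q * (1.0 - q)))
    Xc = X - 2.0 * q if center else X.copy()
    return np.asfortranarray(Xc), max(sum2pq, 1e-12), ids


# ---------------------------------------------------------------------------
# the Gibbs driver
# ---------------------------------------------------------------------------

def fit_probit_wgr(
    y: np.ndarray,
    fixed_design: np.ndarray,
    genetic_part,
    model_spec: ModelSpec | None = None,
    mcmc_config: MCMCConfig | None = None,
    fixed_names: list | None = None,
) -> PosteriorSummary:
    """Run the Gibbs sampler for one model and return posterior summaries.

    Parameters
    ----------
    y : array of shape (n,)
        Binary outcome (probit link) or continuous response (identity link).
    fixed_design : array of shape (n, q)
        Covariate design, intercept column included; flat prior.
    genetic_part : GenotypeMatrix, ndarray, GRM or None
        Marker matrix for the marker-effect priors, a :class:`~wgreg.grm.GRM`
        for ``gblup-grm``, or ``None`` for the covariates-only model.
    """
    spec = model_spec or ModelSpec()
    mcmc = mcmc_config or MCMCConfig()
    rng = np.random.default_rng(mcmc.seed)

    y = np.asarray(y, dtype=np.float64).ravel()
    W = np.asarray(fixed_design, dtype=np.float64)
    if W.ndim != 2 or W.shape[0] != y.size:
        raise ValueError("fixed_design must be n x q")
    n, qdim = W.shape
    names = list(fixed_names) if fixed_names is not None else [f"alpha{i}" for i in range(qdim)]
    _check_full_rank(W, names)

    if spec.link == "probit":
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all() or classes.size < 2:
            raise ValueError("probit link requires a binary y with both classes present")

    chol_WtW = np.linalg.cholesky(W.T @ W)

    marker_prior = spec.prior_family in ("bayes-a", "bayes-c-pi", "b-lasso", "gblup-brr")
    Xc = None
    eigvecs = eigvals = None
    sum2pq = None
    p = 0
    if marker_prior:
        if genetic_part is None:
            raise ValueError(f"{spec.prior_family} requires a marker matrix")
        Xc, sum2pq, marker_ids = _prepare_markers(genetic_part, spec.center)
        if Xc.shape[0] != n:
            raise ValueError("marker matrix row count does not match y")
        p = Xc.shape[1]
        xtx = np.einsum("ij,ij->j", Xc, Xc)
    elif spec.prior_family == "gblup-grm":
        if not isinstance(genetic_part, GRM):
            raise ValueError("gblup-grm requires a GRM")
        if genetic_part.matrix.shape[0] != n:
            raise ValueError("GRM size does not match y")
        eigvals, eigvecs = np.linalg.eigh(genetic_part.matrix)
        if eigvals.min() < -1e-6 * max(eigvals.max(), 1.0):
            raise ValueError("GRM is not positive semidefinite")
        eigvals = np.clip(eigvals, 0.0, None)
        marker_ids = None
    else:
        marker_ids = None

    # variance-prior scales from the R2 rule (prior mean = target variance)
    v_target = spec.r2_prior / (1.0 - spec.r2_prior)
    scale_u = spec.scale_u if spec.scale_u is not None else v_target * (spec.df_u - 2.0) / spec.df_u
    if spec.scale_beta is not None:
        scale_beta = spec.scale_beta
    elif marker_prior:
        share = 1.0
        if spec.prior_family == "bayes-c-pi":
            share = max(1.0 - spec.pi_prior_prob, 1e-3)  # expected non-null fraction
        scale_beta = (v_target / (sum2pq * share)) * (spec.df_beta - 2.0) / spec.df_beta
    else:
        scale_beta = 1.0

    # --- state initialization ---
    z = y.copy() if spec.link == "identity" else np.where(y == 1.0, 0.8, -0.8)
    alpha = np.zeros(qdim)
    beta = np.zeros(p) if (marker_prior) else None
    u = np.zeros(n)
    sigma2_beta = (
        spec.sigma2_beta_fixed if spec.sigma2_beta_fixed is not None else scale_beta
    )
    sigma2_beta_j = np.full(p, sigma2_beta) if spec.prior_family == "bayes-a" else None
    tau2 = np.full(p, sigma2_beta) if spec.prior_family == "b-lasso" else None
    lambda2 = 2.0 * p / max(v_target, 1e-3) if spec.prior_family == "b-lasso" else None
    pi = spec.pi_fixed if spec.pi_fixed is not None else spec.pi_prior_prob
    delta = np.ones(p, dtype=np.int64) if spec.prior_family == "bayes-c-pi" else None
    sigma2_u = spec.sigma2_u_fixed if spec.sigma2_u_fixed is not None else v_target

    resid = z - W @ alpha - u
    eta = z - resid

    # --- traces ---
    traces: dict[str, list] = {}
    if spec.prior_family != "fixed-only":
        traces["sigma2_u"] = []
        traces["var_g"] = []
    if spec.prior_family == "bayes-c-pi":
        traces["pi"] = []
        traces["nonnull_fraction"] = []
        traces["sigma2_beta"] = []
    if spec.prior_family == "gblup-brr":
        traces["sigma2_beta"] = []
    if spec.prior_family == "b-lasso":
        traces["lambda2"] = []

    retained_iters = set(range(mcmc.burn_in, mcmc.n_iter, mcmc.thin))
    n_ret = 0
    alpha_sum = np.zeros(qdim)
    alpha_sq = np.zeros(qdim)
    beta_sum = np.zeros(p) if beta is not None else None
    beta_sq = np.zeros(p) if beta is not None else None
    eta_sum = np.zeros(n)
    u_sum = np.zeros(n)

    for it in range(mcmc.n_iter):
        # 1. latent liabilities
        if spec.link == "probit":
            eta = z - resid
            z = update_latent_liability(eta, y, rng)
            resid = z - eta

        # 2. fixed effects (flat prior)
        target = resid + W @ alpha
        alpha_new = sample_fixed_effects(
            W, target, rng, chol_WtW=chol_WtW, alpha_bound=spec.alpha_bound
        )
        Wa = W @ alpha_new
        resid = target - Wa
        alpha = alpha_new

        # 3. genomic term
        if marker_prior:
            if spec.prior_family == "bayes-c-pi":
                _, pi, sigma2_beta = update_mixture_bayes_c(
                    Xc, xtx, resid, beta, delta, sigma2_beta, pi, spec, scale_beta, rng
                )
            else:
                normals = rng.standard_normal(p)
                if spec.prior_family == "bayes-a":
                    prior_var = sigma2_beta_j
                elif spec.prior_family == "b-lasso":
                    prior_var = tau2
                else:  # gblup-brr
                    prior_var = np.full(p, sigma2_beta)
                sweep_gaussian(Xc, xtx, resid, beta, prior_var, normals)
                if spec.prior_family == "bayes-a" and spec.sigma2_beta_fixed is None:
                    sigma2_beta_j = update_variance_bayes_a(beta, spec.df_beta, scale_beta, rng)
                elif spec.prior_family == "b-lasso" and spec.sigma2_beta_fixed is None:
                    tau2, lambda2 = update_lasso_scales(
                        beta, lambda2, spec.lasso_shape, spec.lasso_rate, rng
                    )
                elif spec.prior_family == "gblup-brr" and spec.sigma2_beta_fixed is None:
                    dfn = spec.df_beta + p
                    ss = float(beta @ beta)
                    sigma2_beta = float(
                        sample_scaled_inv_chi2(
                            rng, dfn, (spec.df_beta * scale_beta + ss) / dfn
                        )
                    )
            u = z - resid - Wa  # current genomic values (resid identity, O(n))
        elif spec.prior_family == "gblup-grm":
            r_u = resid + u
            t = eigvecs.T @ r_u
            v = sigma2_u * eigvals / (sigma2_u * eigvals + 1.0)
            d = v * t + rng.standard_normal(n) * np.sqrt(v)
            u = eigvecs @ d
            resid = r_u - u
            if spec.sigma2_u_fixed is None:
                sigma2_u = update_sigma_u(d, eigvals, spec.df_u, scale_u, rng)

        # periodic residual refresh against float drift
        if marker_prior and it % 1000 == 999:
            u = Xc @ beta
            resid = z - Wa - u

        # 4. track
        if spec.prior_family != "fixed-only":
            if marker_prior:
                var_g = float(u.var())
                if spec.prior_family in ("gblup-brr",):
                    s_u = float(sigma2_beta * sum2pq)
                    traces["sigma2_beta"].append(float(sigma2_beta))
                elif spec.prior_family == "bayes-c-pi":
                    s_u = var_g
                    traces["pi"].append(float(pi))
                    traces["nonnull_fraction"].append(1.0 - float(pi))
                    traces["sigma2_beta"].append(float(sigma2_beta))
                else:
                    s_u = var_g
                if spec.prior_family == "b-lasso":
                    traces["lambda2"].append(float(lambda2))
                traces["sigma2_u"].append(s_u)
                traces["var_g"].append(var_g)
            else:
                traces["sigma2_u"].append(float(sigma2_u))
                traces["var_g"].append(float(u.var()))

        if it in retained_iters:
            n_ret += 1
            alpha_sum += alpha
            alpha_sq += alpha**2
            if beta is not None:
                beta_sum += beta
                beta_sq += beta**2
            eta_sum += z - resid  # eta = W alpha + u under both links
            u_sum += u

    # --- summaries ---
    if n_ret == 0:
        raise RuntimeError("no retained samples")
    alpha_mean = alpha_sum / n_ret
    alpha_sd = np.sqrt(np.maximum(alpha_sq / n_ret - alpha_mean**2, 0.0))
    beta_mean = beta_sum / n_ret if beta_sum is not None else None
    beta_sd = (
        np.sqrt(np.maximum(beta_sq / n_ret - beta_mean**2, 0.0)) if beta_sum is not None else None
    )
    eta_mean = eta_sum / n_ret
    u_mean = u_sum / n_ret

    thinned = {}
    geweke = {}
    for name, chain in traces.items():
        arr = np.asarray(chain)
        kept = summarize_chain(arr, mcmc)
        thinned[name] = kept
        geweke[name] = geweke_zscore(kept)
    if mcmc.n_retained < 100:
        warnings.warn(
            f"only {mcmc.n_retained} retained samples; posterior summaries will be noisy",
            UserWarning,
            stacklevel=2,
        )

    h2 = heritability(thinned["sigma2_u"]) if "sigma2_u" in thinned else None

    return PosteriorSummary(
        model=spec,
        mcmc=mcmc,
        alpha_mean=alpha_mean,
        alpha_sd=alpha_sd,
        alpha_names=names,
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        eta_mean=eta_mean,
        prob=ndtr(eta_mean),
        u_mean=u_mean,
        samples=thinned,
        traces={k: np.asarray(v) for k, v in traces.items()},
        geweke_z=geweke,
        h2=h2,
    )
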