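"""scikit-learn style estimator for probit whole-genome regression.

:class:`ProbitWGR` wraps the Gibbs machinery in :mod:`wgreg.samplers` behind
the familiar ``fit`` / ``decision_function`` / ``predict_proba`` surface so
models compose with sklearn pipelines and model selection. ``X`` is the
subjects-by-markers dosage matrix (or a :class:`~wgreg.grm.GRM` for the
``gblup-grm`` prior); non-genetic covariates enter through the ``covariates``
fit parameter and receive a flat prior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .containers import GenotypeMatrix
from .grm import GRM
from .samplers import MCMCConfig, ModelSpec, fit_probit_wgr


class ProbitWGR(BaseEstimator):
    """Bayesian probit regression on genome-wide markers.

    Parameters
    ----------
    prior : str
        One of ``fixed-only``, ``bayes-a``, ``bayes-c-pi``, ``b-lasso``,
        ``gblup-brr``, ``gblup-grm``.
    link : str
        ``probit`` (binary y, latent-liability augmentation) or ``identity``
        (continuous y, validation runs).
    n_iter, burn_in, thin : int
        Chain length controls.
    r2_prior : float
        Prior model R2 used to solve default variance-prior scales.
    random_state : int
        Seed; chains are bit-reproducible given the seed.

    Attributes
    ----------
    alpha_ : ndarray
        Posterior-mean fixed effects (intercept first).
    beta_ : ndarray or None
        Posterior-mean marker effects (marker priors only).
    u_ : ndarray
        Posterior-mean genomic values of the training subjects.
    h2_ : HeritabilityEstimate or None
        Liability-scale genomic heritability posterior.
    posterior_ : PosteriorSummary
        Full summaries, thinned scalar chains and traces.
    """

    def __init__(
        self,
        prior: str = "gblup-brr",
        link: str = "probit",
        n_iter: int = 40_000,
        burn_in: int = 15_000,
        thin: int = 5,
        r2_prior: float = 0.5,
        df_beta: float = 5.0,
        scale_beta: float | None = None,
        df_u: float = 5.0,
        scale_u: float | None = None,
        pi_prior_prob: float = 0.5,
        pi_prior_counts: float = 10.0,
        pi_fixed: float | None = None,
        lasso_shape: float = 0.55,
        lasso_rate: float = 1e-4,
        sigma2_beta_fixed: float | None = None,
        sigma2_u_fixed: float | None = None,
        center: bool = True,
        random_state: int = 0,
    ):
        self.prior = prior
        self.link = link
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.r2_prior = r2_prior
        self.df_beta = df_beta
        self.scale_beta = scale_beta
        self.df_u = df_u
        self.scale_u = scale_u
        self.pi_prior_prob = pi_prior_prob
        self.pi_prior_counts = pi_prior_counts
        self.pi_fixed = pi_fixed
        self.lasso_shape = lasso_shape
        self.lasso_rate = lasso_rate
        self.sigma2_beta_fixed = sigma2_beta_fixed
        self.sigma2_u_fixed = sigma2_u_fixed
        self.center = center
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _model_spec(self) -> ModelSpec:
        return ModelSpec(
            prior_family=self.prior,
            link=self.link,
            r2_prior=self.r2_prior,
            df_beta=self.df_beta,
            scale_beta=self.scale_beta,
            df_u=self.df_u,
            scale_u=self.scale_u,
            pi_prior_prob=self.pi_prior_prob,
            pi_prior_counts=self.pi_prior_counts,
            pi_fixed=self.pi_fixed,
            lasso_shape=self.lasso_shape,
            lasso_rate=self.lasso_rate,
            sigma2_beta_fixed=self.sigma2_beta_fixed,
            sigma2_u_fixed=self.sigma2_u_fixed,
            center=self.center,
        )

    def _mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(
            n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin, seed=self.random_state
        )

    @staticmethod
    def _design(n: int, covariates) -> tuple[np.ndarray, list]:
        if covariates is None:
            return np.ones((n, 1)), ["intercept"]
        if isinstance(covariates, pd.DataFrame):
            names = ["intercept"] + [str(c) for c in covariates.columns]
            C = covariates.to_numpy(dtype=np.float64)
        else:
            C = np.asarray(covariates, dtype=np.float64)
            if C.ndim == 1:
                C = C[:, None]
            names = ["intercept"] + [f"cov{i}" for i in range(C.shape[1])]
        return np.column_stack([np.ones(len(C)), C]), names

    # ------------------------------------------------------------------
    def fit(self, X, y, covariates=None):
        """Run the Gibbs chain on markers ``X`` (or a GRM) and outcome ``y``."""
        y = np.asarray(y).ravel()
        genetic = None if self.prior == "fixed-only" else X
        if isinstance(genetic, GenotypeMatrix):
            self._train_q_ = genetic.dosages.mean(axis=0) / 2.0
        elif isinstance(genetic, GRM) or genetic is None:
            self._train_q_ = None
        else:
            genetic = np.asarray(genetic, dtype=np.float64)
            self._train_q_ = genetic.mean(axis=0) / 2.0
        W, names = self._design(y.size, covariates)
        self.posterior_ = fit_probit_wgr(
            y, W, genetic, self._model_spec(), self._mcmc_config(), fixed_names=names
        )
        self.alpha_ = self.posterior_.alpha_mean
        self.alpha_names_ = self.posterior_.alpha_names
        self.beta_ = self.posterior_.beta_mean
        self.u_ = self.posterior_.u_mean
        self.h2_ = self.posterior_.h2
        self.samples_ = self.posterior_.samples
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 0 if genetic is None or isinstance(genetic, GRM) else (
            genetic.n_markers if isinstance(genetic, GenotypeMatrix) else genetic.shape[1]
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "posterior_"):
            raise NotFittedError("call fit before predicting")

    def decision_function(self, X, covariates=None) -> np.ndarray:
        """Posterior-mean linear predictor eta for new subjects.

        Marker dosages are centered at the training allele frequencies. Not
        available under the ``gblup-grm`` prior (genetic values are tied to
        training subjects); refit with ``gblup-brr`` for out-of-sample risk.
        """
        self._check_fitted()
        if self.prior == "gblup-grm":
            raise ValueError(
                "gblup-grm carries subject-level genetic values; use the equivalent "
                "gblup-brr (marker) parameterization for out-of-sample prediction"
            )
        if isinstance(X, GenotypeMatrix):
            X = X.dosages
        n = len(X) if X is not None else len(np.asarray(covariates))
        W, _ = self._design(n, covariates)
        eta = W @ self.alpha_
        if self.prior != "fixed-only":
            X = np.asarray(X, dtype=np.float64)
            Xc = X - 2.0 * self._train_q_ if self.center else X
            eta = eta + Xc @ self.beta_
        return eta

    def predict_proba(self, X, covariates=None) -> np.ndarray:
        """P(y = 1) = Phi(eta) per subject, as an (n, 2) class-probability array."""
        p1 = ndtr(self.decision_function(X, covariates=covariates))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, covariates=None) -> np.ndarray:
        return (self.predict_proba(X, covariates=covariates)[:, 1] >= 0.5).astype(int)
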