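"""Numba kernels for the per-marker Gibbs sweeps.

Each sweep updates all marker effects in fixed column order, one conjugate
draw per marker, maintaining the partial residual in place:

    C_j = x_j'x_j + 1/sigma2_j,  c_j = x_j' r + x_j'x_j beta_j,
    beta_j | . ~ N(c_j / C_j, 1 / C_j).

Randomness is passed in as pre-generated arrays (one standard normal and,
for the mixture sweep, one uniform per marker) so chains are bit-reproducible
under a single NumPy Generator regardless of numba's internal RNG state.
Marker matrices must be Fortran-ordered for contiguous column access.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def sweep_gaussian(X, xtx, resid, beta, prior_var, normals):
    """One Gibbs scan with independent Gaussian priors beta_j ~ N(0, prior_var[j]).

    Serves Bayesian ridge (constant prior_var), Bayes A (per-marker
    variances) and the Bayesian LASSO (prior_var = tau2). A zero prior
    variance forces beta_j = 0 deterministically.
    """
    n, p = X.shape
    for j in range(p):
        bj = beta[j]
        cj = 0.0
        for i in range(n):
            cj += X[i, j] * resid[i]
        cj += xtx[j] * bj
        pv = prior_var[j]
        if pv <= 1e-300:
            bnew = 0.0
        else:
            Cj = xtx[j] + 1.0 / pv
            bnew = cj / Cj + normals[j] / np.sqrt(Cj)
        diff = bnew - bj
        if diff != 0.0:
            for i in range(n):
                resid[i] -= X[i, j] * diff
        beta[j] = bnew


@numba.njit(cache=True)
def sweep_mixture(X, xtx, resid, beta, delta, slab_var, pi, normals, uniforms):
    """One spike-and-slab scan: point mass at zero (prob pi) + N(0, slab_var) slab.

    Inclusion is sampled from the marginal odds with beta_j integrated out,
    then beta_j is drawn from its conditional (or set to 0). Returns the
    number of included markers.
    """
    n, p = X.shape
    n_incl = 0
    for j in range(p):
        bj = beta[j]
        cj = 0.0
        for i in range(n):
            cj += X[i, j] * resid[i]
        cj += xtx[j] * bj
        Cj = xtx[j] + 1.0 / slab_var
        # log Bayes factor of slab vs spike: -(1/2)log(slab_var*Cj) + c^2/(2C)
        log_lr = -0.5 * np.log(slab_var * Cj) + 0.5 * cj * cj / Cj
        if pi <= 0.0:
            p_incl = 1.0
        elif pi >= 1.0:
            p_incl = 0.0
        else:
            log_odds = np.log1p(-pi) - np.log(pi) + log_lr
            if log_odds > 35.0:
                p_incl = 1.0
            elif log_odds < -35.0:
                p_incl = 0.0
            else:
                p_incl = 1.0 / (1.0 + np.exp(-log_odds))
        if uniforms[j] < p_incl:
            bnew = cj / Cj + normals[j] / np.sqrt(Cj)
            delta[j] = 1
            n_incl += 1
        else:
            bnew = 0.0
            delta[j] = 0
        diff = bnew - bj
        if diff != 0.0:
            for i in range(n):
                resid[i] -= X[i, j] * diff
        beta[j] = bnew
    return n_incl
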