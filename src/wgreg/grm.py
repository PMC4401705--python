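"""Genomic relationship matrix and liability-scale genomic heritability.

The GRM estimates additive relatedness from markers as the cross-product of
frequency-centered dosages,

    G = (X - 2q')(X - 2q')' / (2 * sum_j q_j (1 - q_j)),

the standard VanRaden scaling: under linkage equilibrium its diagonal has
expectation 1 for non-inbred subjects and off-diagonals estimate twice the
kinship (0.5 for parent-offspring and full sibs). An ``as-printed`` variant
that additionally divides by n is provided for fidelity with a published
formula carrying that factor; it is not the default because the extra 1/n
would shrink relationships toward zero as the sample grows.

With a binary trait modeled on the liability scale the residual variance is
fixed at 1, so genomic heritability is h2 = sigma_u^2 / (sigma_u^2 + 1),
applied per posterior sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .genodata import allele_frequencies

__all__ = ["GRM", "HeritabilityEstimate", "allele_frequencies", "compute_grm", "heritability"]


@dataclass
class GRM:
    """n x n genomic relationship matrix with its scaling metadata."""

    matrix: np.ndarray
    scaling: str                # "vanraden" or "as-printed"
    sum2pq: float               # the denominator 2 * sum q_j (1 - q_j)
    subject_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.subject_ids, columns=self.subject_ids)

    def write_tsv(self, path: str) -> None:
        df = self.to_frame()
        df.index.name = "individual_id"
        df.to_csv(path, sep="\t")


@dataclass
class HeritabilityEstimate:
    """Posterior samples and mean +/- SD of sigma_u^2 and liability-scale h2."""

    sigma_u2_samples: np.ndarray
    h2_samples: np.ndarray

    @property
    def sigma_u2_mean(self) -> float:
        return float(self.sigma_u2_samples.mean())

    @property
    def sigma_u2_sd(self) -> float:
        return float(self.sigma_u2_samples.std(ddof=1)) if self.sigma_u2_samples.size > 1 else 0.0

    @property
    def h2_mean(self) -> float:
        return float(self.h2_samples.mean())

    @property
    def h2_sd(self) -> float:
        return float(self.h2_samples.std(ddof=1)) if self.h2_samples.size > 1 else 0.0

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"HeritabilityEstimate(sigma_u2={self.sigma_u2_mean:.3f}±{self.sigma_u2_sd:.3f}, "
            f"h2={self.h2_mean:.3f}±{self.h2_sd:.3f})"
        )


def compute_grm(G: GenotypeMatrix, scaling: str = "vanraden") -> GRM:
    """Compute the genomic relationship matrix from complete dosages.

    ``scaling="vanraden"`` (default) divides the centered cross-product by
    2 * sum q_j(1-q_j); ``"as-printed"`` additionally divides by n.
    Allele frequencies are re-estimated from the sample.
    """
    if scaling not in ("vanraden", "as-printed"):
        raise ValueError(f"unknown scaling {scaling!r}")
    X = G.dosages
    if np.isnan(X).any():
        raise ValueError("GRM requires complete (imputed) dosages")
    if X.shape[1] < 1:
        raise ValueError("need at least one marker")
    q = allele_frequencies(G)
    sum2pq = float(2.0 * np.sum(q * (1.0 - q)))
    if sum2pq <= 0.0:
        raise ValueError("all markers monomorphic: GRM denominator is zero")
    Xc = X - 2.0 * q
    M = (Xc @ Xc.T) / sum2pq
    if scaling == "as-printed":
        M = M / X.shape[0]
    M = 0.5 * (M + M.T)  # enforce exact symmetry
    return GRM(matrix=M, scaling=scaling, sum2pq=sum2pq, subject_ids=G.subject_ids.copy())


def heritability(sigma_u2_samples: np.ndarray) -> HeritabilityEstimate:
    """Map posterior sigma_u^2 samples to liability-scale h2 = s/(s+1), per sample.

    Summaries are the posterior mean +/- SD of the per-sample ratios (not the
    ratio of posterior means).
    """
    s = np.asarray(sigma_u2_samples, dtype=np.float64)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("expected a non-empty 1-D array of samples")
    if (s < 0).any():
        raise ValueError("sigma_u^2 samples must be non-negative")
    return HeritabilityEstimate(sigma_u2_samples=s, h2_samples=s / (s + 1.0))
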