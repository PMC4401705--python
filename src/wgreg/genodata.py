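"""Genotype I/O, quality control, down-sampling, imputation and ancestry PCs.

QC follows the common GWAS recipe for family panels: drop markers with minor
allele frequency below 5% (strict) or missingness above 10% (strict), with
allele frequencies estimated from observed calls only. Missing dosages are
then mean-imputed (replaced by ``2 q_hat_j``), which preserves per-marker
allele frequencies. Principal components for ancestry adjustment are computed
on a designated subset of informative markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import GenotypeMatrix
from .plink import read_plink, write_plink  # noqa: F401  (re-exported I/O surface)


@dataclass
class QCReport:
    """Counts of markers removed by each QC rule (a marker failing both rules counts once)."""

    n_markers_in: int
    n_removed_maf: int
    n_removed_missing: int
    n_markers_out: int
    maf_min: float
    max_missing: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PCScores:
    """Per-subject ancestry principal-component scores."""

    scores: np.ndarray                 # n x k
    explained_variance_ratio: np.ndarray
    subject_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PC{i + 1}": self.scores[:, i] for i in range(self.scores.shape[1])}
        return pd.DataFrame({"individual_id": self.subject_ids, **cols})


def read_genotypes(path: str, format: str = "tsv-dosage") -> GenotypeMatrix:
    """Read genotypes from ``plink-bed`` (path = file prefix) or ``tsv-dosage``.

    The TSV layout is one header row of marker ids, then one row per subject:
    subject id followed by dosages (empty/NA = missing). Out-of-range dosages
    and duplicate ids raise ``ValueError`` naming the offender.
    """
    if format == "plink-bed":
        return read_plink(path)
    if format != "tsv-dosage":
        raise ValueError(f"unknown genotype format {format!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosages = df.to_numpy(dtype=np.float64)
    return GenotypeMatrix(
        dosages=dosages,
        subject_ids=df.index.to_numpy(dtype=object),
        marker_ids=df.columns.to_numpy(dtype=object),
    )


def write_genotypes(G: GenotypeMatrix, path: str, format: str = "tsv-dosage") -> None:
    if format == "plink-bed":
        write_plink(G, path)
        return
    if format != "tsv-dosage":
        raise ValueError(f"unknown genotype format {format!r}")
    df = pd.DataFrame(G.dosages, index=G.subject_ids, columns=G.marker_ids)
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def allele_frequencies(G: GenotypeMatrix) -> np.ndarray:
    """Estimated frequency q_hat_j = mean observed dosage / 2 of the counted allele."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q = np.nanmean(G.dosages, axis=0) / 2.0
    if np.isnan(q).any():
        j = int(np.flatnonzero(np.isnan(q))[0])
        raise ValueError(f"marker {G.marker_ids[j]!r} has no observed calls")
    return q


def qc_filter(
    G: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.10
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers with MAF < ``maf_min`` or missing fraction > ``max_missing``.

    Both thresholds are strict inequalities; MAF is computed from observed
    calls. Emits a warning if every marker is removed.
    """
    if G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    X = G.dosages
    miss_frac = np.isnan(X).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(q, 1.0 - q)
    fail_maf = np.isnan(maf) | (maf < maf_min)
    fail_miss = miss_frac > max_missing
    keep = ~(fail_maf | fail_miss)
    report = QCReport(
        n_markers_in=G.n_markers,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_missing=int(fail_miss.sum()),
        n_markers_out=int(keep.sum()),
        maf_min=maf_min,
        max_missing=max_missing,
    )
    if report.n_markers_out == 0:
        warnings.warn("QC removed every marker", UserWarning, stacklevel=2)
    return G.take_markers(np.flatnonzero(keep)), report


def downsample_markers(G: GenotypeMatrix, fraction: float, seed: int = 0) -> GenotypeMatrix:
    """Keep a uniform random round(fraction * p) subset of markers, order preserved."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return G.take_markers(np.arange(G.n_markers))
    rng = np.random.default_rng(seed)
    k = int(round(fraction * G.n_markers))
    chosen = np.sort(rng.choice(G.n_markers, size=k, replace=False))
    return G.take_markers(chosen)


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker mean ``2 q_hat_j`` (frequency-preserving)."""
    X = G.dosages
    if not np.isnan(X).any():
        return G.take_markers(np.arange(G.n_markers))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0)
    if np.isnan(col_mean).any():
        j = int(np.flatnonzero(np.isnan(col_mean))[0])
        raise ValueError(
            f"marker {G.marker_ids[j]!r} is fully missing; run qc_filter before imputation"
        )
    out = G.take_markers(np.arange(G.n_markers))
    idx = np.where(np.isnan(out.dosages))
    out.dosages[idx] = col_mean[idx[1]]
    return out


def compute_pcs(
    G: GenotypeMatrix, marker_subset: np.ndarray | list | None = None, k: int = 2
) -> PCScores:
    """Ancestry PCs from the column-centered dosages of a marker subset.

    Constant (monomorphic) columns are excluded with a warning. The sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    if marker_subset is None:
        idx = np.arange(G.n_markers)
    else:
        id_to_col = {m: j for j, m in enumerate(G.marker_ids)}
        subset = list(marker_subset)
        if subset and isinstance(subset[0], (str, np.str_)):
            missing = [m for m in subset if m not in id_to_col]
            if missing:
                raise ValueError(f"unknown markers in subset: {missing[:5]}")
            idx = np.array([id_to_col[m] for m in subset])
        else:
            idx = np.asarray(subset, dtype=int)
    X = G.dosages[:, idx]
    if np.isnan(X).any():
        raise ValueError("impute missing dosages before computing PCs")
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} constant marker columns from PCA",
            UserWarning,
            stacklevel=2,
        )
    X = X[:, keep]
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(n, markers)={min(X.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))
    for i in range(k):
        load = pca.components_[i]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, i] *= -1.0
    return PCScores(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        subject_ids=G.subject_ids.copy(),
    )
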