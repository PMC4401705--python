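"""Family-blocked cross-validation and ROC/AUC evaluation.

In family studies, random subject-level folds leak information: relatives of
a test subject in the training set carry much of its genetic signal. Folds
are therefore blocks of entire families — every member of a family shares
one fold, so a subject is never predicted by a model trained on any of its
relatives.

AUC is the Mann-Whitney pair statistic: the probability that a randomly
chosen case scores above a randomly chosen control, ties counted 1/2.
Per-fold AUCs are summarized as mean +/- SD across folds (pooled-score AUC
is also reported).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .containers import GenotypeMatrix, validate_pedigree
from .samplers import MCMCConfig, ModelSpec, fit_probit_wgr


@dataclass
class FoldAssignment:
    """Family-to-fold map with the derived subject-to-fold table."""

    k: int
    family_to_fold: dict
    subject_to_fold: pd.Series  # index: individual_id

    def fold_of(self, subject_ids) -> np.ndarray:
        return self.subject_to_fold.loc[list(subject_ids)].to_numpy()


@dataclass
class CohortData:
    """Everything cross-validation needs about one cohort."""

    y: np.ndarray
    fixed_design: np.ndarray
    subject_ids: np.ndarray
    genotypes: GenotypeMatrix | None = None
    fixed_names: list | None = None


@dataclass
class RiskScores:
    """Out-of-fold risk scores, one prediction per subject."""

    scores: pd.DataFrame            # individual_id, fold, eta_hat, model
    model_label: str
    skipped_folds: list = field(default_factory=list)


def assign_family_folds(pedigree: pd.DataFrame, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Randomize families and assign each to the currently smallest fold.

    Families are shuffled with the seed, then placed greedily by subject
    count (ties broken by fold index), which balances fold sizes up to the
    largest family size while never splitting a family.
    """
    validate_pedigree(pedigree)
    fam_sizes = pedigree.groupby("family_id", sort=True)["individual_id"].count()
    if k < 1 or k > len(fam_sizes):
        raise ValueError(f"k={k} must be between 1 and the number of families ({len(fam_sizes)})")
    rng = np.random.default_rng(seed)
    families = fam_sizes.index.to_numpy()
    order = rng.permutation(len(families))
    counts = np.zeros(k, dtype=int)
    family_to_fold = {}
    for idx in order:
        fam = families[idx]
        fold = int(np.argmin(counts))  # argmin takes the lowest index on ties
        family_to_fold[fam] = fold
        counts[fold] += fam_sizes[fam]
    subject_to_fold = pedigree.set_index("individual_id")["family_id"].map(family_to_fold)
    return FoldAssignment(k=k, family_to_fold=family_to_fold, subject_to_fold=subject_to_fold)


def auc(y, scores) -> float:
    """Mann-Whitney AUC: fraction of (case, control) pairs with the case scored higher.

    Ties contribute 1/2. Computed via midranks, which is algebraically the
    pair statistic without the O(n^2) enumeration.
    """
    y = np.asarray(y)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape:
        raise ValueError("y and scores must have the same length")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve(y, scores) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (FPR, TPR), one per distinct threshold, from (0,0) to (1,1)."""
    y = np.asarray(y)
    s = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return fpr, tpr


def fold_auc_summary(risk: RiskScores) -> dict:
    """Per-fold AUC mean +/- SD plus the pooled-score AUC."""
    df = risk.scores
    per_fold = []
    for fold, sub in df.groupby("fold"):
        yy = sub["y"].to_numpy()
        if len(np.unique(yy)) < 2:
            continue
        per_fold.append(auc(yy, sub["eta_hat"].to_numpy()))
    pooled = auc(df["y"].to_numpy(), df["eta_hat"].to_numpy())
    per_fold = np.asarray(per_fold)
    return {
        "model": risk.model_label,
        "auc_mean": float(per_fold.mean()) if per_fold.size else float("nan"),
        "auc_sd": float(per_fold.std(ddof=1)) if per_fold.size > 1 else 0.0,
        "auc_pooled": pooled,
        "n_folds": int(per_fold.size),
    }


def cross_validate(
    data: CohortData,
    model_spec: ModelSpec,
    mcmc_config: MCMCConfig,
    folds: FoldAssignment,
    label: str | None = None,
) -> RiskScores:
    """Out-of-fold risk scores under family blocking.

    For each fold the model is fitted on all other folds and the held-out
    linear predictor is assembled from posterior means: fixed part from
    alpha, genetic part from marker-effect posterior means applied to the
    held-out dosages centered at the *training* allele frequencies. GRM-prior
    models are refitted in the equivalent marker (Bayesian ridge)
    parameterization so held-out subjects need no retraining. Per-fold seeds
    derive deterministically from the master seed. Folds whose training data
    contain a single outcome class are skipped with a warning.
    """
    spec = model_spec
    if spec.prior_family == "gblup-grm":
        spec = ModelSpec(**{**spec.__dict__, "prior_family": "gblup-brr"})
    y = np.asarray(data.y)
    W = np.asarray(data.fixed_design, dtype=np.float64)
    fold_of = folds.fold_of(data.subject_ids)
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(mcmc_config.seed).spawn(folds.k)
    ]
    rows = []
    skipped = []
    for fold in range(folds.k):
        test = fold_of == fold
        train = ~test
        if test.sum() == 0:
            continue
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            warnings.warn(f"fold {fold}: single-class training outcome; skipped", UserWarning)
            skipped.append(fold)
            continue
        mc = MCMCConfig(
            n_iter=mcmc_config.n_iter,
            burn_in=mcmc_config.burn_in,
            thin=mcmc_config.thin,
            seed=seeds[fold],
        )
        if spec.prior_family == "fixed-only" or data.genotypes is None:
            fit = fit_probit_wgr(y_tr, W[train], None, spec, mc, fixed_names=data.fixed_names)
            eta_test = W[test] @ fit.alpha_mean
        else:
            X = data.genotypes.dosages
            X_tr = X[train]
            q_tr = X_tr.mean(axis=0) / 2.0
            fit = fit_probit_wgr(
                y_tr, W[train], X_tr, spec, mc, fixed_names=data.fixed_names
            )
            eta_test = W[test] @ fit.alpha_mean + (X[test] - 2.0 * q_tr) @ fit.beta_mean
        for sid, e, yy in zip(data.subject_ids[test], eta_test, y[test]):
            rows.append((sid, fold, float(e), int(yy)))
    scores = pd.DataFrame(rows, columns=["individual_id", "fold", "eta_hat", "y"])
    lbl = label or spec.prior_family
    scores["model"] = lbl
    if scores["individual_id"].duplicated().any():
        raise RuntimeError("internal error: a subject was predicted more than once")
    return RiskScores(scores=scores, model_label=lbl, skipped_folds=skipped)
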