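"""Reporting helpers: odds ratios, genetic score tables, ranked effect exports.

Liability-scale (probit) coefficients are converted to odds ratios with
``exp(beta)``. For a probit model this is an approximation — the exact odds
ratio depends on the covariate values — but it is the conversion consistent
with how such coefficients are conventionally reported.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix


def effect_to_odds_ratio(coefficient: float) -> float:
    """exp(coefficient); an approximation for liability-scale effects."""
    c = float(coefficient)
    if not np.isfinite(c):
        raise ValueError("coefficient must be finite")
    return float(np.exp(c))


def genetic_score_table(
    marker_effects: pd.Series | np.ndarray,
    genotypes: GenotypeMatrix,
    marker_ids=None,
) -> tuple[pd.DataFrame, dict]:
    """Per-subject genetic risk scores sum_j x_cij beta_j on centered dosages.

    ``marker_effects`` may be a Series indexed by marker id (aligned against
    the genotype matrix; mismatches raise listing unmatched ids) or a plain
    array in genotype column order. Returns the score table and a summary
    block (min, max, mean +/- SD).
    """
    if isinstance(marker_effects, pd.Series):
        ids = marker_effects.index.to_numpy()
        missing = set(map(str, ids)) - set(map(str, genotypes.marker_ids))
        if missing:
            raise ValueError(f"effects for markers absent from genotypes: {sorted(missing)[:10]}")
        order = {str(m): j for j, m in enumerate(genotypes.marker_ids)}
        cols = np.array([order[str(m)] for m in ids])
        X = genotypes.dosages[:, cols]
        beta = marker_effects.to_numpy(dtype=np.float64)
    else:
        beta = np.asarray(marker_effects, dtype=np.float64)
        if beta.size != genotypes.n_markers:
            raise ValueError(
                f"{beta.size} effects for {genotypes.n_markers} markers; "
                "pass a Series indexed by marker id to align subsets"
            )
        X = genotypes.dosages
    if np.isnan(X).any():
        raise ValueError("impute missing dosages before scoring")
    q = X.mean(axis=0) / 2.0
    scores = (X - 2.0 * q) @ beta
    table = pd.DataFrame({"individual_id": genotypes.subject_ids, "score": scores})
    summary = {
        "min": float(scores.min()),
        "max": float(scores.max()),
        "mean": float(scores.mean()),
        "sd": float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
    }
    return table, summary


def effect_rank_export(
    marker_ids,
    effects,
    highlight_ids=(),
) -> pd.DataFrame:
    """Markers sorted by posterior-mean effect with a highlight flag column.

    ``highlight_ids`` marks a known-marker panel (e.g. consortium SNPs) in
    the ranked table; unknown ids raise a warning listing them.
    """
    marker_ids = np.asarray(marker_ids, dtype=object)
    effects = np.asarray(effects, dtype=np.float64)
    highlight = set(map(str, highlight_ids))
    unknown = highlight - set(map(str, marker_ids))
    if unknown:
        warnings.warn(f"highlight ids not in effect table: {sorted(unknown)}", UserWarning)
    df = pd.DataFrame(
        {
            "marker_id": marker_ids,
            "effect": effects,
            "highlight": [str(m) in highlight for m in marker_ids],
        }
    )
    return df.sort_values("effect", kind="mergesort", ignore_index=True)


def fixed_effect_report(alpha_names, alpha_mean, alpha_sd) -> pd.DataFrame:
    """Fixed-effect table with approximate odds ratios (exp of the coefficient)."""
    rows = []
    for name, m, s in zip(alpha_names, alpha_mean, alpha_sd):
        rows.append(
            {
                "parameter": name,
                "estimate": float(m),
                "sd": float(s),
                "odds_ratio": effect_to_odds_ratio(m),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["note"] = (
        "odds_ratio = exp(estimate); approximate for liability-scale (probit) effects"
    )
    return df
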