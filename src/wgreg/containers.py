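"""Core in-memory containers shared across the package.

Genotypes are held as an ``n_subjects x n_markers`` float matrix of allele
dosages in ``[0, 2]``, with ``NaN`` marking missing calls. Pedigrees,
covariates and phenotypes are plain :class:`pandas.DataFrame` objects with
documented column contracts (see :func:`validate_pedigree`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Required columns of a pedigree table.
PEDIGREE_COLUMNS = ("individual_id", "father_id", "mother_id", "family_id", "generation")


@dataclass
class GenotypeMatrix:
    """Subjects-by-markers dosage matrix with marker metadata.

    Parameters
    ----------
    dosages : ndarray of shape (n_subjects, n_markers)
        Allele dosages in ``[0, 2]``; ``NaN`` encodes a missing call.
    subject_ids, marker_ids : ndarray of str
        Unique identifiers for rows and columns.
    chrom, pos : ndarray, optional
        1-based marker coordinates (as in PLINK ``.bim``); purely metadata,
        the pipeline never does coordinate arithmetic.
    a1, a2 : ndarray of str, optional
        Counted allele and the other allele (dosage = count of ``a1``).
    """

    dosages: np.ndarray
    subject_ids: np.ndarray
    marker_ids: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    a1: np.ndarray | None = None
    a2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D subjects x markers array")
        n, p = self.dosages.shape
        if len(self.subject_ids) != n:
            raise ValueError(f"{len(self.subject_ids)} subject ids for {n} rows")
        if len(self.marker_ids) != p:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {p} columns")
        self._check_unique(self.marker_ids, "marker id")
        self._check_unique(self.subject_ids, "subject id")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0.0 or obs.max() > 2.0):
            bad = obs[(obs < 0.0) | (obs > 2.0)][0]
            raise ValueError(f"dosage {bad} outside [0, 2]")

    @staticmethod
    def _check_unique(ids: np.ndarray, what: str) -> None:
        vals, counts = np.unique(ids.astype(str), return_counts=True)
        if (counts > 1).any():
            dup = vals[counts > 1][0]
            raise ValueError(f"duplicate {what}: {dup!r}")

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the marker columns in ``index`` (order kept)."""
        index = np.asarray(index)
        return replace(
            self,
            dosages=self.dosages[:, index].copy(),
            marker_ids=self.marker_ids[index].copy(),
            chrom=None if self.chrom is None else np.asarray(self.chrom)[index].copy(),
            pos=None if self.pos is None else np.asarray(self.pos)[index].copy(),
            a1=None if self.a1 is None else np.asarray(self.a1)[index].copy(),
            a2=None if self.a2 is None else np.asarray(self.a2)[index].copy(),
        )

    def take_subjects(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            dosages=self.dosages[index, :].copy(),
            subject_ids=self.subject_ids[index].copy(),
        )


def validate_pedigree(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Check the pedigree column contract and structural invariants.

    Required columns: ``individual_id``, ``father_id``, ``mother_id``,
    ``family_id``, ``generation``. Missing parents are encoded as ``None``/NaN.
    Raises ``ValueError`` on duplicate ids, parents outside the table or in a
    different family, or a cyclic ancestry.
    """
    missing = [c for c in PEDIGREE_COLUMNS if c not in pedigree.columns]
    if missing:
        raise ValueError(f"pedigree missing columns: {missing}")
    if pedigree.empty:
        raise ValueError("pedigree is empty")
    ids = pedigree["individual_id"]
    if ids.duplicated().any():
        raise ValueError(f"duplicate individual_id: {ids[ids.duplicated()].iloc[0]!r}")
    fam_of = dict(zip(pedigree["individual_id"], pedigree["family_id"]))
    parents: dict[object, tuple] = {}
    for row in pedigree.itertuples(index=False):
        pp = []
        for par in (row.father_id, row.mother_id):
            if par is None or (isinstance(par, float) and np.isnan(par)):
                continue
            if par not in fam_of:
                raise ValueError(f"parent {par!r} of {row.individual_id!r} not in pedigree")
            if fam_of[par] != row.family_id:
                raise ValueError(
                    f"parent {par!r} of {row.individual_id!r} is in a different family"
                )
            pp.append(par)
        parents[row.individual_id] = tuple(pp)
    # ancestry acyclicity by iterative DFS
    state: dict[object, int] = {}
    for start in parents:
        stack = [(start, iter(parents[start]))]
        if state.get(start) == 2:
            continue
        state[start] = 1
        while stack:
            node, it = stack[-1]
            nxt = next(it, None)
            if nxt is None:
                state[node] = 2
                stack.pop()
                continue
            s = state.get(nxt)
            if s == 1:
                raise ValueError(f"individual {nxt!r} is its own ancestor")
            if s is None:
                state[nxt] = 1
                stack.append((nxt, iter(parents[nxt])))
    return pedigree


def founders_mask(pedigree: pd.DataFrame) -> np.ndarray:
    """Boolean mask of individuals with no recorded parents."""
    return (pedigree["father_id"].isna() & pedigree["mother_id"].isna()).to_numpy()
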