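"""Minimal PLINK 1 binary (.bed/.bim/.fam) reader and writer.

Implements the SNP-major v1.00 layout: three magic bytes ``6c 1b 01``
followed by one bit-packed block of ceil(n/4) bytes per marker, two bits per
subject. Dosage counts the A1 allele: ``00`` -> 2, ``10`` -> 1, ``11`` -> 0,
``01`` -> missing. Only hard calls are representable; fractional dosages must
go through the TSV dosage format instead.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> dosage of A1 (NaN = missing)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def write_plink(G: GenotypeMatrix, prefix: str) -> None:
    """Write ``prefix``.bed/.bim/.fam. Dosages must be hard calls {0, 1, 2} or missing."""
    X = G.dosages
    obs = ~np.isnan(X)
    if not np.isin(X[obs], (0.0, 1.0, 2.0)).all():
        raise ValueError("PLINK .bed stores hard calls only; found fractional dosage")
    n, p = X.shape
    codes = np.full((p, n), 1, dtype=np.uint8)  # missing
    Xt = X.T
    codes[Xt == 2.0] = 0
    codes[Xt == 1.0] = 2
    codes[Xt == 0.0] = 3
    n_bytes = (n + 3) // 4
    padded = np.zeros((p, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        fh.write(packed.tobytes())

    chrom = G.chrom if G.chrom is not None else np.ones(p, dtype=int)
    pos = G.pos if G.pos is not None else np.arange(1, p + 1)
    a1 = G.a1 if G.a1 is not None else np.full(p, "A", dtype=object)
    a2 = G.a2 if G.a2 is not None else np.full(p, "B", dtype=object)
    bim = pd.DataFrame(
        {"chrom": chrom, "snp": G.marker_ids, "cm": 0, "pos": pos, "a1": a1, "a2": a2}
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": G.subject_ids,
            "iid": G.subject_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read ``prefix``.bed/.bim/.fam into a :class:`GenotypeMatrix`."""
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(prefix + ext)
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str, "a1": str, "a2": str},
    )
    if bim["snp"].duplicated().any():
        dup = bim["snp"][bim["snp"].duplicated()].iloc[0]
        raise ValueError(f"duplicate marker id in .bim: {dup!r}")
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, p = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError(
                f"{prefix}.bed: bad magic bytes {magic.hex()} (expected {_MAGIC.hex()}, "
                "SNP-major v1.00)"
            )
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    if raw.size != p * n_bytes:
        raise ValueError(
            f"{prefix}.bed: {raw.size} data bytes, expected {p * n_bytes} "
            f"for {n} subjects x {p} markers"
        )
    raw = raw.reshape(p, n_bytes)
    codes = np.empty((p, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = raw & 0x03
    codes[:, 1::4] = (raw >> 2) & 0x03
    codes[:, 2::4] = (raw >> 4) & 0x03
    codes[:, 3::4] = (raw >> 6) & 0x03
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    return GenotypeMatrix(
        dosages=dosages,
        subject_ids=fam["iid"].to_numpy(dtype=object),
        marker_ids=bim["snp"].to_numpy(dtype=object),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(),
        a1=bim["a1"].to_numpy(dtype=object),
        a2=bim["a2"].to_numpy(dtype=object),
    )
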