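"""Minimal PLINK 1 bed/bim/fam and GCTA-dialect text file IO.

bed files are SNP-major: magic bytes 0x6c 0x1b 0x01, then ceil(n/4) bytes
per SNP, two bits per individual (00 = hom A1, 01 = missing, 10 = het,
11 = hom A2); genotype values are counts of the A1 allele.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "write_plink",
    "read_plink",
    "write_phenotype_file",
    "read_phenotype_file",
    "write_covariate_files",
]

_MAGIC = bytes([0x6C, 0x1B, 0x01])
# genotype value (A1 count) -> 2-bit code; missing handled separately
_ENCODE = np.array([0b11, 0b10, 0b00], dtype=np.uint8)
_DECODE = {0b00: 2.0, 0b10: 1.0, 0b11: 0.0, 0b01: np.nan}


def write_plink(prefix: str, genotypes: np.ndarray, fam: pd.DataFrame, bim: pd.DataFrame) -> None:
    """Write ``prefix``.bed/.bim/.fam.

    ``genotypes``: (n, m) A1-dosages in {0, 1, 2, NaN}.
    ``fam``: columns fid, iid, pid, mid, sex, pheno.
    ``bim``: columns chrom, snp, cm (optional), pos, a1, a2.
    """
    X = np.asarray(genotypes, dtype=float)
    n, m = X.shape
    if len(fam) != n or len(bim) != m:
        raise ValueError("fam/bim lengths must match the genotype matrix")

    codes = np.full((m, n), 0b01, dtype=np.uint8)  # default missing
    ok = ~np.isnan(X)
    codes.T[ok] = _ENCODE[X[ok].astype(int)]
    pad = (-n) % 4
    if pad:
        codes = np.hstack([codes, np.zeros((m, pad), dtype=np.uint8)])
    quads = codes.reshape(m, -1, 4)
    packed = (quads[:, :, 0] | (quads[:, :, 1] << 2)
              | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC)
        packed.tofile(fh)

    fam_out = fam.copy()
    for col, default in (("pid", "0"), ("mid", "0"), ("sex", 0), ("pheno", -9)):
        if col not in fam_out.columns:
            fam_out[col] = default
    fam_out[["fid", "iid", "pid", "mid", "sex", "pheno"]].to_csv(
        prefix + ".fam", sep=" ", header=False, index=False
    )
    bim_out = bim.copy()
    if "cm" not in bim_out.columns:
        bim_out["cm"] = 0
    bim_out[["chrom", "snp", "cm", "pos", "a1", "a2"]].to_csv(
        prefix + ".bim", sep="\t", header=False, index=False
    )


def read_plink(prefix: str) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read ``prefix``.bed/.bim/.fam; returns (genotypes, fam, bim) with
    genotypes as float A1-dosages (NaN = missing)."""
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pid", "mid", "sex", "pheno"], dtype=str)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype=str)
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
        raw = np.fromfile(fh, dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if len(raw) != m * bytes_per_snp:
        raise ValueError(f"{prefix}.bed size inconsistent with fam/bim dimensions")
    raw = raw.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (raw >> (2 * shift)) & 0b11
    codes = codes[:, :n]
    lut = np.array([_DECODE[c] for c in range(4)])
    return lut[codes].T, fam, bim


def write_phenotype_file(path: str, fids, iids, values) -> None:
    """FID IID value, whitespace delimited, no header (GCTA --pheno)."""
    pd.DataFrame({"fid": fids, "iid": iids, "value": values}).to_csv(
        path, sep=" ", header=False, index=False
    )


def read_phenotype_file(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None, names=["fid", "iid", "value"],
                       dtype={"fid": str, "iid": str})


def write_covariate_files(prefix: str, cov: pd.DataFrame) -> None:
    """Write GCTA-style discrete (``.covar``: sex, batch) and quantitative
    (``.qcovar``: pc_*) covariate files from an assembled covariate table."""
    discrete = [c for c in ("sex", "batch") if c in cov.columns]
    if discrete:
        cov[["fid", "iid", *discrete]].to_csv(
            prefix + ".covar", sep=" ", header=False, index=False
        )
    quant = [c for c in cov.columns if str(c).startswith("pc_")]
    if quant:
        cov[["fid", "iid", *quant]].to_csv(
            prefix + ".qcovar", sep=" ", header=False, index=False
        )
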