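"""Post-imputation SNP quality control.

Filters follow the standard post-imputation panel selection for GREML:
Hardy-Weinberg equilibrium exact-test p >= 1e-6, per-SNP call rate >= 0.90,
minor allele frequency strictly > 0.05, mean imputation INFO strictly > 0.9,
biallelic, non-duplicated.  The HWE test is the exact (conditional
hypergeometric) test: given the observed allele counts, the p-value sums the
probabilities of every heterozygote count no more probable than the one
observed.  HWE is tested in founders (parents) by default, since children
of the same panel are not independent draws from the population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "QCThresholds",
    "hwe_exact_test",
    "compute_snp_stats",
    "filter_snps",
]

# attribution order for the QC report (first failing criterion wins)
CRITERIA = ("hwe", "call_rate", "maf", "info", "multiallelic", "duplicated")


@dataclass(frozen=True)
class QCThresholds:
    hwe_p: float = 1e-6          # keep if p >= hwe_p
    min_call_rate: float = 0.90  # keep if call_rate >= min_call_rate
    min_maf: float = 0.05        # keep if maf > min_maf (strict)
    min_info: float = 0.9        # keep if mean INFO > min_info (strict)

    def __post_init__(self) -> None:
        if not (0 < self.hwe_p <= 1):
            raise ValueError("hwe_p must be in (0, 1]")
        if not (0 <= self.min_call_rate <= 1):
            raise ValueError("min_call_rate must be in [0, 1]")
        if not (0 <= self.min_maf < 0.5):
            raise ValueError("min_maf must be in [0, 0.5)")
        if not (0 <= self.min_info <= 1.5):
            raise ValueError("min_info out of range")


def _hwe_het_logprobs(n: int, n_minor: int) -> tuple[np.ndarray, np.ndarray]:
    """Heterozygote counts attainable given ``n`` diploids carrying
    ``n_minor`` minor alleles, with their log HWE probabilities.

    P(n_het = h) is proportional to 2^h * n! / (n_hom_minor! h! n_hom_major!)
    with n_hom_minor = (n_minor - h) / 2; h shares the parity of n_minor.
    """
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logw = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_minor + 1)
        - gammaln(hets + 1)
        - gammaln(hom_major + 1)
    )
    return hets, logw - logsumexp(logw)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg equilibrium test.

    Sums the probabilities of all heterozygote counts (same parity, allele
    counts fixed) whose conditional probability does not exceed that of the
    observed count.

    Returns the p-value in (0, 1].  Raises ``ValueError`` on negative or
    all-zero counts.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError("genotype counts must be nonnegative integers")
    n = int(n_AA + n_Aa + n_aa)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_minor == 0:
        return 1.0  # monomorphic: single attainable configuration
    hets, logp = _hwe_het_logprobs(n, int(n_minor))
    obs = int(n_Aa)
    logp_obs = logp[np.searchsorted(hets, obs)]
    # include everything at most as probable as observed, with a tiny
    # tolerance so ties are not lost to rounding
    mask = logp <= logp_obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def compute_snp_stats(
    genotypes: np.ndarray,
    metadata: pd.DataFrame,
    hwe_genotypes: np.ndarray | None = None,
    info: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP statistics feeding :func:`filter_snps`.

    Parameters
    ----------
    genotypes : (n, m) dosage matrix, NaN for missing; used for call rate
        and allele frequency.
    metadata : per-SNP table with at least ``snp``; ``chrom``/``pos``/
        ``a1``/``a2`` enable duplicate detection, a boolean
        ``is_multiallelic`` column is honoured if present, and an ``info``
        column is used when ``info`` is not given.
    hwe_genotypes : genotypes of the sample in which HWE is tested
        (founders); defaults to ``genotypes``.
    """
    X = np.asarray(genotypes, dtype=float)
    m = X.shape[1]
    if len(metadata) != m:
        raise ValueError("metadata length must match genotype columns")
    obs = ~np.isnan(X)
    call_rate = obs.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(X, axis=0) / (2 * obs.sum(axis=0))
    maf = np.minimum(p, 1 - p)

    H = np.asarray(hwe_genotypes, dtype=float) if hwe_genotypes is not None else X
    n_AA = np.nansum(H == 2, axis=0).astype(int)
    n_Aa = np.nansum(H == 1, axis=0).astype(int)
    n_aa = np.nansum(H == 0, axis=0).astype(int)

    stats = pd.DataFrame(
        {
            "snp": metadata["snp"].to_numpy(),
            "n_AA": n_AA,
            "n_Aa": n_Aa,
            "n_aa": n_aa,
            "call_rate": call_rate,
            "maf": maf,
        }
    )
    if info is not None:
        stats["info"] = np.asarray(info, dtype=float)
    elif "info" in metadata.columns:
        stats["info"] = metadata["info"].to_numpy(dtype=float)
    else:
        stats["info"] = 1.0
    if "is_multiallelic" in metadata.columns:
        stats["is_multiallelic"] = metadata["is_multiallelic"].to_numpy(dtype=bool)
    else:
        stats["is_multiallelic"] = False
    if {"chrom", "pos", "a1", "a2"} <= set(metadata.columns):
        alleles = [
            "|".join(sorted((str(a), str(b))))
            for a, b in zip(metadata["a1"], metadata["a2"])
        ]
        key = pd.Series(
            metadata["chrom"].astype(str) + ":" + metadata["pos"].astype(str) + ":" + alleles
        )
        stats["is_duplicated"] = key.duplicated(keep="first").to_numpy()
    else:
        stats["is_duplicated"] = False
    return stats


def filter_snps(
    stats: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the SNP selection filters.

    A SNP is kept iff HWE p >= ``hwe_p`` AND call rate >= ``min_call_rate``
    AND MAF > ``min_maf`` (strict) AND mean INFO > ``min_info`` (strict)
    AND biallelic AND not duplicated.

    Returns
    -------
    keep : boolean mask over SNPs.
    report : DataFrame with one row per criterion (in attribution order)
        giving the number of SNPs removed, each SNP attributed to the first
        criterion it fails, plus a final ``kept`` row.
    """
    required = {"call_rate", "maf", "info", "is_multiallelic", "is_duplicated"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    if "hwe_p" in stats.columns:
        hwe_p = stats["hwe_p"].to_numpy(dtype=float)
    else:
        hwe_p = np.array(
            [
                hwe_exact_test(int(r.n_AA), int(r.n_Aa), int(r.n_aa))
                for r in stats.itertuples()
            ]
        )

    fails = {
        "hwe": hwe_p < thresholds.hwe_p,
        "call_rate": stats["call_rate"].to_numpy() < thresholds.min_call_rate,
        "maf": stats["maf"].to_numpy() <= thresholds.min_maf,
        "info": stats["info"].to_numpy() <= thresholds.min_info,
        "multiallelic": stats["is_multiallelic"].to_numpy(dtype=bool),
        "duplicated": stats["is_duplicated"].to_numpy(dtype=bool),
    }
    keep = np.ones(len(stats), dtype=bool)
    attributed = np.zeros(len(stats), dtype=bool)
    removed_counts = {}
    for crit in CRITERIA:
        newly = fails[crit] & ~attributed
        removed_counts[crit] = int(newly.sum())
        attributed |= fails[crit]
        keep &= ~fails[crit]

    report = pd.DataFrame(
        {
            "criterion": list(CRITERIA) + ["kept"],
            "n_snps": [removed_counts[c] for c in CRITERIA] + [int(keep.sum())],
        }
    )
    return keep, report
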