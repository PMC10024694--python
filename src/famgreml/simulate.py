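"""Simulation of genotyped parent-offspring trios with direct and nurture effects.

The generator emulates the input of a family-based GREML study of genetic
nurture: unrelated nuclear families (mother, father, one child), SNP
genotypes drawn under Hardy-Weinberg equilibrium and fair Mendelian
transmission, and a child phenotype built from

``y = g_o + g_m + g_f + beta_sex * sex + batch offset + e``

where ``g_o`` is the child's polygenic score over causal SNPs with per-SNP
effects ``w_o`` on standardized genotypes (direct effect), ``g_m``/``g_f``
are the mother's/father's scores with effects ``w_m``/``w_f`` (genetic
nurture, acting through the rearing environment), and ``e`` is Gaussian
noise.  The direct and nurture effect vectors are given an exact inner
product ``rho * sqrt(v_o * v_parent)`` so the passive gene-environment
covariance component has a closed-form expectation: because parent and
child standardized genotypes correlate 0.5, the model covariance component
is ``v_om = rho_m * sqrt(v_o * v_m)`` (and analogously ``v_of``), and
``cov(g_o, g_m) = v_om / 2``.  Effect vectors are scaled exactly, so the
genetic-plus-noise part of the phenotype has unit population variance and
the configured fractions are the estimands of the downstream REML model.

Questionnaire item responses are generated by thresholding the latent
(standardized) score plus per-item Gaussian noise into ordered categories,
with independent item missingness.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .pheno import PhenotypeTable, ScaleDefinition

__all__ = [
    "SimulationConfig",
    "TrioCohort",
    "VarianceComponentsTruth",
    "simulate_trio_genotypes",
    "simulate_phenotypes",
    "expected_components",
    "simulate_questionnaire",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth architecture of a simulated trio cohort.

    ``v_o``, ``v_m``, ``v_f`` are the direct, maternal-nurture and
    paternal-nurture variance fractions; ``rho_m``/``rho_f`` the
    correlations between the direct and nurture per-SNP effect vectors.
    The implied covariance components ``rho * sqrt(v_o * v_parent)`` count
    toward total variance, and the residual fraction must be nonnegative.
    """

    n_families: int = 3000
    n_snps: int = 2000
    n_causal: int = 2000
    maf_low: float = 0.05
    maf_high: float = 0.5
    v_o: float = 0.3
    v_m: float = 0.15
    v_f: float = 0.0
    rho_m: float = 0.5
    rho_f: float = 0.0
    beta_sex: float = 0.2
    beta_batch: tuple[float, ...] = (0.0, 0.1, -0.1)
    n_batches: int = 3
    seed: int = 2023
    spousal_correlation: float = 0.0  # optional assortative-mating knob, off by default

    def __post_init__(self) -> None:
        if min(self.n_families, self.n_snps, self.n_causal) < 1:
            raise ValueError("n_families, n_snps, n_causal must be positive")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        for name in ("v_o", "v_m", "v_f"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("rho_m", "rho_f"):
            r = getattr(self, name)
            if not (-1 <= r <= 1):
                raise ValueError(f"{name} must be in [-1, 1]")
        if self.n_batches < 1 or len(self.beta_batch) != self.n_batches:
            raise ValueError("beta_batch must have one offset per batch")
        if not (0 <= self.spousal_correlation < 1):
            raise ValueError("spousal_correlation must be in [0, 1)")
        v_e = 1.0 - (self.v_o + self.v_m + self.v_f
                     + self.rho_m * np.sqrt(self.v_o * self.v_m)
                     + self.rho_f * np.sqrt(self.v_o * self.v_f))
        if v_e < -1e-12:
            raise ValueError(
                "variance fractions plus implied covariances exceed 1 "
                f"(residual fraction {v_e:.4f} < 0)"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class VarianceComponentsTruth:
    """Population variance fractions implied by a :class:`SimulationConfig`."""

    v_o: float
    v_m: float
    v_f: float
    v_om: float
    v_of: float
    v_e: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class TrioCohort:
    """Genotypes and family linkage for a set of independent trios.

    Genotype matrices are additive-coded (count of the ``a1`` allele,
    0/1/2), one row per family, one column per SNP.  ``snps`` holds per-SNP
    metadata: ``snp``, ``chrom``, ``pos``, ``a1``, ``a2``, ``freq`` (the
    generating allele frequency of ``a1``) and an ``info`` imputation-quality
    stub.
    """

    family_ids: np.ndarray
    child_genotypes: np.ndarray
    mother_genotypes: np.ndarray
    father_genotypes: np.ndarray
    child_sex: np.ndarray
    batch: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.child_genotypes.shape
        for mat in (self.mother_genotypes, self.father_genotypes):
            if mat.shape != (n, m):
                raise ValueError("genotype matrices must share shape across members")
        if len(self.family_ids) != n or len(self.child_sex) != n or len(self.batch) != n:
            raise ValueError("per-family arrays must match the number of families")
        if len(self.snps) != m:
            raise ValueError("snp metadata must match the number of SNPs")
        if len(np.unique(self.family_ids)) != n:
            raise ValueError("family ids must be unique")

    @property
    def n_families(self) -> int:
        return self.child_genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.child_genotypes.shape[1]

    def member_iids(self, member: str) -> np.ndarray:
        suffix = {"child": "C", "mother": "M", "father": "F"}[member]
        return np.array([f"{fid}-{suffix}" for fid in self.family_ids])

    def mendelian_error_count(self) -> int:
        """Number of (family, SNP) cells where the child genotype is impossible
        given the parents (used as a hard invariant: must be 0)."""
        c = self.child_genotypes.astype(np.int16)
        m = self.mother_genotypes.astype(np.int16)
        f = self.father_genotypes.astype(np.int16)
        # allele from each parent is in [g/2 rounded down over transmission]:
        # possible transmitted alleles: 0 if g<2 ... encode min/max transmissible
        m_min, m_max = (m == 2).astype(np.int16), (m > 0).astype(np.int16)
        f_min, f_max = (f == 2).astype(np.int16), (f > 0).astype(np.int16)
        ok = (c >= m_min + f_min) & (c <= m_max + f_max)
        return int((~ok).sum())


def simulate_trio_genotypes(config: SimulationConfig) -> TrioCohort:
    """Draw genotypes for independent trios.

    Per SNP ``j``, an allele frequency ``p_j ~ Uniform(maf_low, maf_high)``
    is drawn; parental genotypes are Binomial(2, p_j) (Hardy-Weinberg
    equilibrium, spouses independent by default), and each child receives
    one fairly transmitted allele from each parent.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 11])
    n, m = config.n_families, config.n_snps
    p = rng.uniform(config.maf_low, config.maf_high, size=m)

    mother = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    father = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    # fair Mendelian transmission: P(transmit minor allele) = genotype / 2
    child = (
        rng.binomial(1, mother / 2.0).astype(np.int8)
        + rng.binomial(1, father / 2.0).astype(np.int8)
    )
    sex = rng.integers(0, 2, size=n).astype(np.int8)
    batch = rng.integers(0, config.n_batches, size=n).astype(np.int16)

    snps = pd.DataFrame(
        {
            "snp": [f"snp{j + 1:06d}" for j in range(m)],
            "chrom": np.ones(m, dtype=int),
            "pos": (np.arange(m) + 1) * 10_000,
            "a1": "A",
            "a2": "G",
            "freq": p,
            "info": 0.99,  # constant imputation-quality stub
        }
    )
    fids = np.array([f"F{i + 1:06d}" for i in range(n)])
    return TrioCohort(fids, child, mother, father, sex, batch, snps)


def expected_components(config: SimulationConfig) -> VarianceComponentsTruth:
    """Closed-form population variance fractions implied by ``config``.

    ``v_om = rho_m * sqrt(v_o * v_m)`` and ``v_of = rho_f * sqrt(v_o * v_f)``;
    the residual fraction is the remainder so that all components and the
    covariance terms sum to 1.
    """
    v_om = config.rho_m * float(np.sqrt(config.v_o * config.v_m))
    v_of = config.rho_f * float(np.sqrt(config.v_o * config.v_f))
    v_e = 1.0 - (config.v_o + config.v_m + config.v_f + v_om + v_of)
    return VarianceComponentsTruth(
        v_o=config.v_o, v_m=config.v_m, v_f=config.v_f,
        v_om=v_om, v_of=v_of, v_e=max(v_e, 0.0),
    )


def _standardize(genotypes: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    return (genotypes.astype(float) - 2 * freqs) / np.sqrt(2 * freqs * (1 - freqs))


def _effect_vectors(rng: np.random.Generator, config: SimulationConfig) -> tuple[np.ndarray, ...]:
    """Direct/maternal/paternal per-SNP effects with exact norms and inner products.

    ``w_m = rho_m * u + sqrt(1 - rho_m^2) * u_perp`` (scaled by sqrt(v_m)),
    with ``u_perp`` orthonormalized against ``u`` by Gram-Schmidt, so that
    ``|w_o|^2 = v_o``, ``|w_m|^2 = v_m`` and ``w_o . w_m = rho_m *
    sqrt(v_o * v_m)`` hold exactly (not just in expectation).
    """
    c = config.n_causal

    def _unit(v: np.ndarray) -> np.ndarray:
        return v / np.linalg.norm(v)

    u = _unit(rng.standard_normal(c)) if c > 1 else np.ones(1)
    a = rng.standard_normal(c)
    a = _unit(a - (a @ u) * u) if c > 1 else np.zeros(1)
    b = rng.standard_normal(c)
    if c > 2:
        b = _unit(b - (b @ u) * u - (b @ a) * a)
    else:
        b = a
    w_o = np.sqrt(config.v_o) * u
    w_m = np.sqrt(config.v_m) * (config.rho_m * u + np.sqrt(1 - config.rho_m**2) * a)
    w_f = np.sqrt(config.v_f) * (config.rho_f * u + np.sqrt(1 - config.rho_f**2) * b)
    return w_o, w_m, w_f


def simulate_phenotypes(
    cohort: TrioCohort,
    config: SimulationConfig,
    seed: int | None = None,
    include_scores: bool = True,
) -> PhenotypeTable:
    """Generate the child phenotype from the configured genetic architecture.

    Causal SNPs are drawn uniformly without replacement; effects act on
    genotypes standardized by the generating allele frequencies, matching
    the standardization of the relatedness matrices so that the configured
    fractions are the REML estimands.  The genetic + residual part of the
    phenotype has unit population variance; sex and batch effects are added
    on top (they are removed again by covariate residualization downstream).

    Parameters
    ----------
    seed : optional override so several phenotypes can be drawn for one
        cohort; defaults to ``config.seed``.
    include_scores : attach the latent scores ``g_o``, ``g_m``, ``g_f`` as
        extra columns for validation.
    """
    if cohort.n_snps != config.n_snps or cohort.n_families != config.n_families:
        raise ValueError("cohort and config dimensions disagree")
    truth = expected_components(config)  # validates v_e >= 0

    rng = np.random.default_rng([config.seed if seed is None else seed, 101])
    causal = np.sort(rng.choice(config.n_snps, size=config.n_causal, replace=False))
    w_o, w_m, w_f = _effect_vectors(rng, config)

    p = cohort.snps["freq"].to_numpy()[causal]
    g_o = _standardize(cohort.child_genotypes[:, causal], p) @ w_o
    g_m = _standardize(cohort.mother_genotypes[:, causal], p) @ w_m
    g_f = _standardize(cohort.father_genotypes[:, causal], p) @ w_f

    e = rng.normal(0.0, np.sqrt(truth.v_e), size=cohort.n_families)
    batch_offsets = np.asarray(config.beta_batch)[cohort.batch]
    y = g_o + g_m + g_f + config.beta_sex * cohort.child_sex + batch_offsets + e

    data = pd.DataFrame(
        {
            "fid": cohort.family_ids,
            "iid": cohort.member_iids("child"),
            "raw": y,
            "valid": True,
        }
    )
    if include_scores:
        data["g_o"], data["g_m"], data["g_f"] = g_o, g_m, g_f
    return PhenotypeTable(data, name="simulated")


def simulate_questionnaire(
    scores: PhenotypeTable,
    scale_def: ScaleDefinition,
    missing_rate: float = 0.0,
    seed: int = 0,
    item_noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Generate Likert item responses from a latent phenotype.

    Each item response is ``latent + N(0, item_noise_sd^2)`` thresholded
    into ``n_categories`` ordered categories coded ``min_code..max_code``;
    thresholds are normal quantiles of the scale's marginal category
    probabilities on the latent+noise scale.  Items are then masked missing
    independently at ``missing_rate``.  The latent score is the
    standardized score when available, otherwise the raw score standardized
    in-sample.

    Returns a DataFrame with ``fid``, ``iid`` and one float column per item
    (NaN = missing).
    """
    if not (0 <= missing_rate <= 1):
        raise ValueError("missing_rate must be in [0, 1]")
    latent = scores.standardized_score
    if np.isnan(latent).all():
        raw = scores.raw_score
        latent = (raw - np.nanmean(raw)) / np.nanstd(raw)

    cum = scale_def.category_cumprobs
    if cum is None:
        cum = tuple((j + 1) / scale_def.n_categories for j in range(scale_def.n_categories - 1))
    # latent has unit variance; item noise adds item_noise_sd^2
    thresholds = np.sqrt(1.0 + item_noise_sd**2) * ndtri(np.asarray(cum))

    rng = np.random.default_rng([seed, 211])
    n, k = len(latent), scale_def.n_items
    x = latent[:, None] + rng.normal(0.0, item_noise_sd, size=(n, k))
    codes = scale_def.min_code + np.searchsorted(thresholds, x.ravel()).reshape(n, k)
    items = codes.astype(float)
    if missing_rate > 0:
        items[rng.random((n, k)) < missing_rate] = np.nan

    out = pd.DataFrame({"fid": scores.data["fid"].to_numpy(), "iid": scores.data["iid"].to_numpy()})
    for j, col in enumerate(scale_def.item_columns):
        out[col] = items[:, j]
    return out
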