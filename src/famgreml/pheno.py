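"""Questionnaire scale scoring, covariate residualization, and genotype PCs.

Child psychiatric symptom scores are questionnaire totals: the 13-item
Short Mood and Feelings Questionnaire (SMFQ, 3-point Likert) for depressive
symptoms, and the Rating Scale for Disruptive Behaviour Disorders (RS-DBD,
4-point Likert) for disruptive (oppositional-defiant + conduct, 16 items)
and ADHD (18 items) symptoms.  Items are coded ``1..c``; a bounded number of
missing items per respondent is tolerated and imputed with the mean of that
respondent's non-missing items; respondents exceeding the cap get no score.

Before variance-component estimation, scores are residualized on child sex,
genotyping batch, and the top genotype principal components, then scaled to
unit variance, so that estimated components are directly proportions of
(residual) phenotypic variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr

__all__ = [
    "ScaleDefinition",
    "SMFQ",
    "RS_DBD_DISRUPTIVE",
    "RS_DBD_ADHD",
    "BUILTIN_SCALES",
    "PhenotypeTable",
    "LDPruneOptions",
    "score_scale",
    "residualize",
    "compute_pcs",
    "build_covariate_table",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """A Likert questionnaire scale.

    Parameters
    ----------
    name : str
        Scale identifier.
    n_items : int
        Number of items in the scale.
    n_categories : int
        Number of ordered response categories per item.
    min_code : int
        Code of the lowest category (items are coded
        ``min_code .. min_code + n_categories - 1``).
    max_missing : int
        Maximum number of missing items tolerated per respondent; beyond
        this the respondent receives no score.
    category_cumprobs : tuple of float, optional
        Cumulative marginal probabilities of the first ``n_categories - 1``
        categories, used by the questionnaire simulator to place its
        thresholds.  Defaults to equal category probabilities.
    """

    name: str
    n_items: int
    n_categories: int
    min_code: int = 1
    max_missing: int = 0
    category_cumprobs: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_items < 1 or self.n_categories < 2:
            raise ValueError("scale needs >= 1 item and >= 2 categories")
        if not (0 <= self.max_missing < self.n_items):
            raise ValueError("max_missing must be in [0, n_items)")
        if self.category_cumprobs is not None:
            c = np.asarray(self.category_cumprobs, dtype=float)
            if len(c) != self.n_categories - 1:
                raise ValueError("need n_categories - 1 cumulative probabilities")
            if not (np.all(np.diff(c) > 0) and c[0] > 0 and c[-1] < 1):
                raise ValueError("cumulative probabilities must be increasing in (0, 1)")

    @property
    def max_code(self) -> int:
        return self.min_code + self.n_categories - 1

    @property
    def item_columns(self) -> list[str]:
        return [f"{self.name}_item{j + 1:02d}" for j in range(self.n_items)]


# Built-in scales.  Category probabilities are skewed toward the lowest
# category, as is typical for symptom counts in population samples (most
# children endorse few symptoms), and imply item means of roughly 1.15
# (SMFQ), 1.27 (disruptive) and 1.47 (ADHD) on the 1-based coding.
SMFQ = ScaleDefinition(
    "smfq", n_items=13, n_categories=3, min_code=1, max_missing=2,
    category_cumprobs=(0.88, 0.97),
)
RS_DBD_DISRUPTIVE = ScaleDefinition(
    "rs_dbd_disruptive", n_items=16, n_categories=4, min_code=1, max_missing=3,
    category_cumprobs=(0.78, 0.96, 0.99),
)
RS_DBD_ADHD = ScaleDefinition(
    "rs_dbd_adhd", n_items=18, n_categories=4, min_code=1, max_missing=4,
    category_cumprobs=(0.65, 0.90, 0.98),
)
BUILTIN_SCALES: dict[str, ScaleDefinition] = {
    s.name: s for s in (SMFQ, RS_DBD_DISRUPTIVE, RS_DBD_ADHD)
}


@dataclass
class PhenotypeTable:
    """Per-child phenotype scores.

    ``data`` has one row per child with columns ``fid``, ``iid``, ``raw``,
    ``residualized``, ``standardized`` and boolean ``valid``; simulator
    output may additionally carry the latent genetic scores ``g_o``,
    ``g_m``, ``g_f`` for validation.  ``residualized``/``standardized`` are
    NaN until :func:`residualize` has been applied.  ``standardized`` has
    sample mean 0 and variance 1 over valid rows.
    """

    data: pd.DataFrame
    name: str = "phenotype"

    def __post_init__(self) -> None:
        required = {"fid", "iid", "raw", "valid"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"PhenotypeTable missing columns: {sorted(missing)}")
        for col in ("residualized", "standardized"):
            if col not in self.data.columns:
                self.data[col] = np.nan

    def __len__(self) -> int:
        return len(self.data)

    @property
    def valid(self) -> np.ndarray:
        return self.data["valid"].to_numpy(dtype=bool)

    @property
    def raw_score(self) -> np.ndarray:
        return self.data["raw"].to_numpy(dtype=float)

    @property
    def residualized_score(self) -> np.ndarray:
        return self.data["residualized"].to_numpy(dtype=float)

    @property
    def standardized_score(self) -> np.ndarray:
        return self.data["standardized"].to_numpy(dtype=float)


@dataclass(frozen=True)
class LDPruneOptions:
    """Window-based pairwise LD pruning (PLINK ``--indep-pairwise`` style)."""

    window: int = 50
    step: int = 5
    r2: float = 0.2

    def __post_init__(self) -> None:
        if self.window < 2 or self.step < 1 or not (0 < self.r2 < 1):
            raise ValueError("invalid LD pruning options")


def score_scale(items: pd.DataFrame, scale: ScaleDefinition) -> PhenotypeTable:
    """Total-score a table of item responses.

    Missing items (NaN) are imputed with the mean of the respondent's
    non-missing items, so the total equals ``n_items * mean(observed)``.
    Respondents with more than ``scale.max_missing`` missing items are
    flagged invalid and receive no score.

    Parameters
    ----------
    items : DataFrame
        One row per respondent; columns ``fid``, ``iid`` plus one column per
        item (any column other than ``fid``/``iid`` is treated as an item).
        Codes must lie in ``{min_code .. max_code}`` or be NaN.
    scale : ScaleDefinition

    Returns
    -------
    PhenotypeTable with ``raw`` filled and ``valid`` set.
    """
    item_cols = [c for c in items.columns if c not in ("fid", "iid")]
    if len(item_cols) != scale.n_items:
        raise ValueError(
            f"{scale.name}: expected {scale.n_items} item columns, got {len(item_cols)}"
        )
    values = items[item_cols].to_numpy(dtype=float)
    observed = ~np.isnan(values)
    bad = observed & ((values < scale.min_code) | (values > scale.max_code)
                      | (values != np.round(values)))
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0, 0])
        iid = items["iid"].iloc[row] if "iid" in items.columns else str(row)
        raise ValueError(
            f"{scale.name}: out-of-range item code for respondent {iid!r} "
            f"(allowed {scale.min_code}..{scale.max_code})"
        )

    n_missing = (~observed).sum(axis=1)
    valid = n_missing <= scale.max_missing
    with np.errstate(invalid="ignore"):
        row_mean = np.nanmean(np.where(observed, values, np.nan), axis=1)
    raw = np.where(valid, scale.n_items * row_mean, np.nan)

    data = pd.DataFrame(
        {
            "fid": items["fid"].to_numpy() if "fid" in items.columns else items["iid"].to_numpy(),
            "iid": items["iid"].to_numpy(),
            "raw": raw,
            "valid": valid,
        }
    )
    return PhenotypeTable(data, name=scale.name)


def _design_matrix(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Assemble [intercept | sex | batch dummies | pc_*] from a covariate table."""
    n = len(cov)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    if "sex" in cov.columns:
        cols.append(cov["sex"].to_numpy(dtype=float))
        names.append("sex")
    if "batch" in cov.columns:
        dummies = pd.get_dummies(cov["batch"], prefix="batch", drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(str(c))
    for c in cov.columns:
        if str(c).startswith("pc_"):
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    return np.column_stack(cols), names


def residualize(pheno: PhenotypeTable, cov: pd.DataFrame) -> PhenotypeTable:
    """Regress covariates out of the raw score and standardize the residual.

    Ordinary least squares of the score on intercept, sex, batch dummies and
    any ``pc_*`` columns of ``cov``; the residual is stored and additionally
    scaled to unit variance (mean is exactly 0 because an intercept is
    fitted).  Only valid rows enter the fit.  Rows are matched to ``cov`` by
    ``iid``; every valid row must have complete covariates.

    Raises
    ------
    ValueError
        If the covariate design is rank deficient (collinear columns are
        named) or covariates are missing for a valid row.
    """
    merged = pheno.data.merge(cov, on="iid", how="left", suffixes=("", "_cov"))
    if len(merged) != len(pheno.data):
        raise ValueError("covariate table has duplicate iids")
    mask = pheno.valid & ~np.isnan(pheno.raw_score)
    X, names = _design_matrix(merged)
    if np.isnan(X[mask]).any():
        raise ValueError("missing covariate values for scored individuals")

    Xv = X[mask]
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        _, R, piv = qr(Xv, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xv.shape) * np.finfo(float).eps
        collinear = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        collinear += [names[piv[i]] for i in range(len(diag), Xv.shape[1])]
        raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")

    y = pheno.raw_score[mask]
    beta, *_ = np.linalg.lstsq(Xv, y, rcond=None)
    resid = y - Xv @ beta
    sd = resid.std(ddof=0)
    if sd == 0:
        raise ValueError("residual variance is zero; cannot standardize")

    data = pheno.data.copy()
    residualized = np.full(len(data), np.nan)
    residualized[mask] = resid
    data["residualized"] = residualized
    standardized = np.full(len(data), np.nan)
    standardized[mask] = resid / sd
    data["standardized"] = standardized
    return PhenotypeTable(data, name=pheno.name)


def _ld_prune(genotypes: np.ndarray, options: LDPruneOptions) -> np.ndarray:
    """Return indices of SNPs kept after windowed pairwise r^2 pruning."""
    m = genotypes.shape[1]
    keep = np.ones(m, dtype=bool)
    for start in range(0, m, options.step):
        idx = np.flatnonzero(keep[start:start + options.window]) + start
        if len(idx) < 2:
            continue
        block = genotypes[:, idx].astype(float)
        block = block - block.mean(axis=0)
        sd = block.std(axis=0)
        sd[sd == 0] = np.inf
        corr = (block.T @ block) / len(block) / np.outer(sd, sd)
        r2 = corr**2
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if keep[idx[b]] and r2[a, b] > options.r2:
                    keep[idx[b]] = False  # drop the later SNP of the pair
    return np.flatnonzero(keep)


def compute_pcs(
    genotypes: np.ndarray,
    k: int = 10,
    ld_prune: LDPruneOptions | None = LDPruneOptions(),
) -> np.ndarray:
    """Top-``k`` principal components of the standardized genotype matrix.

    Columns are standardized with sample allele frequencies; PCs are the
    top left singular vectors (unit norm, mutually orthogonal), with each
    PC's sign fixed so that its largest-magnitude entry is positive.

    Parameters
    ----------
    genotypes : (n, m) array of 0/1/2 dosages, complete (QC-passed).
    k : number of components.
    ld_prune : optional LD pruning applied first (default window 50 /
        step 5 / r^2 0.2; pass None to disable).

    Returns
    -------
    (n, k) array; column ``j`` is PC ``j+1``.
    """
    X = np.asarray(genotypes, dtype=float)
    if np.isnan(X).any():
        raise ValueError("genotypes must be complete for PCA")
    if ld_prune is not None:
        X = X[:, _ld_prune(X, ld_prune)]
    p = X.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNPs present; apply QC before PCA")
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    n, m = Z.shape
    if n <= m:
        # eigen-decompose the n x n covariance rather than the m x m one
        G = Z @ Z.T / m
        w, U = np.linalg.eigh(G)
        order = np.argsort(w)[::-1]
        w, U = w[order], U[:, order]
        rank = int(np.sum(w > w[0] * 1e-10))
    else:
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-10))
    if k > rank:
        raise ValueError(f"k={k} exceeds genotype matrix rank {rank}")
    pcs = U[:, :k].copy()
    flip = pcs[np.argmax(np.abs(pcs), axis=0), np.arange(k)] < 0
    pcs[:, flip] *= -1
    return pcs


def build_covariate_table(
    iids: np.ndarray,
    sex: np.ndarray | None = None,
    batch: np.ndarray | None = None,
    pcs: np.ndarray | None = None,
    fids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble a covariate table (``fid``, ``iid``, ``sex``, ``batch``, ``pc_*``)."""
    out = pd.DataFrame({"fid": fids if fids is not None else iids, "iid": iids})
    if sex is not None:
        out["sex"] = np.asarray(sex)
    if batch is not None:
        out["batch"] = np.asarray(batch)
    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        for j in range(pcs.shape[1]):
            out[f"pc_{j + 1}"] = pcs[:, j]
    return out
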