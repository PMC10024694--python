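"""End-to-end pipeline: simulate (or load) -> score -> QC -> GRM -> prune -> fit.

``run_pipeline`` executes the stages in order for each requested phenotype
and model, persisting intermediates (QC report, GRM triplets, retained ids,
residualized phenotypes, results TSV) and a run manifest.  With simulated
input and a fixed seed, reruns are bit-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .geno_qc import QCThresholds, compute_snp_stats, filter_snps
from .greml import fit_offspring_model, fit_parent_model
from .grm import GRMSet, build_grm_set, prune_relatedness, write_gcta_grm
from .pheno import (
    BUILTIN_SCALES,
    LDPruneOptions,
    PhenotypeTable,
    build_covariate_table,
    compute_pcs,
    residualize,
    score_scale,
)
from .plink import read_plink, write_phenotype_file, write_plink
from .simulate import (
    SimulationConfig,
    TrioCohort,
    expected_components,
    simulate_phenotypes,
    simulate_questionnaire,
    simulate_trio_genotypes,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_cohort_plink"]

RESULT_COLUMNS = [
    "model", "phenotype", "V_o", "V_o_se", "V_parent", "V_parent_se",
    "V_cross", "V_cross_se", "G", "G_se", "logL", "p", "N",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    ``input_mode`` is ``"simulate"`` (use ``simulation``) or ``"files"``
    (use ``paths``: prefixes ``child``/``mother``/``father`` of PLINK
    filesets plus phenotype files).  Defaults reproduce the study settings:
    QC thresholds HWE 1e-6 / call rate 0.90 / MAF 0.05 / INFO 0.9, a 0.025
    relatedness cutoff, covariates sex + batch + 10 PCs, and offspring,
    maternal and paternal models for all three symptom scales.
    """

    input_mode: str = "simulate"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    paths: dict = field(default_factory=dict)
    scales: tuple[str, ...] = ("smfq", "rs_dbd_disruptive", "rs_dbd_adhd")
    models: tuple[str, ...] = ("offspring", "maternal", "paternal")
    qc: QCThresholds = field(default_factory=QCThresholds)
    relatedness_cutoff: float = 0.025
    n_pcs: int = 10
    missing_rate: float = 0.02
    seed: int = 2023
    ld_prune: bool = True

    def __post_init__(self) -> None:
        if self.input_mode not in ("simulate", "files"):
            raise ValueError("input_mode must be 'simulate' or 'files'")
        if not (0 < self.relatedness_cutoff < 1):
            raise ValueError("relatedness_cutoff must be in (0, 1)")
        unknown = set(self.models) - {"offspring", "maternal", "paternal"}
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        unknown = set(self.scales) - set(BUILTIN_SCALES)
        if unknown:
            raise ValueError(f"unknown scales: {sorted(unknown)}")

    def to_manifest(self) -> dict:
        d = {
            "famgreml_version": __version__,
            "input_mode": self.input_mode,
            "scales": list(self.scales),
            "models": list(self.models),
            "qc": asdict(self.qc),
            "relatedness_cutoff": self.relatedness_cutoff,
            "n_pcs": self.n_pcs,
            "missing_rate": self.missing_rate,
            "seed": self.seed,
            "ld_prune": self.ld_prune,
        }
        if self.input_mode == "simulate":
            d["simulation"] = asdict(self.simulation)
            d["expected_components"] = expected_components(self.simulation).as_dict()
        else:
            d["paths"] = dict(self.paths)
        return d


def write_cohort_plink(cohort: TrioCohort, prefix: str) -> None:
    """Write one PLINK fileset per generation (family linkage in the child
    FAM's parental-id fields) plus sex/batch covariates."""
    bim = cohort.snps.rename(columns={"snp": "snp"})[["chrom", "snp", "pos", "a1", "a2"]]
    child_fam = pd.DataFrame(
        {
            "fid": cohort.family_ids,
            "iid": cohort.member_iids("child"),
            "pid": cohort.member_iids("father"),
            "mid": cohort.member_iids("mother"),
            "sex": np.where(cohort.child_sex == 1, 1, 2),
            "pheno": -9,
        }
    )
    write_plink(prefix + "_child", cohort.child_genotypes, child_fam, bim)
    for member in ("mother", "father"):
        geno = getattr(cohort, f"{member}_genotypes")
        fam = pd.DataFrame(
            {
                "fid": cohort.family_ids,
                "iid": cohort.member_iids(member),
                "pid": "0",
                "mid": "0",
                "sex": 2 if member == "mother" else 1,
                "pheno": -9,
            }
        )
        write_plink(f"{prefix}_{member}", geno, fam, bim)


def _load_cohort_from_files(paths: dict) -> TrioCohort:
    try:
        child_g, child_fam, bim = read_plink(paths["child"])
        mother_g, _, _ = read_plink(paths["mother"])
        father_g, _, _ = read_plink(paths["father"])
    except KeyError as exc:
        raise PipelineError(f"stage input: missing path for {exc}") from exc
    freq = np.nanmean(child_g, axis=0) / 2
    snps = pd.DataFrame(
        {
            "snp": bim["snp"], "chrom": bim["chrom"].astype(int),
            "pos": bim["pos"].astype(int), "a1": bim["a1"], "a2": bim["a2"],
            "freq": freq, "info": 1.0,
        }
    )
    n = len(child_fam)
    return TrioCohort(
        child_fam["fid"].to_numpy(),
        child_g.astype(np.int8), mother_g.astype(np.int8), father_g.astype(np.int8),
        np.where(child_fam["sex"].astype(int) == 1, 1, 0).astype(np.int8),
        np.zeros(n, dtype=np.int16),
        snps,
    )


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(
    config: PipelineConfig,
    outdir: str | None = None,
    cohort: TrioCohort | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full analysis; returns (results table, manifest).

    ``cohort`` overrides the input stage for programmatic use (e.g. planted
    relatedness fixtures).  When ``outdir`` is given, intermediates and the
    results TSV / manifest JSON are persisted there.
    """
    manifest = config.to_manifest()
    counts: dict = {}

    # --- input stage -------------------------------------------------------
    if cohort is None:
        if config.input_mode == "simulate":
            cohort = _stage("simulate")(simulate_trio_genotypes)(config.simulation)
        else:
            cohort = _stage("load")(_load_cohort_from_files)(config.paths)
    counts["families"] = cohort.n_families
    counts["snps_input"] = cohort.n_snps

    # --- SNP QC (HWE in founders) -----------------------------------------
    @_stage("qc")
    def _qc():
        pooled = np.vstack(
            [cohort.child_genotypes, cohort.mother_genotypes, cohort.father_genotypes]
        ).astype(float)
        founders = np.vstack([cohort.mother_genotypes, cohort.father_genotypes]).astype(float)
        stats = compute_snp_stats(pooled, cohort.snps, hwe_genotypes=founders)
        return filter_snps(stats, config.qc)

    keep, qc_report = _qc()
    counts["snps_kept"] = int(keep.sum())
    if counts["snps_kept"] == 0:
        raise PipelineError("stage qc: no SNPs survive the filters")
    child_g = cohort.child_genotypes[:, keep]
    mother_g = cohort.mother_genotypes[:, keep]
    father_g = cohort.father_genotypes[:, keep]

    # --- covariates: sex, batch, genotype PCs ------------------------------
    @_stage("pca")
    def _cov():
        prune = LDPruneOptions() if config.ld_prune else None
        pcs = compute_pcs(child_g, k=config.n_pcs, ld_prune=prune)
        return build_covariate_table(
            cohort.member_iids("child"), sex=cohort.child_sex, batch=cohort.batch,
            pcs=pcs, fids=cohort.family_ids,
        )

    cov = _cov()

    # --- phenotypes ---------------------------------------------------------
    @_stage("phenotypes")
    def _phenos() -> dict[str, PhenotypeTable]:
        out = {}
        for idx, scale_name in enumerate(config.scales):
            scale = BUILTIN_SCALES[scale_name]
            if config.input_mode == "files" and "pheno" in config.paths:
                from .plink import read_phenotype_file

                tab = read_phenotype_file(config.paths["pheno"][scale_name])
                pt = PhenotypeTable(
                    pd.DataFrame(
                        {"fid": tab["fid"], "iid": tab["iid"], "raw": tab["value"],
                         "valid": ~tab["value"].isna()}
                    ),
                    name=scale_name,
                )
            else:
                latent = simulate_phenotypes(
                    cohort, config.simulation, seed=config.seed + 1000 * (idx + 1)
                )
                sd = latent.raw_score.std(ddof=0)
                latent.data["standardized"] = (latent.raw_score - latent.raw_score.mean()) / sd
                items = simulate_questionnaire(
                    latent, scale, missing_rate=config.missing_rate,
                    seed=config.seed + 1000 * (idx + 1) + 7,
                )
                pt = score_scale(items, scale)
            out[scale_name] = residualize(pt, cov)
        return out

    phenotypes = _phenos()
    counts["scored"] = {k: int(v.valid.sum()) for k, v in phenotypes.items()}

    # --- GRMs and pruning ---------------------------------------------------
    @_stage("grm")
    def _grms() -> dict[str, tuple[GRMSet, np.ndarray]]:
        child_ids = pd.DataFrame({"fid": cohort.family_ids, "iid": cohort.member_iids("child")})
        sets = {}
        if "offspring" in config.models:
            gs = build_grm_set(cohort.family_ids, child_g, child_ids=child_ids)
            sets["offspring"] = (gs, prune_relatedness(gs, config.relatedness_cutoff))
        for model, parent_g, member in (
            ("maternal", mother_g, "mother"), ("paternal", father_g, "father"),
        ):
            if model not in config.models:
                continue
            parent_ids = pd.DataFrame(
                {"fid": cohort.family_ids, "iid": cohort.member_iids(member)}
            )
            gs = build_grm_set(cohort.family_ids, child_g, parent_g,
                               child_ids=child_ids, parent_ids=parent_ids)
            sets[model] = (gs, prune_relatedness(gs, config.relatedness_cutoff))
        return sets

    grm_sets = _grms()
    counts["retained_families"] = {k: int(len(v[1])) for k, v in grm_sets.items()}

    # --- model fits ---------------------------------------------------------
    fit_log: list[dict] = []

    @_stage("fit")
    def _fit() -> pd.DataFrame:
        rows = []
        fid_index = {fid: i for i, fid in enumerate(cohort.family_ids)}
        for scale_name, pheno in phenotypes.items():
            valid_fids = set(pheno.data.loc[pheno.valid, "fid"])
            for model in config.models:
                gs, retained = grm_sets[model]
                use_fids = [f for f in retained if f in valid_fids]
                idx = np.array([fid_index[f] for f in use_fids], dtype=int)
                sub = gs.subset(np.isin(gs.family_ids, np.array(use_fids)).nonzero()[0])
                y = pheno.standardized_score[idx]
                y = (y - y.mean()) / y.std(ddof=0)
                if model == "offspring":
                    res = fit_offspring_model(y, sub.offspring)
                else:
                    res = fit_parent_model(y, sub, parent_kind=model)
                rows.append(res.to_row(phenotype=scale_name))
                fit_log.append(
                    {"model": model, "phenotype": scale_name, "n": res.n,
                     "iterations": res.iterations, "converged": bool(res.converged),
                     "logL": res.loglik,
                     "boundary": [str(p) for p, b in
                                  zip(res.param_names, res.boundary) if b]}
                )
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)

    results = _fit()
    manifest["counts"] = counts
    manifest["fits"] = fit_log

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        qc_report.to_csv(os.path.join(outdir, "qc_report.tsv"), sep="\t", index=False)
        for model, (gs, retained) in grm_sets.items():
            write_gcta_grm(gs.offspring, os.path.join(outdir, f"{model}_offspring"))
            if gs.parental is not None:
                write_gcta_grm(gs.parental, os.path.join(outdir, f"{model}_parental"))
            pd.DataFrame({"fid": retained, "iid": retained}).to_csv(
                os.path.join(outdir, f"{model}_retained.ids"),
                sep=" ", header=False, index=False,
            )
        for scale_name, pheno in phenotypes.items():
            ok = pheno.valid
            write_phenotype_file(
                os.path.join(outdir, f"{scale_name}_residualized.pheno"),
                pheno.data.loc[ok, "fid"], pheno.data.loc[ok, "iid"],
                pheno.data.loc[ok, "standardized"].round(10),
            )
        results.to_csv(os.path.join(outdir, "results.tsv"), sep="\t", index=False,
                       float_format="%.10g")
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    return results, manifest
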