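"""End-to-end orchestration: trait preparation, confounder PCs, block
construction, region and per-CpG tests, multiplicity control, and Q-Q / lambda
diagnostics — all driven by one configuration object (or YAML file).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import io_formats as io
from .confounders import compute_pcs, sample_probes
from .kinship import (
    DEFAULT_UNRELATED_THRESHOLD,
    kinship_from_pedigree,
    select_unrelated,
)
from .pcev import fit_pcev, pcev_statistic, pcev_test_analytic
from .regions import build_blocks
from .univariate import cpg_lm_test, cpg_lmm_test
from .vc_score import fit_null_lm, fit_null_lmm, vc_score_test

logger = logging.getLogger("cpgset_ewas")

CHI2_1_MEDIAN = 0.4549364231195724  # scipy.stats.chi2.ppf(0.5, 1)

VALID_METHODS = ("univariate", "pcev", "vc")


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails, naming the stage and unit."""


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run."""

    methylation: str
    annotation: str
    genes: str
    phenotypes: str
    pedigree: str | None = None
    kinship: str | None = None
    out_dir: str = "results"
    trait: str = "tg"
    change_definition: str | None = None  # default: log_ratio for tg, difference for hdl
    covariates: list[str] = field(default_factory=lambda: [
        "age", "sex", "center", "smoking", "metabolic_syndrome",
        "fast_time_pre", "fast_time_post",
    ])
    methods: list[str] = field(default_factory=lambda: ["univariate", "pcev", "vc"])
    family: bool = False
    unrelated_threshold: float = DEFAULT_UNRELATED_THRESHOLD
    n_probes: int = 2000
    k_pcs: int = 4
    seed: int = 0
    flank: int = 20_000
    max_block_size: int = 130
    fwer_alpha: float = 0.10
    scale: str = "beta"

    def __post_init__(self) -> None:
        if not (0.0 < self.fwer_alpha < 1.0):
            raise io.ValidationError("fwer_alpha must lie in (0, 1)")
        if self.trait not in ("hdl", "tg"):
            raise io.ValidationError("trait must be 'hdl' or 'tg'")
        if self.change_definition is None:
            self.change_definition = "log_ratio" if self.trait == "tg" else "difference"
        if self.change_definition not in ("difference", "log_ratio"):
            raise io.ValidationError("change_definition must be difference|log_ratio")
        unknown = set(self.methods) - set(VALID_METHODS)
        if unknown:
            raise io.ValidationError(f"unknown methods {sorted(unknown)}")
        if self.scale not in ("beta", "logit"):
            raise io.ValidationError("scale must be beta|logit")
        if self.family and not (self.pedigree or self.kinship):
            raise io.ValidationError("family analysis requires pedigree or kinship")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def prepare_trait(pheno: pd.DataFrame, trait: str, change_definition: str) -> np.ndarray:
    """Pre-to-post lipid change: ``log(post) - log(pre)`` or ``post - pre``."""
    if trait not in ("hdl", "tg"):
        raise io.ValidationError("trait must be 'hdl' or 'tg'")
    pre = pheno[f"{trait}_pre"].to_numpy(dtype=float)
    post = pheno[f"{trait}_post"].to_numpy(dtype=float)
    if change_definition == "log_ratio":
        bad = (pre <= 0) | (post <= 0)
        if bad.any():
            sample = pheno.loc[bad, "sample_id"].iloc[0]
            raise io.ValidationError(
                f"nonpositive {trait} value for sample {sample!r} under log_ratio"
            )
        return np.log(post) - np.log(pre)
    if change_definition == "difference":
        return post - pre
    raise io.ValidationError(f"unknown change_definition {change_definition!r}")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m controlling FWER over m tests."""
    if m < 1:
        raise io.ValidationError("m must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise io.ValidationError("alpha must lie in (0, 1)")
    return alpha / m


def genomic_inflation(pvalues: np.ndarray) -> float:
    """Genomic inflation factor lambda.

    p-values are transformed to 1-df chi-square quantiles; lambda is their
    median divided by the chi2_1 median (0.4549...).  Calibrated tests give
    lambda close to 1.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size < 10:
        raise io.ValidationError("need at least 10 p-values")
    if np.any((p <= 0) | (p > 1)):
        raise io.ValidationError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def qq_data(pvalues: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p-values for a Q-Q plot."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if np.any((p <= 0) | (p > 1)):
        raise io.ValidationError("p-values must lie in (0, 1]")
    m = p.size
    observed = np.sort(p)
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(observed)}
    )


def build_covariate_matrix(
    pheno: pd.DataFrame, covariates: list[str], pcs: np.ndarray | None = None
) -> np.ndarray:
    """Intercept + covariates (categoricals dummy-coded) + confounder PCs."""
    cols = [np.ones(len(pheno))]
    for cov in covariates:
        if cov not in pheno.columns:
            raise io.ValidationError(f"covariate {cov!r} not in phenotype table")
        series = pheno[cov]
        if series.dtype == object or str(series.dtype) == "category":
            dummies = pd.get_dummies(series, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
        else:
            cols.append(series.to_numpy(dtype=float))
    C = np.column_stack(cols)
    if pcs is not None:
        C = np.column_stack([C, pcs])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise io.ValidationError("covariate matrix is rank deficient")
    return C


def _top_k(results: list[io.AssociationResult], k: int = 5) -> pd.DataFrame:
    ranked = sorted(results, key=lambda r: (r.pvalue, r.unit_id))[:k]
    return pd.DataFrame(
        [
            (r.unit_id, r.gene_id, r.chrom, r.method, r.statistic, r.pvalue)
            for r in ranked
        ],
        columns=["unit_id", "gene_id", "chrom", "method", "statistic", "pvalue"],
    )


def run_ewas(config: AnalysisConfig) -> dict:
    """Run the configured analysis end to end; returns a summary dict.

    Stages: read inputs -> prepare trait -> (family: kinship; otherwise
    greedy unrelated selection) -> confounder PCs -> block construction ->
    per-method tests -> results TSVs, top-5 tables, Bonferroni thresholds,
    genomic-inflation lambdas and Q-Q tables, plus a run manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run_ewas seed=%d trait=%s family=%s", config.seed, config.trait,
                config.family)

    meth = io.read_methylation(config.methylation, scale=config.scale)
    annot = io.read_cpg_annotation(config.annotation)
    genes = io.read_gene_regions(config.genes)
    pheno = io.read_phenotypes(config.phenotypes)
    logger.info("inputs: %d samples x %d CpGs, %d genes, %d phenotype rows",
                meth.n_samples, meth.n_cpgs, len(genes), len(pheno))

    kin = None
    if config.kinship:
        kin = io.read_kinship(config.kinship)
    elif config.pedigree:
        kin = kinship_from_pedigree(io.read_pedigree(config.pedigree))

    # sample selection
    sample_ids = [s for s in meth.sample_ids if s in set(pheno["sample_id"])]
    if config.family:
        if kin is None:
            raise PipelineError("stage=selection: family analysis needs kinship")
    elif kin is not None:
        kin_sub = kin.subset(sample_ids)
        sample_ids = select_unrelated(kin_sub, config.unrelated_threshold)
        logger.info("selected %d unrelated of %d samples", len(sample_ids),
                    kin_sub.n)
    meth = meth.subset_samples(sample_ids)
    pheno = (pheno.set_index("sample_id").loc[sample_ids].reset_index())
    if config.family:
        kin = kin.subset(sample_ids)

    x = prepare_trait(pheno, config.trait, config.change_definition)

    probes = sample_probes(meth, min(config.n_probes, meth.n_cpgs),
                           seed=config.seed, annot=annot)
    pcs = compute_pcs(meth, probes, k=config.k_pcs)
    C = build_covariate_matrix(pheno, config.covariates, pcs.scores)
    logger.info("covariate matrix: %d columns (incl. intercept and %d PCs)",
                C.shape[1], config.k_pcs)

    blocks = build_blocks(annot, genes, flank=config.flank,
                          max_block_size=config.max_block_size)
    annotated_cpgs = sorted({c for b in blocks for c in b.cpg_ids})
    logger.info("stage counts: cpgs_in=%d cpgs_annotated=%d blocks=%d samples=%d",
                meth.n_cpgs, len(annotated_cpgs), len(blocks), len(sample_ids))

    null_lmm = None
    if config.family:
        null_lmm = fit_null_lmm(x, C, kin)

    summary: dict = {
        "n_samples": len(sample_ids),
        "n_cpgs": meth.n_cpgs,
        "n_cpgs_annotated": len(annotated_cpgs),
        "n_blocks": len(blocks),
        "family": config.family,
        "lambda": {},
        "thresholds": {},
        "results_files": {},
    }
    all_results: dict[str, list[io.AssociationResult]] = {}

    for method in config.methods:
        results: list[io.AssociationResult] = []
        try:
            if method == "univariate":
                gene_of = {}
                chrom_of = {}
                for b in blocks:
                    for c in b.cpg_ids:
                        gene_of.setdefault(c, b.gene_id)
                        chrom_of.setdefault(c, b.chrom)
                for cpg in annotated_cpgs:
                    y = meth.column(cpg)
                    if config.family:
                        res = cpg_lmm_test(x, C, y, kin, unit_id=cpg,
                                           gene_id=gene_of[cpg],
                                           chrom=chrom_of[cpg])
                    else:
                        res = cpg_lm_test(x, C, y, unit_id=cpg,
                                          gene_id=gene_of[cpg],
                                          chrom=chrom_of[cpg])
                    results.append(res)
            elif method == "pcev":
                if config.family:
                    logger.warning("pcev supports unrelated samples only; "
                                   "skipping under family analysis")
                    continue
                for b in blocks:
                    Y = meth.subset_cpgs(b.cpg_ids)
                    fit = fit_pcev(Y, x, C)
                    results.append(io.AssociationResult(
                        b.block_id, b.gene_id, b.chrom, len(b), "pcev",
                        pcev_statistic(fit), fit.p,
                        max(pcev_test_analytic(fit), np.nextafter(0, 1)),
                    ))
            elif method == "vc":
                null = null_lmm if config.family else fit_null_lm(x, C)
                label = "vc_family" if config.family else "vc"
                for b in blocks:
                    Y = meth.subset_cpgs(b.cpg_ids)
                    qf = vc_score_test(null, Y)
                    results.append(io.AssociationResult(
                        b.block_id, b.gene_id, b.chrom, len(b), label,
                        qf.Q, len(qf.eigenvalues),
                        max(qf.pvalue, np.nextafter(0, 1)),
                    ))
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            unit = results[-1].unit_id if results else "<first unit>"
            raise PipelineError(
                f"stage={method}: failed after unit {unit!r}: {exc}"
            ) from exc

        all_results[method] = results
        path = out / f"results_{method}.tsv"
        io.write_results(results, path)
        summary["results_files"][method] = str(path)
        m = len(results)
        summary["thresholds"][method] = bonferroni_threshold(config.fwer_alpha, m)
        pvals = np.array([r.pvalue for r in results])
        if m >= 10:
            summary["lambda"][method] = genomic_inflation(pvals)
            qq_data(pvals).to_csv(out / f"qq_{method}.tsv", sep="\t", index=False,
                                  float_format="%.17g")
        _top_k(results).to_csv(out / f"top5_{method}.tsv", sep="\t", index=False,
                               float_format="%.17g")
        logger.info("method=%s: %d tests, threshold %.3g", method, m,
                    summary["thresholds"][method])

    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    manifest = {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
    }
    with open(out / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return summary
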