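"""Synthetic family cohorts with the statistical structure the analysis assumes.

The generator produces nuclear-family pedigrees, block-correlated methylation
with kinship-heritable variation and shared latent confounders (emulating
batch / cell-composition effects), simple covariates, and pre/post lipid
phenotypes under the null or with effects concentrated in chosen CpG blocks.
It exists so every downstream stage — kinship handling, confounder PCs,
region and univariate tests, calibration and power behavior — is testable
without access to any restricted cohort.

Methylation model, per gene block of p CpGs (latent / logit scale, each CpG
marginal variance 1):

    L_c = a + sqrt(block_rho) * u + F l_c + noise_c,   beta = expit(mu_c + L_c)

with ``a ~ N(0, meth_h2 * 2Phi)`` shared across the block (familial
component), ``u ~ N(0, I)`` a per-sample block factor inducing exchangeable
within-block correlation ``block_rho``, ``F`` an n x n_latent matrix of
standard-normal latent confounders shared by all genes and by the phenotype,
loadings ``l_ck ~ N(0, (latent_sd * 0.7^(k-1))^2)`` — factor strengths decay
geometrically, emulating a dominant batch axis plus weaker cell-composition
axes and keeping the factors identifiable from PCs (their squared norm is
capped at 80% of the residual variance budget so noise variance stays
positive) — and independent noise absorbing the remaining variance.

Phenotype model (per trait):

    delta = sum_c beta_c * Ystd_c  +  gamma' F  +  g  +  e,

with ``g ~ N(0, pheno_h2 * 2Phi)``, ``e ~ N(0, 1 - pheno_h2)`` and
``gamma_k ~ N(0, latent_sd^2)``.  Causal CpGs enter on the standardized
latent (logit) scale.  TG changes act multiplicatively on the log scale
(``tg_post = tg_pre * exp(delta)``); HDL changes act additively in mg/dL
(``hdl_post = hdl_pre + 5 * delta``).

Determinism: all randomness flows from ``numpy.random.default_rng`` seeded
by ``[seed, stream]`` with stream 1 for methylation and 2 for phenotypes.
Draw order is fixed: methylation draws F first, then per gene (in order)
CpG count (if ranged), positions, intercepts, familial component, block
factor, latent loadings, noise.  Phenotypes draw covariates (age, sex,
center, smoking, metabolic syndrome, two fasting times), then per-trait
confounder coefficients, polygenic values, noise, and baseline lipids.
The phenotype stream re-derives F as the first block of the methylation
stream, so both stages see the same confounders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .io_formats import (
    MethylationMatrix,
    GeneRegion,
    Pedigree,
    write_cpg_annotation,
    write_gene_regions,
    write_methylation,
    write_pedigree,
    write_phenotypes,
)
from .kinship import KinshipMatrix

FAMILY_SIZES = {"trio": 3, "nuclear2": 4, "three_gen": 7}

#: fraction of the per-CpG residual variance budget the latent confounders
#: may occupy (keeps the independent-noise variance strictly positive)
_LATENT_BUDGET_FRACTION = 0.8

_HDL_DELTA_SCALE = 5.0  # mg/dL per unit of the standardized change score


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a moderately confounded, moderately heritable cohort:
    exchangeable within-block correlation 0.3 between neighboring CpGs, a
    familial (kinship) share of 0.2 of methylation variance, three latent
    batch/cell-composition factors with loading scale 0.6, and a phenotype
    familial variance share of 0.3.
    """

    n_families: int = 60
    family_structure: str = "nuclear2"
    n_genes: int = 20
    cpgs_per_gene: int | tuple[int, int] = 20
    block_rho: float = 0.3
    n_latent: int = 3
    latent_sd: float = 0.6
    meth_h2: float = 0.2
    effect_blocks: Sequence[tuple[str, float, float]] = field(default_factory=list)
    effect_sign_pattern: str = "constant"  # or "alternating"
    pheno_h2: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.family_structure not in FAMILY_SIZES:
            raise ConfigError(
                f"unknown family_structure {self.family_structure!r}; "
                f"choose from {sorted(FAMILY_SIZES)}"
            )
        for name, val in (("block_rho", self.block_rho),
                          ("meth_h2", self.meth_h2),
                          ("pheno_h2", self.pheno_h2)):
            if not (0.0 <= val < 1.0):
                raise ConfigError(f"{name} must lie in [0, 1)")
        if self.meth_h2 + self.block_rho >= 1.0:
            raise ConfigError(
                "meth_h2 + block_rho >= 1: per-CpG noise variance would be "
                "nonpositive"
            )
        if self.n_latent < 0 or self.latent_sd < 0:
            raise ConfigError("n_latent and latent_sd must be nonnegative")
        if self.effect_sign_pattern not in ("constant", "alternating"):
            raise ConfigError(
                "effect_sign_pattern must be 'constant' or 'alternating'"
            )


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Deterministic pedigree of ``n_families`` copies of one structure.

    trio: father, mother, child.  nuclear2: two parents, two children.
    three_gen: grandparents, their two children, a married-in founder, and
    two grandchildren (7 members).
    """
    rows: list[tuple[str, str, str, str, str]] = []
    for i in range(config.n_families):
        fam = f"F{i + 1:04d}"

        def iid(k: int) -> str:
            return f"{fam}-{k:02d}"

        if config.family_structure == "trio":
            rows.append((fam, iid(1), "0", "0", "1"))
            rows.append((fam, iid(2), "0", "0", "2"))
            rows.append((fam, iid(3), iid(1), iid(2), "1" if i % 2 == 0 else "2"))
        elif config.family_structure == "nuclear2":
            rows.append((fam, iid(1), "0", "0", "1"))
            rows.append((fam, iid(2), "0", "0", "2"))
            rows.append((fam, iid(3), iid(1), iid(2), "1"))
            rows.append((fam, iid(4), iid(1), iid(2), "2"))
        else:  # three_gen
            rows.append((fam, iid(1), "0", "0", "1"))  # grandfather
            rows.append((fam, iid(2), "0", "0", "2"))  # grandmother
            rows.append((fam, iid(3), iid(1), iid(2), "1"))  # father
            rows.append((fam, iid(4), iid(1), iid(2), "2"))  # aunt
            rows.append((fam, iid(5), "0", "0", "2"))  # married-in mother
            rows.append((fam, iid(6), iid(3), iid(5), "1"))
            rows.append((fam, iid(7), iid(3), iid(5), "2"))
    table = pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex"]
    )
    return Pedigree(table)


def founder_pedigree(n: int, prefix: str = "S") -> Pedigree:
    """A pedigree of ``n`` unrelated singletons (each its own family)."""
    rows = [
        (f"{prefix}{i + 1:04d}", f"{prefix}{i + 1:04d}", "0", "0",
         "1" if i % 2 == 0 else "2")
        for i in range(n)
    ]
    table = pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex"]
    )
    return Pedigree(table)


def _chol_2phi(kin: KinshipMatrix) -> np.ndarray:
    d, u = kin.eig_2phi()
    return u * np.sqrt(d)[None, :]


def _gene_regions(config: SimConfig) -> list[GeneRegion]:
    regions = []
    for g in range(config.n_genes):
        start = 100_000 + g * 200_000
        regions.append(GeneRegion(f"G{g + 1:04d}", "chr1", start, start + 50_000))
    return regions


def simulate_methylation(
    ped: Pedigree, kin: KinshipMatrix, config: SimConfig
) -> tuple[MethylationMatrix, pd.DataFrame, list[GeneRegion]]:
    """Generate block-structured beta values plus annotation and gene regions.

    CpG positions are placed uniformly inside the gene interval extended by
    15 kb on each side, so every simulated CpG falls inside the default
    20 kb assignment window of its gene.
    """
    if kin.sample_ids != ped.individual_ids:
        raise ConfigError("kinship sample order does not match pedigree")
    n = len(ped)
    rng = np.random.default_rng([config.seed, 1])
    chol = _chol_2phi(kin)
    F = rng.standard_normal((n, config.n_latent)) if config.n_latent else np.zeros((n, 0))
    budget = 1.0 - config.meth_h2 - config.block_rho
    regions = _gene_regions(config)
    betas: list[np.ndarray] = []
    annot_rows: list[tuple[str, str, int]] = []
    for gene in regions:
        if isinstance(config.cpgs_per_gene, int):
            p = config.cpgs_per_gene
        else:
            lo, hi = config.cpgs_per_gene
            p = int(rng.integers(lo, hi + 1))
        if p < 1:
            raise ConfigError("cpgs_per_gene must be >= 1")
        window_lo = gene.start - 15_000 + 1  # 1-based
        window_hi = gene.end + 15_000
        positions = np.sort(
            rng.choice(window_hi - window_lo + 1, size=p, replace=False) + window_lo
        )
        mu = rng.uniform(-2.0, 2.0, size=p)
        a = math.sqrt(config.meth_h2) * (chol @ rng.standard_normal(n))
        u = rng.standard_normal(n)
        if config.n_latent:
            factor_sd = config.latent_sd * 0.7 ** np.arange(config.n_latent)
            loadings = rng.standard_normal((p, config.n_latent)) * factor_sd[None, :]
            norms2 = (loadings**2).sum(axis=1)
            cap = _LATENT_BUDGET_FRACTION * budget
            over = norms2 > cap
            loadings[over] *= np.sqrt(cap / norms2[over])[:, None]
            norms2 = np.minimum(norms2, cap)
        else:
            loadings = np.zeros((p, 0))
            norms2 = np.zeros(p)
        noise_sd = np.sqrt(budget - norms2)
        eps = rng.standard_normal((n, p))
        latent = (
            a[:, None]
            + math.sqrt(config.block_rho) * u[:, None]
            + F @ loadings.T
            + eps * noise_sd[None, :]
        )
        betas.append(expit(mu[None, :] + latent))
        for j in range(p):
            annot_rows.append((f"{gene.gene_id}:cg{j + 1:03d}", gene.chrom,
                               int(positions[j])))
    values = np.concatenate(betas, axis=1)
    annot = pd.DataFrame(annot_rows, columns=["cpg_id", "chrom", "pos"])
    meth = MethylationMatrix(values, ped.individual_ids, list(annot["cpg_id"]))
    return meth, annot, regions


def _standardized_latent(meth: MethylationMatrix) -> np.ndarray:
    lat = logit(np.clip(meth.values, 1e-6, 1.0 - 1e-6))
    lat = lat - lat.mean(axis=0)
    sd = lat.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return lat / sd


def causal_cpgs(meth: MethylationMatrix, gene_id: str, fraction: float) -> list[str]:
    """The first ``ceil(fraction * p)`` CpGs (position order) of a gene."""
    members = [c for c in meth.cpg_ids if c.startswith(f"{gene_id}:")]
    if not members:
        raise ConfigError(f"effect block references unknown gene {gene_id!r}")
    k = max(1, math.ceil(fraction * len(members)))
    return members[:k]


def simulate_phenotypes(
    ped: Pedigree,
    kin: KinshipMatrix,
    meth: MethylationMatrix,
    config: SimConfig,
) -> pd.DataFrame:
    """Covariates and pre/post lipid values for every pedigree member."""
    if meth.sample_ids != ped.individual_ids:
        raise ConfigError("methylation sample order does not match pedigree")
    n = len(ped)
    rng = np.random.default_rng([config.seed, 2])
    age = rng.uniform(20.0, 70.0, n)
    sex = rng.integers(0, 2, n)
    center = rng.integers(0, 3, n)
    smoking = (rng.random(n) < 0.3).astype(int)
    met_syn = (rng.random(n) < 0.4).astype(int)
    fast_pre = rng.uniform(8.0, 14.0, n)
    fast_post = rng.uniform(8.0, 14.0, n)

    # same latent confounders as the methylation stage (its first draw)
    rng_m = np.random.default_rng([config.seed, 1])
    F = (rng_m.standard_normal((n, config.n_latent))
         if config.n_latent else np.zeros((n, 0)))

    causal = np.zeros(n)
    if config.effect_blocks:
        Ystd = _standardized_latent(meth)
        col = {c: j for j, c in enumerate(meth.cpg_ids)}
        for gene_id, effect, fraction in config.effect_blocks:
            for k, c in enumerate(causal_cpgs(meth, gene_id, fraction)):
                # "alternating" flips every second causal CpG: distributed
                # effects with heterogeneous direction, the regime variance-
                # component region tests are designed for
                sign = -1.0 if (config.effect_sign_pattern == "alternating"
                                and k % 2 == 1) else 1.0
                causal += sign * effect * Ystd[:, col[c]]

    chol = _chol_2phi(kin)
    deltas = {}
    factor_sd = config.latent_sd * 0.7 ** np.arange(config.n_latent)
    for trait in ("tg", "hdl"):
        gamma = (rng.standard_normal(config.n_latent) * factor_sd
                 if config.n_latent else np.zeros(0))
        g = math.sqrt(config.pheno_h2) * (chol @ rng.standard_normal(n))
        e = math.sqrt(1.0 - config.pheno_h2) * rng.standard_normal(n)
        deltas[trait] = causal + F @ gamma + g + e

    tg_pre = np.exp(rng.normal(np.log(120.0), 0.4, n))
    hdl_pre = np.exp(rng.normal(np.log(50.0), 0.2, n))
    tg_post = tg_pre * np.exp(deltas["tg"])
    hdl_post = np.maximum(hdl_pre + _HDL_DELTA_SCALE * deltas["hdl"], 1.0)
    return pd.DataFrame(
        {
            "sample_id": ped.individual_ids,
            "hdl_pre": hdl_pre,
            "hdl_post": hdl_post,
            "tg_pre": tg_pre,
            "tg_post": tg_post,
            "age": age,
            "sex": sex,
            "center": [f"C{c + 1}" for c in center],
            "smoking": smoking,
            "metabolic_syndrome": met_syn,
            "fast_time_pre": fast_pre,
            "fast_time_post": fast_post,
        }
    )


def simulate_cohort(config: SimConfig, ped: Pedigree | None = None):
    """Generate a full cohort; returns (ped, kin, meth, annot, regions, pheno).

    A custom pedigree (e.g. :func:`founder_pedigree` for an unrelated design)
    may be supplied; by default :func:`simulate_pedigree` is used.
    """
    from .kinship import kinship_from_pedigree

    if ped is None:
        ped = simulate_pedigree(config)
    kin = kinship_from_pedigree(ped)
    meth, annot, regions = simulate_methylation(ped, kin, config)
    pheno = simulate_phenotypes(ped, kin, meth, config)
    return ped, kin, meth, annot, regions, pheno


def write_cohort(config: SimConfig, out_dir: str | Path,
                 ped: Pedigree | None = None) -> dict:
    """Write all cohort files plus a true-parameter manifest; returns paths."""
    from .io_formats import write_kinship

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped, kin, meth, annot, regions, pheno = simulate_cohort(config, ped=ped)
    paths = {
        "pedigree": out / "pedigree.fam",
        "kinship": out / "kinship.tsv",
        "methylation": out / "methylation.tsv",
        "annotation": out / "cpg_annotation.tsv",
        "genes": out / "genes.bed",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.yaml",
    }
    write_pedigree(ped, paths["pedigree"])
    write_kinship(kin, paths["kinship"])
    write_methylation(meth, paths["methylation"])
    write_cpg_annotation(annot, paths["annotation"])
    write_gene_regions(regions, paths["genes"])
    write_phenotypes(pheno, paths["phenotypes"])
    truth = {
        "n_families": config.n_families,
        "family_structure": config.family_structure,
        "n_samples": len(ped),
        "n_genes": config.n_genes,
        "block_rho": config.block_rho,
        "n_latent": config.n_latent,
        "latent_sd": config.latent_sd,
        "meth_h2": config.meth_h2,
        "pheno_h2": config.pheno_h2,
        "effect_blocks": [list(b) for b in config.effect_blocks],
        "seed": config.seed,
    }
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    return {k: str(v) for k, v in paths.items()}
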