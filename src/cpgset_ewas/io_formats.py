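"""Readers and writers for the on-disk artifacts of the pipeline.

All downstream modules operate on the in-memory domain types defined here.
Coordinate conventions are preserved as read: CpG annotation positions are
1-based, gene regions are 0-based half-open (BED). The single place where
the two conventions meet is :func:`cpgset_ewas.regions.assign_cpgs_to_genes`.

On disk the methylation matrix is CpG x sample (the usual array-manifest
orientation); in memory it is stored samples x CpGs because every analysis
step operates on per-sample vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

LOGIT_EPS = 1e-6

#: columns required of a phenotype/covariate table
PHENOTYPE_COLUMNS = [
    "sample_id",
    "hdl_pre",
    "hdl_post",
    "tg_pre",
    "tg_post",
    "age",
    "sex",
    "center",
    "smoking",
    "metabolic_syndrome",
    "fast_time_pre",
    "fast_time_post",
]

RESULT_COLUMNS = [
    "unit_id",
    "gene_id",
    "chrom",
    "n_cpgs",
    "method",
    "statistic",
    "df_or_neigs",
    "pvalue",
]


class ValidationError(ValueError):
    """Raised when a file or in-memory object violates a format invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed into the expected shape/types."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class MethylationMatrix:
    """Methylation values for n samples at p CpG sites.

    ``values`` is n_samples x n_cpgs.  ``scale`` is ``"beta"`` (values are
    proportions in [0, 1]) or ``"logit"`` (M-values, finite reals).
    """

    values: np.ndarray
    sample_ids: list[str]
    cpg_ids: list[str]
    scale: str = "beta"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.cpg_ids = [str(c) for c in self.cpg_ids]
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValidationError(
                f"row count {n} does not match {len(self.sample_ids)} sample ids"
            )
        if p != len(self.cpg_ids):
            raise ValidationError(
                f"column count {p} does not match {len(self.cpg_ids)} cpg ids"
            )
        _check_unique(self.sample_ids, "sample id")
        _check_unique(self.cpg_ids, "cpg id")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("methylation matrix contains non-finite values")
        if self.scale == "beta":
            if self.values.min() < 0.0 or self.values.max() > 1.0:
                raise ValidationError("beta values must lie in [0, 1]")
        elif self.scale != "logit":
            raise ValidationError(f"unknown scale {self.scale!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    def column(self, cpg_id: str) -> np.ndarray:
        return self.values[:, self.cpg_ids.index(cpg_id)]

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> np.ndarray:
        """Return the n x k submatrix for ``cpg_ids`` in the given order."""
        index = {c: j for j, c in enumerate(self.cpg_ids)}
        cols = [index[c] for c in cpg_ids]
        return self.values[:, cols]

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return MethylationMatrix(
            self.values[rows, :], list(sample_ids), list(self.cpg_ids), self.scale
        )

    def to_logit(self) -> "MethylationMatrix":
        if self.scale == "logit":
            return self
        b = np.clip(self.values, LOGIT_EPS, 1.0 - LOGIT_EPS)
        return MethylationMatrix(
            np.log(b / (1.0 - b)), list(self.sample_ids), list(self.cpg_ids), "logit"
        )


class GeneRegion(NamedTuple):
    """A flat gene interval; ``start``/``end`` are 0-based half-open bp."""

    gene_id: str
    chrom: str
    start: int
    end: int


@dataclass
class Pedigree:
    """PLINK-FAM-style pedigree rows; ``"0"`` denotes a missing parent."""

    table: pd.DataFrame  # columns family_id, individual_id, father_id, mother_id, sex
    _topo: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        required = ["family_id", "individual_id", "father_id", "mother_id", "sex"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"pedigree table missing columns {missing}")
        for c in required[:4]:
            self.table[c] = self.table[c].astype(str)
        ids = list(self.table["individual_id"])
        _check_unique(ids, "individual id")
        present = set(ids)
        for _, row in self.table.iterrows():
            for parent in (row["father_id"], row["mother_id"]):
                if parent != "0" and parent not in present:
                    raise ValidationError(
                        f"individual {row['individual_id']!r} references absent "
                        f"parent {parent!r}"
                    )
        self._topo = self._topological_sort()

    def _topological_sort(self) -> list[str]:
        # Kahn's algorithm over parent -> child edges; leftovers indicate a cycle
        children: dict[str, list[str]] = {i: [] for i in self.table["individual_id"]}
        n_parents: dict[str, int] = {}
        for _, row in self.table.iterrows():
            iid = row["individual_id"]
            parents = [p for p in (row["father_id"], row["mother_id"]) if p != "0"]
            n_parents[iid] = len(parents)
            for p in parents:
                if p == iid:
                    raise ValidationError(f"individual {iid!r} is its own parent")
                children[p].append(iid)
        queue = [i for i in self.table["individual_id"] if n_parents[i] == 0]
        order: list[str] = []
        while queue:
            i = queue.pop(0)
            order.append(i)
            for c in children[i]:
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    queue.append(c)
        if len(order) != len(self.table):
            raise ValidationError("pedigree contains a parentage cycle")
        return order

    @property
    def individual_ids(self) -> list[str]:
        return list(self.table["individual_id"])

    @property
    def topological_order(self) -> list[str]:
        """Individuals ordered so that every parent precedes its children."""
        return list(self._topo)

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        row = self.table.loc[self.table["individual_id"] == iid].iloc[0]
        f = row["father_id"] if row["father_id"] != "0" else None
        m = row["mother_id"] if row["mother_id"] != "0" else None
        return f, m

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class AssociationResult:
    """One association test outcome for a CpG or a CpG block."""

    unit_id: str
    gene_id: str
    chrom: str
    n_cpgs: int
    method: str
    statistic: float
    df_or_neigs: int
    pvalue: float

    VALID_METHODS = frozenset(
        {"univariate_lm", "univariate_lmm", "pcev", "vc", "vc_family"}
    )

    def __post_init__(self) -> None:
        if self.method not in self.VALID_METHODS:
            raise ValidationError(f"unknown method {self.method!r}")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValidationError(f"p-value {self.pvalue} outside (0, 1]")


# ---------------------------------------------------------------------------
# methylation


def read_methylation(path: str | Path, scale: str = "beta") -> MethylationMatrix:
    """Read a CpG x sample TSV into a samples x CpGs :class:`MethylationMatrix`.

    The file's first column holds CpG ids, the header row sample ids.  With
    ``scale="logit"`` beta values are mapped through ``log(b/(1-b))`` after
    clipping to ``[1e-6, 1 - 1e-6]``.
    """
    if scale not in ("beta", "logit"):
        raise ValidationError(f"unknown scale {scale!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    cpg_ids = [str(c) for c in df.index]
    sample_ids = [str(s) for s in df.columns]
    try:
        body = df.to_numpy(dtype=float)
    except ValueError:
        for cpg, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"non-numeric cell at cpg {cpg!r}, sample {sample!r}: {cell!r}"
                    ) from None
        raise
    if np.isnan(body).any():
        i, j = np.argwhere(np.isnan(body))[0]
        raise ValidationError(
            f"missing value at cpg {cpg_ids[i]!r}, sample {sample_ids[j]!r}; "
            "missing methylation values are not supported"
        )
    mat = MethylationMatrix(body.T, sample_ids, cpg_ids, scale="beta")
    return mat.to_logit() if scale == "logit" else mat


def write_methylation(meth: MethylationMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        meth.values.T, index=pd.Index(meth.cpg_ids, name="cpg_id"),
        columns=meth.sample_ids,
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# CpG annotation


def read_cpg_annotation(path: str | Path) -> pd.DataFrame:
    """Read a CpG annotation TSV (columns cpg_id, chrom, pos; pos 1-based)."""
    df = pd.read_csv(path, sep="\t", dtype={"cpg_id": str, "chrom": str})
    missing = [c for c in ("cpg_id", "chrom", "pos") if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation missing columns {missing}")
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        bad = df.loc[df["pos"] < 1, "cpg_id"].iloc[0]
        raise ValidationError(f"cpg {bad!r} has position < 1 (positions are 1-based)")
    _check_unique(list(df["cpg_id"]), "cpg id")
    return df[["cpg_id", "chrom", "pos"]]


def write_cpg_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot[["cpg_id", "chrom", "pos"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene regions (BED4)


def read_gene_regions(path: str | Path) -> list[GeneRegion]:
    """Read BED4 (chrom, start, end, name) into 0-based half-open regions."""
    regions: list[GeneRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"line {lineno}: expected >= 4 BED fields")
            chrom, start_s, end_s, name = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise ValidationError(
                    f"line {lineno}: invalid interval [{start}, {end}) for {name!r}"
                )
            regions.append(GeneRegion(name, chrom, start, end))
    return regions


def write_gene_regions(regions: Iterable[GeneRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\n")


# ---------------------------------------------------------------------------
# pedigree


def read_pedigree(path: str | Path) -> Pedigree:
    """Read whitespace-delimited PLINK-style pedigree text (FID IID PAT MAT SEX)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise ParseError(f"line {lineno}: expected >= 5 columns")
            rows.append(fields[:5])
    df = pd.DataFrame(
        rows, columns=["family_id", "individual_id", "father_id", "mother_id", "sex"]
    )
    return Pedigree(df)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    ped.table[["family_id", "individual_id", "father_id", "mother_id", "sex"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# phenotypes


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype + covariate TSV and validate its invariants."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "center": str},
                     float_precision="round_trip")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns {missing}")
    _check_unique(list(df["sample_id"]), "sample id")
    for col in ("hdl_pre", "hdl_post", "tg_pre", "tg_post"):
        if (df[col] <= 0).any():
            bad = df.loc[df[col] <= 0, "sample_id"].iloc[0]
            raise ValidationError(f"nonpositive {col} for sample {bad!r}")
    return df


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# kinship


def read_kinship(path: str | Path):
    """Read a square kinship TSV (header + index of sample ids)."""
    from .kinship import KinshipMatrix

    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return KinshipMatrix(df.to_numpy(dtype=float), [str(s) for s in df.index])


def write_kinship(kin, path: str | Path) -> None:
    df = pd.DataFrame(kin.values, index=kin.sample_ids, columns=kin.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# association results


def write_results(results: Sequence[AssociationResult], path: str | Path) -> None:
    """Write results as TSV; floats round-trip losslessly at 17 sig. digits."""
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                f"{r.unit_id}\t{r.gene_id}\t{r.chrom}\t{r.n_cpgs}\t{r.method}\t"
                f"{r.statistic:.17g}\t{r.df_or_neigs}\t{r.pvalue:.17g}\n"
            )


def read_results(path: str | Path) -> list[AssociationResult]:
    df = pd.read_csv(
        path, sep="\t", dtype={"unit_id": str, "gene_id": str, "chrom": str},
        float_precision="round_trip",
    )
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"results file missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        gene = "" if (isinstance(row["gene_id"], float) and math.isnan(row["gene_id"])) else str(row["gene_id"])
        chrom = "" if (isinstance(row["chrom"], float) and math.isnan(row["chrom"])) else str(row["chrom"])
        out.append(
            AssociationResult(
                unit_id=str(row["unit_id"]),
                gene_id=gene,
                chrom=chrom,
                n_cpgs=int(row["n_cpgs"]),
                method=str(row["method"]),
                statistic=float(row["statistic"]),
                df_or_neigs=int(row["df_or_neigs"]),
                pvalue=float(row["pvalue"]),
            )
        )
    return out
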