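"""Assignment of CpGs to gene windows and splitting into bounded blocks.

A CpG belongs to a gene if it falls inside the gene interval extended by a
symmetric flank (20 kb by default) on the same chromosome.  Gene sets larger
than ``max_block_size`` CpGs are split into contiguous, nearly equal-sized
blocks so that region tests stay well conditioned relative to sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import GeneRegion, ValidationError

DEFAULT_FLANK = 20_000
DEFAULT_MAX_BLOCK_SIZE = 130


@dataclass
class Block:
    """An ordered set of CpGs assigned to one gene region (post-splitting)."""

    block_id: str
    gene_id: str
    chrom: str
    cpg_ids: list[str]

    def __post_init__(self) -> None:
        if not self.cpg_ids:
            raise ValidationError(f"block {self.block_id!r} is empty")
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValidationError(f"block {self.block_id!r} has duplicate CpG ids")

    def __len__(self) -> int:
        return len(self.cpg_ids)


def assign_cpgs_to_genes(
    annot: pd.DataFrame,
    genes: Sequence[GeneRegion],
    flank: int = DEFAULT_FLANK,
) -> dict[str, list[str]]:
    """Map each gene to the CpGs inside its flanked window, position-ordered.

    ``annot`` has columns (cpg_id, chrom, pos) with 1-based positions; gene
    intervals are 0-based half-open [start, end).  A CpG at 1-based position
    p is assigned iff ``start - flank < p <= end + flank`` on the same
    chromosome — the half-open BED interval plus ``flank`` bp on each side,
    expressed in 1-based inclusive coordinates.  A CpG may land in several
    overlapping gene windows; CpGs hitting no gene are dropped.
    """
    by_chrom: dict[str, pd.DataFrame] = {
        chrom: g.sort_values(["pos", "cpg_id"], kind="mergesort")
        for chrom, g in annot.groupby("chrom")
    }
    mapping: dict[str, list[str]] = {}
    for gene in genes:
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            mapping[gene.gene_id] = []
            continue
        pos = sub["pos"].to_numpy()
        mask = (pos > gene.start - flank) & (pos <= gene.end + flank)
        mapping[gene.gene_id] = list(sub.loc[mask, "cpg_id"])
    return mapping


def split_blocks(
    gene_id: str,
    cpg_ids: Sequence[str],
    max_block_size: int = DEFAULT_MAX_BLOCK_SIZE,
    chrom: str = "",
) -> list[Block]:
    """Split a gene's position-sorted CpG list into <= max_block_size chunks.

    ``k = ceil(p / max_block_size)`` contiguous chunks with sizes as equal as
    possible (the first ``p mod k`` chunks get one extra CpG).  A single
    chunk keeps the bare gene id; otherwise blocks are suffixed ``_1``..``_k``.
    """
    p = len(cpg_ids)
    if p == 0:
        raise ValidationError(f"gene {gene_id!r} has no CpGs to split")
    if max_block_size < 1:
        raise ValidationError("max_block_size must be >= 1")
    k = math.ceil(p / max_block_size)
    base, rem = divmod(p, k)
    blocks: list[Block] = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        chunk = list(cpg_ids[start : start + size])
        start += size
        block_id = gene_id if k == 1 else f"{gene_id}_{i + 1}"
        blocks.append(Block(block_id, gene_id, chrom, chunk))
    return blocks


def build_blocks(
    annot: pd.DataFrame,
    genes: Sequence[GeneRegion],
    flank: int = DEFAULT_FLANK,
    max_block_size: int = DEFAULT_MAX_BLOCK_SIZE,
) -> list[Block]:
    """Assign CpGs to genes and split, skipping genes with no CpGs."""
    mapping = assign_cpgs_to_genes(annot, genes, flank=flank)
    chroms = {g.gene_id: g.chrom for g in genes}
    blocks: list[Block] = []
    for gene in genes:
        cpgs = mapping[gene.gene_id]
        if not cpgs:
            continue
        blocks.extend(
            split_blocks(gene.gene_id, cpgs, max_block_size, chrom=chroms[gene.gene_id])
        )
    return blocks


def blocks_to_table(blocks: Iterable[Block]) -> pd.DataFrame:
    rows = [
        (b.block_id, b.gene_id, b.chrom, c, r)
        for b in blocks
        for r, c in enumerate(b.cpg_ids)
    ]
    return pd.DataFrame(rows, columns=["block_id", "gene_id", "chrom", "cpg_id", "rank"])


def blocks_from_table(table: pd.DataFrame) -> list[Block]:
    blocks = []
    for block_id, g in table.groupby("block_id", sort=False):
        g = g.sort_values("rank")
        blocks.append(
            Block(
                str(block_id),
                str(g["gene_id"].iloc[0]),
                str(g["chrom"].iloc[0]),
                [str(c) for c in g["cpg_id"]],
            )
        )
    return blocks
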