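"""Methylation-derived principal components for unknown-confounder adjustment.

Cell-composition and batch effects leave broad, correlated signatures across
the methylome.  PCs computed from a random subsample of probes capture these
latent factors; including the top few as covariates restores the calibration
of per-CpG and region tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MethylationMatrix, ValidationError

DEFAULT_N_PROBES = 2000
DEFAULT_K = 4

_SEX_CHROMS = {"chrX", "chrY", "X", "Y", "chrM", "MT", "M"}


@dataclass
class ConfounderPCs:
    scores: np.ndarray  # n_samples x k, ordered by decreasing explained variance
    probe_ids_used: list[str]
    explained_variance: np.ndarray  # length k
    sample_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        k = self.scores.shape[1]
        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=[f"PC{i + 1}" for i in range(k)],
        )


def sample_probes(
    meth: MethylationMatrix,
    n_probes: int = DEFAULT_N_PROBES,
    seed: int = 0,
    annot: pd.DataFrame | None = None,
) -> list[str]:
    """Uniformly sample probes without replacement, deterministically by seed.

    When ``annot`` (cpg_id, chrom, pos) is supplied, sampling is restricted
    to autosomal probes; otherwise all supplied probes are eligible.
    """
    eligible = list(meth.cpg_ids)
    if annot is not None:
        autosomal = set(annot.loc[~annot["chrom"].isin(_SEX_CHROMS), "cpg_id"])
        eligible = [c for c in eligible if c in autosomal]
    if n_probes > len(eligible):
        raise ValidationError(
            f"requested {n_probes} probes but only {len(eligible)} available"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(eligible), size=n_probes, replace=False)
    picked.sort()  # stable column order for downstream determinism
    return [eligible[i] for i in picked]


def compute_pcs(
    meth: MethylationMatrix, probe_ids: list[str], k: int = DEFAULT_K
) -> ConfounderPCs:
    """Top-k PCs of the column-centered probe submatrix.

    Scores are the leading left singular vectors scaled by their singular
    values; each component's sign is fixed so its largest-magnitude probe
    loading is positive.
    """
    X = meth.subset_cpgs(probe_ids)
    n, m = X.shape
    if k > min(n - 1, m):
        raise ValidationError(f"k={k} exceeds min(n_samples - 1, n_probes)")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 1e-12 * max(1.0, np.abs(X).max()) * np.sqrt(n * m):
        raise ValidationError("probe submatrix is constant (rank zero)")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    explained = s[:k] ** 2 / (n - 1)
    return ConfounderPCs(scores, list(probe_ids), explained, list(meth.sample_ids))
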