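"""Pedigree kinship and greedy selection of unrelated individuals.

The kinship coefficient phi_ij is the probability that an allele sampled at
random from individual i and one from j are identical by descent.  2*Phi is
the additive genetic relationship matrix used by the mixed models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Pedigree, ValidationError

#: default relatedness cutoff, ~2^-5.5, below the half-first-cousin level;
#: any pair sharing a pedigree ancestor exceeds it.
DEFAULT_UNRELATED_THRESHOLD = 0.0221


@dataclass
class KinshipMatrix:
    """Symmetric matrix of pairwise kinship coefficients phi."""

    values: np.ndarray
    sample_ids: list[str]
    _eig2phi: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"kinship shape {self.values.shape} does not match {n} sample ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValidationError("kinship matrix is not symmetric")
        if np.any(np.diag(self.values) < 0.5 - 1e-12):
            raise ValidationError("kinship diagonal must be >= 0.5")
        if self.values.min() < -1e-12 or self.values.max() > 1.0 + 1e-12:
            raise ValidationError("kinship entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: list[str]) -> "KinshipMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return KinshipMatrix(self.values[np.ix_(rows, rows)], list(sample_ids))

    def eig_2phi(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of 2*Phi (cached; eigenvalues clipped at 0).

        Raises if 2*Phi is materially non-PSD (eigenvalue < -1e-6).
        """
        if self._eig2phi is None:
            d, u = np.linalg.eigh(2.0 * self.values)
            if d.min() < -1e-6:
                raise ValidationError(
                    f"2*kinship matrix is not PSD (min eigenvalue {d.min():.3g})"
                )
            self._eig2phi = (np.clip(d, 0.0, None), u)
        return self._eig2phi


def kinship_from_pedigree(ped: Pedigree) -> KinshipMatrix:
    """Compute pedigree kinship by the standard recursive algorithm.

    Individuals are processed in topological (parents-first) order:

    * founders: phi_ii = 0.5, phi with previously processed individuals = 0;
    * non-founders: phi_ii = 0.5 + 0.5 * phi(father, mother), and for every
      earlier individual j, phi_ij = 0.5 * (phi(father, j) + phi(mother, j)),
      a missing parent contributing 0.

    The result is returned in the pedigree's row order.
    """
    order = ped.topological_order
    idx = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    parent_map = {
        row["individual_id"]: (
            row["father_id"] if row["father_id"] != "0" else None,
            row["mother_id"] if row["mother_id"] != "0" else None,
        )
        for _, row in ped.table.iterrows()
    }
    for k, iid in enumerate(order):
        f, m = parent_map[iid]
        fi = idx[f] if f is not None else None
        mi = idx[m] if m is not None else None
        phi_fm = phi[fi, mi] if (fi is not None and mi is not None) else 0.0
        phi[k, k] = 0.5 + 0.5 * phi_fm
        for j in range(k):
            val = 0.0
            if fi is not None:
                val += 0.5 * phi[fi, j]
            if mi is not None:
                val += 0.5 * phi[mi, j]
            phi[k, j] = phi[j, k] = val
    # back to pedigree row order
    rows = [idx[iid] for iid in ped.individual_ids]
    return KinshipMatrix(phi[np.ix_(rows, rows)], ped.individual_ids)


def select_unrelated(
    kin: KinshipMatrix, threshold: float = DEFAULT_UNRELATED_THRESHOLD
) -> list[str]:
    """Greedily select a mutually unrelated subset of samples.

    An undirected relatedness graph connects pairs with phi >= ``threshold``;
    the vertex of largest current degree is removed repeatedly (ties broken
    by lexicographically smallest sample id) until no edges remain.  The
    survivors, returned in original order, are pairwise unrelated and
    maximal: no removed individual can be re-added without violating the
    threshold.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    n = kin.n
    adj = kin.values >= threshold
    np.fill_diagonal(adj, False)
    alive = np.ones(n, dtype=bool)
    ids = np.array(kin.sample_ids)
    while True:
        degrees = (adj & alive[None, :] & alive[:, None]).sum(axis=1)
        degrees[~alive] = 0
        dmax = degrees.max()
        if dmax == 0:
            break
        candidates = np.flatnonzero(degrees == dmax)
        victim = candidates[np.argmin(ids[candidates])]
        alive[victim] = False
    survivors = [kin.sample_ids[i] for i in np.flatnonzero(alive)]
    return survivors
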