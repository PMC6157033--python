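import numpy as np
import pandas as pd
import pytest

from cpgset_ewas.io_formats import Pedigree
from cpgset_ewas.kinship import kinship_from_pedigree


def make_pedigree(rows):
    return Pedigree(
        pd.DataFrame(
            rows,
            columns=["family_id", "individual_id", "father_id", "mother_id", "sex"],
        )
    )


@pytest.fixture
def trio():
    return make_pedigree(
        [
            ("F1", "dad", "0", "0", "1"),
            ("F1", "mom", "0", "0", "2"),
            ("F1", "kid", "dad", "mom", "1"),
        ]
    )


@pytest.fixture
def nuclear4():
    return make_pedigree(
        [
            ("F1", "dad", "0", "0", "1"),
            ("F1", "mom", "0", "0", "2"),
            ("F1", "kid1", "dad", "mom", "1"),
            ("F1", "kid2", "dad", "mom", "2"),
        ]
    )


@pytest.fixture
def half_sibs():
    return make_pedigree(
        [
            ("F1", "dad", "0", "0", "1"),
            ("F1", "mom1", "0", "0", "2"),
            ("F1", "mom2", "0", "0", "2"),
            ("F1", "kid1", "dad", "mom1", "1"),
            ("F1", "kid2", "dad", "mom2", "2"),
        ]
    )


@pytest.fixture
def trio_kinship(trio):
    return kinship_from_pedigree(trio)


def random_pedigree(rng, n_families=3):
    """Random mix of founders / trios / nuclear families for property tests."""
    rows = []
    for i in range(n_families):
        fam = f"R{i}"
        kind = rng.integers(0, 3)
        if kind == 0:
            rows.append((fam, f"{fam}a", "0", "0", "1"))
        elif kind == 1:
            rows += [
                (fam, f"{fam}a", "0", "0", "1"),
                (fam, f"{fam}b", "0", "0", "2"),
                (fam, f"{fam}c", f"{fam}a", f"{fam}b", "1"),
            ]
        else:
            rows += [
                (fam, f"{fam}a", "0", "0", "1"),
                (fam, f"{fam}b", "0", "0", "2"),
                (fam, f"{fam}c", f"{fam}a", f"{fam}b", "1"),
                (fam, f"{fam}d", f"{fam}a", f"{fam}b", "2"),
                (fam, f"{fam}e", "0", "0", "2"),
                (fam, f"{fam}f", f"{fam}c", f"{fam}e", "1"),
            ]
    return make_pedigree(rows)


def brute_force_max_independent_set(adj):
    """Size of the maximum independent set by subset enumeration (n <= 16)."""
    n = adj.shape[0]
    best = 0
    for mask in range(1 << n):
        members = [i for i in range(n) if mask >> i & 1]
        if all(not adj[i, j] for i in members for j in members if i < j):
            best = max(best, len(members))
    return best
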