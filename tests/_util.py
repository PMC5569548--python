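"""Shared helpers for building random test instances."""

from __future__ import annotations

import numpy as np

from gqlscan.pedigree import (Pedigree, build_relationship_matrix,
                              subset_and_invert)


def random_pedigree(rng: np.random.Generator, n: int,
                    p_founder: float = 0.3) -> Pedigree:
    """Random valid pedigree of ``n`` animals; later animals may draw
    parents among earlier ones, so the ordering is already topological."""
    name = lambda i: f"A{i + 1}"
    rows = []
    for i in range(n):
        if i < 2 or rng.random() < p_founder:
            rows.append((name(i), None, None))
        else:
            s, d = rng.choice(i, size=2, replace=False)
            if rng.random() < 0.15:  # occasional single known parent
                rows.append((name(i), name(s), None))
            else:
                rows.append((name(i), name(s), name(d)))
    return Pedigree.from_records(rows)


def random_ainv(rng: np.random.Generator, n: int) -> np.ndarray:
    """Inverse relationship matrix of a random pedigree subset of size n."""
    ped = random_pedigree(rng, n + rng.integers(0, 5))
    A = build_relationship_matrix(ped)
    ids = list(rng.choice(A.ids, size=n, replace=False))
    try:
        return subset_and_invert(A, ids).values
    except np.linalg.LinAlgError:
        return np.eye(n)


def random_genotype_pair(rng: np.random.Generator, n: int):
    """Two correlated SNP genotype vectors drawn from random haplotype
    frequencies under random mating."""
    f = rng.dirichlet(np.ones(4))  # AB, Ab, aB, ab
    hap_a = np.array([1, 1, 0, 0])
    hap_b = np.array([1, 0, 1, 0])
    h1 = rng.choice(4, size=n, p=f)
    h2 = rng.choice(4, size=n, p=f)
    return hap_a[h1] + hap_a[h2], hap_b[h1] + hap_b[h2]
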