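"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own recursions: the additive
relationship oracle enumerates Wright's ancestor paths, and inbreeding is
derived from path-counted parent relationships.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def random_pedigree_records(rng, n_max: int = 12):
    """Random small pedigree as (id, sire, dam) records, topologically ordered.

    Includes founders, single-known-parent individuals, selfing and
    parent-offspring matings.
    """
    n = int(rng.integers(3, n_max + 1))
    records = []
    ids = []
    for i in range(n):
        name = f"I{i}"
        if i < 2 or rng.random() < 0.25:
            records.append((name, None, None))
        else:
            pick = rng.random()
            sire = ids[int(rng.integers(len(ids)))]
            if pick < 0.15:
                records.append((name, sire, None))  # one parent unknown
            elif pick < 0.30:
                records.append((name, sire, sire))  # selfing
            else:
                dam = ids[int(rng.integers(len(ids)))]
                records.append((name, sire, dam))
        ids.append(name)
    return records


def path_counting_relationship(records):
    """Additive relationship matrix by Wright's path-counting rule.

    a_ij (i != j) sums, over every common ancestor X and every pair of
    parent-link paths from i and j up to X sharing no node except X,
    (1/2)^(links) * (1 + F_X).  a_ii = 1 + F_i with
    F_i = 0.5 * a(sire_i, dam_i).  Parent links are enumerated per slot, so
    selfing contributes two edges to the same parent.
    """
    parents = {ind: (s, d) for ind, s, d in records}
    ids = [ind for ind, _, _ in records]

    @lru_cache(maxsize=None)
    def ancestor_paths(i: str) -> tuple[tuple[str, ...], ...]:
        paths = [(i,)]
        for parent in parents[i]:
            if parent is None:
                continue
            paths.extend((i,) + p for p in ancestor_paths(parent))
        return tuple(paths)

    @lru_cache(maxsize=None)
    def inbreeding_of(x: str) -> float:
        s, d = parents[x]
        if s is None or d is None:
            return 0.0
        return 0.5 * rel(s, d)

    @lru_cache(maxsize=None)
    def rel(i: str, j: str) -> float:
        if i == j:
            return 1.0 + inbreeding_of(i)
        total = 0.0
        for p1 in ancestor_paths(i):
            for p2 in ancestor_paths(j):
                if p1[-1] != p2[-1]:
                    continue
                top = p1[-1]
                if set(p1[:-1]) & set(p2):
                    continue
                if set(p2[:-1]) & set(p1):
                    continue
                links = (len(p1) - 1) + (len(p2) - 1)
                total += 0.5**links * (1.0 + inbreeding_of(top))
        return total

    n = len(ids)
    out = np.zeros((n, n))
    for a, i in enumerate(ids):
        for b, j in enumerate(ids):
            if b < a:
                continue
            out[a, b] = out[b, a] = rel(i, j)
    return ids, out
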