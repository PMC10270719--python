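"""Brute-force Betti numbers by GF(2) rank-nullity, independent of the
reduction algorithm under test.

For the sublevel Vietoris–Rips complex at a fixed scale eps, builds the
full boundary matrices ∂1 (edges → vertices) and ∂2 (triangles → edges)
as dense 0/1 arrays and computes

    Betti_0 = #vertices − rank(∂1)
    Betti_1 = nullity(∂1) − rank(∂2) = #edges − rank(∂1) − rank(∂2)

with plain Gaussian elimination over GF(2).
"""

import itertools

import numpy as np


def gf2_rank(m: np.ndarray) -> int:
    m = (np.asarray(m, dtype=np.uint8) % 2).copy()
    rank = 0
    rows, cols = m.shape
    for c in range(cols):
        pivots = np.nonzero(m[rank:, c])[0]
        if pivots.size == 0:
            continue
        p = rank + pivots[0]
        m[[rank, p]] = m[[p, rank]]
        elim = np.nonzero(m[:, c])[0]
        for r in elim:
            if r != rank:
                m[r] ^= m[rank]
        rank += 1
        if rank == rows:
            break
    return rank


def betti_numbers(d: np.ndarray, eps: float) -> tuple[int, int]:
    """(Betti_0, Betti_1) of the Rips complex of ``d`` at scale ``eps``."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if eps < 0.0:  # vertices enter at scale 0: the complex is empty before
        return 0, 0
    edges = [(i, j) for i, j in itertools.combinations(range(n), 2)
             if d[i, j] <= eps]
    eidx = {e: k for k, e in enumerate(edges)}
    tris = [(i, j, k) for i, j, k in itertools.combinations(range(n), 3)
            if max(d[i, j], d[i, k], d[j, k]) <= eps]

    b1 = np.zeros((n, len(edges)), dtype=np.uint8)
    for col, (i, j) in enumerate(edges):
        b1[i, col] = 1
        b1[j, col] = 1
    b2 = np.zeros((len(edges), len(tris)), dtype=np.uint8)
    for col, (i, j, k) in enumerate(tris):
        b2[eidx[(i, j)], col] = 1
        b2[eidx[(i, k)], col] = 1
        b2[eidx[(j, k)], col] = 1

    rank1 = gf2_rank(b1) if edges else 0
    rank2 = gf2_rank(b2) if tris else 0
    betti0 = n - rank1
    betti1 = len(edges) - rank1 - rank2
    return betti0, betti1


def cycles_homologous(d: np.ndarray, eps: float,
                      cycle_a, cycle_b) -> bool:
    """True iff two GF(2) edge cycles differ by a boundary of triangles
    present at scale ``eps`` (i.e. represent the same homology class)."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    edges = [(i, j) for i, j in itertools.combinations(range(n), 2)
             if d[i, j] <= eps]
    eidx = {e: k for k, e in enumerate(edges)}
    tris = [(i, j, k) for i, j, k in itertools.combinations(range(n), 3)
            if max(d[i, j], d[i, k], d[j, k]) <= eps]
    b2 = np.zeros((len(edges), len(tris)), dtype=np.uint8)
    for col, (i, j, k) in enumerate(tris):
        b2[eidx[(i, j)], col] = 1
        b2[eidx[(i, k)], col] = 1
        b2[eidx[(j, k)], col] = 1
    target = np.zeros((len(edges), 1), dtype=np.uint8)
    for e in set(map(tuple, cycle_a)) ^ set(map(tuple, cycle_b)):
        target[eidx[tuple(sorted(e))], 0] ^= 1
    if not target.any():
        return True
    return gf2_rank(np.hstack([b2, target])) == gf2_rank(b2)


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Symmetric matrix with U(0,1) off-diagonal entries and zero diagonal."""
    m = rng.uniform(0.0, 1.0, size=(n, n))
    d = np.triu(m, k=1)
    return d + d.T
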