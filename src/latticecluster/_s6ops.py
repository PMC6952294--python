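"""Linear algebra of the Selling (S6) representation.

A lattice basis (a, b, c) is extended to the Delaunay tetrad
(a, b, c, d) with d = -(a + b + c).  The six Selling scalars are the
pairwise dot products

    s = (b.c, a.c, a.b, a.d, b.d, c.d)

indexed by the vector pairs in ``PAIRS``.  This module provides the
exact integer matrices that act on S6 vectors:

* ``P24_MATRICES`` -- the 24 coordinate permutations of S6 induced by
  the even/odd permutations of the four tetrad vectors (relabelling a
  lattice basis never changes the lattice).
* ``EXCHANGES`` -- the 12 Selling "boundary exchange" operators.  For a
  scalar s_i = u.v the exchange replaces u by -u and adds u to the two
  tetrad vectors not in {u, v}; this flips the sign of s_i and maps the
  tetrad to another tetrad of the same lattice.  There are two variants
  per boundary (negate u or negate v).

All matrices are unimodular integer matrices; they map realizable S6
vectors to realizable S6 vectors of the same lattice.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

#: tetrad-vector index pairs whose dot products form s1..s6
PAIRS = [(1, 2), (0, 2), (0, 1), (0, 3), (1, 3), (2, 3)]


def _perm24() -> list[list[int]]:
    out = []
    for p in permutations(range(4)):
        mapping = []
        for (u, v) in PAIRS:
            mapping.append(PAIRS.index(tuple(sorted((p[u], p[v])))))
        out.append(mapping)
    return out


#: index form: s_permuted = s[P24[k]]
P24 = _perm24()

#: matrix form: s_permuted = P24_MATRICES[k] @ s
P24_MATRICES = np.array([np.eye(6)[m, :] for m in P24])

# The 12 boundary-exchange operators as exact integer S6 matrices,
# ordered (boundary 0 variant 0, boundary 0 variant 1, boundary 1
# variant 0, ...).  Derived from the tetrad algebra; each matrix is an
# involution-like unimodular map that negates the corresponding scalar.
EXCHANGES = np.array([
    [[-1, 0, 0, 0, 0, 0], [1, 1, 0, 0, 0, 0], [1, 0, 0, 0, 1, 0],
     [-1, 0, 0, 1, 0, 0], [1, 0, 1, 0, 0, 0], [1, 0, 0, 0, 0, 1]],
    [[-1, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 1], [1, 0, 1, 0, 0, 0],
     [-1, 0, 0, 1, 0, 0], [1, 0, 0, 0, 1, 0], [1, 1, 0, 0, 0, 0]],
    [[1, 1, 0, 0, 0, 0], [0, -1, 0, 0, 0, 0], [0, 1, 0, 1, 0, 0],
     [0, 1, 1, 0, 0, 0], [0, -1, 0, 0, 1, 0], [0, 1, 0, 0, 0, 1]],
    [[0, 1, 0, 0, 0, 1], [0, -1, 0, 0, 0, 0], [0, 1, 1, 0, 0, 0],
     [0, 1, 0, 1, 0, 0], [0, -1, 0, 0, 1, 0], [1, 1, 0, 0, 0, 0]],
    [[1, 0, 1, 0, 0, 0], [0, 0, 1, 1, 0, 0], [0, 0, -1, 0, 0, 0],
     [0, 1, 1, 0, 0, 0], [0, 0, 1, 0, 1, 0], [0, 0, -1, 0, 0, 1]],
    [[0, 0, 1, 0, 1, 0], [0, 1, 1, 0, 0, 0], [0, 0, -1, 0, 0, 0],
     [0, 0, 1, 1, 0, 0], [1, 0, 1, 0, 0, 0], [0, 0, -1, 0, 0, 1]],
    [[1, 0, 0, -1, 0, 0], [0, 0, 1, 1, 0, 0], [0, 1, 0, 1, 0, 0],
     [0, 0, 0, -1, 0, 0], [0, 0, 0, 1, 1, 0], [0, 0, 0, 1, 0, 1]],
    [[1, 0, 0, -1, 0, 0], [0, 1, 0, 1, 0, 0], [0, 0, 1, 1, 0, 0],
     [0, 0, 0, -1, 0, 0], [0, 0, 0, 1, 0, 1], [0, 0, 0, 1, 1, 0]],
    [[0, 0, 1, 0, 1, 0], [0, 1, 0, 0, -1, 0], [1, 0, 0, 0, 1, 0],
     [0, 0, 0, 1, 1, 0], [0, 0, 0, 0, -1, 0], [0, 0, 0, 0, 1, 1]],
    [[1, 0, 0, 0, 1, 0], [0, 1, 0, 0, -1, 0], [0, 0, 1, 0, 1, 0],
     [0, 0, 0, 0, 1, 1], [0, 0, 0, 0, -1, 0], [0, 0, 0, 1, 1, 0]],
    [[0, 1, 0, 0, 0, 1], [1, 0, 0, 0, 0, 1], [0, 0, 1, 0, 0, -1],
     [0, 0, 0, 1, 0, 1], [0, 0, 0, 0, 1, 1], [0, 0, 0, 0, 0, -1]],
    [[1, 0, 0, 0, 0, 1], [0, 1, 0, 0, 0, 1], [0, 0, 1, 0, 0, -1],
     [0, 0, 0, 0, 1, 1], [0, 0, 0, 1, 0, 1], [0, 0, 0, 0, 0, -1]],
], dtype=float)


def exchange_matrix(boundary: int, variant: int = 0) -> np.ndarray:
    """Return the exchange operator for one of the six Selling boundaries."""
    if not 0 <= boundary < 6 or variant not in (0, 1):
        raise ValueError("boundary must be 0..5, variant 0 or 1")
    return EXCHANGES[2 * boundary + variant]


def _reflections() -> np.ndarray:
    mats = []
    for i in range(6):
        m = np.eye(6)
        m[i, i] = -1.0
        mats.append(m)
    return np.array(mats)


#: single-coordinate sign flips R_i
REFLECTIONS = _reflections()


def _candidate_stack() -> np.ndarray:
    """Candidate images used by the CS6Dist minimization.

    The stack is {T @ g : g in P24, T in {I} u {R_i @ M_jv, i != j}}
    deduplicated, where M_jv are the 12 exchange operators and R_i the
    coordinate sign flips.  See docs/methods.md for how this set was
    calibrated; the plain exchange operators alone (without the
    reflection factor) are deliberately excluded.
    """
    tset = [np.eye(6)]
    for i in range(6):
        for j in range(6):
            if i == j:
                continue
            for v in (0, 1):
                tset.append(REFLECTIONS[i] @ EXCHANGES[2 * j + v])
    seen = {}
    for t in tset:
        for g in P24_MATRICES:
            m = t @ g
            seen[np.round(m).astype(np.int8).tobytes()] = m
    return np.array(list(seen.values()))


#: the full candidate image stack for cs6dist (744 integer matrices)
CANDIDATES = _candidate_stack()
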