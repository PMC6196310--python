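"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: alignment is checked
by exhaustive enumeration of all global alignments, the tree kernel by a
literal expansion of the recursive definition over explicitly enumerated
child subsequences, and the conic invariant by rotating the quadratic-form
matrix with numpy.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from typing import Sequence, Tuple

import numpy as np


def brute_force_alignment_score(a: Sequence[str], b: Sequence[str],
                                match: float = 2.0, mismatch: float = -2.0,
                                gap: float = -2.0) -> float:
    """Maximum score over every global alignment, by exhaustive recursion."""
    a, b = tuple(a), tuple(b)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            options.append(sub + best(i + 1, j + 1))
        if i < len(a):
            options.append(gap + best(i + 1, j))
        if j < len(b):
            options.append(gap + best(i, j + 1))
        return max(options)

    return best(0, 0)


def brute_force_delta(n1, n2, mu: float, lam: float) -> float:
    """Literal expansion of the smoothed partial-tree delta.

    Leaves score mu*lam*sigma; internal pairs multiply mu*sigma into
    lam^2 plus an explicitly enumerated sum over equal-length child index
    subsequences weighted by lam^(span1 + span2).
    """
    sigma = 1.0 if (n1.kind == n2.kind and n1.label == n2.label) else 0.0
    if sigma == 0.0:
        return 0.0
    if not n1.children and not n2.children:
        return mu * lam * sigma
    c1, c2 = n1.children, n2.children
    total = 0.0
    for p in range(1, min(len(c1), len(c2)) + 1):
        for idx1 in itertools.combinations(range(len(c1)), p):
            d1 = idx1[-1] - idx1[0] + 1
            for idx2 in itertools.combinations(range(len(c2)), p):
                d2 = idx2[-1] - idx2[0] + 1
                prod = 1.0
                for i, j in zip(idx1, idx2):
                    prod *= brute_force_delta(c1[i], c2[j], mu, lam)
                    if prod == 0.0:
                        break
                total += lam ** (d1 + d2) * prod
    return mu * sigma * (lam * lam + total)


def brute_force_kernel(t1, t2, mu: float, lam: float) -> float:
    return sum(brute_force_delta(a, b, mu, lam)
               for a in t1.root.nodes() for b in t2.root.nodes())


def rotated_conic_coefficients(p20: float, p11: float, p02: float,
                               angle: float) -> Tuple[float, float, float]:
    """Coefficients of the quadratic form after rotating the plane."""
    m = np.array([[p20, p11 / 2.0], [p11 / 2.0, p02]])
    c, s = np.cos(angle), np.sin(angle)
    r = np.array([[c, -s], [s, c]])
    q = r @ m @ r.T
    return q[0, 0], 2.0 * q[0, 1], q[1, 1]
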