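"""Smoothed partial tree kernel.

``K(T1, T2)`` sums, over every node pair, the weighted count of shared
partial-tree fragments rooted at that pair.  Fragment matching is graded by
a node similarity sigma; mu decays with fragment depth and lambda with
child-subsequence width and gaps.  The child-subsequence sum is evaluated
with a cubic dynamic program instead of explicit enumeration, and deltas
are cached on structural subtree keys so repeated subtrees across a corpus
are paid for once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .grct import GRCTTree, TreeNode

EXACT_LABEL = "EXACT_LABEL"
LEXICAL_TABLE = "LEXICAL_TABLE"


@dataclass(frozen=True)
class KernelParams:
    mu: float = 0.4
    lam: float = 0.4
    similarity_mode: str = EXACT_LABEL
    normalize: bool = True
    lexical_table: Optional[Dict[Tuple[str, str], float]] = None

    def __post_init__(self):
        if not (0 < self.mu <= 1) or not (0 < self.lam <= 1):
            raise ValueError("decay factors mu and lambda must lie in (0, 1]")
        if self.similarity_mode not in (EXACT_LABEL, LEXICAL_TABLE):
            raise ValueError(f"unknown similarity mode {self.similarity_mode!r}")
        if self.lexical_table:
            for pair, value in self.lexical_table.items():
                if not (0.0 <= value <= 1.0):
                    raise ValueError(
                        f"similarity for {pair} outside [0, 1]: {value}")


def load_lexical_table(path) -> Dict[Tuple[str, str], float]:
    """Read a three-column label_a<TAB>label_b<TAB>similarity file into a
    symmetric lookup table."""
    table: Dict[Tuple[str, str], float] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            a, b, value = parts[0], parts[1], float(parts[2])
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{path}:{lineno}: similarity outside [0, 1]")
            table[(a, b)] = value
            table[(b, a)] = value
    return table


def node_similarity(a: TreeNode, b: TreeNode, params: KernelParams) -> float:
    """Graded node similarity sigma in [0, 1]."""
    if a.kind != b.kind:
        return 0.0
    if params.similarity_mode == LEXICAL_TABLE and a.kind == "LEX":
        if a.label == b.label:
            return 1.0
        return (params.lexical_table or {}).get((a.label, b.label), 0.0)
    return 1.0 if a.label == b.label else 0.0


class _DeltaComputer:
    """Memoized evaluation of the smoothed partial tree delta.

    Memoization is keyed on structural subtree keys (label + kind + child
    keys), so identical subtrees — extremely common across corpus-scale
    Gram computations — share one cached value.
    """

    def __init__(self, params: KernelParams):
        self.params = params
        self._keys: Dict[int, int] = {}       # id(node) -> structural key
        self._interned: Dict[Tuple, int] = {}
        self._cache: Dict[Tuple[int, int], float] = {}
        self._sigma_cache: Dict[Tuple, float] = {}

    def key(self, node: TreeNode) -> int:
        cached = self._keys.get(id(node))
        if cached is not None:
            return cached
        struct = (node.label, node.kind, tuple(self.key(c) for c in node.children))
        interned = self._interned.setdefault(struct, len(self._interned))
        self._keys[id(node)] = interned
        return interned

    def sigma(self, a: TreeNode, b: TreeNode) -> float:
        sig_key = (a.label, a.kind, b.label, b.kind)
        value = self._sigma_cache.get(sig_key)
        if value is None:
            value = node_similarity(a, b, self.params)
            self._sigma_cache[sig_key] = value
        return value

    def delta(self, a: TreeNode, b: TreeNode) -> float:
        ka, kb = self.key(a), self.key(b)
        cached = self._cache.get((ka, kb))
        if cached is not None:
            return cached
        mu, lam = self.params.mu, self.params.lam
        sigma = self.sigma(a, b)
        if sigma == 0.0:
            value = 0.0
        elif not a.children and not b.children:
            value = mu * lam * sigma
        else:
            value = mu * sigma * (lam * lam +
                                  self._subsequence_sum(a.children, b.children))
        self._cache[(ka, kb)] = value
        self._cache[(kb, ka)] = value
        return value

    def _subsequence_sum(self, ca: List[TreeNode], cb: List[TreeNode]) -> float:
        """Sum over equal-length non-empty child subsequences of
        lambda^(d1 + d2) * prod(delta) with d the index span of each
        subsequence."""
        m, l = len(ca), len(cb)
        if m == 0 or l == 0:
            return 0.0
        lam = self.params.lam
        pair_delta = [[self.delta(ca[i], cb[j]) for j in range(l)]
                      for i in range(m)]
        total = 0.0
        # T[i][j] holds sum over subsequence pairs of length p whose last
        # elements lie at positions <= i, <= j, discounted by lambda per
        # index step away from (i, j); T for p = 0 is identically 1.
        t_prev = [[1.0] * (l + 1) for _ in range(m + 1)]
        for p in range(1, min(m, l) + 1):
            w = [[0.0] * (l + 1) for _ in range(m + 1)]
            t_cur = [[0.0] * (l + 1) for _ in range(m + 1)]
            for i in range(1, m + 1):
                for j in range(1, l + 1):
                    d = pair_delta[i - 1][j - 1]
                    if d != 0.0 and (p == 1 or t_prev[i - 1][j - 1] != 0.0):
                        w[i][j] = d * lam * lam * t_prev[i - 1][j - 1]
                        total += w[i][j]
                    t_cur[i][j] = (w[i][j] + lam * t_cur[i - 1][j]
                                   + lam * t_cur[i][j - 1]
                                   - lam * lam * t_cur[i - 1][j - 1])
            t_prev = t_cur
        return total


def delta_sptk(a: TreeNode, b: TreeNode, params: KernelParams,
               _computer: Optional[_DeltaComputer] = None) -> float:
    """Weighted count of shared fragments rooted at the two nodes: the leaf
    case is mu * lambda * sigma, the internal case multiplies mu * sigma
    into lambda^2 plus the child-subsequence expansion."""
    computer = _computer or _DeltaComputer(params)
    return computer.delta(a, b)


def _raw_kernel(t1: GRCTTree, t2: GRCTTree, computer: _DeltaComputer) -> float:
    total = 0.0
    for n1 in t1.root.nodes():
        for n2 in t2.root.nodes():
            total += computer.delta(n1, n2)
    return total


def kernel(t1: GRCTTree, t2: GRCTTree,
           params: KernelParams = KernelParams(),
           _computer: Optional[_DeltaComputer] = None) -> float:
    """Tree kernel value: double sum of deltas over all node pairs,
    optionally normalized by the self-kernel geometric mean."""
    computer = _computer or _DeltaComputer(params)
    value = _raw_kernel(t1, t2, computer)
    if not params.normalize:
        return value
    self1 = _raw_kernel(t1, t1, computer)
    self2 = _raw_kernel(t2, t2, computer)
    if self1 <= 0 or self2 <= 0:
        raise ValueError("zero self-kernel under normalization "
                         "(degenerate tree or similarity)")
    return value / np.sqrt(self1 * self2)


@dataclass
class KernelMatrix:
    row_ids: List[str]
    col_ids: List[str]
    values: np.ndarray

    def write_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t" + "\t".join(self.col_ids) + "\n")
            for rid, row in zip(self.row_ids, self.values):
                fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def kernel_matrix(rows: Sequence[Tuple[str, GRCTTree]],
                  cols: Optional[Sequence[Tuple[str, GRCTTree]]] = None,
                  params: KernelParams = KernelParams()) -> KernelMatrix:
    """Assemble a (normalized) Gram matrix; duplicate trees are detected by
    their structural key and computed once, and the symmetric case fills
    both triangles from one."""
    if not rows:
        raise ValueError("empty row list")
    symmetric = cols is None
    cols = rows if symmetric else cols
    if not cols:
        raise ValueError("empty column list")
    computer = _DeltaComputer(params)

    def unique(trees: Sequence[Tuple[str, GRCTTree]]):
        keys = []
        reps: Dict[int, GRCTTree] = {}
        for _, tree in trees:
            k = computer.key(tree.root)
            keys.append(k)
            reps.setdefault(k, tree)
        return keys, reps

    row_keys, row_reps = unique(rows)
    col_keys, col_reps = unique(cols)
    all_reps = {**row_reps, **col_reps}

    selfk: Dict[int, float] = {}
    if params.normalize:
        for k, tree in all_reps.items():
            selfk[k] = _raw_kernel(tree, tree, computer)
            if selfk[k] <= 0:
                raise ValueError("zero self-kernel under normalization")

    raw: Dict[Tuple[int, int], float] = {}
    for rk in sorted(row_reps):
        for ck in sorted(col_reps):
            if (rk, ck) in raw:
                continue
            value = _raw_kernel(row_reps[rk], col_reps.get(ck, all_reps[ck]),
                                computer)
            raw[(rk, ck)] = value
            raw[(ck, rk)] = value

    values = np.empty((len(rows), len(cols)))
    for i, rk in enumerate(row_keys):
        for j, ck in enumerate(col_keys):
            v = raw[(rk, ck)]
            if params.normalize:
                v /= np.sqrt(selfk[rk] * selfk[ck])
            values[i, j] = v
    return KernelMatrix([rid for rid, _ in rows], [cid for cid, _ in cols], values)
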