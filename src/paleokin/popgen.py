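"""f-statistics with weighted block jackknife, and neighbor joining.

Outgroup-f3(O; A, B) = E[(a - o)(b - o)] measures shared drift between A
and B relative to the outgroup; f4(A, B; C, D) = E[(a - b)(c - d)] tests
treeness.  Standard errors use a leave-one-block-out weighted jackknife
(blocks of 5 Mb by physical position, or per-cM for synthetic maps), with
block SNP counts as weights, and Z = value / SE.  1/f3 converts shared
drift to a distance for neighbor-joining tree construction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GroupFrequencies",
    "FStatResult",
    "outgroup_f3",
    "f4",
    "f3_distance_matrix",
    "neighbor_joining",
    "tree_splits",
    "blocks_from_positions",
]


@dataclass
class GroupFrequencies:
    """Per-group per-SNP allele frequencies with jackknife block ids.

    Pseudohaploid groups of size one contribute their single allele as the
    frequency (0 or 1); missing data are NaN.
    """

    groups: list[str]
    freq: np.ndarray  # (n_groups, n_snps), NaN = missing
    block: np.ndarray  # (n_snps,) int block ids
    transversion: Optional[np.ndarray] = None  # bool mask

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        self.block = np.asarray(self.block, dtype=np.int64)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.freq) < -1e-9 or np.nanmax(self.freq) > 1 + 1e-9:
                raise ValueError("frequencies must lie in [0, 1]")

    def row(self, name: str) -> np.ndarray:
        return self.freq[self.groups.index(name)]


def blocks_from_positions(
    chrom: np.ndarray, pos: np.ndarray, block_size: float = 5e6
) -> np.ndarray:
    """Contiguous jackknife block ids from per-SNP positions."""
    block = np.zeros(len(pos), dtype=np.int64)
    offset = 0
    for c in dict.fromkeys(chrom):
        m = np.asarray(chrom) == c
        b = (np.asarray(pos)[m] // block_size).astype(np.int64)
        _, b = np.unique(b, return_inverse=True)
        block[m] = b + offset
        offset += (b.max() + 1) if len(b) else 0
    return block


@dataclass
class FStatResult:
    value: float
    se: float
    z: float
    n_blocks: int
    n_snps: int


def _weighted_jackknife(per_site: np.ndarray, block: np.ndarray) -> FStatResult:
    """Weighted delete-one-block jackknife for a mean statistic."""
    n = len(per_site)
    theta = float(per_site.mean())
    ids, inv = np.unique(block, return_inverse=True)
    g = len(ids)
    if g < 2:
        return FStatResult(theta, float("nan"), float("nan"), g, n)
    w = np.bincount(inv).astype(float)
    sums = np.bincount(inv, weights=per_site)
    total = per_site.sum()
    loo = (total - sums) / (n - w)
    W = float(n)
    h = W / w
    pseudo = h * theta - (h - 1.0) * loo
    theta_j = g * theta - float(((1.0 - w / W) * loo).sum())
    var = float((((pseudo - theta_j) ** 2) / (h - 1.0)).sum()) / g
    se = math.sqrt(var)
    z = theta / se if se > 0 else float("nan")
    return FStatResult(theta, se, z, g, n)


def _select_sites(gf: GroupFrequencies, names, tv_only: bool):
    rows = [gf.row(n) for n in names]
    ok = ~np.any(np.isnan(np.vstack(rows)), axis=0)
    if tv_only:
        if gf.transversion is None:
            raise ValueError("no transversion annotation on this panel")
        ok &= gf.transversion
    if ok.sum() == 0:
        raise ValueError("no sites with complete data for these groups")
    return [r[ok] for r in rows], gf.block[ok]


def outgroup_f3(
    gf: GroupFrequencies, outgroup: str, a: str, b: str, tv_only: bool = False
) -> FStatResult:
    """f3(outgroup; a, b): mean over SNPs of (a - o)(b - o)."""
    (o, fa, fb), block = _select_sites(gf, (outgroup, a, b), tv_only)
    return _weighted_jackknife((fa - o) * (fb - o), block)


def f4(
    gf: GroupFrequencies, a: str, b: str, c: str, d: str, tv_only: bool = False
) -> FStatResult:
    """f4(a, b; c, d): mean over SNPs of (a - b)(c - d)."""
    (fa, fb, fc, fd), block = _select_sites(gf, (a, b, c, d), tv_only)
    return _weighted_jackknife((fa - fb) * (fc - fd), block)


def f3_distance_matrix(
    f3_values: dict[frozenset, float], labels: list[str]
) -> np.ndarray:
    """Distance matrix d(i, j) = 1 / f3(O; i, j); zero diagonal."""
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        key = frozenset((labels[i], labels[j]))
        f3v = f3_values[key]
        if f3v <= 0:
            raise ValueError(
                f"nonpositive f3 for pair ({labels[i]}, {labels[j]}): {f3v}"
            )
        d[i, j] = d[j, i] = 1.0 / f3v
    return d


# ---------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------

@dataclass
class _Node:
    label: Optional[str]
    children: list = field(default_factory=list)  # (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(
            f"{c.newick()}:{bl:.6g}" for c, bl in self.children
        )
        return f"({inner})"

    def leaves(self) -> set:
        if not self.children:
            return {self.label}
        out = set()
        for c, _ in self.children:
            out |= c.leaves()
        return out


def neighbor_joining(
    d: np.ndarray, labels: list[str], outgroup: Optional[str] = None
) -> str:
    """Standard neighbor-joining agglomeration; returns a newick string.

    Branch lengths are retained (clamped at zero); ties in the Q criterion
    break to the lexicographically smallest pair for determinism.  With an
    outgroup given, the tree is written rooted on the outgroup's edge.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    nodes = [_Node(lab) for lab in labels]
    active = list(range(n))
    dist = {
        (i, j): d[i, j] for i in range(n) for j in range(n) if i < j
    }

    def get(i, j):
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    next_id = n
    node_of = {i: nodes[i] for i in range(n)}
    while len(active) > 2:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(sorted(active), 2):
            q = (m - 2) * get(i, j) - r[i] - r[j]
            key = (q, node_of[i].label or "", node_of[j].label or "")
            if best is None or q < best[0][0] - 1e-12 or (
                abs(q - best[0][0]) <= 1e-12 and key < best[0]
            ):
                best = (key, i, j)
        _, i, j = best
        li = 0.5 * get(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = get(i, j) - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(None, [(node_of[i], li), (node_of[j], lj)])
        node_of[next_id] = new
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = 0.5 * (
                get(i, k) + get(j, k) - get(i, j)
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    i, j = active
    bl = max(get(i, j), 0.0)
    root = _Node(None, [(node_of[i], 0.5 * bl), (node_of[j], 0.5 * bl)])

    if outgroup is not None:
        if outgroup not in labels:
            raise ValueError(f"outgroup {outgroup!r} not among labels")
        root = _reroot_on_leaf_edge(root, outgroup)
    return root.newick() + ";"


def _edges(node, parent=None):
    for c, bl in node.children:
        yield (node, c, bl)
        yield from _edges(c, node)


def _reroot_on_leaf_edge(root: _Node, leaf: str) -> _Node:
    """Re-root an unrooted (arbitrarily rooted) tree on a leaf's edge."""
    # build adjacency
    adj: dict[int, list] = {}
    nodes: dict[int, _Node] = {}

    def add(a, b, w):
        adj.setdefault(id(a), []).append((id(b), w))
        adj.setdefault(id(b), []).append((id(a), w))
        nodes[id(a)] = a
        nodes[id(b)] = b

    for a, b, w in _edges(root):
        add(a, b, w)
    target = next(
        nid for nid, nd in nodes.items() if nd.label == leaf and not nd.children
    )
    (nbr, w0) = adj[target][0]

    def build(nid, avoid) -> _Node:
        nd = nodes[nid]
        kids = [
            (build(k, nid), wl) for k, wl in adj[nid] if k != avoid
        ]
        # suppress the old degree-2 root
        if nd.label is None and len(kids) == 1:
            child, wl = kids[0]
            return child if not child.children else _Node(
                child.label, child.children
            )
        return _Node(nd.label, kids) if kids else _Node(nd.label)

    inner = build(nbr, target)
    return _Node(None, [(nodes[target], 0.5 * w0), (inner, 0.5 * w0)])


def tree_splits(newick: str) -> set[frozenset]:
    """Nontrivial leaf bipartitions (as the smaller side's leaf sets)."""
    tree = _parse_newick(newick)
    all_leaves = frozenset(tree.leaves())
    splits = set()

    def walk(node):
        for c, _ in node.children:
            lv = frozenset(c.leaves())
            if 1 < len(lv) < len(all_leaves) - 1:
                other = all_leaves - lv
                splits.add(min(lv, other, key=lambda s: (len(s), sorted(s))))
            walk(c)

    walk(tree)
    return splits


def _parse_newick(s: str) -> _Node:
    s = s.strip().rstrip(";")
    pos = [0]

    def parse() -> _Node:
        if s[pos[0]] == "(":
            pos[0] += 1
            kids = []
            while True:
                child = parse()
                bl = 0.0
                if pos[0] < len(s) and s[pos[0]] == ":":
                    pos[0] += 1
                    start = pos[0]
                    while pos[0] < len(s) and s[pos[0]] not in ",()":
                        pos[0] += 1
                    bl = float(s[start : pos[0]])
                kids.append((child, bl))
                if s[pos[0]] == ",":
                    pos[0] += 1
                    continue
                if s[pos[0]] == ")":
                    pos[0] += 1
                    break
            return _Node(None, kids)
        start = pos[0]
        while pos[0] < len(s) and s[pos[0]] not in ":,()":
            pos[0] += 1
        return _Node(s[start : pos[0]])

    return parse()
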