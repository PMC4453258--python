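"""Topology-based diversification-shift detection under the ERM (Yule) null.

The null model is the equal-rates Markov (ERM) process: every extant
lineage splits at the same rate. Under ERM the size of a designated
daughter of an n-tip clade is uniform on 1..n-1, so an internal branch
whose focal clade is far larger (or smaller) than its sister carries
evidence of a rate shift.

The alternative is a two-rate pure-birth partition: if the focal clade
diversifies at rho times the sibling rate, the conditional law of the
focal size k given the parent size m is the tilted-geometric

    P(k | m, rho) = rho**(k-1) / sum_{j=1..m-1} rho**(j-1),

which reduces to the ERM value 1/(m-1) at rho = 1. Per-branch support is

    delta1(b) = sup_rho log P(k | m, rho) - log P_ERM(k | m)

and the headline statistic contrasts a shift on the stem b against the
rival hypothesis of a nested shift inside the focal clade:

    delta2(b) = delta1(k | m) - delta1(max(l, r) | k),

where l, r are the focal clade's two daughter sizes. Significance is
Monte-Carlo: random resolutions of soft polytomies, and ERM null trees
of the same tip count scanned for their maximum delta2 (familywise,
tree-wide control) and for per-size-class maxima (local diagnostics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .tree import Node, RootedTree, TreeError

__all__ = [
    "SplitCounts",
    "BranchShiftScore",
    "NullSettings",
    "erm_split_prob",
    "tilted_split_ml",
    "delta_stats",
    "resolve_polytomies",
    "branch_shift_scan",
    "detect_shifts",
]


# ----------------------------------------------------------------------
# ERM split probability and the tilted two-rate likelihood

def erm_split_prob(i: int, n: int) -> float:
    """P(designated daughter of an n-tip ERM clade has i tips) = 1/(n-1)."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if not 1 <= i <= n - 1:
        raise ValueError(f"need 1 <= i <= n-1, got i={i}, n={n}")
    return 1.0 / (n - 1)


@dataclass(frozen=True)
class TiltedFit:
    """MLE of the tilted-geometric split law. ``rho`` is None on the boundary."""

    rho: float | None
    logL: float
    boundary: bool


def _tilted_logL(k: int, m: int, log_rho: float) -> float:
    # log P(k|m,rho) with x = log rho, stable via logsumexp
    j = np.arange(m - 1)
    return (k - 1) * log_rho - logsumexp(j * log_rho)


@lru_cache(maxsize=None)
def tilted_split_ml(k: int, m: int) -> TiltedFit:
    """Maximize the tilted-geometric partition likelihood P(k | m, rho) over rho.

    The score equation is E_rho[J] = k-1 where J has the tilted law on
    0..m-2; the expectation is strictly increasing in rho, so the root is
    found by bracketed solving on log rho. At k in {1, m-1} the supremum
    is attained in the limit rho -> 0 (or inf) with sup log L = 0.
    """
    if m < 2:
        raise ValueError(f"need m >= 2, got {m}")
    if not 1 <= k <= m - 1:
        raise ValueError(f"need 1 <= k <= m-1, got k={k}, m={m}")
    if m == 2:
        # only one possible split; L = 1 for every rho
        return TiltedFit(rho=1.0, logL=0.0, boundary=False)
    if k == 1 or k == m - 1:
        return TiltedFit(rho=None, logL=0.0, boundary=True)

    j = np.arange(m - 1)
    target = float(k - 1)

    def mean_j(x: float) -> float:
        w = j * x
        w -= w.max()
        p = np.exp(w)
        return float((j * p).sum() / p.sum())

    if abs(2 * k - m) < 1e-12:  # perfectly balanced: rho = 1 by symmetry
        x_hat = 0.0
    else:
        lo, hi = -1.0, 1.0
        while mean_j(lo) > target:
            lo *= 2
        while mean_j(hi) < target:
            hi *= 2
        x_hat = brentq(lambda x: mean_j(x) - target, lo, hi, xtol=1e-12)
    return TiltedFit(rho=math.exp(x_hat), logL=_tilted_logL(k, m, x_hat), boundary=False)


# ----------------------------------------------------------------------
# the delta statistics

@dataclass(frozen=True)
class SplitCounts:
    """Tip counts around one internal branch of a (resolved) slice tree.

    m: tips below the branch's parent node; k: tips in the focal clade;
    l, r: the focal clade's two daughter sizes (None for a pendant branch).
    Ghost leaves count as single tips.
    """

    m: int
    k: int
    l: int | None = None
    r: int | None = None

    def __post_init__(self):
        if not 1 <= self.k <= self.m - 1:
            raise ValueError(f"need 1 <= k <= m-1, got k={self.k}, m={self.m}")
        if (self.l is None) != (self.r is None):
            raise ValueError("l and r must be given together")
        if self.l is not None and self.l + self.r != self.k:
            raise ValueError(f"l + r must equal k, got {self.l}+{self.r} != {self.k}")


def _delta1(k: int, m: int) -> float:
    return tilted_split_ml(k, m).logL + math.log(m - 1)


def delta_stats(counts: SplitCounts) -> tuple[float, float]:
    """(delta1, delta2) for one branch.

    delta1 >= 0 always (the tilted family contains the ERM null);
    delta2 may be negative when a nested shift explains the data better.
    A pendant focal clade (k = 1) has delta2 = 0 by convention.
    """
    d1 = _delta1(counts.k, counts.m)
    if counts.k == 1 or counts.l is None:
        return d1, 0.0
    d2 = d1 - _delta1(max(counts.l, counts.r), counts.k)
    return d1, d2


# ----------------------------------------------------------------------
# random resolution of soft polytomies

def resolve_polytomies(tree: RootedTree, rng: np.random.Generator | int) -> RootedTree:
    """Resolve every polytomy by ERM-style sequential random joins.

    Each polytomy's children are joined pairwise, uniformly at random,
    until the node is binary; for a 3-child polytomy each of the three
    rooted resolutions has probability 1/3. New internal nodes carry no
    label; original nodes keep their identity (the returned tree's nodes
    expose ``orig_id`` mapping back to the input tree's node ids).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    def copy_with_ids(node: Node) -> Node:
        new = Node(label=node.label, length=node.length)
        new.orig_id = node.id
        for c in node.children:
            new.add_child(copy_with_ids(c))
        return new

    root = copy_with_ids(tree.root)
    stack = [root]
    while stack:
        node = stack.pop()
        stack.extend(node.children)
        while len(node.children) > 2:
            cs = node.children
            i = int(rng.integers(len(cs)))
            j = int(rng.integers(len(cs) - 1))
            if j >= i:
                j += 1
            a, b = cs[i], cs[j]
            joint = Node()
            joint.orig_id = None
            joint.add_child(a)
            joint.add_child(b)
            node.children = [c for c in cs if c is not a and c is not b]
            node.add_child(joint)
    out = RootedTree(root, validate=False)
    return out


# ----------------------------------------------------------------------
# Monte-Carlo null machinery

def _size_class(k: int) -> int:
    """Size classes for the local null: k grouped on a log2 grid."""
    return k.bit_length() - 1


@dataclass
class NullSettings:
    """Monte-Carlo budgets for the shift scan.

    Defaults are desk-scale; raise ``resolutions`` / ``null_trees`` for
    production runs. All randomness flows from ``seed``.
    """

    resolutions: int = 100
    null_trees: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.resolutions < 1 or self.null_trees < 1:
            raise ValueError("resolutions and null_trees must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def delta1_table(n: int) -> np.ndarray:
    """D[k, m] = delta1(k|m) for 1 <= k < m <= n (NaN elsewhere)."""
    D = np.full((n + 1, n + 1), np.nan)
    for m in range(2, n + 1):
        for k in range(1, m):
            D[k, m] = _delta1(k, m)
    return D


def _erm_branch_counts(n: int, rng: np.random.Generator) -> list[tuple[int, int, int]]:
    """(m, k, j) for every internal branch of one n-tip ERM topology.

    Built by uniform random joins (the coalescent-style construction of
    the ERM shape distribution): j = max daughter size of the focal node.
    """
    sizes = [1] * n
    tops = [0] * n  # max daughter size; 0 marks a leaf
    out: list[tuple[int, int, int]] = []
    cnt = n
    ints = rng.integers(0, 1 << 62, size=2 * (n - 1))
    pos = 0
    while cnt > 1:
        i = int(ints[pos] % cnt)
        j = int(ints[pos + 1] % (cnt - 1))
        pos += 2
        if j >= i:
            j += 1
        sa, sb = sizes[i], sizes[j]
        m = sa + sb
        if sa > 1:
            out.append((m, sa, tops[i]))
        if sb > 1:
            out.append((m, sb, tops[j]))
        # overwrite i with the join; remove j by swap-pop
        sizes[i], tops[i] = m, max(sa, sb)
        last = cnt - 1
        sizes[j], tops[j] = sizes[last], tops[last]
        sizes.pop()
        tops.pop()
        cnt -= 1
    return out


def erm_null_max_delta2(
    n: int, n_null: int, rng: np.random.Generator, D: np.ndarray | None = None
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Null distribution of max delta2 over ERM trees with n tips.

    Returns (tree_max, class_max): tree_max[t] is the maximum delta2 over
    all internal branches of null tree t; class_max[c][t] the maximum over
    branches whose focal clade falls in size class c (-inf when absent).
    """
    if D is None:
        D = delta1_table(n)
    tree_max = np.full(n_null, -np.inf)
    classes = range(1, _size_class(n - 1) + 1)
    class_max = {c: np.full(n_null, -np.inf) for c in classes}
    for t in range(n_null):
        for m, k, j in _erm_branch_counts(n, rng):
            d2 = D[k, m] - D[j, k]
            if d2 > tree_max[t]:
                tree_max[t] = d2
            c = _size_class(k)
            if d2 > class_max[c][t]:
                class_max[c][t] = d2
    return tree_max, class_max


# ----------------------------------------------------------------------
# the scan

@dataclass
class BranchShiftScore:
    """Scores for one internal branch, averaged over polytomy resolutions."""

    clade: frozenset[str]
    delta1: float
    delta2: float
    p_local: float
    p_tree: float
    n_resolutions: int
    significant: bool = False


def _branch_counts_for_resolution(
    resolved: RootedTree,
) -> dict[int, tuple[int, int, int]]:
    """orig_id -> (m, k, j) for original internal non-root branches."""
    tips: dict[int, int] = {}
    top: dict[int, int] = {}
    for node in resolved.postorder():
        if node.is_leaf:
            tips[id(node)] = 1
            top[id(node)] = 0
        else:
            cs = [tips[id(c)] for c in node.children]
            tips[id(node)] = sum(cs)
            top[id(node)] = max(cs)
    out: dict[int, tuple[int, int, int]] = {}
    for node in resolved.preorder():
        oid = getattr(node, "orig_id", node.id)
        if oid is None or node.parent is None or node.is_leaf:
            continue
        out[oid] = (tips[id(node.parent)], tips[id(node)], top[id(node)])
    return out


def branch_shift_scan(
    tree: RootedTree,
    settings: NullSettings | None = None,
    null_dist: tuple[np.ndarray, dict[int, np.ndarray]] | None = None,
) -> list[BranchShiftScore]:
    """Score every internal branch of ``tree`` for a diversification shift.

    Polytomies are handled by averaging delta1/delta2 over random ERM
    resolutions; p-values compare the averaged delta2 against ERM null
    trees of the same tip count. ``p_tree`` uses the tree-wide maximum
    (familywise control); ``p_local`` the per-size-class maximum.
    Deterministic given ``settings.seed``.

    ``null_dist`` optionally supplies a precomputed null sample (the
    output of :func:`erm_null_max_delta2` for the same tip count), so
    batch scans of equal-sized trees can share one null.
    """
    settings = settings or NullSettings()
    n = len(tree)
    if n < 4:
        raise TreeError(f"shift scan needs >= 4 leaves, got {n}")
    rng = np.random.default_rng(settings.seed)

    branch_ids = [
        node.id
        for node in tree.preorder()
        if not node.is_leaf and node.parent is not None
    ]
    clade_of = {node.id: tree.clade(node) for node in tree.nodes if not node.is_leaf}

    n_res = 1 if tree.is_binary else settings.resolutions
    D = delta1_table(n)
    sums1 = {b: 0.0 for b in branch_ids}
    sums2 = {b: 0.0 for b in branch_ids}
    for _ in range(n_res):
        resolved = resolve_polytomies(tree, rng)
        counts = _branch_counts_for_resolution(resolved)
        for b in branch_ids:
            m, k, j = counts[b]
            d1 = D[k, m]
            sums1[b] += d1
            sums2[b] += d1 - D[j, k]

    if null_dist is None:
        tree_max, class_max = erm_null_max_delta2(n, settings.null_trees, rng, D)
    else:
        tree_max, class_max = null_dist
    N = len(tree_max)
    scores = []
    for b in branch_ids:
        d1 = sums1[b] / n_res
        d2 = sums2[b] / n_res
        c = _size_class(len(clade_of[b]))
        p_tree = (1 + int((tree_max >= d2).sum())) / (1 + N)
        loc = class_max.get(c)
        p_local = (1 + int((loc >= d2).sum())) / (1 + N) if loc is not None else p_tree
        scores.append(
            BranchShiftScore(
                clade=clade_of[b],
                delta1=d1,
                delta2=d2,
                p_local=p_local,
                p_tree=p_tree,
                n_resolutions=n_res,
                significant=p_tree <= settings.alpha,
            )
        )
    return scores


def detect_shifts(
    series, settings: NullSettings | None = None
) -> list[tuple[int, list[BranchShiftScore]]]:
    """Run the branch scan on every slice of a nested (or sliced) series.

    Returns (bin_index, scores) pairs ordered old -> young; bins whose
    slice tree has fewer than 4 leaves yield an empty score list. Each
    bin draws from its own seed stream so single-bin reruns reproduce.
    """
    settings = settings or NullSettings()
    out: list[tuple[int, list[BranchShiftScore]]] = []
    for entry in series.entries:
        if len(entry.tree) < 4:
            out.append((entry.bin_index, []))
            continue
        bin_seed = int(
            np.random.SeedSequence([settings.seed, entry.bin_index]).generate_state(1)[0]
            % (2**31)
        )
        sub = NullSettings(
            resolutions=settings.resolutions,
            null_trees=settings.null_trees,
            alpha=settings.alpha,
            seed=bin_seed,
        )
        out.append((entry.bin_index, branch_shift_scan(entry.tree, sub)))
    return out
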