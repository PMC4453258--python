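"""Matrix-representation-with-parsimony supertree assembly.

Source trees are coded Baum-Ragan style: one binary character per
non-root internal node (clade members 1, other taxa present in that
source tree 0, absent taxa missing), the matrix is analysed by heuristic
parsimony search (random-addition starting trees plus NNI/SPR/TBR
hill-climbing), the best trees are summarised by strict consensus,
rogue taxa are pruned greedily by reduced-consensus stability, and a
resolved crown-group subtree can be grafted over its terminal
placeholder in the backbone.

This is a compact re-implementation of the standard TNT-style workflow,
not a general search engine: search scale is configurable and desk-scale
by default.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .tree import Node, RootedTree, TreeError, build_from_clades

MISSING = -1


@dataclass
class MRPMatrix:
    """Taxa x binary characters with missing entries.

    ``data[i, j]`` is taxon i's state in column j: 0, 1 or -1 (missing).
    ``provenance[j]`` records (source-tree index, node id) for column j.
    """

    taxa: list[str]
    data: np.ndarray
    provenance: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.taxa) < 3:
            raise ValueError("MRP matrix needs at least 3 taxa")
        if self.data.shape[0] != len(self.taxa):
            raise ValueError("data rows must match taxa")

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def to_nexus(self) -> str:
        buf = io.StringIO()
        buf.write("#NEXUS\nBEGIN DATA;\n")
        buf.write(f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.n_columns};\n")
        buf.write('  FORMAT SYMBOLS="01" MISSING=?;\n  MATRIX\n')
        for i, taxon in enumerate(self.taxa):
            row = "".join("?" if v == MISSING else str(v) for v in self.data[i])
            buf.write(f"    {taxon} {row}\n")
        buf.write("  ;\nEND;\n")
        return buf.getvalue()

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("taxon," + ",".join(f"c{j+1}" for j in range(self.n_columns)) + "\n")
        for i, taxon in enumerate(self.taxa):
            row = ",".join("?" if v == MISSING else str(v) for v in self.data[i])
            buf.write(f"{taxon},{row}\n")
        return buf.getvalue()


@dataclass
class SearchSettings:
    replicates: int = 100
    hold: int = 5
    swapper: str = "TBR"
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1 or self.hold < 1:
            raise ValueError("replicates and hold must be >= 1")
        if self.swapper not in ("NNI", "SPR", "TBR"):
            raise ValueError("swapper must be NNI, SPR or TBR")


def encode_mrp(
    source_trees: list[RootedTree],
    all_taxa: set[str] | None = None,
    add_allzero_outgroup: bool = False,
) -> MRPMatrix:
    """Baum-Ragan coding of source-tree clades into a binary matrix.

    One column per non-root internal node; duplicated columns from
    repeated source trees are retained (repetition acts as weighting).
    Constant columns are dropped; a fully unresolved source tree simply
    contributes no columns. With ``add_allzero_outgroup`` a hypothetical
    all-zero outgroup taxon polarises the matrix in the classic variant;
    by default columns are polarised by each source tree's own root.
    """
    if all_taxa is None:
        all_taxa = set()
        for t in source_trees:
            all_taxa |= set(t.label_set)
    taxa = sorted(all_taxa)
    if add_allzero_outgroup:
        taxa = ["__OUTGROUP__"] + taxa
    index = {x: i for i, x in enumerate(taxa)}
    cols: list[np.ndarray] = []
    prov: list[tuple[int, int]] = []
    for s, tree in enumerate(source_trees):
        if len(tree) < 3:
            raise ValueError(f"source tree {s} has fewer than 3 leaves")
        unknown = tree.label_set - set(all_taxa)
        if unknown:
            raise ValueError(f"source tree {s} has taxa outside all_taxa: {sorted(unknown)}")
        present = tree.label_set
        for node in tree.preorder():
            if node.is_leaf or node.parent is None:
                continue
            members = tree.clade(node)
            col = np.full(len(taxa), MISSING, dtype=np.int8)
            for x in present:
                col[index[x]] = 1 if x in members else 0
            if add_allzero_outgroup:
                col[0] = 0
            if (col == 0).any() and (col == 1).any():
                cols.append(col)
                prov.append((s, node.id))
    if not cols:
        raise ValueError("no informative columns (all source trees unresolved?)")
    data = np.stack(cols, axis=1)
    return MRPMatrix(taxa=taxa, data=data, provenance=prov)


# ----------------------------------------------------------------------
# Fitch parsimony

def _leaf_masks(matrix: MRPMatrix) -> dict[str, np.ndarray]:
    # state sets as bitmasks over all columns: {0}->1, {1}->2, missing->3
    out = {}
    for i, taxon in enumerate(matrix.taxa):
        row = matrix.data[i]
        mask = np.where(row == MISSING, 3, np.where(row == 1, 2, 1)).astype(np.uint8)
        out[taxon] = mask
    return out


def fitch_score(tree: RootedTree, matrix: MRPMatrix, polarized: bool = False) -> int:
    """Total Fitch parsimony length of ``matrix`` on a bifurcating tree.

    Missing states are the full state set {0,1}: union-compatible with
    anything at no cost. With ``polarized`` the root is constrained to
    state 0 (equivalent to a hypothetical all-zero outgroup), which is
    how the search respects the rooting each column inherits from its
    source tree; the plain score is rooting-invariant.
    """
    if set(tree.leaf_labels) != set(matrix.taxa):
        raise TreeError("tree leaves and matrix taxa differ")
    if not tree.is_binary:
        raise TreeError("fitch_score needs a fully bifurcating tree")
    masks = _leaf_masks(matrix)
    return _fitch_score_masks(tree, masks, polarized=polarized)


def _fitch_score_masks(
    tree: RootedTree, masks: dict[str, np.ndarray], polarized: bool = False
) -> int:
    score = 0
    state: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            state[id(node)] = masks[node.label]
        else:
            acc = None
            for c in node.children:
                s = state.pop(id(c))
                if acc is None:
                    acc = s
                else:
                    inter = acc & s
                    empty = inter == 0
                    score += int(empty.sum())
                    acc = np.where(empty, acc | s, inter)
            state[id(node)] = acc
    if polarized:
        root_set = state[id(tree.root)]
        score += int((root_set & 1 == 0).sum())
    return score


# ----------------------------------------------------------------------
# tree moves and heuristic search

def _attach_points(root: Node) -> list[Node]:
    """Every node of the subtree; attaching above node X bisects X's edge
    (attaching above the root adds a new root)."""
    out = []
    stack = [root]
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _detach(tree_root: Node, v: Node) -> Node:
    """Remove subtree v; splice the unary parent; return new tree root."""
    u = v.parent
    sib = [c for c in u.children if c is not v][0]
    g = u.parent
    if g is None:
        sib.parent = None
        return sib
    g.children[g.children.index(u)] = sib
    sib.parent = g
    return tree_root


def _attach(tree_root: Node, v: Node, at: Node) -> Node:
    """Insert v as sister of ``at``; returns the (possibly new) root."""
    new = Node()
    parent = at.parent
    new.add_child(at)
    new.add_child(v)
    if parent is None:
        return new
    parent.children[parent.children.index(at)] = new
    new.parent = parent
    return tree_root


def _copy(node: Node) -> Node:
    new = Node(label=node.label)
    for c in node.children:
        new.add_child(_copy(c))
    return new


def _spr_neighbors(tree: RootedTree, tbr: bool = False):
    """Yield SPR (or TBR) neighbors as RootedTrees.

    TBR additionally enumerates rerootings of the pruned clade before
    reattachment (reconnection-point enumeration on its own edge set).
    """
    nodes = [n for n in tree.nodes if n.parent is not None]
    for i, _ in enumerate(nodes):
        root = _copy(tree.root)
        work = RootedTree(root, validate=False)
        v = [n for n in work.nodes if n.parent is not None][i]
        base = _detach(root, v)
        v.parent = None
        reroots = _reroot_variants(v) if (tbr and not v.is_leaf) else [v]
        for w in reroots:
            for at in _attach_points(base):
                r2 = _copy(base)
                # find the corresponding attach point in the copy
                at2 = _match_node(base, r2, at)
                new_root = _attach(r2, _copy(w), at2)
                yield RootedTree(new_root, validate=False)


def _match_node(orig_root: Node, copy_root: Node, target: Node) -> Node:
    stack = [(orig_root, copy_root)]
    while stack:
        o, c = stack.pop()
        if o is target:
            return c
        stack.extend(zip(o.children, c.children))
    raise AssertionError("node not found in copy")


def _reroot_variants(v: Node) -> list[Node]:
    """All rootings of the pruned clade obtained by picking a new root edge."""
    out = [v]
    seen = {_clade_key(v)}
    originals = _attach_points(v)
    for idx, edge_child in enumerate(originals):
        if edge_child is v:
            continue
        root_copy = _copy(v)
        target = _attach_points(root_copy)[idx]
        r = _reroot_at_edge(root_copy, target)
        key = _clade_key(r)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def _clade_key(root: Node) -> frozenset:
    clades = set()

    def walk(n: Node) -> frozenset:
        if n.is_leaf:
            return frozenset([n.label])
        cl = frozenset().union(*(walk(c) for c in n.children))
        clades.add(cl)
        return cl

    walk(root)
    return frozenset(clades)


def _reroot_at_edge(root: Node, target: Node) -> Node:
    """Reroot the (unrooted-equivalent) subtree on the edge above ``target``."""
    u = target.parent
    u.children.remove(target)
    target.parent = None
    # reverse parent pointers from u back up to the old root
    node, parent = u, u.parent
    node.parent = None
    while parent is not None:
        gp = parent.parent
        parent.children.remove(node)
        node.add_child(parent)
        node = parent
        parent = gp
    rest = _splice_unary(u)
    new_root = Node()
    new_root.add_child(target)
    new_root.add_child(rest)
    return new_root


def _splice_unary(root: Node) -> Node:
    while not root.is_leaf and len(root.children) == 1:
        root = root.children[0]
        root.parent = None
    stack = [root]
    while stack:
        n = stack.pop()
        i = 0
        while i < len(n.children):
            c = n.children[i]
            if not c.is_leaf and len(c.children) == 1:
                gc = c.children[0]
                n.children[i] = gc
                gc.parent = n
            else:
                stack.append(c)
                i += 1
    return root


def _nni_neighbors(tree: RootedTree):
    """Rooted NNI: swap a child of an internal non-root node with its uncle."""
    for i, node in enumerate(tree.nodes):
        if node.is_leaf or node.parent is None:
            continue
        for ci in range(len(node.children)):
            for si, sib in enumerate(c for c in node.parent.children if c is not node):
                root = _copy(tree.root)
                work = RootedTree(root, validate=False)
                v = work.nodes[i]
                u = v.parent
                siblings = [c for c in u.children if c is not v]
                uncle = siblings[si]
                child = v.children[ci]
                u.children[u.children.index(uncle)] = child
                v.children[v.children.index(child)] = uncle
                child.parent, uncle.parent = u, v
                yield RootedTree(root, validate=False)


def _random_addition_tree(
    matrix: MRPMatrix, order: list[str], masks: dict[str, np.ndarray]
) -> RootedTree:
    root = Node()
    root.add_child(Node(label=order[0]))
    root.add_child(Node(label=order[1]))
    tree = RootedTree(root, validate=False)
    for taxon in order[2:]:
        best = None
        best_tree = None
        for at in list(_attach_points(tree.root)):
            r2 = _copy(tree.root)
            at2 = _match_node(tree.root, r2, at)
            new_root = _attach(r2, Node(label=taxon), at2)
            cand = RootedTree(new_root, validate=False)
            score = _fitch_score_masks(cand, masks, polarized=True)
            if best is None or score < best:
                best = score
                best_tree = cand
        tree = best_tree
    return tree


def heuristic_search(matrix: MRPMatrix, settings: SearchSettings | None = None) -> list[RootedTree]:
    """Random-addition + branch-swapping parsimony search.

    Each replicate builds a random stepwise-addition tree and hill-climbs
    with the chosen swapper (first-improvement, deterministic neighbor
    order) to a local optimum. All best-scoring distinct trees across
    replicates are returned (capped at hold x replicates); ties keep
    earlier-found trees, so the result is stable under the seed.
    """
    settings = settings or SearchSettings()
    rng = np.random.default_rng(settings.seed)
    masks = _leaf_masks(matrix)
    neighbor_fn = {
        "NNI": lambda t: _nni_neighbors(t),
        "SPR": lambda t: _spr_neighbors(t, tbr=False),
        "TBR": lambda t: _spr_neighbors(t, tbr=True),
    }[settings.swapper]

    best_score: int | None = None
    best: list[RootedTree] = []
    seen: set[frozenset] = set()
    cap = settings.hold * settings.replicates
    for _ in range(settings.replicates):
        order = list(matrix.taxa)
        rng.shuffle(order)
        tree = _random_addition_tree(matrix, order, masks)
        score = _fitch_score_masks(tree, masks, polarized=True)
        improved = True
        while improved:
            improved = False
            for nb in neighbor_fn(tree):
                s = _fitch_score_masks(nb, masks, polarized=True)
                if s < score:
                    tree, score = nb, s
                    improved = True
                    break
        key = _clade_key(tree.root)
        if best_score is None or score < best_score:
            best_score = score
            best = [tree]
            seen = {key}
        elif score == best_score and key not in seen and len(best) < cap:
            best.append(tree)
            seen.add(key)
    return best


# ----------------------------------------------------------------------
# consensus, rogue pruning, grafting

def strict_consensus(trees: list[RootedTree]) -> RootedTree:
    """Tree containing exactly the clades present in every input tree."""
    if not trees:
        raise ValueError("strict consensus of an empty set")
    leafset = trees[0].label_set
    for t in trees[1:]:
        if t.label_set != leafset:
            raise TreeError("strict consensus needs identical leaf sets")
    common = trees[0].clades()
    for t in trees[1:]:
        common &= t.clades()
    return build_from_clades(leafset, common)


def _resolution(trees: list[RootedTree]) -> int:
    """Number of non-trivial clades in the strict consensus."""
    cons = strict_consensus(trees)
    full = cons.label_set
    return sum(
        1
        for c in cons.clades()
        if 1 < len(c) < len(full)
    )


def prune_unstable(
    trees: list[RootedTree], max_removals: int = 10
) -> tuple[list[tuple[str, set[frozenset[str]]]], RootedTree]:
    """Greedy reduced-consensus pruning of unstable (rogue) taxa.

    Repeatedly removes the taxon whose deletion most increases the number
    of resolved nodes in the strict consensus of the leaf-pruned tree
    set; stops when no removal helps or ``max_removals`` is reached.
    Each removed taxon is reported with its alternative attachment
    positions: the set of sibling clades (restricted to retained taxa) it
    takes across the input trees.
    """
    if len(trees) < 2:
        raise ValueError("need at least 2 trees")
    kept = set(trees[0].label_set)
    removed: list[tuple[str, set[frozenset[str]]]] = []
    current = list(trees)
    base = _resolution(current)
    while len(removed) < max_removals and len(kept) > 3:
        best_taxon = None
        best_gain = 0
        for taxon in sorted(kept):
            reduced = [t.restrict(kept - {taxon}) for t in current]
            gain = _resolution(reduced) - base
            if gain > best_gain:
                best_gain = gain
                best_taxon = taxon
        if best_taxon is None:
            break
        attachments: set[frozenset[str]] = set()
        for t in current:
            sub = t.restrict((kept - {best_taxon}) | {best_taxon})
            leaf = sub.leaf(best_taxon)
            sibs = [c for c in leaf.parent.children if c is not leaf]
            sib_clade = frozenset().union(*(sub.clade(c) for c in sibs)) - {best_taxon}
            attachments.add(frozenset(sib_clade))
        removed.append((best_taxon, attachments))
        kept -= {best_taxon}
        current = [t.restrict(kept) for t in current]
        base = _resolution(current)
    return removed, strict_consensus(current)


def graft(backbone: RootedTree, subtree: RootedTree, terminal: str) -> RootedTree:
    """Replace leaf ``terminal`` of the backbone by the subtree's root.

    The combined leaf count is backbone n - 1 + subtree n; label overlap
    between the subtree and the rest of the backbone is an error.
    """
    if terminal not in backbone.label_set:
        raise TreeError(f"terminal {terminal!r} not in backbone")
    collision = subtree.label_set & (backbone.label_set - {terminal})
    if collision:
        raise TreeError(f"label collision: {sorted(collision)[:5]}")
    root = _copy(backbone.root)
    work = RootedTree(root, validate=False)
    leaf = work.leaf(terminal)
    sub = _copy(subtree.root)
    if leaf.parent is None:
        return RootedTree(sub)
    parent = leaf.parent
    parent.children[parent.children.index(leaf)] = sub
    sub.parent = parent
    return RootedTree(root)
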