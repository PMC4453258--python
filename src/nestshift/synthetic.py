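"""Synthetic chronograms, fossil ages and source trees for pipeline testing.

The generator embodies the statistical structure the analysis assumes:

* a constant-rate pure-birth (Yule / ERM) chronogram as the null;
* the two-rate violation of it — a planted rate shift on one stem,
  optionally with extinction restricted to a clade (the feedstock for
  extinction-artefact scenarios);
* incomplete fossil sampling: a Poisson process of fossil finds along
  terminal branches, binned into ordered stratigraphic intervals, giving
  per-taxon first/last appearance data with realistic ghost lineages;
* noisy overlapping source trees (induced subtrees perturbed by random
  NNI moves) for supertree tests.

All draws flow from a single seeded generator; (spec, seed) reproduces
every dataset exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .slicing import AgeTable, TimeBins
from .tree import Node, RootedTree, TreeError


@dataclass(frozen=True)
class ShiftSpec:
    """A planted diversification-rate shift.

    When the growing tree reaches ``select_at_tips`` extant lineages, the
    current node whose extant-descendant count is closest to
    ``tip_fraction`` of the standing diversity is selected; from then on
    its descendants speciate at ``multiplier`` times the base rate (and
    die at ``death_rate`` if set, for artefact scenarios). The selector
    is reproducible without naming node ids that vary by seed.
    """

    multiplier: float
    tip_fraction: float = 0.5
    select_at_tips: int = 16
    death_rate: float = 0.0

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("rate multiplier must be > 0")
        if not 0 < self.tip_fraction <= 1:
            raise ValueError("tip_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic dataset.

    n_tips counts all terminal taxa (extant plus extinct fossils);
    base_rate is the per-lineage speciation rate (1/time);
    sampling_rate is the per-lineage-time fossil-recovery rate used by
    :func:`fossilize`; bin_boundaries (absolute times since the root,
    increasing, oldest bin first) map fossil finds to time bins.
    """

    n_tips: int
    base_rate: float = 1.0
    shifts: tuple[ShiftSpec, ...] = ()
    death_rate: float = 0.0
    sampling_rate: float = 2.0
    bin_boundaries: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("need n_tips >= 4")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if self.sampling_rate < 0:
            raise ValueError("sampling_rate must be >= 0")


class _Lineage:
    __slots__ = ("node", "birth", "death", "t0")

    def __init__(self, node: Node, birth: float, death: float, t0: float):
        self.node = node
        self.birth = birth
        self.death = death
        self.t0 = t0


def _simulate(spec: SimSpec, rng: np.random.Generator) -> tuple[RootedTree, list[Node], dict[int, float]]:
    """Gillespie birth(-death); returns (tree, shift stem nodes, node origin times).

    Extinct lineages are retained as fossil tips (their terminal branch
    ends at the death time); the process stops when the total tip count
    reaches n_tips. Node.length is set on every non-root node; origin
    times (time of the branch's start) returned per node id granted after
    tree construction.
    """
    root = Node()
    t = 0.0
    shifts_pending = sorted(spec.shifts, key=lambda s: s.select_at_tips)
    shift_stems: list[Node] = []
    # root immediately splits into two lineages (time zero at the root split)
    left, right = Node(), Node()
    root.add_child(left)
    root.add_child(right)
    origin: dict[int, float] = {}  # id(node) -> origin time of its branch
    end: dict[int, float] = {}
    origin[id(left)] = origin[id(right)] = 0.0
    lam, mu = spec.base_rate, spec.death_rate
    extant = [_Lineage(left, lam, mu, 0.0), _Lineage(right, lam, mu, 0.0)]
    done_tips = 0  # extinct tips finalized
    pending = list(shifts_pending)

    while done_tips + len(extant) < spec.n_tips or pending:
        if pending and len(extant) >= pending[0].select_at_tips:
            sh = pending.pop(0)
            stem = _select_stem(extant, sh.tip_fraction)
            shift_stems.append(stem)
            for lin in extant:
                if _descends(lin.node, stem):
                    lin.birth = spec.base_rate * sh.multiplier
                    lin.death = sh.death_rate
            continue
        if done_tips + len(extant) >= spec.n_tips:
            break
        if not extant:
            raise TreeError("all lineages went extinct")
        rates = np.array([lin.birth + lin.death for lin in extant])
        total = rates.sum()
        t += rng.exponential(1.0 / total)
        i = int(rng.choice(len(extant), p=rates / total))
        lin = extant[i]
        if rng.random() < lin.birth / (lin.birth + lin.death):
            a, b = Node(), Node()
            lin.node.add_child(a)
            lin.node.add_child(b)
            end[id(lin.node)] = t
            origin[id(a)] = origin[id(b)] = t
            extant[i] = _Lineage(a, lin.birth, lin.death, t)
            extant.append(_Lineage(b, lin.birth, lin.death, t))
        else:
            end[id(lin.node)] = t
            lin.node.label = "FOSSIL"  # placeholder; renamed below
            extant.pop(i)
            done_tips += 1

    # sample the tree at a time strictly inside the n-tip interval: extend
    # by one further exponential waiting time so no terminal branch is
    # zero-length
    present = t
    if extant:
        total = sum(lin.birth + lin.death for lin in extant)
        present = t + rng.exponential(1.0 / total)
    for lin in extant:
        end[id(lin.node)] = present

    # branch lengths and labels
    counter = 0
    for node in RootedTree(root, validate=False).preorder():
        if node.parent is not None:
            node.length = end.get(id(node), present) - origin[id(node)]
        if node.is_leaf:
            counter += 1
            node.label = f"T{counter:03d}"
    tree = RootedTree(root)
    times = {
        node.id: origin.get(id(node), 0.0) for node in tree.nodes if node.parent is not None
    }
    return tree, shift_stems, times


def _descends(node: Node, ancestor: Node) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


def _select_stem(extant: list[_Lineage], fraction: float) -> Node:
    """Node whose extant-descendant count is closest to fraction*total.

    The root itself is excluded (a shift on the whole tree is no shift);
    ties prefer the larger clade, then the earlier-created node.
    """
    total = len(extant)
    target = fraction * total
    counts: dict[int, tuple[Node, int]] = {}
    for lin in extant:
        node = lin.node
        while node is not None:
            key = id(node)
            counts[key] = (node, counts.get(key, (node, 0))[1] + 1)
            node = node.parent
    best: tuple[float, int, int] | None = None
    best_node: Node | None = None
    order = {k: i for i, (k, _) in enumerate(counts.items())}
    for key, (node, cnt) in counts.items():
        if node.parent is None or cnt == total:
            continue
        score = (abs(cnt - target), -cnt, order[key])
        if best is None or score < best:
            best = score
            best_node = node
    if best_node is None:
        raise TreeError("no eligible shift stem")
    return best_node


def yule_tree(spec: SimSpec) -> RootedTree:
    """Constant-rate pure-birth chronogram with n_tips extant tips."""
    if spec.shifts or spec.death_rate:
        raise ValueError("yule_tree is the no-shift, no-extinction case")
    rng = np.random.default_rng(spec.seed)
    tree, _, _ = _simulate(spec, rng)
    return tree


def shifted_tree(spec: SimSpec, max_retries: int = 20) -> tuple[RootedTree, list[frozenset[str]]]:
    """Two-rate (or birth-death) tree with planted stem shifts.

    Returns the tree and the true shift clades (tip-label sets descending
    from each selected stem) for recovery scoring. A run in which a shift
    clade dies out completely is resampled up to ``max_retries``.
    """
    if not spec.shifts:
        raise ValueError("shifted_tree needs at least one planted shift")
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_retries):
        try:
            tree, stems, _ = _simulate(spec, rng)
        except TreeError:
            continue
        clades = [tree.clade(stem) for stem in stems]
        if all(len(c) >= 2 for c in clades):
            return tree, clades
    raise TreeError(f"planted shift clade died out in {max_retries} attempts")


# ----------------------------------------------------------------------
# fossil sampling

def default_boundaries(tree: RootedTree, n_bins: int = 10) -> tuple[float, ...]:
    """Equal-width bin boundaries covering the tree's time span."""
    span = _tree_depth(tree)
    return tuple(span * (i + 1) / n_bins for i in range(n_bins))


def _tree_depth(tree: RootedTree) -> float:
    depth: dict[int, float] = {id(tree.root): 0.0}
    out = 0.0
    for node in tree.preorder():
        if node.parent is not None:
            d = depth[id(node.parent)] + (node.length or 0.0)
            depth[id(node)] = d
            if node.is_leaf:
                out = max(out, d)
    return out


def fossilize(
    tree: RootedTree,
    spec: SimSpec,
    bins: TimeBins | None = None,
    rng: np.random.Generator | None = None,
    lineage_path: bool = False,
    drop_unsampled: bool = False,
) -> tuple[AgeTable, set[str]]:
    """Sample fossil finds and bin them into first/last appearance data.

    Finds are a Poisson process (rate ``spec.sampling_rate`` per unit
    time) along each taxon's terminal branch (with ``lineage_path`` the
    whole root-to-tip path). FAD = bin of the oldest find, LAD = bin of
    the youngest. Unsampled taxa fall back to the bin of their tip time
    and are returned in the flagged set (or omitted with
    ``drop_unsampled``, in which case the caller prunes the tree).
    """
    if spec.sampling_rate <= 0:
        raise ValueError("fossilize needs sampling_rate > 0")
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    boundaries = spec.bin_boundaries or default_boundaries(tree, n_bins=10)
    bins = bins or TimeBins(tuple(f"B{i+1:02d}" for i in range(len(boundaries))))
    if len(bins) != len(boundaries):
        raise ValueError("bin boundaries and bin names disagree in length")
    depth_end = _tree_depth(tree)
    if boundaries[-1] < depth_end - 1e-9:
        raise ValueError("bin boundaries do not cover the tree's time span")

    def to_bin(time: float) -> int:
        for i, b in enumerate(boundaries):
            if time <= b + 1e-12:
                return i + 1
        return len(boundaries)

    depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node.parent is not None:
            depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)

    fad: dict[str, int] = {}
    lad: dict[str, int] = {}
    flagged: set[str] = set()
    for leaf in tree.leaves:
        if lineage_path:
            t0, t1 = 0.0, depth[id(leaf)]
        else:
            t0, t1 = depth[id(leaf.parent)], depth[id(leaf)]
        dur = max(t1 - t0, 0.0)
        n_finds = rng.poisson(spec.sampling_rate * dur)
        if n_finds > 0:
            finds = t0 + dur * rng.random(n_finds)
            fad[leaf.label] = to_bin(float(finds.min()))
            lad[leaf.label] = to_bin(float(finds.max()))
        else:
            flagged.add(leaf.label)
            if not drop_unsampled:
                fad[leaf.label] = to_bin(t1)
                lad[leaf.label] = to_bin(t1)
    return AgeTable(fad=fad, lad=lad), flagged


# ----------------------------------------------------------------------
# source trees for supertree tests

def nni_move(tree: RootedTree, rng: np.random.Generator) -> RootedTree:
    """One random rooted NNI: swap a random grandchild with its uncle."""
    tree = tree.copy()
    candidates = [
        n for n in tree.nodes if not n.is_leaf and n.parent is not None
    ]
    if not candidates:
        return tree
    v = candidates[int(rng.integers(len(candidates)))]
    u = v.parent
    siblings = [c for c in u.children if c is not v]
    uncle = siblings[int(rng.integers(len(siblings)))]
    child = v.children[int(rng.integers(len(v.children)))]
    # swap child <-> uncle
    u.children[u.children.index(uncle)] = child
    v.children[v.children.index(child)] = uncle
    child.parent, uncle.parent = u, v
    return RootedTree(tree.root)


def make_source_trees(
    true_tree: RootedTree,
    k: int,
    coverage: float,
    error_moves: int,
    rng: np.random.Generator | int = 0,
) -> list[RootedTree]:
    """Overlapping, partly erroneous source trees for supertree assembly.

    Each source tree is the induced subtree of ``true_tree`` on a random
    ``coverage`` fraction of the leaves, perturbed by ``error_moves``
    random NNI moves. Subsets smaller than 3 leaves are resampled.
    """
    if k < 1:
        raise ValueError("need k >= 1 source trees")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    labels = sorted(true_tree.label_set)
    n_take = max(3, int(round(coverage * len(labels))))
    if n_take > len(labels):
        raise ValueError("tree too small for 3-leaf source trees")
    out = []
    for _ in range(k):
        subset = rng.choice(len(labels), size=n_take, replace=False)
        sub = true_tree.restrict([labels[i] for i in subset])
        for _ in range(error_moves):
            sub = nni_move(sub, rng)
        out.append(sub)
    return out
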