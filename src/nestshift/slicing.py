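"""Stratigraphic binning and time-slice tree construction.

Two slicing modes are provided. Nested growth builds one tree per time
bin such that taxa, once added by first appearance, are never removed:
the series simulates speciation but not extinction, which is what lets a
downstream older-taxon criterion separate genuine radiations from
extinction artefacts. The classic (non-nested) variant retains only taxa
whose stratigraphic range overlaps the bin.

In both modes, any maximal clade of the full tree whose members all
first appear after the focal bin is collapsed to a single *ghost leaf*:
one inferred lineage, regardless of the clade's later diversity, so
future diversity cannot leak into an earlier bin's tree shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .tree import Node, RootedTree, TreeError

log = logging.getLogger(__name__)

GHOST_PREFIX = "GHOST:"

#: The default stratigraphic binning: ten composite intervals spanning the
#: Late Triassic through the Recent, oldest first.
DEFAULT_INTERVALS = (
    "Carnian-Aalenian",
    "Bajocian-Oxfordian",
    "Kimmeridgean-Barremian",
    "Aptian-Albian",
    "Cenomanian-Santonian",
    "Campanian-Maastrichtian",
    "Palaeocene",
    "Eocene",
    "Oligocene-Miocene",
    "Pliocene-Recent",
)


@dataclass(frozen=True)
class TimeBins:
    """Ordered stratigraphic intervals; index 1 = oldest."""

    names: tuple[str, ...] = DEFAULT_INTERVALS

    def __post_init__(self):
        if len(self.names) < 2:
            raise ValueError("need at least 2 time bins")
        if len(set(self.names)) != len(self.names):
            raise ValueError("time-bin names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """1-based bin index of an interval name."""
        try:
            return self.names.index(name) + 1
        except ValueError:
            raise KeyError(f"unknown interval name: {name!r}") from None


@dataclass
class AgeTable:
    """Per-taxon first (and optional last) appearance bin indices."""

    fad: dict[str, int]
    lad: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for taxon, f in self.fad.items():
            l = self.lad.get(taxon)
            if l is not None and l < f:
                raise ValueError(f"{taxon}: lad bin {l} older than fad bin {f}")

    def require(self, taxa) -> None:
        missing = set(taxa) - set(self.fad)
        if missing:
            raise ValueError(f"taxa missing from age table: {sorted(missing)[:10]}")


def assign_bins(raw_ages: dict[str, list[str] | str], bins: TimeBins) -> AgeTable:
    """Resolve interval names to bin indices, oldest-record rule for FADs.

    A taxon listed in several intervals (or with an uncertain age spanning
    intervals) is scored by its oldest record: fad = min index among the
    listed intervals; lad = max index when more than one is listed.
    """
    fad: dict[str, int] = {}
    lad: dict[str, int] = {}
    for taxon, intervals in raw_ages.items():
        if isinstance(intervals, str):
            intervals = [intervals]
        if not intervals:
            raise ValueError(f"{taxon}: no interval listed")
        try:
            idx = [bins.index(name) for name in intervals]
        except KeyError as exc:
            raise ValueError(f"taxon {taxon!r}: {exc.args[0]}") from None
        fad[taxon] = min(idx)
        if len(idx) > 1:
            lad[taxon] = max(idx)
    return AgeTable(fad=fad, lad=lad)


# ----------------------------------------------------------------------
# ghost-lineage collapse

@dataclass
class SliceEntry:
    bin_index: int
    tree: RootedTree
    ghosts: dict[str, frozenset[str]]  # ghost leaf label -> collapsed full-tree clade

    @property
    def ghost_leaves(self) -> frozenset[str]:
        return frozenset(self.ghosts)

    @property
    def non_ghost_count(self) -> int:
        return len(self.tree) - len(self.ghosts)


@dataclass
class SlicedSeries:
    """One slice tree per bin, oldest first."""

    full_tree: RootedTree
    ages: AgeTable
    bins: TimeBins
    mode: str
    entries: list[SliceEntry]

    def __len__(self) -> int:
        return len(self.entries)


def ghost_collapse(
    full_tree: RootedTree, ages: AgeTable, t: int, *, keep: set[str] | None = None
) -> tuple[RootedTree, dict[str, frozenset[str]]]:
    """Collapse every maximal all-younger clade at bin ``t`` to a ghost leaf.

    A clade is all-younger when every member has fad > t; the maximal such
    clades each become a single leaf labeled ``GHOST:<x>`` where x is the
    lexicographically smallest member (deterministic, so clade tracking
    across bins is stable). ``keep`` optionally restricts the non-ghost
    leaves retained (used by the non-nested variant); by default all taxa
    with fad <= t are retained.

    Raises on a slice with no occurring taxa at all; a slice with fewer
    than two non-ghost leaves is legal here but treated as degenerate by
    the series builders.
    """
    ages.require(full_tree.leaf_labels)
    present = {x for x in full_tree.leaf_labels if ages.fad[x] <= t}
    if not present:
        raise TreeError(f"no taxon has appeared by bin {t}")
    if keep is None:
        keep = present

    ghosts: dict[str, frozenset[str]] = {}

    def collapse(node: Node) -> Node | None:
        members = frozenset(
            l.label for l in _subtree_leaves(node)
        )
        if all(ages.fad[x] > t for x in members):
            label = GHOST_PREFIX + min(members)
            ghosts[label] = members
            return Node(label=label)
        if node.is_leaf:
            return Node(label=node.label) if node.label in keep else None
        kept = [collapse(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = Node()
        for c in kept:
            new.add_child(c)
        return new

    root = collapse(full_tree.root)
    assert root is not None  # present is non-empty
    root.parent = None
    return RootedTree(root), ghosts


def _subtree_leaves(node: Node):
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def nested_series(full_tree: RootedTree, ages: AgeTable, bins: TimeBins) -> SlicedSeries:
    """Build the nested-growth series: taxa are added, never removed.

    Emits one entry per bin from the first bin whose slice has at least
    two non-ghost taxa through the last bin; earlier degenerate slices are
    skipped with a warning. Last-appearance data are ignored in this mode.
    """
    ages.require(full_tree.leaf_labels)
    entries: list[SliceEntry] = []
    for t in range(1, len(bins) + 1):
        present = sum(1 for x in full_tree.leaf_labels if ages.fad[x] <= t)
        if not entries and present < 2:
            log.warning("bin %d: fewer than 2 occurring taxa, slice skipped", t)
            continue
        tree, ghosts = ghost_collapse(full_tree, ages, t)
        entries.append(SliceEntry(bin_index=t, tree=tree, ghosts=ghosts))
    if not entries:
        raise TreeError("no bin has two or more occurring taxa")
    return SlicedSeries(full_tree=full_tree, ages=ages, bins=bins, mode="nested", entries=entries)


def timeslice_series(full_tree: RootedTree, ages: AgeTable, bins: TimeBins) -> SlicedSeries:
    """Classic time slicing: bin t keeps taxa whose [fad, lad] range overlaps t.

    Requires a last-appearance bin for every taxon. Taxa already extinct
    by bin t are dropped; clades not yet appeared collapse to ghosts as in
    nested mode, so at every bin the nested leaf set contains this one.
    """
    ages.require(full_tree.leaf_labels)
    missing = [x for x in full_tree.leaf_labels if x not in ages.lad]
    if missing:
        raise ValueError(
            f"sliced mode needs last_interval for every taxon; missing: {sorted(missing)[:10]}"
        )
    entries: list[SliceEntry] = []
    for t in range(1, len(bins) + 1):
        alive = {
            x for x in full_tree.leaf_labels if ages.fad[x] <= t <= ages.lad[x]
        }
        if not entries and len(alive) < 2:
            log.warning("bin %d: fewer than 2 ranging-through taxa, slice skipped", t)
            continue
        if not alive:
            log.warning("bin %d: no taxon ranges through, slice skipped", t)
            continue
        tree, ghosts = ghost_collapse(full_tree, ages, t, keep=alive)
        entries.append(SliceEntry(bin_index=t, tree=tree, ghosts=ghosts))
    if not entries:
        raise TreeError("no bin has two or more ranging-through taxa")
    return SlicedSeries(full_tree=full_tree, ages=ages, bins=bins, mode="sliced", entries=entries)
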