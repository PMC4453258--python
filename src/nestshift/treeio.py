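"""Reading and writing trees (Newick / NEXUS) and the taxon-age table.

Parsing and serialization are delegated to dendropy; trees are converted
to and from the package's own :class:`~nestshift.tree.RootedTree`, which
is what every analysis stage consumes. Polytomies are preserved, never
auto-resolved; branch lengths are carried through if present.
"""

from __future__ import annotations

import io
from pathlib import Path

import dendropy
import pandas as pd

from .tree import Node, RootedTree, TreeError

FORMATS = ("newick", "nexus")


class TreeParseError(ValueError):
    """Malformed tree file; message carries dendropy's line/column info."""


def _from_dendropy(dtree: dendropy.Tree) -> RootedTree:
    def conv(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(label=label, length=dnode.edge.length)
        else:
            node = Node(length=dnode.edge.length)
            for c in dnode.child_nodes():
                node.add_child(conv(c))
        return node

    root = conv(dtree.seed_node)
    # dendropy may hang a knuckle (unary seed node) on some inputs
    while len(root.children) == 1 and not root.is_leaf:
        root = root.children[0]
        root.parent = None
    return RootedTree(root)


def _to_dendropy(tree: RootedTree, taxon_namespace=None) -> dendropy.Tree:
    tns = taxon_namespace or dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)

    def conv(node: Node, dnode) -> None:
        for c in node.children:
            dchild = dnode.new_child(edge_length=c.length)
            if c.is_leaf:
                dchild.taxon = tns.require_taxon(label=c.label)
            conv(c, dchild)

    if tree.root.is_leaf:
        dtree.seed_node.taxon = tns.require_taxon(label=tree.root.label)
    conv(tree.root, dtree.seed_node)
    dtree.is_rooted = True
    return dtree


def parse_tree(text: str, format: str = "newick") -> RootedTree:
    """Parse a single tree from a string."""
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {format!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=format,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific subclasses
        raise TreeParseError(f"could not parse {format} tree: {exc}") from exc
    try:
        return _from_dendropy(dtree)
    except TreeError as exc:
        raise TreeError(f"invalid tree: {exc}") from exc


def read_tree(path: str | Path, format: str | None = None) -> RootedTree:
    """Read one rooted tree from a file. Format inferred from suffix if None."""
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in (".nex", ".nexus", ".tre") else "newick"
    return parse_tree(path.read_text(), format=format)


def read_trees(path: str | Path, format: str | None = None) -> list[RootedTree]:
    """Read a list of trees (one per line for newick, TREES block for nexus)."""
    path = Path(path)
    if format is None:
        format = "nexus" if path.suffix.lower() in (".nex", ".nexus") else "newick"
    try:
        dlist = dendropy.TreeList.get(
            path=str(path),
            schema=format,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeParseError(f"could not parse {format} trees: {exc}") from exc
    return [_from_dendropy(t) for t in dlist]


def write_tree(tree: RootedTree, format: str = "newick") -> str:
    """Serialize a tree; round-trips through :func:`parse_tree` isomorphically."""
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}, got {format!r}")
    dtree = _to_dendropy(tree)
    text = dtree.as_string(
        schema=format,
        suppress_rooting=(format == "newick"),
        unquoted_underscores=True,
    )
    return text if text.endswith("\n") else text + "\n"


def write_trees(trees: list[RootedTree], format: str = "newick") -> str:
    return "".join(write_tree(t, format=format) for t in trees)


# ----------------------------------------------------------------------
# taxon-age CSV

def read_age_csv(path: str | Path) -> dict[str, list[str]]:
    """Read the taxon-age table.

    CSV with header ``taxon,first_interval,last_interval`` (last optional,
    may be empty). Returns taxon -> list of interval names; binning against
    a TimeBins definition happens in :func:`nestshift.slicing.assign_bins`.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    cols = {c.lower().strip(): c for c in df.columns}
    if "taxon" not in cols or "first_interval" not in cols:
        raise ValueError("age table needs columns: taxon, first_interval[, last_interval]")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        taxon = row[cols["taxon"]].strip()
        intervals = [row[cols["first_interval"]].strip()]
        last = row[cols["last_interval"]].strip() if "last_interval" in cols else ""
        if last:
            intervals.append(last)
        if taxon in out:
            raise ValueError(f"duplicate taxon in age table: {taxon!r}")
        out[taxon] = intervals
    return out


def write_age_csv(ages: dict[str, list[str]]) -> str:
    buf = io.StringIO()
    buf.write("taxon,first_interval,last_interval\n")
    for taxon, intervals in ages.items():
        first = intervals[0]
        last = intervals[-1] if len(intervals) > 1 else ""
        buf.write(f"{taxon},{first},{last}\n")
    return buf.getvalue()
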