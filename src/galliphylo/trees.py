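"""Unrooted trees, bipartitions, Robinson–Foulds distances, and consensus.

Topologies are compared through their internal bipartitions (splits): the two
leaf sets induced by deleting an internal edge.  All comparison utilities in
the package (RF distances, consensus trees, concordance summaries, conflict
reports) reduce to set algebra on :class:`Bipartition` objects, so this module
is the common currency of the analysis.

Newick reading is delegated to :mod:`dendropy`; writing is a small native
serializer so that support values and branch lengths are formatted
predictably.  Rooted newick inputs are unrooted on read (the two root edges
are fused), matching the convention of the distance- and likelihood-based
methods here, which are all unrooted.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "Bipartition",
    "Node",
    "Tree",
    "TreeSample",
    "parse_newick",
    "read_newicks",
    "write_newick",
    "bipartition_set",
    "rf_distance",
    "majority_rule_consensus",
    "tree_from_bipartitions",
    "resolution",
    "sample_metrics",
    "collapse_by_support",
    "conflict_report",
    "enumerate_topologies",
    "random_topology",
]


# ---------------------------------------------------------------------------
# Bipartitions


@dataclass(frozen=True)
class Bipartition:
    """An unrooted split of a taxon set, in canonical orientation.

    ``clade`` is the side *not* containing the lexicographically smallest
    taxon; ``taxa`` is the full leaf set.  Two bipartitions are equal iff they
    cut the same taxon set the same way.
    """

    clade: frozenset
    taxa: frozenset

    @classmethod
    def of(cls, side: Iterable[str], taxa: Iterable[str]) -> "Bipartition":
        taxa = frozenset(taxa)
        side = frozenset(side)
        if not side <= taxa:
            raise ValueError("bipartition side is not a subset of the taxon set")
        anchor = min(taxa)
        if anchor in side:
            side = taxa - side
        return cls(clade=side, taxa=taxa)

    @property
    def other(self) -> frozenset:
        return self.taxa - self.clade

    def is_trivial(self) -> bool:
        return len(self.clade) <= 1 or len(self.other) <= 1

    def compatible_with(self, b: "Bipartition") -> bool:
        """Two splits of one taxon set can coexist in a tree iff one of the
        four pairwise side intersections is empty."""
        if self.taxa != b.taxa:
            raise ValueError("bipartitions are over different taxon sets")
        a1, a2 = self.clade, self.other
        b1, b2 = b.clade, b.other
        return not (a1 & b1) or not (a1 & b2) or not (a2 & b1) or not (a2 & b2)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Bipartition({sorted(self.clade)} | {sorted(self.other)})"


# ---------------------------------------------------------------------------
# Trees


class Node:
    __slots__ = ("label", "length", "support", "children", "parent")

    def __init__(self, label=None, length=None, support=None):
        self.label = label
        self.length = length
        self.support = support
        self.children: list["Node"] = []
        self.parent: "Node | None" = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return reversed(out)

    def leaves(self) -> Iterator["Node"]:
        for nd in self.postorder():
            if nd.is_leaf():
                yield nd


class Tree:
    """A phylogenetic tree over uniquely labelled leaves.

    ``rooted=False`` (the analysis default) means the root node is a purely
    representational anchor of degree >= 3; ``rooted=True`` is used for
    simulated gene trees where the root is meaningful.
    """

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        if not rooted:
            _suppress_root_degree_two(root)
        labels = [lf.label for lf in root.leaves()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        self._taxa = frozenset(labels)

    # -- basic properties ---------------------------------------------------

    @property
    def taxa(self) -> frozenset:
        return self._taxa

    @property
    def n_leaves(self) -> int:
        return len(self._taxa)

    def copy(self) -> "Tree":
        def rec(nd: Node) -> Node:
            new = Node(nd.label, nd.length, nd.support)
            for c in nd.children:
                new.add(rec(c))
            return new

        return Tree(rec(self.root), rooted=self.rooted)

    def unrooted(self) -> "Tree":
        if not self.rooted:
            return self
        return Tree(self.copy().root, rooted=False)

    # -- bipartitions -------------------------------------------------------

    def bipartition_edges(self) -> dict:
        """Map each internal bipartition to the Node below its edge."""
        t = self.unrooted()
        out: dict[Bipartition, Node] = {}
        leafsets: dict[int, frozenset] = {}
        for nd in t.root.postorder():
            if nd.is_leaf():
                leafsets[id(nd)] = frozenset([nd.label])
            else:
                ls = frozenset().union(*(leafsets[id(c)] for c in nd.children))
                leafsets[id(nd)] = ls
                if nd.parent is not None and 1 < len(ls) < t.n_leaves - 1:
                    out[Bipartition.of(ls, t.taxa)] = nd
        return out

    def bipartitions(self) -> frozenset:
        return frozenset(self.bipartition_edges())

    def newick(self, **kw) -> str:
        return write_newick(self, **kw)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.n_leaves} leaves, {len(self.bipartitions())} internal splits)"


def _suppress_root_degree_two(root: Node) -> None:
    """Fuse the two root edges of a rooted binary representation in place."""
    while len(root.children) == 2:
        a, b = root.children
        absorb = b if b.children else a
        keep = a if absorb is b else b
        if not absorb.children:  # two leaves: n == 2, leave as a cherry
            break
        if keep.length is not None or absorb.length is not None:
            keep.length = (keep.length or 0.0) + (absorb.length or 0.0)
        if keep.support is None:
            keep.support = absorb.support
        root.children = list(absorb.children) + [keep]
        for c in root.children:
            c.parent = root
    _suppress_unifurcations(root)


def _suppress_unifurcations(root: Node) -> None:
    for nd in list(root.postorder()):
        if nd.parent is not None and len(nd.children) == 1:
            child = nd.children[0]
            if nd.length is not None or child.length is not None:
                child.length = (child.length or 0.0) + (nd.length or 0.0)
            if child.support is None:
                child.support = nd.support
            siblings = nd.parent.children
            siblings[siblings.index(nd)] = child
            child.parent = nd.parent
    while len(root.children) == 1 and root.children[0].children:
        root.children = root.children[0].children
        for c in root.children:
            c.parent = root


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str, rooted: bool = False) -> Tree:
    """Parse a single newick string.

    Internal node labels are interpreted as edge support values when numeric
    (values <= 1 are posteriors, > 1 bootstrap percentages — both are stored
    verbatim).  Rooted (bifurcating-root) inputs are silently unrooted unless
    ``rooted=True``; a debug message is logged.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise ValueError(f"invalid newick: {exc}") from exc

    def convert(dnd) -> Node:
        if dnd.is_leaf():
            label = dnd.taxon.label if dnd.taxon is not None else dnd.label
            nd = Node(label=label, length=dnd.edge.length)
        else:
            nd = Node(length=dnd.edge.length)
            raw = dnd.label
            if raw is not None:
                try:
                    nd.support = float(raw)
                except ValueError:
                    nd.label = raw
            for c in dnd.child_nodes():
                nd.add(convert(c))
        return nd

    root = convert(dtree.seed_node)
    if not rooted and len(root.children) == 2:
        logger.debug("rooted newick input: unrooting by fusing the root edges")
    return Tree(root, rooted=rooted)


def read_newicks(source, rooted: bool = False) -> list:
    """Read a multi-newick file (or file-like / string with one tree per line)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source) as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(source)
    trees = []
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if chunk:
            trees.append(parse_newick(chunk + ";", rooted=rooted))
    return trees


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return format(x, ".10g")


def write_newick(tree: Tree, lengths: bool = True, supports: bool = True) -> str:
    def rec(nd: Node) -> str:
        if nd.is_leaf():
            s = nd.label
        else:
            s = "(" + ",".join(rec(c) for c in nd.children) + ")"
            if supports and nd.support is not None:
                s += _fmt_num(nd.support)
            elif nd.label:
                s += nd.label
        if lengths and nd.length is not None and nd.parent is not None:
            s += f":{_fmt_num(nd.length)}"
        return s

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# Samples


@dataclass
class TreeSample:
    """An ordered multiset of trees over one taxon set, with provenance."""

    trees: list
    locus: str | None = None
    seed: int | None = None
    replicate_ids: list | None = None

    def __post_init__(self):
        if not self.trees:
            raise ValueError("TreeSample must be nonempty")
        taxa = self.trees[0].taxa
        for i, t in enumerate(self.trees):
            if t.taxa != taxa:
                raise ValueError(f"tree {i} has a different leaf set")

    @property
    def taxa(self) -> frozenset:
        return self.trees[0].taxa

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


# ---------------------------------------------------------------------------
# Operations


def bipartition_set(tree: Tree) -> frozenset:
    """The set of internal (nontrivial) bipartitions of an unrooted tree."""
    return tree.bipartitions()


def _check_same_taxa(t1: Tree, t2: Tree) -> None:
    if t1.taxa != t2.taxa:
        only1 = sorted(t1.taxa - t2.taxa)
        only2 = sorted(t2.taxa - t1.taxa)
        raise ValueError(
            f"leaf sets differ: only in first {only1}, only in second {only2}"
        )


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson–Foulds distance: |B1 symmetric-difference B2|.

    Raw (unnormalized) count over internal bipartitions; defined for
    multifurcating trees, zero iff the topologies are identical.
    """
    _check_same_taxa(t1, t2)
    return len(t1.bipartitions() ^ t2.bipartitions())


def tree_from_bipartitions(
    taxa: Iterable[str],
    bips: Iterable[Bipartition],
    supports: Mapping[Bipartition, float] | None = None,
    lengths: Mapping[Bipartition, float] | None = None,
) -> Tree:
    """Build the unique tree containing exactly a compatible bipartition set.

    Starts from the star tree and refines clades largest-first; incompatible
    input raises ``ValueError``.
    """
    taxa = sorted(set(taxa))
    bips = list(dict.fromkeys(bips))
    for b in bips:
        if b.taxa != frozenset(taxa):
            raise ValueError("bipartition over a different taxon set")
        if b.is_trivial():
            raise ValueError("trivial bipartition in input")
    root = Node()
    for lab in taxa:
        root.add(Node(label=lab))
    leafset = {id(c): frozenset([c.label]) for c in root.children}
    leafset[id(root)] = frozenset(taxa)
    for b in sorted(bips, key=lambda b: -len(b.clade)):
        clade = b.clade
        v = root
        while True:
            nxt = next(
                (c for c in v.children if clade <= leafset[id(c)] and c.children), None
            )
            if nxt is None:
                break
            v = nxt
        group = [c for c in v.children if leafset[id(c)] <= clade]
        covered = frozenset().union(*(leafset[id(c)] for c in group)) if group else frozenset()
        if covered != clade:
            raise ValueError("incompatible bipartition set")
        nd = Node()
        if supports is not None and b in supports:
            nd.support = supports[b]
        if lengths is not None and b in lengths:
            nd.length = lengths[b]
        for c in group:
            v.children.remove(c)
            nd.add(c)
        v.add(nd)
        leafset[id(nd)] = clade
    return Tree(root, rooted=False)


def majority_rule_consensus(sample: TreeSample, threshold: float = 0.5) -> Tree:
    """Majority-rule consensus: exactly the splits with frequency > threshold.

    Edge supports are set to the split frequency x 100.  For thresholds >= 0.5
    the retained splits are automatically mutually compatible.
    """
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0.5, 1]")
    n = len(sample)
    counts: dict[Bipartition, int] = {}
    for t in sample:
        for b in t.bipartitions():
            counts[b] = counts.get(b, 0) + 1
    keep = {b: c / n for b, c in counts.items() if c / n > threshold}
    supports = {b: 100.0 * f for b, f in keep.items()}
    return tree_from_bipartitions(sorted(sample.taxa), keep, supports=supports)


def resolution(tree: Tree) -> float:
    """Fraction of the n-3 possible internal edges that are present."""
    n = tree.n_leaves
    if n < 4:
        raise ValueError("resolution requires at least 4 leaves")
    return len(tree.bipartitions()) / (n - 3)


def sample_metrics(sample: TreeSample) -> dict:
    """Distinct-topology percentage and resolution statistics of a tree sample.

    Mirrors how MCMC tree samples are summarized when diagnosing whether a
    locus has the signal to resolve branches: a chain that keeps revisiting
    the same (possibly polytomous) trees samples few distinct topologies.
    """
    seen = {t.bipartitions() for t in sample}
    res = [resolution(t) for t in sample]
    return {
        "percent_unique": 100.0 * len(seen) / len(sample),
        "mean_resolution": sum(res) / len(res),
        "resolution_range": (min(res), max(res)),
    }


def _support_passes(support, bootstrap_min, posterior_min) -> bool:
    if support <= 1.0:
        return support >= posterior_min
    return support >= bootstrap_min


def collapse_by_support(
    tree: Tree,
    bootstrap_min: float = 70.0,
    posterior_min: float = 0.95,
    on_missing: str = "error",
) -> Tree:
    """Contract internal edges whose support is strictly below threshold.

    Supports <= 1 are read as posterior probabilities, > 1 as bootstrap
    percentages.  An edge at exactly the threshold is retained.  Edges with no
    support raise unless ``on_missing='keep'`` or ``'collapse'``.
    """
    if on_missing not in ("error", "keep", "collapse"):
        raise ValueError("on_missing must be 'error', 'keep' or 'collapse'")
    t = tree.unrooted().copy()
    for nd in list(t.root.postorder()):
        if nd.is_leaf() or nd.parent is None:
            continue
        if nd.support is None:
            if on_missing == "error":
                raise ValueError("internal edge without support value")
            drop = on_missing == "collapse"
        else:
            drop = not _support_passes(nd.support, bootstrap_min, posterior_min)
        if drop:
            siblings = nd.parent.children
            idx = siblings.index(nd)
            siblings[idx : idx + 1] = nd.children
            for c in nd.children:
                c.parent = nd.parent
    return Tree(t.root, rooted=False)


def conflict_report(
    tree_a: Tree, tree_b: Tree, support_min: float = 70.0
) -> list:
    """Pairs of incompatible, strongly supported splits unique to each tree.

    An empty list is the 'no strongly supported conflict' outcome used when
    comparing trees from disjoint data partitions.  Supports are compared on
    their own scale (posterior vs bootstrap) against ``support_min`` expressed
    as a bootstrap percentage; posteriors are compared to ``support_min/100``.
    """
    _check_same_taxa(tree_a, tree_b)
    ea = tree_a.bipartition_edges()
    eb = tree_b.bipartition_edges()
    only_a = {b: nd for b, nd in ea.items() if b not in eb}
    only_b = {b: nd for b, nd in eb.items() if b not in ea}

    def strong(nd) -> bool:
        s = nd.support
        if s is None:
            return False
        return _support_passes(s, support_min, support_min / 100.0)

    pairs = []
    for ba, nda in only_a.items():
        if not strong(nda):
            continue
        for bb, ndb in only_b.items():
            if strong(ndb) and not ba.compatible_with(bb):
                pairs.append((ba, bb))
    return pairs


# ---------------------------------------------------------------------------
# Topology generation (used by oracles and the synthetic-data module)


def _tree_from_nested(nested, labels=None) -> Tree:
    def build(x) -> Node:
        if isinstance(x, str):
            return Node(label=x)
        nd = Node()
        for c in x:
            nd.add(build(c))
        return nd

    return Tree(build(nested), rooted=False)


def enumerate_topologies(labels: Sequence[str]) -> Iterator[Tree]:
    """Yield every distinct unrooted binary topology on the given leaves.

    There are (2n-5)!! of them; practical for n <= ~10.  Trees are generated
    by inserting each new leaf on every edge of every smaller topology.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")

    def grow(edge_lists, label):
        out = []
        for edges in edge_lists:
            for i in range(len(edges)):
                new = [list(e) for e in edges]
                u, v = new[i]
                w = object()  # fresh internal vertex
                new[i] = [u, w]
                new.append([w, v])
                new.append([w, label])
                out.append(new)
        return out

    # edge list representation on abstract vertices; leaves are label strings
    center = object()
    topo_edges = [[[center, labels[0]], [center, labels[1]], [center, labels[2]]]]
    for lab in labels[3:]:
        topo_edges = grow(topo_edges, lab)

    for edges in topo_edges:
        yield _tree_from_edges(edges)


def _vkey(v):
    return v if isinstance(v, str) else id(v)


def _tree_from_edges(edges) -> Tree:
    """Build a Tree from an edge list on (leaf-label | object) vertices."""
    nbrs: dict = {}
    for u, v in edges:
        nbrs.setdefault(_vkey(u), []).append(v)
        nbrs.setdefault(_vkey(v), []).append(u)
    start = next(u for u, _ in edges if not isinstance(u, str))

    def build(vertex, came_from) -> Node:
        if isinstance(vertex, str):
            return Node(label=vertex)
        nd = Node()
        for nb in nbrs[_vkey(vertex)]:
            if came_from is not None and _vkey(nb) == _vkey(came_from):
                continue
            nd.add(build(nb, vertex))
        return nd

    return Tree(build(start, None), rooted=False)


def random_topology(labels: Sequence[str], rng) -> Tree:
    """A uniformly random unrooted binary topology (random edge insertion)."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 leaves")
    center = object()
    edges = [[center, labels[0]], [center, labels[1]], [center, labels[2]]]
    for lab in labels[3:]:
        i = int(rng.integers(len(edges)))
        u, v = edges[i]
        w = object()
        edges[i] = [u, w]
        edges.append([w, v])
        edges.append([w, lab])
    return _tree_from_edges(edges)
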