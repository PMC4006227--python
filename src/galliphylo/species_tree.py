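"""Species-tree estimation from gene-tree samples.

Individual gene trees disagree with the species tree (and with each other)
under the multispecies coalescent.  Two summary approaches are provided:

* **NJst**: for every gene tree, count the edges on the path between each
  pair of leaves (the topological internode distance); average these matrices
  over all sampled trees of all loci; run neighbor joining on the average.
  A consistent species-tree estimator under the coalescent.  Branch lengths
  of the result are internode-distance units, not substitutions.

* **Concordance factors** (naive two-level estimator): per locus, the
  frequency of a clade among that locus's sampled trees; the concordance
  factor is the unweighted mean across loci — an estimate of the proportion
  of sampled genes whose true tree contains the clade.  This is the
  no-pooling limit of hierarchical Bayesian concordance analysis; a CF is a
  property of the genome sample, *not* a support value.  The primary
  concordance tree assembles mutually compatible clades greedily in
  descending CF order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import DistanceMatrix, neighbor_joining
from .trees import Bipartition, Node, Tree, TreeSample, tree_from_bipartitions

__all__ = [
    "GeneTreeSet",
    "internode_matrix",
    "njst",
    "concordance_factors",
    "primary_concordance_tree",
    "support_vs_concordance_report",
]


@dataclass
class GeneTreeSet:
    """Per-locus tree samples over one shared taxon set (complete design)."""

    loci: list  # list of (locus_id, TreeSample)

    def __post_init__(self):
        if not self.loci:
            raise ValueError("empty gene-tree set")
        taxa = self.loci[0][1].taxa
        for name, sample in self.loci:
            if sample.taxa != taxa:
                raise ValueError(f"locus {name}: leaf set differs")

    @property
    def taxa(self) -> frozenset:
        return self.loci[0][1].taxa

    @property
    def locus_ids(self) -> list:
        return [name for name, _ in self.loci]


def internode_matrix(tree: Tree) -> DistanceMatrix:
    """Topological path lengths (edge counts) between all leaf pairs."""
    t = tree.unrooted() if not tree.rooted else tree
    # adjacency over node ids
    nodes = list(t.root.postorder())
    adj: dict[int, list] = {id(nd): [] for nd in nodes}
    for nd in nodes:
        for c in nd.children:
            adj[id(nd)].append(c)
            adj[id(c)].append(nd)
    leaves = sorted((nd for nd in nodes if nd.is_leaf()), key=lambda nd: nd.label)
    taxa = [nd.label for nd in leaves]
    n = len(taxa)
    d = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {id(src): 0}
        frontier = [src]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[id(u)]:
                    if id(v) not in dist:
                        dist[id(v)] = dist[id(u)] + 1
                        nxt.append(v)
            frontier = nxt
        for j, dst in enumerate(leaves):
            d[i, j] = dist[id(dst)]
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(taxa, d)


def average_internode_matrix(g: GeneTreeSet, pool: bool = False) -> DistanceMatrix:
    """Mean internode matrix: per-locus mean, then across-locus mean.

    ``pool=True`` instead weights every sampled tree equally regardless of
    locus sample sizes.
    """
    taxa = sorted(g.taxa)
    per_locus = []
    all_trees = []
    for _, sample in g.loci:
        mats = [internode_matrix(t).values for t in sample]
        per_locus.append(np.mean(mats, axis=0))
        all_trees.extend(mats)
    if pool:
        avg = np.mean(all_trees, axis=0)
    else:
        avg = np.mean(per_locus, axis=0)
    return DistanceMatrix(taxa, avg)


def njst(g: GeneTreeSet, pool: bool = False) -> Tree:
    """NJst species tree: NJ on the average internode-distance matrix.

    The result's branch lengths are in internode-distance units (reported but
    not substitution-scaled).  Loci are weighted equally by default; see
    ``pool`` for equal-tree weighting.
    """
    return neighbor_joining(average_internode_matrix(g, pool=pool))


def concordance_factors(g: GeneTreeSet, clades=None) -> list:
    """Naive concordance factors for a clade set (default: all observed).

    Returns a list of dicts with the bipartition, its CF (mean across loci of
    the within-locus sample frequency), and the per-locus frequencies.
    Trivial bipartitions are excluded.
    """
    taxa = g.taxa
    if clades is None:
        observed = set()
        for _, sample in g.loci:
            for t in sample:
                observed |= t.bipartitions()
        clades = sorted(observed, key=lambda b: (len(b.clade), sorted(b.clade)))
    else:
        clades = list(clades)
        for b in clades:
            if b.taxa != taxa:
                raise ValueError("clade references taxa outside the gene-tree set")
    out = []
    for b in clades:
        per_locus = {}
        for name, sample in g.loci:
            hits = sum(1 for t in sample if b in t.bipartitions())
            per_locus[name] = hits / len(sample)
        cf = float(np.mean(list(per_locus.values())))
        out.append({"bipartition": b, "cf": cf, "per_locus": per_locus})
    return out


def primary_concordance_tree(concordance: list) -> Tree:
    """Greedy compatibility tree from clades in descending CF order.

    Ties on CF are broken lexicographically on the clade's taxon labels.
    The output tree is annotated with the CF of each retained clade as edge
    support (on the 0-1 scale).
    """
    if not concordance:
        raise ValueError("empty concordance table")
    taxa = concordance[0]["bipartition"].taxa
    ranked = sorted(
        concordance, key=lambda r: (-r["cf"], sorted(r["bipartition"].clade))
    )
    accepted: list[Bipartition] = []
    supports = {}
    for row in ranked:
        b = row["bipartition"]
        if all(b.compatible_with(a) for a in accepted):
            accepted.append(b)
            supports[b] = row["cf"]
    return tree_from_bipartitions(sorted(taxa), accepted, supports=supports)


def support_vs_concordance_report(
    species_trees: dict,
    concordance: list,
    support_min: float = 85.0,
    cf_max: float = 0.5,
) -> pd.DataFrame:
    """Per-clade table contrasting support values with concordance factors.

    ``species_trees`` maps an analysis label to a support-annotated tree.
    Clades with support >= ``support_min`` in any analysis but CF <
    ``cf_max`` are flagged: strong support for a clade that most gene trees
    do not contain is exactly the pattern that distinguishes support from
    concordance.
    """
    rows = []
    support_maps = {}
    for label, t in species_trees.items():
        support_maps[label] = {
            b: nd.support for b, nd in t.bipartition_edges().items()
        }
    for rec in concordance:
        b = rec["bipartition"]
        row = {"clade": "|".join(sorted(b.clade)), "cf": rec["cf"]}
        strong = False
        for label, smap in support_maps.items():
            s = smap.get(b)
            row[f"support_{label}"] = s
            if s is not None:
                val = s * 100.0 if s <= 1.0 else s
                strong = strong or val >= support_min
        row["flagged"] = bool(strong and rec["cf"] < cf_max)
        rows.append(row)
    return pd.DataFrame(rows)
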