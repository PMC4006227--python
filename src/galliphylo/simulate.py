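"""Synthetic multilocus datasets with the structure of a rapid radiation.

The generator produces, from one master seed:

1. a random ultrametric species tree in coalescent units, with a configurable
   set of internal branches shortened to "radiation" lengths;
2. per-locus gene trees under the multispecies coalescent (via msprime; one
   haploid lineage per species, population size 1, so time is measured in
   coalescent units and gene-tree discordance follows coalescent theory —
   e.g. a rooted triple with internal branch t is discordant with probability
   (2/3)exp(-t));
3. gap-free sequence alignments evolved along each gene tree under a
   reversible substitution model, with a per-class coalescent-to-substitution
   scale (mitochondrial regions share a single gene tree, evolve faster, and
   have their own base composition);
4. sparse IUPAC two-state ambiguity codes emulating heterozygous calls; and
5. an exclusion mask plus a manifest of every derived seed.

Defaults emulate the galliform study design: 46 taxa, 15 nuclear loci plus 3
mitochondrial regions with the published aligned lengths.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np

from . import alignment as al
from .alignment import MITOCHONDRIAL, NUCLEAR, MultiLocusAlignment
from .datasets import galliform_locus_config
from .inference import SubstitutionModel
from .seeding import derive_seed
from .trees import Node, Tree, parse_newick, write_newick

logger = logging.getLogger(__name__)

_BASES = "ACGT"
#: heterozygous two-state code joining a base with its transition partner
_HET_CODE = {"A": "R", "G": "R", "C": "Y", "T": "Y"}


# ---------------------------------------------------------------------------
# Species trees


@dataclass(frozen=True)
class RadiationSpec:
    """Internal branches to shorten: ``count`` branches set to ``length``
    coalescent units (the hallmark of a rapid radiation)."""

    count: int = 4
    length: float = 0.05


def node_times(tree: Tree) -> dict:
    """Time above the leaves for every node of an ultrametric rooted tree."""
    times: dict[int, float] = {}
    for nd in tree.root.postorder():
        if nd.is_leaf():
            times[id(nd)] = 0.0
        else:
            times[id(nd)] = max(
                times[id(c)] + (c.length or 0.0) for c in nd.children
            )
    return times


def simulate_species_tree(
    n: int,
    seed: int,
    depth: float | None = None,
    radiation: RadiationSpec | None = None,
) -> Tree:
    """Random coalescent-shaped ultrametric species tree on ``n`` taxa.

    Branch lengths are coalescent units.  ``depth`` rescales the whole tree
    to a fixed root height.  ``radiation`` shortens randomly chosen internal
    branches (never the root edge) to the given length by sliding the lower
    node up and compressing its subtree, preserving ultrametricity.
    """
    if n < 2:
        raise ValueError("need >= 2 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1:02d}" for i in range(n)]
    lineages = [(Node(label=lab), 0.0) for lab in labels]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ta), (b, tb) = lineages[i], lineages[j]
        parent = Node()
        a.length = t - ta
        b.length = t - tb
        parent.add(a)
        parent.add(b)
        lineages[i] = (parent, t)
        del lineages[j]
    root = lineages[0][0]
    tree = Tree(root, rooted=True)
    if depth is not None:
        times = node_times(tree)
        scale = depth / times[id(root)]
        for nd in root.postorder():
            if nd.length is not None:
                nd.length *= scale
    if radiation is not None and radiation.count > 0:
        _shorten_branches(tree, radiation, rng)
    return tree


def _shorten_branches(tree: Tree, radiation: RadiationSpec, rng) -> None:
    internal = [
        nd
        for nd in tree.root.postorder()
        if nd.children and nd.parent is not None
    ]
    if radiation.count > len(internal):
        raise ValueError(
            f"radiation names {radiation.count} branches but only "
            f"{len(internal)} internal branches exist"
        )
    times = node_times(tree)
    chosen = rng.choice(len(internal), size=radiation.count, replace=False)
    # root-most first: compressing a subtree rescales everything below it,
    # so deeper chosen branches must be set afterwards
    ordered = sorted(
        (int(i) for i in chosen), key=lambda i: -times[id(internal[i])]
    )
    for idx in ordered:
        nd = internal[idx]
        times = node_times(tree)
        parent_t = times[id(nd.parent)]
        old_t = times[id(nd)]
        new_t = parent_t - radiation.length
        if new_t <= 0 or old_t <= 0:
            continue
        factor = new_t / old_t
        # compress the subtree below nd so it fits under the raised node
        for sub in nd.postorder():
            if sub is nd:
                continue
            if sub.length is not None:
                sub.length *= factor
        nd.length = radiation.length


# ---------------------------------------------------------------------------
# Gene trees (multispecies coalescent via msprime)


def _demography(species_tree: Tree, scale: float = 1.0) -> msprime.Demography:
    times = node_times(species_tree)
    demo = msprime.Demography()
    names: dict[int, str] = {}
    counter = 0
    for nd in species_tree.root.postorder():
        if nd.is_leaf():
            names[id(nd)] = nd.label
            demo.add_population(name=nd.label, initial_size=1.0)
        else:
            counter += 1
            names[id(nd)] = f"anc{counter}"
            demo.add_population(name=f"anc{counter}", initial_size=1.0)
    for nd in species_tree.root.postorder():
        if nd.children:
            demo.add_population_split(
                time=times[id(nd)] * scale,
                derived=[names[id(c)] for c in nd.children],
                ancestral=names[id(nd)],
            )
    demo.sort_events()
    return demo


def simulate_gene_trees(
    species_tree: Tree, k: int, seed: int, scale: float = 1.0
) -> list:
    """``k`` independent gene trees under the multispecies coalescent.

    One haploid lineage per species; population size 1 throughout, so both
    the species-tree input and the gene-tree output are in coalescent units.
    ``scale`` multiplies the species-tree times first (used to emulate the
    smaller effective size of the mitochondrial genome).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    demo = _demography(species_tree, scale=scale)
    labels = sorted(species_tree.taxa)
    reps = msprime.sim_ancestry(
        samples={lab: 1 for lab in labels},
        demography=demo,
        ploidy=1,
        random_seed=seed if 0 < seed < 2**32 else derive_seed(seed),
        num_replicates=k,
    )
    out = []
    for ts in reps:
        t = ts.first()
        node_labels = {}
        for u in ts.samples():
            node_labels[u] = ts.population(ts.node(u).population).metadata["name"]
        newick = t.as_newick(node_labels=node_labels, precision=10)
        out.append(parse_newick(newick, rooted=True))
    return out


# ---------------------------------------------------------------------------
# Sequences


def simulate_sequences(
    gene_tree: Tree,
    length: int,
    model: SubstitutionModel,
    seed: int,
    rate: float = 1.0,
) -> dict:
    """Evolve a gap-free alignment along a rooted gene tree.

    Branch lengths are multiplied by ``rate`` to convert them to expected
    substitutions per site.  Site-to-site rate variation follows the model's
    discrete-gamma categories when ``alpha`` is set.  Returns an ordered
    taxon -> sequence mapping (taxon-sorted).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    pi = np.asarray(model.pi)
    cat_rates = model.category_rates()
    ncat = len(cat_rates)
    cats = rng.integers(0, ncat, size=length) if ncat > 1 else np.zeros(length, int)
    states: dict[int, np.ndarray] = {}
    root = gene_tree.root
    states[id(root)] = rng.choice(4, size=length, p=pi)
    order = [nd for nd in root.postorder()][::-1]  # preorder
    for nd in order:
        if nd is root:
            continue
        t = (nd.length or 0.0) * rate
        parent_states = states[id(nd.parent)]
        child = np.empty(length, dtype=int)
        for c in range(ncat):
            p_mat = model.transition_matrix(t, cat_rates[c])
            cum = p_mat.cumsum(axis=1)
            in_cat = cats == c
            u = rng.random(int(in_cat.sum()))
            rows = cum[parent_states[in_cat]]
            child[in_cat] = (u[:, None] > rows).sum(axis=1)
        states[id(nd)] = child
    seqs = {}
    for leaf in root.leaves():
        seqs[leaf.label] = "".join(_BASES[s] for s in states[id(leaf)])
    return {k: seqs[k] for k in sorted(seqs)}


def inject_ambiguities(aln: dict, rate: float, seed: int) -> dict:
    """Replace ``round(rate * cells)`` random cells with the IUPAC two-state
    code joining the current base and its transition partner (heterozygous
    calls).  ``rate`` is capped at 0.05 — these codes are sparse in real
    data."""
    if not 0.0 <= rate <= 0.05:
        raise ValueError("ambiguity rate must be in [0, 0.05]")
    taxa = list(aln)
    L = len(next(iter(aln.values())))
    cells = len(taxa) * L
    count = round(rate * cells)
    if count == 0:
        return dict(aln)
    rng = np.random.default_rng(seed)
    picks = rng.choice(cells, size=count, replace=False)
    rows = [list(aln[t]) for t in taxa]
    for cell in picks:
        i, j = divmod(int(cell), L)
        base = rows[i][j]
        if base in _HET_CODE:
            rows[i][j] = _HET_CODE[base]
    return {t: "".join(r) for t, r in zip(taxa, rows)}


# ---------------------------------------------------------------------------
# Whole-dataset generation


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped defaults: 46 taxa, 15 nuclear loci + 3 mitochondrial
    regions (published lengths), one shared mitochondrial gene tree, faster
    mitochondrial evolution with its own base composition, sparse
    heterozygosity codes, and a handful of very short internal branches.
    """

    n_taxa: int = 46
    loci: tuple = tuple(galliform_locus_config())
    radiation: RadiationSpec = RadiationSpec(count=4, length=0.05)
    tree_depth: float | None = None
    #: substitutions per coalescent unit for nuclear loci
    nuclear_scale: float = 0.01
    #: mitochondrial rate multiplier (per-generation rate, relative to nuclear)
    mito_rate_multiplier: float = 5.0
    #: mitochondrial effective size is this factor smaller (haploid, maternal)
    mito_ne_factor: float = 4.0
    ambiguity_rate: float = 0.002
    nuclear_model: SubstitutionModel = SubstitutionModel.hky(
        kappa=3.0, pi=(0.27, 0.23, 0.23, 0.27), alpha=1.0
    )
    mito_model: SubstitutionModel = SubstitutionModel.hky(
        kappa=8.0, pi=(0.30, 0.33, 0.12, 0.25), alpha=0.4
    )
    #: fraction of concatenated columns put in the exclusion mask
    exclusion_fraction: float = 0.02
    seed: int = 20140422

    def __post_init__(self):
        if not any(c == MITOCHONDRIAL for _, c, _ in self.loci):
            return
        if self.mito_rate_multiplier <= 1:
            raise ValueError("mitochondrial rate multiplier must exceed 1")


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    species_tree: Tree
    gene_trees: dict  # locus name -> rooted gene tree (mito regions share one)
    locus_alignments: dict  # locus name -> taxon -> sequence
    matrix: MultiLocusAlignment
    exclusion_mask: set
    seeds: dict


def generate_dataset(cfg: GeneratorConfig) -> SyntheticDataset:
    """Deterministically generate the full dataset from ``cfg.seed``.

    Seed paths (see :mod:`galliphylo.seeding`): 0 = species tree; (1, i) =
    gene tree of locus i (one shared draw for all mitochondrial regions);
    (2, i) = sequences of locus i; (3, i) = ambiguity injection; 4 =
    exclusion mask.
    """
    seeds = {"species_tree": derive_seed(cfg.seed, 0)}
    sp = simulate_species_tree(
        cfg.n_taxa, seed=seeds["species_tree"], depth=cfg.tree_depth,
        radiation=cfg.radiation,
    )
    gene_trees: dict[str, Tree] = {}
    mito_tree = None
    loci = list(cfg.loci)
    for i, (name, cls, _L) in enumerate(loci):
        if cls == MITOCHONDRIAL:
            if mito_tree is None:
                s = derive_seed(cfg.seed, 1, i)
                seeds["mito_gene_tree"] = s
                mito_tree = simulate_gene_trees(
                    sp, 1, seed=s, scale=cfg.mito_ne_factor
                )[0]
            gene_trees[name] = mito_tree
        else:
            s = derive_seed(cfg.seed, 1, i)
            seeds[f"gene_tree_{name}"] = s
            gene_trees[name] = simulate_gene_trees(sp, 1, seed=s)[0]

    # mitochondrial substitutions per mito-coalescent unit: per-generation
    # rate is nuclear x multiplier, and one mito coalescent unit is
    # 1/ne_factor of a nuclear one
    mito_scale = cfg.nuclear_scale * cfg.mito_rate_multiplier / cfg.mito_ne_factor
    locus_alignments = {}
    for i, (name, cls, L) in enumerate(loci):
        s = derive_seed(cfg.seed, 2, i)
        seeds[f"sequences_{name}"] = s
        model = cfg.mito_model if cls == MITOCHONDRIAL else cfg.nuclear_model
        scale = mito_scale if cls == MITOCHONDRIAL else cfg.nuclear_scale
        aln = simulate_sequences(gene_trees[name], L, model, seed=s, rate=scale)
        if cls == NUCLEAR and cfg.ambiguity_rate > 0:
            s2 = derive_seed(cfg.seed, 3, i)
            seeds[f"ambiguities_{name}"] = s2
            aln = inject_ambiguities(aln, cfg.ambiguity_rate, seed=s2)
        locus_alignments[name] = aln
    matrix = al.concatenate(
        [(name, cls, locus_alignments[name]) for name, cls, _ in loci]
    )
    seeds["exclusion_mask"] = derive_seed(cfg.seed, 4)
    rng = np.random.default_rng(seeds["exclusion_mask"])
    n_excl = int(round(cfg.exclusion_fraction * matrix.length))
    mask = set(
        int(c) for c in rng.choice(matrix.length, size=n_excl, replace=False)
    )
    return SyntheticDataset(
        config=cfg,
        species_tree=sp,
        gene_trees=gene_trees,
        locus_alignments=locus_alignments,
        matrix=matrix,
        exclusion_mask=mask,
        seeds=seeds,
    )


def write_dataset(cfg: GeneratorConfig, outdir) -> SyntheticDataset:
    """Generate and write the dataset; regeneration from the same config is
    byte-identical.  Emits per-locus FASTA, a concatenated NEXUS with
    charsets, a partition table, true trees, the exclusion mask and a JSON
    manifest of derived seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = generate_dataset(cfg)
    for name, aln in ds.locus_alignments.items():
        al.write_fasta(aln, outdir / f"{name}.fasta")
    al.write_nexus(ds.matrix, outdir / "concatenated.nex")
    al.write_partition_table(ds.matrix, outdir / "partitions.tsv")
    al.write_exclusion_mask(ds.exclusion_mask, outdir / "exclusions.txt")
    (outdir / "species_tree.nwk").write_text(write_newick(ds.species_tree) + "\n")
    with open(outdir / "gene_trees.nwk", "w") as fh:
        for name in ds.gene_trees:
            fh.write(write_newick(ds.gene_trees[name]) + "\n")
    with open(outdir / "gene_trees_manifest.tsv", "w") as fh:
        fh.write("locus\tclass\tlength\n")
        for name, cls, L in cfg.loci:
            fh.write(f"{name}\t{cls}\t{L}\n")
    manifest = {
        "master_seed": cfg.seed,
        "n_taxa": cfg.n_taxa,
        "nuclear_scale": cfg.nuclear_scale,
        "mito_rate_multiplier": cfg.mito_rate_multiplier,
        "mito_ne_factor": cfg.mito_ne_factor,
        "seeds": ds.seeds,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return ds
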