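"""Configuration-driven orchestration of the whole analysis.

One :func:`run` call takes a dataset (synthetic by default) through the full
program: site-class summary, base-composition diagnostics, per-locus gene
trees with bootstrap samples, concatenated-data trees per class and their RF
table, the NJst species tree, concordance factors and the primary concordance
tree, the jackknife size series, and a summary tree with weakly supported or
conflicting nodes collapsed.  Everything is written as TSV / newick / JSON
into a run directory, every stage seed is derived from the master seed, and
two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as al
from . import basecomp, inference, resampling, species_tree, trees
from .alignment import MITOCHONDRIAL, NUCLEAR, MultiLocusAlignment
from .seeding import derive_seed
from .simulate import GeneratorConfig, generate_dataset, write_dataset
from .trees import Tree, TreeSample, write_newick

logger = logging.getLogger(__name__)

_STAGES = (
    "simulate",
    "summarize",
    "basecomp",
    "genetrees",
    "speciestree",
    "jackknife",
    "report",
)


@dataclass
class RunConfig:
    """Settings for a full run.

    Defaults mirror the study design: 500 bootstrap replicates, the 11-size
    jackknife ladder with 100 replicates per size, and 70% bootstrap / 0.95
    posterior support thresholds.  Tests and desk runs scale ``bootstrap_B``,
    ``jackknife_sizes`` and ``jackknife_replicates`` down explicitly.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    data_dir: str | None = None  # load instead of simulating when set
    stages: tuple = _STAGES
    bootstrap_B: int = 500
    bootstrap_method: str = "nj"
    jackknife_sizes: tuple = resampling.STUDY_SIZES
    jackknife_replicates: int = 100
    jackknife_method: str = "nj-jc"
    support_min: float = 70.0
    posterior_min: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.support_min <= 100:
            raise ValueError("support_min must be a percentage in (0, 100]")
        if not 0 < self.posterior_min <= 1:
            raise ValueError("posterior_min must be in (0, 1]")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        need = {
            "summarize": "simulate",
            "basecomp": "simulate",
            "genetrees": "simulate",
            "speciestree": "genetrees",
            "jackknife": "simulate",
            "report": "speciestree",
        }
        for stage, prereq in need.items():
            if stage in self.stages and prereq not in self.stages:
                if prereq == "simulate" and self.data_dir:
                    continue
                raise ValueError(f"stage {stage!r} requires {prereq!r}")


def _load_matrix(data_dir: Path) -> MultiLocusAlignment:
    scheme = al.read_partition_table(data_dir / "partitions.tsv")
    loci = []
    for e in scheme.entries:
        loci.append((e.name, e.locus_class, al.read_fasta(data_dir / f"{e.name}.fasta")))
    return al.concatenate(loci)


def _species_tree_loci(m: MultiLocusAlignment) -> list:
    """Coalescent-unit loci: each nuclear locus alone; all mitochondrial
    regions concatenated as the single locus they really are."""
    out = []
    mito = [e.name for e in m.scheme.entries if e.locus_class == MITOCHONDRIAL]
    for e in m.scheme.entries:
        if e.locus_class == NUCLEAR:
            out.append((e.name, m.partition(e.name)))
    if mito:
        cols = m.scheme.class_columns(MITOCHONDRIAL)
        out.append(("mito", m.take_columns(cols)))
    return out


def run(config: RunConfig, outdir) -> Path:
    """Execute the enabled stages; returns the run directory.

    Deterministic given ``config.seed``: stage seeds are derived by fixed
    paths (10=bootstrap base, 20=jackknife).  Any stage failure aborts with
    the stage name in the exception.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": _config_dict(config), "outputs": {}}
    matrix = None
    reference = {}
    boot_samples: dict[str, TreeSample] = {}

    def emit(name: str, path: Path):
        log["outputs"][name] = path.name

    try:
        if "simulate" in config.stages:
            stage = "simulate"
            data_dir = outdir / "data"
            ds = write_dataset(config.generator, data_dir)
            matrix = ds.matrix
            emit("dataset", data_dir / "manifest.json")
        elif config.data_dir:
            stage = "load"
            matrix = _load_matrix(Path(config.data_dir))
        if matrix is None:
            log_path = outdir / "run_log.json"
            log_path.write_text(json.dumps(log, indent=2, default=str) + "\n")
            return outdir

        if "summarize" in config.stages:
            stage = "summarize"
            summ = al.summarize(matrix)
            summ.to_tsv(outdir / "site_summary.tsv")
            emit("site_summary", outdir / "site_summary.tsv")

        if "basecomp" in config.stages:
            stage = "basecomp"
            rep = basecomp.basecomp_report(matrix)
            rep.to_csv(outdir / "basecomp.tsv", sep="\t", index=False)
            ct = basecomp.composition(matrix, sites="variable")
            nj = basecomp.composition_distance_tree(ct)
            (outdir / "composition_nj.nwk").write_text(write_newick(nj) + "\n")
            emit("basecomp", outdir / "basecomp.tsv")

        if "genetrees" in config.stages:
            stage = "genetrees"
            loci = _species_tree_loci(matrix)
            with open(outdir / "locus_trees.nwk", "w") as fh, open(
                outdir / "bootstrap_manifest.tsv", "w"
            ) as mf:
                mf.write("locus\tseed\treplicates\tmethod\n")
                for i, (name, sub) in enumerate(loci):
                    s = derive_seed(config.seed, 10, i)
                    sample = inference.bootstrap_trees(
                        sub, config.bootstrap_B, method=config.bootstrap_method,
                        seed=s, locus=name,
                    )
                    boot_samples[name] = sample
                    best = resampling.METHODS["nj-jc"](sub)
                    fh.write(f"{write_newick(best)}\n")
                    with open(outdir / f"bootstrap_{name}.nwk", "w") as bh:
                        for t in sample:
                            bh.write(write_newick(t) + "\n")
                    mf.write(f"{name}\t{s}\t{config.bootstrap_B}\t"
                             f"{config.bootstrap_method}\n")
            # concatenated trees per class, with bootstrap-consensus supports
            class_trees = {}
            subsets = {"total": matrix}
            nuc = matrix.scheme.class_columns(NUCLEAR)
            mit = matrix.scheme.class_columns(MITOCHONDRIAL)
            if nuc.size:
                subsets["nuclear"] = matrix.take_columns(nuc)
            if mit.size:
                subsets["mitochondrial"] = matrix.take_columns(mit)
            for j, (label, sub) in enumerate(subsets.items()):
                s = derive_seed(config.seed, 11, j)
                sample = inference.bootstrap_trees(
                    sub, config.bootstrap_B, method=config.bootstrap_method,
                    seed=s, locus=label,
                )
                cons = trees.majority_rule_consensus(sample)
                class_trees[label] = cons
                (outdir / f"concat_{label}.nwk").write_text(
                    write_newick(cons) + "\n"
                )
            rows = []
            labels = list(class_trees)
            for a in range(len(labels)):
                for b in range(a + 1, len(labels)):
                    rows.append(
                        {
                            "tree_a": labels[a],
                            "tree_b": labels[b],
                            "rf": trees.rf_distance(
                                class_trees[labels[a]], class_trees[labels[b]]
                            ),
                        }
                    )
            pd.DataFrame(rows).to_csv(outdir / "class_rf.tsv", sep="\t", index=False)
            reference.update(class_trees)
            emit("class_rf", outdir / "class_rf.tsv")

        if "speciestree" in config.stages:
            stage = "speciestree"
            gts = species_tree.GeneTreeSet(
                [(n, s) for n, s in boot_samples.items()]
            )
            nj_st = species_tree.njst(gts)
            (outdir / "njst.nwk").write_text(write_newick(nj_st) + "\n")
            cf = species_tree.concordance_factors(gts)
            pct = species_tree.primary_concordance_tree(cf)
            (outdir / "primary_concordance.nwk").write_text(
                write_newick(pct) + "\n"
            )
            cf_rows = [
                {"clade": "|".join(sorted(r["bipartition"].clade)), "cf": r["cf"]}
                for r in cf
            ]
            pd.DataFrame(cf_rows).to_csv(outdir / "cf_table.tsv", sep="\t", index=False)
            reference["njst"] = nj_st
            reference["_cf"] = cf
            emit("njst", outdir / "njst.nwk")

        if "jackknife" in config.stages:
            stage = "jackknife"
            nuc_cols = matrix.scheme.class_columns(NUCLEAR)
            nuc = matrix.take_columns(nuc_cols)
            ref = reference.get("nuclear") or resampling.METHODS[
                config.jackknife_method
            ](nuc)
            sizes = tuple(s for s in config.jackknife_sizes if s <= nuc.length)
            design = resampling.JackknifeDesign(
                sizes=sizes,
                replicates=config.jackknife_replicates,
                method=config.jackknife_method,
                seed=derive_seed(config.seed, 20),
            )
            table = resampling.size_series(nuc, design, ref)
            table.to_tsv(outdir / "jackknife.tsv")
            table.summary().to_csv(
                outdir / "jackknife_summary.tsv", sep="\t", index=False
            )
            emit("jackknife", outdir / "jackknife.tsv")

        if "report" in config.stages:
            stage = "report"
            total = reference.get("total")
            nj_st = reference.get("njst")
            if total is not None and nj_st is not None:
                summary = summary_tree(
                    total, nj_st, config.support_min, config.posterior_min
                )
                (outdir / "summary_tree.nwk").write_text(
                    write_newick(summary) + "\n"
                )
                cf = reference.get("_cf")
                if cf is not None:
                    svc = species_tree.support_vs_concordance_report(
                        {"total": total, "njst_consensus": nj_st}, cf
                    )
                    svc.to_csv(
                        outdir / "support_vs_cf.tsv", sep="\t", index=False
                    )
                emit("summary_tree", outdir / "summary_tree.nwk")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, default=str) + "\n")
    checksums = run_checksums(outdir)
    (outdir / "checksums.json").write_text(
        json.dumps(checksums, indent=2) + "\n"
    )
    return outdir


def summary_tree(
    supported: Tree,
    other: Tree,
    support_min: float = 70.0,
    posterior_min: float = 0.95,
) -> Tree:
    """Best-estimate summary: collapse weakly supported nodes and nodes in
    conflict between two analyses.

    Keeps a split of ``supported`` iff its support passes the thresholds and
    it is compatible with every split of ``other``.
    """
    collapsed = trees.collapse_by_support(
        supported, support_min, posterior_min, on_missing="collapse"
    )
    other_bips = other.bipartitions()
    edges = collapsed.bipartition_edges()
    keep = {
        b: nd.support
        for b, nd in edges.items()
        if all(b.compatible_with(o) for o in other_bips)
    }
    return trees.tree_from_bipartitions(sorted(supported.taxa), keep, supports=keep)


def independent_evidence(
    matrix: MultiLocusAlignment,
    subsets: tuple,
    B: int = 100,
    support_min: float = 70.0,
    seed: int = 0,
    method: str = "nj",
) -> dict:
    """Disjoint-locus comparison: infer a bootstrap-consensus tree per locus
    subset and count strongly supported conflicts between them.

    Zero conflicts is the 'little or no conflicting signal' outcome that
    justifies combining independent data matrices.
    """
    a, b = subsets
    if set(a) & set(b):
        raise ValueError("subsets overlap")
    if not a or not b:
        raise ValueError("both subsets must be nonempty")
    first = matrix.take_columns(
        np.concatenate([matrix.scheme.columns_of(n) for n in a])
    )
    second = matrix.take_columns(
        np.concatenate([matrix.scheme.columns_of(n) for n in b])
    )
    cons = []
    for i, sub in enumerate((first, second)):
        sample = inference.bootstrap_trees(
            sub, B, method=method, seed=derive_seed(seed, 30, i)
        )
        cons.append(trees.majority_rule_consensus(sample))
    conflicts = trees.conflict_report(cons[0], cons[1], support_min=support_min)
    return {
        "tree_a": cons[0],
        "tree_b": cons[1],
        "conflicts": conflicts,
        "n_strong_conflicts": len(conflicts),
    }


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def run_checksums(outdir) -> dict:
    """sha256 of every regular output file in a run directory (recursive),
    excluding the checksum file itself."""
    outdir = Path(outdir)
    out = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "checksums.json":
            out[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    return out
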