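"""Site-jackknife experiments: does more sequence help, and how much?

A jackknifed dataset is a fixed number of alignment columns sampled *without*
replacement from the (nuclear) concatenated matrix.  Repeating this at a
ladder of sizes and measuring each replicate tree's RF distance to the
full-data reference traces how estimation error shrinks as data grow; the
companion comparison asks whether an individual locus does better or worse
than a random site sample of the same size (it usually does worse, because a
single locus carries a single gene history plus its own idiosyncrasies).

Only nuclear data enter the series by default: the mitochondrial genome is
one finite, fast-evolving locus, so "more data" in practice means more
nuclear sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference
from .alignment import NUCLEAR, MultiLocusAlignment
from .seeding import derive_seed
from .trees import Tree, rf_distance

logger = logging.getLogger(__name__)

#: the size ladder used in the galliform study (nuclear matrix = 12731 bp)
STUDY_SIZES = (450, 550, 650, 750, 1000, 1100, 1650, 2000, 5000, 8000, 11000)


def _infer_nj(aln: MultiLocusAlignment, distance: str = "JC") -> Tree:
    return inference.neighbor_joining(inference.distance_matrix(aln, distance))


def _infer_nj_nni(aln: MultiLocusAlignment) -> Tree:
    start = _infer_nj(aln)
    model = inference.SubstitutionModel.gtr(
        (1.0, 2.0, 1.0, 1.0, 2.0, 1.0),
        tuple(inference.empirical_frequencies(aln)),
        alpha=0.5,
    )
    return inference.nni_hill_climb(start, aln, model)


#: replicate-inference registry; results are only comparable within one tag
METHODS = {
    "nj-jc": _infer_nj,
    "nj-p": lambda aln: _infer_nj(aln, "p"),
    "nj+nni": _infer_nj_nni,
}


@dataclass
class JackknifeDesign:
    sizes: tuple = STUDY_SIZES
    replicates: int = 100
    method: str = "nj-jc"
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(s < 1 for s in self.sizes):
            raise ValueError("sizes must be positive")
        if self.method not in METHODS:
            raise ValueError(f"unknown method tag {self.method!r}")


@dataclass
class ExperimentTable:
    """Tidy (size, replicate, seed, rf) records plus the method tag."""

    records: pd.DataFrame
    method: str

    def summary(self) -> pd.DataFrame:
        g = self.records.groupby("size")["rf"]
        out = pd.DataFrame(
            {"mean_rf": g.mean(), "sd_rf": g.std(ddof=1).fillna(0.0)}
        ).reset_index()
        return out

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def jackknife_dataset(
    m: MultiLocusAlignment, L: int, seed: int, replace: bool = False
) -> MultiLocusAlignment:
    """Sample ``L`` columns uniformly without replacement (with, if asked).

    Columns are kept in their original order; each sampled column's partition
    identity and original coordinate survive via the remapped scheme and
    ``source_columns``.
    """
    if not 1 <= L <= m.length:
        raise ValueError(f"L={L} out of range 1..{m.length}")
    rng = np.random.default_rng(seed)
    cols = rng.choice(m.length, size=L, replace=replace)
    cols.sort()
    return m.take_columns(cols)


def size_series(
    m: MultiLocusAlignment,
    design: JackknifeDesign,
    reference: Tree,
    allow_non_nuclear: bool = False,
) -> ExperimentTable:
    """Jackknife at every design size, infer a tree per replicate, record RF
    to the reference.

    Per-replicate seeds come from ``derive_seed(design.seed, size_index,
    replicate)``, so any single replicate is reproducible alone.  Non-nuclear
    partitions are an error unless ``allow_non_nuclear``.
    """
    if not allow_non_nuclear:
        bad = [e.name for e in m.scheme.entries if e.locus_class != NUCLEAR]
        if bad:
            raise ValueError(
                f"non-nuclear partitions {bad}; pass allow_non_nuclear=True to "
                "override"
            )
    if reference.taxa != frozenset(m.taxa):
        raise ValueError("reference tree taxa do not match the matrix")
    infer = METHODS[design.method]
    rows = []
    for si, size in enumerate(design.sizes):
        for rep in range(design.replicates):
            s = derive_seed(design.seed, si, rep)
            sub = jackknife_dataset(m, size, seed=s)
            tree = infer(sub)
            rows.append(
                {
                    "size": size,
                    "replicate": rep,
                    "seed": s,
                    "rf": rf_distance(tree, reference),
                }
            )
    return ExperimentTable(records=pd.DataFrame(rows), method=design.method)


def locus_vs_jackknife(
    locus_trees: dict,
    locus_lengths: dict,
    table: ExperimentTable,
    reference: Tree,
) -> pd.DataFrame:
    """Compare each locus tree against jackknife replicates of similar size.

    Per locus: its RF to the reference, the jackknife mean +/- SD at the
    nearest size, and a flag — 'better than average' / 'comparable' / 'worse
    than average' beyond one SD, or 'no comparable size' when no jackknife
    size is within a factor of two of the locus length.
    """
    summary = table.summary()
    sizes = summary["size"].to_numpy()
    rows = []
    for name, tree in locus_trees.items():
        L = locus_lengths[name]
        rf = rf_distance(tree, reference)
        diffs = np.abs(sizes - L)
        nearest = int(sizes[diffs.argmin()])
        if not (L / 2 <= nearest <= L * 2):
            rows.append(
                {
                    "locus": name, "length": L, "rf": rf, "nearest_size": nearest,
                    "mean_rf": np.nan, "sd_rf": np.nan, "flag": "no comparable size",
                }
            )
            continue
        row = summary[summary["size"] == nearest].iloc[0]
        mean, sd = float(row["mean_rf"]), float(row["sd_rf"])
        if rf < mean - sd:
            flag = "better than average"
        elif rf > mean + sd:
            flag = "worse than average"
        else:
            flag = "comparable"
        rows.append(
            {
                "locus": name, "length": L, "rf": rf, "nearest_size": nearest,
                "mean_rf": mean, "sd_rf": sd, "flag": flag,
            }
        )
    return pd.DataFrame(rows)
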