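"""Base-composition heterogeneity diagnostics.

Nonstationary base composition can make unrelated taxa attract each other in
tree estimation.  Before trusting a multilocus phylogeny, three cheap
diagnostics are run per data partition:

* a Pearson chi-square test of composition homogeneity across taxa (with the
  standard caveat that taxa are not independent draws, so the p-value is an
  index, not a calibrated error rate);
* relative composition variability (RCV), the mean absolute deviation of
  per-taxon base counts from the across-taxon mean, normalized by taxa x
  sites — a single comparable heterogeneity number per partition;
* a neighbor-joining tree on Euclidean distances between per-taxon
  composition vectors — if that tree mirrors the phylogeny, composition may
  be driving clades.

All three default to variable sites only, where compositional signal
concentrates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import inference, trees
from .alignment import MultiLocusAlignment, _column_classes

logger = logging.getLogger(__name__)

CHI2_CAVEAT = (
    "chi-square p-values assume independent taxa; related taxa violate this, "
    "so treat p as a heterogeneity index rather than a calibrated test"
)


@dataclass
class CompositionTable:
    """Per-taxon A,C,G,T counts over a designated site set."""

    taxa: list
    counts: np.ndarray  # (n_taxa, 4) nonnegative ints
    site_set: str = "variable"

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.taxa), 4):
            raise ValueError("counts must be n_taxa x 4")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> np.ndarray:
        """Per-taxon frequency vectors (rows with zero total stay zero)."""
        tot = self.totals
        out = np.zeros_like(self.counts)
        nz = tot > 0
        out[nz] = self.counts[nz] / tot[nz, None]
        return out

    @property
    def mean_frequencies(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts.sum(axis=0) / tot if tot else np.zeros(4)

    def zero_taxa(self) -> list:
        return [t for t, tot in zip(self.taxa, self.totals) if tot == 0]


def composition(
    m: MultiLocusAlignment,
    partition: str | None = None,
    sites: str = "variable",
) -> CompositionTable:
    """Tally A,C,G,T per taxon; ambiguity codes and gaps are never counted.

    ``partition=None`` pools the whole matrix; ``sites`` is ``'variable'``
    (default) or ``'all'``.
    """
    sub = m if partition is None else m.partition(partition)
    codes = sub.codes()
    if sites == "variable":
        variable, _ = _column_classes(sub)
        codes = codes[:, variable]
    elif sites != "all":
        raise ValueError("sites must be 'variable' or 'all'")
    counts = np.stack([(codes == k).sum(axis=1) for k in range(4)], axis=1)
    ct = CompositionTable(list(sub.taxa), counts, site_set=sites)
    if ct.zero_taxa():
        logger.warning("taxa with no countable sites: %s", ct.zero_taxa())
    return ct


def chi2_homogeneity(ct: CompositionTable) -> dict:
    """Pearson chi-square test of across-taxon composition homogeneity.

    Rows (taxa) with zero totals are dropped; base columns with zero pooled
    count are dropped with a warning and the degrees of freedom adjusted.
    Returns statistic, df, p_value and the non-independence caveat.
    """
    counts = ct.counts[ct.totals > 0]
    if counts.shape[0] < 2:
        raise ValueError("need >= 2 taxa with positive totals")
    col_tot = counts.sum(axis=0)
    if (col_tot == 0).any():
        dropped = [b for b, c in zip("ACGT", col_tot) if c == 0]
        logger.warning("bases with zero pooled count dropped: %s", dropped)
        counts = counts[:, col_tot > 0]
    n_rows, n_cols = counts.shape
    grand = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / grand
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = (n_rows - 1) * (n_cols - 1)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return {"statistic": statistic, "df": df, "p_value": p, "caveat": CHI2_CAVEAT}


def rcv(ct: CompositionTable, on: str = "counts") -> float:
    """Relative composition variability.

    On counts (default): sum over taxa of the absolute deviations of the four
    base counts from their across-taxon means, divided by (n_taxa x n_sites),
    with n_sites the mean per-taxon total of counted sites.  ``on='frequencies'``
    applies the same formula to per-taxon frequency vectors with denominator
    n_taxa.
    """
    n_taxa = len(ct.taxa)
    if on == "counts":
        t = ct.totals.mean()
        if t == 0:
            raise ValueError("no counted sites")
        dev = np.abs(ct.counts - ct.counts.mean(axis=0)).sum()
        return float(dev / (n_taxa * t))
    elif on == "frequencies":
        freqs = ct.frequencies
        dev = np.abs(freqs - freqs.mean(axis=0)).sum()
        return float(dev / n_taxa)
    raise ValueError("on must be 'counts' or 'frequencies'")


def composition_distance_tree(ct: CompositionTable) -> trees.Tree:
    """NJ tree on Euclidean distances between composition frequency vectors.

    A visual diagnostic: clusters here that match clades in the phylogeny
    would suggest composition-driven attraction.
    """
    if len(ct.taxa) < 4:
        raise ValueError("need >= 4 taxa")
    freqs = ct.frequencies
    diff = freqs[:, None, :] - freqs[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    dm = inference.DistanceMatrix(list(ct.taxa), d)
    return inference.neighbor_joining(dm)


def composition_distance_matrix(ct: CompositionTable) -> "inference.DistanceMatrix":
    freqs = ct.frequencies
    diff = freqs[:, None, :] - freqs[None, :, :]
    return inference.DistanceMatrix(list(ct.taxa), np.sqrt((diff**2).sum(axis=2)))


def rcv_ranking(per_partition_rcv: dict) -> pd.DataFrame:
    """Rank partitions by RCV (descending) and flag the top quartile.

    ``ceil(k/4)`` partitions are flagged; ties are broken by partition name so
    the ranking is stable.
    """
    if len(per_partition_rcv) < 4:
        raise ValueError("need >= 4 partitions to rank quartiles")
    items = sorted(per_partition_rcv.items(), key=lambda kv: (-kv[1], kv[0]))
    k_flag = math.ceil(len(items) / 4)
    return pd.DataFrame(
        {
            "partition": [n for n, _ in items],
            "rcv": [v for _, v in items],
            "top_quartile": [i < k_flag for i in range(len(items))],
        }
    )


def basecomp_report(m: MultiLocusAlignment, sites: str = "variable") -> pd.DataFrame:
    """Per-partition chi-square + RCV table with top-quartile flags."""
    rows = []
    rcvs = {}
    for e in m.scheme.entries:
        ct = composition(m, partition=e.name, sites=sites)
        test = chi2_homogeneity(ct)
        rcvs[e.name] = rcv(ct)
        rows.append(
            {
                "partition": e.name,
                "class": e.locus_class,
                "chi2": test["statistic"],
                "df": test["df"],
                "p_value": test["p_value"],
                "rcv": rcvs[e.name],
            }
        )
    df = pd.DataFrame(rows)
    if len(rcvs) >= 4:
        ranking = rcv_ranking(rcvs)
        flags = dict(zip(ranking["partition"], ranking["top_quartile"]))
        df["rcv_top_quartile"] = [flags[n] for n in df["partition"]]
    return df
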