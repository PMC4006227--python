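"""Multilocus alignment assembly, partitioning, masking and site-class counts.

The data matrix is deliberately *complete*: every locus sampled for every
taxon.  That is a design feature of the study system this package targets
(missing data can then play no role in the results), so ragged input is an
error here, never silently padded.

Columns are IUPAC nucleotide symbols.  Site classification (constant /
variable-uninformative / parsimony-informative) by default treats ambiguity
codes, ``-`` and ``?`` as missing; an ``ambiguity='expand'`` mode instead
counts a site as variable only when no single state is compatible with every
symbol in the column.

Coordinates are 0-based half-open internally; every user-facing partition or
exclusion file is 1-based inclusive, the convention of common partition files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEAR = "nuclear"
MITOCHONDRIAL = "mitochondrial"

#: IUPAC nucleotide symbols -> compatible unambiguous states ('' = missing)
IUPAC_STATES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
    "-": "", "?": "",
}

CONSTANT = "constant"
VARIABLE_UNINFORMATIVE = "variable_uninformative"
PARSIMONY_INFORMATIVE = "parsimony_informative"

_BASES = "ACGT"
# byte-value lookup: 0..3 for unambiguous bases, -1 for missing/ambiguous
_CODE = np.full(256, -2, dtype=np.int8)
for _sym, _states in IUPAC_STATES.items():
    _CODE[ord(_sym)] = _BASES.index(_states) if len(_states) == 1 else -1
    _CODE[ord(_sym.lower())] = _CODE[ord(_sym)]


def round_half_up_percent(x: float) -> int:
    """Integer percent with ties rounded up (55.5 -> 56), matching
    whole-percent reporting conventions."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Partition scheme


@dataclass(frozen=True)
class PartitionEntry:
    name: str
    locus_class: str  # NUCLEAR or MITOCHONDRIAL
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PartitionScheme:
    entries: tuple

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate partition names")
        pos = 0
        for e in self.entries:
            if e.start != pos or e.end <= e.start:
                raise ValueError(
                    "partition intervals must be contiguous, ordered and nonempty"
                )
            if e.locus_class not in (NUCLEAR, MITOCHONDRIAL):
                raise ValueError(f"unknown locus class {e.locus_class!r}")
            pos = e.end

    @property
    def total_length(self) -> int:
        return self.entries[-1].end if self.entries else 0

    @property
    def names(self) -> list:
        return [e.name for e in self.entries]

    def __getitem__(self, name: str) -> PartitionEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def columns_of(self, name: str) -> np.ndarray:
        e = self[name]
        return np.arange(e.start, e.end)

    def class_columns(self, locus_class: str) -> np.ndarray:
        cols = [
            np.arange(e.start, e.end)
            for e in self.entries
            if e.locus_class == locus_class
        ]
        return np.concatenate(cols) if cols else np.empty(0, dtype=int)


# ---------------------------------------------------------------------------
# The matrix


class MultiLocusAlignment:
    """Rectangular taxa x sites IUPAC matrix with a partition scheme.

    ``source_columns`` records, for each current column, its coordinate in
    the matrix as originally assembled — provenance that survives exclusion
    masking and jackknife subsampling.
    """

    def __init__(
        self,
        taxa: Sequence[str],
        data: np.ndarray,
        scheme: PartitionScheme,
        source_columns: np.ndarray | None = None,
    ):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        data = np.asarray(data, dtype="S1")
        if data.ndim != 2 or data.shape[0] != len(self.taxa):
            raise ValueError("data must be a taxa x sites matrix")
        bad = set(np.unique(data)) - {s.encode() for s in IUPAC_STATES} - {
            s.lower().encode() for s in IUPAC_STATES
        }
        if bad:
            raise ValueError(f"non-IUPAC symbols in matrix: {sorted(bad)}")
        self.data = np.char.upper(data)
        if scheme.total_length != data.shape[1]:
            raise ValueError("partition scheme does not cover the matrix")
        self.scheme = scheme
        if source_columns is None:
            source_columns = np.arange(data.shape[1])
        self.source_columns = np.asarray(source_columns, dtype=int)
        if self.source_columns.shape != (data.shape[1],):
            raise ValueError("source_columns must have one entry per column")

    # -- basics -------------------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def sequence(self, taxon: str) -> str:
        i = self.taxa.index(taxon)
        return self.data[i].tobytes().decode()

    def codes(self) -> np.ndarray:
        """int8 matrix: 0..3 = A,C,G,T; -1 = ambiguous/gap/missing."""
        return _CODE[self.data.view(np.uint8)]

    def take_columns(
        self,
        cols: np.ndarray,
        scheme: PartitionScheme | None = None,
        warn_dropped: bool = False,
    ):
        cols = np.asarray(cols, dtype=int)
        if scheme is None:
            scheme = _remap_scheme(self.scheme, cols, warn_dropped=warn_dropped)
        return MultiLocusAlignment(
            self.taxa, self.data[:, cols], scheme, self.source_columns[cols]
        )

    def partition(self, name: str) -> "MultiLocusAlignment":
        e = self.scheme[name]
        cols = np.arange(e.start, e.end)
        sub = PartitionScheme([PartitionEntry(e.name, e.locus_class, 0, e.length)])
        return self.take_columns(cols, scheme=sub)

    def column_partition_names(self) -> np.ndarray:
        out = np.empty(self.length, dtype=object)
        for e in self.scheme.entries:
            out[e.start : e.end] = e.name
        return out


def _remap_scheme(
    scheme: PartitionScheme, cols: np.ndarray, warn_dropped: bool = False
) -> PartitionScheme:
    """Scheme for a column subset, preserving per-column partition identity.

    Valid when the subset keeps columns in partition order (exclusion masks,
    per-partition slices).  Zero-length partitions are dropped with a warning.
    """
    names = np.empty(scheme.total_length, dtype=object)
    classes = {}
    for e in scheme.entries:
        names[e.start : e.end] = e.name
        classes[e.name] = e.locus_class
    kept = names[cols]
    entries = []
    pos = 0
    for e in scheme.entries:
        n = int((kept == e.name).sum())
        if n == 0:
            if warn_dropped:
                logger.warning(
                    "partition %s has no remaining columns; dropped", e.name
                )
            continue
        entries.append(PartitionEntry(e.name, e.locus_class, pos, pos + n))
        pos += n
    return PartitionScheme(entries)


# ---------------------------------------------------------------------------
# Assembly


def concatenate(loci: Iterable[tuple]) -> MultiLocusAlignment:
    """Concatenate per-locus alignments into one complete matrix.

    ``loci`` is an iterable of ``(name, locus_class, alignment)`` where the
    alignment is a mapping taxon -> sequence.  Every locus must cover exactly
    the same taxon set; offenders are listed in the error.
    """
    loci = list(loci)
    if not loci:
        raise ValueError("no loci given")
    ref_taxa = list(loci[0][2].keys())
    ref_set = set(ref_taxa)
    entries = []
    blocks = []
    pos = 0
    for name, cls, aln in loci:
        tset = set(aln.keys())
        if tset != ref_set:
            missing = sorted(ref_set - tset)
            extra = sorted(tset - ref_set)
            raise ValueError(
                f"locus {name}: taxon set mismatch (missing {missing}, extra {extra})"
            )
        lens = {len(s) for s in aln.values()}
        if len(lens) != 1:
            raise ValueError(f"locus {name}: ragged alignment")
        L = lens.pop()
        block = np.array(
            [np.frombuffer(aln[t].upper().encode(), dtype="S1") for t in ref_taxa]
        )
        blocks.append(block)
        entries.append(PartitionEntry(name, cls, pos, pos + L))
        pos += L
    data = np.concatenate(blocks, axis=1)
    return MultiLocusAlignment(ref_taxa, data, PartitionScheme(entries))


def apply_exclusions(m: MultiLocusAlignment, mask: Iterable[int]) -> MultiLocusAlignment:
    """Drop the masked columns (0-based, in current coordinates).

    The result's ``source_columns`` keep pointing at the original assembly, so
    excluded-site bookkeeping survives downstream subsetting.
    """
    mask = set(int(i) for i in mask)
    bad = [i for i in mask if not 0 <= i < m.length]
    if bad:
        raise IndexError(f"mask indices out of range: {sorted(bad)[:10]}")
    keep = np.array([i for i in range(m.length) if i not in mask], dtype=int)
    return m.take_columns(keep, warn_dropped=True)


def split_disjoint(
    m: MultiLocusAlignment, subset: Iterable[str]
) -> tuple[MultiLocusAlignment, MultiLocusAlignment]:
    """Split into two disjoint-locus matrices: (subset, complement)."""
    subset = list(dict.fromkeys(subset))
    unknown = [s for s in subset if s not in m.scheme.names]
    if unknown:
        raise KeyError(f"unknown locus names: {unknown}")
    if not subset or len(subset) == len(m.scheme.names):
        raise ValueError("subset must be nonempty and proper")
    inside = [n for n in m.scheme.names if n in subset]
    outside = [n for n in m.scheme.names if n not in subset]

    def build(names):
        cols = np.concatenate([m.scheme.columns_of(n) for n in names])
        return m.take_columns(cols)

    return build(inside), build(outside)


# ---------------------------------------------------------------------------
# Site classification


def site_class(column: Iterable[str], ambiguity: str = "missing") -> str:
    """Classify one alignment column.

    ``ambiguity='missing'`` (default): ambiguity codes, ``-`` and ``?`` are
    ignored; the column is variable iff >= 2 distinct unambiguous states occur
    and parsimony-informative iff >= 2 states each occur in >= 2 taxa.
    ``ambiguity='expand'``: the column counts as variable only if no single
    state is compatible with every non-missing symbol.
    """
    syms = [str(s).upper() for s in column]
    if not syms:
        raise ValueError("empty column")
    for s in syms:
        if s not in IUPAC_STATES:
            raise ValueError(f"non-IUPAC symbol {s!r}")
    plain = [s for s in syms if len(IUPAC_STATES[s]) == 1]
    counts = {b: plain.count(b) for b in set(plain)}
    if ambiguity == "missing":
        variable = len(counts) >= 2
    elif ambiguity == "expand":
        sets = [set(IUPAC_STATES[s]) for s in syms if IUPAC_STATES[s]]
        variable = bool(sets) and not set.intersection(*sets)
    else:
        raise ValueError("ambiguity must be 'missing' or 'expand'")
    if not variable:
        return CONSTANT
    informative = sum(1 for c in counts.values() if c >= 2) >= 2
    return PARSIMONY_INFORMATIVE if informative else VARIABLE_UNINFORMATIVE


def _column_classes(m: MultiLocusAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (variable, informative) boolean vectors over columns."""
    codes = m.codes()
    counts = np.stack([(codes == k).sum(axis=0) for k in range(4)])
    variable = (counts > 0).sum(axis=0) >= 2
    informative = (counts >= 2).sum(axis=0) >= 2
    return variable, informative


# ---------------------------------------------------------------------------
# Summaries


@dataclass
class SiteClassSummary:
    """Per-partition and per-class site counts (a Table-2-style report)."""

    per_partition: pd.DataFrame  # name, class, length, variable, informative, pct_*
    pooled: pd.DataFrame  # class, length, variable, informative, pct_*

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            self.per_partition.to_csv(fh, sep="\t", index=False)
            fh.write("\n")
            self.pooled.to_csv(fh, sep="\t", index=False)


def _with_percentages(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["pct_variable"] = [
        round_half_up_percent(100.0 * v / l) for v, l in zip(df["variable"], df["length"])
    ]
    df["pct_informative"] = [
        round_half_up_percent(100.0 * i / l)
        for i, l in zip(df["informative"], df["length"])
    ]
    return df


def summarize(m: MultiLocusAlignment) -> SiteClassSummary:
    """Site-class accounting per partition and pooled per locus class."""
    variable, informative = _column_classes(m)
    rows = []
    for e in m.scheme.entries:
        sl = slice(e.start, e.end)
        rows.append(
            {
                "name": e.name,
                "class": e.locus_class,
                "length": e.length,
                "variable": int(variable[sl].sum()),
                "informative": int(informative[sl].sum()),
            }
        )
    per = _with_percentages(pd.DataFrame(rows))
    pooled = summarize_pooled(per)
    return SiteClassSummary(per_partition=per, pooled=pooled)


def summarize_pooled(per_partition: pd.DataFrame) -> pd.DataFrame:
    """Pool per-partition counts by locus class (plus a total row) and derive
    integer percentages.  Works on any table with class/length/variable/
    informative columns, including published summary tables."""
    rows = []
    for cls, grp in per_partition.groupby("class", sort=False):
        rows.append(
            {
                "class": cls,
                "length": int(grp["length"].sum()),
                "variable": int(grp["variable"].sum()),
                "informative": int(grp["informative"].sum()),
            }
        )
    rows.append(
        {
            "class": "total",
            "length": int(per_partition["length"].sum()),
            "variable": int(per_partition["variable"].sum()),
            "informative": int(per_partition["informative"].sum()),
        }
    )
    return _with_percentages(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# File formats


def read_fasta(path) -> dict:
    """One locus from FASTA, as an ordered taxon -> sequence mapping."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate taxon {rec.id} in {path}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


def write_fasta(aln: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in aln.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_nexus(m: MultiLocusAlignment, path) -> None:
    """Sequential NEXUS with a sets block of 1-based inclusive charsets."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nbegin data;\n")
        fh.write(f"  dimensions ntax={m.n_taxa} nchar={m.length};\n")
        fh.write("  format datatype=dna missing=? gap=-;\n  matrix\n")
        width = max(len(t) for t in m.taxa) + 2
        for i, t in enumerate(m.taxa):
            fh.write(f"    {t.ljust(width)}{m.data[i].tobytes().decode()}\n")
        fh.write("  ;\nend;\n\nbegin sets;\n")
        for e in m.scheme.entries:
            fh.write(f"  charset {e.name} = {e.start + 1}-{e.end};\n")
        fh.write("end;\n")


def read_nexus(path) -> dict:
    """Sequential NEXUS data block as a taxon -> sequence mapping."""
    from Bio.Nexus import Nexus

    nx = Nexus.Nexus(str(path))
    return {t: str(nx.matrix[t]).upper() for t in nx.taxlabels}


def write_partition_table(m: MultiLocusAlignment, path) -> None:
    rows = [
        {
            "locus": e.name,
            "class": e.locus_class,
            "start": e.start + 1,
            "end": e.end,
        }
        for e in m.scheme.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_partition_table(path) -> PartitionScheme:
    df = pd.read_csv(path, sep="\t")
    entries = [
        PartitionEntry(r["locus"], r["class"], int(r["start"]) - 1, int(r["end"]))
        for _, r in df.iterrows()
    ]
    return PartitionScheme(entries)


def read_exclusion_mask(path) -> set:
    """Exclusion mask file: whitespace/comma-separated 1-based inclusive
    ranges (``120-180 455 900-912``) -> 0-based column index set."""
    text = Path(path).read_text()
    out: set[int] = set()
    for tok in text.replace(",", " ").split():
        if "-" in tok[1:]:
            a, b = tok.split("-")
            out.update(range(int(a) - 1, int(b)))
        else:
            out.add(int(tok) - 1)
    return out


def write_exclusion_mask(mask: Iterable[int], path) -> None:
    cols = sorted(set(int(i) for i in mask))
    ranges = []
    for c in cols:
        if ranges and c == ranges[-1][1] + 1:
            ranges[-1][1] = c
        else:
            ranges.append([c, c])
    with open(path, "w") as fh:
        fh.write(
            " ".join(f"{a + 1}-{b + 1}" if a != b else f"{a + 1}" for a, b in ranges)
            + "\n"
        )
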