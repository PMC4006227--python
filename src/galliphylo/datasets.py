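"""Published summary tables for the galliform multilocus study system.

The package's analyses were designed around a complete 46-taxon galliform
data matrix of 15 nuclear loci (mostly introns) and 3 mitochondrial regions.
The sequence data themselves live in GenBank and are not shipped here; what
is shipped is the published per-region site-class summary (length, variable
sites, parsimony-informative sites after exclusion of hard-to-align regions),
which serves as an input for arithmetic checks and as the default locus
configuration of the synthetic-data generator.
"""

from __future__ import annotations

import pandas as pd

from .alignment import MITOCHONDRIAL, NUCLEAR

#: (name, class, aligned length bp, variable sites, parsimony-informative sites)
_GALLIFORM_REGIONS = [
    ("ALDOB", NUCLEAR, 555, 329, 216),
    ("CALB1", NUCLEAR, 623, 260, 159),
    ("CHRNG", NUCLEAR, 673, 262, 167),
    ("CLTC", NUCLEAR, 735, 396, 287),
    ("CLTCL1", NUCLEAR, 427, 260, 173),
    ("CRYAA", NUCLEAR, 1061, 582, 396),
    ("EEF2", NUCLEAR, 975, 329, 261),
    ("FGB", NUCLEAR, 1645, 952, 694),
    ("GAPDH", NUCLEAR, 417, 238, 172),
    ("HMGN2", NUCLEAR, 758, 501, 399),
    ("HSP90B1", NUCLEAR, 656, 427, 324),
    ("OVM", NUCLEAR, 519, 253, 168),
    ("PCBD1", NUCLEAR, 575, 357, 236),
    ("RHO", NUCLEAR, 1105, 647, 494),
    ("SERPIN", NUCLEAR, 2007, 729, 439),
    ("ND2", MITOCHONDRIAL, 1041, 604, 523),
    ("CYB", MITOCHONDRIAL, 1143, 543, 473),
    ("12S", MITOCHONDRIAL, 951, 345, 282),
]

#: Loci of the earlier four-locus galliform study; the complementary set is
#: the "independent evidence" data matrix (no overlapping loci).
EARLIER_STUDY_LOCI = ["CLTC", "OVM", "RHO", "SERPIN", "ND2", "CYB"]

#: Number of taxa in the full matrix.
N_TAXA = 46


def galliform_site_summary() -> pd.DataFrame:
    """The published per-region site-class summary as a tidy DataFrame.

    Columns: name, class, length, variable, informative.  Pooled class totals
    and whole-percent shares are derived from it with
    :func:`galliphylo.alignment.summarize_pooled`.
    """
    return pd.DataFrame(
        _GALLIFORM_REGIONS,
        columns=["name", "class", "length", "variable", "informative"],
    )


def galliform_locus_config() -> list:
    """(name, class, length) triples for the synthetic-data generator."""
    return [(n, c, l) for n, c, l, _, _ in _GALLIFORM_REGIONS]
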