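"""Gene-body genotype strings, the discrimination-capacity statistic, the
homology-hit filter defining a candidate gene panel, and the qPCR
relative-expression formula.

A gene's "genotype" for a sample is the ordered concatenation of its call
states at SNPs inside the gene span — a cheap haplotype surrogate that
needs no phasing.  Discrimination capacity is the number of distinct such
strings in a group divided by the group size: 1/n when the group is
genotypically uniform at the gene, 1.0 when every individual differs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import MISSING, GenomicRegion, GenotypeMatrix

#: symbols used in genotype strings, indexed by dosage code
_CALL_SYMBOL = {0: "0", 1: "1", 2: "2", MISSING: "."}
_SEP = "-"


@dataclass(frozen=True)
class GeneGenotype:
    gene_id: str
    sample_id: str
    genotype: str
    completeness: float  # fraction of non-missing calls; NaN for 0-SNP genes


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise protein-alignment hit (BLAST outfmt-6 style)."""

    query: str
    subject: str
    identity: float  # percent, [0, 100]
    length: int  # alignment length
    mismatches: int
    query_coverage: float  # fraction of query length aligned, [0, 1]
    subject_coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.query_coverage <= 1.0 and 0.0 <= self.subject_coverage <= 1.0):
            raise ValueError(f"coverage out of [0,1] for {self.query}/{self.subject}")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity out of [0,100] for {self.query}/{self.subject}")


def gene_genotype_strings(
    matrix: GenotypeMatrix,
    gene_region: GenomicRegion,
    samples: Sequence[str],
) -> list[GeneGenotype]:
    """Genotype string per sample over the SNPs inside ``gene_region``.

    Sites are taken in genomic order regardless of input order; the
    missing call has its own symbol.  Genes with zero SNPs yield empty
    strings (completeness NaN).
    """
    mask = matrix.site_mask(gene_region.chromosome, gene_region.start, gene_region.end)
    idx = matrix.sample_indices(samples)
    sub = matrix.calls[np.ix_(idx, np.flatnonzero(mask))]
    out = []
    for sample, row in zip(samples, sub):
        s = _SEP.join(_CALL_SYMBOL[int(c)] for c in row)
        comp = float((row != MISSING).mean()) if row.size else float("nan")
        out.append(GeneGenotype(gene_region.label, sample, s, comp))
    return out


def representative_genotype(strings: Sequence[str]) -> str:
    """Most abundant genotype string; ties break to the lexicographically
    smallest mode."""
    if not strings:
        raise ValueError("empty group")
    counts: dict[str, int] = {}
    for s in strings:
        counts[s] = counts.get(s, 0) + 1
    best = max(counts.values())
    return min(s for s, c in counts.items() if c == best)


def discrimination_capacity(strings: Sequence[str]) -> float:
    """Number of distinct genotype strings divided by group size, in (0, 1].

    Strings containing missing symbols count as distinct genotypes.
    """
    if not strings:
        raise ValueError("empty group")
    return len(set(strings)) / len(strings)


# -------------------------------------------------------------------------
# homology filter

def parse_homology_hits(
    table_path: str,
    query_lengths: dict[str, int],
    subject_lengths: dict[str, int],
) -> list[HomologyHit]:
    """Parse a 12+-column tabular alignment file (outfmt-6 layout:
    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore) and attach mutual coverage from sequence lengths.

    A hit whose query or subject length is unknown is fatal.
    """
    df = pd.read_csv(table_path, sep="\t", header=None, comment="#")
    hits = []
    for row in df.itertuples(index=False):
        q, s = str(row[0]), str(row[1])
        if q not in query_lengths:
            raise ValueError(f"no length for query {q!r}")
        if s not in subject_lengths:
            raise ValueError(f"no length for subject {s!r}")
        qspan = abs(int(row[7]) - int(row[6])) + 1
        sspan = abs(int(row[9]) - int(row[8])) + 1
        hits.append(
            HomologyHit(
                query=q,
                subject=s,
                identity=float(row[2]),
                length=int(row[3]),
                mismatches=int(row[4]),
                query_coverage=qspan / query_lengths[q],
                subject_coverage=sspan / subject_lengths[s],
            )
        )
    return hits


def filter_homology(
    hits: Sequence[HomologyHit],
    min_coverage: float = 0.70,
    min_identity: float = 75.0,
    max_mismatch_rate: float = 0.25,
) -> list[HomologyHit]:
    """Retain hits with mutual coverage > 70%, identity > 75% and a
    mismatch rate (mismatches per aligned position) < 25%.

    All three inequalities are strict.
    """
    out = []
    for h in hits:
        if (
            min(h.query_coverage, h.subject_coverage) > min_coverage
            and h.identity > min_identity
            and (h.length > 0 and h.mismatches / h.length < max_mismatch_rate)
        ):
            out.append(h)
    return out


def relative_expression(ct_target: float, ct_control: float) -> float:
    """qPCR relative expression in arbitrary units:
    ``2^−(CT_target − CT_control) × 1000``."""
    return float(2.0 ** (-(ct_target - ct_control)) * 1000.0)
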