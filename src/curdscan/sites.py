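"""Fourfold-degenerate-site classification and the neutral-SNP filter.

Every CDS base is classified by how many of the four nucleotides at its
codon position encode the same amino acid under the standard genetic
code (1 → non-degenerate, recorded as 0-fold; 2, 3 or 4 otherwise).
Minus-strand genes are classified on the reverse complement and mapped
back to forward coordinates.  Positions covered by transcripts that
disagree are marked conflicted and excluded from the 4d set — a
conservative choice for a neutrality proxy.

The neutral-SNP filter keeps 4d SNPs with minor allele frequency
strictly above 0.05 and a missing-call fraction strictly below 20%.
"""

from __future__ import annotations

import logging
import os

import gffutils
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from pyfaidx import Fasta

from .io import EmptyMatrixError
from .model import MISSING, GenotypeMatrix

log = logging.getLogger("curdscan")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASES = "ACGT"

# standard genetic code incl. stops
_CODE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODE[_stop] = "*"


def _degeneracy(codon: str, offset: int) -> int:
    """How many of the 4 bases at ``offset`` keep the amino acid; 1 → 0."""
    aa = _CODE[codon]
    count = sum(
        1
        for b in _BASES
        if _CODE[codon[:offset] + b + codon[offset + 1 :]] == aa
    )
    return 0 if count == 1 else count


def _make_db(gff_path: str | os.PathLike) -> gffutils.FeatureDB:
    return gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )


def load_gene_spans(gff_path: str | os.PathLike) -> pd.DataFrame:
    """Gene spans from a GFF3: columns gene_id, chrom, start, end, strand."""
    db = _make_db(gff_path)
    rows = [
        (g.id, g.seqid, g.start, g.end, g.strand)
        for g in db.features_of_type("gene")
    ]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def classify_degeneracy(
    fasta_path: str | os.PathLike, gff_path: str | os.PathLike
) -> pd.DataFrame:
    """Classify every CDS base of every transcript.

    Returns a DataFrame with columns ``chrom``, ``pos`` (1-based forward
    strand), ``degeneracy`` (0, 2, 3 or 4), ``gene_id``, ``codon_pos``
    (1–3 in transcript orientation) and ``conflicted``.

    Genes whose phase-adjusted CDS length is not a multiple of 3, or that
    contain an internal stop codon, are skipped with a warning.  A CDS on
    a contig absent from the FASTA is fatal.
    """
    fa = Fasta(str(fasta_path))
    db = _make_db(gff_path)

    records: dict[tuple[str, int], tuple[int, str, int]] = {}
    conflicted: set[tuple[str, int]] = set()

    transcripts = list(db.features_of_type("mRNA"))
    if not transcripts:
        transcripts = list(db.features_of_type("gene"))
    for tx in transcripts:
        cds_list = sorted(db.children(tx, featuretype="CDS"), key=lambda f: f.start)
        if not cds_list:
            continue
        strand = cds_list[0].strand
        chrom = cds_list[0].seqid
        if chrom not in fa:
            raise ValueError(f"CDS of {tx.id} references absent contig {chrom!r}")
        parents = list(db.parents(tx, featuretype="gene"))
        gene_id = parents[0].id if parents else tx.id

        coords: list[int] = []  # genomic positions in transcript orientation
        seq_parts: list[str] = []
        ordered = cds_list if strand == "+" else list(reversed(cds_list))
        for cds in ordered:
            piece = str(fa[chrom][cds.start - 1 : cds.end]).upper()
            pos_range = range(cds.start, cds.end + 1)
            if strand == "-":
                piece = piece.translate(_COMPLEMENT)[::-1]
                coords.extend(reversed(pos_range))
            else:
                coords.extend(pos_range)
            seq_parts.append(piece)
        seq = "".join(seq_parts)

        phase = ordered[0].frame
        trim = int(phase) if phase not in (None, ".") else 0
        seq = seq[trim:]
        coords = coords[trim:]
        if len(seq) % 3 != 0:
            log.warning("%s: CDS length %d not divisible by 3; skipped", tx.id, len(seq))
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if any(c not in _CODE for c in codons):
            log.warning("%s: ambiguous bases in CDS; skipped", tx.id)
            continue
        aas = [_CODE[c] for c in codons]
        if "*" in aas[:-1]:
            log.warning("%s: internal stop codon; skipped", tx.id)
            continue

        for ci, codon in enumerate(codons):
            for off in range(3):
                pos = coords[3 * ci + off]
                deg = _degeneracy(codon, off)
                key = (chrom, pos)
                prior = records.get(key)
                if prior is None:
                    records[key] = (deg, gene_id, off + 1)
                elif prior[0] != deg:
                    conflicted.add(key)

    rows = [
        (chrom, pos, deg, gene, cpos, (chrom, pos) in conflicted)
        for (chrom, pos), (deg, gene, cpos) in records.items()
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "degeneracy", "gene_id", "codon_pos", "conflicted"]
    )
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


def fourfold_positions(classes: pd.DataFrame) -> set[tuple[str, int]]:
    """Positions classified 4-fold in every covering transcript."""
    keep = classes[(classes["degeneracy"] == 4) & (~classes["conflicted"])]
    return set(zip(keep["chrom"], keep["pos"]))


def select_4d_snps(
    matrix: GenotypeMatrix,
    classes: pd.DataFrame,
    maf_min: float = 0.05,
    missing_max: float = 0.20,
) -> GenotypeMatrix:
    """Neutral-SNP filter: 4-fold degenerate, MAF > ``maf_min`` (strict,
    computed over non-missing alleles) and missing fraction < ``missing_max``
    (strict).  The result shares the sample set and is a site subset."""
    four_d = fourfold_positions(classes)
    in_4d = np.array(
        [(c, p) in four_d for c, p in zip(matrix.sites["chrom"], matrix.sites["pos"])]
    )
    calls = matrix.calls
    present = calls != MISSING
    n_alleles = 2.0 * present.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_alt = np.where(calls == MISSING, 0, calls).sum(axis=0) / n_alleles
        maf = np.minimum(p_alt, 1.0 - p_alt)
    missing_frac = (calls == MISSING).mean(axis=0)
    keep = in_4d & (n_alleles > 0) & (maf > maf_min) & (missing_frac < missing_max)
    if not keep.any():
        raise EmptyMatrixError("no SNPs pass the 4d/MAF/missingness filter")
    return matrix.subset_sites(keep)
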