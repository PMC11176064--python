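"""Readers and writers: VCF, group TSV, BED, window-stat TSV.

All genomic intervals are 1-based inclusive in memory; BED files are
written and read as 0-based half-open, per the BED convention.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    GenomicRegion,
    GenotypeMatrix,
    GroupAssignment,
    WindowStat,
    _VALID_BASES,
)

log = logging.getLogger("curdscan")


class EmptyMatrixError(ValueError):
    """Raised when zero sites survive loading or filtering."""


def load_genotypes(vcf_path: str | os.PathLike) -> GenotypeMatrix:
    """Load a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are admitted; multi-allelic records and
    indels are dropped and the drop count is logged.  Phasing separators
    are ignored (genotypes are treated as unphased).

    Raises
    ------
    OSError
        If the file cannot be read.
    ValueError
        If the VCF has no samples.
    EmptyMatrixError
        If no biallelic SNPs remain after filtering.
    """
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{vcf_path}: VCF has no samples")

    contig_lengths: dict[str, int] = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        contig_lengths[name] = int(length)

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    calls: list[np.ndarray] = []
    n_dropped = 0
    for rec in vcf:
        if (
            len(rec.ALT) != 1
            or len(rec.REF) != 1
            or len(rec.ALT[0]) != 1
            or rec.REF not in _VALID_BASES
            or rec.ALT[0] not in _VALID_BASES
        ):
            n_dropped += 1
            continue
        chroms.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        # gts012: 0 homref, 1 het, 2 homalt, 3 unknown
        gt = rec.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        calls.append(gt)
    vcf.close()
    if n_dropped:
        log.info("%d non-biallelic-SNP record(s) dropped from %s", n_dropped, vcf_path)
    if not calls:
        raise EmptyMatrixError(f"{vcf_path}: no biallelic SNPs after filtering")

    sites = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts}
    )
    matrix = np.column_stack(calls)
    if not contig_lengths:
        contig_lengths = {
            c: int(sites.loc[sites["chrom"] == c, "pos"].max())
            for c in sites["chrom"].drop_duplicates()
        }
    # sort by header contig order then position
    order = {c: i for i, c in enumerate(contig_lengths)}
    for c in sites["chrom"]:
        if c not in order:
            order[c] = len(order)  # contig absent from header: first-appearance order
    key = sites["chrom"].map(order).to_numpy() * (2**40) + sites["pos"].to_numpy()
    idx = np.argsort(key, kind="stable")
    return GenotypeMatrix(
        samples, sites.iloc[idx], matrix[:, idx], contig_lengths
    )


def load_groups(tsv_path: str | os.PathLike, matrix: GenotypeMatrix) -> GroupAssignment:
    """Read a two-column (sample, group) TSV, validating against ``matrix``.

    Raises
    ------
    ValueError
        On duplicate sample rows (with row numbers) or samples absent from
        the matrix (named in the message).
    """
    mapping: dict[str, str] = {}
    first_row: dict[str, int] = {}
    with open(tsv_path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{tsv_path}:{i}: expected 2 tab-separated columns")
            sample, group = parts[0], parts[1]
            if sample in mapping:
                raise ValueError(
                    f"{tsv_path}: duplicate sample {sample!r} "
                    f"(rows {first_row[sample]} and {i})"
                )
            mapping[sample] = group
            first_row[sample] = i
    known = set(matrix.sample_ids)
    unknown = sorted(s for s in mapping if s not in known)
    if unknown:
        raise ValueError(
            f"{tsv_path}: sample(s) not in genotype matrix: {', '.join(unknown)}"
        )
    return GroupAssignment(mapping)


# -- BED ------------------------------------------------------------------

def write_regions_bed(regions: Sequence[GenomicRegion], path: str | os.PathLike) -> None:
    """Write regions as BED (0-based half-open), label in column 4."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.label}\n")


def read_regions_bed(path: str | os.PathLike) -> list[GenomicRegion]:
    """Read a BED file back into 1-based inclusive regions."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3] if len(parts) > 3 else ""
            regions.append(GenomicRegion(chrom, start0 + 1, end, label))
    return regions


# -- window-stat / tabular emitters ---------------------------------------

def write_window_stats(
    stats: Iterable[WindowStat], path: str | os.PathLike, header_comment: str = ""
) -> None:
    """TSV emitter: chrom, start, end, n_sites, statistic, value (NA if undefined)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("chrom\tstart\tend\tn_sites\tstatistic\tvalue\n")
        for w in stats:
            val = "NA" if np.isnan(w.value) else repr(float(w.value))
            fh.write(
                f"{w.region.chromosome}\t{w.region.start}\t{w.region.end}\t"
                f"{w.n_sites}\t{w.statistic_name}\t{val}\n"
            )


def write_table(df: pd.DataFrame, path: str | os.PathLike, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_vcf(matrix: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal uncompressed VCF 4.2 with GT fields.

    Used to materialise synthetic cohorts; round-trips through
    :func:`load_genotypes`.
    """
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in matrix.contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, row in enumerate(matrix.sites.itertuples()):
            gts = "\t".join(code_to_gt[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
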