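"""Core domain types shared by every analysis stage.

Coordinate convention: 1-based, fully inclusive intervals everywhere in
memory.  The only place 0-based half-open coordinates appear is BED
emission/ingestion (see :mod:`curdscan.io`).

Genotype calls are stored as alternate-allele dosage codes::

    0  homozygous reference (0/0)
    1  heterozygous         (0/1)
    2  homozygous alternate (1/1)
    -1 missing              (./.)

Only biallelic SNPs are admitted; multi-allelic records and indels are
dropped at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: genotype call codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class Site:
    """A biallelic SNP site (1-based position)."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt at {self.chromosome}:{self.position}")
        if self.ref_allele not in _VALID_BASES or self.alt_allele not in _VALID_BASES:
            raise ValueError(
                f"non-ACGT allele at {self.chromosome}:{self.position}: "
                f"{self.ref_allele}/{self.alt_allele}"
            )


@dataclass(frozen=True)
class GenomicRegion:
    """A chromosome interval, 1-based inclusive on both ends."""

    chromosome: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"start > end: {self.chromosome}:{self.start}-{self.end}"
            )
        if self.start < 1:
            raise ValueError(f"start < 1: {self.chromosome}:{self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chromosome == other.chromosome
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, chromosome: str, position: int) -> bool:
        return self.chromosome == chromosome and self.start <= position <= self.end


@dataclass(frozen=True)
class WindowStat:
    """A window plus a scalar statistic.

    ``value`` is NaN when the statistic is undefined for the window (fewer
    usable sites than the statistic's minimum).
    """

    region: GenomicRegion
    statistic_name: str
    value: float
    n_sites: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.value)


class GenotypeMatrix:
    """Samples x biallelic-SNP-sites diploid genotype matrix.

    Parameters
    ----------
    sample_ids:
        Ordered unique sample identifiers.
    sites:
        DataFrame with columns ``chrom``, ``pos``, ``ref``, ``alt``; one row
        per site, sorted by (chromosome order, position), positions unique
        per chromosome.
    calls:
        int8 array of shape ``(n_samples, n_sites)`` holding dosage codes.
    contig_lengths:
        Optional mapping chromosome -> length in bp (from VCF contig header
        lines or a FASTA index).  Chromosome order is the order of this
        mapping when given, else first-appearance order in ``sites``.
    """

    def __init__(
        self,
        sample_ids: Iterable[str],
        sites: pd.DataFrame,
        calls: np.ndarray,
        contig_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.sample_ids = list(sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.sites = sites.reset_index(drop=True)
        self.calls = np.asarray(calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.sample_ids)}, {len(self.sites)})"
            )
        bad = ~np.isin(self.calls, (HOM_REF, HET, HOM_ALT, MISSING))
        if bad.any():
            raise ValueError("calls contain codes outside {-1,0,1,2}")
        if contig_lengths is not None:
            self.contig_lengths = dict(contig_lengths)
        else:
            self.contig_lengths = {
                c: int(self.sites.loc[self.sites["chrom"] == c, "pos"].max())
                for c in self.sites["chrom"].drop_duplicates()
            }
        self._validate_sites()
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    def _validate_sites(self) -> None:
        order = {c: i for i, c in enumerate(self.chromosomes)}
        prev_key: tuple[int, int] | None = None
        for chrom, pos in zip(self.sites["chrom"], self.sites["pos"]):
            key = (order[chrom], int(pos))
            if prev_key is not None and key <= prev_key:
                raise ValueError(
                    "sites not sorted by (chromosome, position) or duplicated"
                )
            prev_key = key

    # -- accessors ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chromosomes(self) -> list[str]:
        if self.contig_lengths:
            return list(self.contig_lengths)
        return list(self.sites["chrom"].drop_duplicates())

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def site_mask(self, chromosome: str, start: int, end: int) -> np.ndarray:
        """Boolean mask over sites inside [start, end] on a chromosome."""
        pos = self.sites["pos"].to_numpy()
        return (
            (self.sites["chrom"].to_numpy() == chromosome)
            & (pos >= start)
            & (pos <= end)
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sample_ids,
            self.sites.loc[np.asarray(mask)],
            self.calls[:, np.asarray(mask)],
            self.contig_lengths,
        )

    def site_tuples(self) -> list[Site]:
        return [
            Site(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in self.sites.itertuples()
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.sites.equals(other.sites)
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeMatrix({self.n_samples} samples x {self.n_sites} sites, "
            f"{len(self.chromosomes)} chromosomes)"
        )


@dataclass
class GroupAssignment:
    """Mapping sample id -> group label, validated against a matrix."""

    mapping: dict[str, str] = field(default_factory=dict)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.mapping.items() if g == group]

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.mapping.values():
            seen.setdefault(g, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.mapping)
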