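"""Consensus-genotype ancestral inference and identity-by-state painting.

A group's pseudo-ancestral genotype is its per-site modal call.  Each
candidate donor accession is then compared to this consensus in
consecutive (non-overlapping) 5-kb windows; windows sharing at least five
genotyped SNPs with similarity above 96% are "identical" (syntenic)
windows, and maximal runs of passing windows form identical regions.
Identity is a strict genotype-state match: a heterozygous donor call
against a homozygous consensus counts as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MISSING, GenomicRegion, GenotypeMatrix, GroupAssignment


@dataclass(frozen=True)
class ConsensusGenotype:
    """Per-site modal genotype of a group.

    ``calls`` holds dosage codes (missing where every member is missing);
    ``support`` the count of members carrying the modal call;
    ``group_size`` the number of members.
    """

    group: str
    calls: np.ndarray  # int8, aligned with the source matrix's sites
    support: np.ndarray  # int32
    group_size: int


@dataclass(frozen=True)
class IdentityWindow:
    region: GenomicRegion
    shared_snps: int  # sites where donor and consensus both non-missing
    matches: int
    similarity: float  # matches / shared_snps; NaN when shared_snps == 0
    passed: bool


MIN_SHARED_SNPS = 5
MIN_SIMILARITY = 0.96  # strict: similarity must exceed this


def build_consensus(
    matrix: GenotypeMatrix, groups: GroupAssignment, label: str
) -> ConsensusGenotype:
    """Per-site mode over the group's non-missing calls.

    Ties break toward the smaller alternate-allele dosage
    (homRef < het < homAlt); all-missing sites stay missing.
    """
    samples = groups.samples_in(label)
    if not samples:
        raise ValueError(f"group {label!r} has no samples")
    calls = matrix.calls[matrix.sample_indices(samples), :]
    counts = np.stack([(calls == code).sum(axis=0) for code in (0, 1, 2)])
    support = counts.max(axis=0).astype(np.int32)
    modal = counts.argmax(axis=0).astype(np.int8)  # argmax takes the smallest code on ties
    modal[support == 0] = MISSING
    return ConsensusGenotype(label, modal, support, len(samples))


def identity_windows(
    matrix: GenotypeMatrix,
    donor: str,
    consensus: ConsensusGenotype,
    window: int = 5_000,
    min_shared: int = MIN_SHARED_SNPS,
    min_similarity: float = MIN_SIMILARITY,
) -> list[IdentityWindow]:
    """Donor-vs-consensus identity in non-overlapping windows tiled from
    position 1 of each chromosome."""
    donor_calls = matrix.calls[matrix.sample_indices([donor])[0], :]
    comparable = (donor_calls != MISSING) & (consensus.calls != MISSING)
    match = comparable & (donor_calls == consensus.calls)
    pos = matrix.sites["pos"].to_numpy()
    chrom_arr = matrix.sites["chrom"].to_numpy()
    out: list[IdentityWindow] = []
    for chrom in matrix.chromosomes:
        length = matrix.contig_lengths[chrom]
        on_chrom = chrom_arr == chrom
        cpos = pos[on_chrom]
        ccomp = np.concatenate([[0], np.cumsum(comparable[on_chrom])])
        cmatch = np.concatenate([[0], np.cumsum(match[on_chrom])])
        for start in range(1, length + 1, window):
            end = min(start + window - 1, length)
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, end, side="right")
            shared = int(ccomp[hi] - ccomp[lo])
            matches = int(cmatch[hi] - cmatch[lo])
            sim = matches / shared if shared else float("nan")
            passed = shared >= min_shared and sim > min_similarity
            out.append(
                IdentityWindow(GenomicRegion(chrom, start, end), shared, matches, sim, passed)
            )
    return out


def call_identical_regions(windows: list[IdentityWindow]) -> list[GenomicRegion]:
    """Merge maximal runs of consecutive passing tiles into regions.

    Tiles are contiguous by construction, so a run merges into one region
    whose length is a multiple of the tile size (up to chromosome-end
    truncation of the last tile).
    """
    out: list[GenomicRegion] = []
    run_start: GenomicRegion | None = None
    prev: GenomicRegion | None = None
    for w in windows:
        if w.passed:
            if (
                run_start is not None
                and prev is not None
                and w.region.chromosome == prev.chromosome
                and w.region.start == prev.end + 1
            ):
                prev = w.region
            else:
                if run_start is not None:
                    out.append(
                        GenomicRegion(run_start.chromosome, run_start.start, prev.end)
                    )
                run_start = w.region
                prev = w.region
        else:
            if run_start is not None:
                out.append(GenomicRegion(run_start.chromosome, run_start.start, prev.end))
                run_start = None
                prev = None
    if run_start is not None:
        out.append(GenomicRegion(run_start.chromosome, run_start.start, prev.end))
    return out


def contribution_summary(
    regions_by_donor: dict[str, list[GenomicRegion]],
    genome_length: int,
    histogram_bin: int = 5_000,
) -> pd.DataFrame:
    """Per-donor genome fraction covered by identical regions and a
    region-length histogram with 5-kb bins.

    Output columns: donor, fraction, n_regions, mean_length, plus one
    ``hist_<lo>`` column per occupied length bin (lower edge in bp).
    """
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    rows = []
    all_bins: set[int] = set()
    per_donor_hist: dict[str, dict[int, int]] = {}
    for donor, regions in regions_by_donor.items():
        lengths = np.array([r.length for r in regions], dtype=float)
        hist: dict[int, int] = {}
        for ln in lengths:
            lo = int((ln - 1) // histogram_bin) * histogram_bin
            hist[lo] = hist.get(lo, 0) + 1
        per_donor_hist[donor] = hist
        all_bins.update(hist)
        rows.append(
            {
                "donor": donor,
                "fraction": float(lengths.sum()) / genome_length,
                "n_regions": len(regions),
                "mean_length": float(lengths.mean()) if len(regions) else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    for lo in sorted(all_bins):
        df[f"hist_{lo}"] = [per_donor_hist[d].get(lo, 0) for d in df["donor"]]
    return df
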