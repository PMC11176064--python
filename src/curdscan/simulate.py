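"""Seeded generators for every synthetic fixture the pipeline consumes.

The generators emulate, at toy scale, the data a domestication
resequencing study works with:

* a toy genome (FASTA + GFF3) with multi-codon coding genes on both
  strands, valid phases and no internal stop codons;
* a nested multi-group cohort whose per-site allele frequencies drift
  from a shared ancestral frequency, with planted high-divergence blocks
  between designated group pairs;
* donor accessions carrying planted tracts identical to a recipient
  group's consensus genotype (with site-level noise);
* an F2 cross with one causal locus, phenotype-selected bulks of
  individuals and binomially sampled read depths.

Every generator is a pure function of its configuration and seed, and
machine-readable ground truth is produced alongside each fixture so that
any pipeline stage can be scored for recall and precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .ancestry import build_consensus
from .model import MISSING, GenomicRegion, GenotypeMatrix, GroupAssignment

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# sense codons only (no stops), for building clean reading frames
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


@dataclass
class SweepBlock:
    """A planted high-F_ST block between two groups."""

    chromosome: str
    start: int
    end: int
    group_hi: str
    group_lo: str
    gap: float  # allele-frequency gap between the two groups


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the structure of a nested domestication series —
    three categories of decreasing diversity plus a wild donor pool — at
    a scale a workstation handles in seconds.
    """

    seed: int = 0
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000}
    )
    snp_per_kb: float = 1.0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"Curdless": 20, "GreenCurd": 20, "WhiteCurd": 20}
    )
    # frequency-drift scale per group; larger drift -> more differentiation
    drift: dict[str, float] = field(
        default_factory=lambda: {"Curdless": 0.06, "GreenCurd": 0.09, "WhiteCurd": 0.12}
    )
    missing_rate: float = 0.03
    sweep_blocks: list[SweepBlock] = field(default_factory=list)
    # toy-genome parameters
    genes_per_chromosome: int = 20
    # F2 / BSA design
    bulk_size: int = 20
    bulk_depth: int = 50
    recombination_rate: float = 4e-8  # Morgans per bp (4 cM/Mb)

    def __post_init__(self) -> None:
        for block in self.sweep_blocks:
            length = self.chromosome_lengths.get(block.chromosome)
            if length is None or block.start < 1 or block.end > length:
                raise ValueError(f"sweep block outside chromosome bounds: {block}")


@dataclass
class GroundTruth:
    """Planted features, serialized alongside each fixture."""

    sweep_regions: list[dict] = field(default_factory=list)
    introgression_tracts: dict[str, list[dict]] = field(default_factory=dict)
    causal_locus: dict | None = None
    site_frequencies: list[float] | None = None

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# -------------------------------------------------------------------------
# toy genome

def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(_BASES, size=length)


def _coding_sequence(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + stop; no internal stops by construction."""
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(sorted(_STOPS))
    return "ATG" + "".join(body) + stop


def make_toy_genome(
    config: SimulationConfig, fasta_path: str, gff_path: str
) -> None:
    """Write a random genome FASTA and a GFF3 with coding genes.

    Genes are non-overlapping, appear on both strands (at least one per
    strand per chromosome) and may have a two-exon CDS with a correct
    non-zero phase on the second coding exon.  Deterministic per seed.
    """
    for chrom, length in config.chromosome_lengths.items():
        if length < 10_000:
            raise ValueError(f"{chrom}: length {length} < 10 kb")
    rng = np.random.default_rng(config.seed)
    gff_lines = ["##gff-version 3"]
    with open(fasta_path, "w") as fa:
        for chrom, length in config.chromosome_lengths.items():
            seq = _random_sequence(rng, length)
            n_genes = config.genes_per_chromosome
            slot = length // (n_genes + 1)
            for gi in range(n_genes):
                n_codons = int(rng.integers(20, 61))
                cds_len = 3 * n_codons
                two_exon = bool(rng.integers(0, 2))
                if two_exon:
                    l1 = int(rng.integers(1, cds_len - 1))
                    intron = int(rng.integers(60, 200))
                else:
                    l1, intron = cds_len, 0
                total = cds_len + intron
                start = gi * slot + int(rng.integers(1, max(2, slot - total - 1)))
                start = max(1, min(start, length - total))
                strand = "+" if gi % 2 == 0 else "-"  # both strands guaranteed
                coding = _coding_sequence(rng, n_codons)
                if two_exon:
                    intron_seq = "".join(_random_sequence(rng, intron))
                    fragment = coding[:l1] + intron_seq + coding[l1:]
                else:
                    fragment = coding
                if strand == "-":
                    fragment = fragment.translate(_COMPLEMENT)[::-1]
                seq[start - 1 : start - 1 + total] = list(fragment)

                gid = f"{chrom}_g{gi + 1}"
                g_start, g_end = start, start + total - 1
                gff_lines.append(
                    f"{chrom}\tcurdscan\tgene\t{g_start}\t{g_end}\t.\t{strand}\t.\tID={gid}"
                )
                gff_lines.append(
                    f"{chrom}\tcurdscan\tmRNA\t{g_start}\t{g_end}\t.\t{strand}\t.\t"
                    f"ID={gid}.t1;Parent={gid}"
                )
                phase2 = (3 - l1 % 3) % 3
                if two_exon:
                    l2 = cds_len - l1
                    if strand == "+":
                        exons = [
                            (g_start, g_start + l1 - 1, 0),
                            (g_start + l1 + intron, g_end, phase2),
                        ]
                    else:
                        # transcript-first exon is the rightmost block
                        exons = [
                            (g_start, g_start + l2 - 1, phase2),
                            (g_end - l1 + 1, g_end, 0),
                        ]
                else:
                    exons = [(g_start, g_end, 0)]
                for es, ee, ph in exons:
                    gff_lines.append(
                        f"{chrom}\tcurdscan\tCDS\t{es}\t{ee}\t.\t{strand}\t{ph}\t"
                        f"ID=cds_{gid};Parent={gid}.t1"
                    )
            fa.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, length, 80):
                fa.write(s[i : i + 80] + "\n")
    with open(gff_path, "w") as gff:
        gff.write("\n".join(gff_lines) + "\n")


# -------------------------------------------------------------------------
# structured cohort

def simulate_groups(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, GroupAssignment, GroundTruth]:
    """Simulate a multi-group cohort with planted divergent blocks.

    Per site: an ancestral frequency is drawn Uniform(0.05, 0.95); each
    group's frequency is the ancestral one perturbed by a truncated
    normal whose scale is the group's drift parameter times the binomial
    standard deviation sqrt(p(1−p)).  Inside planted blocks the two
    designated groups are set to (1±gap)/2.  Diploid genotypes are drawn
    binomially; missingness is uniform at the configured rate.
    """
    rng = np.random.default_rng(config.seed)
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for chrom, length in config.chromosome_lengths.items():
        n = int(length / 1000 * config.snp_per_kb)
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        chroms.extend([chrom] * n)
        positions.append(pos)
    pos_all = np.concatenate(positions)
    n_sites = len(pos_all)
    chrom_all = np.array(chroms)

    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    refs = _BASES[ref_idx]
    alts = _BASES[(ref_idx + alt_shift) % 4]

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)

    sample_ids: list[str] = []
    group_map: dict[str, str] = {}
    call_blocks: list[np.ndarray] = []
    for group, size in config.group_sizes.items():
        drift = config.drift.get(group, 0.0)
        scale = drift * np.sqrt(p_anc * (1 - p_anc))
        p_g = np.clip(p_anc + rng.normal(0.0, 1.0, size=n_sites) * scale, 0.0, 1.0)
        for block in config.sweep_blocks:
            in_block = (
                (chrom_all == block.chromosome)
                & (pos_all >= block.start)
                & (pos_all <= block.end)
            )
            if group == block.group_hi:
                p_g[in_block] = (1.0 + block.gap) / 2.0
            elif group == block.group_lo:
                p_g[in_block] = (1.0 - block.gap) / 2.0
        geno = rng.binomial(2, p_g, size=(size, n_sites)).astype(np.int8)
        if config.missing_rate > 0:
            miss = rng.random((size, n_sites)) < config.missing_rate
            geno[miss] = MISSING
        call_blocks.append(geno)
        for i in range(size):
            sid = f"{group}_{i + 1:03d}"
            sample_ids.append(sid)
            group_map[sid] = group

    sites = pd.DataFrame(
        {"chrom": chrom_all, "pos": pos_all, "ref": refs, "alt": alts}
    )
    matrix = GenotypeMatrix(
        sample_ids,
        sites,
        np.vstack(call_blocks),
        dict(config.chromosome_lengths),
    )
    truth = GroundTruth(
        sweep_regions=[asdict(b) for b in config.sweep_blocks],
        site_frequencies=[float(x) for x in p_anc],
    )
    return matrix, GroupAssignment(group_map), truth


# -------------------------------------------------------------------------
# introgression tracts

def plant_introgressions(
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    recipient_group: str,
    tracts: dict[str, list[GenomicRegion]],
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Copy the recipient group's consensus into donors inside tracts.

    Inside each tract the donor's calls are replaced by the consensus
    call, then each site is flipped to a different call state with the
    given noise probability.  Overlapping tracts for one donor are fatal.
    """
    rng = np.random.default_rng(seed)
    consensus = build_consensus(matrix, groups, recipient_group)
    calls = matrix.calls.copy()
    pos = matrix.sites["pos"].to_numpy()
    chrom_arr = matrix.sites["chrom"].to_numpy()
    truth_tracts: dict[str, list[dict]] = {}
    for donor, regions in tracts.items():
        srt = sorted(regions, key=lambda r: (r.chromosome, r.start))
        for a, b in zip(srt, srt[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping tracts for donor {donor!r}: {a} / {b}")
        di = matrix.sample_indices([donor])[0]
        for region in srt:
            in_tract = (
                (chrom_arr == region.chromosome)
                & (pos >= region.start)
                & (pos <= region.end)
            )
            idx = np.flatnonzero(in_tract & (consensus.calls != MISSING))
            calls[di, idx] = consensus.calls[idx]
            if noise > 0 and idx.size:
                flip = idx[rng.random(idx.size) < noise]
                # move to a different (non-missing) call state
                calls[di, flip] = (calls[di, flip] + rng.integers(1, 3, size=flip.size)) % 3
        truth_tracts[donor] = [
            {"chromosome": r.chromosome, "start": r.start, "end": r.end} for r in srt
        ]
    out = GenotypeMatrix(matrix.sample_ids, matrix.sites, calls, matrix.contig_lengths)
    return out, GroundTruth(introgression_tracts=truth_tracts)


# -------------------------------------------------------------------------
# F2 cross and bulks

def simulate_f2_bulks(
    config: SimulationConfig,
    causal_chromosome: str,
    causal_position: int,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Depth-sampled bulk allele counts for an F2 cross with one causal locus.

    The high bulk holds ``bulk_size`` F2 individuals homozygous for the
    parent-A allele at the causal locus, the low bulk the same number
    homozygous for parent-B.  On the causal chromosome each of an
    individual's two gametes carries the causal-locus allele and switches
    parent with the Haldane recombination fraction
    r(d) = (1 − e^(−2·rate·d))/2 at distance d; other chromosomes are
    unlinked (r = 1/2).  Reads per bulk and site are Binomial(depth, p)
    on the bulk's parent-A allele frequency.
    """
    length = config.chromosome_lengths.get(causal_chromosome)
    if length is None or not 1 <= causal_position <= length:
        raise ValueError("causal locus outside chromosome bounds")
    rng = np.random.default_rng(config.seed)
    rows = []
    n_hap = 2 * config.bulk_size
    for chrom, clen in config.chromosome_lengths.items():
        n = int(clen / 1000 * config.snp_per_kb)
        pos = np.sort(rng.choice(np.arange(1, clen + 1), size=n, replace=False))
        if chrom == causal_chromosome:
            d = np.abs(pos - causal_position)
            r = 0.5 * (1.0 - np.exp(-2.0 * config.recombination_rate * d))
        else:
            r = np.full(n, 0.5)
        # high bulk: gametes carry parent-A at the causal locus
        hi_A = rng.binomial(n_hap, 1.0 - r) / n_hap
        lo_A = rng.binomial(n_hap, r) / n_hap
        b1_a = rng.binomial(config.bulk_depth, hi_A)
        b2_a = rng.binomial(config.bulk_depth, lo_A)
        for p, a1, a2 in zip(pos, b1_a, b2_a):
            rows.append(
                (
                    chrom,
                    int(p),
                    int(a1),
                    config.bulk_depth - int(a1),
                    int(a2),
                    config.bulk_depth - int(a2),
                )
            )
    table = pd.DataFrame(
        rows, columns=["chrom", "pos", "b1_a", "b1_b", "b2_a", "b2_b"]
    )
    truth = GroundTruth(
        causal_locus={"chromosome": causal_chromosome, "position": causal_position}
    )
    return table, truth
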