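"""End-to-end demo pipeline on a synthetic cohort with known ground truth.

This module wires every stage together in dependency order — toy genome
and site classification, cohort simulation, diversity/divergence scans,
identity-by-state ancestry painting, gene-genotype discrimination and
bulked-segregant mapping — and scores each stage against the planted
truth.  It is what the ``demo`` CLI subcommand and the reproduction
script run.

Problem sizes: one 10-Mb chromosome at 1 SNP/kb for the cohort (plus a
5-Mb unlinked chromosome in the F2 design for null calibration), three
nested crop groups of 20 plus 6 wild donors.
"""

from __future__ import annotations

import json
import os
from dataclasses import replace

import numpy as np
import pandas as pd

from . import ancestry, bsa, io, popstats, simulate, sites, sweep
from .model import GenomicRegion


def default_config(seed: int) -> simulate.SimulationConfig:
    """The demo study conditions: nested crop groups, one planted 300-kb
    divergent block (frequency gap 0.8) and a wild donor pool."""
    return simulate.SimulationConfig(
        seed=seed,
        chromosome_lengths={"chr1": 10_000_000},
        snp_per_kb=30.0,
        group_sizes={"Curdless": 20, "GreenCurd": 20, "WhiteCurd": 20, "Wild": 6},
        drift={"Curdless": 0.06, "GreenCurd": 0.09, "WhiteCurd": 0.12, "Wild": 0.18},
        sweep_blocks=[
            simulate.SweepBlock("chr1", 4_850_001, 5_150_000, "WhiteCurd", "Curdless", 0.8)
        ],
    )


DEMO_TRACTS: dict[str, list[GenomicRegion]] = {
    "Wild_001": [
        GenomicRegion("chr1", 1_000_001, 1_050_000),
        GenomicRegion("chr1", 3_000_001, 3_050_000),
        GenomicRegion("chr1", 7_500_001, 7_550_000),
    ],
    "Wild_002": [
        GenomicRegion("chr1", 2_000_001, 2_050_000),
        GenomicRegion("chr1", 6_000_001, 6_050_000),
    ],
}


def _atomic(path: str):
    """Return (tmp_path, commit) for temp-then-rename output writing."""
    tmp = path + ".tmp"

    def commit() -> None:
        os.replace(tmp, path)

    return tmp, commit


def base_recall_precision(
    called: list[GenomicRegion], truth: list[GenomicRegion]
) -> tuple[float, float]:
    """Base-level recall and precision of called vs true regions."""

    def bases(regions: list[GenomicRegion]) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for r in regions:
            out.update((r.chromosome, p) for p in range(r.start, r.end + 1))
        return out

    called_b = bases(called)
    truth_b = bases(truth)
    recall = len(called_b & truth_b) / len(truth_b) if truth_b else float("nan")
    precision = len(called_b & truth_b) / len(called_b) if called_b else float("nan")
    return recall, precision


def run_demo(seed: int, out_dir: str, ld: bool = True) -> dict:
    """Run every stage on a seeded synthetic cohort; returns a summary dict
    and writes artifacts (VCF, BED, TSV, ground truth JSON) to ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    summary: dict[str, float | int] = {"seed": seed}
    config = default_config(seed)

    # -- toy genome + site classification ---------------------------------
    fasta = os.path.join(out_dir, "genome.fa")
    gff = os.path.join(out_dir, "genes.gff3")
    simulate.make_toy_genome(config, fasta, gff)
    classes = sites.classify_degeneracy(fasta, gff)
    io.write_table(classes, os.path.join(out_dir, "site_classes.tsv"))

    # -- cohort with planted sweep + introgressions -----------------------
    matrix, groups, truth_groups = simulate.simulate_groups(config)
    matrix, truth_introg = simulate.plant_introgressions(
        matrix, groups, "WhiteCurd", DEMO_TRACTS, noise=0.02, seed=seed + 1
    )
    io.write_vcf(matrix, os.path.join(out_dir, "cohort.vcf"))
    with open(os.path.join(out_dir, "groups.tsv"), "w") as fh:
        for s, g in groups.mapping.items():
            fh.write(f"{s}\t{g}\n")
    truth_groups.introgression_tracts = truth_introg.introgression_tracts
    truth_groups.to_json(os.path.join(out_dir, "ground_truth.json"))

    # -- diversity ---------------------------------------------------------
    for label in ("Curdless", "GreenCurd", "WhiteCurd"):
        summary[f"pi_{label.lower()}"] = popstats.mean_pi(matrix, groups, label)

    # -- divergence scan ---------------------------------------------------
    fst = popstats.fst_windows(matrix, groups, "Curdless", "WhiteCurd", 100_000, 10_000)
    io.write_window_stats(fst, os.path.join(out_dir, "fst_windows.tsv"),
                          header_comment=f"curdscan demo seed={seed}")
    block = config.sweep_blocks[0]
    in_block = [
        w.value for w in fst
        if w.defined and w.region.start >= block.start and w.region.end <= block.end
    ]
    outside = [
        w.value for w in fst
        if w.defined and (w.region.end < block.start or w.region.start > block.end)
    ]
    summary["fst_planted_block_mean"] = float(np.mean(in_block))
    summary["fst_background_mean"] = float(np.mean(outside))

    selected, threshold = sweep.top_percentile_select(fst, 0.05)
    regions = sweep.merge_to_regions(selected, bridge=100_000)
    io.write_regions_bed(regions, os.path.join(out_dir, "sweep_regions.bed"))
    summary["sweep_threshold"] = threshold
    summary["n_sweep_regions"] = len(regions)
    midpoint = (block.start + block.end) // 2
    summary["sweep_block_midpoint_recovered"] = int(
        any(r.contains(block.chromosome, midpoint) for r in regions)
    )

    # -- gene overlap + discrimination ------------------------------------
    spans = sites.load_gene_spans(gff)
    profile = sweep.discrimination_profile(regions, matrix, groups, spans)
    io.write_table(profile, os.path.join(out_dir, "discrimination.tsv"))
    caps = profile.dropna(subset=["capacity"])
    for label in ("Curdless", "GreenCurd", "WhiteCurd"):
        vals = caps.loc[caps["group"] == label, "capacity"]
        if len(vals):
            summary[f"discrimination_{label.lower()}"] = float(vals.mean())

    # -- neutral-SNP filter -------------------------------------------------
    try:
        four_d = sites.select_4d_snps(matrix, classes)
        summary["n_4d_snps"] = four_d.n_sites
    except io.EmptyMatrixError:
        summary["n_4d_snps"] = 0

    # -- ancestry painting --------------------------------------------------
    consensus = ancestry.build_consensus(matrix, groups, "WhiteCurd")
    genome_length = sum(config.chromosome_lengths.values())
    regions_by_donor: dict[str, list[GenomicRegion]] = {}
    for donor in DEMO_TRACTS:
        wins = ancestry.identity_windows(matrix, donor, consensus)
        regs = ancestry.call_identical_regions(wins)
        regions_by_donor[donor] = regs
        io.write_regions_bed(
            regs, os.path.join(out_dir, f"identical_regions_{donor}.bed")
        )
    contrib = ancestry.contribution_summary(regions_by_donor, genome_length)
    io.write_table(contrib, os.path.join(out_dir, "contribution.tsv"))
    called = [r for regs in regions_by_donor.values() for r in regs]
    truth_regs = [
        GenomicRegion(t["chromosome"], t["start"], t["end"])
        for tracts in truth_introg.introgression_tracts.values()
        for t in tracts
    ]
    rec, prec = base_recall_precision(called, truth_regs)
    summary["introgression_recall_pct"] = 100.0 * rec
    summary["introgression_precision_pct"] = 100.0 * prec
    summary["donor_genome_fraction_pct"] = float(contrib["fraction"].mean() * 100.0)

    # -- LD decay -----------------------------------------------------------
    if ld:
        # thin to ~5k sites so the all-pairs scan stays fast
        stride = max(1, matrix.n_sites // 5_000)
        thin = np.zeros(matrix.n_sites, dtype=bool)
        thin[::stride] = True
        bins = popstats.ld_decay(matrix.subset_sites(thin), groups, "WhiteCurd",
                                 max_dist=100_000)
        df = pd.DataFrame(
            [(b.lower, b.mean_r2, b.n_pairs) for b in bins],
            columns=["bin_start", "mean_r2", "n_pairs"],
        )
        io.write_table(df, os.path.join(out_dir, "ld_bins.tsv"))
        occupied = df[df["n_pairs"] > 0]
        summary["ld_background_mean_r2"] = float(occupied["mean_r2"].mean())

    # -- bulked segregant analysis -----------------------------------------
    f2_config = replace(
        config,
        chromosome_lengths={"chr1": 10_000_000, "chr2": 5_000_000},
        snp_per_kb=1.0,  # BSA uses the sparser parent-polarized SNP subset
        seed=seed + 2,
    )
    causal = ("chr1", 5_000_000)
    bulks, truth_f2 = simulate.simulate_f2_bulks(f2_config, *causal)
    io.write_table(bulks, os.path.join(out_dir, "bulks.tsv"))
    windows = bsa.windowed_delta(bulks, f2_config.chromosome_lengths)
    bands = bsa.simulate_band_grid(seed=seed + 3)
    candidates = bsa.call_candidate_regions(windows, bands)
    io.write_regions_bed(candidates, os.path.join(out_dir, "bsa_regions.bed"))

    per_site = bsa.delta_snp_index(bulks)
    on_chrom = per_site[per_site["chrom"] == causal[0]]
    nearest = on_chrom.iloc[(on_chrom["pos"] - causal[1]).abs().argmin()]
    summary["bsa_delta_near_causal"] = float(nearest["delta"])
    summary["n_bsa_regions"] = len(candidates)
    summary["bsa_causal_in_region"] = int(
        any(r.contains(*causal) for r in candidates)
    )
    null_windows = windows[(windows["chrom"] == "chr2") & windows["mean_delta"].notna()]
    grid = np.array(sorted(bands))
    exceed = 0
    for row in null_windows.itertuples():
        band = bands[int(grid[np.argmin(np.abs(grid - row.mean_depth))])]
        if row.mean_delta > band.upper or row.mean_delta < band.lower:
            exceed += 1
    summary["bsa_null_exceed_pct"] = 100.0 * exceed / max(1, len(null_windows))

    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
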