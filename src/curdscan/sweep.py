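"""Selective-sweep scan: top-percentile window selection and two-stage
region merging, plus gene overlap annotation.

The scan takes windowed F_ST values, selects windows in the top 5% (by a
nearest-rank quantile over defined windows, ties at the threshold all
included), merges overlapping/bookended selected windows into fragments,
and then merges fragments separated by less than a 100-kb bridge into the
final highly diverged regions.  Both thresholds are strict as quoted:
selection is ``value >= threshold`` where the threshold is the ⌈qN⌉-th
largest value, and fragments merge only when the intervening gap is
strictly smaller than the bridge.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GenomicRegion, GenotypeMatrix, GroupAssignment, WindowStat
from . import genes as _genes

log = logging.getLogger("curdscan")


def top_percentile_select(
    stats: Sequence[WindowStat], q: float = 0.05
) -> tuple[list[WindowStat], float]:
    """Select windows whose value is in the top fraction ``q``.

    The threshold is the k-th largest defined value with ``k = ⌈q·N⌉``
    (nearest-rank); every window with value >= threshold is selected, so
    ties at the threshold inflate the count.  ``q = 0`` degenerates to the
    maximum-tied windows.

    Returns (selected windows, threshold).
    """
    defined = [w for w in stats if w.defined]
    if not defined:
        raise ValueError("no defined windows to select from")
    if len(defined) < 20:
        log.warning("only %d defined windows; threshold is degenerate", len(defined))
    values = np.sort(np.array([w.value for w in defined]))[::-1]
    k = max(1, math.ceil(q * len(values)))
    threshold = float(values[k - 1])
    if values[0] == values[-1]:
        log.warning("all window values equal; every window selected")
    selected = [w for w in defined if w.value >= threshold]
    return selected, threshold


def merge_to_regions(
    windows: Sequence[WindowStat | GenomicRegion], bridge: int = 100_000
) -> list[GenomicRegion]:
    """Two-stage merge of selected windows into final regions.

    Stage 1 merges overlapping or bookended windows into fragments;
    stage 2 merges fragments whose gap (``next.start − prev.end − 1``) is
    strictly less than ``bridge`` bp.  Regions never span chromosomes.
    Idempotent: merging the output again returns it unchanged.
    """
    regions = [
        w.region if isinstance(w, WindowStat) else w for w in windows
    ]
    if not regions:
        return []
    regions = sorted(regions, key=lambda r: (r.chromosome, r.start, r.end))

    def _merge(items: list[GenomicRegion], max_gap: int) -> list[GenomicRegion]:
        out: list[GenomicRegion] = []
        cur = items[0]
        for nxt in items[1:]:
            gap = nxt.start - cur.end - 1
            if nxt.chromosome == cur.chromosome and gap < max_gap:
                if nxt.end > cur.end:
                    cur = GenomicRegion(cur.chromosome, cur.start, nxt.end, cur.label)
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
        return out

    fragments = _merge(regions, 1)  # gap < 1 bp: overlapping or bookended
    return _merge(fragments, bridge)


def genes_in_regions(
    regions: Sequence[GenomicRegion], gene_spans: pd.DataFrame
) -> dict[GenomicRegion, list[str]]:
    """Assign genes to regions by >= 1 bp span overlap.

    ``gene_spans`` needs columns ``gene_id``, ``chrom``, ``start``, ``end``
    (1-based inclusive), e.g. from :func:`curdscan.sites.load_gene_spans`.
    """
    out: dict[GenomicRegion, list[str]] = {}
    for region in regions:
        hit = gene_spans[
            (gene_spans["chrom"] == region.chromosome)
            & (gene_spans["start"] <= region.end)
            & (gene_spans["end"] >= region.start)
        ]
        out[region] = list(hit["gene_id"])
    return out


def discrimination_profile(
    regions: Sequence[GenomicRegion],
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    gene_spans: pd.DataFrame,
) -> pd.DataFrame:
    """Discrimination capacity of every gene overlapping the regions, per group.

    Long-format output: region, gene_id, group, n, n_distinct, capacity,
    representative.  Genes containing zero SNPs get NaN capacity.
    """
    assignment = genes_in_regions(regions, gene_spans)
    spans = gene_spans.set_index("gene_id")
    rows = []
    for region, gene_ids in assignment.items():
        region_label = f"{region.chromosome}:{region.start}-{region.end}"
        for gid in gene_ids:
            span = spans.loc[gid]
            gene_region = GenomicRegion(
                str(span["chrom"]), int(span["start"]), int(span["end"]), gid
            )
            for group in groups.groups:
                samples = groups.samples_in(group)
                strings = _genes.gene_genotype_strings(matrix, gene_region, samples)
                n = len(samples)
                if strings and len(strings[0].genotype) == 0:
                    rows.append((region_label, gid, group, n, 0, float("nan"), ""))
                    continue
                cap = _genes.discrimination_capacity([s.genotype for s in strings])
                rep = _genes.representative_genotype([s.genotype for s in strings])
                n_distinct = len({s.genotype for s in strings})
                rows.append((region_label, gid, group, n, n_distinct, cap, rep))
    return pd.DataFrame(
        rows,
        columns=[
            "region",
            "gene_id",
            "group",
            "n",
            "n_distinct",
            "capacity",
            "representative",
        ],
    )
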