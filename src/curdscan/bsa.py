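"""SNP-index / ΔSNP-index bulked-segregant analysis with simulated
confidence bands under the no-QTL null.

The mapping signal is the per-site SNP index — the fraction of a bulk's
reads carrying the parent-A allele — and the ΔSNP index, the difference
between the high and low bulks.  Windowed mean Δ is compared with a
depth-matched 95% band obtained by Monte-Carlo simulation of bulks of
F2 individuals under Mendelian (no-QTL) segregation.

Input is a per-SNP table with columns ``chrom``, ``pos``, ``b1_a``,
``b1_b``, ``b2_a``, ``b2_b`` giving reads supporting the parent-A and
parent-B alleles in each bulk (parental polarization applied upstream).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GenomicRegion

log = logging.getLogger("curdscan")

REQUIRED_COLUMNS = ("chrom", "pos", "b1_a", "b1_b", "b2_a", "b2_b")
DEFAULT_MIN_DEPTH = 8
DEPTH_GRID = tuple(range(10, 101, 10))


@dataclass(frozen=True)
class NullBand:
    """95% ΔSNP-index interval under the no-QTL null at one read depth."""

    depth: int
    lower: float
    upper: float
    replicates: int
    bulk_size: int
    mean_delta: float = 0.0  # empirical mean of the simulated null Δ


def snp_index(allele_a: np.ndarray, allele_b: np.ndarray, min_depth: int = DEFAULT_MIN_DEPTH) -> np.ndarray:
    """Parent-A read fraction per site; NaN below the depth floor."""
    a = np.asarray(allele_a, dtype=float)
    b = np.asarray(allele_b, dtype=float)
    total = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = a / total
    idx[total < min_depth] = np.nan
    return idx


def delta_snp_index(table: pd.DataFrame, min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Per-site SNP indices and Δ = index(bulk1) − index(bulk2).

    Sites where either bulk is below the depth floor get NaN Δ and are
    skipped downstream.  Adds columns ``index1``, ``index2``, ``delta``
    and ``depth`` (mean of the two bulk depths).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"bulk table lacks column(s): {', '.join(missing)}")
    out = table.copy()
    out["index1"] = snp_index(out["b1_a"].to_numpy(), out["b1_b"].to_numpy(), min_depth)
    out["index2"] = snp_index(out["b2_a"].to_numpy(), out["b2_b"].to_numpy(), min_depth)
    out["delta"] = out["index1"] - out["index2"]
    out["depth"] = (
        out[["b1_a", "b1_b"]].sum(axis=1) + out[["b2_a", "b2_b"]].sum(axis=1)
    ) / 2.0
    return out


def windowed_delta(
    table: pd.DataFrame,
    contig_lengths: dict[str, int],
    window: int = 1_000_000,
    step: int = 10_000,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Sliding-window unweighted mean of defined per-site Δ indices.

    Output columns: chrom, start, end, n_sites, mean_delta, mean_depth.
    Empty windows are NaN.
    """
    per_site = delta_snp_index(table, min_depth)
    rows = []
    for chrom in contig_lengths:
        sub = per_site[per_site["chrom"] == chrom].sort_values("pos")
        ok = sub["delta"].notna().to_numpy()
        pos = sub["pos"].to_numpy()[ok]
        delta = sub["delta"].to_numpy()[ok]
        depth = sub["depth"].to_numpy()[ok]
        cdelta = np.concatenate([[0.0], np.cumsum(delta)])
        cdepth = np.concatenate([[0.0], np.cumsum(depth)])
        length = contig_lengths[chrom]
        for start in range(1, length + 1, step):
            end = min(start + window - 1, length)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            n = int(hi - lo)
            if n == 0:
                rows.append((chrom, start, end, 0, np.nan, np.nan))
            else:
                rows.append(
                    (
                        chrom,
                        start,
                        end,
                        n,
                        (cdelta[hi] - cdelta[lo]) / n,
                        (cdepth[hi] - cdepth[lo]) / n,
                    )
                )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "mean_delta", "mean_depth"]
    )


def simulate_null_band(
    depth: int,
    bulk_size: int = 20,
    replicates: int = 10_000,
    confidence: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> NullBand:
    """Monte-Carlo ΔSNP-index band under Mendelian no-QTL segregation.

    Per replicate and per bulk independently: ``bulk_size`` F2 genotypes
    are drawn with probabilities (1/4, 1/2, 1/4) for (AA, Aa, aa); the
    bulk's parent-A allele frequency is (2·nAA + nAa)/(2·bulk_size); read
    counts follow Binomial(depth, p); Δ is the difference of the two bulk
    indices.  The band is the empirical (α/2, 1−α/2) quantile pair.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if replicates < 100:
        log.warning("only %d replicates; band will be noisy", replicates)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = 1.0 - confidence

    def bulk_index() -> np.ndarray:
        geno = rng.multinomial(bulk_size, [0.25, 0.5, 0.25], size=replicates)
        p = (2 * geno[:, 0] + geno[:, 1]) / (2.0 * bulk_size)
        reads_a = rng.binomial(depth, p)
        return reads_a / depth

    delta = bulk_index() - bulk_index()
    lower, upper = np.quantile(delta, [alpha / 2.0, 1.0 - alpha / 2.0])
    return NullBand(
        depth, float(lower), float(upper), replicates, bulk_size, float(delta.mean())
    )


def simulate_band_grid(
    depths: tuple[int, ...] = DEPTH_GRID,
    bulk_size: int = 20,
    replicates: int = 10_000,
    confidence: float = 0.95,
    seed: int = 0,
) -> dict[int, NullBand]:
    """Null bands on a grid of read depths (one RNG stream, reproducible)."""
    rng = np.random.default_rng(seed)
    return {
        d: simulate_null_band(d, bulk_size, replicates, confidence, rng) for d in depths
    }


def call_candidate_regions(
    window_stats: pd.DataFrame, bands: dict[int, NullBand]
) -> list[GenomicRegion]:
    """Merge consecutive windows whose |mean Δ| exceeds the depth-matched
    95% band (nearest-depth lookup) into candidate QTL regions."""
    grid = np.array(sorted(bands))
    out: list[GenomicRegion] = []
    cur: GenomicRegion | None = None
    for row in window_stats.itertuples():
        exceeds = False
        if not (np.isnan(row.mean_delta) or np.isnan(row.mean_depth)):
            nearest = int(grid[np.argmin(np.abs(grid - row.mean_depth))])
            band = bands[nearest]
            exceeds = row.mean_delta > band.upper or row.mean_delta < band.lower
        if exceeds:
            win = GenomicRegion(row.chrom, int(row.start), int(row.end))
            if cur is not None and cur.chromosome == win.chromosome and win.start <= cur.end + 1:
                cur = GenomicRegion(cur.chromosome, cur.start, max(cur.end, win.end))
            else:
                if cur is not None:
                    out.append(cur)
                cur = win
        else:
            if cur is not None:
                out.append(cur)
                cur = None
    if cur is not None:
        out.append(cur)
    return out
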