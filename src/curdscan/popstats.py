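"""Windowed nucleotide diversity, Weir–Cockerham F_ST and LD decay.

Estimator choices
-----------------
* π per physical window: the unbiased per-site heterozygosity
  ``2·c_ref·c_alt / (n·(n−1))`` summed over sites and divided by the window
  length in bp, where ``c_ref``/``c_alt`` are non-missing allele counts at
  the site and ``n = c_ref + c_alt``.
* F_ST: Weir & Cockerham (1984) two-level variance components on allele
  frequencies and observed heterozygosity; windows aggregate as the
  weighted ratio-of-sums ``Σa / Σ(a+b+c)``.  Negative values are reported
  as computed, never clipped.
* LD: composite (genotype-dosage) r² — the squared Pearson correlation of
  0/1/2 dosage vectors over samples non-missing at both sites — averaged
  in 100-bp physical-distance bins.

Windows are anchored at position 1 of each chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MISSING, GenomicRegion, GenotypeMatrix, GroupAssignment, WindowStat

__all__ = [
    "FstComponents",
    "LdBin",
    "pi_windows",
    "mean_pi",
    "fst_site",
    "fst_windows",
    "ld_decay",
    "half_decay_distance",
]


@dataclass(frozen=True)
class FstComponents:
    """Per-site Weir–Cockerham (1984) variance components for two populations.

    ``a`` is the among-population component; ``denominator`` is a+b+c.
    The per-site estimate is ``a / denominator``; it can be negative in
    small samples and equals 1 only when the populations are fixed for
    different alleles.
    """

    a: float
    denominator: float

    @property
    def ratio(self) -> float:
        return self.a / self.denominator


@dataclass(frozen=True)
class LdBin:
    """Mean r² over SNP pairs whose separation falls in (lower, lower+width]."""

    lower: int
    mean_r2: float  # NaN when n_pairs == 0
    n_pairs: int


# -------------------------------------------------------------------------
# helpers

def _group_calls(
    matrix: GenotypeMatrix, groups: GroupAssignment, label: str
) -> np.ndarray:
    samples = groups.samples_in(label)
    if not samples:
        raise ValueError(f"group {label!r} has no samples")
    return matrix.calls[matrix.sample_indices(samples), :]


def _tiles(chrom: str, length: int, window: int) -> list[tuple[int, int]]:
    """Non-overlapping tiles of ``window`` bp from position 1."""
    return [(s, min(s + window - 1, length)) for s in range(1, length + 1, window)]


def _sliding(chrom: str, length: int, window: int, step: int) -> list[tuple[int, int]]:
    return [(s, min(s + window - 1, length)) for s in range(1, length + 1, step)]


# -------------------------------------------------------------------------
# nucleotide diversity

def _pi_site_terms(calls: np.ndarray) -> np.ndarray:
    """Per-site unbiased heterozygosity 2·c_ref·c_alt/(n(n−1)); NaN if n<2."""
    present = calls != MISSING
    n = 2 * present.sum(axis=0).astype(float)
    c_alt = np.where(calls == MISSING, 0, calls).sum(axis=0).astype(float)
    c_ref = n - c_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = 2.0 * c_ref * c_alt / (n * (n - 1.0))
    terms[n < 2] = np.nan
    return terms


def pi_windows(
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    label: str,
    window: int = 100_000,
) -> list[WindowStat]:
    """π per non-overlapping physical window for one group.

    Windows tile each chromosome from position 1; monomorphic windows get
    π = 0; a window value is the sum of per-site terms divided by the
    window length in bp.
    """
    calls = _group_calls(matrix, groups, label)
    if calls.shape[0] < 2:
        raise ValueError(f"group {label!r} has fewer than 2 samples")
    terms = _pi_site_terms(calls)
    pos = matrix.sites["pos"].to_numpy()
    chrom_arr = matrix.sites["chrom"].to_numpy()
    out: list[WindowStat] = []
    for chrom in matrix.chromosomes:
        length = matrix.contig_lengths[chrom]
        on_chrom = chrom_arr == chrom
        for start, end in _tiles(chrom, length, window):
            in_win = on_chrom & (pos >= start) & (pos <= end)
            t = terms[in_win]
            t = t[~np.isnan(t)]
            region = GenomicRegion(chrom, start, end)
            out.append(
                WindowStat(region, "pi", float(t.sum()) / region.length, int(t.size))
            )
    return out


def mean_pi(
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    label: str,
    window: int = 100_000,
) -> float:
    """Genome-wide π: unweighted mean of defined window values (NaN if none)."""
    vals = [w.value for w in pi_windows(matrix, groups, label, window) if w.defined]
    return float(np.mean(vals)) if vals else float("nan")


# -------------------------------------------------------------------------
# Weir–Cockerham F_ST

def _wc_components(callsA: np.ndarray, callsB: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised WC84 two-population components per site.

    Returns (a, denominator, usable).  A site is usable when both groups
    have at least one non-missing diploid, n̄ > 1, and the two groups are
    not jointly monomorphic.
    """
    r = 2.0
    out_a = np.full(callsA.shape[1], np.nan)
    out_d = np.full(callsA.shape[1], np.nan)

    def tally(calls: np.ndarray):
        present = calls != MISSING
        n = present.sum(axis=0).astype(float)  # diploid count
        alt = np.where(calls == MISSING, 0, calls).sum(axis=0).astype(float)
        het = (calls == 1).sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = alt / (2.0 * n)
            h = het / n
        return n, p, h

    n1, p1, h1 = tally(callsA)
    n2, p2, h2 = tally(callsB)
    n_bar = (n1 + n2) / r
    usable = (n1 >= 1) & (n2 >= 1) & (n_bar > 1)
    # jointly monomorphic sites carry no information
    tot = n1 + n2
    with np.errstate(invalid="ignore"):
        p_bar = (n1 * p1 + n2 * p2) / tot
    with np.errstate(invalid="ignore"):
        usable &= ~np.isnan(p_bar) & (p_bar > 0) & (p_bar < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / tot
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1.0))
            * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
    out_a[usable] = a[usable]
    out_d[usable] = (a + b + c)[usable]
    return out_a, out_d, usable


def fst_site(
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    label_a: str,
    label_b: str,
    site_index: int,
) -> FstComponents | None:
    """WC84 components at one site; ``None`` if the site is unusable
    (jointly monomorphic, or too few genotyped diploids)."""
    callsA = _group_calls(matrix, groups, label_a)[:, [site_index]]
    callsB = _group_calls(matrix, groups, label_b)[:, [site_index]]
    a, d, usable = _wc_components(callsA, callsB)
    if not usable[0]:
        return None
    return FstComponents(float(a[0]), float(d[0]))


def fst_windows(
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    label_a: str,
    label_b: str,
    window: int = 100_000,
    step: int = 10_000,
) -> list[WindowStat]:
    """Sliding-window F_ST as the ratio-of-sums Σa / Σ(a+b+c).

    ``window`` must be a multiple of ``step``.  Windows with zero usable
    sites are undefined (NaN).
    """
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    callsA = _group_calls(matrix, groups, label_a)
    callsB = _group_calls(matrix, groups, label_b)
    a, d, usable = _wc_components(callsA, callsB)
    pos = matrix.sites["pos"].to_numpy()
    chrom_arr = matrix.sites["chrom"].to_numpy()
    out: list[WindowStat] = []
    for chrom in matrix.chromosomes:
        length = matrix.contig_lengths[chrom]
        on_chrom = chrom_arr == chrom
        # per-chromosome cumulative sums over sorted site positions
        idx = np.flatnonzero(on_chrom & usable)
        cpos = pos[idx]
        ca = np.concatenate([[0.0], np.cumsum(a[idx])])
        cd = np.concatenate([[0.0], np.cumsum(d[idx])])
        for start, end in _sliding(chrom, length, window, step):
            lo = np.searchsorted(cpos, start, side="left")
            hi = np.searchsorted(cpos, end, side="right")
            n_sites = int(hi - lo)
            region = GenomicRegion(chrom, start, end)
            if n_sites == 0:
                out.append(WindowStat(region, "fst", float("nan"), 0))
                continue
            num = ca[hi] - ca[lo]
            den = cd[hi] - cd[lo]
            val = float("nan") if den == 0 else float(num / den)
            out.append(WindowStat(region, "fst", val, n_sites))
    return out


# -------------------------------------------------------------------------
# linkage disequilibrium

def ld_decay(
    matrix: GenotypeMatrix,
    groups: GroupAssignment,
    label: str,
    max_dist: int = 1_000_000,
    bin_width: int = 100,
) -> list[LdBin]:
    """Dosage-r² decay: all intra-chromosomal SNP pairs within ``max_dist``,
    averaged into ``bin_width``-bp distance bins covering (0, max_dist].

    Pairs with fewer than 2 shared non-missing samples or zero dosage
    variance at either site are skipped.
    """
    calls = _group_calls(matrix, groups, label).astype(float)
    if calls.shape[0] < 4:
        raise ValueError(f"group {label!r} has fewer than 4 samples")
    pos = matrix.sites["pos"].to_numpy()
    chrom_arr = matrix.sites["chrom"].to_numpy()
    n_bins = max_dist // bin_width
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for chrom in matrix.chromosomes:
        idx = np.flatnonzero(chrom_arr == chrom)
        cpos = pos[idx]
        g = calls[:, idx]
        present = g != MISSING
        gz = np.where(present, g, 0.0)
        m = len(idx)
        for i in range(m - 1):
            hi = int(np.searchsorted(cpos, cpos[i] + max_dist, side="right"))
            if hi <= i + 1:
                continue
            J = slice(i + 1, hi)
            ok = present[:, [i]] & present[:, J]
            c = ok.sum(axis=0).astype(float)
            x = np.where(ok, gz[:, [i]], 0.0)
            y = np.where(ok, gz[:, J], 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                mx = x.sum(axis=0) / c
                my = y.sum(axis=0) / c
                vx = (x * x).sum(axis=0) / c - mx * mx
                vy = (y * y).sum(axis=0) / c - my * my
                cov = (x * y).sum(axis=0) / c - mx * my
                r2 = cov * cov / (vx * vy)
            dist = cpos[J] - cpos[i]
            good = (c >= 2) & (vx > 0) & (vy > 0) & (dist > 0)
            b = (dist[good] - 1) // bin_width
            np.add.at(sums, b, r2[good])
            np.add.at(counts, b, 1)
    out = []
    for b in range(n_bins):
        mean = sums[b] / counts[b] if counts[b] else float("nan")
        out.append(LdBin(b * bin_width, float(mean), int(counts[b])))
    return out


def half_decay_distance(bins: list[LdBin], bin_width: int = 100) -> float:
    """Distance at which mean r² first falls to half its maximum.

    The maximum bin mean m* is located; scanning outward in distance, the
    first crossing of m*/2 is linearly interpolated between bin centers.
    Returns NaN if the curve never reaches m*/2; raises if every bin is
    empty.
    """
    defined = [(b.lower + bin_width / 2.0, b.mean_r2) for b in bins if b.n_pairs > 0]
    if not defined:
        raise ValueError("all LD bins are empty")
    centers = np.array([d for d, _ in defined])
    means = np.array([m for _, m in defined])
    k = int(np.argmax(means))
    target = means[k] / 2.0
    for i in range(k + 1, len(defined)):
        if means[i] <= target:
            d0, m0 = centers[i - 1], means[i - 1]
            d1, m1 = centers[i], means[i]
            if m1 == m0:
                return float(d1)
            return float(d0 + (m0 - target) * (d1 - d0) / (m0 - m1))
    return float("nan")
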