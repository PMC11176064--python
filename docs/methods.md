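# Methods

This note documents the statistical procedures implemented in `curdscan`,
the defaults and their rationale, what the synthetic cohorts do and do not
emulate, and the numerical conventions that matter for reproducing output.

## Data model and coordinates

Genotypes are diploid biallelic-SNP calls coded as alternate-allele dosage
(0, 1, 2) with missing (−1) as a first-class state that is never imputed.
Multi-allelic records and indels are dropped at VCF load (counts logged):
every downstream statistic is defined on biallelic SNPs, and no imputation
or phasing step exists anywhere in the pipeline, so phase separators in
input are ignored. All intervals are 1-based and inclusive in memory; BED
emission/ingestion converts to and from 0-based half-open. Windows are
anchored at position 1 of each chromosome and never span chromosomes;
trailing windows are truncated at the chromosome end. Chromosome order is
the VCF header contig order, for determinism.

## Nucleotide diversity (π)

Per site, the unbiased expected heterozygosity
`2·c_ref·c_alt / (n·(n−1))`, where `c_ref`, `c_alt` are non-missing allele
counts and `n = c_ref + c_alt`. Window π is the sum of site terms divided by
the window length in bp (default 100 kb, non-overlapping); genome-wide π is
the unweighted mean of defined windows. Sites with fewer than two
non-missing alleles contribute nothing. Because the divisor is physical
window length, π is comparable across windows of equal size but the
(truncated) last window of a chromosome uses its actual length.

## F_ST

Per-site two-population Weir–Cockerham (1984) variance components `a`
(among-population) and `a+b+c` (total), computed from per-group sample
sizes, alternate-allele frequencies and observed heterozygote proportions.
A site is skipped when either group has no genotyped diploid, when the
average sample size n̄ ≤ 1, or when the two groups are jointly monomorphic.
Windowed F_ST is the weighted ratio-of-sums `Σa / Σ(a+b+c)` over the
window's usable sites (50-kb/5-kb windows for between-group divergence,
100-kb/10-kb for the sweep scan). One estimator family is used throughout:
the scan thresholds are rank-based, so the choice between closely related
WC-style estimators barely moves the selected set. Negative per-site or
per-window values (possible in small samples) are reported as computed,
never clipped — clipping would distort window ranking.

## Sweep scan

1. **Selection.** The threshold is the k-th largest defined window value
   with `k = ⌈q·N⌉` (nearest-rank; default q = 0.05); every window with
   value ≥ threshold is selected, so threshold ties inflate the count.
   Nearest-rank avoids interpolation ambiguity under ties; `q = 0`
   degenerates to the maximum-tied windows. Selection is genome-wide, not
   per-chromosome. Fewer than 20 defined windows triggers a degenerate
   threshold warning.
2. **Merging.** Stage 1 merges overlapping or bookended selected windows
   into fragments ("neighboring" is read as overlap-or-adjacency, since
   sliding windows overlap by construction); stage 2 merges fragments whose
   gap `next.start − prev.end − 1` is strictly less than 100 kb. The
   procedure is idempotent.
3. **Annotation.** A gene is assigned to a region on ≥ 1 bp span overlap.

Note a structural property of percentile selection: it always selects ~q of
all windows, so a planted divergent block covering less than q of the
genome is necessarily accompanied by selected background windows; recovery
of a planted sweep is therefore judged by the uniqueness and coverage of
the region containing the block, not by the total region count.

## Identity-by-state ancestry painting

The pseudo-ancestral reference of a group is its per-site modal genotype
over non-missing calls, ties broken toward the smaller alternate dosage
(homRef < het < homAlt) for determinism; an all-missing site stays missing.
Donor accessions are compared to this consensus in consecutive
**non-overlapping** 5-kb windows ("consecutive" is taken to mean tiling;
overlapping steps would break the 5-kb granularity of region lengths). Per
window: shared = sites where both calls are non-missing, similarity =
exact-state matches / shared. A window passes iff shared ≥ 5 and
similarity > 0.96 (both strict as stated); identity is a strict
genotype-state match, so donor het vs consensus hom counts as a mismatch —
a conservative choice that slightly deflates similarity for heterozygous
donors. Maximal runs of passing tiles merge into identical regions;
per-donor contribution is summed region length over genome length, with
5-kb-binned length histograms.

With 2 % site-level noise and a similarity floor of 0.96, the per-tile pass
probability depends strongly on SNPs per tile (binomial discreteness):
about 0.82 at 10 SNPs/tile but ≥ 0.93 above ~130 SNPs/tile. The fixtures
therefore use SNP densities of 30–36/kb, which also matches what a
resequencing cohort of this genus yields genome-wide.

## Gene-body genotypes and discrimination capacity

A gene's genotype string is the genomic-order concatenation of call symbols
(0/1/2, "." for missing) at SNPs inside the gene span. The representative
genotype of a group is the modal string (ties: lexicographically smallest).
Discrimination capacity is distinct strings / group size ∈ (0, 1]; strings
containing missing symbols count as distinct, which upper-bounds the
capacity. The homology filter retains alignment hits with
min(query, subject coverage) > 0.70, percent identity > 75 and
mismatches/alignment-length < 0.25 (the mismatch-rate denominator is the
aligned span — the natural reading of a mismatch rate; the choice is
isolated in one predicate). Relative expression is
`2^−(CT_target − CT_control) × 1000` arbitrary units.

## BSA / QTL-seq

Per site and bulk, the SNP index is the parent-A read fraction; sites below
a depth floor (default 8 reads per bulk; the floor suppresses index noise
at thin coverage and is configurable) are undefined. ΔSNP index =
index(high bulk) − index(low bulk); windows (default 1,000 kb sliding,
10-kb step, as quoted — the width is configurable since it is unusually
wide relative to the step) take the unweighted mean of defined site Δs.
Confidence bands under the no-QTL null are Monte-Carlo: per replicate and
bulk, 20 F2 genotypes are drawn Mendelian (¼, ½, ¼), the bulk allele
frequency is the realised parent-A fraction, read counts are
Binomial(depth, p), and the band is the empirical 2.5/97.5 % quantile pair
of Δ over 10,000 replicates, simulated on a depth grid {10, 20, …, 100}
with nearest-depth lookup. Candidate regions are maximal runs of
consecutive windows whose mean Δ escapes the depth-matched band. Indices
are polarized on the parent-A allele (polarization is applied upstream of
the bulk table); unpolarized Δ signs are meaningless. Because a window
averages many sites, its null variance is far below the single-site band,
so the per-window exceedance rate under the null is well below 5 % — the
band is deliberately the paper-style per-position band, not a
window-adjusted one.

## Fourfold-degenerate sites

Each CDS base of each transcript is classified by how many of the four
bases at its codon position conserve the amino acid (standard genetic code;
1 → recorded as 0-fold). Spliced CDSs are assembled in transcript
orientation (minus-strand genes on the reverse complement, mapped back to
forward coordinates), leading bases trimmed per the first exon's phase.
Genes whose adjusted length is not a multiple of 3, or with an internal
stop, are skipped with a warning; a CDS on a missing contig is fatal.
Positions where overlapping transcripts disagree are marked conflicted and
excluded from 4d sets — a conservative rule, since the 4d set is a
neutrality proxy. The neutral-SNP filter keeps 4d SNPs with MAF > 0.05
(computed on non-missing alleles) and missing fraction < 0.20, both strict.

## LD decay

r² is the squared Pearson correlation of genotype-dosage vectors over
samples non-missing at both sites (composite LD — the data are unphased, so
no EM haplotype phase is estimated), for every intra-chromosomal pair
within 1,000 kb, averaged into 100-bp distance bins. Pairs with fewer than
two shared samples or zero dosage variance are skipped. The half-decay
distance locates the maximum bin mean m*, then linearly interpolates
between bin centers to the first crossing of m*/2; NaN if never reached.

## Synthetic cohorts: what they emulate, and what not

`simulate_groups` draws per-site ancestral frequencies Uniform(0.05, 0.95)
and perturbs each group by a truncated normal with scale
drift·√(p(1−p)) — a frequency-drift caricature of nested population
structure with controllable divergence. Planted sweep blocks force the two
designated groups to frequencies (1±gap)/2. Genotypes are binomial
(Hardy–Weinberg within groups); missingness is uniform at random (default
3 %, matching the regime the missing-rate filters target). Defaults: three
crop groups of 20 with drift 0.06/0.09/0.12 (diversity declining along the
domestication series) plus wild donors at 0.18; 10-Mb chromosome at
30 SNPs/kb; demo block 300 kb with gap 0.8.

Deliberately **not** emulated: linkage disequilibrium from recombination
maps (sites are exchangeable given frequencies, so LD decay on these
cohorts is flat at the ~1/n sampling floor — the half-decay estimator is
instead validated on closed-form exponential curves), genealogical
structure (no coalescent), site-frequency-spectrum realism, and alignment/
calling artifacts. Passing tests therefore demonstrate correctness of the
estimators and threshold rules and recovery of planted signals, not
robustness to real-data artifacts.

`plant_introgressions` copies the recipient consensus into donor tracts and
flips each site to a different call state with the noise probability.
`simulate_f2_bulks` conditions bulks on causal-locus homozygosity and lets
each gamete switch parental origin with the Haldane recombination fraction
r(d) = (1 − e^(−2·rate·d))/2 (default 4 cM/Mb) — a single-locus linkage
simplification without full meiosis; unlinked chromosomes use r = ½ and
serve as no-QTL calibration controls.

Problem sizes in the demo/reproduction script: 10-Mb cohort at 30 SNPs/kb
(300k sites, 66 samples), 1,000 scan windows, five 50-kb planted tracts,
F2 design of 10-Mb + 5-Mb chromosomes at 1 SNP/kb and 50× bulk depth, LD on
a 5,000-site thinned subset. These sizes make every planted feature
recoverable with comfortable statistical margin while the whole pipeline
runs in seconds.

## Numerical conventions and edge cases

* Undefined window statistics are NaN and excluded from means and
  percentile thresholds; an all-undefined scan is an error.
* All strict/non-strict inequalities follow the quoted rules: MAF > 0.05,
  missing < 0.20, similarity > 0.96, shared ≥ 5, top-5 % selection
  ≥ threshold, merge gap < 100 kb, homology coverage > 0.70 / identity
  > 75 / mismatch rate < 0.25.
* Ties: consensus → smaller dosage; representative genotype →
  lexicographic; percentile threshold → all ties included.
* Every random draw flows from one `numpy` Generator seeded explicitly;
  generators are pure functions of (config, seed).

## Known limitations

* The IBS painter reports similarity at the genotype-state level; a
  donor–consensus allele-sharing variant (half-credit for het overlap)
  would be less conservative but is not implemented.
* Windowed F_ST assumes the two groups are fixed panels; no correction for
  relatedness or inbreeding within groups.
* The BSA null band assumes equal, fixed per-site depth within a bulk;
  overdispersed coverage would widen the true null slightly.
* The 4d classifier trusts the annotation's phases; it does not re-derive
  reading frames.
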