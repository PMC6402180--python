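# Methods

This note documents the models and procedures implemented in rohscape,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that pin down
behaviour in edge cases.

## Genotype representation and QC

Genotypes are dense int8 call codes (HOM_A / HET / HOM_B / MISSING) with
variant metadata in 1-based base pairs. A/B allele roles are assigned per
variant by first occurrence among fully-called genotypes in the input
file; a half-missing pair ("A 0") is treated as missing and does not
influence the assignment, which makes read → write → read the identity.
The roles are cosmetic: every analysis depends only on
hom/het/missing status and allele-sharing counts.

Variant QC applies three rules in a fixed order — excluded chromosomes
(default X, Y and unplaced "0"), then missingness (> 10%), then minor
allele frequency (< 0.01, computed on non-missing calls). The order is
pinned because removing variants never changes per-variant MAF
denominators, so the composition is idempotent; the QC report counts
removals per rule in that order. Sample-level QC is out of scope.

## ROH calling

A qualifying segment on one chromosome must satisfy, as a whole:

| constraint | standard | fine-scale |
|---|---|---|
| span (last − first SNP bp) | > 500 kb | ≥ 80 kb |
| homozygous SNPs | > 80 | ≥ 20 |
| heterozygous calls | ≤ 1 | ≤ 1 |
| missing calls | ≤ 2 | ≤ 2 |
| max inter-SNP gap | ≤ 100 kb | ≤ 100 kb |
| density (span / SNP count) | ≤ 50 kb/SNP | ≤ 50 kb/SNP |

plus a homozygous first and last SNP (segment ends are trimmed to
homozygous calls, as PLINK's reporting does). The standard preset honours
the strict ">" comparisons as printed in the settings it reproduces; the
fine-scale preset ("80 kb window, min. 20 SNPs") reads as inclusive
minima. Both strictness switches and the choice to count only homozygous
SNPs toward the minimum (rather than all SNPs) are exposed as parameters.
Heterozygous and missing calls count toward the segment's SNP total and
the gap/density checks, never toward the homozygous count. Segments never
span chromosomes; span is `end − start` (a difference, not +1), matching
how the interval lengths are reported downstream.

The caller is a greedy left-to-right scan: repeatedly select the
qualifying segment with the smallest start (ties broken by the largest
end) that does not overlap anything already emitted, then resume after
it. This selection rule is deterministic and is verified in the test
suite against exhaustive enumeration of all qualifying subintervals on
random instances (both presets). Implementation-wise, the scan
precomputes prefix counts and budget-limited extents with numpy, so the
per-individual cost is near-linear in SNP count except in pathological
density-failure regions.

Two deliberate consequences of this definition are worth knowing:

* **Boundary extension.** With one heterozygote permitted, a maximal
  segment extends past a true autozygous tract into flanking
  chance-homozygous SNPs, and may annex one flanking heterozygote when a
  homozygous run continues beyond it. At 5 kb SNP spacing with ~64%
  homozygous background the extension has a geometric tail (a few SNPs
  on average, occasionally tens of kb). This is a property of the data
  and the segment definition, not an implementation artifact; recovery
  experiments therefore measure boundary accuracy on tracts of 3–12 Mb,
  where the extension is negligible relative to length, rather than on
  minimum-length tracts where a 5% overlap tolerance would mostly
  measure the flank process.
* **Allowance non-monotonicity.** The *set* of qualifying subintervals
  grows monotonically when the het/missing budgets are raised, and the
  property tests assert exactly that. Total covered bp after greedy
  selection is not guaranteed monotone — a larger budget can merge two
  segments across a heterozygote into one that consumes a middle run too
  short to stand alone — so no such guarantee is claimed.

## Genomic inbreeding and length classes

F_ROH = S_ROH / L_AUTO with L_AUTO defaulting to 2243 Mb (the equine
autosome; configurable). L_ROH is the per-individual mean segment length,
and group summaries average per-individual values (sample SD, ddof = 1).
Length classes use half-open bins [lo, hi) in Mb with edges
0.5, 1, 2, 4, 6, 8, 10 — a segment of exactly 2.0 Mb falls in 2–4 Mb. A
bin's F_ROH contribution is the group-mean per-individual summed length
in the bin over L_AUTO, in percent; cumulative values below each upper
edge accumulate those contributions, so the total equals their sum to
machine precision. Percentages are rounded to one decimal only at the
reporting layer. A segment shorter than the smallest bin edge raises an
error, since it indicates the caller's minimum length was violated.

## ROH islands

Incidence is the per-SNP fraction of a group's individuals covered by at
least one segment (each individual counts once per SNP; the denominator
is the full group, including individuals without segments). Islands are
maximal runs of SNPs with incidence strictly above the threshold
("more than 50%" is strict: a run at exactly 0.5 is not an island).
Sub-threshold gaps are never bridged. `min_snps` defaults to 2 to
suppress single-SNP spikes while keeping very short (~10 kb) islands
callable. The reported island frequency is the maximum per-SNP incidence
inside the run, which matches the "shared by X%" reading at the island
core; the mean incidence is also emitted. Island begin/end are SNP
positions (not mid-gap boundaries), and length is end − begin.

Cross-group classification matches islands by reciprocal overlap ≥ 0.5
(both directions) with transitive closure; an island matching no island
of any other group is private. Gene annotation lists genes overlapping an
island by ≥ 1 bp, in position order; BED input is converted from 0-based
half-open to the internal 1-based closed convention, GFF3 is taken as
1-based closed.

## Population structure

IBS between two individuals is the mean over mutually non-missing SNPs of
the per-SNP shared-allele fraction (0, 0.5, 1); a pair with no
overlapping genotyped SNP is an error rather than a silent NaN. PCA
double-centers the relationship matrix and reports eigenvalue fractions
over the positive spectrum; an all-equal matrix is flagged degenerate.
Exact numeric parity with any particular PLINK IBS normalization is not
claimed.

F_ST is the Weir & Cockerham (1984) estimator: per-locus variance
components a, b, c from sample sizes, allele frequencies and observed
heterozygosity per group, combined across loci as Σa / Σ(a+b+c). Loci
monomorphic across the pair, or with fewer than two genotyped individuals
in either group, are excluded. The original study computed F_ST with an
unspecified estimator, so small absolute differences from its printed
values are expected; the estimator here is validated against a
hand-computed two-deme case and by parameter recovery on Balding–Nichols
simulations.

The k-NN network uses distance 1 − IBS, k = 10 by default, ties broken
by sample order, and symmetrizes by union (an edge exists if either
endpoint lists the other), which preserves the asymmetric "cross-link"
bridges between clusters; a mutual mode is available. The optional
minimum-spanning-tree backbone of some network pipelines is intentionally
omitted. Node sizes map S_ROH affinely onto [4, 20] display units (purely
presentational); admixture fractions are consumed from an external
ADMIXTURE-style Q matrix (rows checked to sum to 1 within 1e-3, then
renormalized) — estimating Q is out of scope. The label-partition
modularity of the network is compared against a label-permutation null
when a structure test is needed.

## Synthetic-data generator

`simulate_population` emulates the structure of a multi-subpopulation
array panel:

* **Frequencies.** Ancestral B-allele frequencies uniform on
  [0.05, 0.95]; per-subpopulation frequencies Balding–Nichols
  Beta(p(1−F)/F, (1−p)(1−F)/F) at target F_ST = F (independent across
  subpopulations and loci). F = 0 short-circuits to identical
  frequencies.
* **Positions.** One SNP per `snp_spacing` on average, with uniform
  ±40% jitter on inter-SNP gaps, exercising the gap and density rules.
* **Autozygosity.** Per individual, tract lengths are drawn from a
  configurable (length, weight) mixture (default mirroring the observed
  segment-length spectrum: 0.75–12 Mb representative lengths with ±15%
  jitter) until the per-individual F_ROH budget is met; the final tract
  is trimmed to the remaining budget but never below the mixture's
  smallest class, so trimming cannot create tracts outside the
  configured spectrum. Tracts are placed uniformly (chromosome chosen
  proportional to length, centers kept half a tract length from the
  ends) and overlaps are merged in the ground truth. Inside a tract both
  haplotypes copy a single allele draw — tract-level identity by
  descent — so tract allele content follows local frequencies, exactly
  what a detector sees in real autozygosity.
* **Island.** A chosen fraction of individuals (rounded) receives a
  forced self-copied tract over the island interval.
* **Noise.** Each call independently becomes heterozygous with
  `het_error_rate` (default 0.005, i.e. ~0.5 heterozygotes per 100 tract
  SNPs, so the single-heterozygote allowance is exercised) and missing
  with `missing_rate` (default 0.002).

Defaults describe the study-scale conditions (377 individuals in
subpopulations of 254/55/45/23, 31 autosomes totalling ~2243 Mb at 4 kb
spacing, F_ST 0.05, F_ROH 0.13, a ~400 kb island on chromosome 25 with
carrier fraction 0.66). Tests and the acceptance script run deliberately
smaller configurations — typically 2–5 chromosomes of 10–90 Mb and
40–200 individuals — chosen so every experiment still contains hundreds
of planted tracts or thousands of loci.

What the generator does **not** emulate: linkage disequilibrium beyond
subpopulation divergence, recombination-map or coalescent realism, allele
ascertainment of a real array, sex chromosomes, and pedigree structure.
Consequently, passing tests demonstrate correctness of the detection,
summary and network machinery under planted truth; they do not
demonstrate that biological conclusions transfer to any particular real
panel. The generator targets S_ROH/F_ROH, not the segment-count
distribution N_ROH, exactly.

## Numerical conventions and degenerate inputs

* Coordinates 1-based bp internally; kb/Mb only in reports (kb printed
  with 3 decimals is exact bp).
* Variants are sorted by (chromosome, position) with numeric chromosome
  order, then X, Y, unplaced; duplicate positions within a chromosome are
  rejected.
* Empty segment lists summarize to zeros (L_ROH = 0 when N_ROH = 0); an
  empty region in a fine rescan returns an empty list, not an error.
* All randomness flows from one `numpy.random.Generator`; identical
  configurations produce bit-identical panels, and the pipeline writes no
  timestamps, so reruns are byte-identical.
* The acceptance script derives sub-seeds below 2^31 from the given seed
  via `numpy.random.SeedSequence`.

## Known limitations

* The greedy segment selection is one defensible resolution of
  overlapping candidates; other tools (notably window-based callers) can
  report slightly different boundaries around heterozygotes. Bit-level
  parity with PLINK's windowed heuristic is explicitly not a goal.
* Island frequency definitions vary in the literature (per-SNP maximum
  vs. whole-island sharing); both the maximum and the mean are reported,
  and downstream comparisons should state which is used.
* The W&C F_ST estimator is unbiased only asymptotically in loci; on
  panels below ~1,000 informative SNPs the estimate is noticeably noisy.
* IBS-based PCA variance fractions depend on the relationship scaling
  and are not comparable across panels with different SNP counts.
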