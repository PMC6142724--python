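# Methods

## Score model

The polygenic score is the raw weighted allele count
`S_i = Σ_j g_ij β_j`, with `g` the effect-allele dosage (0/1/2) and `β`
the per-allele effect in mm of height. No centering or allele-frequency
normalization is applied (no `−2p̄β` term): the raw convention is the one
under which the genotype-class decomposition of a score — the four sums
over (positive/negative β) × (homozygous-effect/heterozygous) cells —
reconstructs the total exactly, which is the property the composition
analysis relies on. Scores are therefore comparable only within a fixed
SNP panel; that is how every analysis here uses them.

Missing genotypes are mean-imputed with the cohort mean dosage of the SNP
(logged per cell). This keeps scores comparable across individuals with
different missingness and is standard practice for additive scores; the
alternative of dropping SNPs per individual would give each person a
different panel.

Harmonization matches effect-table rows to VCF records by chromosome +
position + unordered allele pair; SNP identifiers are reporting-only,
since ids drift across annotation builds. When REF is the effect allele
the ALT count is flipped (`2 − count`). Strand-ambiguous SNPs (A/T, C/G)
are retained with a warning by default (an option drops them): without
strand information for the source GWAS, silently dropping them would be
as arbitrary as keeping them, and the warning leaves the decision
auditable. Imputed SNPs with imputation info score strictly below 0.4 are
removed; directly genotyped SNPs and SNPs without a score are never
filtered on info.

## LD pruning

LD is measured as the squared Pearson correlation of dosage vectors over
individuals observed at both SNPs — the composite (Rogers–Huff style)
estimator. It needs no phasing, is deterministic, and on unphased
diploid data is the standard phase-free r². Pairs with fewer than two
complete observations, and pairs involving a monomorphic SNP, get r² = 0
(flagged); r² is computed within chromosomes only.

Tag selection is a greedy maximum-coverage cover: repeatedly pick the SNP
with r² ≥ threshold (default 0.8) to the largest number of currently
uncovered SNPs, ties broken by lowest position then lexicographic id;
each SNP is assigned to the first tag that covers it. Greedy cover is not
guaranteed minimal, but on 6-SNP instances checked exhaustively it is
within one tag of the optimum, and on block-structured panels (the
realistic case) it recovers exactly one tag per block. The tagger's tag
counts on real data are an approximation to any particular tool's output
(tagging software differs in estimator and search order) and are not
treated as externally comparable numbers.

## Rank statistics

Percentile of a focal score against N comparison scores uses mid-ranks:
`100 × (#below + 0.5 × #ties) / N`, with the focal individual excluded
from the denominator when it is part of the cohort. A percentile of
exactly 100 means strictly above every comparison score; that state is
flagged (`is_highest`) and rendered as `*` in bootstrap tables.
Conventions differ on whether the focal individual joins the denominator
and how ties are split; mid-rank-with-exclusion is declared once here and
used everywhere.

The subset bootstrap draws, for each replicate, a subset of m distinct
SNPs uniformly (an option switches to with-replacement resampling),
rescores every individual on that subset alone, and records the focal
percentile. Summaries are min / Q1 / median / Q3 / max with quartiles by
linear interpolation between order statistics (numpy default, "type 7"),
plus the fraction of replicates in which the focal score ranked strictly
highest. The default is 10,000 replicates per size at sizes
100–2000 — enough for quartiles stable to well under one percentile
point; the extremes (min/max) of a bootstrap distribution keep drifting
outward as replicates grow, so they should only be compared at equal
replicate counts. Replicates are computed as one matrix product between
the dosage×β contribution matrix and a 0/1 subset indicator, so
replicate counts of 10⁶ per size remain reachable by raising `reps`.

## Null simulation

The "no evolutionary constraints" null draws each SNP's genotype
uniformly from {0,1,2} (probability ⅓ each) independently across SNPs —
deliberately ignoring allele frequencies, which is the point of that
null — and scores it with the real βs. A `hwe` mode instead draws
dosage ~ Binomial(2, p_j), i.e. a random-mating population at the
observed frequencies; it is a labeled alternative, not the same null.
Both have closed forms (uniform: mean Σβ, variance ⅔Σβ²; HWE: mean
Σ2pβ, variance Σ2p(1−p)β²) that the simulator is tested against at 4
standard errors.

Moments are accumulated streaming: per-chunk mean and sum of squared
deviations merged with the parallel (Chan) update, min/max tracked
exactly, so memory is independent of the simulation count. Genotypes are
drawn in fixed row-major order, making results independent of chunk size
up to floating-point merge order (verified to 1e−12 relative; min/max
are bit-identical). Reported variance is the sample variance (ddof 1).

## Composition statistics

Each SNP of one individual falls in exactly one (sign β) × (genotype
class) cell; β = 0 SNPs are excluded from the sign cells and counted
separately. Cell contributions are `Σ dosage×β` over the cell's SNPs;
the four scoring cells sum to the individual's score (identical
accumulation order; equality asserted at 1e−9 relative, since BLAS dot
products may reassociate the panel-wide sum). The homozygote excess is
`count(hom-effect, β>0) − count(hom-effect, β<0)`.

The goodness-of-fit test compares the six observed cell counts with
expected proportions — by default the cohort-average composition — via
the Pearson χ² statistic with df = 5 and an upper-tail p. The test
structure (six cells, cohort-average expectations) is a declared choice;
with rounded cohort-average inputs the p-value is reproducible only to
the precision of those averages. Score–phenotype association uses
Pearson's product-moment correlation with the exact t-based two-sided p.

## Synthetic cohorts

The generator emulates the study conditions end to end. Defaults: 1020
individuals × 2910 SNPs, allele frequencies ~ Uniform(0.05, 0.95)
(common variants), genotypes Binomial(2, p) (HWE), ~14.4% of SNPs marked
imputed with info ~ Uniform(0.4, 1). Effect sizes are Normal(0, 0.05 mm)
clipped to [−0.14, 0.19] mm — σ chosen so essentially all draws fall
inside the observed per-allele effect range before clipping, with the
asymmetric clip bounds matching that range.

LD blocks (default ~5 SNPs per block, random sizes from uniform cut
points, never spanning chromosomes) copy a founder dosage column; each
individual's genotype in a copy is independently redrawn from HWE with
probability `f = 1 − √r²_target`, so founder–copy correlation is exactly
`1 − f` and founder–copy r² hits the target analytically (copy–copy
pairs land at the target squared — at the 0.95 default, ≈ 0.90, still
within one block-calibration band). Phenotypes are
`height_cm = 176.8 + (S − S̄)/10 + ε`, with the mm→cm factor explicit and
`Var(ε)` set from the realized score variance so the score explains a
configurable fraction of phenotypic variance (default 0.20; the
generator recovers 0.20 ± 0.05 at n = 2000, and 0.10 with a 160-SNP
panel, in tests).

The extreme individual sets each SNP, with probability equal to the
enrichment parameter (default 0.3), to the height-increasing homozygote
(dosage 2 if β > 0, 0 if β < 0) and otherwise draws from HWE. It is a
generative construct for "a rare combination of common alleles" — it
makes rank-stability qualitatively testable (strictly highest full-panel
rank, positive homozygote excess, bootstrap medians non-decreasing in
subset size) and is not a model of any real individual. Enrichment 1
saturates at the maximum possible panel score; enrichment 0 is an
ordinary cohort member.

What the generator does *not* emulate: realistic demography or
coalescent LD decay, rare variants, genotyping error, relatedness,
gene–environment interaction, non-additive loci. Passing tests therefore
show the pipeline's operations are correct under their stated models,
not that a real cohort would produce any particular tag count, score SD,
or correlation.

## Problem sizes and numerical choices

The shipped analyses run at desk scale, chosen so the full suite
completes in well under a minute of compute for the unit layers and a
few tens of seconds for the cohort-scale integration: bootstrap 10⁴
replicates per size (10⁶ reachable via `reps`), null simulation 10⁶
individuals (larger counts via chunked streaming), LD-block recovery
checks at 1020 × 400. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; independent stages derive separate
seed streams, and reruns with the same configuration are byte-identical
in their numeric artifacts. Exit codes of the CLI: 0 success, 2
validation error, 3 data-format error.

## Known limitations

- One effect table at a time; no merging of overlapping genotype sources
  per individual (precedence would be configurable upstream).
- No dosage-format (GP/DS) VCF support; GT genotypes only.
- The greedy tagger is an approximation to minimum tag cover (bounded in
  tests on small instances only).
- The percentile and quartile conventions are declared, not universal;
  comparisons with tables produced under other conventions can differ in
  the last decimal.
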