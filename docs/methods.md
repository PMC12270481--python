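# Methods

## The measurement problem

Bulk RNA-seq of a female tissue mixes cells that inactivated either
parental X. At a heterozygous SNP the expected reference-read fraction
from such a mosaic is ~0.5 regardless of the gene's XCI status, so
escape from X-inactivation cannot be read off bulk allele counts. In a
non-mosaic XCI (nmXCI) female — skew δ ≈ 1, i.e. every cell silenced the
same parental X — the inactive-X (Xi) haplotype is the same in every
cell, and the fraction of reads it contributes at a hetSNP estimates the
gene's Xi expression fraction π directly. The pipeline therefore has two
halves: find nmXCI donors (screen), then quantify and test Xi expression
gene by gene in those donors (classify, curate).

## Statistics

**Allelic expression.** `AE = |0.5 − ref/(ref+alt)|`, evaluated as
`|ref − alt| / (2(ref+alt))` — algebraically identical and exactly
symmetric under ref/alt exchange in floating point. Anchor points:
(50,50) → 0, (100,0) → 0.5, (975,25) → 0.475 (exactly 2.5% minor-allele
reads).

**Screen statistic.** Median AE over nonPAR X genes not previously
classified as variable, one designated sample per donor. Verdict nmXCI
iff median **> 0.475** (strict). The standard error shown with each
median is a nonparametric bootstrap over genes (1,000 resamples by
default, seeded); it is descriptive only and plays no part in the
verdict. With fewer than 10 usable genes the verdict is withheld — a
median over a handful of genes is too unstable to call skew either way.

**Escape test.** Per gene × tissue, `xiCount` of `usedDepth` reads from
the Xi allele is tested one-sided against Binomial(usedDepth, 0.025):
`p = P(X ≥ xiCount)`, exact tail via the regularized incomplete beta
(scipy). The 2.5% null absorbs sequencing error and residual mapping
noise rather than asserting true silence. p-values are
Benjamini–Hochberg-adjusted **within each donor × tissue** (the
adjustment universe is all tested hetSNPs of that donor in that tissue;
the per-donor choice keeps donors exchangeable and is configurable in
effect by pre-grouping). Significance is `q < 0.01`, strict. A
configured threshold of 1.0 degenerates to "every tested site
significant" — the limit used to disable the filter deliberately.

**Consensus.** Within a donor: PAR genes are always `PAR`; all expressed
tissues significant → `escape_across_tissues`; none → `inactive_across_
tissues`; more than one but not all → `variable`; a single expressed
tissue gets the corresponding single-tissue label. Significance in
exactly one of several tissues is not `variable` by the wording of the
category system; it is classified inactive and flagged
`single_tissue_signal` so curation reviews it. Across donors: PAR stays
PAR, unanimous escape-type or inactive-type verdicts propagate (named by
the multi-tissue label when any donor has multi-tissue coverage), and
any within-donor `variable` or between-donor disagreement yields
`variable` — the label deliberately covers both intra- and
inter-individual variation.

## Filters and site selection

Two modes, with deliberately mixed strict/inclusive inequalities:

| parameter | screen | detailed |
|---|---|---|
| genotype depth per allele | ≥ 20 (WES only) | ≥ 10 (contributing assay) |
| minor-allele genotype fraction | > 0.10 | > 0.10 |
| RNA depth (ref+alt) | > 10 | > 7 |

"RNA depth" is `refCount + altCount`, not the total including other
bases: AE is defined over the two genotype alleles and other-base reads
are most plausibly errors. Sites contributed by both the WES- and
WGS-derived site lists are merged keeping the record with the larger
total count; exact ties go to WGS (PCR-free, hence less reference-biased).
One hetSNP represents each gene: in screen mode the deepest SNP per
sample; in detailed mode the SNP surviving filters in the most tissues,
ties broken by summed depth, then lowest coordinate (determinism). The
donor's Xi allele at a SNP is the allele with the smaller read count
summed over all tissues, fixed across tissues; an exact tie goes to alt
with a warning. Samples can be excluded by an explicit (donor, tissue)
list, and optionally by an outlier rule — median nonPAR AE more than
0.05 below the donor's median-of-medians — which operationalizes
dropping a tissue whose skew is conspicuously below the donor's others;
the rule is off by default because it is a stand-in for a judgement call.

PAR1/PAR2 default to the GRCh38 assembly definition
(chrX:10,001–2,781,479 and chrX:155,701,383–156,030,895) and live in
config, not code. A gene straddling a PAR boundary is labelled by its
body midpoint, because the classification tables need exactly one label
per gene.

## Curation

The exact binomial test mismodels over-dispersed count data in two
directions: very deep sites become significant at biologically
negligible Xi fractions, and shallow sites miss genuine escape. Three
rules re-label consensus calls, in fixed order, at most one change per
gene, every evaluation logged:

* **over_estimation** — every tissue monoallelic by the empirical
  allelic-ratio > 0.4 guideline (Xi fraction < 0.1) yet ≥ 1 tissue
  significant → inactive.
* **low_read_count** — a `variable` gene with exactly one non-significant
  tissue whose Xi fraction still ≥ τ = 0.05, all other tissues
  significant (fraction ≥ 0.9 of expressed tissues) with Xi fraction ≥ τ
  → escape.
* **low_power** — an inactive/variable gene whose non-significant tissues
  are all *underpowered* (the smallest detectable Xi fraction at their
  depth, `f_min = k_min/d` with `k_min` the smallest count significant at
  α = 0.01, exceeds τ) while observing Xi fraction ≥ τ, with ≥ 1 tissue
  genuinely significant → escape. A single-tissue underpowered gene is
  flagged but never re-labelled: one shallow tissue is not evidence.

Both rescue rules decline genes whose significant tissues are all
monoallelic (AE > 0.4) — that is over-estimation territory — which makes
the rule order stable and curation idempotent. Rules re-label between
escape/inactive/variable only; they never touch PAR and never invent
significance. The τ = 0.05 consistency threshold, the 0.9 tissue
fraction, and the AE > 0.4 ⇔ Xi fraction < 0.1 mapping are this module's
quantitative stand-ins for what is inherently a manual review; they are
exposed in `CurationParams` and are the module's main documented
assumption.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not reads or alignment. Per donor a skew δ ∈ [0.5, 1]; per gene a class
and Xi fraction π: PAR genes π = 0.5, constitutive escape
π ~ U(0.15, 0.40), inactive genes a small leak π = 0.005 (the binomial
null is 2.5% Xi expression, not zero, so a realistic inactive gene leaks
a little), variable genes a per-tissue Bernoulli(0.5) escape indicator
with tissue-specific π when escaping. The expected Xi-majority-haplotype
read fraction at a hetSNP is `f = δπ + (1−δ)(1−π)`; counts are binomial
(optionally beta-binomial with concentration c; ∞/None = binomial) at a
negative-binomial depth, pushed through an odds-scale reference-mapping
bias (b = 0.5 unbiased), with the haplotype→ref/alt assignment
randomized per donor-SNP. Genotype depths are drawn independently per
assay (WES mean 60, WGS mean 35, dispersion 10), and RNA count rows are
replicated per genotype source the way joining per-assay ASEReadCounter
outputs does upstream — so the merge step is exercised.

Cohort defaults reproduce the screening design: 285 donors, 3 at
δ = 1.0, the rest δ ~ U(0.5, 0.9) (the population distribution of mosaic
skew is not well characterized; this uniform is an explicit stand-in),
one tissue per donor sampled from a muscle-heavy mix. The gene panel
defaults to 400 genes at 5% PAR / 15% escape / 10% variable / 70%
inactive, consistent with the field's consensus that roughly 15% of
X-linked genes constitutively escape and ~10% vary. RNA depth is
NB(mean 50, dispersion 5); donors are heterozygous at each SNP with
probability 0.75; 2 SNPs per gene.

Truth (per-donor δ and nmXCI label, per-gene class and π, per-tissue
escape indicators, the true Xi haplotype per donor-SNP) is emitted in a
separate `truth/` directory and never consumed by the pipeline. Two
seeds separate truth structure from count noise so power studies can
redraw noise over fixed truth; all randomness flows through
`numpy.random.SeedSequence`, and identical configs produce byte-identical
outputs.

**What the simulation does not model** — and hence what passing tests do
not show about real data: alignment artefacts beyond the single
reference-bias parameter (no WASP-class multi-mapping effects), genotype
errors (simulated het calls are always correct), linkage between SNPs of
a gene (counts are drawn independently per SNP), expression differences
between genes and tissues beyond the shared depth model, and incomplete
skew in "nmXCI" donors other than through δ < 1.

## Problem sizes and numerical choices

The test suite runs the screen at its design size (285 donors; also a
1,000-donor all-mosaic cohort for specificity) and classification at 500
genes × 10 tissues of one nmXCI donor; law-of-large-number checks use
depth 10⁵ at tolerance 0.01, and SNP-level AE recovery uses depth 10³
against a 3σ binomial envelope. The binomial test is verified against
exact rational-arithmetic tail summation for every (depth ≤ 200, count)
pair at 10⁻¹². Bootstrap SEs in large screened cohorts use fewer
resamples (50–100) since they do not enter any verdict. Degenerate
inputs are defined explicitly: AE of a zero-total site is an error, an
empty cohort screens to an empty table, a gene with no surviving SNP is
absent rather than erroring, and Xi-allele ties resolve to alt with a
warning.

## Known limitations

* Xi-allele assignment is count-based (summed minor allele); for a gene
  with true π near 0.5 the assignment can flip at finite depth, so
  xiFraction is biased downward toward min(π, 1−π). PAR genes are
  unaffected in practice because their consensus label overrides.
* The screen assumes the prior-variable exclusion list is supplied; with
  an empty list, variable escape genes dilute the median and the screen
  loses a little sensitivity (the 0.475 cutoff is conservative enough
  that planted δ = 1 donors still clear it at default panel mixes).
* Consensus treats any disagreement as `variable`; with many donors or
  tissues, a single shallow sample can create disagreement, which is
  exactly what the curation rules are for — but genes whose blocking
  tissue shows Xi fraction below τ stay un-rescued by design.
* The FDR universe is per donor × tissue; pooling donors within a tissue
  would change q-values for multi-donor designs.
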