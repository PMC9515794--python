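# Methods

## The screen

`updscreen` classifies per-chromosome inheritance in a mother–father–child
trio from genotypes at common biallelic SNVs. The model is deliberately
simple: no linkage, no haplotype phasing, no mosaicism. Each site is treated
independently; the statistics that drive the calls are plain fractions over
site classes.

**Site classes.** A site is *informative* when the parents are homozygous
for different alleles (AA × BB); the only genotype consistent with
biparental transmission is then AB. A *Mendelian error* is any child
genotype that no choice of one transmitted allele per parent can produce;
the implementation is equivalent to brute-force enumeration of parental
allele transmissions (and is tested against exactly that oracle). A missing
genotype anywhere makes a site neither informative (for matching) nor an
error — filters must never manufacture signal.

**Whole-chromosome metrics and thresholds.** Two statistics per chromosome:
heterozygosity (% het child calls over non-missing sites) and uniparental
skew (largest of the two parent-identity percentages at informative sites;
a child AB call matches neither parent). Calls use strict inequalities:

| call | skew | heterozygosity |
|---|---|---|
| UPiD | > 90 % | < 10 % |
| UPhD | > 90 % | > 30 % |
| ambiguous_skewed | > 90 % | 10–30 % |
| het_excess_flag (advisory) | ≤ 90 % | > 60 % |

The 10–30 % zone with high skew is reported as `ambiguous_skewed` rather
than forced into either class: only the two extremes are well defined, and
an intermediate value on real data would warrant manual review. The 60 %
advisory bound sits clearly above the ~50 % heterozygosity ceiling expected
at MAF ≥ 0.4 under Hardy–Weinberg; it flags trisomy-like chromosomes
without ever making a UPD call. Exact ties between the two parent-match
percentages report `undetermined`, never an arbitrary parent.

Stability floors (`min_informative = 200` non-missing informative sites,
`min_nonmissing = 1000` sites) return `insufficient_data` instead of a
percentage computed on a handful of sites. WGS-density data never trips
these; sparse panels do, by design. The X chromosome is screened only in
female probands.

**Segmental scan.** Every Mendelian-error site at position p anchors the
window [p, p + 5 Mb). Forward-only anchoring is sufficient: merging the
retained overlapping windows recovers leftward extent, since any error deep
inside an event also anchors a window. Retention requires ≥ 50 Mendelian
errors (read as a ≥ threshold; exact equality would be arbitrary) and
≤ 10 % child heterozygosity at the window's informative sites — windows
with no informative sites cannot be removed on heterozygosity. Retained
windows are merged into minimal disjoint intervals (adjacent intervals
merge; the merge is idempotent and is property-tested against a
union-of-points oracle).

**Deletion discrimination.** A hemizygous deletion looks exactly like
segmental isodisomy in genotypes, because callers emit the surviving allele
as a homozygous diploid call. The discriminator is depth: a merged region
is partial UPD only if its mean child depth is strictly greater than 90 %
of the genome-wide mean; otherwise it is a deletion. Genome-wide coverage
is proxied by the mean per-site child DP over all loaded sites, computed
before filtering (masked genotypes keep their depth). Per-site DP at dense
common SNPs is an essentially unbiased coverage estimator and is fully
under the simulator's control, which lets tests compare it exactly.

**Ordering of the two screens.** When a chromosome receives a
whole-chromosome call, its segmental scan is suppressed (and logged): a
whole-chromosome isodisomy floods the chromosome with error-anchored
windows that would only restate the call.

**Filters.** Sites: biallelic SNVs with population minor allele frequency
≥ 0.4 (MAF = min(af, 1 − af) of the configured frequency source — an INFO
field, default `AF`, or an external chrom/pos/ref/alt/af site list).
Genotypes: per-sample depth in [15, 100] and GQ ≥ 15; a failing genotype is
masked for that sample only, so the site can stay informative for the other
members. The depth filter is applied per sample (the natural reading of
per-genotype filtering); accounting reports what each criterion removed,
and filtering is idempotent.

## The synthetic cohort

The generator emulates joint-genotyped trio calls at a shared panel of
common SNVs. Parental haplotypes are explicit (two alleles per parent per
site, independent Hardy–Weinberg draws at the panel frequency), so the
inheritance classes are generative, not painted on:

* *isodisomy*: both child alleles copy one randomly chosen parental
  homolog — homozygous everywhere;
* *heterodisomy*: the child genotype equals that parent's genotype —
  heterozygosity preserved, skew total;
* *deletion*: one transmitted allele survives and is reported as a
  homozygous diploid call, with expected depth halved inside the interval;
* *trisomy-like*: heterozygous calls forced at rate 0.5 on top of
  biparental transmission (diploid callers over a trisomy see excess het);
* *autozygosity*: at a fraction f of sites both parents carry a shared
  ancestral allele and transmit it, so child heterozygosity falls to
  ≈ (1 − f)·2pq with no uniparental skew — the consanguinity confounder.

Noise: genotype errors replace a call with a uniformly chosen different
diploid genotype (the simplest model producing both false hets and false
homozygotes) at rate 3×10⁻⁴ by default, chosen to reproduce the ~99.97 %
parent-match level that sequencing and calling errors leave on a real
isodisomic chromosome. Depths are negative-binomial (mean 40, shape 25 —
mid-30s–40× WGS with realistic overdispersion); GQ is 99 except for a 0.5 %
fraction drawn uniformly below the GQ filter. Male probands get no X
records; for female probands the father is hemizygous on X (single
haplotype, homozygous calls, half depth).

**Scale.** Default chromosome lengths are GRCh38 divided by 10. At the
desk-scale panel density of 2,000 sites per chromosome this preserves the
per-5 Mb-window site count (~400–500) of a WGS screen, so the 50-error
window rule operates in the same statistical regime; with full-length
chromosomes at this site count no window could ever reach 50 errors.
Positions are uniform without replacement — no attempt to mimic real SNP
density heterogeneity, recombination or linkage. Consequences for
interpretation: passing tests show the decision logic and thresholds behave
correctly under the assumed error and coverage model; they say nothing
about caller-specific artefacts, reference bias, segmental-duplication
false positives or mosaic events, none of which the generator produces.

The reference cohort (`trio_sim.study_cohort`) has 164 trios (95 male / 69
female probands) with planted events: one maternal chr1 UPiD, two paternal
chr2 UPiD, one maternal chr15 UPhD (a classic clinical UPhD chromosome),
8 Mb and 6 Mb deletions on chr4 and chr9 (mirroring the chromosomes where
large deletion artefacts typically masquerade as segmental UPD), one
trisomy-like chr21, and three probands with genome-wide autozygous fraction
0.25. Each trio draws an independent child seed from the cohort seed; all
randomness flows from a single integer.

## Cohort aggregation

Per chromosome, five-number summaries of the AB percentage and
heterozygosity across probands support boxplot-style review. Outlier
flagging is advisory (the authoritative calls come from the thresholds):
the fence is Q1 − max(1.5·IQR, 5 pp) for AB% (low tail only — skew can only
depress AB) and symmetric on both tails for heterozygosity. The minimum
fence width of 5 percentage points guards the degenerate case IQR = 0,
which a desk-scale cohort reaches easily (most probands sit at exactly
100 % AB with ~230 informative sites, where one miscalled site moves a
proband by 0.4 pp); 5 pp is far above single-site granularity and far below
the ≥ 35 pp displacement of any real whole-chromosome or multi-megabase
event. Prevalence is rendered as "1 in N" with N rounded half away from
zero, reported separately for UPiD and for all whole-chromosome UPD.

## Numerical and degenerate-input choices

* Percentages with an empty denominator are NaN (undefined), never 0; a
  chromosome with zero informative sites cannot be called.
* All threshold comparisons are strict, including the 0.9 coverage ratio —
  a region at exactly 90 % of genome coverage is a deletion.
* Interval conventions: 1-based positions internally, half-open intervals
  everywhere; BED exports are 0-based half-open.
* `chr1` and `1` chromosome naming are both accepted and normalized.
* Determinism: identical (panel, scenario, seed) give byte-identical VCFs;
  the screen itself is deterministic.

## Limitations

Mosaic/low-fraction UPD is out of scope, as are breakpoint refinement below
the 5 Mb window resolution, imprinting-phenotype interpretation, and
anything upstream of the joint-genotyped VCF (alignment, calling, GVCF
merging). The skew denominator excludes informative sites where the proband
is missing; with per-sample filters this is the only self-consistent
choice, but it means heavy proband dropout shrinks the informative count
toward the `min_informative` floor rather than biasing the percentage.
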