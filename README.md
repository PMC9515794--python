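# updscreen

A uniparental disomy (UPD) screen for whole-genome-sequenced parent–child
trios. Given a joint-genotyped trio VCF, a pedigree and population allele
frequencies, `updscreen` detects whole-chromosome isodisomy (UPiD) and
heterodisomy (UPhD), determines the parent of origin, scans for segmental
UPD, separates segmental candidates from hemizygous deletions by read depth,
and aggregates per-trio results into cohort-level summaries and prevalence.

UPD — inheritance of both homologs of a chromosome from a single parent —
matters clinically because isodisomy renders an entire chromosome
homozygous and can unmask recessive deleterious variants carried by one
parent, with very different recurrence-risk implications than biallelic
inheritance. Rare-disease cohorts are enriched for such events, so a cheap
in-silico screen over trio genotypes is a useful triage step in WGS
analysis.

## Method

The screen works from common biallelic SNVs (population minor allele
frequency ≥ 0.4; genotypes filtered to depth 15–100 and GQ ≥ 15) and two
per-chromosome statistics:

* **Uniparental skew.** At *informative* sites — one parent AA, the other
  BB — the biparental expectation for the child is AB. The skew is
  max(%child = mother, %child = father) over informative sites; the argmax
  parent gives the direction of disomy.
* **Heterozygosity.** % heterozygous child calls over all non-missing sites
  of the chromosome.

Calls: skew > 90 % with heterozygosity < 10 % → **UPiD** (one homolog
duplicated); skew > 90 % with heterozygosity > 30 % → **UPhD** (both
homologs of one parent). Heterozygosity excess without skew is flagged as
trisomy-like (advisory); genome-wide low heterozygosity without skew is the
consanguinity signature and is deliberately *not* called.

Segmental events: every Mendelian-error site anchors a 5 Mb window
[p, p + 5 Mb); windows with ≥ 50 Mendelian errors and ≤ 10 % child
heterozygosity at informative sites are retained and merged. A merged
region whose mean child depth exceeds 90 % of the genome-wide mean is
partial UPD; at or below it is a deletion (hemizygous sites are emitted by
callers as homozygous diploid calls, so depth is the only discriminator).

A synthetic trio generator (`updscreen.trio_sim`) produces VCF + truth
files with all of these inheritance classes planted, so the whole pipeline
is testable end to end without patient data.

## Worked example

Simulate a trio with paternal isodisomy of chromosome 2 and an 8 Mb
deletion on chromosome 4, then screen it:

```
$ cat scenario.yaml
proband_sex: female
genotype_error_rate: 0.0003
events:
  chr2: {kind: upid_paternal}
  chr4: {kind: deletion, start: 5000000, end: 13000000, inherited_from: mother}

$ updscreen simulate --scenario scenario.yaml --seed 42 --out-prefix trio --sites 2000
$ updscreen run --vcf trio.vcf --ped trio.ped --out-dir out
```

Selected rows of `out/PROBAND.chromosomes.tsv`:

```
proband  chromosome  n_nonmissing  n_het  pct_het  n_informative  n_ab  pct_ab   pct_match_mother  pct_match_father  call  parent
PROBAND  1           1985          997    50.2267  237            237   100.0    0.0               0.0               none  not_applicable
PROBAND  2           1989          1      0.0503   233            0     0.0      0.0               100.0             upid  father
PROBAND  4           1839          561    30.5057  217            132   60.8295  39.1705           0.0               none  not_applicable
```

Chromosome 1 is ordinary biparental inheritance: ~50 % heterozygosity and
AB at every informative site. Chromosome 2 shows the isodisomy signature —
100 % of informative-site genotypes match the father with heterozygosity
near zero — and is called `upid father`. Chromosome 4's AB percentage is
depressed (60.8 %) but its skew never approaches 90 %, so no UPD is called;
instead the segmental scan reports in `out/PROBAND.regions.bed`:

```
chr4  5047563  13405537  deletion:mother  165  .
```

a merged Mendelian-error region overlapping the planted interval, resolved
as a deletion because its coverage ratio is ~0.5, with the surviving allele
matching the mother.

`updscreen cohort --manifest manifest.tsv --out-dir D` runs many trios and
adds cohort boxplot tables, outlier flags, an event tally and a prevalence
line ("1 in N" probands with whole-chromosome UPiD).

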