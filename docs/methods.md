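# Methods

## The calling model

An SDM call needs three ingredients: phased haplotypes, a biallelic SNV at
two adjacent positions, and a high-confidence ancestral allele at both.
Variants are polarized against a case-encoded ancestral sequence (uppercase =
high confidence, lowercase = low, `.`/`-`/`N` = unknown); a variant whose
high-confidence ancestral base matches neither allele is rejected as
`mismatch`, low-confidence or unknown sites as `low_confidence`. These four
outcomes (match-ref, match-alt, low-confidence, mismatch) partition all
inputs, and the pipeline reports a count for every filter so the cascade can
be audited on real data.

Classification looks at the set of (left, right) allele combinations over
**all** cohort haplotypes — the intermediate haplotype only needs to exist
somewhere in the cohort, per-population analyses subset carriers afterwards.
A single intermediate haplotype suffices (no frequency threshold), and order
inference assumes no back mutation and no recombination between adjacent
bases. Pairs showing both intermediates are excluded as ambiguous rather than
resolved; chains of ≥ 3 consecutive variants are kept but annotated with
their run length for sensitivity analysis. Putative MNPs whose double-derived
haplotype is a singleton carry a `singleton_dd` sub-flag, since it is
ambiguous whether such pairs belong with MNPs or unobservable SDMs.

An individual is a *carrier* of an SDM only if at least one of their
haplotypes carries both derived alleles; (DA, AD) genotypes are not carriers.

## Contexts and consequences

Every single change is keyed by (ancestral triplet, mutated position within
the triplet, derived base) — 576 keys. Noncoding SNPs are recorded in all
three frames on the reference strand; noncoding SDMs yield two
ancestral→intermediate→derived triplet paths, one anchored at the 5′
neighbour and one at the 3′. Within-codon SDMs yield one path on the coding
strand with per-step and net consequences from the standard genetic code;
SDMs spanning a codon boundary are flagged `cross_codon` and excluded from
codon-path tables. Unchanged flanking bases are taken from the *ancestral*
sequence (not the possibly-derived reference), so the recorded ancestral
triplet is truly ancestral; records with low-confidence flanks are dropped
and logged. CpG effects compare the CpG-site sets of the local window before
and after a change (classes: creates / destroys / both / none). For path
*classes* (where flanks outside the triplet are undefined) the CpG labels are
evaluated within the triplet padded by a non-C/G base; this affects labels,
not detection, since any CG created inside the triplet is seen.

## Expectation model

P(change1) is the raw mutational fraction of the first change among
intergenic, isolated (non-adjacent) SNPs. P(change2 | change1) divides the
SNP count of the second change by the summed SNP counts at the intermediate
triplet's *two other* positions. Expected counts over the 2304 ordered
two-step path classes are normalized and scaled so the expected total equals
the observed total; classes with a zero conditional denominator are flagged
undefined and excluded from the scale. Coding expectations divide intergenic
counts by the intergenic/coding abundance ratio of the ancestral triplet
(abundance counted on the coding strand for codons, in a sliding window at
least 2 bp away from any CDS for intergenic triplets), renormalize, and scale
by the total coding SDM count.

Two conditionals are exposed. The default is the proportion conditional
above. The `rate` variant divides the second change's SNP count by the
genomic abundance of the intermediate triplet, i.e. it models a second
mutation whose hazard is proportional to the *absolute* mutability of the
created context. The distinction matters: under a generator (or genome)
where second changes arrive at absolute context-dependent rates, every path
through a highly mutable intermediate (CpG-containing triplets foremost) sits
above the proportion-based expectation by a shared structural factor. The
planted-coupling recovery in the acceptance script therefore uses the rate
conditional, normalized by the aggregate observed/expected ratio of all
other classes (which cancels the total-matching scale), and recovers a
planted multiplier essentially unbiased; the regression analyses keep the
proportion conditional, whose structural CpG elevation is exactly what the
interaction model then decomposes.

## Statistical battery

*Iterative conditionally-independent chi-square*: the loop computes the
overall 2×K chi-square, tests the top-contributing class marginally (2×2,
class vs rest), Bonferroni-corrects by the initial class count, and removes
significant classes until the top class fails or one class remains. Classes
with expected cells below 1 are merged into an `other` bucket. This concrete
loop is this package's definition of the procedure; measured family-wise
error under a matching multinomial null is ≈ 0.05–0.06 at α = 0.05.

*Enrichment screen*: Fisher exact per class per population pair with BH
q-values per pair; reported rows need ≥ 150 sites in each population,
|log2 ratio| ≥ 0.3 and p < 0.05 in at least one comparison (these thresholds
are the defaults and are exposed as parameters).

*CpG interaction model*: observed path-class counts are regressed on
log expected counts, the 12-level first base change, the per-step CpG-effect
label, and their interaction, as a negative-binomial GLM. The dispersion is
estimated by the method of moments iterated against NB fitted means. The
interaction is assessed by a deviance F-test scaled by the full model's
Pearson dispersion rather than a likelihood-ratio chi-square: at the real
design size (2304 classes) the LR chi-square rejected a true null 13–17% of
the time at nominal 5%, while the scaled F-test is calibrated
(rejection fraction 0.04–0.07 across independent 200-replicate sweeps).
McFadden's pseudo-R² is reported against an intercept-only fit.

*Coding models*: four ordinary least-squares regressions (first/second
change × intergenic-SDM/coding-SNP baselines) over the 576 codon-change
classes, with the functional-class × CpG-effect interaction and
internally-studentized residuals for outlier labelling. Rank-deficient
interaction cells (impossible substitution × CpG combinations) are pruned by
QR column pivoting; the same pruning backs all categorical designs here.

*Single-codon contrast*: per class, observed and expected counts form a
binomial response and the indicator "derived codon is ATG or TGG" is the
lone covariate of a logistic model. Both columns are counts, so the binomial
conditioning is exact under the null.

*Flow proportions and dependence*: counts of paths through a given
intermediate triplet, with proportions within each ancestral-triplet row; the
dependence test is a chi-square on the 2×K derived-triplet contingency of two
ancestral states, pooling classes whose expected count falls below 1.

*Strand asymmetry*: each coding path class is paired with its reverse
complement; a 2×2 Fisher test compares the per-ancestral-codon SDM rates on
the coding strand. Ties for the enriched member are broken by a seeded draw.

*Epistasis model*: Poisson GLM (OLS optional) of per-class coding SDM counts
on the log intergenic baseline, second-change functional class, codon count
of the final amino acid, and both CpG-effect covariates, restricted to
classes whose first change is missense (enforced). The reported contrast is
missense vs synonymous second change, with BH q over the functional-class
contrasts. The 663 classes used in the published analysis are the classes
*observed* in that cohort; the enumerable universe of missense-first
within-codon ordered paths is larger (1704), and the model accepts whatever
classes the data supply.

All multiple-testing corrections are Bonferroni or Benjamini–Hochberg; BH is
the default wherever a false-discovery rate is quoted.

## Synthetic cohorts

The generator is deliberately coalescent-free: every polymorphism receives a
carrier set drawn from a discretized neutral 1/x frequency spectrum over
1..2N−1 haplotypes, with carriers weighted 4:1 toward the event's population
of origin, and origins biased by mildly divergent per-population substitution
profiles. This reproduces the features the analyses consume — site counts,
carrier sets, population-divergent spectra, exact mutation order — while
making no attempt at realistic linkage disequilibrium, genealogy, or
demography. Passing tests therefore validate counting, conditioning and
inference logic, not robustness to LD or demographic structure in real data.

Defaults: transition rate 0.008 and transversion rate 0.002 per alternative
base (Ts/Tv = 2) as per-site segregation probabilities; CpG transitions
elevated 18×; second-change channel scale 0.4 with coupling multipliers of
1 (a configurable coupling plants e.g. CA→CG→TG and its reverse complement);
MNP start rate 3 × 10⁻⁴ per site with GA→TT and GC→AA favoured at
probability 0.6 given a matching ancestral dinucleotide; 10% of variant
sites carry the derived allele in the reference; genome length 1 Mb and
3 populations × 50 diploids for the full-pipeline runs (about 25,000
variants and 700–900 SDMs, generated and analysed in ~10 s). Second-round
mutations are placed only on a proper, nonempty subset of the first event's
carriers, so the intermediate haplotype exists and the planted order is well
defined; second-change probabilities are proportional to the SNP rate of the
change in the *intermediate* sequence context. Switch errors flip downstream
phase per individual at heterozygous sites with a configurable probability;
the ledger keeps the true phase. Identical seeds produce byte-identical
output files.

## Null calibrations and problem sizes

Each statistical test has a matching null simulator at the summary level the
test consumes: multinomial spectra (20,000 sites over ~20–24 classes),
NB/Poisson class-count tables at the real design sizes (2304 path classes,
576 codon classes, 663 epistasis classes), and binomial strand counts at
20,000 codons — magnitudes chosen to match a population-scale SDM catalogue.
The linear coding models are calibrated under Gaussian noise, the matching
null of a least-squares model. Uniformity is checked by a
Kolmogorov–Smirnov test on 200 replicate p-values; a KS check at this depth
has its own Monte-Carlo noise, so a near-calibrated test will occasionally
fail at one seed while passing at others.

## Numerical choices and degenerate inputs

Internal coordinates are 0-based half-open; VCF and GFF3 are converted at the
I/O boundary only. Multiallelic records and indels are skipped (counted, not
decomposed); unphased genotypes are a hard error naming the record, as is a
cohort sample missing from the population panel (silent drops would bias
population fractions). Transcripts whose phase-adjusted CDS length is not a
multiple of 3 are dropped with a warning. Overlapping transcripts yield one
path record each, deduplicated on identical codon paths and flagged
`multi_transcript`. Individuals carrying no SDM are dropped from spectrum
matrices. PCA fixes each component's sign by making its largest-magnitude
loading positive. Empty inputs return empty tables, not errors. The VCF,
FASTA and GFF3 *writers* in the synthetic module emit minimal fixed-column
text directly — the files carry only the handful of columns the generator
populates, and plain emitters keep byte-identical determinism simple;
reading always goes through cyvcf2, Biopython and gffutils.

## Known limitations

- No recombination or recurrent-mutation modelling: ambiguous pairs are
  excluded, not resolved, and the order-inference assumption (no back
  mutation, no recombination between adjacent bases) is untested against
  violations other than injected switch errors.
- The multi-way-alignment support filter behind real ancestral-allele
  confidence cannot be reproduced from a FASTA alone; confidence is taken
  from the case encoding as given.
- Consequence annotation covers synonymous / missense / stop gained / stop
  lost (start-codon disruptions are reported but grouped with missense);
  no splice, UTR or regulatory classes.
- Per-individual spectra count each SDM once per carrier individual; a
  per-haplotype variant of that choice is exposed but the published
  convention is ambiguous.
- Extended sequence contexts beyond one flanking base are out of scope.
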