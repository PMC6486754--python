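# Methods

## Problem and model

Tumor sequencing reports, for each somatic variant, the number of reads
supporting the mutant allele (`t_alt_count`) out of the total coverage
(`t_depth`). The observed variant allele fraction (VAF) is diluted by
two factors the raw counts do not show: only a fraction *p* of the
sampled cells are tumor cells (purity), and the locus may not be
diploid in the tumor. Given allele-specific copy number at the locus
(major + minor = `CN_t` tumor copies; normal cells contribute
`CN_n = 2` autosomal copies), a clonal mutation present at integer
multiplicity *m* copies per tumor cell has expected VAF

```
q(m) = m · p / (p · CN_t + 2 · (1 − p))
```

The model assumes clonality (the mutation is in every tumor cell),
autosomal loci (X/Y variants are excluded upstream rather than modeling
sex-dependent normal copy number), and a correct, sample-wide purity
estimate. Subclonal deconvolution and cancer-cell-fraction estimation
are out of scope.

Two inverse estimators are computed per variant:

* **Point estimate** `m_hat = vaf · (p·CN_t + 2(1−p)) / p`, clamped to
  `[0, CN_t]`; values more than half a copy outside that range flag the
  call `OUT_OF_RANGE`. Reported for diagnostics.
* **Integer maximum likelihood** (the primary caller):
  `m* = argmax_{m ∈ {1..CN_t}} log Binom(t_alt | t_depth, q(m))`, ties
  broken toward smaller *m* — conservative against over-calling
  amplification. The confidence margin `llr` is the natural-log
  likelihood gap to the runner-up (`+inf` when `CN_t = 1`); calls with
  `llr < 2.0` (configurable) are flagged `LOW_CONFIDENCE` but still
  classified.

The call is classified by the residual wild-type copy count
`wt = CN_t − m*`: `SINGLE_COPY` (m*=1, wt≥1), `WT_LOST` (m*=1, wt=0),
`MULTI_COPY` (m*≥2, wt≥1), `MULTI_COPY_WT_LOST` (m*≥2, wt=0). The
stratification predicate "multiple mutant alleles" means any allelic
imbalance: `m* ≥ 2` or `wt = 0` (i.e., WT-lost single-copy LOH cases
count), since loss of the wild-type allele raises the mutant dosage per
remaining copy just as amplification does. Because the literature is
ambiguous about whether single-copy LOH belongs in that tally, the
summary also carries the raw counts so either convention can be
re-derived.

## Filtering

Variants pass two order-independent filters before calling:

* **Low-VAF rescue**: variants with VAF < 0.05 are retained only when a
  second caller (default `mutect2`) corroborates the primary
  (`varscan2`) call — sub-5% VAF singletons are overwhelmingly
  sequencing/alignment artifacts at exome depth.
* **Functional selection**: gene in the analysis panel (PIK3CA plus the
  proximal pathway genes PTEN, PIK3R1, AKT1, AKT2, AKT3), a
  protein-altering `Variant_Classification` (missense, nonsense,
  nonstop, frameshift, in-frame indel, splice site, translation start),
  depth ≥ 10, autosomal. The consequence-class whitelist replaces an
  external functional annotator: the MAF input already carries
  consequence classes, so re-annotation would add a heavy dependency
  without new information. The depth floor is a design choice:
  multiplicity estimates from fewer than 10 reads are uninformative.

## Segment join and degenerate inputs

Copy-number context comes from point containment of the variant
position in an ASCAT-style segment (1-based, closed intervals, the
MAF/ASCAT convention; implemented with an interval tree). Variants with
no covering segment are excluded from dosage calling by default and
flagged `NO_SEGMENT` (an `assume_diploid` policy exists but silently
biased diploid assumptions are avoided by default); positions inside
overlapping segments use the first by sort order and are flagged
`AMBIGUOUS`; a mutation at a locus with zero tumor copies is
contradictory and flagged `INCONSISTENT`. Samples whose only oncogene
variants were so flagged still count as mutant for prevalence but are
excluded from the multi-allele denominator (`n_dosage_assessable`),
where dosage is genuinely unassessable.

## Stratification

The sample universe is the purity table (mutation-free samples count in
prevalence denominators; a mutation table cannot supply its own
denominator). Per cancer type and pooled (`AGGREGATE`, computed from
pooled counts, never averaged fractions) the summary reports: mutant
prevalence; the fraction of dosage-assessable mutant samples with at
least one imbalanced oncogene call; and the fraction of mutant samples
with a "second hit" — ≥ 2 distinct oncogene variants (distinct
(position, alt allele) pairs; two callers reporting the same change are
one mutation) or ≥ 1 retained pathway-gene variant, the union of the
two clauses. Cancer-type selection keeps strata with prevalence
strictly above a floor (default 0.10). Fractions with empty
denominators are NA, never 0. No co-occurrence statistics, hotspot
breakdowns, or outcome analyses are computed.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
emitting the exact input dialects plus a ground-truth table. Per
sample: purity ~ U(0.4, 0.9) (typical of purity-filtered exome
cohorts; known exactly to the caller — purity estimation error is out
of scope, though a `purity_noise_sd` hook exists for sensitivity
tests); one allele-specific CN state per mutated gene drawn from a
mixture over {(1,0), (1,1), (2,0), (2,1), (2,2), (3,1), (4,2)}
weighted toward diploid-heterozygous (0.45) with modest aneuploidy;
mutation presence with probability 0.21; allelic imbalance, given
mutation, with probability 0.40; a second hit (pathway co-mutation or
second distinct oncogene variant, 50/50) with probability 0.25. The
presence/imbalance/co-hit defaults are the aggregate rates the analysis
is designed to measure in real cohorts; cohort sizes default to
TCGA-scale per-study counts (≈ 5,000 samples over 11 types).

Mutations are placed on the major allele with multiplicity ≤ major CN
(biologically: amplification of the mutant haplotype). The imbalance
parameter is drawn first and the CN state is resampled to be
compatible: imbalanced draws require major ≥ 2 and get
m ~ U{2..major}; balanced draws get m = 1 on a state with total CN ≥ 2
(the (1,0) LOH state is resampled away so a "balanced" draw never lands
in the WT-lost class). This makes the truth-level imbalance fraction
equal the generating parameter exactly, which is what the recovery
properties compare against. Depth is negative binomial with mean 80
and size 10 (exome coverage is overdispersed; size → ∞ degenerates to
Poisson), `t_alt ~ Binom(depth, q(m))`. Artifact rows (probability
0.05 per sample) get VAF ~ U(0.005, 0.045) and single-caller
provenance, exercising the rescue filter. One CN segment per mutated
gene suffices because the pipeline only queries point containment; no
germline contamination, subclones, or read-level simulation (all
simulated mutations are clonal, matching the model's assumption).

All randomness flows from a single integer seed through one
`numpy.random.Generator`; identical configurations yield byte-identical
files, and every CLI run writes a manifest (config hash, seed, input
checksums, stage counts) for exact reproduction.

### What passing tests do and do not show

The generator draws read counts from the same binomial forward model
the caller inverts, so recovery tests validate the estimator's
correctness and its noise behavior — not robustness to model
violations present in real data: purity estimation error, subclonal
mutations (which bias multiplicity downward), copy-number segmentation
errors, mapping bias, and non-binomial sequencing error. Recovery
accuracy reported here is therefore an upper bound on real-data
performance.

## Numerical choices and problem sizes

Binomial log-pmfs are evaluated in log space (`scipy.stats.binom`),
with `q = 1` handled exactly (likelihood −∞ unless all reads are
mutant). The forward/inverse grid uses p ∈ {0.1..1.0}, CN_t ∈ {1..6},
m ∈ {1..CN_t} (210 cases, agreement to 1e−9). The ML caller is checked
against an independently coded log-factorial pmf argmax on 1,000 random
instances, tie-breaks included. Recovery properties use 2,000 clonal
mutations (accuracy ≥ 0.9 at mean depth 80, strictly above the mean
depth-20 run, confusion confined to adjacent multiplicities) and an
end-to-end cohort of ≈ 2,700 samples (≥ 500 mutant), whose recovered
fractions must land in the exact binomial 99% intervals of the
generating probabilities. The noise-free limit (counts set to
`round(q · 10,000)`) must recover every multiplicity exactly. These
sizes make the whole suite run in seconds while leaving the binomial
intervals tight enough to detect systematic bias of a few percent.

## Known limitations

* Clonality is assumed; subclonal variants yield fractional true
  multiplicities the integer caller cannot represent.
* Purity is trusted as given; errors propagate linearly into `m_hat`
  and can shift `m*` by whole copies at low purity.
* `CN_n = 2` everywhere: X/Y variants are dropped rather than modeled.
* The multiplicity likelihood ignores sequencing error in the reference
  direction (a read-error term would matter mainly near VAF 0 or 1).
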