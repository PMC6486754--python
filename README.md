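# allelic-dosage

Mutant-allele multiplicity calling and PI3K-pathway co-hit
stratification for tumor sequencing cohorts.

Oncogenic point mutations such as *PIK3CA* hotspots are usually pictured
as heterozygous, but tumors frequently carry **more than one mutant
copy** — through amplification of the mutant haplotype or loss of the
wild-type allele (LOH) — and the resulting dosage difference matters
biologically. This package takes the three tables a standard tumor
exome workflow produces and determines, per sample, how many copies of
the mutant allele the tumor carries and whether the PI3K pathway has
accumulated additional hits:

* a MAF-style somatic mutation table with tumor read counts
  (`t_alt_count`, `t_depth`) and caller provenance;
* an ASCAT-style allele-specific copy-number segment table
  (`sample, chr, startpos, endpos, nMajor, nMinor`);
* a per-sample purity/ploidy table.

## Model

For a clonal mutation at multiplicity *m* (mutant copies per tumor
cell), tumor purity *p*, and locus tumor copy number CN_t (normal cells
contribute 2 copies), the expected variant allele fraction is

    q(m) = m·p / (p·CN_t + 2(1 − p))

The caller maximizes the binomial read-count likelihood
Binom(t_alt | t_depth, q(m)) over integer m ∈ {1..CN_t} (ties toward
smaller m; log-likelihood-ratio margin as confidence) and classifies
each call as `SINGLE_COPY`, `MULTI_COPY`, `WT_LOST`, or
`MULTI_COPY_WT_LOST`. A sample shows "multiple mutant alleles" when
m ≥ 2 or the wild-type allele is lost. Cohort stratification then
reports, per cancer type and pooled: mutation prevalence, the fraction
of mutant samples with allelic imbalance, and the fraction with a
second hit (a second distinct *PIK3CA* variant or a protein-altering
co-mutation in PTEN, PIK3R1, AKT1/2/3). Variants are pre-filtered by
the low-VAF two-caller rescue rule (VAF < 0.05 requires MuTect2
corroboration of the Varscan2 call) and a protein-altering
consequence-class whitelist. See `docs/methods.md` for the full model,
assumptions, and design choices.

A seeded synthetic-cohort generator (`allelic_dosage.synthetic_cohort`)
emits all three input dialects plus a ground-truth table, and is used
throughout the tests to validate parameter recovery.

## Worked example

```python
import allelic_dosage as ad

# simulate a small cohort: 300 BRCA + 200 UCEC samples, 21% mutant,
# 40% of mutants allelically imbalanced, 25% with a second hit
cfg = ad.SimulationConfig(seed=7, n_samples_per_type={"BRCA": 300, "UCEC": 200})
paths = ad.simulate_cohort(cfg, "example_cohort")

variants = ad.read_maf(paths.maf)
segments = ad.read_segments(paths.segments)
purities = ad.read_purity(paths.purity)

calls, rejections, counts = ad.call_multiplicities(variants, segments, purities)
summary = ad.summarize_cohort(calls, purities)
print(summary.to_string(index=False))
```

prints

```
cancer_type  n_samples  n_mut_samples  prevalence  n_dosage_assessable  n_multi_allele  frac_multi_allele  n_second_hit  frac_second_hit
       BRCA        300             67    0.223333                   67              26           0.388060            18         0.268657
       UCEC        200             36    0.180000                   36              12           0.333333             4         0.111111
  AGGREGATE        500            103    0.206000                  103              38           0.368932            22         0.213592
```

Reading the AGGREGATE row: 103 of 500 samples (20.6%) carry a retained
*PIK3CA* mutation; 38 of the 103 assessable mutant samples (36.9%) carry
multiple mutant alleles (including wild-type loss); 22 (21.4%) carry a
second pathway hit — all close to the generating rates (0.21 / 0.40 /
0.25) at this cohort size. Comparing calls against the generator's
truth table:

```python
metrics = ad.evaluate_recovery(calls, ad.read_truth(paths.truth))
print(metrics["multiplicity_accuracy"], metrics["artifact_rejection_rate"])
# 0.96 1.0
```

The same workflow is available from the shell:

```sh
allelic-dosage simulate -c config.yaml -o cohort/
allelic-dosage call-multiplicity -c config.yaml -o calls/
allelic-dosage stratify --calls calls/calls.tsv --purity cohort/purity.tsv -o summary/
allelic-dosage evaluate --calls calls/calls.tsv --truth cohort/truth.tsv -o eval/
```

Every run writes a `run_manifest.json` (config hash, seed, input
checksums, stage counts); identical seeds and configs produce
byte-identical outputs.

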