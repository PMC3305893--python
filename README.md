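# xwas

X-chromosome-wide association analysis for disorders with a male-skewed
prevalence, combining family-based transmission tests with unrelated
case-control cohorts.

The X chromosome needs its own association machinery: males are
hemizygous outside the pseudoautosomal regions (PAR1/PAR2), so allele
counting, Hardy-Weinberg testing, Mendelian-error rules, missingness QC
and transmission statistics all differ from the autosomal versions, and
sex-differential genotype missingness can manufacture spurious
associations when the trait itself is sex-skewed. `xwas` implements:

* **X-APL family test** — per nuclear family, the deviation of the
  candidate-allele count in affected offspring from its Mendelian
  expectation given the parental mating type, `D = Σ (x − E[x | mt])`,
  with sons scored on the maternal transmission only and daughters on
  both parents. Missing parental genotypes are handled by an EM over
  mating-type frequencies (HWE-parameterized allele frequency per
  cohort cluster); unaffected siblings sharpen the parental posterior.
  On complete affected-son trios the statistic is exactly McNemar's TDT,
  `(b − c)/√(b + c)`. Sex-specific strata decompose additively.
* **Joint cluster-stratified test** — unrelated cases enter as probands
  of triads with missing parents, controls anchor the EM; per-cluster
  score numerators and variances are summed, `Z = ΣS_k / √(ΣV_k)`, with
  allele frequencies never pooled across clusters.
* **Case-control allelic tests** with X-aware chromosome counting,
  genomic control (`λ = median(χ²)/0.455`), a female recessive-model
  test, and a male haplotype test (phase read directly off hemizygous
  genotypes).
* **Meta-analysis** — weighted Z combination
  `Z = Σw_i Z_i / √(Σw_i²)`, `w = √N_eff`.
* **simpleM multiplicity** — effective number of tests from the
  eigenvalues of the dosage correlation matrix (components explaining
  99.5% of variance); thresholds `α_snp = 0.05/M_eff` and replication
  threshold `√α_snp` for the two-data-set discovery/validation rule.
* **X-aware QC** — call rates, X-heterozygosity sex inference, X-specific
  Mendel rules, exact HWE in females, male-heterozygote screening,
  per-sex missingness limits and the male-vs-female missingness test.
* **Synthetic cohorts** — ascertained singleton/multiplex families and
  case-control samples under a multiplicative X-linked disease model with
  LD-block haplotypes, two-cluster structure and artifact injection, for
  validation, calibration and power studies.

See `docs/methods.md` for the statistical details and design decisions.

## Worked example

Simulate a family cohort (200 singleton + 80 multiplex families) and a
case-control cohort (300/600) sharing one causal SNP (`snp00015`,
per-allele relative risk 1.6, risk-allele frequency 0.3, a batch artifact
planted in the controls), then run the full pipeline:

```python
from xwas.simulate import SimConfig, simulate_cohort, inject_artifacts
from xwas import pedio
from xwas.pipeline import run_pipeline

common = dict(n_markers=30, ld_block_size=3, causal_marker_index=15,
              causal_allele_freq=0.3, rr_per_allele=1.6, par_fraction=0.1,
              missing_base_rate=0.005)
fam, _ = simulate_cohort(SimConfig(**common, n_singleton_families=200,
                                   n_multiplex_families=80, n_cases=0,
                                   n_controls=0, seed=101))
cc_cfg = SimConfig(**common, n_singleton_families=0, n_multiplex_families=0,
                   n_cases=300, n_controls=600,
                   batch_freq_perturbation=0.02, seed=102)
cc, _ = simulate_cohort(cc_cfg)
cc = inject_artifacts(cc, cc_cfg, seed=7)
pedio.write_ped_map(fam, "fam.ped", "fam.map")
pedio.write_ped_map(cc, "cc.ped", "cc.map")

bundle = run_pipeline({
    "datasets": [
        {"name": "fam", "ped": "fam.ped", "map": "fam.map", "kind": "family"},
        {"name": "cc", "ped": "cc.ped", "map": "cc.map", "kind": "casecontrol"},
    ],
    "candidate_genes": "genes.bed",   # BED with GENE1 spanning snp00015
    "seed": 1,
})
res = bundle["results"]
print(res[res.stratum == "overall"].sort_values("p_joint").head(3))
```

Output (best three markers, overall stratum):

```
marker_id       bp   maf  p_discovery  p_validation   p_meta  p_joint    replication  candidate_gene_hit gene_ids
 snp00015 40777776 0.335     7.39e-05      0.000149 4.16e-08 4.15e-08     REPLICATED                True    GENE1
 snp00023 65962960 0.218        0.133         0.206   0.0496   0.0442 NOT_REPLICATED               False
 snp00002  1819680 0.227       0.0462         0.821    0.185     0.13 NOT_REPLICATED               False

M_eff: 26 | alpha_snp: 0.00192 | alpha_replication: 0.04385
lambda_overall: 1.178
```

Reading it: the planted SNP is recovered with discovery (family) P =
7.4×10⁻⁵, validation (genomic-control-corrected case-control) P =
1.5×10⁻⁴, and joint P = 4.2×10⁻⁸ — beyond the simpleM chromosome-wide
threshold (0.05/26 ≈ 1.9×10⁻³); it passes the replication rule (both
sides below √α_snp ≈ 0.044) and the candidate-gene screen. The planted
batch artifact shows up as the inflation factor λ = 1.18, which the GC
correction removed before validation P values were computed. Null markers
stay near their null expectations.

The same workflow is scriptable from the shell:

```bash
xwas simulate --config sim.yaml --out cohort/ --seed 5
xwas qc --ped cohort/cohort.ped --map cohort/cohort.map --report qc.tsv
xwas assoc-family --ped ... --map ... --stratum male --out fam.tsv
xwas assoc-cc --ped ... --map ... --gc --out cc.tsv
xwas simplem --ped ... --map ...
xwas thresholds --meff 8000
xwas run --config pipeline.yaml --out results/
xwas power --config scenario.yaml --alpha 6.25e-6 --test joint --reps 500 --seed 1
```

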