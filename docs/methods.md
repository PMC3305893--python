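# Methods

`xwas` implements a complete X-chromosome-wide association workflow for
disorders with a male-skewed prevalence, combining family-based
transmission tests with unrelated case-control data. This note documents
the statistical models, the defaults and why they were chosen, the
synthetic-data generator's assumptions, and the numerical decisions that
shape results.

## The family transmission statistic

For a biallelic SNP with counted ("candidate") allele frequency *p*, the
unit of analysis is a nuclear family or an unrelated individual treated as
a proband-only triad. Each unit contributes

    D = Σ_affected offspring (observed candidate count − E[count | mating type]),

where the *mating type* is the ordered pair of parental genotypes. On the
non-PAR X there are six mating types (mother 0/1/2 × father 0/1) and the
Mendelian expectations are E[son] = g_M/2 and E[daughter] = g_M/2 + g_F;
in the pseudoautosomal regions markers behave autosomally (nine mating
types, E = g_M/2 + g_F/2 for either sex). The test statistic per cluster
is Z = S/√V with S = Σ D over independent units; sex-specific strata
restrict the scored offspring to affected males or affected females, so
S_overall = S_male + S_female identically.

**Missing parents and the EM.** When parents are ungenotyped, mating-type
frequencies are estimated by EM over all units of a *cluster* (a cohort
with its own allele frequencies). The model is parameterized by the allele
frequency under Hardy-Weinberg proportions and random mating; this is the
identifiable choice — a free 6-cell mating-type distribution is not
identifiable from offspring genotypes alone, and its EM fixed point
depends on initialization (a free-cell variant is retained as
`constraint="free"` for complete-parent data, where it equals the
empirical mating-type proportions). Unrelated cases and controls enter the
EM as single offspring of unobserved matings; this is how case-control
data anchor the frequency inference.

**The contribution posterior.** A unit's expectation averages over its
posterior mating-type weights given the observed parents and genotyped
*unaffected* siblings only. The affected offspring being scored are
excluded from that posterior: conditioning the expectation on the quantity
whose deviation is being measured would not leave E[D] = 0 under the null
hypothesis. With both parents genotyped the posterior is a point mass and
D is the direct Mendelian deviation, so on complete affected-son trios the
statistic reduces exactly to McNemar's TDT, (b − c)/√(b + c).

**Variance.** The default variance is the sum of squared influence
contributions

    ψ_u = D_u + S′(p̂) · s_u / I,   V = Σ ψ_u²,

where s_u is the unit's score for the allele frequency, I the observed
information, and S′(p̂) the derivative of the summed numerator in p̂
(computed by central differences; step 10⁻³·p(1−p)). The augmentation
accounts for the statistic being centered at the *estimated* frequency:
unrelated cases are compared against an expectation fitted partly from
themselves and the controls, which makes the naive Σ D² systematically too
large (measured type-I error 0.029 at nominal 0.05 before the correction,
0.044 after). When no unit's expectation depends on p̂ — all parents
genotyped — S′ = 0 and V = Σ D² exactly, preserving the TDT identity.
Alternatives: `variance_method="plain"` (Σ D²) and
`variance_method="bootstrap"` (unit-level nonparametric bootstrap with the
EM refitted in each resample; agrees with the influence form within ~4% on
a 200-family fixture and is used as a cross-check in the test suite).

**Linkage in multiplex families.** Expectations are conditional on
parental genotypes and therefore linkage-free; correlation between
affected siblings is absorbed at the unit level because D sums within a
family before squaring. No IBD parameter is estimated; the multiplex-heavy
null-calibration suite is the guard for this simplification.

**Degenerate inputs.** Markers monomorphic within a cluster are skipped
for that cluster with a logged reason; units whose genotypes are jointly
inconsistent with every mating type (Mendelian errors that survived QC)
are dropped from both the EM and the score; V = 0 results are flagged
non-informative with P = 1.

## Case-control tests and genomic control

Allele-based 1-df chi-square tests count one chromosome per male at
non-PAR X markers and two otherwise, with Woolf-CI odds ratios; under a
multiplicative model the allelic OR estimates the per-allele relative
risk. Genomic control divides all chi-squares by
λ = median(χ²)/0.4549364 (the exact 1-df median) when λ > 1, and never
deflates. A female recessive-model test (candidate homozygote vs the rest)
and a male multi-marker haplotype test (phase observed directly through
hemizygosity; haplotypes with expected count < 5 pooled) cover the
secondary analyses.

## Joint and meta-analysis

The joint statistic sums per-cluster numerators and variances,
Z = (Σ_k S_k)/√(Σ_k V_k), with allele frequencies inferred separately per
cluster — the stratification that protects against between-cohort
frequency differences (a pooled-frequency mode exists solely to
demonstrate the inflation it causes). The meta-analysis combines signed
study Z scores, Z_meta = Σ w_i Z_i / √(Σ w_i²), with case-control Z taken
as sign(OR − 1)·√(GC-corrected χ²). Default weights are √N_eff with N_eff
the number of affected contributors (affected children for family cohorts,
cases for the case-control cohort); the weight choice is configurable and
echoed in output headers.

Replication requires P < t in both the discovery (families) and validation
(case-control) sets with t = √(0.05/M_eff); with M_eff = 8,000 this is
t = 0.0025 and the family-wise chance of any replicated null marker is
1 − (1 − t²)^M_eff = 0.0488 ≤ 0.05. The candidate-gene screen flags
markers with discovery, validation and joint P all below 0.05 that lie in
a listed candidate gene; the reported expected-by-chance count
n·0.05³ is an approximation (the three analyses share data), used for
context only.

## Multiplicity

simpleM estimates the effective number of tests from founder/unrelated
dosages (males coded 0/2 at non-PAR markers so mixed-sex correlations are
not attenuated): markers are split by map order into blocks of ≤ 1,000,
missing dosages are mean-imputed *only* inside the eigen step, and the
block contribution is the smallest number of principal components whose
eigenvalues reach C = 0.995 of the total (simpleM's published constant).
Zero-variance markers count one test each. A permutation min-P threshold
(label permutation, trend-test statistic) serves as a validation oracle
and agrees with 0.05/M_eff within a factor of 1.5 on an LD-structured
panel in the test suite.

## Quality control

Thresholds (all overridable): sample and SNP call rate ≥ 0.95, family
Mendel rate ≤ 0.02, SNP Mendel rate ≤ 0.04, female HWE exact P ≥ 1e-4,
MAF ≥ 0.01, per-sex missingness ≤ 0.025, male heterozygote fraction
≤ 0.01. Sex is inferred from non-PAR X heterozygosity (male if ≤ 0.05);
mismatches with the reported sex are removed, samples with no informative
X calls are flagged uninferrable and excluded from non-PAR statistics.
SNP filters apply in a fixed order (XY-homologous region, call rate,
Mendel, HWE, MAF, per-sex missingness, male heterozygosity) so removal
ledgers are reproducible, and each removed entity records the first rule
it tripped. HWE is tested in females only (founder females plus female
controls; hemizygous males carry no genotype-proportion information) with
an exact test — the conditional distribution of the heterozygote count
given the allele counts, summed over outcomes no more likely than the
observed one — validated against full rational-arithmetic enumeration.
Mendel rates use child-level errors over child-level opportunities (an
opportunity is a child-SNP pair with the needed parental genotypes; a
son's check needs only his mother). Surviving male-heterozygote calls are
set to missing, matching their interpretation as call errors.

## The synthetic-data generator

The generator stands in for non-public cohort data and reproduces the
structure the analysis assumes: LD blocks (no recombination within,
free recombination between; haplotype frequencies Dirichlet-distributed,
marker frequencies constrained to a configurable range), X-correct
transmission (sons receive a maternal haplotype only; daughters the
paternal X; PAR blocks transmit diploidly), a multiplicative sex-aware
penetrance, and a two-cluster design with tilted haplotype frequencies and
batch perturbation of control allele labels.

Defaults encode the emulated study's realized composition: 758 singleton +
698 multiplex families, 1,204 cases and 6,472 controls, case male fraction
0.82 (the 4.6:1 affected sex ratio), control male fraction 0.52, and a
4.6:1 male:female penetrance ratio with male baseline prevalence 0.015.
Male hemizygote risk defaults to one-allele female risk (dosage
equivalence, γ = 1), configurable. The default marker panel is desk-scale
(200 markers in blocks of 5 with 4 haplotypes); analyses that need a
specific panel size set it explicitly.

**Ascertainment** is exact rather than literal rejection sampling:
affection depends on genotype only through the causal marker, so parental
causal genotypes are drawn from the analytically tilted mating-type
distribution P*(mt) ∝ P(mt)·P(affected child | mt)^k and proband children
i.i.d. from the affected-child conditional. For the supported family
structures (singleton: one affected child; multiplex: two affected
children) this is the same distribution as resampling families until the
ascertainment criterion holds, without the 1/prevalence² cost; a literal
rejection sampler is retained and an equivalence test compares the two.
Extra siblings (rate 0.3) are drawn unconditionally — proband-based
ascertainment — and parents can be structurally ungenotyped at a
configurable rate.

**What the generator does not emulate:** realistic recombination maps or
coalescent LD decay (the causal marker sits in its own block, so LD
partners of the causal variant are absent), genotype-intensity artifacts,
three-generation pedigrees, relatedness between families, and fine-scale
population structure beyond the two-cluster shift. Passing tests therefore
demonstrate correctness of the statistics under the stated model, not
robustness to every real-data pathology.

## Calibration and power study design

Type-I error suites exploit block independence: a cohort simulated with
block size 1 yields one independent draw of the test statistic per marker
(conditional on the pedigree design), so four cohorts × 600 markers give
2,400 i.i.d. null replicates per scenario at a fraction of the cost of
re-simulating cohorts. Scenarios cover multiplex-heavy families with 20%
missing parents, case-control, and the two-cluster joint test under a
frequency shift of 0.1 (where the pooled-frequency alternative visibly
inflates). The power study runs 500 full cohort replicates at the study's
realized sizes (multiplicative RR 1.3, frequency 0.3, α = 6.25×10⁻⁶) —
roughly a minute of CPU. The replication family-wise-error simulation
draws 2,000 replicates of 8,000 independent P-value pairs and has the
closed form 1 − (1 − t²)^M as its cross-check.

## Known limitations

* The influence-function variance is first-order; at very small cluster
  sizes (tens of units) the bootstrap is the safer choice.
* The EM assumes random mating and HWE within cluster; strong inbreeding
  or assortative mating would bias both p̂ and the expectations.
* Family-based haplotype tests are deliberately absent (phase ambiguity);
  the haplotype test is male-only case-control.
* The candidate-gene expected-by-chance count ignores the correlation
  between discovery, validation and joint P values.
* PED/MAP is the only supported genotype format; binary PLINK and VCF
  ingress are out of scope.
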