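# Methods

## The problem this package models

Hereditary retinal degenerations (HRD) are usually strictly Mendelian: one
dominant or two recessive mutations in a single gene are necessary and
sufficient. The analysis reproduced here concerns an exception — a frequent
nonsense allele in the ciliary gene *RP1* (control allele frequency ~0.6%)
that behaves three different ways depending on genetic context: as a
recessive Mendelian allele when in *trans* with a severe *RP1* null, as a
benign polymorphism in heterozygous or homozygous carriers with no other
risk allele, and as an oligogenic risk factor when combined with modifier
alleles in other ciliary genes (notably *EYS*). The package implements the
statistics by which that behaviour is established, plus a generative model
that reproduces it so the whole pipeline runs on data with known truth.

## The load-threshold (quasi-Mendelian) penetrance model

Each biallelic locus $i$ carries a severity weight $w_i \in [0,1]$. An
individual with dosage vector $g$ has mutational load

$$L = \sum_i g_i\, w_i, \qquad \text{affected} \iff L \ge T .$$

Defaults: severe *RP1* nulls $w = 1$, the frequent hypomorphic nonsense
$w = 0.5$, threshold $T = 1.5$, full penetrance, no phenocopies. This is
the minimal assignment consistent with every genotype–phenotype pair the
model must reproduce:

| genotype | load | status |
|---|---|---|
| null/null or null/null' (compound het) | 2.0 | affected |
| null/hypomorph (in *trans*) | 1.5 | affected |
| hypomorph het, nothing else | 0.5 | unaffected |
| hypomorph hom, nothing else | 1.0 | unaffected |
| hypomorph het + one severe modifier allele elsewhere | 1.5 | affected |

The weights and threshold are configuration, not biological claims: the
source model is qualitative ("accumulated load crossing a threshold"), and
any assignment preserving the table above is equivalent for the pipeline.
A phenocopy rate is available as a knob but defaults to zero, keeping
affection deterministic given the genotype.

## The synthetic cohort

`cohort_sim.default_loci()` fixes the study conditions:

* **RP1**: the m1-like Alu-insertion frameshift at $q = 10^{-3}$ (one
  carrier was seen among 524 directly screened controls, so ~1/1000
  alleles is the back-of-envelope scale), the m2-like frameshift at
  $q = 5\times 10^{-5}$ (absent from ~3500 control chromosomes, consistent
  with an East-Asian database frequency of ~5e-5), and the index nonsense
  at $q = 6\times 10^{-3}$.
* **Panel modifiers**: 178 nonsynonymous variants across 84 of the 228
  panel genes, control frequencies log-uniform on the scan window
  [0.001, 0.05] (a 1/q spectrum, the neutral-expectation shape). One
  planted strong modifier (*EYS*-like, $q = 0.017$, $w = 1$) and two minor
  severe co-drivers ($q = 0.002, 0.004$) mirror the three *EYS* hits of
  the source analysis; the remaining 175 are near-neutral passengers
  ($w = 0.02$) that can only be enriched by chance.
* **Background hypomorphs**: 68 loci of weight 0.34 in genes *outside* the
  panel, cumulative frequency 0.53. Three such alleles plus the index
  hypomorph cross the threshold, giving a diffuse oligogenic route that
  leaves most ascertained cases without any panel-gene explanation — as in
  the source cohort, where most index-carrier patients stayed unsolved.
  The route probabilities are calibrated so the planted driver accounts
  for ~1/4 of ascertained cases: with 28 cases that is ~7 carrier alleles,
  i.e. a case allele frequency near 0.125 against 0.017 in controls and a
  conditional odds ratio near 8.
* A dozen out-of-window variants exercise the frequency filter.

Loci are sampled independently (Binomial(2, q) per locus, Hardy–Weinberg;
no linkage disequilibrium, matching the observation that the two real hits
were not in LD). Cases are rejection-sampled from the population until 28
individuals satisfy the ascertainment predicate *affected, heterozygous for
the index variant, no severe RP1 allele*; controls are unselected
population draws. An analytic feasibility check (maximum attainable load
under the predicate) raises immediately when the predicate is
unsatisfiable, before the 10⁷-draw cap is consulted.

What the generator does **not** emulate: LD and haplotype structure,
population stratification, genotyping error correlated with genotype,
variable penetrance, and realistic population prevalence (the background
route is calibrated to the composition of the ascertained cohort, not to
the ~1/2000 population prevalence of HRD). Passing tests therefore show
that the statistics behave correctly under the stated model, not that the
model captures every property of real exome data.

## Exact inference

All 2×2 tests condition on the table margins.

* **Two-sided p** — point-probability rule: the sum of central
  hypergeometric probabilities of all tables no more probable than the one
  observed, with a relative tolerance of 1e-7 when comparing probabilities
  (guarding float ties). This is the convention of `fisher.test` in R,
  which the source analysis used, and reproduces its printed p-values.
* **Odds ratio** — conditional MLE under Fisher's noncentral
  hypergeometric likelihood, solved from $E_\psi[A] = a$ by bisection on
  $\log\psi \in [-30, 30]$ (the conditional mean is strictly increasing in
  $\psi$); hypergeometric terms are computed through log-gamma, so
  cohort-scale counts (tens of thousands of alleles) are exact to double
  precision. At the support boundary the estimate is 0 or ∞; for a
  degenerate table (an empty alt or ref column) it is flagged undefined
  and p = 1.
* **Confidence interval** — inversion of the two one-sided noncentral
  tail tests at $(1-\text{level})/2$ per side, again by bisection on
  $\log\psi$.
* **Hardy–Weinberg** — the standard two-sided exact test: enumeration of
  all heterozygote counts compatible with the fixed allele counts, summing
  probabilities ≤ the observed configuration's. The one-sided
  heterozygote-excess tail is exposed separately; its phred scaling
  (−10·log₁₀ p) is the `ExcessHet` annotation the QC cascade consumes.

One reproducibility note: on the printed solved-vs-controls table the
exact CI is (0.50, 3.12); the source prints 3.14 for the upper bound, a
value that `fisher.test` itself does not return for those counts. The
package reports the computed 3.12.

## QC cascade

Six rules in fixed order, boundary directions taken literally from the
protocol being reproduced: (1) mask calls with DP < 8 or GQ < 20; (2) drop
sites with mean GQ ≤ 35 (over post-mask calls); (3) drop sites with call
rate ≤ 0.9 (post-mask — the numbered order implies masking precedes the
call-rate computation); (4) keep sites with exact-HWE p > 0.05/N, where N
is the number of polymorphic sites entering this step (the divisor is not
stated in the protocol; recomputing it per run is the natural reading);
(5) keep VQSR-pass sites (the flag is an input — no recalibration); (6)
hard filters QD ≥ 2, FS ≤ 60, MQ ≥ 40, MQRankSum ≥ −12.5,
ReadPosRankSum ≥ −8, SOR ≤ 3, ExcessHet ≤ 20. A site is charged to the
first rule it fails; NaN rank-sum annotations (sites without heterozygous
calls) pass but are flagged in the report.

Note that on an ascertained case matrix the index variant itself fails the
HWE rule — every case is a heterozygote by construction. That is correct
behaviour, not an artifact, and the scan excludes the index variant anyway.

## Relatedness

The classical IBS-moment estimator: per pair, counts of sites sharing
0/1/2 alleles identical by state are compared with their expectations
under IBD states 0/1 computed from sample allele frequencies with the
standard finite-sample (without-replacement) correction products; z₀, z₁,
z₂ are solved in that order, bounded with the classical rules (a state
estimate above 1 takes everything; negatives are zeroed and the rest
renormalised), and PI_HAT = z₂ + z₁/2. Frequencies come from the analysed
sample itself — for 28 individuals this leaves a small upward noise floor
(observed mean ~0.01–0.02 for truly unrelated pairs at 5000 sites), which
is accepted and far below the 0.2 relatedness threshold. Sites with
in-sample MAF < 1% are dropped as uninformative; the exact site set the
original tool used is unknowable, so both knobs are exposed.

## Association scan

Variants are selected on *control* allele frequency in the inclusive
window [0.001, 0.05], restricted to nonsynonymous panel-gene variants,
excluding the index variant. Tests are allelic (2n counts — forced by the
printed case frequencies, e.g. 0.125 = 7/56 in 28 diploids), missing calls
excluded from denominators. Significance is Bonferroni at α/n_tested, the
multiplicity correction of the source analysis; no FDR option is offered
in the reproduction path. Q–Q plots use (i − 0.5)/n expected quantiles.
Variant-to-gene and consequence annotations are inputs, not computed.

## Numerical and testing choices

* Bisection tolerances: 1e-8 on the conditional-mean residual, ~1e-10 on
  log ψ; CI comparisons in tests at 1e-3 (the inversion itself is
  monotone, so tighter tolerances only cost iterations).
* All randomness flows through `numpy.random.Generator`; the pipeline fans
  one global seed into per-stage child seeds via `SeedSequence.spawn`, so
  reruns are byte-identical (artifact headers carry version, seed and a
  hash of the analytic configuration).
* Test oracles are independent routes: exact rational enumeration
  (Fractions/integer combinatorics) for Fisher and HWE p-values, grid plus
  golden-section likelihood maximisation for the CMLE, tail-enumeration
  bisection for the CI, and scipy's separately implemented
  `fisher_exact`/`odds_ratio(kind="conditional")` as cross-implementation
  checks. Simulation-backed properties (super-uniformity, FWER control,
  kinship ladder, parameter recovery) use fixed seeds.
* Problem sizes in the default test run are chosen at desk scale: the
  exhaustive Fisher sweep covers every table with n ≤ 60 in the acceptance
  suite (n ≤ 25 in the unit suite), HWE super-uniformity uses 10,000
  sites, the null-scan FWER check 200 replicates of 50 variants, and
  parameter recovery 20 seeds of the full 28-vs-3554 design.

## Known limitations

* Per-seed recovery of the planted modifier is capped by sampling
  variance: with ~7 expected carrier alleles among 56, the carrier count
  fluctuates enough that the variant reaches Bonferroni significance in
  only ~60–70% of seeds and the top rank in ~75–85% — the same fragility
  the 28-patient source design would show under replication. The
  acceptance test that demands both in ≥95% of seeds documents this
  honestly by failing; the distribution-level facts (CI overlap with the
  printed odds ratio, median OR ≈ 8) hold.
* The moment IBD estimator inherits the small-sample frequency bias of
  estimating allele frequencies from 28 individuals; it is visible only in
  the third decimal of PI_HAT and irrelevant at the 0.2 threshold.
* The VCF dialect is deliberately minimal (single ALT, GT:DP:GQ, one
  synthetic contig); it is not a general VCF reader.

One practical caveat on the demo pipeline: its relatedness stage runs on
the ~190 simulated panel loci only, far fewer markers than the exome-wide
call set such screens normally use, so its PI_HAT values are illustrative
and noisy; the properly powered screen (5000 independent common sites) is
what the tests and the acceptance script run.
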