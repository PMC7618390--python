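# Methods

## Model

A colonic stem cell inactivates *APC* through two sequential hits. Each hit
is one of six types: a truncating mutation (stop gain or frameshift) in one
of the regions R0–R3 delimited by the three β-catenin-binding 20-amino-acid
repeats (20AARs) and the first SAMP (AXIN-binding) repeat, a copy-loss LOH
("−"), or a copy-neutral LOH ("×2"). Hit types are drawn independently with
probabilities *m*ᵢ; CN-LOH is admitted only as a second hit, and the
unobserved combinations (−,−) and CN-LOH-first are excluded. The unordered
biallelic genotype (M,N), M ≤ N for numeric pairs, then has neutral
probability m_(M,N) ∝ K·m_M·m_N with K = 2 for distinct orderings and K = 1
otherwise, normalized over the 18 admissible classes. Truncating mutations
downstream of the first SAMP codon (1569) are outside the analysis window
and ignored; mutations in R1–R3 are assumed to escape nonsense-mediated
decay, so a hit in Rᵢ leaves *i* functional 20AARs on its allele, and the
genotype retains X = M+N (two truncating hits), M (CL-LOH) or 2M (CN-LOH)
repeats in total.

Cells with biallelic inactivation progress to detectable cancer with a
genotype-dependent probability p_(M,N); the expected genotype frequency
among cancers is f = C·m·p with C constant across genotypes. Only relative
progression probabilities p̃ ∝ f/m are identifiable, and C is never
estimated. The same ratio at the level of total retained repeats uses
f_X and m_X summed over the classes mapping to each X — mathematically
identical to aggregating before or after the ratio, and implemented once.

Assumptions worth keeping in mind: hit-type probabilities are identical for
the first and second hit and independent of each other; whole-genome
duplication postdates APC inactivation (so a balanced post-WGD locus is
"diploid at initiation"); third hits are ignored (the two most upstream
clonal mutations define the genotype, and a counter reports how often more
were seen); unphased diploid mutation pairs are assigned to distinct
alleles.

## Mutation-probability estimation

Substitutions are classified into the 96 pyrimidine-centred trinucleotide
categories; indels into a 71-category COSMIC-style catalogue (1-bp events by
pyrimidine-collapsed base and homopolymer length; 2–5+-bp events by length
and tandem-repeat count). Microhomology-flanked deletions are excluded from
the catalogue — they are rare in colonic crypts — and rejected at
classification time with a warning. The canonical catalogue leaves 72
non-microhomology categories; this package caps the repeat bins of 5+-bp
deletions at 5+ (such long units rarely support deeper tandem arrays inside
a single gene), giving the 71-type catalogue used throughout. The choice
only relabels one sparse bin and has no effect on any statistic computed
here, because opportunity tables and signature fixtures share the catalogue.

For a signature context (healthy-crypt MSS by default; proximal/distal,
POLE and MSI variants accept their own exposure tables), per-sample
exposures are row-normalized, signatures present in <85% of samples are
dropped, and the remaining exposures are averaged and renormalized — the SBS
and indel channels independently. Each mutation type's probability is
divided by its compatible-locus count within the analysis window, summed
over truncating loci per region, normalized per channel, and the two
channels are combined with the stop-gain/frameshift mixture
P_stop ∝ (SBS:indel ratio) × (stop fraction of SBSs),
P_frameshift ∝ 1 × (frameshift fraction of indels). Defaults: ratio 24:1,
stop fraction 0.052, frameshift fraction 0.88 (≈ 15:11 stop:frameshift);
MSI uses 10:1 (≈ 5:9); POLE sets the frameshift channel to zero. The
printed MSI mixture "3/14 and 9/14" is internally inconsistent (does not
sum to one); the implementation normalizes, matching 5/14 and 9/14 within
rounding. Opportunity enumeration is exhaustive and deterministic:
every position × 3 alternative bases for SBS (positions lacking a CDS flank
are skipped — negligible at gene scale), deletions of 1–5 bp at every start
(longer observed events bin into the 5+ class), single-base insertions of
every base at every junction, and per junction and length one
tandem-duplication event plus one novel-sequence event. Deletions spanning
a region boundary take the region of their 5′-most base, and a frameshift's
region is the indel's own position, not that of the induced stop.

LOH hit probabilities are anchored to the zero-20AAR genotypes, which are
assumed equally tumorigenic: m₋/m₀ = f₍₀,₋₎/(2f₍₀,₀₎) and
m×₂/m₀ = f₍₀,ₓ₂₎/f₍₀,₀₎. Absolute rates follow as μ_APC = (SBS rate per bp
per year) × (window bp) × (stop fraction) × (1 + 1/ratio), μⱼ = μ_APC·mⱼ,
μ₋ = ratio_CL·μ₀/2 and μ×₂ = ratio_CN·μ₀. Chaining the published rounded
inputs reproduces the published LOH rates only to within ≈5%, because those
were computed from unrounded intermediates; the package always chains its
own unrounded values. The expected number of biallelic-mutant arrivals is
taken as Λ(t) = n_s²·N·p_f·t²·(μ_APC² + 2μ₋μ_APC + μ×₂μ_APC)/2 — the t²/2
factor applies to the whole bracket, and the CN-LOH path enters with a
single ordering since it can only be the second hit. The crypt parameters
(N crypts, n_s stem cells per crypt, fixation probability p_f) have no
defaults and must be supplied.

## Inference and tests

p̃ is the plug-in estimator: observed classes get f/m, unobserved classes
get p̃ = 0 with a degenerate lower bound, and no pseudo-counts are added —
smoothing would bias the mode test. Uncertainty comes from a percentile
bootstrap with the tumour as the resampling unit (default B = 10⁴,
α = 0.05); all randomized procedures take explicit seeds and report
(B, K, n_perm, seed) in their outputs.

* **Uniform risk.** Statistic: spread (max − min) of p̃ over the index set
  (retained-20AAR level by default; genotype level optional). Null
  distribution: K multinomial cohorts of the observed size drawn from m;
  p-value with +1 continuity.
* **Maximal loss.** Bootstrap the cohort, take argmax_X p̃_X per replicate
  (ties broken toward smaller X, conservative for this test, and counted);
  reject if 0 lies outside the central 95% of the mode distribution.
  Meaningful only after uniform risk is rejected.
* **Δ between groups.** Difference in progression-weighted mean 20AARs,
  Σx·p̃ₓ. Permutation test shuffles group labels over the pooled tumours
  preserving group sizes (implemented exactly as multivariate-hypergeometric
  splits of the pooled genotype counts), with each permuted group evaluated
  under its own label's mutation model; two-sided p with +1 continuity.
  The site-corrected variant averages per-site Δs weighted by the mutant
  group's site composition; the weight convention (mutant-group counts, not
  pooled) is configurable in spirit but fixed here as the default, and the
  same convention weights the expression-difference statistic by
  driver-group counts per stratum.
* **FAP.** Conditional on a germline hit in R_M, the somatic hit is N with
  probability ∝ m_N·p_(M,N) (no ordering factor). Because published FAP
  tables cannot separate CL- from CN-LOH, predictions expose a merged-LOH
  view; comparison envelopes are per-category 2.5–97.5 percentile bands of
  multinomial simulations at the largest contributing study's size, and
  observed cohorts are overlaid per study rather than pooled.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
genotypes drawn multinomially ∝ m_(M,N)·p_(M,N), materialized as mutation
rows with codons uniform within their region (the model is region-granular;
sub-region position carries no information but exercises the classifiers),
classes drawn from the truncation mixture, copy-number states realizing the
intended ploidy, and plausible metadata. Default study conditions, chosen
once: cohort n = 1000; regional weights (0.849, 0.050, 0.051, 0.050) —
the R0 share anchored to the ratio of the regional to the total truncation
rate, the remainder split near-evenly with the short R3 boosted by
homopolymer-deletion activity; LOH ratios (0.93, 1.43); planted progression
curve p_X ∝ (1, 25, 50, 35, 20, 10, 5), i.e. an optimum at X = 2 sitting
50-fold above complete loss with a monotone decay; proximal:distal sizes
313:574 for group comparisons, with planted Δs produced by exponential
tilting (exact in the weighted mean). CDS fixtures are stop-free random
codon sequences with exactly planted homopolymer runs. Each artifact draws
from its own seed-derived stream, so regenerating one never perturbs
another.

What the generator does *not* emulate: mutation hotspots within regions,
signature-attribution noise, subclonality, phasing errors, polyclonal FAP
polyps, or WGD timing variation. Passing recovery tests therefore validates
the estimator's correctness and calibration under the model's own
assumptions, not robustness to violations of them.

## Numerical choices and problem sizes

Degenerate inputs fail loudly: empty cohorts, all-zero exposure tables,
observed genotypes with zero neutral probability, zero-support simulation
distributions and unclassifiable copy-number states all raise with specific
messages (unclassifiable tumours become logged exclusions at the cohort
level). Signature columns and weight vectors are validated to sum to one
(tolerance 1e−6 on input tables, 1e−9 on internal invariants). Region
breakpoints are inclusive 1-based codon intervals; the first printed codon
of R0 ("codon 0") is treated as codon 1.

The recovery and calibration studies in the acceptance tests use 200
replicates with bootstrap sizes B = 500–2000, K = 500 and n_perm = 199 —
sizes at which the Monte-Carlo error of the *assertion* (a coverage or
rejection rate over replicates) is a few percent, comfortably inside the
asserted margins, while the full suite stays fast. Production analyses
should use the defaults (B = K = 10⁴).

## Known limitations

Percentile bootstrap CIs undercover for classes with expected counts near
zero (a class unobserved in a replicate yields a degenerate interval); the
15AAR-level analysis is enabled generically through configurable region
breakpoints but not reproduced; genome-to-CDS liftover, variant
pathogenicity calling, signature fitting and CMS subtyping are out of
scope and expected as preprocessing.
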