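# Methods

## The partition model

Each patient contributes two variant lists: lymph-node tumor (LN) and bone
marrow / peripheral blood (BM/PB), matched across compartments by exact site
and alleles (chrom, pos, ref, alt) — identical mutations are treated as the
same event, gene-level matching is deliberately not used.

The involvement-attributable VAF ceiling is

    max_involvement_vaf = tb_high / 2 × (1 + tolerance),    tolerance = 0.5

reasoning: a clonal heterozygous variant carried by every neoplastic cell at
tumor burden TB has expected VAF TB/2; the 50% relative tolerance absorbs
copy-number effects and sampling noise, and `tb_high` (the upper end of the
burden estimate) is used so that borderline variants err toward
"involvement" rather than CH. When there is no evidence of involvement the
ceiling falls to an absolute attribution floor of 0.001 (0.1% VAF, the
cross-compartment genotyping limit). A BM/PB variant above the ceiling is CH
(shared if also called in the LN, otherwise BM/PB-only); at or below the
ceiling it is attributed to involvement when the LN carries the same
mutation, and to CH otherwise (a mutation absent from the tumor cannot be
explained by tumor infiltration). LN variants with no CH-classified BM/PB
counterpart are late, lymphoma-specific mutations. No additional absolute
VAF floor is applied to CH calls: the observed CH VAF range (down to ~0.2%)
argues against one, and the attribution rule alone suffices. The
`tolerance` is exposed in the pipeline config.

Tumor burden is estimated per patient down a fixed evidence hierarchy:

1. **flow cytometry** — `tb = flow_pct/100`, ±20% relative interval;
2. **TCRG clonality** (analytic sensitivity 1–5%) — a positive result bounds
   TB to [0.01, 0.05] with point estimate 0.03;
3. **marker-gene VAF** — a lymphoma-marker variant (RHOA hotspot by default)
   in the BM/PB implies `tb = 2 × VAF` under heterozygosity;
4. otherwise TB = 0.

Morphology percentages corroborate but never set the estimate (histology is
the least sensitive tier). Raising TB can only move labels from CH to
involvement, never the reverse (monotonicity, property-tested).

## Mutation catalogs and spectra

SBS-96 contexts follow the conventional lexicographic order — classes C>A,
C>G, C>T, T>A, T>C, T>G, each with the sixteen 5'/3' flank combinations
A..A … T..T — and purine-reference SNVs are reverse-complement-collapsed
onto the pyrimidine strand. Strand-split catalogs (192 bins) stack the
coding-strand half over the template-strand half, where "coding" means the
mutated pyrimidine lies on the coding (untranscribed) strand; the
orientation comes from the per-variant `coding_strand_ref` annotation — no
gene models are consulted. Variants with unknown orientation enter only the
unstranded catalog, so the pairs-sum-to-bin invariant holds exactly on
fully annotated data.

Strand bias for a class is reported as the fold *excess*
(n_forward − n_reverse)/n_reverse, the definition under which counts of 17
vs 5 give exactly 2.4; the plain ratio (3.4) is inconsistent with that
value. The transition-vs-transversion comparison is a paired two-sided
t test on per-sample fractions (the per-sample fraction is the plotted and
compared unit throughout); between-group class comparisons use Welch's
t test on per-case fractions plus the fraction of cases carrying the class
at all.

## Signature inference

Extraction follows bootstrapped consensus NMF:

1. each bootstrap resamples every sample's 96-bin counts multinomially,
   conserving the sample total;
2. each resampled matrix V (96 × samples) is factorized V ≈ WH by
   multiplicative updates minimizing the generalized Kullback–Leibler
   (Poisson) divergence, with uniform-random non-negative initialization
   from the seeded generator; W columns are normalized to sum 1 (scale moves
   into H). The objective is checked non-increasing every 100 iterations;
   convergence is declared at relative objective change ≤ 1e-9 (checked
   every 10 iterations, cap 10 000);
3. the pooled bootstrap signatures are clustered into k groups by
   partitioning around medoids under cosine distance (greedy farthest-point
   seeding, alternating assignment/medoid update); cluster means
   (renormalized) are the consensus signatures and mean silhouette widths
   their stability;
4. exposures are refit on the *original* catalog by per-sample non-negative
   least squares against the consensus profiles, rescaled to the sample's
   SNV total — consensus signatures exist only after all bootstraps, so no
   single run's H is reused.

k is user-supplied (no automatic selection; an over-factorized k shows up as
degraded minimum silhouette, which is tested). Bootstrap count defaults
to 100 — stable clusters at desk-scale runtime for 96-dimensional data.
Signatures are ordered by total attributed mutations for deterministic
naming; identical seeds give bit-identical profiles. CCS matching is plain
cosine similarity (scale-invariant, in [0, 1] for non-negative profiles)
against every reference row, ties broken toward the lowest reference index.
A Frobenius objective is not offered: the Poisson objective is the natural
choice for count catalogs and the only one used here.

## Biomarker and survival

The multiple-hit TET2 call requires ≥ `min_hits` (2) TET2 variants, each
pathogenic (tier 1/2 as annotated on input — tiering itself is out of
scope) and each with VAF ≥ 15%. The threshold is inclusive (≥) and the
operator configurable, since printed sources alternate between "≥15%" and
">15%".

CHN-free survival (time from lymphoma diagnosis to concomitant hematologic
neoplasm, censored otherwise) is analyzed with the product-limit estimator,
the two-group log-rank test, and a binary-covariate Cox model with Efron tie
handling (better small-sample behavior than Breslow) and Wald 95% CIs on the
log scale; these go through lifelines behind the module surface, and the
Kaplan–Meier and log-rank paths are pinned to hand-computed worked examples
in the tests. Complete separation (all events in one group) is reported as a
monotone-likelihood flag with an unbounded CI; near-separation that breaks
the unpenalized Newton–Raphson triggers one retry with a light ridge
(penalizer 0.1), and runaway coefficients (|β| > 15 or SE > 10) are flagged
the same way. The Cox model is unstratified by default; a stratification
variable is not modeled because none is identifiable from the inputs.

Diagnostic metrics are reported as percentages rounded half-up to one
decimal. `reconstruct_confusion` searches all non-negative integer 2×2
tables of a given size whose sensitivity and specificity round to given
values — an exact combinatorial oracle for printed metrics (unique at
N=47 for 72.7/97.2: tp=8, fp=1, fn=3, tn=35, implying PPV 88.9 / NPV 92.1).

## Epidemiology

Direct age standardization: Σ_g (cases_g / population_g) × 100 000 × w_g,
with stratum weights required to sum to 1 ± 1e-6 (e.g. 2010 US standard
population shares). Age-band tables ship as configurable CSVs; no specific
band table is hard-coded. All tests are two-sided: the two-proportion z test
uses the pooled-variance statistic (degenerate pools return z=0, p=1,
flagged), and the t test on fractions is Welch with Satterthwaite df since
equal variances cannot be assumed.

## The synthetic cohort

The generator emulates the cohort structure the analysis assumes, with every
draw recorded as ground truth:

- **CH**: present in 70% of patients. `n_ch_mut_mean = 1.6` is the
  cohort-wide mean (variants per patient across carriers and non-carriers),
  so carriers draw 1 + Poisson(1.6/0.7 − 1) ≈ 2.3 mutations, TET2-heavy
  (weights TET2 0.50, DNMT3A 0.25, then ASXL1/SRSF2/TP53/CBL). BM/PB VAFs
  are Beta with mean 0.225 and concentration 4 — reproducing the observed
  mean (22.5%), median (~17%) and heavy right skew — clipped to
  [0.002, 0.6]. Each CH variant is also seen in the lymphoma with
  probability 0.84 (37/44 shared), with LN VAF = BM VAF × LogNormal(0, 0.2).
- **Involvement**: 63% of patients have BM/PB involvement with TB uniform on
  [0.01, 0.10]. LN variants propagate into BM/PB at
  TB/2 × f × LogNormal(0, 0.2) where the detection-efficiency factor
  f = inv_vaf_mean/(mean TB/2) makes the cohort mean involvement VAF equal
  the configured 1% while staying proportional to TB; generated involvement
  VAFs stay below the TB/2 × 1.5 ceiling with probability > 0.99, and the
  CH-to-involvement mean-VAF ratio is ≈ 22.5.
- **Late mutations**: 1 + Poisson(1.4) per patient (mean 2.4), genes
  RHOA-led (one RHOA hotspot site per patient doubles as the tumor-burden
  marker). Contexts are drawn 60/40 from a smoking-like profile (C>A at
  NpCpC) and a CpCpC C>T profile; smoking-like variants put the pyrimidine
  on the coding strand with probability 17/22, reproducing the 17:5
  asymmetry (fold excess 2.4). Each profile's low-level background mass is
  restricted to its characteristic substitution classes — real signatures
  concentrate in-class, and a flat 96-bin background would make rank-2
  factorization rotation-ambiguous.
- **CHN survival**: hazard = 0.0007/month × 14^(biomarker status),
  administratively censored at 120 months. The baseline gives ~8% events in
  biomarker-negative and ~70% in biomarker-positive patients over
  follow-up, the event split a 2×2 table like tp=8/fn=3 vs fp=1/tn=35
  implies.
- Representation strand of each variant (pyrimidine vs purine reference) is
  randomized 50/50 to exercise the collapsing rules; per-sample signature
  activities for catalog simulations are Dirichlet(0.5) — skewed, so one
  process dominates most samples, as dominance analyses observe.

What it does **not** model: sequencing reads and depth (VAF noise is
multiplicative log-normal σ=0.2, not binomial read sampling), copy-number
events, clonal phylogenies (multi-clone CH appears only as independent
per-variant labels), non-CHN death as a competing risk, and
covariate-dependent CHN hazards. Passing tests therefore demonstrate
correctness of the estimators under these idealized conditions, not
robustness to read-level artifacts or purity/ploidy distortion.

## Problem sizes and numerical conventions

Test and acceptance runs use desk-scale sizes chosen for tight Monte-Carlo
bounds: 200–1000-patient cohorts for partition recovery and generator
calibration; 20 samples × 100 mutations × 100 bootstraps × 20 seeds for
signature recovery; 500 patients per group × 100 replicates for Cox
recovery; 2000 null replicates (n=30/30) for log-rank calibration and 5000
each for the z and Welch tests. Coordinates are 1-based fully closed;
contexts are reported on the reference strand; all randomness flows through
`numpy.random.default_rng` seeds, and identical seeds reproduce every output
bit-for-bit (tested at the pipeline level). Degenerate inputs follow the
rule "explicit, not NaN": empty spectra return zeros, zero-denominator
metrics return missing, zero-event log-rank returns p=1 with a warning.
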