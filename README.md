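# chlymph

Analysis toolkit for the interplay between **clonal hematopoiesis (CH)** and
**angioimmunoblastic T-cell lymphoma (AITL) / peripheral T-cell lymphoma
(PTCL-NOS)** from paired variant tables: a lymph-node (LN) tumor sample and a
bone-marrow / peripheral-blood (BM/PB) sample per patient.

A somatic variant found in the BM/PB of a lymphoma patient has two possible
origins: infiltration of the marrow by the lymphoma itself, or an independent
CH clone. A clonal heterozygous variant confined to neoplastic cells at tumor
burden *TB* is expected at VAF ≈ *TB*/2, so a BM/PB variant whose allele
burden clearly exceeds that level must derive from CH — and, when the same
mutation is also present in the lymphoma, it marks a common mutated
hematopoietic ancestor ("early" mutation). Variants restricted to the tumor
are "late", lymphoma-specific events. On top of this partition the package
provides:

- **`cohort_io`** — typed variant/clinical/signature-matrix I/O and the
  post-alignment variant filter (VAF ≥ 5%, population frequency ≤ 0.01%,
  strand balance ≥ 1:5).
- **`clonal_partition`** — tumor-burden estimation from the evidence
  hierarchy (flow cytometry → TCRG clonality (1–5% sensitivity) → marker-gene
  VAF) and the early/involvement/late partition with the attribution rule
  VAF<sub>max</sub> = TB<sub>high</sub>/2 × (1 + tolerance).
- **`mutation_catalog`** — SBS-96 trinucleotide catalogs (optionally
  strand-split to 192 bins), six-class substitution spectra,
  transition/transversion summaries, coding-strand bias
  ((n<sub>F</sub> − n<sub>R</sub>)/n<sub>R</sub> fold excess), and Welch
  comparisons of per-case class fractions.
- **`signature_inference`** — de novo mutational signatures by bootstrapped
  NMF (multiplicative updates on the generalized Kullback–Leibler objective,
  consensus by partitioning-around-medoids under cosine distance, silhouette
  stability), cosine-correlation-similarity (CCS) matching against a
  30-signature reference set, NNLS exposures and ≥50% dominance calls.
- **`biomarker_survival`** — the multiple-hit TET2 biomarker (≥2 pathogenic
  tier-1/2 TET2 variants, each VAF ≥ 15%), Kaplan–Meier / log-rank / Cox
  analysis of CHN-free survival (CHN = concomitant hematologic neoplasm),
  sensitivity/specificity/PPV/NPV, and a brute-force oracle that reconstructs
  the 2×2 confusion table behind printed, rounded accuracy metrics.
- **`epi_stats`** — direct age standardization
  (Σ<sub>g</sub> cases<sub>g</sub>/population<sub>g</sub> × 100 000 × w<sub>g</sub>),
  rate ratios, pooled two-proportion z test, Welch t test.
- **`synthetic_cohort`** — a generator of paired-compartment cohorts with
  full ground truth (CH prevalence 70%, CH VAF mean 22.5%, involvement VAFs
  ≈ 1%, TET2/DNMT3A-dominated early mutations, C>A-rich smoking-like late
  mutations with 17:5 coding-strand asymmetry, and a 14-fold CHN hazard for
  multiple-hit TET2 carriers), used by every downstream test.
- **`pipeline` / `chlymph` CLI** — one-command orchestration with a
  machine-readable report bundle; identical seeds reproduce every number.

## Worked example

`python examples/extract_signatures.py` simulates twenty 100-mutation
catalogs from a smoking-like and an APOBEC-like signature and re-extracts
them:

```
Sign.01: stability 0.99, truth CCS smoking-like 0.972 / APOBEC-like 0.204
Sign.02: stability 0.99, truth CCS smoking-like 0.001 / APOBEC-like 0.998
Sign.01 best reference match: RefSig.04 (CCS 0.972)
Sign.02 best reference match: RefSig.02 (CCS 0.998)
fraction of samples dominated (>=50% of mutations) per signature: [0.55 0.45]
```

Both generating processes come back at CCS ≈ 0.97–1.0 and match the correct
members of the packaged 30-signature reference set. The other scripts under
`examples/` walk through the partition (`partition_cohort.py`), the survival
biomarker (`biomarker_survival.py` — Cox HR 14.0, 95% CI 6.8–29.0 against a
simulated truth of 14), age-standardized rates (`incidence_rates.py`) and the
full pipeline (`full_pipeline.py`).

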