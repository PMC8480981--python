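"""One-command run of the whole analysis on a simulated cohort.

Produces the full report bundle (partitions, catalogs, signatures,
CHN/survival report, summary) under ./pipeline_out and prints the
headline numbers.
"""

from chlymph import run_pipeline

config = {
    "simulate": {"n_patients": 150},
    "signatures": {"k": 2, "n_bootstrap": 30},
    "biomarker": {"vaf_min": 0.15, "min_hits": 2},
}
report = run_pipeline(config, "pipeline_out", seed=7)

print(f"patients: {report['n_patients']}")
print(f"cases with CH: {report['ch_case_fraction']:.1%}")
spec = report["spectrum"]
print(f"late-mutation C>A fraction: {spec['late_fractions']['C>A']:.2f} "
      f"vs early {spec['early_fractions']['C>A']:.2f}")
print(f"late C>A strand counts (coding/template): "
      f"{spec['late_c_to_a_strand_counts']}, "
      f"fold excess {spec['late_c_to_a_fold_excess']:.2f}")
for group, sig in (report["signatures"] or {}).items():
    if sig:
        best = sig["matches"][0]
        print(f"{group}: top match {best['best_reference']} (CCS {best['ccs']:.2f}), "
              f"stability {sig['stability'][0]:.2f}")
print(f"CHN biomarker: {report['chn']['n_positive']} positive, "
      f"log-rank p = {report['chn']['logrank']['p_value']:.1e}")
print()
print("The bundle under pipeline_out/ holds the per-variant partition table,")
print("the 96-context catalogs, signature profiles/exposures and the survival")
print("report; rerunning with the same seed reproduces it bit for bit.")
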