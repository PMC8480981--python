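"""Multiple-hit TET2 biomarker and CHN-free survival.

Simulates a cohort in which carrying >= 2 pathogenic TET2 variants at
VAF >= 15% multiplies the hazard of a concomitant hematologic neoplasm
(CHN) by 14, then re-detects that risk with Kaplan-Meier / log-rank /
Cox, and shows the confusion-table oracle for printed accuracy metrics.
"""

from chlymph import (
    SimulationConfig,
    call_multihit_tet2,
    chn_free_analysis,
    diagnostic_metrics,
    reconstruct_confusion,
    simulate_cohort,
)
from chlymph.biomarker_survival import SurvivalRecord
from chlymph.clonal_partition import PartitionLabel
from chlymph.cohort_io import Compartment

cohort, truth = simulate_cohort(SimulationConfig(n_patients=300, seed=29))

calls = {}
for p in cohort.patients:
    ch_vars = [
        v for v in cohort.variants_of(p.patient_id, Compartment.BMPB)
        if truth.variant_labels.get((p.patient_id, *v.site))
        in (PartitionLabel.CH_shared, PartitionLabel.CH_bmpb_only)
    ]
    calls[p.patient_id] = call_multihit_tet2(ch_vars)

records = [
    SurvivalRecord(p.patient_id, p.followup_months, p.chn_event,
                   "high_burden" if calls[p.patient_id].positive else "low_or_absent")
    for p in cohort.patients
]
report = chn_free_analysis(records, calls)
print(f"biomarker-positive patients: {report['n_positive']}/{len(records)}")
print(f"log-rank p = {report['logrank']['p_value']:.2e}")
cox = report["cox"]
print(f"Cox HR = {cox.hr:.1f} (95% CI {cox.ci_low:.1f}-{cox.ci_high:.1f}); "
      f"true simulated HR = 14")
print(f"diagnostic metrics vs observed CHN: {report['metrics']}")
print()

(table,) = reconstruct_confusion(47, 72.7, 97.2)
print(f"unique 47-patient table with sens 72.7% / spec 97.2%: "
      f"tp={table.tp} fp={table.fp} fn={table.fn} tn={table.tn}")
print(f"its PPV/NPV: {diagnostic_metrics(table)['ppv']} / "
      f"{diagnostic_metrics(table)['npv']} %")
print()
print("A HR near 14 with a tiny log-rank p shows the survival machinery")
print("recovers the risk the biomarker was simulated to confer.")
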