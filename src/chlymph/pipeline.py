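"""End-to-end orchestration: ingest/simulate -> partition -> catalogs ->
signatures -> biomarker/survival -> epidemiology -> summary report.

The pipeline is configured by a single mapping (usually loaded from
YAML) with per-stage blocks; every threshold of the analysis (variant
filter cutoffs, partition tolerance, biomarker VAF/hit rules, dominance
threshold) is surfaced there.  All stochastic stages derive their
randomness from the single top-level seed, so a re-run with the same
config reproduces every numeric output exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import cohort_io, clonal_partition, mutation_catalog, signature_inference
from . import biomarker_survival, epi_stats, synthetic_cohort
from .cohort_io import Compartment, Cohort
from .clonal_partition import PartitionLabel

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfigError", "run_pipeline"]

_EARLY = (PartitionLabel.CH_shared, PartitionLabel.CH_bmpb_only)
_LATE = (PartitionLabel.late_ln_only, PartitionLabel.involvement)


class PipelineConfigError(ValueError):
    """Raised when the pipeline configuration is incomplete or invalid."""


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    if isinstance(obj, PartitionLabel):
        return obj.value
    return obj


def _load_cohort(config: Mapping, seed: int | None) -> tuple[Cohort, Any]:
    if "simulate" in config:
        if seed is None:
            raise PipelineConfigError("a seed is required for simulation")
        sim_kwargs = dict(config["simulate"] or {})
        sim_kwargs.setdefault("seed", seed)
        sim = synthetic_cohort.SimulationConfig(**sim_kwargs)
        return synthetic_cohort.simulate_cohort(sim)
    inputs = config.get("inputs")
    if not inputs or "variants" not in inputs or "clinical" not in inputs:
        raise PipelineConfigError(
            "config must provide a 'simulate' block or 'inputs' with "
            "'variants' and 'clinical' paths"
        )
    cohort = Cohort(
        patients=cohort_io.read_clinical_table(inputs["clinical"]),
        variants=cohort_io.read_variant_table(inputs["variants"]),
    )
    return cohort, None


def partition_cohort(
    cohort: Cohort, tolerance: float = 0.5
) -> dict[str, list[clonal_partition.PartitionedVariant]]:
    """Per-patient tumor-burden estimation and variant partitioning."""
    partitions = {}
    for patient in cohort.patients:
        ln = cohort.variants_of(patient.patient_id, Compartment.LN)
        bm = cohort.variants_of(patient.patient_id, Compartment.BMPB)
        tb = clonal_partition.estimate_tumor_burden(patient, bm)
        partitions[patient.patient_id] = clonal_partition.partition_variants(
            ln, bm, tb, tolerance=tolerance
        )
    return partitions


def partitions_to_frame(partitions) -> pd.DataFrame:
    rows = []
    for pid, pvs in partitions.items():
        for pv in pvs:
            rows.append(
                {
                    "patient_id": pid,
                    "gene": pv.variant.gene,
                    "chrom": pv.variant.chrom,
                    "pos": pv.variant.pos,
                    "ref": pv.variant.ref,
                    "alt": pv.variant.alt,
                    "label": pv.label.value,
                    "vaf_ln": pv.vaf_ln,
                    "vaf_bmpb": pv.vaf_bmpb,
                }
            )
    return pd.DataFrame(rows)


def _group_variants(partitions, labels, use_bmpb_vaf: bool = False):
    out = []
    for pvs in partitions.values():
        for pv in pvs:
            if pv.label not in labels:
                continue
            v = pv.variant
            if use_bmpb_vaf and pv.vaf_bmpb is not None:
                v = dataclasses.replace(
                    v, compartment=Compartment.BMPB, vaf=pv.vaf_bmpb
                )
            out.append(v)
    return out


def run_pipeline(
    config: Mapping, out_dir: str | Path, seed: int | None = None
) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns the summary report as a dict (also written as
    ``summary.json``).  See the module docstring for the config layout.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = seed if seed is not None else config.get("seed")

    cohort, truth = _load_cohort(config, seed)
    logger.info("cohort: %d patients, %d variant rows", len(cohort.patients),
                len(cohort.variants))

    filt = config.get("filter") or {}
    if filt.get("apply", False):
        cohort = Cohort(
            patients=cohort.patients,
            variants=cohort_io.apply_post_filters(
                cohort.variants,
                vaf_min=filt.get("vaf_min", 0.05),
                popfreq_max=filt.get("popfreq_max", 0.0001),
                strand_balance_min=filt.get("strand_balance_min", 0.2),
            ),
        )

    # ---- partition -----------------------------------------------------
    tolerance = (config.get("partition") or {}).get("tolerance", 0.5)
    partitions = partition_cohort(cohort, tolerance=tolerance)
    partitions_to_frame(partitions).to_csv(out / "partitions.tsv", sep="\t", index=False)
    summary = clonal_partition.summarize_partition(partitions)

    # ---- catalogs and spectrum stats ------------------------------------
    early_vars = _group_variants(partitions, _EARLY, use_bmpb_vaf=True)
    late_vars = _group_variants(partitions, _LATE)
    early_cat = mutation_catalog.build_catalog(early_vars, stranded=True)
    late_cat = mutation_catalog.build_catalog(late_vars, stranded=True)
    mutation_catalog.write_catalog(early_cat, out / "catalog_early.tsv")
    mutation_catalog.write_catalog(late_cat, out / "catalog_late.tsv")

    pooled_early, per_early = mutation_catalog.substitution_fractions(early_cat)
    pooled_late, per_late = mutation_catalog.substitution_fractions(late_cat)
    titv_early = mutation_catalog.titv_summary(per_early) if len(per_early) else None
    titv_late = mutation_catalog.titv_summary(per_late) if len(per_late) else None
    ca_compare = None
    if len(per_early) >= 2 and len(per_late) >= 2:
        ca_compare = mutation_catalog.compare_class_between_groups(
            per_late["C>A"].to_numpy(), per_early["C>A"].to_numpy()
        )
    fwd, rev = mutation_catalog.stranded_class_counts(late_cat, "C>A")
    fold = mutation_catalog.strand_fold_excess(fwd, rev) if rev > 0 else None

    # ---- signatures ------------------------------------------------------
    sig_cfg = config.get("signatures") or {}
    k = sig_cfg.get("k", 2)
    n_bootstrap = sig_cfg.get("n_bootstrap", 100)
    if sig_cfg.get("ref"):
        refset = cohort_io.read_reference_signatures(sig_cfg["ref"])
    else:
        refset = synthetic_cohort.make_reference_fixture(seed=0)
    sig_report = {}
    for name, cat in (("CH_Sign", early_cat), ("LM_Sign", late_cat)):
        keep = cat.totals > 0
        if keep.sum() < max(k, 2):
            sig_report[name] = None
            continue
        sub = mutation_catalog.TrinucleotideCatalog(
            [s for s, m in zip(cat.sample_ids, keep) if m], cat.counts[keep]
        )
        if seed is None:
            raise PipelineConfigError("a seed is required for signature extraction")
        denovo, expo = signature_inference.extract_signatures(
            sub, k=k, n_bootstrap=n_bootstrap, seed=seed, name_prefix=name
        )
        matches = signature_inference.match_to_reference(denovo, refset)
        _, active_frac = signature_inference.call_dominance(
            expo, threshold=config.get("dominance_threshold", 0.5)
        )
        pd.DataFrame(
            denovo.profiles.T,
            index=list(mutation_catalog.CONTEXTS_96),
            columns=denovo.names,
        ).to_csv(out / f"signatures_{name}.tsv", sep="\t")
        pd.DataFrame(expo.values, index=expo.sample_ids, columns=denovo.names).to_csv(
            out / f"exposures_{name}.tsv", sep="\t"
        )
        sig_report[name] = {
            "names": denovo.names,
            "stability": denovo.stability.tolist(),
            "matches": [
                {"denovo": m.denovo_name, "best_reference": m.best_reference_name,
                 "ccs": m.ccs}
                for m in matches
            ],
            "active_sample_fraction": active_frac.tolist(),
        }

    # ---- biomarker + survival -------------------------------------------
    bio_cfg = config.get("biomarker") or {}
    calls = {}
    by_patient: dict[str, list] = {p.patient_id: [] for p in cohort.patients}
    for pvs in partitions.values():
        for pv in pvs:
            if pv.label in _EARLY:
                v = dataclasses.replace(
                    pv.variant, compartment=Compartment.BMPB, vaf=pv.vaf_bmpb
                )
                by_patient[v.patient_id].append(v)
    for pid, ch_vars in by_patient.items():
        call = biomarker_survival.call_multihit_tet2(
            ch_vars,
            vaf_min=bio_cfg.get("vaf_min", 0.15),
            min_hits=bio_cfg.get("min_hits", 2),
        )
        calls[pid] = dataclasses.replace(call, patient_id=pid)
    records = [
        biomarker_survival.SurvivalRecord(
            patient_id=p.patient_id,
            time_months=p.followup_months,
            event=p.chn_event,
            group="high_burden" if calls[p.patient_id].positive else "low_or_absent",
        )
        for p in cohort.patients
    ]
    chn_report = biomarker_survival.chn_free_analysis(records, calls)
    chn_json = {
        "n_positive": chn_report["n_positive"],
        "n_negative": chn_report["n_negative"],
        "confusion": _jsonify(chn_report["confusion"]),
        "metrics": chn_report["metrics"],
        "logrank": chn_report["logrank"],
        "cox": _jsonify(chn_report["cox"]) if chn_report["cox"] else None,
    }
    (out / "chn_report.json").write_text(json.dumps(chn_json, indent=2))

    # ---- epidemiology ----------------------------------------------------
    rates = None
    epi_cfg = config.get("epi") or {}
    if epi_cfg.get("cohort_strata") and epi_cfg.get("control_strata"):
        r_cohort = epi_stats.age_adjusted_rate(
            epi_stats.read_strata(epi_cfg["cohort_strata"])
        )
        r_control = epi_stats.age_adjusted_rate(
            epi_stats.read_strata(epi_cfg["control_strata"])
        )
        rates = {
            "cohort_rate_per_100k": r_cohort.rate_per_100k,
            "control_rate_per_100k": r_control.rate_per_100k,
            "rate_ratio": epi_stats.rate_ratio(
                r_cohort.rate_per_100k, r_control.rate_per_100k
            ),
        }
        (out / "rates.json").write_text(json.dumps(rates, indent=2))

    report = {
        "seed": seed,
        "n_patients": len(cohort.patients),
        "partition_summary": _jsonify(summary),
        "ch_case_fraction": summary.n_cases_with_ch / summary.n_cases_total,
        "spectrum": {
            "early_fractions": pooled_early.to_dict(),
            "late_fractions": pooled_late.to_dict(),
            "titv_early": titv_early,
            "titv_late": titv_late,
            "c_to_a_late_vs_early": ca_compare,
            "late_c_to_a_strand_counts": {"forward": fwd, "reverse": rev},
            "late_c_to_a_fold_excess": fold,
        },
        "signatures": sig_report,
        "chn": chn_json,
        "rates": rates,
    }
    (out / "summary.json").write_text(json.dumps(_jsonify(report), indent=2))
    return report
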