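"""Cohort data model and I/O.

Variant tables are TSV (one row per variant per compartment), clinical
tables are CSV, and reference mutational-signature matrices follow the
COSMIC v2 layout (96 trinucleotide-context rows by signature columns).
Also houses the post-alignment variant filter applied to raw calls:
minimum VAF 5%, maximum population frequency 0.01%, minimum strand
balance 1:5 (minor/major read ratio 0.2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .contexts import CONTEXTS_96, canonical_context_index

logger = logging.getLogger(__name__)

__all__ = [
    "Compartment",
    "VariantClass",
    "Variant",
    "PatientRecord",
    "Cohort",
    "ReferenceSignatureSet",
    "read_variant_table",
    "write_variant_table",
    "read_clinical_table",
    "write_clinical_table",
    "read_reference_signatures",
    "write_reference_signatures",
    "read_vcf_variants",
    "apply_post_filters",
]


class Compartment(str, Enum):
    """Tissue compartment a variant was called in."""

    LN = "LN"  # lymph-node tumor
    BMPB = "BMPB"  # bone marrow / peripheral blood


class VariantClass(str, Enum):
    missense = "missense"
    nonsense = "nonsense"
    frameshift_ins = "frameshift_ins"
    frameshift_del = "frameshift_del"
    inframe_ins = "inframe_ins"
    inframe_del = "inframe_del"
    splice = "splice"
    other = "other"


_VALID_TIERS = {1, 2, 3, 4, None}
_BASES = set("ACGT")


@dataclass(frozen=True)
class Variant:
    """One called alteration in one compartment of one patient.

    Coordinates are 1-based and fully closed; ``context3`` is the
    reference-strand trinucleotide centered on the mutated base.
    ``coding_strand_ref`` says whether the reference strand is the coding
    (untranscribed) strand at this site, which is what transcriptional
    strand-bias statistics need.  ``tier`` is the pathogenicity tier as
    annotated upstream (1/2 = pathogenic, ``None`` = unclassified).
    """

    patient_id: str
    compartment: Compartment
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vaf: float
    context3: str | None = None
    coding_strand_ref: str = "unknown"  # {"same", "opposite", "unknown"}
    vclass: VariantClass = VariantClass.other
    tier: int | None = None
    popfreq: float | None = None
    strand_balance: float | None = None
    rescued: bool = False
    n_damaging_predictions: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf must be in [0,1], got {self.vaf!r}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.tier not in _VALID_TIERS:
            raise ValueError(f"tier must be 1-4 or None, got {self.tier!r}")
        if self.coding_strand_ref not in ("same", "opposite", "unknown"):
            raise ValueError(f"bad coding_strand_ref {self.coding_strand_ref!r}")
        if self.is_snv and self.context3 is not None:
            if len(self.context3) != 3 or self.context3[1] != self.ref:
                raise ValueError(
                    f"context3 {self.context3!r} inconsistent with ref {self.ref!r}"
                )

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _BASES
            and self.alt in _BASES
        )

    @property
    def site(self) -> tuple[str, int, str, str]:
        """Matching key across compartments: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    diagnosis: str = "AITL"  # {"AITL", "PTCL_NOS"}
    age_at_dx: float | None = None
    smoking: str = "unknown"  # {"smoker", "nonsmoker", "unknown"}
    flow_pct: float | None = None
    tcrg: str | None = None  # {"positive", "negative", None}
    morphology_pct: float | None = None
    chn_event: int = 0
    followup_months: float = 0.0

    def __post_init__(self) -> None:
        if self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")
        if self.chn_event not in (0, 1):
            raise ValueError("chn_event must be 0 or 1")
        if self.flow_pct is not None and not 0 <= self.flow_pct <= 100:
            raise ValueError(f"flow_pct outside [0,100]: {self.flow_pct}")


@dataclass
class Cohort:
    patients: list[PatientRecord] = field(default_factory=list)
    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = {p.patient_id for p in self.patients}
        orphans = {v.patient_id for v in self.variants} - ids
        if orphans:
            raise ValueError(f"variants reference unknown patients: {sorted(orphans)}")

    def variants_of(
        self, patient_id: str, compartment: Compartment | None = None
    ) -> list[Variant]:
        out = [v for v in self.variants if v.patient_id == patient_id]
        if compartment is not None:
            out = [v for v in out if v.compartment == compartment]
        return out


@dataclass
class ReferenceSignatureSet:
    """A set of reference mutational signatures (rows) over the 96 contexts."""

    names: list[str]
    profiles: np.ndarray  # (n_signatures, 96), rows sum to 1

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[1] != 96:
            raise ValueError(f"profiles must be (n, 96), got {self.profiles.shape}")
        if len(self.names) != self.profiles.shape[0]:
            raise ValueError("names / profiles length mismatch")
        if (self.profiles < 0).any():
            raise ValueError("signature profiles must be non-negative")
        sums = self.profiles.sum(axis=1)
        if (sums <= 0).any():
            raise ValueError("signature profile with zero mass")
        self.profiles = self.profiles / sums[:, None]


# ---------------------------------------------------------------------------
# variant / clinical tables

_MANDATORY_VARIANT_COLS = [
    "patient_id",
    "compartment",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vaf",
]
_OPTIONAL_VARIANT_COLS = [
    "context3",
    "coding_strand_ref",
    "vclass",
    "tier",
    "popfreq",
    "strand_balance",
    "rescued",
    "n_damaging_predictions",
]


def _opt_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x in ("", "NA"):
        return None
    return float(x)


def _opt_int(x) -> int | None:
    f = _opt_float(x)
    return None if f is None else int(f)


def read_variant_table(path: str | Path) -> list[Variant]:
    """Read a TSV variant table into a list of :class:`Variant`.

    Unknown variant-class strings map to ``other`` with a logged warning;
    a missing mandatory column or an out-of-range VAF raises.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "patient_id": str})
    missing = [c for c in _MANDATORY_VARIANT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table {path} missing columns: {missing}")
    variants: list[Variant] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        vclass_raw = str(d.get("vclass", "other") or "other")
        try:
            vclass = VariantClass(vclass_raw)
        except ValueError:
            logger.warning("unknown variant class %r mapped to 'other'", vclass_raw)
            vclass = VariantClass.other
        ctx = d.get("context3")
        if isinstance(ctx, float) and math.isnan(ctx):
            ctx = None
        csr = d.get("coding_strand_ref", "unknown")
        if csr is None or (isinstance(csr, float) and math.isnan(csr)):
            csr = "unknown"
        variants.append(
            Variant(
                patient_id=str(d["patient_id"]),
                compartment=Compartment(d["compartment"]),
                gene=str(d["gene"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                vaf=float(d["vaf"]),
                context3=ctx,
                coding_strand_ref=str(csr),
                vclass=vclass,
                tier=_opt_int(d.get("tier")),
                popfreq=_opt_float(d.get("popfreq")),
                strand_balance=_opt_float(d.get("strand_balance")),
                rescued=bool(d.get("rescued", False)),
                n_damaging_predictions=_opt_int(d.get("n_damaging_predictions")),
            )
        )
    return variants


def write_variant_table(variants: Iterable[Variant], path: str | Path) -> None:
    rows = []
    for v in variants:
        rows.append(
            {
                "patient_id": v.patient_id,
                "compartment": v.compartment.value,
                "gene": v.gene,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "vaf": v.vaf,
                "context3": v.context3,
                "coding_strand_ref": v.coding_strand_ref,
                "vclass": v.vclass.value,
                "tier": v.tier,
                "popfreq": v.popfreq,
                "strand_balance": v.strand_balance,
                "rescued": v.rescued,
                "n_damaging_predictions": v.n_damaging_predictions,
            }
        )
    cols = _MANDATORY_VARIANT_COLS + _OPTIONAL_VARIANT_COLS
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        tcrg = d.get("tcrg")
        if tcrg is None or (isinstance(tcrg, float) and math.isnan(tcrg)) or tcrg == "NA":
            tcrg = None
        records.append(
            PatientRecord(
                patient_id=str(d["patient_id"]),
                diagnosis=str(d.get("diagnosis", "AITL")),
                age_at_dx=_opt_float(d.get("age_at_dx")),
                smoking=str(d.get("smoking", "unknown") or "unknown"),
                flow_pct=_opt_float(d.get("flow_pct")),
                tcrg=tcrg,
                morphology_pct=_opt_float(d.get("morphology_pct")),
                chn_event=int(d["chn_event"]),
                followup_months=float(d["followup_months"]),
            )
        )
    return records


def write_clinical_table(patients: Iterable[PatientRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "diagnosis": p.diagnosis,
                "age_at_dx": p.age_at_dx,
                "smoking": p.smoking,
                "flow_pct": p.flow_pct,
                "tcrg": p.tcrg,
                "morphology_pct": p.morphology_pct,
                "chn_event": p.chn_event,
                "followup_months": p.followup_months,
            }
            for p in patients
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# post-alignment filter

def apply_post_filters(
    variants: Sequence[Variant],
    vaf_min: float = 0.05,
    popfreq_max: float = 0.0001,
    strand_balance_min: float = 0.2,
    min_damaging_predictions: int | None = None,
) -> list[Variant]:
    """Post-alignment variant filter.

    Keeps variants with ``vaf >= vaf_min`` (5% default), population
    frequency missing or ``<= popfreq_max`` (0.01% default), and strand
    balance missing or ``>= strand_balance_min`` (minor/major read ratio
    0.2, i.e. 1:5).  Variants flagged ``rescued`` (genotyped across
    compartments below the calling cutoff) bypass the VAF floor.  The
    damaging-prediction count filter is applied only when a threshold is
    given and the variant carries the annotation.  Order is preserved.
    """
    if not 0 <= vaf_min <= 1 or not 0 <= popfreq_max <= 1:
        raise ValueError("thresholds must be in [0,1]")
    out = []
    for v in variants:
        if v.vaf < vaf_min and not v.rescued:
            continue
        if v.popfreq is not None and v.popfreq > popfreq_max:
            continue
        if v.strand_balance is not None and v.strand_balance < strand_balance_min:
            continue
        if (
            min_damaging_predictions is not None
            and v.n_damaging_predictions is not None
            and v.n_damaging_predictions <= min_damaging_predictions
        ):
            continue
        out.append(v)
    return out


# ---------------------------------------------------------------------------
# reference signatures

def read_reference_signatures(path: str | Path) -> ReferenceSignatureSet:
    """Read a COSMIC v2-style signature matrix (TSV).

    Accepts either orientation — 96 context rows by signature columns, or
    the transpose — auto-detected by which axis carries 96 labels that
    parse as trinucleotide substitution contexts.  Profiles are
    renormalized to row sums of 1 and contexts put in the canonical
    lexicographic order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    idx_ctx = _all_contexts(df.index)
    col_ctx = _all_contexts(df.columns)
    if idx_ctx and len(df.index) == 96:
        context_labels, names = list(df.index), list(df.columns)
        mat = df.to_numpy(dtype=float).T  # -> signatures x contexts
    elif col_ctx and len(df.columns) == 96:
        context_labels, names = list(df.columns), list(df.index)
        mat = df.to_numpy(dtype=float)
    else:
        raise ValueError(
            f"{path}: could not identify a 96-context axis "
            f"(shape {df.shape})"
        )
    if (mat < 0).any():
        raise ValueError(f"{path}: negative signature entry")
    order = np.array([canonical_context_index(c) for c in context_labels])
    mat_canon = np.empty_like(mat)
    mat_canon[:, order] = mat
    return ReferenceSignatureSet(names=[str(n) for n in names], profiles=mat_canon)


def write_reference_signatures(refset: ReferenceSignatureSet, path: str | Path) -> None:
    """Write in COSMIC v2 layout: 96 context rows x signature columns."""
    df = pd.DataFrame(refset.profiles.T, index=CONTEXTS_96, columns=refset.names)
    df.index.name = "context"
    df.to_csv(path, sep="\t")


def _all_contexts(labels) -> bool:
    try:
        for lab in labels:
            canonical_context_index(str(lab))
    except (ValueError, KeyError):
        return False
    return True


# ---------------------------------------------------------------------------
# optional minimal VCF reader

def read_vcf_variants(
    path: str | Path,
    patient_id: str,
    compartment: Compartment,
    gene_info_key: str = "GENE",
) -> list[Variant]:
    """Minimal single-sample VCF reader mapping records to :class:`Variant`.

    Uses ``INFO/AF`` for the VAF and (when present) an INFO key for the
    gene symbol.  Only a convenience entry point; the TSV table is the
    primary interchange format.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required for VCF input") from exc
    variants = []
    for rec in VCF(str(path)):
        af = rec.INFO.get("AF")
        if af is None:
            continue
        if isinstance(af, tuple):
            af = af[0]
        gene = rec.INFO.get(gene_info_key) or "NA"
        for alt in rec.ALT:
            variants.append(
                Variant(
                    patient_id=patient_id,
                    compartment=compartment,
                    gene=str(gene),
                    chrom=str(rec.CHROM),
                    pos=int(rec.POS),
                    ref=str(rec.REF),
                    alt=str(alt),
                    vaf=float(af),
                )
            )
    return variants
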