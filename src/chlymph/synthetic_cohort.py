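"""Synthetic paired-compartment cohort generator with ground truth.

Emulates the statistical structure the analysis assumes: ~70% of
patients carry clonal hematopoiesis (CH) dominated by TET2/DNMT3A with
BM/PB VAFs around a mean of 22.5%; lymphoma involvement of the marrow
propagates lymph-node driver variants into BM/PB at VAFs near 1%; late
lymphoma-specific mutations draw their trinucleotide contexts from a
C>A-rich smoking-like signature with coding-strand asymmetry (17:5)
mixed with a C>T profile; and the hazard of a concomitant hematologic
neoplasm (CHN) is multiplied by a configurable factor (default 14) in
patients whose CH carries >= 2 pathogenic TET2 variants at VAF >= 15%.

Every generated variant, biomarker status and signature attribution is
recorded in a :class:`GroundTruth` object so downstream estimators can
be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import (
    Cohort,
    Compartment,
    PatientRecord,
    ReferenceSignatureSet,
    Variant,
    VariantClass,
)
from .contexts import CONTEXTS_96, revcomp
from .clonal_partition import PartitionLabel
from .mutation_catalog import TrinucleotideCatalog

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_catalogs",
    "simulate_survival_groups",
    "draw_signature_activities",
    "make_reference_fixture",
    "apobec_like_profile",
    "smoking_like_profile",
    "cpc_ct_profile",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# pseudo-genomic anchors so generated sites are well-formed and unique
_GENE_LOCI = {
    "TET2": ("4", 106_155_000),
    "DNMT3A": ("2", 25_457_000),
    "ASXL1": ("20", 31_015_000),
    "SRSF2": ("17", 74_732_000),
    "CBL": ("11", 119_103_000),
    "RHOA": ("3", 49_405_000),
    "IDH2": ("15", 90_630_000),
    "PLCG1": ("20", 39_765_000),
    "TP53": ("17", 7_574_000),
    "VAV1": ("19", 6_772_000),
    "CD28": ("2", 204_594_000),
    "FYN": ("6", 111_981_000),
    "STAT3": ("17", 40_465_000),
}

RHOA_HOTSPOT = ("3", 49_412_973, "G", "T")  # the G17V-style marker site


def _normalized(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    return {g: w / total for g, w in weights.items()}


def _profile_from_peaks(
    peaks: dict[str, float],
    background: float,
    background_classes: tuple[str, ...] | None = None,
) -> np.ndarray:
    """96-profile with named context peaks plus a low background.

    Real signatures concentrate their mass within their characteristic
    substitution classes, so the background is spread over the bins of
    ``background_classes`` (all 96 bins when None).
    """
    idx = {lab: i for i, lab in enumerate(CONTEXTS_96)}
    if background_classes is None:
        bg_bins = np.arange(96)
    else:
        bg_bins = np.array(
            [i for i, lab in enumerate(CONTEXTS_96) if lab[2:5] in background_classes]
        )
    p = np.zeros(96)
    p[bg_bins] = background / len(bg_bins)
    for lab, w in peaks.items():
        p[idx[lab]] += w
    return p / p.sum()


def apobec_like_profile() -> np.ndarray:
    """APOBEC-deamination-like profile: C>T and C>G peaks at TpCpA/TpCpT."""
    return _profile_from_peaks(
        {
            "T[C>T]A": 0.34,
            "T[C>T]T": 0.12,
            "T[C>G]A": 0.22,
            "T[C>G]T": 0.10,
            "C[C>T]A": 0.04,
            "G[C>G]G": 0.03,
        },
        background=0.15,
        background_classes=("C>T", "C>G"),
    )


def smoking_like_profile() -> np.ndarray:
    """Tobacco-carcinogen-like profile: C>A concentrated at NpCpC motifs."""
    return _profile_from_peaks(
        {
            "T[C>A]C": 0.24,
            "C[C>A]C": 0.16,
            "A[C>A]C": 0.12,
            "G[C>A]C": 0.10,
            "T[C>A]A": 0.08,
            "C[C>A]A": 0.06,
            "T[C>A]T": 0.06,
        },
        background=0.18,
        background_classes=("C>A",),
    )


def cpc_ct_profile() -> np.ndarray:
    """C>T-at-CpCpC profile, the second late-mutation component."""
    return _profile_from_peaks(
        {
            "C[C>T]C": 0.30,
            "A[C>T]C": 0.12,
            "G[C>T]C": 0.10,
            "C[C>T]T": 0.10,
            "T[C>T]C": 0.08,
        },
        background=0.30,
        background_classes=("C>T",),
    )


def draw_signature_activities(
    n_samples: int,
    k: int,
    total_mutations: float,
    rng: np.random.Generator,
    concentration: float = 0.5,
) -> np.ndarray:
    """Per-sample signature exposure draws (counts summing to
    ``total_mutations``).

    Shares follow a sparse Dirichlet (concentration 0.5 per signature),
    reflecting the skewed activity patterns seen in tumor samples where
    one mutational process usually dominates a given sample.
    """
    shares = rng.dirichlet(np.full(k, concentration), size=n_samples)
    return shares * total_mutations


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the cohort structure the analysis targets: CH in
    70% of patients with BM/PB VAF mean 22.5%, involvement VAFs ~1%,
    TET2-dominated early mutations, smoking-like late mutations with
    ~17:5 coding-strand asymmetry, and a 14-fold CHN hazard ratio for
    multiple-hit TET2 carriers.
    """

    n_patients: int = 200
    p_ch: float = 0.70
    p_bmpb_involved: float = 0.63
    p_ch_shared: float = 0.84  # CH variant also seen in the lymphoma
    ch_vaf_mean: float = 0.225
    ch_vaf_shape: float = 4.0  # Beta concentration (a+b)
    inv_vaf_mean: float = 0.01
    tb_range: tuple[float, float] = (0.01, 0.10)
    n_ch_mut_mean: float = 1.6
    n_late_mut_mean: float = 2.4
    ln_vaf_mean: float = 0.25
    ln_vaf_shape: float = 8.0
    vaf_noise_sigma: float = 0.2  # multiplicative log-normal sd
    ch_gene_weights: dict[str, float] = field(
        default_factory=lambda: {
            "TET2": 0.50,
            "DNMT3A": 0.25,
            "ASXL1": 0.10,
            "SRSF2": 0.05,
            "TP53": 0.05,
            "CBL": 0.05,
        }
    )
    late_gene_weights: dict[str, float] = field(
        default_factory=lambda: {
            "RHOA": 0.30,
            "TET2": 0.22,
            "IDH2": 0.15,
            "PLCG1": 0.06,
            "TP53": 0.06,
            "VAV1": 0.06,
            "CD28": 0.05,
            "FYN": 0.05,
            "STAT3": 0.05,
        }
    )
    p_tet2_pathogenic: float = 0.9  # tier 1/2 assignment for CH TET2 variants
    late_mix_weights: tuple[float, float] = (0.6, 0.4)  # smoking-like, C>T
    smoking_forward_prob: float = 17.0 / 22.0  # coding-strand asymmetry
    p_smoker: float = 0.27
    biomarker_hr: float = 14.0
    baseline_chn_hazard: float = 0.0007  # per month
    censor_time_months: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_ch", "p_bmpb_involved", "p_ch_shared", "ch_vaf_mean",
                     "inv_vaf_mean", "p_tet2_pathogenic", "p_smoker"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.biomarker_hr <= 0:
            raise ValueError("biomarker_hr must be > 0")


@dataclass
class GroundTruth:
    """True labels behind a simulated cohort.

    ``variant_labels`` keys are (patient_id, chrom, pos, ref, alt); the
    late-mutation ``signature_counts`` tally, per patient, how many late
    LN mutations each generating component produced.
    """

    variant_labels: dict[tuple, PartitionLabel] = field(default_factory=dict)
    biomarker_positive: dict[str, bool] = field(default_factory=dict)
    tumor_burden: dict[str, float] = field(default_factory=dict)
    signature_counts: dict[str, dict[str, int]] = field(default_factory=dict)


def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    return mean * conc, (1.0 - mean) * conc


def _draw_context(rng: np.random.Generator, profile: np.ndarray) -> tuple[str, str, str]:
    """Draw (ref, alt, context3) from a 96-profile; the representation
    strand (pyrimidine vs purine reference) is randomized to exercise
    downstream complement-collapsing."""
    label = CONTEXTS_96[rng.choice(96, p=profile)]
    five, ref, alt, three = label[0], label[2], label[4], label[6]
    ctx = five + ref + three
    if rng.random() < 0.5:  # present on the purine strand
        ctx = revcomp(ctx)
        ref, alt = _COMP[ref], _COMP[alt]
    return ref, alt, ctx


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a paired LN + BM/PB cohort with full ground truth."""
    rng = np.random.default_rng(config.seed)
    mean_tb = (config.tb_range[0] + config.tb_range[1]) / 2.0
    # involvement detection efficiency relative to the heterozygous tb/2
    # expectation, chosen so the cohort mean involvement VAF matches
    # inv_vaf_mean
    inv_factor = config.inv_vaf_mean / (mean_tb / 2.0)
    ch_a, ch_b = _beta_params(config.ch_vaf_mean, config.ch_vaf_shape)
    ln_a, ln_b = _beta_params(config.ln_vaf_mean, config.ln_vaf_shape)
    ch_profile = apobec_like_profile()
    late_components = {
        "smoking_like": (config.late_mix_weights[0], smoking_like_profile(),
                         config.smoking_forward_prob),
        "cpc_ct": (config.late_mix_weights[1], cpc_ct_profile(), 0.5),
    }
    comp_names = list(late_components)
    comp_w = np.array([late_components[c][0] for c in comp_names], dtype=float)
    comp_w /= comp_w.sum()

    ch_genes = list(config.ch_gene_weights)
    ch_gw = np.array(list(_normalized(config.ch_gene_weights).values()))
    late_genes = list(config.late_gene_weights)
    late_gw = np.array(list(_normalized(config.late_gene_weights).values()))

    patients: list[PatientRecord] = []
    variants: list[Variant] = []
    truth = GroundTruth()
    pos_counter: dict[str, int] = {g: 0 for g in _GENE_LOCI}

    def next_site(gene: str) -> tuple[str, int]:
        pos_counter[gene] += 1
        chrom, base = _GENE_LOCI[gene]
        return chrom, base + pos_counter[gene]

    def noisy(v: float) -> float:
        return float(min(v * rng.lognormal(0.0, config.vaf_noise_sigma), 0.99))

    for i in range(config.n_patients):
        pid = f"P{i + 1:04d}"
        truth.signature_counts[pid] = {c: 0 for c in comp_names}
        has_ch = rng.random() < config.p_ch
        # n_ch_mut_mean is the cohort-wide mean (CH variants per patient
        # across carriers and non-carriers); carriers get mean / p_ch
        ch_mut_mean_carrier = (
            config.n_ch_mut_mean / config.p_ch if config.p_ch > 0 else 0.0
        )
        involved = rng.random() < config.p_bmpb_involved
        tb = float(rng.uniform(*config.tb_range)) if involved else 0.0
        truth.tumor_burden[pid] = tb

        ln_rows: list[Variant] = []
        bm_rows: list[Variant] = []

        # --- early, CH-associated variants ------------------------------
        ch_records: list[Variant] = []
        if has_ch:
            n_ch = 1 + rng.poisson(max(ch_mut_mean_carrier - 1.0, 0.0))
            for _ in range(n_ch):
                gene = ch_genes[rng.choice(len(ch_genes), p=ch_gw)]
                chrom, pos = next_site(gene)
                ref, alt, ctx = _draw_context(rng, ch_profile)
                vaf_bm = float(rng.beta(ch_a, ch_b))
                vaf_bm = min(max(vaf_bm, 0.002), 0.6)
                if gene == "TET2":
                    vclass = VariantClass(
                        rng.choice(["nonsense", "frameshift_del", "frameshift_ins",
                                    "missense"], p=[0.4, 0.25, 0.15, 0.2])
                    )
                    tier = int(rng.choice([1, 2])) if rng.random() < config.p_tet2_pathogenic else 3
                else:
                    vclass = VariantClass(rng.choice(["missense", "nonsense"], p=[0.7, 0.3]))
                    tier = int(rng.choice([2, 3]))
                if vclass in (VariantClass.missense, VariantClass.nonsense):
                    v_ref, v_alt = ref, alt
                else:
                    v_ref, v_alt = ref, ref + "A"  # simple insertion alleles
                    ctx = None
                shared = rng.random() < config.p_ch_shared
                csr = "same" if rng.random() < 0.5 else "opposite"
                common = dict(
                    patient_id=pid, gene=gene, chrom=chrom, pos=pos,
                    ref=v_ref, alt=v_alt,
                    context3=ctx if v_ref == ref and ctx is not None else None,
                    coding_strand_ref=csr, vclass=vclass, tier=tier,
                )
                bm_v = Variant(compartment=Compartment.BMPB, vaf=vaf_bm, **common)
                bm_rows.append(bm_v)
                ch_records.append(bm_v)
                key = (pid, chrom, pos, v_ref, v_alt)
                if shared:
                    ln_rows.append(
                        Variant(compartment=Compartment.LN, vaf=noisy(vaf_bm), **common)
                    )
                    truth.variant_labels[key] = PartitionLabel.CH_shared
                else:
                    truth.variant_labels[key] = PartitionLabel.CH_bmpb_only

        # --- late, lymphoma-specific variants ---------------------------
        n_late = 1 + rng.poisson(max(config.n_late_mut_mean - 1.0, 0.0))
        used_hotspot = False
        for _ in range(n_late):
            gene = late_genes[rng.choice(len(late_genes), p=late_gw)]
            comp_idx = int(rng.choice(len(comp_names), p=comp_w))
            comp = comp_names[comp_idx]
            _, profile, fwd_prob = late_components[comp]
            if gene == "RHOA" and not used_hotspot:
                used_hotspot = True
                chrom, pos, ref, alt = RHOA_HOTSPOT
                ctx = "AGA"  # center base = ref G; collapses to T[C>A]T
                comp = "smoking_like"  # hotspot is a C>A-class change
                fwd_prob = config.smoking_forward_prob
                pyr_on_ref = False
            else:
                chrom, pos = next_site(gene)
                ref, alt, ctx = _draw_context(rng, profile)
                pyr_on_ref = ref in "CT"
            truth.signature_counts[pid][comp] += 1
            # orient the coding strand so the pyrimidine lands on it with
            # the component's forward probability
            pyr_on_coding = rng.random() < fwd_prob
            csr = "same" if (pyr_on_coding == pyr_on_ref) else "opposite"
            vaf_ln = float(np.clip(rng.beta(ln_a, ln_b), 0.02, 0.9))
            common = dict(
                patient_id=pid, gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
                context3=ctx, coding_strand_ref=csr,
                vclass=VariantClass.missense, tier=2,
            )
            ln_rows.append(Variant(compartment=Compartment.LN, vaf=vaf_ln, **common))
            key = (pid, chrom, pos, ref, alt)
            if involved:
                vaf_inv = float(
                    min(tb / 2.0 * inv_factor * rng.lognormal(0.0, config.vaf_noise_sigma), 0.5)
                )
                if vaf_inv >= 0.001:
                    bm_rows.append(
                        Variant(
                            compartment=Compartment.BMPB, vaf=vaf_inv,
                            rescued=vaf_inv < 0.05, **common,
                        )
                    )
                    truth.variant_labels[key] = PartitionLabel.involvement
                else:
                    truth.variant_labels[key] = PartitionLabel.late_ln_only
            else:
                truth.variant_labels[key] = PartitionLabel.late_ln_only

        # --- biomarker status and CHN survival --------------------------
        qualifying = [
            v for v in ch_records
            if v.gene == "TET2" and v.tier in (1, 2) and v.vaf >= 0.15
        ]
        positive = len(qualifying) >= 2
        truth.biomarker_positive[pid] = positive
        hazard = config.baseline_chn_hazard * (config.biomarker_hr if positive else 1.0)
        t_event = float(rng.exponential(1.0 / hazard))
        if t_event < config.censor_time_months:
            chn_event, followup = 1, t_event
        else:
            chn_event, followup = 0, config.censor_time_months

        # --- clinical evidence of involvement ---------------------------
        flow_pct = tcrg = None
        if involved:
            if rng.random() < 0.7:
                flow_pct = tb * 100.0
                tcrg = "positive"
            else:
                tcrg = "positive"
        else:
            tcrg = "negative" if rng.random() < 0.9 else None

        patients.append(
            PatientRecord(
                patient_id=pid,
                diagnosis="AITL" if rng.random() < 0.9 else "PTCL_NOS",
                age_at_dx=float(np.clip(round(rng.normal(62, 11)), 33, 84)),
                smoking="smoker" if rng.random() < config.p_smoker else "nonsmoker",
                flow_pct=flow_pct,
                tcrg=tcrg,
                morphology_pct=None,
                chn_event=chn_event,
                followup_months=followup,
            )
        )
        variants.extend(ln_rows)
        variants.extend(bm_rows)

    return Cohort(patients=patients, variants=variants), truth


def simulate_survival_groups(
    n_per_group: int,
    hr: float,
    baseline_hazard: float = 0.01,
    censor_time: float = 60.0,
    seed: int = 0,
):
    """Two-group exponential survival data for estimator checks.

    Group "low_or_absent" has the baseline event hazard (per month);
    group "high_burden" has ``baseline_hazard * hr``.  Administrative
    censoring at ``censor_time``; the defaults give roughly 30% overall
    censoring at HR 14.  Returns a list of SurvivalRecord.
    """
    from .biomarker_survival import SurvivalRecord

    rng = np.random.default_rng(seed)
    records = []
    for group, rate in (
        ("low_or_absent", baseline_hazard),
        ("high_burden", baseline_hazard * hr),
    ):
        times = rng.exponential(1.0 / rate, size=n_per_group)
        for i, t in enumerate(times):
            event = int(t < censor_time)
            records.append(
                SurvivalRecord(
                    patient_id=f"{group}_{i}",
                    time_months=float(min(t, censor_time)),
                    event=event,
                    group=group,
                )
            )
    return records


def simulate_catalogs(
    profiles: np.ndarray, exposures: np.ndarray, seed: int = 0
) -> TrinucleotideCatalog:
    """Multinomial catalogs from signature profiles and exposure counts.

    Each sample draws ``sum(exposures[i])`` mutations from the
    exposure-weighted mixture of the profiles.
    """
    profiles = np.asarray(profiles, dtype=float)
    exposures = np.asarray(exposures, dtype=float)
    if (exposures < 0).any():
        raise ValueError("exposures must be non-negative")
    rng = np.random.default_rng(seed)
    n = exposures.shape[0]
    counts = np.zeros((n, 96), dtype=int)
    for i in range(n):
        total = exposures[i].sum()
        if total == 0:
            continue
        mix = exposures[i] @ profiles / total
        mix = mix / mix.sum()
        counts[i] = rng.multinomial(int(round(total)), mix)
    return TrinucleotideCatalog([f"S{i + 1:04d}" for i in range(n)], counts)


def make_reference_fixture(seed: int = 0) -> ReferenceSignatureSet:
    """Synthetic 30-signature reference set.

    Stand-in for a COSMIC-v2-style matrix: includes an APOBEC-like
    member (position 2) and a smoking-like member (position 4), with all
    distinct pairs below CCS 0.6.  Fully synthetic; not the published
    signature values.
    """
    rng = np.random.default_rng(seed)
    profiles = np.zeros((30, 96))
    profiles[1] = apobec_like_profile()
    profiles[3] = smoking_like_profile()

    def random_profile() -> np.ndarray:
        p = np.full(96, 0.25 / 96.0)
        peaks = rng.choice(96, size=6, replace=False)
        p[peaks] += rng.dirichlet(np.ones(6) * 0.8) * 0.75
        return p / p.sum()

    def max_ccs(idx: int) -> float:
        others = [j for j in range(30) if j != idx and profiles[j].sum() > 0]
        a = profiles[idx] / np.linalg.norm(profiles[idx])
        return max(
            float(a @ (profiles[j] / np.linalg.norm(profiles[j]))) for j in others
        )

    for idx in range(30):
        if idx in (1, 3):
            continue
        for _ in range(200):
            profiles[idx] = random_profile()
            if max_ccs(idx) < 0.6:
                break
        else:  # pragma: no cover - extremely unlikely
            raise RuntimeError("could not place a sufficiently distinct signature")
    names = [f"RefSig.{i + 1:02d}" for i in range(30)]
    return ReferenceSignatureSet(names=names, profiles=profiles)
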