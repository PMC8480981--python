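import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chlymph.cohort_io import Compartment, Variant
from chlymph.contexts import CONTEXTS_96, complement
from chlymph.mutation_catalog import (
    build_catalog,
    classify_substitution,
    compare_class_between_groups,
    is_transition,
    strand_fold_excess,
    stranded_class_counts,
    substitution_fractions,
    titv_summary,
)
from chlymph.synthetic_cohort import smoking_like_profile


def _snv(ref, alt, ctx, pos=100, pid="P1", csr="unknown"):
    return Variant(
        patient_id=pid, compartment=Compartment.LN, gene="G", chrom="1",
        pos=pos, ref=ref, alt=alt, vaf=0.2, context3=ctx,
        coding_strand_ref=csr,
    )


class TestClassify:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [("C", "T", "C>T"), ("G", "T", "C>A"), ("A", "G", "T>C"),
         ("T", "G", "T>G"), ("G", "A", "C>T")],
    )
    def test_pyrimidine_collapse(self, ref, alt, expected):
        assert classify_substitution(ref, alt) == expected

    @pytest.mark.parametrize("ref, alt", [("C", "C"), ("C", "N"), ("CA", "T")])
    def test_non_snv_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            classify_substitution(ref, alt)

    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"))
    def test_strand_involution(self, ref, alt):
        if ref == alt:
            return
        assert classify_substitution(ref, alt) == classify_substitution(
            complement(ref), complement(alt)
        )

    @pytest.mark.parametrize(
        "cls, expected",
        [("C>T", True), ("T>C", True), ("C>A", False), ("C>G", False),
         ("T>A", False), ("T>G", False)],
    )
    def test_transition_classes(self, cls, expected):
        assert is_transition(cls) is expected


class TestCatalog:
    def test_purine_reference_is_reverse_complemented(self):
        # G>T seen in reference context AGC collapses to C>A at G[C>A]T
        cat = build_catalog([_snv("G", "T", "AGC")])
        assert cat.counts.sum() == 1
        assert cat.counts[0, CONTEXTS_96.index("G[C>A]T")] == 1

    def test_row_sums_count_snvs_and_skip_indels(self):
        variants = [_snv("C", "T", "ACA", pos=100 + i) for i in range(10)]
        variants.append(
            Variant(patient_id="P1", compartment=Compartment.LN, gene="G",
                    chrom="1", pos=500, ref="C", alt="CA", vaf=0.2)
        )
        cat = build_catalog(variants)
        assert cat.totals.tolist() == [10]

    def test_context_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="context3"):
            _snv("C", "T", "AGA")

    def test_stranded_halves_sum_to_unstranded(self):
        rng = np.random.default_rng(0)
        profile = smoking_like_profile()
        variants = []
        from chlymph.synthetic_cohort import _draw_context

        for i in range(200):
            ref, alt, ctx = _draw_context(rng, profile)
            variants.append(_snv(ref, alt, ctx, pos=100 + i,
                                 csr="same" if rng.random() < 0.5 else "opposite"))
        cat = build_catalog(variants, stranded=True)
        assert cat.stranded_counts is not None
        halves = cat.stranded_counts[:, :96] + cat.stranded_counts[:, 96:]
        assert np.array_equal(halves, cat.counts)

    def test_empirical_profile_recovers_generating_profile(self):
        # 5000 draws from a known 96-profile land within total variation 0.05
        rng = np.random.default_rng(42)
        profile = smoking_like_profile()
        from chlymph.synthetic_cohort import _draw_context

        variants = [
            _snv(*_draw_context(rng, profile), pos=100 + i) for i in range(5000)
        ]
        cat = build_catalog(variants)
        empirical = cat.pooled() / cat.pooled().sum()
        assert 0.5 * np.abs(empirical - profile).sum() <= 0.05


class TestSpectrum:
    def test_toy_fractions(self):
        variants = [
            _snv("C", "T", "ACA", pos=1),
            _snv("C", "T", "ACA", pos=2),
            _snv("C", "A", "ACA", pos=3),
            _snv("T", "G", "ATA", pos=4),
        ]
        pooled, per_sample = substitution_fractions(variants)
        assert pooled["C>T"] == pytest.approx(0.5)
        assert pooled["C>A"] == pytest.approx(0.25)
        assert pooled["T>G"] == pytest.approx(0.25)
        assert pooled.sum() == pytest.approx(1.0, abs=1e-9)
        assert per_sample.loc["P1"].sum() == pytest.approx(1.0)

    def test_single_class_gives_unit_fraction(self):
        pooled, _ = substitution_fractions([_snv("C", "T", "ACA", pos=i + 1)
                                            for i in range(3)])
        assert pooled["C>T"] == pytest.approx(1.0)

    def test_zero_snvs_yield_empty_not_nan(self):
        pooled, per_sample = substitution_fractions([])
        assert not pooled.isna().any()
        assert pooled.sum() == 0.0
        assert per_sample.empty

    def test_fractions_invariant_to_variant_order(self, rng):
        variants = [
            _snv("C", "T", "ACA", pos=1), _snv("C", "A", "ACA", pos=2),
            _snv("T", "C", "ATA", pos=3, pid="P2"),
        ]
        a, _ = substitution_fractions(variants)
        b, _ = substitution_fractions(variants[::-1])
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestTiTv:
    def test_balanced_samples_give_p_one(self):
        frac = pd.DataFrame(
            {"C>A": [0.25, 0.25], "C>G": [0.25, 0.25], "C>T": [0.25, 0.25],
             "T>A": [0.0, 0.0], "T>C": [0.25, 0.25], "T>G": [0.0, 0.0]}
        )
        out = titv_summary(frac)
        assert out["median_ti"] == pytest.approx(0.5)
        assert out["p_value"] == pytest.approx(1.0)

    def test_single_sample_has_no_p_value(self):
        frac = pd.DataFrame(
            {c: [0.2] for c in ["C>A", "C>G", "C>T", "T>A", "T>C"]}
        ).assign(**{"T>G": [0.0]})
        assert titv_summary(frac)["p_value"] is None

    def test_known_means_recovered(self, rng):
        ti = rng.normal(0.55, 0.05, size=30).clip(0, 1)
        frac = pd.DataFrame(
            {"C>T": ti * 0.8, "T>C": ti * 0.2, "C>A": (1 - ti) * 0.5,
             "C>G": (1 - ti) * 0.2, "T>A": (1 - ti) * 0.2, "T>G": (1 - ti) * 0.1}
        )
        out = titv_summary(frac)
        assert out["mean_ti"] == pytest.approx(ti.mean(), abs=1e-12)
        assert out["mean_tv"] == pytest.approx(1 - ti.mean(), abs=1e-12)


class TestStrandBias:
    @pytest.mark.parametrize(
        "fwd, rev, expected", [(17, 5, 2.4), (5, 5, 0.0), (19, 10, 0.9)]
    )
    def test_fold_excess(self, fwd, rev, expected):
        assert strand_fold_excess(fwd, rev) == pytest.approx(expected)

    def test_zero_reverse_count_flagged_infinite(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert strand_fold_excess(3, 0) == np.inf

    def test_pooled_class_counts_reflect_orientation(self):
        # C>A on the coding strand twice, once on the template strand
        variants = [
            _snv("C", "A", "TCC", pos=1, csr="same"),
            _snv("C", "A", "TCC", pos=2, csr="same"),
            _snv("G", "T", "GGA", pos=3, csr="same"),  # pyrimidine on template
        ]
        cat = build_catalog(variants, stranded=True)
        assert stranded_class_counts(cat, "C>A") == (2, 1)


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        with pytest.warns(UserWarning):
            out = compare_class_between_groups([0.3, 0.3], [0.3, 0.3])
        assert out["welch_p"] == 1.0

    def test_zero_group_median(self):
        out = compare_class_between_groups([0.4, 0.5, 0.3], [0.0, 0.0, 0.0])
        assert out["median_b"] == 0.0
        assert out["case_fraction_b"] == 0.0

    def test_separated_groups_detected_with_high_power(self):
        # per-case C>A fractions near 0.39 vs 0.06
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            a = rng.beta(3.9, 6.1, size=50)  # mean 0.39
            b = rng.beta(0.6, 9.4, size=50)  # mean 0.06
            if compare_class_between_groups(a, b)["welch_p"] < 0.05:
                hits += 1
        assert hits >= 95
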