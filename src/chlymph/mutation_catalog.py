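"""96-context SNV catalogs and substitution-spectrum statistics.

Builds per-sample trinucleotide mutation catalogs (optionally split by
transcriptional strand into 192 bins), and computes the six-class
substitution spectrum, transition/transversion summaries, coding-strand
bias, and between-group class comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contexts import (
    CONTEXTS_96,
    SUBSTITUTION_CLASSES,
    complement,
    context_label,
    revcomp,
)
from .cohort_io import Variant

__all__ = [
    "TrinucleotideCatalog",
    "classify_substitution",
    "is_transition",
    "build_catalog",
    "substitution_fractions",
    "titv_summary",
    "strand_fold_excess",
    "compare_class_between_groups",
    "write_catalog",
    "read_catalog",
]

_PYRIMIDINES = {"C", "T"}
_BASES = set("ACGT")


def classify_substitution(ref: str, alt: str) -> str:
    """Pyrimidine-collapsed substitution class of a single-base change.

    Purine-reference changes are complemented onto the opposite strand,
    so e.g. G>T maps to C>A.
    """
    if ref not in _BASES or alt not in _BASES or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref!r}>{alt!r}")
    if ref not in _PYRIMIDINES:
        ref, alt = complement(ref), complement(alt)
    return f"{ref}>{alt}"


def is_transition(cls: str) -> bool:
    """True for the purine<->purine / pyrimidine<->pyrimidine classes."""
    if cls not in SUBSTITUTION_CLASSES:
        raise ValueError(f"unknown substitution class {cls!r}")
    return cls in ("C>T", "T>C")


@dataclass
class TrinucleotideCatalog:
    """Per-sample 96-context SNV counts, optionally strand-split to 192.

    ``counts`` has shape (n_samples, 96) in the canonical context order.
    ``stranded_counts`` (n_samples, 192) stacks the coding-strand half
    (mutated pyrimidine on the coding/untranscribed strand, columns
    0..95) over the template-strand half (columns 96..191); variants
    with unknown orientation contribute to ``counts`` only.
    """

    sample_ids: list[str]
    counts: np.ndarray
    stranded_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != 96:
            raise ValueError(f"counts must be (n_samples, 96), got {self.counts.shape}")
        if len(self.sample_ids) != self.counts.shape[0]:
            raise ValueError("sample_ids / counts length mismatch")
        if (self.counts < 0).any():
            raise ValueError("negative catalog count")
        if self.stranded_counts is not None:
            self.stranded_counts = np.asarray(self.stranded_counts, dtype=int)
            if self.stranded_counts.shape != (self.counts.shape[0], 192):
                raise ValueError("stranded_counts must be (n_samples, 192)")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def pooled(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def _catalog_bin(v: Variant) -> tuple[int, bool | None]:
    """(96-bin index, pyrimidine-on-coding-strand flag or None) for an SNV."""
    ctx = v.context3
    if ctx is None:
        raise ValueError(f"SNV at {v.chrom}:{v.pos} lacks context3")
    if len(ctx) != 3 or ctx[1] != v.ref:
        raise ValueError(f"context3 {ctx!r} middle base != ref {v.ref!r}")
    ref, alt = v.ref, v.alt
    if ref in _PYRIMIDINES:
        five, three = ctx[0], ctx[2]
        pyr_on_ref = True
    else:
        rc = revcomp(ctx)
        five, three = rc[0], rc[2]
        ref, alt = complement(ref), complement(alt)
        pyr_on_ref = False
    cls = f"{ref}>{alt}"
    idx = CONTEXTS_96.index(context_label(cls, five, three))
    if v.coding_strand_ref == "unknown":
        return idx, None
    # pyrimidine sits on the coding strand iff its strand is the coding one
    coding = pyr_on_ref == (v.coding_strand_ref == "same")
    return idx, coding


def build_catalog(
    variants: Iterable[Variant],
    stranded: bool = False,
    sample_ids: Sequence[str] | None = None,
) -> TrinucleotideCatalog:
    """Count SNVs per sample into 96 (or 192 strand-split) context bins.

    Indels and other non-SNVs are skipped.  Samples are the variants'
    patient IDs unless ``sample_ids`` fixes the roster (and order).
    """
    variants = list(variants)
    if sample_ids is None:
        seen: dict[str, None] = {}
        for v in variants:
            seen.setdefault(v.patient_id, None)
        sample_ids = list(seen)
    index = {s: i for i, s in enumerate(sample_ids)}
    counts = np.zeros((len(sample_ids), 96), dtype=int)
    stranded_counts = np.zeros((len(sample_ids), 192), dtype=int) if stranded else None
    for v in variants:
        if not v.is_snv or v.patient_id not in index:
            continue
        bin_idx, coding = _catalog_bin(v)
        row = index[v.patient_id]
        counts[row, bin_idx] += 1
        if stranded_counts is not None and coding is not None:
            stranded_counts[row, bin_idx + (0 if coding else 96)] += 1
    return TrinucleotideCatalog(list(sample_ids), counts, stranded_counts)


def _class_slices() -> dict[str, slice]:
    return {cls: slice(16 * i, 16 * (i + 1)) for i, cls in enumerate(SUBSTITUTION_CLASSES)}


def substitution_fractions(
    source: TrinucleotideCatalog | Iterable[Variant],
) -> tuple[pd.Series, pd.DataFrame]:
    """Six-class substitution fractions, pooled and per sample.

    Returns ``(pooled, per_sample)`` where ``pooled`` is a Series over
    the six classes summing to 1 and ``per_sample`` a samples x classes
    DataFrame (rows of zero-SNV samples are all-zero, not NaN).  With no
    SNVs at all the results are explicitly empty/zero.
    """
    catalog = source if isinstance(source, TrinucleotideCatalog) else build_catalog(source)
    per_class = np.stack(
        [catalog.counts[:, sl].sum(axis=1) for sl in _class_slices().values()], axis=1
    )
    totals = per_class.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, per_class / np.maximum(totals, 1), 0.0)
    per_sample = pd.DataFrame(frac, index=catalog.sample_ids, columns=SUBSTITUTION_CLASSES)
    grand = per_class.sum(axis=0)
    pooled = pd.Series(
        grand / grand.sum() if grand.sum() > 0 else np.zeros(6),
        index=SUBSTITUTION_CLASSES,
    )
    return pooled, per_sample


def titv_summary(per_sample_fractions: pd.DataFrame) -> dict:
    """Per-sample transition vs transversion comparison.

    ``per_sample_fractions`` is the samples x six-class table from
    :func:`substitution_fractions`.  The paired two-sided t test compares
    each sample's transition fraction against its transversion fraction;
    with fewer than two samples no p-value is reported.
    """
    ti_cols = [c for c in SUBSTITUTION_CLASSES if is_transition(c)]
    tv_cols = [c for c in SUBSTITUTION_CLASSES if not is_transition(c)]
    ti = per_sample_fractions[ti_cols].sum(axis=1).to_numpy()
    tv = per_sample_fractions[tv_cols].sum(axis=1).to_numpy()
    out = {
        "median_ti": float(np.median(ti)),
        "median_tv": float(np.median(tv)),
        "mean_ti": float(np.mean(ti)),
        "mean_tv": float(np.mean(tv)),
        "p_value": None,
    }
    if len(ti) >= 2:
        diff = ti - tv
        if np.allclose(diff, diff[0]) and math.isclose(diff[0], 0.0, abs_tol=1e-12):
            out["p_value"] = 1.0
        else:
            out["p_value"] = float(stats.ttest_rel(ti, tv).pvalue)
    return out


def strand_fold_excess(n_forward: int, n_reverse: int) -> float:
    """Fold excess of coding-strand over template-strand mutations.

    Defined as ``(n_forward - n_reverse) / n_reverse`` so that counts of
    17 vs 5 give 2.4.  A zero reverse count is undefined and returns
    ``inf`` with a warning.
    """
    if n_forward < 0 or n_reverse < 0:
        raise ValueError("counts must be non-negative")
    if n_reverse == 0:
        warnings.warn("strand fold excess undefined with zero reverse count")
        return math.inf
    return (n_forward - n_reverse) / n_reverse


def stranded_class_counts(catalog: TrinucleotideCatalog, cls: str) -> tuple[int, int]:
    """Pooled (coding-strand, template-strand) counts for one class."""
    if catalog.stranded_counts is None:
        raise ValueError("catalog was built without strand information")
    sl = _class_slices()[cls]
    fwd = int(catalog.stranded_counts[:, sl].sum())
    rev = int(catalog.stranded_counts[:, 96 + sl.start : 96 + sl.stop].sum())
    return fwd, rev


def compare_class_between_groups(
    fractions_a: Sequence[float], fractions_b: Sequence[float]
) -> dict:
    """Welch t test on per-case fractions of one substitution class.

    Also reports, per group, the fraction of cases carrying at least one
    variant of the class (cases with fraction > 0).  Degenerate
    zero-variance-in-both input yields p = 1 with a warning.
    """
    a = np.asarray(fractions_a, dtype=float)
    b = np.asarray(fractions_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 cases")
    out = {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "case_fraction_a": float((a > 0).mean()),
        "case_fraction_b": float((b > 0).mean()),
    }
    if a.var() == 0 and b.var() == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups; p set to 1")
            out["welch_p"] = 1.0
        else:
            out["welch_p"] = 0.0
    else:
        out["welch_p"] = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return out


def write_catalog(catalog: TrinucleotideCatalog, path: str | Path) -> None:
    """Write in the 96-rows-by-samples matrix layout."""
    pd.DataFrame(
        catalog.counts.T, index=CONTEXTS_96, columns=catalog.sample_ids
    ).rename_axis("context").to_csv(path, sep="\t")


def read_catalog(path: str | Path) -> TrinucleotideCatalog:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(CONTEXTS_96):
        from .contexts import canonical_context_index

        order = np.array([canonical_context_index(c) for c in df.index])
        mat = np.empty_like(df.to_numpy(dtype=float))
        mat[order, :] = df.to_numpy(dtype=float)
    else:
        mat = df.to_numpy(dtype=float)
    return TrinucleotideCatalog([str(c) for c in df.columns], mat.T.astype(int))
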