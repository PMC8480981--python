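"""Canonical SBS-96 trinucleotide context ordering and strand helpers.

The 96 single-base-substitution contexts are ordered lexicographically:
the six pyrimidine substitution classes C>A, C>G, C>T, T>A, T>C, T>G,
and within each class the 16 flanking-base combinations with the 5'
base cycling slowest (A[C>A]A, A[C>A]C, ..., T[T>G]T).  Labels use the
conventional ``X[R>A]Y`` form.
"""

from __future__ import annotations

__all__ = [
    "SUBSTITUTION_CLASSES",
    "CONTEXTS_96",
    "complement",
    "revcomp",
    "context_label",
    "canonical_context_index",
    "parse_context_label",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def complement(base: str) -> str:
    return _COMP[base]


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def context_label(cls: str, five: str, three: str) -> str:
    ref, alt = cls.split(">")
    return f"{five}[{ref}>{alt}]{three}"


CONTEXTS_96 = tuple(
    context_label(cls, five, three)
    for cls in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
)

_INDEX = {lab: i for i, lab in enumerate(CONTEXTS_96)}


def parse_context_label(label: str) -> tuple[str, str, str]:
    """Parse ``A[C>T]G``-style (or ``ACG>ATG``-style) labels.

    Returns (substitution class, 5' base, 3' base) on the pyrimidine
    strand, collapsing purine-reference labels by reverse complement.
    """
    label = label.strip()
    if "[" in label:
        five = label[0]
        three = label[-1]
        cls = label[2:5]
    elif ">" in label and len(label.replace(">", "")) == 6:
        src, dst = label.split(">")
        five, ref, three = src[0], src[1], src[2]
        cls = f"{ref}>{dst[1]}"
    else:
        raise ValueError(f"unrecognized context label {label!r}")
    ref, alt = cls.split(">")
    if ref in "AG":  # collapse to the pyrimidine strand
        five, three = _COMP[three], _COMP[five]
        ref, alt = _COMP[ref], _COMP[alt]
        cls = f"{ref}>{alt}"
    if cls not in SUBSTITUTION_CLASSES or five not in _BASES or three not in _BASES:
        raise ValueError(f"unrecognized context label {label!r}")
    return cls, five, three


def canonical_context_index(label: str) -> int:
    cls, five, three = parse_context_label(label)
    return _INDEX[context_label(cls, five, three)]
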