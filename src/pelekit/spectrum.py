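"""Pyrimidine-strand substitution classification.

A substitution is reported by the pyrimidine member of its base pair,
yielding six classes (C>A, C>G, C>T, T>A, T>C, T>G); purine
substitutions map through the complement (G>A == C>T, A>G == T>C, ...).
"""

from __future__ import annotations

from collections import Counter

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def classify_spectrum(ref: str, alt: str) -> str:
    """Six-class pyrimidine label of a single-base substitution."""
    if ref not in _COMP or alt not in _COMP:
        raise ValueError(f"invalid base in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":
        ref, alt = _COMP[ref], _COMP[alt]
    return f"{ref}>{alt}"


def summarize_spectrum(substitutions) -> dict:
    """Class counts and fractions for an iterable of (ref, alt) pairs."""
    counts = Counter(classify_spectrum(r, a) for r, a in substitutions)
    total = sum(counts.values())
    return {
        "counts": {c: counts.get(c, 0) for c in CLASSES},
        "fractions": {
            c: (counts.get(c, 0) / total if total else 0.0) for c in CLASSES
        },
        "total": total,
    }
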