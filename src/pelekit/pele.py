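"""Dual-barcode combination logic (List A / List B).

List A: strict calling on the pooled (both-barcode) pileup of merged
reads.  List B: lenient calling on each barcode's pileup separately,
keeping only variants called under *both* barcodes — a PCR-lineage
error lives under a single barcode and cannot enter List B.  The final
call set is the union of the two lists; where a variant appears in
both, List A's (pooled) record wins and is labelled ``both``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .caller import CallerParams, VariantCall, call_variants
from .pileup import Pileup

__all__ = ["PeleParams", "PeleCallSet", "call_list_a", "call_list_b", "combine_pele"]


@dataclass(frozen=True)
class PeleParams:
    strict: CallerParams = field(
        default_factory=lambda: CallerParams(min_af=0.002, alpha=0.05)
    )
    lenient: CallerParams = field(
        default_factory=lambda: CallerParams(
            min_af=0.0005, alpha=0.05, min_call_quality=150.0
        )
    )
    #: documented working range for the lenient per-barcode quality cutoff
    lenient_q_range: tuple[float, float] = (150.0, 820.0)

    def __post_init__(self) -> None:
        if self.lenient.min_af > self.strict.min_af:
            raise ValueError("lenient.min_af must be <= strict.min_af")


@dataclass
class PeleCallSet:
    calls: list[VariantCall]
    n_list_a: int
    n_list_b: int
    n_both: int

    @property
    def keys(self) -> set:
        return {c.key for c in self.calls}


def call_list_a(pooled: Pileup, strict: CallerParams) -> list[VariantCall]:
    """Strict calls on the pooled-barcode merged-read pileup."""
    calls = call_variants(pooled, strict, barcode_index="pooled")
    for c in calls:
        c.source = "listA"
    return calls


def call_list_b(
    pileup_b0: Pileup, pileup_b1: Pileup, lenient: CallerParams
) -> list[VariantCall]:
    """Lenient per-barcode calls intersected across the two barcodes.

    The intersected record reports the pooled depth and allele
    frequency; its p-value is the worse (larger) of the two per-barcode
    p-values and its quality the smaller — the conservative summary of
    two independent detections.
    """
    c0 = {c.key: c for c in call_variants(pileup_b0, lenient, barcode_index=0)}
    c1 = {c.key: c for c in call_variants(pileup_b1, lenient, barcode_index=1)}
    out: list[VariantCall] = []
    for key in sorted(c0.keys() & c1.keys()):
        a, b = c0[key], c1[key]
        alt = a.alt_depth + b.alt_depth
        tot = a.total_depth + b.total_depth
        out.append(
            VariantCall(
                tag_id=a.tag_id,
                offset=a.offset,
                ref=a.ref,
                alt=a.alt,
                alt_depth=alt,
                total_depth=tot,
                af=alt / tot,
                p_raw=max(a.p_raw, b.p_raw),
                p_corrected=max(a.p_corrected, b.p_corrected),
                call_quality=min(a.call_quality, b.call_quality),
                barcode_index="pooled",
                source="listB",
            )
        )
    return out


def combine_pele(
    list_a: Sequence[VariantCall], list_b: Sequence[VariantCall]
) -> PeleCallSet:
    """Union of Lists A and B on (tag, offset, alt); A's record wins."""
    by_key = {c.key: replace(c, source="listB") for c in list_b}
    n_both = 0
    for c in list_a:
        if c.key in by_key:
            n_both += 1
            by_key[c.key] = replace(c, source="both")
        else:
            by_key[c.key] = replace(c, source="listA")
    calls = [by_key[k] for k in sorted(by_key)]
    return PeleCallSet(
        calls=calls,
        n_list_a=len(list_a),
        n_list_b=len(list_b),
        n_both=n_both,
    )
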