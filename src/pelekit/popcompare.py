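"""Two-population comparison: de-novo / lost alleles and fold changes.

A "putative de novo" allele is one called in population 2 with zero
supporting observations in population 1, at a required minimum merged
(OPE) depth in *both* populations — presence/absence, not a test.  The
converse direction is a "lost" allele.  Alleles called in both
populations are "shared" and annotated with the plain frequency ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .caller import VariantCall
from .pileup import Pileup
from .spectrum import classify_spectrum, summarize_spectrum  # re-exported

__all__ = [
    "PopCompareParams",
    "SharedSite",
    "PopComparison",
    "compare_populations",
    "fold_change",
    "classify_spectrum",
    "summarize_spectrum",
    "write_comparison_tsvs",
]


@dataclass(frozen=True)
class PopCompareParams:
    min_depth: int = 900  # OPE depth required in BOTH populations
    max_other_af: float = 0.0  # tolerated AF in the "absent" population

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 <= self.max_other_af < 1.0:
            raise ValueError("max_other_af must be in [0, 1)")


@dataclass
class SharedSite:
    tag_id: str
    offset: int
    ref: str
    alt: str
    af1: float
    af2: float
    fold_change: float
    depth1: int
    depth2: int


@dataclass
class PopComparison:
    shared: list[SharedSite]
    de_novo: list[VariantCall]  # called in pop 2, absent in pop 1
    lost: list[VariantCall]  # called in pop 1, absent in pop 2
    params: PopCompareParams
    n_sites_excluded_depth: int = 0
    n_sites_excluded_other: int = 0


def fold_change(af1: float, af2: float) -> float:
    """Plain frequency ratio af2/af1; af1 = 0 is a de-novo, not a ratio."""
    if af1 <= 0.0:
        raise ValueError("fold change undefined at af1 = 0; route to de_novo")
    return af2 / af1


def compare_populations(
    pileup1: Pileup,
    calls1: Sequence[VariantCall],
    pileup2: Pileup,
    calls2: Sequence[VariantCall],
    params: PopCompareParams = PopCompareParams(),
) -> PopComparison:
    """Classify called alleles into shared / de-novo / lost.

    Only sites with depth >= ``min_depth`` in *both* populations are
    classified; the categories are disjoint by construction, and
    swapping the population order swaps de_novo and lost exactly.
    """
    if {t.tag_id for t in pileup1.tags} != {t.tag_id for t in pileup2.tags}:
        raise ValueError("populations must share the same tag space")
    k1 = {c.key: c for c in calls1}
    k2 = {c.key: c for c in calls2}
    shared: list[SharedSite] = []
    de_novo: list[VariantCall] = []
    lost: list[VariantCall] = []
    n_depth = 0
    n_other = 0
    for key in sorted(set(k1) | set(k2)):
        tag_id, offset, alt = key
        d1 = pileup1.depth(tag_id, offset)
        d2 = pileup2.depth(tag_id, offset)
        if d1 < params.min_depth or d2 < params.min_depth:
            n_depth += 1
            continue
        if key in k1 and key in k2:
            c1, c2 = k1[key], k2[key]
            shared.append(
                SharedSite(
                    tag_id=tag_id,
                    offset=offset,
                    ref=c1.ref,
                    alt=alt,
                    af1=c1.af,
                    af2=c2.af,
                    fold_change=fold_change(c1.af, c2.af),
                    depth1=d1,
                    depth2=d2,
                )
            )
        elif key in k2:
            other_alt = pileup1.base_count(tag_id, offset, alt)
            if other_alt <= params.max_other_af * d1:
                de_novo.append(k2[key])
            else:
                n_other += 1
        else:
            other_alt = pileup2.base_count(tag_id, offset, alt)
            if other_alt <= params.max_other_af * d2:
                lost.append(k1[key])
            else:
                n_other += 1
    return PopComparison(
        shared=shared,
        de_novo=de_novo,
        lost=lost,
        params=params,
        n_sites_excluded_depth=n_depth,
        n_sites_excluded_other=n_other,
    )


def write_comparison_tsvs(cmp: PopComparison, prefix) -> None:
    """Shared / de-novo / lost tables, one TSV each."""
    with open(f"{prefix}.shared.tsv", "w") as fh:
        fh.write("tag_id\toffset\tref\talt\taf1\taf2\tfold_change\tdepth1\tdepth2\n")
        for s in cmp.shared:
            fh.write(
                f"{s.tag_id}\t{s.offset}\t{s.ref}\t{s.alt}\t{s.af1:.6g}\t"
                f"{s.af2:.6g}\t{s.fold_change:.4g}\t{s.depth1}\t{s.depth2}\n"
            )
    for name, calls in (("de_novo", cmp.de_novo), ("lost", cmp.lost)):
        with open(f"{prefix}.{name}.tsv", "w") as fh:
            fh.write("tag_id\toffset\tref\talt\taf\talt_depth\ttotal_depth\tclass\n")
            for c in calls:
                fh.write(
                    f"{c.tag_id}\t{c.offset}\t{c.ref}\t{c.alt}\t{c.af:.6g}\t"
                    f"{c.alt_depth}\t{c.total_depth}\t"
                    f"{classify_spectrum(c.ref, c.alt)}\n"
                )
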