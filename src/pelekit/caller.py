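"""Quality-aware rare-SNV calling.

The significance model treats each retained observation at a column as
an independent Bernoulli trial of being an *erroneous* call of a given
alternate base, with per-observation probability ``10**(-q/10) / 3``
(the uniform three-way split of the error probability across alternate
bases).  The p-value of seeing ``k`` or more alternate observations is
the exact Poisson-binomial upper tail, Bonferroni-corrected by (by
default) three alternate alleles times the number of tested columns.
A variant is reported only when, additionally, its allele frequency
clears ``min_af`` — on overlap-merged data this floor is what removes
PCR-lineage errors, which survive merging but sit below it.

The tail probability is computed by a grouped dynamic programme with an
absorbing ">= k" state: equal probabilities are collapsed into Binomial
blocks, and every update adds non-negative mass to the tail, so there
is no catastrophic cancellation even for tails near 1e-300.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import binom

from ._seq import BASES
from .pileup import Pileup
from .spectrum import summarize_spectrum

__all__ = [
    "CallerParams",
    "VariantCall",
    "ErrorProfile",
    "poisson_binomial_tail",
    "call_variants",
    "estimate_background",
    "write_vcf",
    "read_vcf_calls",
]

MAX_CALL_QUALITY = 3000.0


@dataclass(frozen=True)
class CallerParams:
    """Thresholds for one calling pass.

    ``bonferroni_n = None`` means "3 x number of tested columns",
    resolved against the pileup at call time.
    """

    min_af: float = 0.002
    alpha: float = 0.05
    bonferroni_n: Optional[int] = None
    min_call_quality: float = 0.0
    min_depth: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_af < 1.0:
            raise ValueError("min_af must be in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.bonferroni_n is not None and self.bonferroni_n < 1:
            raise ValueError("bonferroni_n must be >= 1")


@dataclass
class VariantCall:
    tag_id: str
    offset: int
    ref: str
    alt: str
    alt_depth: int
    total_depth: int
    af: float
    p_raw: float
    p_corrected: float
    call_quality: float
    barcode_index: object = "pooled"  # 0, 1 or "pooled"
    source: Optional[str] = None  # listA / listB / both (set by pele)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.tag_id, self.offset, self.alt)


@dataclass
class ErrorProfile:
    """Background error landscape of a pure (variant-free) control."""

    per_column_rates: dict
    max_rate: float
    overall_rate: float
    spectrum: dict
    recommended_min_af: float


def poisson_binomial_tail(error_probs, k: int) -> float:
    """Exact ``P(X >= k)`` for a sum of independent Bernoulli trials.

    ``error_probs`` are the per-trial success probabilities.  Equal
    probabilities are grouped into Binomial blocks internally, so
    homogeneous inputs cost O(k log-ish) instead of O(n k); heavily
    quantised inputs (e.g. Phred-derived) are similarly cheap.
    """
    p = np.asarray(error_probs, dtype=float)
    if p.size and (p.min() < 0.0 or p.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    if k < 0 or k > p.size:
        raise ValueError(f"k={k} outside [0, n={p.size}]")
    if k == 0:
        return 1.0
    vals, cnts = np.unique(p, return_counts=True)
    return _pb_tail_grouped(vals, cnts, k)


def _pb_tail_grouped(probs, counts, k: int) -> float:
    """Absorbing-tail DP over Binomial blocks; all updates add
    non-negative mass, so tiny tails keep full relative precision."""
    body = np.zeros(k)
    body[0] = 1.0
    tail = 0.0
    a = np.arange(k)
    for p, m in zip(probs, counts):
        if p == 0.0 or m == 0:
            continue
        # Mass jumping from body state a to >= k: needs >= k-a successes.
        tail += float((body * binom.sf(k - a - 1, int(m), p)).sum())
        pmf = binom.pmf(np.arange(min(int(m), k - 1) + 1), int(m), p)
        body = np.convolve(body, pmf)[:k]
    return float(min(1.0, tail))


def _phred_of(p: float) -> float:
    if p <= 0.0:
        return MAX_CALL_QUALITY
    return min(MAX_CALL_QUALITY, -10.0 * math.log10(p))


def call_variants(
    pu: Pileup,
    params: CallerParams = CallerParams(),
    barcode_index: object = "pooled",
) -> list[VariantCall]:
    """Test every non-reference base of every covered column.

    A call is emitted iff the Bonferroni-corrected Poisson-binomial
    p-value is <= alpha, AF >= min_af, depth >= min_depth and the
    Phred-scaled call quality >= min_call_quality.  Deterministic.
    """
    bonf = params.bonferroni_n
    if bonf is None:
        bonf = max(1, 3 * pu.n_covered_columns())
    calls: list[VariantCall] = []
    for ti, tag in enumerate(pu.tags):
        cnt = pu.counts[ti]
        depth_per_col = cnt.sum(axis=0)
        ref_codes = pu.ref_codes[ti]
        nonref = depth_per_col - cnt[ref_codes, np.arange(tag.length)]
        for off in np.flatnonzero(nonref > 0):
            off = int(off)
            depth = int(depth_per_col[off])
            if depth < params.min_depth:
                continue
            qh = pu.qhist[ti][:, :, off].sum(axis=0)
            qs = np.flatnonzero(qh)
            probs = np.power(10.0, -qs / 10.0) / 3.0
            ref_b = int(ref_codes[off])
            for alt in range(4):
                k = int(cnt[alt, off])
                if alt == ref_b or k == 0:
                    continue
                af = k / depth
                if af < params.min_af:
                    continue
                p_raw = _pb_tail_grouped(probs, qh[qs], k)
                p_corr = min(1.0, p_raw * bonf)
                if p_corr > params.alpha:
                    continue
                q = _phred_of(p_corr)
                if q < params.min_call_quality:
                    continue
                calls.append(
                    VariantCall(
                        tag_id=tag.tag_id,
                        offset=off,
                        ref=BASES[ref_b],
                        alt=BASES[alt],
                        alt_depth=k,
                        total_depth=depth,
                        af=af,
                        p_raw=p_raw,
                        p_corrected=p_corr,
                        call_quality=q,
                        barcode_index=barcode_index,
                    )
                )
    return calls


_AF_GRID = sorted(
    {m * 10.0 ** e for e in range(-6, 0) for m in (1, 2, 5)} | {1.0}
)


def estimate_background(pu: Pileup) -> ErrorProfile:
    """Profile the residual error of a pure control pileup.

    Reports the per-column non-reference fraction, its maximum (the
    quantity an allele-frequency floor must clear), the overall rate,
    the pyrimidine-class spectrum of non-reference observations, and
    the smallest round value strictly above the maximum as the
    recommended ``min_af``.
    """
    rates: dict[tuple[str, int], float] = {}
    total_obs = 0
    total_err = 0
    subs: list[tuple[str, str]] = []
    for ti, tag in enumerate(pu.tags):
        cnt = pu.counts[ti]
        depth = cnt.sum(axis=0)
        ref_codes = pu.ref_codes[ti]
        for off in np.flatnonzero(depth > 0):
            off = int(off)
            d = int(depth[off])
            ref_b = int(ref_codes[off])
            err = d - int(cnt[ref_b, off])
            rates[(tag.tag_id, off)] = err / d
            total_obs += d
            total_err += err
            if err:
                for alt in range(4):
                    if alt != ref_b and cnt[alt, off]:
                        subs.extend(
                            [(BASES[ref_b], BASES[alt])] * int(cnt[alt, off])
                        )
    if total_obs == 0:
        raise ValueError("cannot profile a zero-depth pileup")
    max_rate = max(rates.values()) if rates else 0.0
    rec = next(v for v in _AF_GRID if v > max_rate)
    return ErrorProfile(
        per_column_rates=rates,
        max_rate=max_rate,
        overall_rate=total_err / total_obs,
        spectrum=summarize_spectrum(subs),
        recommended_min_af=rec,
    )


# ---------------------------------------------------------------------------
# VCF output (4.2, 1-based positions)


def write_vcf(calls: Sequence[VariantCall], path, source_info: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        fh.write('##INFO=<ID=ADP,Number=1,Type=Integer,Description="Alt depth">\n')
        fh.write('##INFO=<ID=PRAW,Number=1,Type=Float,Description="Raw p-value">\n')
        fh.write(
            '##INFO=<ID=PCORR,Number=1,Type=Float,Description="Corrected p-value">\n'
        )
        fh.write(
            '##INFO=<ID=SRC,Number=1,Type=String,Description="Call list (A/B/AB)">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        src_map = {"listA": "A", "listB": "B", "both": "AB", None: "."}
        for c in calls:
            info = (
                f"AF={c.af:.6g};DP={c.total_depth};ADP={c.alt_depth};"
                f"PRAW={c.p_raw:.6g};PCORR={c.p_corrected:.6g}"
            )
            if source_info:
                info += f";SRC={src_map.get(c.source, '.')}"
            fh.write(
                f"{c.tag_id}\t{c.offset + 1}\t.\t{c.ref}\t{c.alt}\t"
                f"{c.call_quality:.1f}\tPASS\t{info}\n"
            )


def read_vcf_calls(path) -> list[VariantCall]:
    calls: list[VariantCall] = []
    src_map = {"A": "listA", "B": "listB", "AB": "both", ".": None}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            info = dict(
                kv.split("=", 1) for kv in f[7].split(";") if "=" in kv
            )
            calls.append(
                VariantCall(
                    tag_id=f[0],
                    offset=int(f[1]) - 1,
                    ref=f[3],
                    alt=f[4],
                    alt_depth=int(info.get("ADP", 0)),
                    total_depth=int(info.get("DP", 0)),
                    af=float(info.get("AF", 0.0)),
                    p_raw=float(info.get("PRAW", 1.0)),
                    p_corrected=float(info.get("PCORR", 1.0)),
                    call_quality=float(f[5]) if f[5] != "." else 0.0,
                    source=src_map.get(info.get("SRC", "."), None),
                )
            )
    return calls
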