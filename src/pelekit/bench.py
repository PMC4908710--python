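"""Benchmark harness: truth evaluation, matched-budget method
comparison, depth sweeps and the lane-fraction cost model.

``run_experiment`` simulates one dual-barcoded spike-in library and
analyses the *same raw reads* three ways:

* ``standard`` — no merging; raw reads piled with single-read
  qualities, truncated to 2.4x the (pooled) OPE depth.  The 2.4 factor
  converts between overlap-merged consensus depth and the raw-read
  depth the same sequencing budget buys, and is applied as depth
  accounting.
* ``orp`` — merged consensus reads, barcodes pooled, strict calling
  (List A only).
* ``pele`` — the full List A union List B call set.

All arms share the caller, so differences isolate the read-level
method, not the test statistic.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._seq import qual_to_phred
from .caller import CallerParams, VariantCall, call_variants
from .libsim import (
    LibraryConfig,
    ReadPairRecord,
    amplify_pcr,
    sequence_pairs,
    simulate_molecules,
)
from .pele import PeleParams, call_list_a, call_list_b, combine_pele
from .pileup import align_to_tags, build_pileup, downsample
from .readprep import MergedRead, MergeParams, demultiplex, merge_stream
from .refsim import TruthVariant, digest_tags, make_genome, make_truth

__all__ = [
    "TruthEvaluation",
    "CostModel",
    "ExperimentConfig",
    "ExperimentReport",
    "evaluate_calls",
    "lane_fraction",
    "format_lane_percent",
    "run_experiment",
]

STANDARD_TO_OPE_DEPTH = 2.4  # raw standard depth per unit of pooled OPE depth


@dataclass
class TruthEvaluation:
    n_expected: int
    true_positives: int
    false_positives: int
    vacuous: bool = False  # empty call set: precision reported as 1.0

    @property
    def sensitivity(self) -> float:
        return self.true_positives / self.n_expected if self.n_expected else 0.0

    @property
    def precision(self) -> float:
        called = self.true_positives + self.false_positives
        return self.true_positives / called if called else 1.0

    def as_dict(self) -> dict:
        return {
            "n_expected": self.n_expected,
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "vacuous": self.vacuous,
        }


def evaluate_calls(
    calls: Sequence[VariantCall], truth: Sequence[TruthVariant]
) -> TruthEvaluation:
    """Exact-key scoring: a call is true iff (tag, offset, alt) matches."""
    truth_keys = {v.key for v in truth}
    call_keys = {c.key for c in calls}
    tp = len(call_keys & truth_keys)
    fp = len(call_keys - truth_keys)
    return TruthEvaluation(
        n_expected=len(truth_keys),
        true_positives=tp,
        false_positives=fp,
        vacuous=not call_keys,
    )


@dataclass(frozen=True)
class CostModel:
    read_len: int = 100
    reads_per_lane: float = 4e8
    overlap_retention: float = 0.80

    def __post_init__(self) -> None:
        if min(self.read_len, self.reads_per_lane) <= 0:
            raise ValueError("read_len and reads_per_lane must be positive")
        if not 0.0 < self.overlap_retention <= 1.0:
            raise ValueError("overlap_retention must be in (0, 1]")


def lane_fraction(
    region_bp: float, depth: float, model: CostModel = CostModel()
) -> float:
    """Fraction of a sequencing lane to cover ``region_bp`` at ``depth``
    with overlap-merged reads: region x depth / read_len /
    reads_per_lane / retention."""
    if region_bp < 0 or depth < 0:
        raise ValueError("region and depth must be non-negative")
    return (
        region_bp
        * depth
        / model.read_len
        / model.reads_per_lane
        / model.overlap_retention
    )


def format_lane_percent(fraction: float) -> str:
    """Percent at 2 significant figures, truncating (0.0625% -> 0.062%)."""
    v = fraction * 100.0
    if v == 0.0:
        return "0"
    e = math.floor(math.log10(abs(v)))
    scale = 10.0 ** (e - 1)
    t = math.floor(v / scale) * scale
    decimals = max(0, 1 - e)
    return f"{t:.{decimals}f}"


# ---------------------------------------------------------------------------
# End-to-end experiment


@dataclass
class ExperimentConfig:
    n_tags: int = 20
    tag_len: int = 100
    motif: str = "CCTGCAGG"
    genome_spacing: int = 150
    n_truth: int = 16
    truth_af: object = 0.0042
    depths: tuple[int, ...] = (5000,)  # OPE per barcode
    library: LibraryConfig = field(default_factory=LibraryConfig)
    merge: MergeParams = field(default_factory=MergeParams)
    pele: PeleParams = field(default_factory=PeleParams)
    #: standard-arm caller; the AF floor defaults to 0 so the arm shows the
    #: raw false-positive behaviour of unfiltered deep data
    standard: CallerParams = field(
        default_factory=lambda: CallerParams(min_af=0.0)
    )
    headroom: float = 1.05  # molecules beyond the deepest truncation target

    def n_molecules(self) -> int:
        per_tag = math.ceil(
            STANDARD_TO_OPE_DEPTH * 2 * max(self.depths) * self.headroom
        )
        return self.n_tags * per_tag


@dataclass
class ExperimentReport:
    seed: int
    truth: list[TruthVariant]
    per_depth: dict  # depth -> {arm -> TruthEvaluation}
    calls: dict  # depth -> {arm -> list[VariantCall]}
    raw_read_budget: int  # identical for every arm by construction
    merge_stats: dict

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "raw_read_budget": self.raw_read_budget,
            "merge_stats": self.merge_stats,
            "per_depth": {
                str(d): {arm: ev.as_dict() for arm, ev in arms.items()}
                for d, arms in self.per_depth.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)


def _raw_reads_as_single(
    pairs_by_barcode: dict[int, list[ReadPairRecord]]
) -> list[MergedRead]:
    """Both mates of each demultiplexed pair as single-end reads with
    their own (single-read) qualities."""
    out: list[MergedRead] = []
    qcache: dict[str, object] = {}

    def _q(qs: str):
        arr = qcache.get(qs)
        if arr is None:
            arr = qual_to_phred(qs)
            qcache[qs] = arr
        return arr

    for bi in sorted(pairs_by_barcode):
        for p in pairs_by_barcode[bi]:
            out.append(
                MergedRead(
                    read_id=p.read_id + "/1",
                    barcode_index=bi,
                    seq=p.seq1,
                    qual=_q(p.qual1),
                    n_masked_mismatch=0,
                    n_trimmed_overhang=0,
                )
            )
            out.append(
                MergedRead(
                    read_id=p.read_id + "/2",
                    barcode_index=bi,
                    seq=p.seq2,
                    qual=_q(p.qual2),
                    n_masked_mismatch=0,
                    n_trimmed_overhang=0,
                )
            )
    return out


def run_experiment(config: ExperimentConfig, seed: int) -> ExperimentReport:
    """Simulate one library and evaluate all three arms at each depth."""
    gseed = (seed * 1_000_003 + 17) % (2**31)
    n_sites = math.ceil(config.n_tags / 2)
    spacing = max(config.genome_spacing, config.tag_len + 8)
    genome = make_genome(
        length=n_sites * (len(config.motif) + spacing) + 4 * spacing,
        gc=0.5,
        motif=config.motif,
        n_sites=n_sites,
        min_spacing=spacing,
        seed=gseed,
    )
    tags = digest_tags(genome, config.tag_len)[: config.n_tags]
    truth = make_truth(
        tags, config.n_truth, config.truth_af, seed=(gseed + 1) % (2**31)
    )

    lib = dataclasses.replace(config.library, seed=seed % (2**31))
    mols = simulate_molecules(tags, truth, config.n_molecules(), lib)
    mols = amplify_pcr(mols, tags, lib)
    pairs = sequence_pairs(mols, tags, lib)

    by_bc, _discarded = demultiplex(pairs, lib.barcodes, max_mismatch=1)

    # Merged (OPE) arm inputs, per barcode in stream order.
    merged, mstats = merge_stream(by_bc, config.merge)
    merged_by_bc = {0: [], 1: []}
    for r in merged:
        merged_by_bc[r.barcode_index].append(r)
    aln_by_bc = {}
    for bi in (0, 1):
        alns, _ = align_to_tags(merged_by_bc[bi], tags)
        aln_by_bc[bi] = alns

    # Standard arm inputs: raw single-end reads, both barcodes pooled.
    raw_reads = _raw_reads_as_single(by_bc)
    raw_alns, _ = align_to_tags(raw_reads, tags)

    per_depth: dict = {}
    calls_out: dict = {}
    for d in config.depths:
        sub = {bi: downsample(aln_by_bc[bi], tags, d) for bi in (0, 1)}
        pu0 = build_pileup(sub[0], merged_by_bc[0], tags)
        pu1 = build_pileup(sub[1], merged_by_bc[1], tags)
        # Pooling the two barcode files before strict calling == summing
        # their per-column pileups.
        pooled = pu0 + pu1

        list_a = call_list_a(pooled, config.pele.strict)
        list_b = call_list_b(pu0, pu1, config.pele.lenient)
        pele_set = combine_pele(list_a, list_b)

        std_target = round(STANDARD_TO_OPE_DEPTH * 2 * d)
        std_alns = downsample(raw_alns, tags, std_target)
        std_pu = build_pileup(std_alns, raw_reads, tags)
        std_calls = call_variants(std_pu, config.standard)

        per_depth[d] = {
            "pele": evaluate_calls(pele_set.calls, truth),
            "orp": evaluate_calls(list_a, truth),
            "standard": evaluate_calls(std_calls, truth),
        }
        calls_out[d] = {
            "pele": pele_set.calls,
            "orp": list_a,
            "standard": std_calls,
        }

    return ExperimentReport(
        seed=seed,
        truth=truth,
        per_depth=per_depth,
        calls=calls_out,
        raw_read_budget=2 * len(pairs),
        merge_stats=mstats.as_dict(),
    )
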