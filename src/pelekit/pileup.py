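"""Tag-space alignment, pileup construction and depth truncation.

Reads are assigned to RAD tags by ungapped best-Hamming placement over
every (tag, offset, strand); the tag space is small and unique by
construction, so a general-purpose gapped aligner is unnecessary (SAM
import covers interoperability with external aligners).  ``N`` bases
are invisible: they neither match nor mismatch and contribute nothing
to depth — they were discarded upstream.

The pileup keeps, per tag column: per-base counts, per-barcode per-base
counts, and a joint (base, Phred) histogram from which per-observation
error probabilities are reconstructed exactly (merged qualities are
deterministic functions of the input profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from ._seq import (
    BASES,
    N_CODE,
    decode,
    encode,
    encode_rows,
    phred_to_prob,
    phred_to_qual,
    revcomp_codes,
)
from .readprep import MergedRead
from .refsim import RadTag

__all__ = [
    "TagAlignment",
    "PileupColumn",
    "Pileup",
    "align_to_tags",
    "build_pileup",
    "downsample",
    "import_sam",
    "export_sam",
    "write_pileup_tsv",
    "read_pileup_tsv",
]

MAX_Q = 93
_SEED_K = 20


@dataclass
class TagAlignment:
    read_id: str
    tag_id: str
    offset: int  # leftmost tag coordinate of the placement
    strand: str  # '+' read as-is, '-' read reverse-complemented onto the tag
    n_mismatch: int
    barcode_index: int
    n_bases: int = 0  # retained (non-N) bases, used for depth accounting
    read_index: int = -1  # position in the co-passed read list


@dataclass
class PileupColumn:
    tag_id: str
    offset: int
    ref_base: str
    base_counts: dict[str, int]
    obs: list[tuple[str, float]]  # (base, error_prob) per retained observation
    per_barcode_counts: dict[int, dict[str, int]]

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())


class Pileup:
    """Per-tag count arrays over all covered positions.

    Storage per tag: ``counts[4, L]``, ``bc_counts[2, 4, L]`` and a
    joint base-quality histogram ``qhist[4, MAX_Q+1, L]``.
    """

    def __init__(self, tags: Sequence[RadTag]):
        self.tags = list(tags)
        self.tag_index = {t.tag_id: i for i, t in enumerate(self.tags)}
        self.ref_codes = [encode(t.ref_seq) for t in self.tags]
        self.counts = [np.zeros((4, t.length), dtype=np.int64) for t in self.tags]
        self.bc_counts = [
            np.zeros((2, 4, t.length), dtype=np.int64) for t in self.tags
        ]
        self.qhist = [
            np.zeros((4, MAX_Q + 1, t.length), dtype=np.int64) for t in self.tags
        ]

    def __add__(self, other: "Pileup") -> "Pileup":
        """Column-wise sum of two pileups over the same tag space."""
        if [t.tag_id for t in self.tags] != [t.tag_id for t in other.tags]:
            raise ValueError("pileups cover different tag spaces")
        out = Pileup(self.tags)
        for ti in range(len(self.tags)):
            out.counts[ti] = self.counts[ti] + other.counts[ti]
            out.bc_counts[ti] = self.bc_counts[ti] + other.bc_counts[ti]
            out.qhist[ti] = self.qhist[ti] + other.qhist[ti]
        return out

    # -- accessors ---------------------------------------------------------
    def depth(self, tag_id: str, offset: int) -> int:
        ti = self.tag_index[tag_id]
        return int(self.counts[ti][:, offset].sum())

    def base_count(self, tag_id: str, offset: int, base: str) -> int:
        ti = self.tag_index[tag_id]
        return int(self.counts[ti][BASES.index(base), offset])

    def n_covered_columns(self) -> int:
        return int(sum((c.sum(axis=0) > 0).sum() for c in self.counts))

    def column(self, tag_id: str, offset: int) -> PileupColumn:
        ti = self.tag_index[tag_id]
        cnt = self.counts[ti][:, offset]
        qh = self.qhist[ti][:, :, offset]
        obs: list[tuple[str, float]] = []
        for b in range(4):
            for q in np.flatnonzero(qh[b]):
                obs.extend([(BASES[b], float(phred_to_prob(q)))] * int(qh[b, q]))
        bc = {
            bi: {BASES[b]: int(self.bc_counts[ti][bi, b, offset]) for b in range(4)}
            for bi in (0, 1)
        }
        return PileupColumn(
            tag_id=tag_id,
            offset=offset,
            ref_base=self.tags[ti].ref_seq[offset],
            base_counts={BASES[b]: int(cnt[b]) for b in range(4)},
            obs=obs,
            per_barcode_counts=bc,
        )

    def covered_positions(self) -> Iterator[tuple[str, int]]:
        for ti, t in enumerate(self.tags):
            for off in np.flatnonzero(self.counts[ti].sum(axis=0) > 0):
                yield t.tag_id, int(off)

    def total_depth(self) -> int:
        return int(sum(c.sum() for c in self.counts))


# ---------------------------------------------------------------------------
# Alignment


class _TagIndex:
    """Exact k-mer seed index over the forward tag sequences."""

    def __init__(self, tags: Sequence[RadTag], k: int = _SEED_K):
        self.tags = list(tags)
        self.k = k
        self.codes = [encode(t.ref_seq) for t in tags]
        self.index: dict[int, list[tuple[int, int]]] = {}
        for ti, c in enumerate(self.codes):
            for off in range(len(c) - k + 1):
                key = self._pack(c[off : off + k])
                self.index.setdefault(key, []).append((ti, off))

    @staticmethod
    def _pack(window: np.ndarray) -> int:
        v = 0
        for b in window:
            v = (v << 2) | int(b)
        return v

    def seeds(self, codes: np.ndarray) -> set[tuple[int, int]]:
        """Candidate (tag_index, read_offset_on_tag) placements."""
        k = self.k
        cands: set[tuple[int, int]] = set()
        for pos in range(0, max(1, len(codes) - k + 1), k):
            win = codes[pos : pos + k]
            if len(win) < k or (win == N_CODE).any():
                continue
            for ti, off in self.index.get(self._pack(win), ()):
                cands.add((ti, off - pos))
        return cands


def _verify(codes: np.ndarray, tag_codes: np.ndarray, off: int) -> Optional[int]:
    if off < 0 or off + len(codes) > len(tag_codes):
        return None
    seg = tag_codes[off : off + len(codes)]
    return int(np.count_nonzero((codes != seg) & (codes != N_CODE)))


def _place_read(
    codes: np.ndarray, idx: _TagIndex, max_mismatches: int
) -> Optional[tuple[int, int, str, int]]:
    """Best (tag_i, offset, strand, n_mismatch) or None (unaligned/tie)."""
    rc = revcomp_codes(codes)
    cands: list[tuple[int, int, str]] = []
    cands += [(ti, off, "+") for ti, off in idx.seeds(codes)]
    cands += [(ti, off, "-") for ti, off in idx.seeds(rc)]
    if not cands:
        # Exhaustive fallback for reads whose every seed window is broken.
        for ti, tc in enumerate(idx.codes):
            for strand, q in (("+", codes), ("-", rc)):
                for off in range(len(tc) - len(q) + 1):
                    cands.append((ti, off, strand))
    best: Optional[tuple[int, int, str, int]] = None
    best_set: list[tuple[int, int, str, int]] = []
    for ti, off, strand in sorted(set(cands)):
        q = codes if strand == "+" else revcomp_codes(codes)
        mm = _verify(q, idx.codes[ti], off)
        if mm is None:
            continue
        if best is None or mm < best[3]:
            best = (ti, off, strand, mm)
            best_set = [best]
        elif mm == best[3]:
            best_set.append((ti, off, strand, mm))
    if best is None or best[3] > max_mismatches:
        return None
    if len({b[0] for b in best_set}) > 1:
        return None  # equidistant to two tags -> dropped
    return best_set[0]


def align_to_tags(
    merged: Sequence[MergedRead],
    tags: Sequence[RadTag],
    max_mismatches: int = 5,
) -> tuple[list[TagAlignment], int]:
    """Place each read at its best ungapped position in tag space.

    Reads whose best placement exceeds ``max_mismatches``, or with tied
    best placements on different tags, are dropped and counted.
    Identical sequences share one placement via a cache.
    """
    if not tags:
        raise ValueError("tag list must be non-empty")
    idx = _TagIndex(tags)
    cache: dict[str, Optional[tuple[int, int, str, int]]] = {}
    out: list[TagAlignment] = []
    unaligned = 0
    for ri, r in enumerate(merged):
        hit = cache.get(r.seq, "?")
        if hit == "?":
            hit = _place_read(encode(r.seq), idx, max_mismatches)
            cache[r.seq] = hit
        if hit is None:
            unaligned += 1
            continue
        ti, off, strand, mm = hit
        out.append(
            TagAlignment(
                read_id=r.read_id,
                tag_id=tags[ti].tag_id,
                offset=off,
                strand=strand,
                n_mismatch=mm,
                barcode_index=r.barcode_index,
                n_bases=r.n_bases,
                read_index=ri,
            )
        )
    return out, unaligned


# ---------------------------------------------------------------------------
# Pileup construction


def build_pileup(
    alignments: Sequence[TagAlignment],
    reads: Sequence[MergedRead],
    tags: Sequence[RadTag],
) -> Pileup:
    """Accumulate every retained (non-N) base into its tag column.

    The per-observation error probability is taken from the read's
    Phred value at that base.  Per-barcode counts are maintained.
    """
    pu = Pileup(tags)
    groups: dict[tuple[int, int, str, int, int], list[TagAlignment]] = {}
    for a in alignments:
        ti = pu.tag_index[a.tag_id]
        r = reads[a.read_index]
        if len(r.seq) + a.offset > tags[ti].length or a.offset < 0:
            raise ValueError(
                f"alignment of {a.read_id} exceeds tag bounds on {a.tag_id}"
            )
        bi = a.barcode_index if a.barcode_index in (0, 1) else 0
        groups.setdefault((ti, a.offset, a.strand, len(r.seq), bi), []).append(a)
    for (ti, off, strand, rlen, bi), alns in groups.items():
        L = tags[ti].length
        S = encode_rows((reads[a.read_index].seq for a in alns), rlen)
        Q = np.empty((len(alns), rlen), dtype=np.int64)
        for i, a in enumerate(alns):
            Q[i] = reads[a.read_index].qual
        if strand == "-":
            S = revcomp_codes(S)
            Q = Q[:, ::-1]
        mask = S != N_CODE
        cols = np.broadcast_to(np.arange(rlen) + off, S.shape)
        flat_bc = S[mask].astype(np.int64) * L + cols[mask]
        pu.counts[ti] += np.bincount(flat_bc, minlength=4 * L).reshape(4, L)
        pu.bc_counts[ti][bi] += np.bincount(flat_bc, minlength=4 * L).reshape(4, L)
        qcap = np.clip(Q[mask], 0, MAX_Q)
        flat_q = (S[mask].astype(np.int64) * (MAX_Q + 1) + qcap) * L + cols[mask]
        pu.qhist[ti] += np.bincount(
            flat_q, minlength=4 * (MAX_Q + 1) * L
        ).reshape(4, MAX_Q + 1, L)
    return pu


def downsample(
    alignments: Sequence[TagAlignment],
    tags: Sequence[RadTag],
    target_depth: int,
    seed: Optional[int] = None,
    shuffle: bool = False,
) -> list[TagAlignment]:
    """Truncate the alignment stream to a target mean depth per tag.

    Reads are retained in input order until each tag's mean covered
    depth (retained bases / tag length) first reaches ``target_depth``
    — a truncation, not a random subsample.  ``seed`` is used only when
    ``shuffle`` is requested.
    """
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    alns = list(alignments)
    if shuffle:
        rng = np.random.default_rng(seed)
        rng.shuffle(alns)
    tag_len = {t.tag_id: t.length for t in tags}
    budget = {t.tag_id: target_depth * t.length for t in tags}
    acc: dict[str, int] = {t.tag_id: 0 for t in tags}
    out: list[TagAlignment] = []
    for a in alns:
        if acc[a.tag_id] < budget[a.tag_id]:
            out.append(a)
            acc[a.tag_id] += a.n_bases if a.n_bases else tag_len[a.tag_id]
    return out


# ---------------------------------------------------------------------------
# SAM interoperability (text SAM only, ungapped records)


def export_sam(
    alignments: Sequence[TagAlignment],
    reads: Sequence[MergedRead],
    tags: Sequence[RadTag],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for t in tags:
            fh.write(f"@SQ\tSN:{t.tag_id}\tLN:{t.length}\n")
        for a in alignments:
            r = reads[a.read_index]
            flag = 16 if a.strand == "-" else 0
            seq = r.seq
            qual = phred_to_qual(np.asarray(r.qual))
            if a.strand == "-":
                seq = decode(revcomp_codes(encode(seq)))
                qual = qual[::-1]
            fh.write(
                f"{a.read_id}\t{flag}\t{a.tag_id}\t{a.offset + 1}\t60\t"
                f"{len(seq)}M\t*\t0\t0\t{seq}\t{qual}\tBC:i:{a.barcode_index}\n"
            )


def import_sam(path, tags: Sequence[RadTag]) -> tuple[list[TagAlignment], int]:
    """Convert mapped, primary, ungapped SAM records to alignments.

    Records with indels or clips are dropped and counted (second return
    value).  Malformed lines raise with the offending line number.
    """
    import pysam

    tag_len = {t.tag_id: t.length for t in tags}
    out: list[TagAlignment] = []
    dropped = 0
    try:
        af = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed SAM file {path}: {exc}") from exc
    with af:
        for lineno, rec in enumerate(af, start=1):
            try:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                cig = rec.cigartuples or []
                if any(op not in (0, 7, 8) for op, _ in cig):
                    dropped += 1
                    continue
                if rec.reference_name not in tag_len:
                    dropped += 1
                    continue
                seq = rec.query_sequence or ""
                bi = rec.get_tag("BC") if rec.has_tag("BC") else 0
                out.append(
                    TagAlignment(
                        read_id=rec.query_name,
                        tag_id=rec.reference_name,
                        offset=rec.reference_start,
                        strand="-" if rec.is_reverse else "+",
                        n_mismatch=0,
                        barcode_index=int(bi),
                        n_bases=sum(1 for c in seq if c != "N"),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"malformed SAM record at line {lineno}: {exc}")
    return out, dropped


# ---------------------------------------------------------------------------
# TSV dump / restore


def write_pileup_tsv(pu: Pileup, path) -> None:
    """Covered columns as TSV with per-barcode counts and the joint
    base:qual histogram (lossless restore via ``read_pileup_tsv``)."""
    with open(path, "w") as fh:
        fh.write(
            "tag_id\toffset\tref\tA\tC\tG\tT\tdepth\tbc0_acgt\tbc1_acgt\tqhist\n"
        )
        for tag_id, off in pu.covered_positions():
            ti = pu.tag_index[tag_id]
            cnt = pu.counts[ti][:, off]
            bc0 = ",".join(str(int(x)) for x in pu.bc_counts[ti][0, :, off])
            bc1 = ",".join(str(int(x)) for x in pu.bc_counts[ti][1, :, off])
            qh = pu.qhist[ti][:, :, off]
            items = [
                f"{BASES[b]}:{q}:{int(qh[b, q])}"
                for b in range(4)
                for q in np.flatnonzero(qh[b])
            ]
            fh.write(
                f"{tag_id}\t{off}\t{pu.tags[ti].ref_seq[off]}\t"
                + "\t".join(str(int(c)) for c in cnt)
                + f"\t{int(cnt.sum())}\t{bc0}\t{bc1}\t" + ";".join(items) + "\n"
            )


def read_pileup_tsv(path, tags: Sequence[RadTag]) -> Pileup:
    pu = Pileup(tags)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("tag_id"):
            raise ValueError("not a pileup TSV")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            tag_id, off = f[0], int(f[1])
            ti = pu.tag_index[tag_id]
            for b in range(4):
                pu.counts[ti][b, off] = int(f[3 + b])
            for bi, col in ((0, 8), (1, 9)):
                vals = [int(x) for x in f[col].split(",")]
                pu.bc_counts[ti][bi, :, off] = vals
            if f[10]:
                for item in f[10].split(";"):
                    b, q, c = item.split(":")
                    pu.qhist[ti][BASES.index(b), int(q), off] = int(c)
    return pu
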