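"""Synthetic reference genomes, in-silico RAD digestion and truth sets.

Reduced-representation (RAD) sequencing reads only the fixed-length
segments flanking a restriction enzyme's recognition site.  This module
builds synthetic genomes with an exactly controlled number of
non-overlapping recognition sites, digests them into RAD tags (one tag
per flank, so an interior site yields two 100 bp tags), optionally
applies a second, complexity-reducing digest that destroys any tag
containing a second motif, and plants a truth set of rare alleles at
known positions and target frequencies for benchmarking.

Conventions
-----------
* Coordinates are 0-based half-open throughout; only VCF output is
  1-based.
* Tags are pure flanks: the recognition-site bases themselves are not
  part of any tag, so tag coordinates are symmetric around the site and
  site bases can never host a planted variant.
* The upstream (5') flank is reported reverse-complemented with strand
  ``-``; the downstream flank is reported forward with strand ``+``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, decode, encode, revcomp

__all__ = [
    "SyntheticGenome",
    "RadTag",
    "TruthVariant",
    "find_sites",
    "make_genome",
    "digest_tags",
    "apply_second_digest",
    "make_truth",
    "write_genome_fasta",
    "write_tags_fasta",
    "write_tags_bed",
    "write_truth_vcf",
    "write_truth_tsv",
]


@dataclass
class SyntheticGenome:
    """A synthetic reference with a known restriction-site census.

    ``site_positions`` is exactly the ordered set of all occurrences of
    ``motif`` in ``sequence``; occurrences are non-overlapping by
    construction.
    """

    genome_id: str
    sequence: str
    motif: str
    site_positions: list[int] = field(default_factory=list)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class RadTag:
    """One fixed-length reference segment flanking a restriction site."""

    tag_id: str
    genome_pos: int
    strand: str  # '+' downstream flank, '-' upstream flank (rev-comp'd)
    length: int
    ref_seq: str


@dataclass(frozen=True)
class TruthVariant:
    """A planted rare allele used for simulation and benchmarking."""

    tag_id: str
    offset: int
    ref_base: str
    alt_base: str
    target_af: float

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.tag_id, self.offset, self.alt_base)


def find_sites(sequence: str, motif: str) -> list[int]:
    """All 0-based offsets where ``motif`` occurs exactly, ascending.

    Overlapping occurrences are reported; spacing constraints belong to
    the caller.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if len(motif) >= len(sequence):
        raise ValueError("motif must be shorter than the sequence")
    out: list[int] = []
    i = sequence.find(motif)
    while i != -1:
        out.append(i)
        i = sequence.find(motif, i + 1)
    return out


def _random_fill(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def make_genome(
    length: int,
    gc: float = 0.5,
    motif: str = "CCTGCAGG",
    n_sites: int = 0,
    min_spacing: int = 300,
    seed: int = 0,
    genome_id: str = "synthetic",
) -> SyntheticGenome:
    """Generate a genome containing exactly ``n_sites`` motif occurrences.

    Sites are placed uniformly at random subject to a pairwise start
    separation of at least ``len(motif) + min_spacing`` bases (so sites
    are non-overlapping and flanks of up to ``min_spacing`` bases never
    collide) and at least ``min_spacing`` bases from either genome end.
    Accidental motif occurrences created by the random fill are
    destroyed by patching a single base; the scan/patch cycle is bounded
    at 100 rounds.

    Deterministic for a fixed ``seed``.
    """
    m = len(motif)
    if not motif or any(b not in BASES for b in motif):
        raise ValueError("motif must be a non-degenerate string over ACGT")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    if length < n_sites * (m + min_spacing):
        raise ValueError(
            f"length {length} cannot host {n_sites} sites of {m} bp with "
            f"spacing {min_spacing}"
        )
    rng = np.random.default_rng(seed)
    seq = _random_fill(rng, length, gc)
    motif_codes = encode(motif)

    positions: list[int] = []
    if n_sites > 0:
        step = m + min_spacing
        margin = min_spacing
        slack = (length - 2 * margin - m) - (n_sites - 1) * step
        if slack < 0:
            raise ValueError(
                f"cannot place {n_sites} sites with spacing {min_spacing} and "
                f"end margin {margin} in a {length} bp genome"
            )
        # Order-statistics placement: no rejection loop needed.
        offs = np.sort(rng.integers(0, slack + 1, size=n_sites))
        positions = [int(margin + offs[i] + i * step) for i in range(n_sites)]
        for p in positions:
            seq[p : p + m] = motif_codes

    planted = set(positions)
    planted_iv = [(p, p + m) for p in positions]
    for _round in range(100):
        found = find_sites(decode(seq), motif)
        extras = [p for p in found if p not in planted]
        if not extras:
            break
        for p in extras:
            # Patch one base of the accidental occurrence that lies outside
            # every planted site, preferring the middle of the occurrence.
            cand = sorted(range(p, p + m), key=lambda i: abs(i - (p + m // 2)))
            pos = next(
                (i for i in cand if not any(a <= i < b for a, b in planted_iv)),
                None,
            )
            if pos is None:  # pragma: no cover - cannot happen for extras
                continue
            forbidden = motif_codes[pos - p]
            choices = [c for c in range(4) if c != forbidden and c != seq[pos]]
            seq[pos] = choices[int(rng.integers(len(choices)))]
    else:  # pragma: no cover - bounded-retry guard
        raise RuntimeError(
            "could not remove accidental motif occurrences within 100 rounds"
        )

    genome = SyntheticGenome(
        genome_id=genome_id,
        sequence=decode(seq),
        motif=motif,
        site_positions=sorted(planted),
    )
    assert find_sites(genome.sequence, motif) == genome.site_positions
    return genome


def digest_tags(genome: SyntheticGenome, tag_len: int = 100) -> list[RadTag]:
    """In-silico digestion: two flanking tags per interior site.

    For a site starting at ``p`` the upstream tag covers
    ``[p - tag_len, p)`` (reported reverse-complemented, strand ``-``)
    and the downstream tag covers ``[p + m, p + m + tag_len)`` (strand
    ``+``).  Sites too close to a genome end yield only the feasible
    flank.
    """
    if tag_len <= 0:
        raise ValueError("tag_len must be positive")
    m = len(genome.motif)
    L = len(genome.sequence)
    tags: list[RadTag] = []
    for i, p in enumerate(genome.site_positions):
        if p - tag_len >= 0:
            sub = genome.sequence[p - tag_len : p]
            tags.append(
                RadTag(
                    tag_id=f"{genome.genome_id}_s{i:04d}u",
                    genome_pos=p - tag_len,
                    strand="-",
                    length=tag_len,
                    ref_seq=revcomp(sub),
                )
            )
        if p + m + tag_len <= L:
            sub = genome.sequence[p + m : p + m + tag_len]
            tags.append(
                RadTag(
                    tag_id=f"{genome.genome_id}_s{i:04d}d",
                    genome_pos=p + m,
                    strand="+",
                    length=tag_len,
                    ref_seq=sub,
                )
            )
    return tags


def apply_second_digest(tags: list[RadTag], motif2: str) -> list[RadTag]:
    """Keep only tags whose sequence lacks any ``motif2`` occurrence.

    Models a second, complexity-reducing digestion: tags carrying the
    second recognition site are cut and lost from the library.
    Idempotent by construction.
    """
    if not motif2:
        raise ValueError("motif2 must be non-empty")
    return [t for t in tags if motif2 not in t.ref_seq]


def make_truth(
    tags: list[RadTag],
    n_snps: int,
    target_af,
    seed: int = 0,
    min_offset_margin: int = 5,
) -> list[TruthVariant]:
    """Plant ``n_snps`` rare alleles on distinct (tag, offset) pairs.

    Offsets are drawn uniformly at least ``min_offset_margin`` bases
    from either tag end; the alternate base is uniform over the three
    non-reference bases.  ``target_af`` may be a scalar (shared by all
    variants) or a sequence assigned round-robin.  Deterministic for a
    fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    eligible: list[tuple[int, int]] = []
    for ti, t in enumerate(tags):
        lo, hi = min_offset_margin, t.length - min_offset_margin
        eligible.extend((ti, o) for o in range(lo, hi))
    if n_snps > len(eligible):
        raise ValueError(
            f"n_snps {n_snps} exceeds the {len(eligible)} eligible positions"
        )
    afs = np.atleast_1d(np.asarray(target_af, dtype=float))
    if np.any((afs <= 0) | (afs > 1)):
        raise ValueError("target allele frequencies must lie in (0, 1]")
    picks = rng.choice(len(eligible), size=n_snps, replace=False)
    out: list[TruthVariant] = []
    for j, idx in enumerate(sorted(int(i) for i in picks)):
        ti, off = eligible[idx]
        ref = tags[ti].ref_seq[off]
        alts = [b for b in BASES if b != ref]
        alt = alts[int(rng.integers(3))]
        out.append(
            TruthVariant(
                tag_id=tags[ti].tag_id,
                offset=off,
                ref_base=ref,
                alt_base=alt,
                target_af=float(afs[j % len(afs)]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Writers


def write_genome_fasta(genome: SyntheticGenome, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(genome.sequence), id=genome.genome_id, description="")],
        str(path),
        "fasta",
    )


def write_tags_fasta(tags: list[RadTag], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(t.ref_seq), id=t.tag_id, description="") for t in tags],
        str(path),
        "fasta",
    )


def write_tags_bed(tags: list[RadTag], genome_id: str, path) -> None:
    """Tag intervals on the genome, BED (0-based half-open)."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(
                f"{genome_id}\t{t.genome_pos}\t{t.genome_pos + t.length}\t"
                f"{t.tag_id}\t0\t{t.strand}\n"
            )


def write_truth_vcf(truth: list[TruthVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=TAF,Number=1,Type=Float,Description='
            '"Target allele frequency of the planted variant">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in truth:
            fh.write(
                f"{v.tag_id}\t{v.offset + 1}\t.\t{v.ref_base}\t{v.alt_base}"
                f"\t.\tPASS\tTAF={v.target_af:g}\n"
            )


def write_truth_tsv(truth: list[TruthVariant], path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_id\toffset\tref\talt\ttarget_af\n")
        for v in truth:
            fh.write(
                f"{v.tag_id}\t{v.offset}\t{v.ref_base}\t{v.alt_base}\t"
                f"{v.target_af:g}\n"
            )
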