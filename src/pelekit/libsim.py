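"""Pooled-library preparation and paired-end sequencing simulator.

Emulates the error structure that the downstream filters exploit:

* each DNA molecule is ligated to one of two inline barcodes, so a PCR
  error arising in one molecule's amplification lineage is *confined to
  a single barcode* and appears *in both mates* of every read pair from
  that molecule;
* sequencing errors are drawn independently per read base, so they are
  (almost surely) seen by only one mate of a pair;
* PCR errors are biased toward C>T transitions when classified on the
  pyrimidine strand (G>A counts as C>T), mimicking deamination-driven
  polymerase error spectra.

Rather than simulating the full PCR tree, each sequenced fragment draws
an independent error lineage of ``pcr_cycles`` duplications.  This
drops duplicate-family correlation (two fragments sharing one early
error) but preserves the two properties the filters act on: barcode
confinement and mate agreement.

Randomness: one PRNG stream per operation, seeded by
``(config.seed, operation id)``, so stages are reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import (
    BASES,
    decode,
    decode_rows,
    encode,
    phred_to_qual,
    prob_to_phred,
    revcomp_codes,
)
from .refsim import RadTag, TruthVariant

__all__ = [
    "SeqErrorProfile",
    "LibraryConfig",
    "MoleculeRecord",
    "ReadPairRecord",
    "simulate_molecules",
    "amplify_pcr",
    "sequence_pairs",
    "write_fastq",
    "read_fastq_pairs",
    "write_provenance",
]

_OP_IDS = {"molecules": 11, "pcr": 22, "sequence": 33}

_CHUNK = 65536


@dataclass(frozen=True)
class SeqErrorProfile:
    """Per-position sequencing error curve with matching Phred values.

    Quality characters are deterministic given the profile
    (``q = round(-10 log10 p)``), so a consumer can reconstruct the
    error probabilities exactly from the FASTQ.
    """

    probs: tuple[float, ...]

    @classmethod
    def flat(cls, p: float, length: int = 1) -> "SeqErrorProfile":
        return cls(probs=(float(p),) * max(1, length))

    def prob_array(self, length: int) -> np.ndarray:
        p = np.asarray(self.probs, dtype=float)
        if len(p) < length:
            p = np.concatenate([p, np.full(length - len(p), p[-1])])
        return p[:length]

    def phred_array(self, length: int) -> np.ndarray:
        p = self.prob_array(length)
        with np.errstate(divide="ignore"):
            q = np.where(p > 0, np.rint(prob_to_phred(p)), 93.0)
        return np.clip(q, 0, 93).astype(np.int64)


@dataclass(frozen=True)
class LibraryConfig:
    sample_id: str = "sample"
    barcodes: tuple[str, str] = ("ACGTAC", "TGACTG")
    barcode_mix: float = 0.5
    pcr_cycles: int = 18
    pcr_error_rate: float = 1e-5
    ct_bias: float = 0.8
    insert_len_mean: int = 100
    insert_len_jitter: int = 0
    read_len: int = 100
    seq_error_profile: SeqErrorProfile = field(
        default_factory=lambda: SeqErrorProfile.flat(1e-3)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        b0, b1 = self.barcodes
        if len(b0) != len(b1) or b0 == b1:
            raise ValueError("barcodes must be two distinct strings of equal length")
        if sum(a != b for a, b in zip(b0, b1)) < 2:
            raise ValueError("barcodes must differ in at least 2 positions")
        if not 0.0 < self.barcode_mix < 1.0:
            raise ValueError("barcode_mix must be in (0, 1)")
        for r in (self.pcr_error_rate, self.ct_bias):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.read_len <= 0:
            raise ValueError("read_len must be positive")


@dataclass
class MoleculeRecord:
    molecule_id: int
    tag_id: str
    haplotype: list[tuple[int, str]]  # (offset, alt) true alleles carried
    barcode_index: int
    pcr_errors: list[tuple[int, str, str]]  # (offset, from, to)
    insert_len: int


@dataclass
class ReadPairRecord:
    read_id: str
    barcode: str  # the assigned barcode (read 1 prefix, pre-error)
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    source_molecule_id: int


def _rng(config: LibraryConfig, op: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(config.seed) & 0x7FFFFFFF, _OP_IDS[op]))
    )


def simulate_molecules(
    tags: list[RadTag],
    truth: list[TruthVariant],
    n_molecules: int,
    config: LibraryConfig,
) -> list[MoleculeRecord]:
    """Draw molecules: tag uniform, alleles Bernoulli(target_af), barcode
    Bernoulli(barcode_mix), insert length uniform in mean +/- jitter
    (clamped to the tag length)."""
    if not tags:
        raise ValueError("tag list must be non-empty")
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    rng = _rng(config, "molecules")
    n_tags = len(tags)
    tag_idx = rng.integers(0, n_tags, size=n_molecules)
    barcode = (rng.random(n_molecules) >= config.barcode_mix).astype(np.int8)
    lo = config.insert_len_mean - config.insert_len_jitter
    hi = config.insert_len_mean + config.insert_len_jitter
    ins = rng.integers(lo, hi + 1, size=n_molecules)
    tag_lens = np.array([t.length for t in tags])
    ins = np.minimum(np.maximum(ins, 1), tag_lens[tag_idx])

    # Sparse haplotype assignment: per truth variant, Bernoulli over the
    # molecules of its tag.
    haplo: dict[int, list[tuple[int, str]]] = {}
    tag_pos = {t.tag_id: i for i, t in enumerate(tags)}
    by_tag: dict[int, np.ndarray] = {}
    for v in truth:
        ti = tag_pos[v.tag_id]
        if ti not in by_tag:
            by_tag[ti] = np.flatnonzero(tag_idx == ti)
        idx = by_tag[ti]
        carriers = idx[rng.random(idx.size) < v.target_af]
        for mi in carriers:
            haplo.setdefault(int(mi), []).append((v.offset, v.alt_base))

    tag_ids = [t.tag_id for t in tags]
    return [
        MoleculeRecord(
            molecule_id=i,
            tag_id=tag_ids[tag_idx[i]],
            haplotype=sorted(haplo.get(i, [])),
            barcode_index=int(barcode[i]),
            pcr_errors=[],
            insert_len=int(ins[i]),
        )
        for i in range(n_molecules)
    ]


def _true_insert_codes(mol: MoleculeRecord, tag_codes: np.ndarray) -> np.ndarray:
    ins = tag_codes[: mol.insert_len].copy()
    for off, alt in mol.haplotype:
        if off < mol.insert_len:
            ins[off] = BASES.index(alt)
    return ins


def amplify_pcr(
    molecules: list[MoleculeRecord],
    tags: list[RadTag],
    config: LibraryConfig,
) -> list[MoleculeRecord]:
    """Populate ``pcr_errors`` from an independent duplication lineage.

    Each fragment accumulates ``Binomial(pcr_cycles * insert_len,
    pcr_error_rate)`` errors.  With probability ``ct_bias`` an error is
    a C>T-class event (C->T or G->A) at a uniformly chosen C/G position
    of the fragment; otherwise it is one of the remaining substitutions
    at a uniformly chosen position.  Errors live on the molecule, hence
    appear identically in both mates and only under that molecule's
    barcode.
    """
    rng = _rng(config, "pcr")
    if config.pcr_error_rate == 0:
        return molecules
    tag_code = {t.tag_id: encode(t.ref_seq) for t in tags}
    ins_lens = np.array([m.insert_len for m in molecules])
    n_err = rng.binomial(config.pcr_cycles * ins_lens, config.pcr_error_rate)
    for mi in np.flatnonzero(n_err):
        mol = molecules[int(mi)]
        seq = _true_insert_codes(mol, tag_code[mol.tag_id])
        for _ in range(int(n_err[mi])):
            if rng.random() < config.ct_bias:
                cg = np.flatnonzero((seq == 1) | (seq == 2))
                if cg.size:
                    pos = int(cg[int(rng.integers(cg.size))])
                    src = int(seq[pos])
                    dst = 3 if src == 1 else 0  # C->T, G->A
                else:  # no pyrimidine-class site available in this insert
                    pos = int(rng.integers(mol.insert_len))
                    src = int(seq[pos])
                    dst = int((src + 1 + rng.integers(3)) % 4)
            else:
                pos = int(rng.integers(mol.insert_len))
                src = int(seq[pos])
                if src == 1:  # C: exclude the C>T-class target T
                    dst = int(rng.choice([0, 2]))
                elif src == 2:  # G: exclude A
                    dst = int(rng.choice([1, 3]))
                else:
                    dst = int((src + 1 + rng.integers(3)) % 4)
            mol.pcr_errors.append((pos, BASES[src], BASES[dst]))
            seq[pos] = dst
    return molecules


def sequence_pairs(
    molecules: list[MoleculeRecord],
    tags: list[RadTag],
    config: LibraryConfig,
) -> list[ReadPairRecord]:
    """Sequence each molecule once as an overlapping read pair.

    Read 1 is the barcode followed by the 5'->3' insert prefix (up to
    ``read_len`` insert bases); read 2 is the reverse complement of the
    insert suffix.  Each base is flipped to a uniform different base
    with the per-position probability of ``seq_error_profile``; quality
    characters encode the profile's Phred values.  Inserts shorter than
    ``read_len`` yield shorter reads (padded only by the insert).
    """
    rng = _rng(config, "sequence")
    tag_code = {t.tag_id: encode(t.ref_seq) for t in tags}
    bc_codes = [encode(b) for b in config.barcodes]
    bc_len = len(config.barcodes[0])
    profile = config.seq_error_profile

    pairs: list[ReadPairRecord] = [None] * len(molecules)  # type: ignore
    order = np.argsort([m.insert_len for m in molecules], kind="stable")
    prefix = f"{config.sample_id}:"

    start = 0
    while start < len(order):
        L = molecules[order[start]].insert_len
        end = start
        while end < len(order) and molecules[order[end]].insert_len == L:
            end += 1
        for c0 in range(start, end, _CHUNK):
            chunk = order[c0 : min(end, c0 + _CHUNK)]
            n = len(chunk)
            rl = min(config.read_len, L)
            inserts = np.empty((n, L), dtype=np.uint8)
            bcs = np.empty(n, dtype=np.int8)
            for row, mi in enumerate(chunk):
                mol = molecules[int(mi)]
                seq = tag_code[mol.tag_id][:L].copy()
                for off, alt in mol.haplotype:
                    if off < L:
                        seq[off] = BASES.index(alt)
                for off, _src, dst in mol.pcr_errors:
                    seq[off] = BASES.index(dst)
                inserts[row] = seq
                bcs[row] = mol.barcode_index
            r1 = np.empty((n, bc_len + rl), dtype=np.uint8)
            for b in (0, 1):
                r1[bcs == b, :bc_len] = bc_codes[b]
            r1[:, bc_len:] = inserts[:, :rl]
            r2 = revcomp_codes(inserts[:, L - rl :])
            for mat in (r1, r2):
                w = mat.shape[1]
                perr = profile.prob_array(w)
                hits = rng.random((n, w), dtype=np.float32) < perr[None, :]
                if hits.any():
                    shift = rng.integers(1, 4, size=int(hits.sum()))
                    mat[hits] = (mat[hits] + shift) % 4
            q1 = phred_to_qual(profile.phred_array(r1.shape[1]))
            q2 = phred_to_qual(profile.phred_array(r2.shape[1]))
            s1_rows = decode_rows(r1)
            s2_rows = decode_rows(r2)
            for row, mi in enumerate(chunk):
                mol = molecules[int(mi)]
                pairs[int(mi)] = ReadPairRecord(
                    read_id=f"{prefix}{mol.molecule_id}",
                    barcode=config.barcodes[mol.barcode_index],
                    seq1=s1_rows[row],
                    qual1=q1,
                    seq2=s2_rows[row],
                    qual2=q2,
                    source_molecule_id=mol.molecule_id,
                )
        start = end
    return pairs


def write_fastq(pairs: list[ReadPairRecord], path1, path2) -> None:
    """Standard 4-line FASTQ, Phred+33, /1 and /2 mate suffixes."""
    try:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for p in pairs:
                f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
                f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")
    except OSError as exc:  # pragma: no cover - I/O failure path
        raise OSError(f"failed writing FASTQ to {path1!r}/{path2!r}: {exc}") from exc


def read_fastq_pairs(path1, path2) -> list[ReadPairRecord]:
    def _records(path):
        out = []
        with open(path) as fh:
            while True:
                head = fh.readline()
                if not head:
                    break
                seq = fh.readline().strip()
                fh.readline()
                qual = fh.readline().strip()
                rid = head.strip().lstrip("@")
                if rid.endswith("/1") or rid.endswith("/2"):
                    rid = rid[:-2]
                out.append((rid, seq, qual))
        return out

    r1s, r2s = _records(path1), _records(path2)
    if len(r1s) != len(r2s):
        raise ValueError("mate files differ in record count")
    pairs = []
    for (id1, s1, q1), (id2, s2, q2) in zip(r1s, r2s):
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
        pairs.append(
            ReadPairRecord(
                read_id=id1, barcode="", seq1=s1, qual1=q1, seq2=s2, qual2=q2,
                source_molecule_id=-1,
            )
        )
    return pairs


def write_provenance(
    molecules: list[MoleculeRecord], path, sample_id: str = "sample"
) -> None:
    """Sidecar TSV tying each read pair to its molecule's ground truth."""
    with open(path, "w") as fh:
        fh.write("read_id\tmolecule_id\ttag_id\tbarcode_index\tinsert_len\t"
                 "haplotype\tpcr_errors\n")
        for m in molecules:
            hap = ";".join(f"{o}>{a}" for o, a in m.haplotype)
            pcr = ";".join(f"{o}:{s}>{d}" for o, s, d in m.pcr_errors)
            fh.write(
                f"{sample_id}:{m.molecule_id}\t{m.molecule_id}\t{m.tag_id}\t"
                f"{m.barcode_index}\t{m.insert_len}\t{hap}\t{pcr}\n"
            )
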