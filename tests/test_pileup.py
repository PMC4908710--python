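"""Tag-space alignment, pileup bookkeeping, truncation, SAM round trip."""

import numpy as np
import pytest

from conftest import simulate_library
from pelekit._seq import revcomp
from pelekit.pileup import (
    Pileup,
    align_to_tags,
    build_pileup,
    downsample,
    export_sam,
    import_sam,
    read_pileup_tsv,
    write_pileup_tsv,
)
from pelekit.readprep import MergedRead, demultiplex, merge_stream
from pelekit.refsim import RadTag


def mk_read(seq, rid="r", bc=0, qual=60):
    return MergedRead(
        read_id=rid, barcode_index=bc, seq=seq,
        qual=np.full(len(seq), qual), n_masked_mismatch=0, n_trimmed_overhang=0,
    )


def rand_tag(tid, seed, length=100):
    rng = np.random.default_rng(seed)
    return RadTag(tid, 0, "+", length,
                  "".join(rng.choice(list("ACGT"), size=length)))


class TestAlign:
    def test_planted_placement_recovered(self):
        tag = rand_tag("t0", 1)
        read = mk_read(tag.ref_seq[3:83])
        alns, un = align_to_tags([read], [tag])
        assert un == 0
        a = alns[0]
        assert (a.tag_id, a.offset, a.strand, a.n_mismatch) == ("t0", 3, "+", 0)

    def test_reverse_strand_placement(self):
        tag = rand_tag("t0", 2)
        read = mk_read(revcomp(tag.ref_seq[10:90]))
        alns, un = align_to_tags([read], [tag])
        assert un == 0
        assert (alns[0].offset, alns[0].strand) == (10, "-")

    def test_tie_between_tags_dropped(self):
        tag1 = rand_tag("t1", 3)
        tag2 = RadTag("t2", 0, "+", 100, tag1.ref_seq)  # duplicate sequence
        read = mk_read(tag1.ref_seq[:60])
        alns, un = align_to_tags([read], [tag1, tag2])
        assert alns == [] and un == 1

    def test_excess_mismatches_dropped(self):
        tag = rand_tag("t0", 4)
        seq = list(tag.ref_seq[:60])
        for i in (5, 15, 25, 35, 45, 55):
            seq[i] = "A" if seq[i] != "A" else "C"
        alns, un = align_to_tags([mk_read("".join(seq))], [tag],
                                 max_mismatches=3)
        assert un == 1

    def test_n_bases_ignored_by_matching(self):
        tag = rand_tag("t0", 5)
        seq = "N" * 5 + tag.ref_seq[5:80]
        alns, _ = align_to_tags([mk_read(seq)], [tag])
        assert alns[0].n_mismatch == 0
        assert alns[0].n_bases == 75

    def test_simulated_reads_match_provenance(self, small_tags, small_truth):
        mols, pairs, cfg = simulate_library(small_tags, small_truth, 10_000,
                                            seed=21)
        by_bc, _ = demultiplex(pairs, cfg.barcodes)
        merged, _ = merge_stream(by_bc)
        alns, un = align_to_tags(merged, small_tags)
        tag_of = {m.molecule_id: m.tag_id for m in mols}
        ok = sum(
            1 for a in alns
            if tag_of[int(a.read_id.split(":")[1])] == a.tag_id and a.offset == 0
        )
        assert (len(alns) - un) and ok / len(alns) >= 0.999


class TestBuildPileup:
    def test_single_perfect_read_hundred_columns(self):
        tag = rand_tag("t0", 6)
        read = mk_read(tag.ref_seq)
        alns, _ = align_to_tags([read], [tag])
        pu = build_pileup(alns, [read], [tag])
        depths = pu.counts[0].sum(axis=0)
        assert (depths == 1).all()
        col = pu.column("t0", 0)
        assert col.depth == 1 and col.obs == [(tag.ref_seq[0], 1e-6)]

    def test_depths_match_naive_recount(self, small_tags, small_truth):
        _, pairs, cfg = simulate_library(small_tags, small_truth, 400, seed=22)
        by_bc, _ = demultiplex(pairs, cfg.barcodes)
        merged, _ = merge_stream(by_bc)
        alns, _ = align_to_tags(merged, small_tags)
        pu = build_pileup(alns, merged, small_tags)
        # Naive recount straight from the alignment list.
        naive = {t.tag_id: np.zeros(t.length) for t in small_tags}
        for a in alns:
            r = merged[a.read_index]
            for i, c in enumerate(r.seq):
                if c != "N":
                    naive[a.tag_id][a.offset + i] += 1
        for ti, t in enumerate(small_tags):
            assert (pu.counts[ti].sum(axis=0) == naive[t.tag_id]).all()

    def test_per_barcode_counts_track_mixture(self):
        tag = rand_tag("t0", 7)
        reads = [mk_read(tag.ref_seq, rid=f"a{i}", bc=0) for i in range(60)]
        reads += [mk_read(tag.ref_seq, rid=f"b{i}", bc=1) for i in range(40)]
        alns, _ = align_to_tags(reads, [tag])
        pu = build_pileup(alns, reads, [tag])
        assert (pu.bc_counts[0][0].sum(axis=0) == 60).all()
        assert (pu.bc_counts[0][1].sum(axis=0) == 40).all()
        assert (pu.bc_counts[0].sum(axis=0) == pu.counts[0]).all()

    def test_conservation_of_observations(self, small_tags, small_truth):
        _, pairs, cfg = simulate_library(small_tags, small_truth, 300, seed=23)
        by_bc, _ = demultiplex(pairs, cfg.barcodes)
        merged, _ = merge_stream(by_bc)
        alns, _ = align_to_tags(merged, small_tags)
        pu = build_pileup(alns, merged, small_tags)
        assert pu.total_depth() == sum(a.n_bases for a in alns)

    def test_pileup_tsv_roundtrip(self, small_tags):
        tag = small_tags[0]
        reads = [mk_read(tag.ref_seq, rid=f"r{i}", bc=i % 2) for i in range(5)]
        alns, _ = align_to_tags(reads, [tag])
        pu = build_pileup(alns, reads, [tag])
        import io, tempfile, os

        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "p.tsv")
            write_pileup_tsv(pu, path)
            back = read_pileup_tsv(path, [tag])
        assert (back.counts[0] == pu.counts[0]).all()
        assert (back.qhist[0] == pu.qhist[0]).all()
        assert (back.bc_counts[0] == pu.bc_counts[0]).all()


class TestDownsample:
    def _alns(self, tag, n, bc=0):
        reads = [mk_read(tag.ref_seq, rid=f"x{bc}_{i}", bc=bc) for i in range(n)]
        alns, _ = align_to_tags(reads, [tag])
        return reads, alns

    def test_truncates_to_target_mean_depth(self):
        tag = rand_tag("t0", 8)
        _, alns = self._alns(tag, 100)
        sub = downsample(alns, [tag], target_depth=10)
        assert len(sub) == 10
        assert sub == alns[:10]  # prefix of the stream

    def test_target_above_supply_is_identity(self):
        tag = rand_tag("t0", 9)
        _, alns = self._alns(tag, 20)
        assert downsample(alns, [tag], 500) == alns

    def test_per_barcode_truncation_equalises_depths(self):
        tag = rand_tag("t0", 10)
        _, a0 = self._alns(tag, 80, bc=0)
        _, a1 = self._alns(tag, 120, bc=1)
        s0 = downsample(a0, [tag], 50)
        s1 = downsample(a1, [tag], 50)
        assert len(s0) == len(s1) == 50

    def test_never_increases_depth(self):
        tag = rand_tag("t0", 11)
        _, alns = self._alns(tag, 30)
        assert len(downsample(alns, [tag], 5)) <= len(alns)


class TestSam:
    def test_roundtrip_preserves_placement(self, tmp_path):
        tag = rand_tag("t0", 12)
        reads = [
            mk_read(tag.ref_seq[5:85], rid="f", bc=0),
            mk_read(revcomp(tag.ref_seq[10:90]), rid="r", bc=1),
        ]
        alns, _ = align_to_tags(reads, [tag])
        sam = tmp_path / "x.sam"
        export_sam(alns, reads, [tag], sam)
        back, dropped = import_sam(sam, [tag])
        assert dropped == 0
        got = {(a.read_id, a.tag_id, a.offset, a.strand) for a in back}
        want = {(a.read_id, a.tag_id, a.offset, a.strand) for a in alns}
        assert got == want

    def test_minimal_record_and_unmapped_skip(self, tmp_path):
        tag = rand_tag("t0", 13, length=50)
        sam = tmp_path / "m.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:t0\tLN:50\n"
            f"read1\t0\tt0\t3\t60\t10M\t*\t0\t0\t{tag.ref_seq[2:12]}\t{'I'*10}\n"
            "read2\t4\t*\t0\t0\t*\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n"
        )
        alns, dropped = import_sam(sam, [tag])
        assert len(alns) == 1 and dropped == 0
        assert (alns[0].tag_id, alns[0].offset) == ("t0", 2)

    def test_indel_records_dropped_with_count(self, tmp_path):
        tag = rand_tag("t0", 14, length=50)
        sam = tmp_path / "i.sam"
        sam.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:t0\tLN:50\n"
            f"read1\t0\tt0\t1\t60\t5M1I4M\t*\t0\t0\t{tag.ref_seq[:10]}\t{'I'*10}\n"
        )
        alns, dropped = import_sam(sam, [tag])
        assert alns == [] and dropped == 1
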