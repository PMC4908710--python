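"""Poisson-binomial tail, variant calling thresholds, background profiling."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from conftest import simulate_library
from pelekit.caller import (
    CallerParams,
    call_variants,
    estimate_background,
    poisson_binomial_tail,
)
from pelekit.pileup import align_to_tags, build_pileup
from pelekit.readprep import demultiplex, merge_stream
from pelekit.libsim import SeqErrorProfile


def enumerate_tail(probs, k):
    """Brute-force P(X >= k) over all 2^n outcomes."""
    total = 0.0
    n = len(probs)
    for bits in itertools.product((0, 1), repeat=n):
        if sum(bits) >= k:
            pr = 1.0
            for b, p in zip(bits, probs):
                pr *= p if b else (1 - p)
            total += pr
    return total


class TestPoissonBinomialTail:
    def test_k_zero_is_one(self):
        assert poisson_binomial_tail([0.1, 0.2, 0.3], 0) == 1.0

    def test_all_zero_probs(self):
        assert poisson_binomial_tail([0.0] * 10, 1) == 0.0

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial_tail([0.1], 2)

    def test_binomial_closed_form_small(self):
        p = 0.001
        expect = 1 - (1 - p) ** 10 - 10 * p * (1 - p) ** 9
        got = poisson_binomial_tail([p] * 10, 2)
        assert math.isclose(got, expect, rel_tol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        probs = rng.uniform(0, 0.5, size=n)
        k = int(rng.integers(1, n + 1))
        got = poisson_binomial_tail(probs, k)
        want = enumerate_tail(list(probs), k)
        assert abs(got - want) < 1e-12

    @pytest.mark.parametrize("n,p", [(100, 3e-4), (10_000, 3e-4), (10_000, 0.01)])
    def test_equal_probs_reproduce_binomial_survival(self, n, p):
        for k in (1, 2, 5, 20):
            got = poisson_binomial_tail([p] * n, k)
            want = float(binom.sf(k - 1, n, p))
            assert math.isclose(got, want, rel_tol=1e-12)

    def test_two_group_mixture_matches_convolution_oracle(self):
        n1, p1, n2, p2, k = 500, 1e-4, 700, 3e-3, 4
        got = poisson_binomial_tail([p1] * n1 + [p2] * n2, k)
        want = float(binom.sf(k - 1, n1, p1)) + sum(
            float(binom.pmf(a, n1, p1)) * float(binom.sf(k - a - 1, n2, p2))
            for a in range(k)
        )
        assert math.isclose(got, want, rel_tol=1e-10)

    def test_tiny_tail_keeps_relative_precision(self):
        # Deep column, few hits: the tail is ~1e-18 and must not collapse
        # to 0 through cancellation.
        got = poisson_binomial_tail([3.3e-7] * 10_000, 7)
        want = float(binom.sf(6, 10_000, 3.3e-7))
        assert got > 0
        assert math.isclose(got, want, rel_tol=1e-10)

    @given(
        st.lists(st.floats(0.0, 0.9), min_size=2, max_size=10),
        st.integers(1, 5),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_k_and_probs(self, probs, k):
        k = min(k, len(probs))
        t1 = poisson_binomial_tail(probs, k)
        if k + 1 <= len(probs):
            assert poisson_binomial_tail(probs, k + 1) <= t1 + 1e-15
        bumped = [min(1.0, p + 0.05) for p in probs]
        assert poisson_binomial_tail(bumped, k) >= t1 - 1e-15


def make_column_pileup(ref_count, alt_count, q=60, tag_seed=31, bc_alt=None):
    """Single-tag pileup with given ref/alt counts at column 10, built
    through the real read/alignment machinery."""
    from pelekit.refsim import RadTag
    from pelekit.readprep import MergedRead

    rng = np.random.default_rng(tag_seed)
    tag = RadTag("t0", 0, "+", 30, "".join(rng.choice(list("ACGT"), size=30)))
    ref = tag.ref_seq
    alt_base = "A" if ref[10] != "A" else "C"
    reads = []
    for i in range(ref_count):
        reads.append(
            MergedRead(f"ref{i}", i % 2, ref, np.full(30, q), 0, 0)
        )
    for i in range(alt_count):
        seq = ref[:10] + alt_base + ref[11:]
        bc = bc_alt if bc_alt is not None else i % 2
        reads.append(MergedRead(f"alt{i}", bc, seq, np.full(30, q), 0, 0))
    alns, _ = align_to_tags(reads, [tag], max_mismatches=2)
    pu = build_pileup(alns, reads, [tag])
    return pu, tag, alt_base


class TestCallVariants:
    def test_af_below_floor_filtered_regardless_of_p(self):
        pu, _, alt = make_column_pileup(10_000 - 15, 15)
        calls = call_variants(pu, CallerParams(min_af=0.002))
        assert all(c.alt != alt or c.offset != 10 for c in calls)
        assert calls == []

    def test_significant_above_floor_called(self):
        pu, tag, alt = make_column_pileup(10_000 - 25, 25)
        calls = call_variants(pu, CallerParams(min_af=0.002))
        assert len(calls) == 1
        c = calls[0]
        assert (c.tag_id, c.offset, c.alt) == ("t0", 10, alt)
        assert c.af == 25 / 10_000
        assert c.p_corrected <= 0.05
        assert c.p_corrected >= c.p_raw

    def test_no_alt_no_call(self):
        pu, _, _ = make_column_pileup(200, 0)
        assert call_variants(pu, CallerParams(min_af=0.0)) == []

    def test_min_call_quality_gate(self):
        pu, _, _ = make_column_pileup(5000 - 3, 3)
        lenient = CallerParams(min_af=0.0, min_call_quality=0.0)
        strict_q = CallerParams(min_af=0.0, min_call_quality=150.0)
        got = call_variants(pu, lenient)
        assert len(got) == 1 and got[0].call_quality < 150
        assert call_variants(pu, strict_q) == []

    def test_variant_free_simulations_stay_clean_with_af_floor(
        self, small_tags
    ):
        """The central specificity claim at desk scale: with the AF floor
        above the background error rate, pure-control libraries produce
        zero calls.  Depths above ~1000x per barcode are the floor's
        stated domain of validity."""
        for seed in range(3):
            _, pairs, cfg = simulate_library(
                small_tags, [], 40_000,
                pcr_error_rate=1e-5,
                seq_error_profile=SeqErrorProfile.flat(1e-3),
                seed=100 + seed,
            )
            by_bc, _ = demultiplex(pairs, cfg.barcodes)
            merged, _ = merge_stream(by_bc)
            alns, _ = align_to_tags(merged, small_tags)
            pu = build_pileup(alns, merged, small_tags)
            calls = call_variants(pu, CallerParams(min_af=0.002))
            assert calls == []


class TestEstimateBackground:
    def test_error_free_control_is_zero(self):
        pu, _, _ = make_column_pileup(50, 0)
        prof = estimate_background(pu)
        assert prof.max_rate == 0.0 and prof.overall_rate == 0.0
        assert prof.recommended_min_af > 0.0

    def test_planted_rates_match_provenance(self, small_tags):
        mols, pairs, cfg = simulate_library(
            small_tags, [], 4000, pcr_error_rate=3e-4, seed=41
        )
        by_bc, _ = demultiplex(pairs, cfg.barcodes)
        merged, _ = merge_stream(by_bc)
        alns, _ = align_to_tags(merged, small_tags)
        pu = build_pileup(alns, merged, small_tags)
        prof = estimate_background(pu)
        # Independent recount of surviving PCR errors from provenance.
        aligned_mids = {int(a.read_id.split(":")[1]) for a in alns}
        expect_err = sum(
            len([e for e in m.pcr_errors if e[0] < m.insert_len])
            for m in mols if m.molecule_id in aligned_mids
        )
        assert expect_err > 0
        observed_err = round(prof.overall_rate * pu.total_depth())
        assert abs(observed_err - expect_err) <= 0.05 * expect_err + 5
        assert prof.recommended_min_af > prof.max_rate

    def test_spectrum_reflects_ct_bias(self, small_tags):
        _, pairs, cfg = simulate_library(
            small_tags, [], 6000, pcr_error_rate=1e-3, ct_bias=0.8, seed=42
        )
        by_bc, _ = demultiplex(pairs, cfg.barcodes)
        merged, _ = merge_stream(by_bc)
        alns, _ = align_to_tags(merged, small_tags)
        pu = build_pileup(alns, merged, small_tags)
        prof = estimate_background(pu)
        frac = prof.spectrum["fractions"]["C>T"]
        assert abs(frac - 0.8) < 0.08

    def test_zero_depth_rejected(self, small_tags):
        from pelekit.pileup import Pileup

        with pytest.raises(ValueError):
            estimate_background(Pileup(small_tags))
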