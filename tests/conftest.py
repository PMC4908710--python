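"""Shared fixtures: small simulated libraries with provenance tracking."""

from __future__ import annotations

import dataclasses

import pytest

from pelekit.libsim import (
    LibraryConfig,
    SeqErrorProfile,
    amplify_pcr,
    sequence_pairs,
    simulate_molecules,
)
from pelekit.refsim import digest_tags, make_genome, make_truth


@pytest.fixture(scope="session")
def small_genome():
    return make_genome(
        length=20000, gc=0.5, motif="CCTGCAGG", n_sites=5, min_spacing=150, seed=11
    )


@pytest.fixture(scope="session")
def small_tags(small_genome):
    return digest_tags(small_genome, tag_len=100)


@pytest.fixture(scope="session")
def small_truth(small_tags):
    # High-frequency truth alleles so small simulations detect them reliably.
    return make_truth(small_tags, n_snps=6, target_af=0.05, seed=7)


def simulate_library(tags, truth, n_molecules, **overrides):
    """Simulate molecules -> PCR -> read pairs; returns (mols, pairs, cfg)."""
    defaults = dict(
        sample_id="t",
        pcr_error_rate=0.0,
        seq_error_profile=SeqErrorProfile.flat(0.0),
        seed=overrides.pop("seed", 5),
    )
    defaults.update(overrides)
    cfg = LibraryConfig(**defaults)
    mols = simulate_molecules(tags, truth, n_molecules, cfg)
    mols = amplify_pcr(mols, tags, cfg)
    pairs = sequence_pairs(mols, tags, cfg)
    return mols, pairs, cfg


@pytest.fixture(scope="session")
def clean_library(small_tags, small_truth):
    """No sequencing or PCR errors."""
    return simulate_library(small_tags, small_truth, 4000, seed=5)


@pytest.fixture(scope="session")
def noisy_library(small_tags, small_truth):
    """Sequencing errors on, PCR errors off."""
    return simulate_library(
        small_tags,
        small_truth,
        4000,
        seq_error_profile=SeqErrorProfile.flat(1e-3),
        seed=6,
    )


@pytest.fixture(scope="session")
def pcr_library(small_tags, small_truth):
    """PCR errors on (inflated rate), sequencing errors off."""
    return simulate_library(
        small_tags,
        small_truth,
        4000,
        pcr_error_rate=2e-4,
        ct_bias=0.8,
        seed=8,
    )
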