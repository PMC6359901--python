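"""Shared fixtures: primer contexts and cached end-to-end community runs."""

from __future__ import annotations

import pytest

import silicamp.extender as ex
import silicamp.kmer_tables as kt
import silicamp.region_filter as rf
from silicamp.seqcore import PrimerPairContext
from silicamp.synthetic import (EMP_V4_FORWARD, EMP_V4_REVERSE,
                                make_community, make_strain_pair,
                                simulate_reads)


@pytest.fixture(scope="session")
def emp_ctx() -> PrimerPairContext:
    return PrimerPairContext.from_strings(EMP_V4_FORWARD, EMP_V4_REVERSE)


def run_phases(community, reads, *, rng_seed=1, min_count=2,
               variant_ratio=kt.DEFAULT_VARIANT_RATIO):
    """Run the three phases in memory; returns a dict of the artefacts."""
    ctx = community.context()
    filt, region_reads = rf.build_region_reads(reads, ctx)
    starting = [r for r in region_reads if r.is_starting]
    ladder = kt.build_ladder(region_reads,
                             kt.k_values(kt.modal_read_length(region_reads)))
    denoised = kt.denoise_ladder(ladder, min_count=min_count,
                                 variant_ratio=variant_ratio)
    results, stats = ex.extend_all(starting, denoised, ctx,
                                   ex.ExtensionConfig(rng_seed=rng_seed))
    return {
        "ctx": ctx,
        "filter": filt,
        "region_reads": region_reads,
        "starting": starting,
        "ladder": denoised,
        "raw_ladder": ladder,
        "results": results,
        "stats": stats,
        "outputs": [r.sequence for r in results if r.terminated],
    }


@pytest.fixture(scope="session")
def phase_runner():
    """The in-memory three-phase runner, for tests building ad-hoc pools."""
    return run_phases


@pytest.fixture(scope="session")
def perfect_community():
    """15 members, 250 bp regions, 30x depth, error-free, fully covered."""
    com = make_community(n_members=15, region_length=250, seed=42,
                         read_length=100, depth=30.0, error_rate=0.0)
    reads = simulate_reads(com)
    return com, reads


@pytest.fixture(scope="session")
def perfect_run(perfect_community):
    com, reads = perfect_community
    return com, reads, run_phases(com, reads)


@pytest.fixture(scope="session")
def gap_run(perfect_community):
    """Same community, one member's region with a 40 bp read-free window."""
    com, _ = perfect_community
    reads = simulate_reads(com, coverage_gap=(3, 100, 40))
    return com, reads, run_phases(com, reads)


@pytest.fixture(scope="session")
def strain_run():
    """Two strains at 90:10 sharing primers, one SNP near the region start."""
    com = make_strain_pair(region_length=250, snps=1, snp_positions=[34],
                           abundances=(0.9, 0.1), seed=7,
                           read_length=100, depth=500.0)
    reads = simulate_reads(com)
    return com, reads, run_phases(com, reads)
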