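from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myelomap.datamodel import AnalysisConfig, GenomicBreakpoint, SVCall, load_genome_model
from myelomap.io_formats import load_chr1_cohort_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def genome():
    return load_genome_model("hg38")


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def fixture_cohort():
    return load_chr1_cohort_fixture()


@pytest.fixture
def mk_call():
    """Factory for quick SVCall construction in tests."""

    def make(
        sv_type="deletion",
        chrom_a="1",
        pos_a=1_000_000,
        chrom_b=None,
        pos_b=None,
        size_bp="auto",
        vaf_pct=20.0,
        n_molecules=15,
        sample_id="S1",
        call_id=None,
        pipeline="merged",
        **kwargs,
    ):
        chrom_b = chrom_b if chrom_b is not None else chrom_a
        pos_b = pos_b if pos_b is not None else pos_a + 100
        if size_bp == "auto":
            size_bp = None if sv_type == "translocation_inter" else abs(pos_b - pos_a)
        make.counter += 1
        return SVCall(
            call_id=call_id or f"c{make.counter:04d}",
            sample_id=sample_id,
            pipeline=pipeline,
            sv_type=sv_type,
            bp_a=GenomicBreakpoint(chrom_a, pos_a),
            bp_b=GenomicBreakpoint(chrom_b, pos_b),
            size_bp=size_bp,
            vaf_pct=vaf_pct,
            n_molecules=n_molecules,
            **kwargs,
        )

    make.counter = 0
    return make


def random_calls(rng: np.random.Generator, n: int, genome, sample_id="S1", types=None):
    """Random valid calls spread over the genome (shared test helper)."""
    types = types or ("deletion", "insertion", "duplication", "inversion")
    chroms = [c for c in genome.chromosomes]
    calls = []
    for k in range(n):
        sv_type = str(rng.choice(types))
        chrom = str(rng.choice(chroms))
        if sv_type == "translocation_inter":
            other = str(rng.choice([c for c in chroms if c != chrom]))
            pos_a = int(rng.integers(1, genome[chrom]))
            pos_b = int(rng.integers(1, genome[other]))
            (ca, pa), (cb, pb) = sorted([(chrom, pos_a), (other, pos_b)])
            call = SVCall(
                call_id=f"{sample_id}_r{k:05d}",
                sample_id=sample_id,
                pipeline="merged",
                sv_type=sv_type,
                bp_a=GenomicBreakpoint(ca, pa),
                bp_b=GenomicBreakpoint(cb, pb),
                vaf_pct=float(rng.uniform(6, 50)),
                n_molecules=int(rng.integers(10, 60)),
            )
        else:
            size = int(rng.integers(500, 2_000_000))
            lo = int(rng.integers(1, genome[chrom] - size))
            call = SVCall(
                call_id=f"{sample_id}_r{k:05d}",
                sample_id=sample_id,
                pipeline="merged",
                sv_type=sv_type,
                bp_a=GenomicBreakpoint(chrom, lo),
                bp_b=GenomicBreakpoint(chrom, lo + size),
                size_bp=size,
                vaf_pct=float(rng.uniform(6, 50)),
                n_molecules=int(rng.integers(10, 60)),
            )
        calls.append(call)
    return calls
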