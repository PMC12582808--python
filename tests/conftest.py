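"""Shared builders for summary-stat records and harmonized sets."""

from __future__ import annotations

import numpy as np
import pytest

from medmr.sumstats import HarmonizedSet, SumStatRecord


def make_record(
    snp_id="rs1",
    ea="A",
    oa="G",
    beta=0.1,
    se=0.01,
    pval=1e-6,
    eaf=0.3,
    n=10_000,
    chrom="1",
    pos=1_000_000,
) -> SumStatRecord:
    return SumStatRecord(
        snp_id=snp_id, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pval=pval, eaf=eaf, n=n, chrom=chrom, pos=pos,
    )


def make_hset(bx, by, sy, sx=None, n_exp=10_000, n_out=20_000) -> HarmonizedSet:
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    sy = np.asarray(sy, dtype=float)
    sx = np.full_like(bx, 0.01) if sx is None else np.asarray(sx, dtype=float)
    return HarmonizedSet(
        snp_ids=[f"rs{i}" for i in range(len(bx))],
        beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy,
        n_exp=n_exp, n_out=n_out,
    )


def random_hset(rng, n=8, beta=0.3) -> HarmonizedSet:
    """A generic harmonized set with heterogeneous weights and mild noise."""
    bx = rng.normal(0.1, 0.04, n)
    bx[np.abs(bx) < 0.01] = 0.02  # keep ratios well defined
    sx = rng.uniform(0.005, 0.02, n)
    sy = rng.uniform(0.005, 0.03, n)
    by = beta * bx + rng.normal(0, 1, n) * sy
    return make_hset(bx, by, sy, sx=sx)


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def hset_factory():
    return make_hset
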