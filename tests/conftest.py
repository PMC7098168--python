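"""Shared fixtures: small hand-built genotype matrices and simulator runs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from feralscan import GenotypeMatrix, SimConfig, simulate


def make_gm(
    calls,
    pos=None,
    chrom="chr1",
    samples=None,
    ref="A",
    alt="C",
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (n_samples, n_sites) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 10
    if samples is None:
        samples = [f"s{i:02d}" for i in range(n_samples)]
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": np.asarray(pos, dtype=np.int64),
            "ref": [ref] * n_sites,
            "alt": [alt] * n_sites,
        }
    )
    return GenotypeMatrix(sites, list(samples), calls)


@pytest.fixture(scope="session")
def small_sim():
    """One modest simulated panel reused by read-only tests."""
    cfg = SimConfig(
        n_loci=2000,
        n_chrom=2,
        chrom_length=2_000_000,
        n_dom_loci=2,
        n_feral_in=1,
        n_feral_out=2,
        n_lineages=2,
        weed_founders=(0,),
        n_wild_samples=10,
        n_crop_samples=6,
        n_weed_samples=10,
        seed=20_260_901,
    )
    return simulate(cfg)
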