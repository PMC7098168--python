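"""Allele frequencies, windowed nucleotide diversity, and heterozygosity.

Per-site quantities are computed complete-case within the focal
population: missing genotypes contribute neither to the haplotype count
nor to allele counts, so the called haplotype number varies by site.

Windowed pi follows the VCFtools ``--window-pi`` convention: the sum of
per-site diversity over SNPs in a window divided by the full window
length in bp (monomorphic and uncalled positions contribute zero).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from feralscan._windows import chrom_lengths_from_sites, make_windows, window_sums
from feralscan.io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class SiteFreqs:
    """Per-site called counts and frequencies for one population.

    Attributes
    ----------
    n_hap : called haplotype count per site (2 x called diploids).
    alt_count : alt allele count per site.
    alt_freq : alt_count / n_hap (NaN where nothing called).
    het_count : heterozygous diploid count per site.
    """

    n_hap: np.ndarray
    alt_count: np.ndarray
    alt_freq: np.ndarray
    het_count: np.ndarray

    @property
    def n_diploid(self) -> np.ndarray:
        return self.n_hap // 2

    @property
    def het_freq(self) -> np.ndarray:
        """Observed heterozygote fraction among called diploids (NaN if none)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_hap > 0, self.het_count / (self.n_hap / 2), np.nan)


def site_freqs(G: GenotypeMatrix, pop: Sequence[str]) -> SiteFreqs:
    """Per-site allele counts/frequencies over the samples in ``pop``."""
    if len(pop) == 0:
        raise ValueError("population subset is empty")
    calls = G.calls[G.sample_indices(pop)]
    called = calls != MISSING
    n_hap = 2 * called.sum(axis=0)
    alt_count = np.where(called, calls, 0).sum(axis=0)
    het_count = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(n_hap > 0, alt_count / n_hap, np.nan)
    return SiteFreqs(
        n_hap=n_hap.astype(np.int64),
        alt_count=alt_count.astype(np.int64),
        alt_freq=alt_freq,
        het_count=het_count.astype(np.int64),
    )


def site_pi(n_hap: np.ndarray | int, alt_count: np.ndarray | int) -> np.ndarray | float:
    """Per-site nucleotide diversity: mean pairwise difference among haplotypes.

    pi = 2 * ref_count * alt_count / (n * (n - 1)) for n called haplotypes;
    NaN where n < 2 (such sites are skipped by the window scan).
    """
    n = np.asarray(n_hap, dtype=float)
    k = np.asarray(alt_count, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * k * (n - k) / (n * (n - 1)), np.nan)
    if np.ndim(n_hap) == 0:
        return float(pi)
    return pi


def pi_windows(
    G: GenotypeMatrix,
    pop: Sequence[str],
    window: int = 100_000,
    step: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed nucleotide diversity for one population.

    Returns a DataFrame with columns chrom, start, end (0-based
    half-open), n_sites, pi_per_bp and a ``partial`` flag for truncated
    terminal windows.  pi_per_bp divides by the true window length.
    """
    sf = site_freqs(G, pop)
    pi = site_pi(sf.n_hap, sf.alt_count)
    n_undef = int(np.sum(sf.n_hap < 2))
    if n_undef:
        logger.info("pi_windows: %d sites with <2 called haplotypes skipped", n_undef)
    if chrom_lengths is None:
        chrom_lengths = chrom_lengths_from_sites(G)
    win = make_windows(chrom_lengths, window, step)
    sums, counts = window_sums(G.sites, win, pi)
    win = win.copy()
    win["n_sites"] = counts
    win["pi_per_bp"] = sums / (win["end"] - win["start"])
    return win[["chrom", "start", "end", "n_sites", "pi_per_bp", "partial"]]


def observed_heterozygosity(G: GenotypeMatrix, pop: Sequence[str]) -> pd.Series:
    """Per-sample fraction of heterozygous calls among non-missing calls.

    Samples with zero called sites get NaN (logged).
    """
    idx = G.sample_indices(pop)
    calls = G.calls[idx]
    called = (calls != MISSING).sum(axis=1)
    het = (calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(called > 0, het / called, np.nan)
    n_empty = int(np.sum(called == 0))
    if n_empty:
        logger.warning("observed_heterozygosity: %d samples with no called sites", n_empty)
    return pd.Series(frac, index=list(pop), name="obs_het")
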