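"""Weir-Cockerham F_ST scan and de-domestication region calling.

The per-site estimator is the two-population Weir & Cockerham (1984)
variance-component form (a: among populations, b: among individuals
within populations, c: within individuals), computed from called
diploid counts, allele frequencies and observed heterozygote fractions.
Windowed F_ST is the ratio of sums sum(a)/sum(a+b+c) over informative
sites — the "weighted" estimate reported by VCFtools.  Negative
per-site components are retained, so window values can be slightly
negative under no differentiation.

Candidate de-domestication regions are windows whose Z-transformed
F_ST (population-SD standardisation across all windows of the
comparison) exceeds a threshold (default 3), merged when overlapping
or bookended.  The overlap rate against a domestication-region
interval set is measured in base pairs of the merged regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from feralscan._windows import chrom_lengths_from_sites, make_windows, window_sums
from feralscan.diversity import SiteFreqs, site_freqs
from feralscan.io import GenotypeMatrix, IntervalSet

logger = logging.getLogger(__name__)


def wc_fst_site(freqA: SiteFreqs, freqB: SiteFreqs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components (a, b, c) for two populations.

    Sites with fewer than two called diploids in either population get
    NaN components (skipped by the window scan, with a logged count).
    The per-site estimate is theta = a / (a + b + c) where the
    denominator is positive.
    """
    n1 = freqA.n_diploid.astype(float)
    n2 = freqB.n_diploid.astype(float)
    p1, p2 = freqA.alt_freq, freqB.alt_freq
    h1, h2 = freqA.het_freq, freqB.het_freq

    valid = (n1 >= 2) & (n2 >= 2)
    n_skipped = int(np.sum(~valid))
    if n_skipped:
        logger.info("wc_fst_site: %d sites with <2 called diploids in a population", n_skipped)

    with np.errstate(invalid="ignore", divide="ignore"):
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0

    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def fst_windows(
    G: GenotypeMatrix,
    popA: Sequence[str],
    popB: Sequence[str],
    window: int = 100_000,
    step: int = 10_000,
    min_sites: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed Weir-Cockerham F_ST between two disjoint sample subsets.

    Each window's F_ST is sum(a)/sum(a+b+c) over its informative sites;
    windows with fewer than ``min_sites`` informative sites carry NaN
    (a handful of sites gives a wildly noisy ratio, so sparse and
    truncated terminal windows are excluded from the outlier scan).
    Returns chrom, start, end, n_sites, fst, partial.
    """
    overlap = set(popA) & set(popB)
    if overlap:
        raise ValueError(f"populations overlap: {sorted(overlap)[:5]}")
    sfA = site_freqs(G, popA)
    sfB = site_freqs(G, popB)
    a, b, c = wc_fst_site(sfA, sfB)
    denom_site = a + b + c
    # uninformative sites (e.g. fixed for the same allele in both pops)
    # have a+b+c == 0 and are excluded from the ratio of sums
    informative = np.isfinite(denom_site) & (denom_site != 0.0)
    n_uninf = int(np.sum(np.isfinite(denom_site) & ~informative))
    if n_uninf:
        logger.info("fst_windows: %d uninformative sites excluded", n_uninf)
    a_used = np.where(informative, a, np.nan)
    d_used = np.where(informative, denom_site, np.nan)

    if chrom_lengths is None:
        chrom_lengths = chrom_lengths_from_sites(G)
    win = make_windows(chrom_lengths, window, step)
    sums, counts = window_sums(G.sites, win, np.vstack([a_used, d_used]))
    num, den = sums
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where((counts >= max(min_sites, 1)) & (den != 0), num / den, np.nan)
    win = win.copy()
    win["n_sites"] = counts
    win["fst"] = fst
    return win[["chrom", "start", "end", "n_sites", "fst", "partial"]]


def filter_informative_windows(
    table: pd.DataFrame, frac_of_median: float = 0.75
) -> pd.DataFrame:
    """Mask windows with atypically few informative sites.

    The Z-standardisation pools all windows, but a window's sampling
    variance scales inversely with its informative-site count: windows
    much sparser than typical (sweep cores fixed in both populations,
    chromosome ends) otherwise dominate the upper tail.  Windows with
    n_sites below ``frac_of_median`` x median(n_sites) get NaN F_ST and
    drop out of the outlier scan.
    """
    out = table.copy()
    informative = out["n_sites"][np.isfinite(out["fst"])]
    if informative.empty:
        return out
    cut = frac_of_median * float(informative.median())
    out.loc[out["n_sites"] < cut, "fst"] = np.nan
    return out


def z_transform(values: np.ndarray | pd.Series) -> np.ndarray:
    """Standardise a window statistic: z = (x - mean) / population SD.

    NaN entries stay NaN and are excluded from the mean/SD.  A spread of
    zero (or <2 non-missing values) is a degenerate input.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need >=2 non-missing values to Z-transform")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=0)
    if sd == 0:
        raise ValueError("zero spread: Z-transform undefined")
    z = np.full_like(x, np.nan)
    z[finite] = (x[finite] - mu) / sd
    return z


@dataclass
class CandidateRegions:
    """Merged significant windows with per-region peak Z and window count.

    ``regions`` has columns chrom, start, end, peak_z, n_windows; the
    ``intervals`` view is the bare IntervalSet of the same regions.
    """

    regions: pd.DataFrame

    @property
    def intervals(self) -> IntervalSet:
        if self.regions.empty:
            return IntervalSet()
        return IntervalSet(self.regions[["chrom", "start", "end"]].copy())

    @property
    def total_length(self) -> int:
        return self.intervals.total_length

    def __len__(self) -> int:
        return len(self.regions)


def call_candidate_regions(
    table: pd.DataFrame, z_threshold: float = 3.0, z_column: str = "z_fst"
) -> CandidateRegions:
    """Merge windows with z > threshold into candidate regions.

    With step < window, consecutive significant windows overlap and
    merge into one region; per-region peak Z and contributing window
    count are recorded.  An empty result is valid.
    """
    if z_column not in table.columns:
        raise ValueError(f"window table lacks column {z_column!r}")
    sig = table[np.asarray(table[z_column], dtype=float) > z_threshold]
    if sig.empty:
        return CandidateRegions(
            pd.DataFrame(columns=["chrom", "start", "end", "peak_z", "n_windows"])
        )
    sig = sig.sort_values(["chrom", "start", "end"], kind="mergesort")
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        cur = None
        for _, w in grp.iterrows():
            if cur is None:
                cur = [chrom, int(w["start"]), int(w["end"]), float(w[z_column]), 1]
            elif int(w["start"]) <= cur[2]:
                cur[2] = max(cur[2], int(w["end"]))
                cur[3] = max(cur[3], float(w[z_column]))
                cur[4] += 1
            else:
                rows.append(tuple(cur))
                cur = [chrom, int(w["start"]), int(w["end"]), float(w[z_column]), 1]
        rows.append(tuple(cur))
    return CandidateRegions(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_z", "n_windows"])
    )


def overlap_rate(
    candidates: CandidateRegions | IntervalSet,
    domestication: IntervalSet,
    by: str = "bp",
) -> float:
    """Percent of candidate-region length falling inside domestication regions.

    100 x (intersection bp) / (candidate bp); returns 0 (with a warning)
    when there are no candidate regions.  For a window-count variant use
    :func:`window_overlap_rate`.
    """
    if by != "bp":
        raise ValueError("only by='bp' is supported; see window_overlap_rate")
    cand = candidates.intervals if isinstance(candidates, CandidateRegions) else candidates
    cand = cand.normalize()
    if cand.total_length == 0:
        logger.warning("overlap_rate: no candidate regions; returning 0")
        return 0.0
    inter = cand.intersect(domestication.normalize())
    return 100.0 * inter.total_length / cand.total_length


def window_overlap_rate(
    table: pd.DataFrame,
    domestication: IntervalSet,
    z_threshold: float = 3.0,
    z_column: str = "z_fst",
) -> float:
    """Percent of significant windows that intersect domestication regions.

    Window-count alternative to the base-pair :func:`overlap_rate`.
    """
    z = np.asarray(table[z_column], dtype=float)
    sig = table[z > z_threshold]
    if sig.empty:
        logger.warning("window_overlap_rate: no significant windows; returning 0")
        return 0.0
    dom = domestication.normalize()
    n_hit = 0
    for _, w in sig.iterrows():
        probe = IntervalSet(
            pd.DataFrame(
                [(w["chrom"], int(w["start"]), int(w["end"]))],
                columns=["chrom", "start", "end"],
            )
        )
        if probe.intersect(dom).total_length > 0:
            n_hit += 1
    return 100.0 * n_hit / len(sig)
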