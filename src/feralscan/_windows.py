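"""Sliding-window bookkeeping shared by the diversity and FST scans."""

from __future__ import annotations

import numpy as np
import pandas as pd

from feralscan.io import GenotypeMatrix


def chrom_lengths_from_sites(G: GenotypeMatrix) -> dict[str, int]:
    """Per-chromosome length inferred as the largest 1-based position."""
    out = {}
    for chrom, grp in G.sites.groupby("chrom", sort=False):
        out[chrom] = int(grp["pos"].max())
    return out


def make_windows(
    chrom_lengths: dict[str, int], window: int, step: int
) -> pd.DataFrame:
    """Tile each chromosome with [start, start+window) windows at ``step``.

    Terminal windows are truncated at the chromosome end and flagged
    ``partial``.  Coordinates are 0-based half-open.
    """
    if step <= 0 or window < step:
        raise ValueError("require window >= step > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, max(length, 1), step, dtype=np.int64)
        for s in starts:
            e = min(s + window, length)
            if e <= s:
                continue
            rows.append((chrom, int(s), int(e), e - s < window))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "partial"])


def window_sums(
    sites: pd.DataFrame, windows: pd.DataFrame, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-site ``values`` (NaN = skip) into each window.

    Returns (sums, n_sites) aligned to ``windows`` rows.  Sites are
    matched by 0-based coordinate pos-1 in [start, end).
    ``values`` may be 2-D (k, n_sites); sums then has shape (k, n_windows).
    """
    values = np.asarray(values, dtype=float)
    squeeze = values.ndim == 1
    if squeeze:
        values = values[None, :]
    finite = np.all(np.isfinite(values), axis=0)
    sums = np.zeros((values.shape[0], len(windows)))
    counts = np.zeros(len(windows), dtype=np.int64)
    for chrom, grp in sites.groupby("chrom", sort=False):
        widx = np.flatnonzero(windows["chrom"].to_numpy() == chrom)
        if len(widx) == 0:
            continue
        site_idx = grp.index.to_numpy()
        keep = finite[site_idx]
        site_idx = site_idx[keep]
        pos0 = grp["pos"].to_numpy()[keep] - 1
        vals = values[:, site_idx]
        cum = np.concatenate([np.zeros((values.shape[0], 1)), np.cumsum(vals, axis=1)], axis=1)
        starts = windows["start"].to_numpy()[widx]
        ends = windows["end"].to_numpy()[widx]
        lo = np.searchsorted(pos0, starts, side="left")
        hi = np.searchsorted(pos0, ends, side="left")
        sums[:, widx] = cum[:, hi] - cum[:, lo]
        counts[widx] = hi - lo
    if squeeze:
        return sums[0], counts
    return sums, counts
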