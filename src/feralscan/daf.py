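"""Outgroup polarization and derived-allele-frequency spectra.

A divergent outgroup is used to call the ancestral allele at each SNP:
under the strict rule (default) a site is polarized only when at least
``min_outgroup`` outgroup individuals are called and every called
outgroup genotype carries the same allele; a majority-rule alternative
takes the outgroup major allele.  Derived allele frequencies are then
binned into equal-width spectra separately for sites inside and
outside a set of domestication regions, and the per-bin ratio
(domestication / non-domestication) traces the characteristic U shape
left by domestication sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from feralscan.diversity import SiteFreqs
from feralscan.io import MISSING, GenotypeMatrix, IntervalSet

#: Codes for the polarized ancestral allele.
ANC_REF, ANC_ALT, UNASSIGNED = 0, 1, -1


@dataclass
class Polarization:
    """Per-site ancestral-allele assignment.

    ``ancestral`` holds ANC_REF (0), ANC_ALT (1) or UNASSIGNED (-1);
    ``n_outgroup_called`` counts called outgroup individuals per site.
    """

    ancestral: np.ndarray
    n_outgroup_called: np.ndarray

    @property
    def assigned(self) -> np.ndarray:
        return self.ancestral != UNASSIGNED


def polarize(
    G: GenotypeMatrix,
    outgroup: Sequence[str],
    min_outgroup: int = 8,
    rule: str = "strict",
) -> Polarization:
    """Call the ancestral allele per site from outgroup genotypes.

    ``rule='strict'`` (default): ancestral is the single allele carried
    by all called outgroup genotypes, provided >= ``min_outgroup``
    outgroup individuals are called; polymorphic outgroup -> unassigned.
    ``rule='majority'``: ancestral is the outgroup major allele (ties
    unassigned), same calling threshold.
    """
    if rule not in ("strict", "majority"):
        raise ValueError("rule must be 'strict' or 'majority'")
    calls = G.calls[G.sample_indices(outgroup)]
    called = calls != MISSING
    n_called = called.sum(axis=0).astype(np.int64)
    alt = np.where(called, calls, 0).sum(axis=0)
    n_hap = 2 * n_called
    anc = np.full(G.n_sites, UNASSIGNED, dtype=np.int8)
    enough = n_called >= min_outgroup
    if rule == "strict":
        anc[enough & (alt == 0)] = ANC_REF
        anc[enough & (alt == n_hap) & (n_hap > 0)] = ANC_ALT
    else:
        anc[enough & (2 * alt < n_hap)] = ANC_REF
        anc[enough & (2 * alt > n_hap)] = ANC_ALT
    return Polarization(ancestral=anc, n_outgroup_called=n_called)


def derived_freq(freq: SiteFreqs, pol: Polarization) -> np.ndarray:
    """Derived allele frequency per site; NaN where unassigned or uncalled.

    DAF = alt_freq when the ancestral allele is ref, 1 - alt_freq when
    it is alt.
    """
    daf = np.full(len(pol.ancestral), np.nan)
    ref_anc = pol.ancestral == ANC_REF
    alt_anc = pol.ancestral == ANC_ALT
    daf[ref_anc] = freq.alt_freq[ref_anc]
    daf[alt_anc] = 1.0 - freq.alt_freq[alt_anc]
    return daf


@dataclass
class DafSpectrum:
    """Binned derived-allele-frequency spectrum for one region class."""

    bin_edges: np.ndarray
    counts: np.ndarray
    region_class: str

    @property
    def proportions(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / total


def _bin_index(daf: np.ndarray, n_bins: int) -> np.ndarray:
    # equal-width bins over (0, 1]; a DAF of exactly 1 lands in the last bin
    idx = np.floor(daf * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def daf_spectrum(
    dafs: np.ndarray,
    sites: pd.DataFrame,
    regions: IntervalSet,
    n_bins: int = 20,
    exclude_zero: bool = True,
) -> tuple[DafSpectrum, DafSpectrum]:
    """Split sites by region membership and bin their DAFs.

    Returns (in-region spectrum, out-of-region spectrum) with identical
    equal-width bin edges.  Sites with missing DAF are dropped; DAF = 0
    sites (ancestral fixed) are excluded by default.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    dafs = np.asarray(dafs, dtype=float)
    if len(dafs) != len(sites):
        raise ValueError("dafs not aligned to site table")
    keep = np.isfinite(dafs)
    if exclude_zero:
        keep &= dafs > 0
    in_region = regions.contains(
        sites["chrom"].to_numpy(), sites["pos"].to_numpy() - 1
    )
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    out = []
    for cls, mask in (
        ("domestication", keep & in_region),
        ("non_domestication", keep & ~in_region),
    ):
        counts = np.bincount(_bin_index(dafs[mask], n_bins), minlength=n_bins)
        out.append(DafSpectrum(bin_edges=edges, counts=counts, region_class=cls))
    return out[0], out[1]


def daf_ratio(
    spec_dom: DafSpectrum, spec_non: DafSpectrum, mode: str = "proportion"
) -> np.ndarray:
    """Per-bin ratio of the two spectra (domestication / non-domestication).

    ``mode='proportion'`` (default) ratios the per-class normalised
    proportions so unequal region sizes do not dominate;
    ``mode='count'`` ratios raw counts.  Bins with a zero denominator
    get NaN.
    """
    if not np.array_equal(spec_dom.bin_edges, spec_non.bin_edges):
        raise ValueError("spectra have different bin edges")
    if mode == "proportion":
        num, den = spec_dom.proportions, spec_non.proportions
    elif mode == "count":
        num, den = spec_dom.counts.astype(float), spec_non.counts.astype(float)
    else:
        raise ValueError("mode must be 'proportion' or 'count'")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def spectrum_table(
    spec_dom: DafSpectrum, spec_non: DafSpectrum, mode: str = "proportion"
) -> pd.DataFrame:
    """Tabulate both spectra and their per-bin ratio for reporting."""
    ratio = daf_ratio(spec_dom, spec_non, mode=mode)
    return pd.DataFrame(
        {
            "bin_left": spec_dom.bin_edges[:-1],
            "bin_right": spec_dom.bin_edges[1:],
            "count_dom": spec_dom.counts,
            "count_non": spec_non.counts,
            "prop_dom": spec_dom.proportions,
            "prop_non": spec_non.proportions,
            "ratio": ratio,
        }
    )
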