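"""Allele-frequency ABBA-BABA (Patterson's D) with a block jackknife.

For the phylogeny (((P1, P2), P3), O), an excess of ABBA over BABA
site patterns indicates allele sharing between P2 and P3 (e.g.
wild -> weed introgression).  With population samples, per-site
pattern weights use derived allele frequencies:

    ABBA = (1 - p1) * p2 * p3 * (1 - p4)
    BABA = p1 * (1 - p2) * p3 * (1 - p4)

and D = sum(ABBA - BABA) / sum(ABBA + BABA).  Sites are oriented so
that the outgroup major allele is ancestral (ties skipped); outgroup
polymorphism is down-weighted through the (1 - p4) factor.  Standard
errors come from a delete-one block jackknife over genomic blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from feralscan.diversity import site_freqs
from feralscan.io import GenotypeMatrix

logger = logging.getLogger(__name__)


def site_patterns(p1, p2, p3, p4):
    """ABBA and BABA weights from four derived allele frequencies.

    Accepts scalars or aligned arrays; all inputs must lie in [0, 1].
    """
    arrs = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    for p in arrs:
        if np.any((p < 0) | (p > 1)):
            raise ValueError("allele frequencies must be in [0, 1]")
    q1, q2, q3, q4 = arrs
    abba = (1 - q1) * q2 * q3 * (1 - q4)
    baba = q1 * (1 - q2) * q3 * (1 - q4)
    if np.ndim(p1) == 0 and np.ndim(p2) == 0:
        return float(abba), float(baba)
    return abba, baba


@dataclass
class DStatResult:
    """Patterson's D with jackknife uncertainty for one scope."""

    d: float
    abba_sum: float
    baba_sum: float
    se: float  # NaN when fewer than 2 non-empty blocks
    z: float
    n_blocks: int
    n_sites_used: int
    scope: str = "genome"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scope": self.scope,
                    "D": self.d,
                    "se": self.se,
                    "z": self.z,
                    "abba_sum": self.abba_sum,
                    "baba_sum": self.baba_sum,
                    "n_sites_used": self.n_sites_used,
                    "n_blocks": self.n_blocks,
                }
            ]
        )


def _jackknife(num: np.ndarray, den: np.ndarray, blocks: np.ndarray) -> tuple[float, int]:
    """Delete-one-block jackknife SE for D = sum(num)/sum(den).

    ``blocks`` assigns each site to a block id; empty blocks are
    ignored.  Returns (se, n_blocks); se is NaN with <2 usable blocks.
    """
    ids = np.unique(blocks)
    tot_num, tot_den = num.sum(), den.sum()
    d_del = []
    for b in ids:
        m = blocks == b
        den_b = den[m].sum()
        if not np.any(m):
            continue
        rest_den = tot_den - den_b
        if rest_den == 0:
            continue
        d_del.append((tot_num - num[m].sum()) / rest_den)
    m_blocks = len(d_del)
    if m_blocks < 2:
        return float("nan"), m_blocks
    d_del = np.asarray(d_del)
    se = np.sqrt((m_blocks - 1) / m_blocks * np.sum((d_del - d_del.mean()) ** 2))
    return float(se), m_blocks


def d_statistic(
    G: GenotypeMatrix,
    p1: Sequence[str],
    p2: Sequence[str],
    p3: Sequence[str],
    outgroup: Sequence[str],
    block: int = 5_000_000,
    by_chromosome: bool = False,
) -> DStatResult | pd.DataFrame:
    """Patterson's D for (((P1, P2), P3), O) from genotype frequencies.

    Sites need at least one called genotype in each of the four groups;
    sites where the outgroup's two allele counts tie are skipped (no
    orientation).  ``block`` sets the jackknife block size in bp.  With
    ``by_chromosome``, returns a table with one genome row plus one row
    per chromosome (each chromosome jackknifed over its own blocks).
    """
    groups = [list(p1), list(p2), list(p3), list(outgroup)]
    flat = [s for g in groups for s in g]
    if len(set(flat)) != len(flat):
        raise ValueError("P1, P2, P3 and outgroup sample sets must be disjoint")
    freqs = [site_freqs(G, g) for g in groups]
    defined = np.ones(G.n_sites, dtype=bool)
    for f in freqs:
        defined &= f.n_hap > 0
    out_f = freqs[3].alt_freq
    tie = defined & (out_f == 0.5)
    if tie.any():
        logger.info("d_statistic: %d sites skipped (outgroup allele tie)", int(tie.sum()))
    usable = defined & ~tie
    n_dropped = int(np.sum(~usable))
    if n_dropped:
        logger.info("d_statistic: %d of %d sites unusable", n_dropped, G.n_sites)

    # orient so the outgroup major allele is ancestral
    flip = usable & (out_f > 0.5)
    p = np.vstack([f.alt_freq for f in freqs])
    p[:, flip] = 1.0 - p[:, flip]
    p = p[:, usable]
    abba, baba = site_patterns(p[0], p[1], p[2], p[3])

    num = abba - baba
    den = abba + baba
    if den.sum() == 0:
        raise ValueError("no informative sites: sum(ABBA + BABA) is zero")

    chrom = G.sites["chrom"].to_numpy()[usable]
    pos0 = G.sites["pos"].to_numpy()[usable] - 1
    chrom_codes = pd.factorize(chrom)[0]
    blocks = chrom_codes * 10_000_000 + pos0 // block

    def _result(mask: np.ndarray, scope: str) -> DStatResult:
        nm, dm = num[mask], den[mask]
        d = nm.sum() / dm.sum() if dm.sum() != 0 else float("nan")
        se, m = _jackknife(nm, dm, blocks[mask])
        if m < 2:
            logger.warning("d_statistic[%s]: <2 blocks, SE undefined", scope)
        z = d / se if np.isfinite(se) and se > 0 else float("nan")
        return DStatResult(
            d=float(d),
            abba_sum=float(abba[mask].sum()),
            baba_sum=float(baba[mask].sum()),
            se=se,
            z=float(z),
            n_blocks=m,
            n_sites_used=int(mask.sum()),
            scope=scope,
        )

    genome = _result(np.ones(len(num), dtype=bool), "genome")
    if not by_chromosome:
        return genome
    rows = [genome.to_frame()]
    for c in dict.fromkeys(chrom):
        rows.append(_result(chrom == c, str(c)).to_frame())
    return pd.concat(rows, ignore_index=True)
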