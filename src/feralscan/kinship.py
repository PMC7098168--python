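"""Centred-IBD kinship, nearest-cultivar origin assignment, founder hubs.

The kinship matrix is the centred realised-relationship form: genotype
dosages (0/1/2) are centred by twice the panel allele frequency at each
site and cross-multiplied,

    k[i][j] = sum_s (x_is - 2 p_s)(x_js - 2 p_s) / sum_s 2 p_s (1 - p_s),

with missing dosages mean-imputed (x = 2 p_s) for this computation
only.  Allele frequencies are taken from the combined panel passed in,
matching a single joint kinship run over weeds plus candidate ancestor
cultivars.  Each weed is then assigned to the cultivar maximising
kinship; cultivars that are nearest kin to many weeds are reported as
founder "hubs".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from feralscan.io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficients over an ordered sample panel."""

    samples: list[str]
    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        n = len(self.samples)
        if self.k.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample count")

    def value(self, a: str, b: str) -> float:
        ia, ib = self.samples.index(a), self.samples.index(b)
        return float(self.k[ia, ib])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.k, index=self.samples, columns=self.samples)


def centered_ibd_kinship(G: GenotypeMatrix, panel: Sequence[str]) -> KinshipMatrix:
    """Centred-IBD kinship matrix over ``panel`` samples.

    Centering frequencies come from the panel itself; monomorphic and
    fully missing sites contribute nothing.  Raises if no polymorphic
    site remains.
    """
    panel = list(panel)
    if len(panel) < 2:
        raise ValueError("kinship needs at least two samples")
    calls = G.calls[G.sample_indices(panel)].astype(float)
    miss = calls == MISSING
    calls[miss] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(calls, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic sites in panel: kinship undefined")
    x = calls[:, poly]
    p = p[poly]
    x = np.where(np.isnan(x), 2 * p, x)  # mean imputation
    xc = x - 2 * p
    denom = np.sum(2 * p * (1 - p))
    k = xc @ xc.T / denom
    k = (k + k.T) / 2.0  # enforce exact symmetry
    return KinshipMatrix(samples=panel, k=k)


def assign_origins(
    K: KinshipMatrix, weeds: Sequence[str], cultivars: Sequence[str]
) -> pd.DataFrame:
    """Assign each weed to its highest-kinship cultivar.

    Ties are broken toward the lexicographically smaller cultivar id
    and flagged.  Returns columns weed, best_cultivar, kinship,
    runner_up, runner_up_kinship, margin, tie.
    """
    weeds, cultivars = list(weeds), list(cultivars)
    if not cultivars:
        raise ValueError("empty cultivar panel")
    overlap = set(weeds) & set(cultivars)
    if overlap:
        raise ValueError(f"weed and cultivar panels overlap: {sorted(overlap)[:5]}")
    idx = {s: i for i, s in enumerate(K.samples)}
    cult_sorted = sorted(cultivars)  # lexicographic order for tie-breaks
    cidx = np.array([idx[c] for c in cult_sorted])
    rows = []
    for w in weeds:
        kin = K.k[idx[w], cidx]
        order = np.argsort(-kin, kind="stable")  # stable: ties keep lex order
        best, runner = order[0], (order[1] if len(order) > 1 else None)
        tie = bool(len(order) > 1 and kin[order[1]] == kin[best])
        rows.append(
            {
                "weed": w,
                "best_cultivar": cult_sorted[best],
                "kinship": float(kin[best]),
                "runner_up": cult_sorted[runner] if runner is not None else "",
                "runner_up_kinship": float(kin[runner]) if runner is not None else np.nan,
                "margin": float(kin[best] - kin[runner]) if runner is not None else np.nan,
                "tie": tie,
            }
        )
    return pd.DataFrame(rows)


def founder_hubs(assignments: pd.DataFrame, min_count: int = 2) -> pd.DataFrame:
    """Cultivars that are the nearest kin of at least ``min_count`` weeds.

    Sorted by weed count descending (cultivar id as tie-break);
    columns: cultivar, n_weeds, weeds (comma-joined ids).
    """
    if assignments.empty:
        raise ValueError("no assignments given")
    grouped = (
        assignments.groupby("best_cultivar")["weed"]
        .agg(list)
        .reset_index()
        .rename(columns={"best_cultivar": "cultivar", "weed": "weed_list"})
    )
    grouped["n_weeds"] = grouped["weed_list"].map(len)
    grouped = grouped[grouped["n_weeds"] >= min_count]
    grouped = grouped.sort_values(
        ["n_weeds", "cultivar"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    grouped["weeds"] = grouped["weed_list"].map(lambda ws: ",".join(ws))
    return grouped[["cultivar", "n_weeds", "weeds"]]


def founder_fraction(assignments: pd.DataFrame, cultivar: str) -> float:
    """Percent of weeds whose nearest cultivar is ``cultivar``.

    The 27-of-75 style summary: what share of a regional weed panel
    traces back to a single founder cultivar.
    """
    if assignments.empty:
        raise ValueError("no assignments given")
    n = int((assignments["best_cultivar"] == cultivar).sum())
    return 100.0 * n / len(assignments)
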