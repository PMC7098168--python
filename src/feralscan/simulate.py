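"""Seeded forward Wright-Fisher simulator of domestication and feralization.

The generator produces a truth-known panel mirroring the structure of a
crop de-domestication study: a wild source population; a cultivated
branch passed through a domestication bottleneck with selective sweeps
at designated domestication loci; a panel of cultivar sub-lineages; one
or more weedy populations founded from single cultivar lineages with
sweeps at feralization loci placed inside and outside the domestication
regions; optional wild-to-weed migration; an optional admixed weed
population; and a divergent outgroup for polarization.

Loci are unlinked and tracked as derived-allele frequencies; each
generation applies genic selection p' = p (1 + s) / (1 + s p) at
selected loci, then binomial drift at the population size.  Diploid
genotypes are drawn as Binomial(2, p) per individual, so simulated
populations are Hardy-Weinberg at every locus by construction.
Ancestral frequencies follow a neutral-like spectrum (mass proportional
to 1/i over derived counts i = 1 .. 2N_wild - 1); loci destined for
selection are redrawn until their initial derived frequency is at least
``sel_init_min``, emulating sweeps from standing variation rather than
from alleles likely lost to early drift.

Everything is driven by one NumPy RNG keyed by ``seed``: identical
configs give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
import numpy as np
import pandas as pd

from feralscan.io import GenotypeMatrix, IntervalSet, PopulationMap

logger = logging.getLogger(__name__)

#: Per-locus truth classes.
NEUTRAL = "neutral"
DOMESTICATION = "domestication"
FERAL_IN = "feralization_in"
FERAL_OUT = "feralization_out"


class SimConfigError(ValueError):
    """Raised for inconsistent simulator configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic crop/weed/wild panel.

    Defaults define a desk-scale analogue of a rice feralization study:
    a large wild population, a bottlenecked cultivated branch with
    sweeps at domestication loci, cultivar sub-lineages, and weed
    populations founded from single lineages with feralization sweeps
    both inside and outside domestication regions.  The mutation rate
    of such studies (~6.5e-9 per bp per generation) is recorded as
    metadata only: loci are unlinked and tracked as frequencies, so no
    new mutations arise during the simulated history.
    """

    # genome layout
    n_loci: int = 3000
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    # population sizes (diploid)
    N_wild: int = 1000
    N_crop: int = 200
    N_lineage: int = 100
    N_weed: int = 200
    # branch lengths (generations)
    T_wild: int = 150
    T_dom: int = 200
    T_lineage: int = 40
    T_feral: int = 100
    # selection
    s_dom: float = 0.15
    s_feral: float = 0.1
    sel_init_min: float = 0.05
    sweep_footprint: int = 75_000
    # fraction of T_dom over which domestication sweep onsets are
    # staggered (0 = all sweeps start at the domestication split;
    # 1 = onsets uniform over the whole domestication period, so some
    # sweeps are still in transit when sampled)
    dom_onset_spread: float = 0.0
    # locus classes and domestication-region layout
    n_dom_loci: int = 6
    n_feral_in: int = 3
    n_feral_out: int = 5
    dom_region_width: int = 300_000
    feral_margin: int = 200_000
    # cultivar panel and weed founding
    n_lineages: int = 4
    weed_founders: tuple[int, ...] = (0, 1)
    admixed: bool = False
    admix_alpha: float = 0.5
    # wild -> weed migration (into the first weed population)
    mig_rate: float = 0.0
    mig_gens: int = 50
    # sampling
    n_wild_samples: int = 20
    n_crop_samples: int = 6  # per cultivar lineage
    n_weed_samples: int = 20  # per weed population
    n_outgroup_samples: int = 10
    missing_rate: float = 0.01
    outgroup_div: float = 0.02
    # metadata only (frequency-based simulation has no mutation process)
    mutation_rate: float = 6.5e-9
    seed: int = 0

    def validate(self) -> None:
        counts = dict(
            n_loci=self.n_loci, n_chrom=self.n_chrom, chrom_length=self.chrom_length,
            n_dom_loci=self.n_dom_loci, n_feral_in=self.n_feral_in,
            n_feral_out=self.n_feral_out, n_lineages=self.n_lineages,
        )
        for name, v in counts.items():
            if v < 0:
                raise SimConfigError(f"{name} must be >= 0")
        for name, v in dict(
            mig_rate=self.mig_rate, admix_alpha=self.admix_alpha,
            missing_rate=self.missing_rate, outgroup_div=self.outgroup_div,
            sel_init_min=self.sel_init_min,
        ).items():
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1]")
        if self.n_feral_in > 0 and self.n_dom_loci == 0:
            raise SimConfigError(
                "n_feral_in > 0 requires at least one domestication region"
            )
        if any(f >= self.n_lineages for f in self.weed_founders):
            raise SimConfigError("weed founder lineage index out of range")
        if self.admixed and len(self.weed_founders) < 2:
            raise SimConfigError("admixed weed needs at least two weed populations")
        n_special = self.n_dom_loci + self.n_feral_in + self.n_feral_out
        if n_special > self.n_loci:
            raise SimConfigError("more selected loci than loci")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the genotypes.

    ``loci``: per-locus table (site_id, chrom, pos, locus_class,
    derived_is_ref).  ``freqs``: final derived-allele frequency per
    population per locus.  ``founders``: weed population -> founder
    cultivar lineage label.  ``config``: the SimConfig used.
    """

    loci: pd.DataFrame
    freqs: pd.DataFrame
    founders: dict[str, str]
    config: SimConfig

    def to_frame(self) -> pd.DataFrame:
        """Single flat table (loci columns + per-population frequencies)."""
        return pd.concat([self.loci.reset_index(drop=True), self.freqs], axis=1)


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    popmap: PopulationMap
    dom_regions: IntervalSet
    truth: SimTruth


# ---------------------------------------------------------------------------


def _neutral_spectrum_freqs(rng: np.random.Generator, n: int, two_n: int) -> np.ndarray:
    """Derived frequencies i/2N with P(i) proportional to 1/i, i = 1..2N-1."""
    i = np.arange(1, two_n)
    w = 1.0 / i
    w /= w.sum()
    draws = rng.choice(i, size=n, p=w)
    return draws / two_n


def _evolve(
    rng: np.random.Generator,
    p: np.ndarray,
    N: int,
    gens: int,
    s_vec: np.ndarray | None = None,
    onset: np.ndarray | None = None,
    mig_from: np.ndarray | None = None,
    m: float = 0.0,
    mig_gens: int = 0,
) -> np.ndarray:
    """Wright-Fisher recursion: genic selection, optional migration, drift.

    ``s_vec`` is a per-locus selection coefficient for the derived
    allele (p' = p (1 + s) / (1 + s p)); ``onset`` optionally delays
    each locus's selection until that generation.  Migration
    (p <- (1-m) p + m p_source) applies during the final ``mig_gens``
    generations.
    """
    p = p.copy()
    two_n = 2 * N
    use_sel = s_vec is not None and np.any(s_vec != 0.0)
    for g in range(gens):
        if use_sel:
            s_g = s_vec if onset is None else s_vec * (g >= onset)
            p = p * (1 + s_g) / (1 + s_g * p)
        if mig_from is not None and m > 0.0 and g >= gens - mig_gens:
            p = (1 - m) * p + m * mig_from
        p = rng.binomial(two_n, p) / two_n
    return p


def _layout(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[pd.DataFrame, IntervalSet]:
    """Place loci on chromosomes and build domestication regions.

    Domestication loci sit at evenly spaced region centres; the regions
    are ``dom_region_width`` windows around them.  Feralization-inside
    loci are offset slightly from region centres; feralization-outside
    loci keep at least ``feral_margin`` bp clear of any region so that
    truth classes stay unambiguous at scan-window scale.  Neutral loci
    fill the genome uniformly (some land inside regions, as in real
    data).
    """
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    L = cfg.chrom_length
    half = cfg.dom_region_width // 2

    dom_rows: list[tuple[str, int]] = []
    region_rows: list[tuple[str, int, int]] = []
    per_chrom = np.zeros(cfg.n_chrom, dtype=int)
    for k in range(cfg.n_dom_loci):
        per_chrom[k % cfg.n_chrom] += 1
    for ci, chrom in enumerate(chroms):
        k = per_chrom[ci]
        centers = [(j + 1) * L // (k + 1) for j in range(k)]
        for c in centers:
            dom_rows.append((chrom, int(c)))
            region_rows.append((chrom, max(0, c - half), min(L, c + half)))
    regions = (
        IntervalSet(pd.DataFrame(region_rows, columns=["chrom", "start", "end"])).normalize()
        if region_rows
        else IntervalSet()
    )

    feral_in_rows: list[tuple[str, int]] = []
    for j in range(cfg.n_feral_in):
        chrom, c = dom_rows[j % len(dom_rows)]
        # stay inside the region but off the domestication locus itself
        feral_in_rows.append((chrom, c + half // 4 + 1 + j))

    feral_out_rows: list[tuple[str, int]] = []
    if cfg.n_feral_out:
        forbidden = []
        for chrom, s, e in (regions.df.itertuples(index=False) if len(regions) else []):
            forbidden.append((chrom, s - cfg.feral_margin, e + cfg.feral_margin))
        candidates = []
        for ci, chrom in enumerate(chroms):
            grid = np.linspace(L // 20, L - L // 20, 50, dtype=np.int64)
            for g in grid:
                ok = all(
                    not (chrom == fc and fs <= g < fe) for fc, fs, fe in forbidden
                )
                if ok:
                    candidates.append((chrom, int(g)))
        if len(candidates) < cfg.n_feral_out:
            raise SimConfigError("not enough room for feralization-out loci")
        pick = np.linspace(0, len(candidates) - 1, cfg.n_feral_out).astype(int)
        feral_out_rows = [candidates[i] for i in pick]

    used = set(dom_rows) | set(feral_in_rows) | set(feral_out_rows)
    n_neutral = cfg.n_loci - cfg.n_dom_loci - cfg.n_feral_in - cfg.n_feral_out
    neutral_rows: list[tuple[str, int]] = []
    while len(neutral_rows) < n_neutral:
        need = n_neutral - len(neutral_rows)
        cs = rng.integers(0, cfg.n_chrom, size=need)
        ps = rng.integers(1, L, size=need)
        for c, p in zip(cs, ps):
            key = (chroms[c], int(p))
            if key not in used:
                used.add(key)
                neutral_rows.append(key)

    rows = (
        [(c, p, DOMESTICATION) for c, p in dom_rows]
        + [(c, p, FERAL_IN) for c, p in feral_in_rows]
        + [(c, p, FERAL_OUT) for c, p in feral_out_rows]
        + [(c, p, NEUTRAL) for c, p in neutral_rows]
    )
    loci = pd.DataFrame(rows, columns=["chrom", "pos0", "locus_class"])
    loci = loci.sort_values(["chrom", "pos0"], kind="mergesort").reset_index(drop=True)
    return loci, regions


def _sweep_multiplier(
    loci: pd.DataFrame, focal: np.ndarray, footprint: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus selection multiplier (and owning sweep) around focal loci.

    The focal locus gets 1; loci within ``footprint`` bp get a linearly
    decaying share max(0, 1 - d/footprint) of the sweep's selection
    coefficient (the maximum over nearby sweeps).  This emulates the
    hitchhiking footprint a hard sweep leaves on linked variation —
    full sweeps near the target, progressively weaker partial sweeps
    toward the edge — without modelling recombination explicitly.
    Returns (multiplier, owner) where owner is the site index of the
    dominating focal locus (-1 for unaffected loci).
    """
    mult = focal.astype(float)
    owner = np.where(focal, np.arange(len(focal)), -1)
    if footprint <= 0 or not focal.any():
        return mult, owner
    chrom = loci["chrom"].to_numpy()
    pos = loci["pos0"].to_numpy()
    for k, (c, p) in enumerate(zip(chrom[focal], pos[focal])):
        d = np.abs(pos - p)
        share = np.where((chrom == c) & (d <= footprint), 1.0 - d / footprint, 0.0)
        take = share > mult
        mult[take] = share[take]
        owner[take] = np.flatnonzero(focal)[k]
    return mult, owner


def simulate(config: SimConfig) -> SimResult:
    """Run the forward simulation and emit genotypes, popmap, regions, truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    loci, dom_regions = _layout(rng, cfg)
    S = len(loci)
    cls = loci["locus_class"].to_numpy()
    # sweeps drag loci within `sweep_footprint` bp of the selected site
    # with a distance-decaying intensity, so windowed scans and DAF
    # spectra see the footprint a real sweep would leave
    dom_mult, dom_owner = _sweep_multiplier(loci, cls == DOMESTICATION, cfg.sweep_footprint)
    feral_focal = (cls == FERAL_IN) | (cls == FERAL_OUT)
    feral_mult, _ = _sweep_multiplier(loci, feral_focal, cfg.sweep_footprint)
    selected = (dom_mult > 0) | (feral_mult > 0)

    # ancestral derived frequencies; selected loci start from standing
    # variation at frequency >= sel_init_min
    p0 = _neutral_spectrum_freqs(rng, S, 2 * cfg.N_wild)
    if selected.any() and cfg.sel_init_min > 0:
        lo, hi = cfg.sel_init_min, 1 - cfg.sel_init_min
        bad = selected & ((p0 < lo) | (p0 > hi))
        while bad.any():
            p0[bad] = _neutral_spectrum_freqs(rng, int(bad.sum()), 2 * cfg.N_wild)
            bad = selected & ((p0 < lo) | (p0 > hi))

    # wild branch: pure drift
    p_wild = _evolve(rng, p0, cfg.N_wild, cfg.T_wild)

    # crop branch: bottleneck + domestication sweeps, optionally with
    # staggered onsets (domestication as a protracted process)
    dom_onset = None
    if cfg.dom_onset_spread > 0 and (cls == DOMESTICATION).any():
        focal_idx = np.flatnonzero(cls == DOMESTICATION)
        sweep_onsets = rng.uniform(
            0, cfg.dom_onset_spread * cfg.T_dom, size=len(focal_idx)
        )
        onset_by_focal = dict(zip(focal_idx, sweep_onsets))
        dom_onset = np.array(
            [onset_by_focal.get(o, 0.0) for o in dom_owner], dtype=float
        )
    p_crop = _evolve(
        rng, p0, cfg.N_crop, cfg.T_dom, s_vec=cfg.s_dom * dom_mult, onset=dom_onset
    )

    # cultivar sub-lineages
    lineage_labels = [f"L{i:02d}" for i in range(cfg.n_lineages)]
    p_lineages = [
        _evolve(rng, p_crop, cfg.N_lineage, cfg.T_lineage) for _ in lineage_labels
    ]

    # weed populations founded from single cultivar lineages
    weed_labels: list[str] = []
    founders: dict[str, str] = {}
    p_weeds: list[np.ndarray] = []
    for wi, f in enumerate(cfg.weed_founders):
        label = f"weed{wi}"
        mig = cfg.mig_rate if wi == 0 else 0.0
        p_w = _evolve(
            rng,
            p_lineages[f],
            cfg.N_weed,
            cfg.T_feral,
            s_vec=cfg.s_feral * feral_mult,
            mig_from=p_wild,
            m=mig,
            mig_gens=min(cfg.mig_gens, cfg.T_feral),
        )
        weed_labels.append(label)
        founders[label] = lineage_labels[f]
        p_weeds.append(p_w)
    if cfg.admixed:
        p_adx = cfg.admix_alpha * p_weeds[0] + (1 - cfg.admix_alpha) * p_weeds[1]
        weed_labels.append("weed_admixed")
        founders["weed_admixed"] = (
            f"{founders['weed0']}x{founders['weed1']}"
        )
        p_weeds.append(p_adx)

    # outgroup: fixed ancestral except fixed derived at a small fraction of loci
    out_fixed_derived = rng.random(S) < cfg.outgroup_div

    # assemble samples
    sample_names: list[str] = []
    pop_rows: list[tuple[str, str, str, str]] = []
    blocks: list[np.ndarray] = []

    def _draw(label: str, role: str, subgroup: str, n: int, p: np.ndarray) -> None:
        g = rng.binomial(2, np.broadcast_to(p, (n, S)))
        blocks.append(g.astype(np.int8))
        for i in range(n):
            name = f"{label}_{i:03d}"
            sample_names.append(name)
            pop_rows.append((name, label, role, subgroup))

    _draw("wild", "wild", "", cfg.n_wild_samples, p_wild)
    for lab, p_l in zip(lineage_labels, p_lineages):
        _draw(f"cultivar_{lab}", "cultivated", lab, cfg.n_crop_samples, p_l)
    for lab, p_w in zip(weed_labels, p_weeds):
        _draw(lab, "weedy", founders[lab], cfg.n_weed_samples, p_w)
    g_out = np.where(out_fixed_derived, 2, 0)[None, :].repeat(cfg.n_outgroup_samples, axis=0)
    blocks.append(g_out.astype(np.int8))
    for i in range(cfg.n_outgroup_samples):
        name = f"outgroup_{i:03d}"
        sample_names.append(name)
        pop_rows.append((name, "outgroup", "outgroup", ""))

    derived_counts = np.vstack(blocks)

    # map derived counts to alt-allele counts; half the loci have the
    # derived allele as REF so polarization is exercised
    derived_is_ref = rng.random(S) < 0.5
    calls = np.where(derived_is_ref[None, :], 2 - derived_counts, derived_counts)

    # missingness mask
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(miss, -1, calls)

    # allele letters: ref/alt pairs drawn per locus
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=S)
    alt_off = rng.integers(1, 4, size=S)
    alt_idx = (ref_idx + alt_off) % 4

    sites = pd.DataFrame(
        {
            "chrom": loci["chrom"],
            "pos": loci["pos0"] + 1,
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
        }
    )
    G = GenotypeMatrix(sites, sample_names, calls.astype(np.int8))
    pm = PopulationMap(
        pd.DataFrame(pop_rows, columns=["sample", "population", "role", "subgroup"])
    )

    all_pops = (
        {"wild": p_wild}
        | {f"cultivar_{lab}": p for lab, p in zip(lineage_labels, p_lineages)}
        | {lab: p for lab, p in zip(weed_labels, p_weeds)}
        | {"outgroup": out_fixed_derived.astype(float)}
    )
    freqs = pd.DataFrame({f"p_{k}": v for k, v in all_pops.items()})
    truth_loci = pd.DataFrame(
        {
            "site_id": np.arange(S),
            "chrom": loci["chrom"],
            "pos": loci["pos0"] + 1,
            "locus_class": loci["locus_class"],
            "derived_is_ref": derived_is_ref,
            "sel_dom_mult": dom_mult,
            "sel_feral_mult": feral_mult,
        }
    )
    truth = SimTruth(loci=truth_loci, freqs=freqs, founders=founders, config=cfg)
    logger.info(
        "simulate: %d loci (%d dom, %d feral-in, %d feral-out), %d samples",
        S, int((cls == DOMESTICATION).sum()), int((cls == FERAL_IN).sum()),
        int((cls == FERAL_OUT).sum()), len(sample_names),
    )
    return SimResult(genotypes=G, popmap=pm, dom_regions=dom_regions, truth=truth)


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a parsed YAML/JSON mapping; seed is required."""
    if "seed" not in d:
        raise SimConfigError("config must specify a seed")
    known = {f.name for f in SimConfig.__dataclass_fields__.values()}
    unknown = set(d) - known
    if unknown:
        raise SimConfigError(f"unknown config keys: {sorted(unknown)}")
    if "weed_founders" in d:
        d = dict(d)
        d["weed_founders"] = tuple(d["weed_founders"])
    return SimConfig(**d)


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["weed_founders"] = list(d["weed_founders"])
    return d
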