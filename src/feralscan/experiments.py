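"""Seeded calibration and power studies run on the built-in simulator.

Each function sets up truth-known study conditions with the forward
simulator, runs the corresponding pipeline stage, and reports rates or
summary values.  The acceptance tests and the reproduction script both
call these, so reported numbers always come from a live computation.

Problem sizes are desk-scale analogues of the original study design:
thousands of unlinked loci over a few multi-megabase chromosomes, tens
of samples per population, and replicate counts large enough for the
binomial rates to be stable at the percentage level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from feralscan.daf import daf_ratio, daf_spectrum, derived_freq, polarize
from feralscan.diversity import site_freqs
from feralscan.dstat import d_statistic
from feralscan.kinship import assign_origins, centered_ibd_kinship, founder_fraction, founder_hubs
from feralscan.scan import (
    call_candidate_regions,
    filter_informative_windows,
    fst_windows,
    overlap_rate,
    z_transform,
)
from feralscan.simulate import SimConfig, simulate

WINDOW, STEP, Z_THRESHOLD = 100_000, 10_000, 3.0


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent 31-bit seeds derived from one master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# ABBA-BABA calibration and power


def _dstat_config(seed: int, mig_rate: float = 0.0, mig_gens: int = 50) -> SimConfig:
    # (((P1=cultivar, P2=weed), P3=wild), O): drift-only except migration
    return SimConfig(
        n_loci=2000,
        n_chrom=4,
        chrom_length=2_500_000,
        s_dom=0.0,
        s_feral=0.0,
        n_dom_loci=0,
        n_feral_in=0,
        n_feral_out=0,
        n_lineages=1,
        weed_founders=(0,),
        T_wild=400,
        T_dom=150,
        T_lineage=20,
        T_feral=50,
        n_wild_samples=20,
        n_crop_samples=20,
        n_weed_samples=20,
        n_outgroup_samples=10,
        mig_rate=mig_rate,
        mig_gens=mig_gens,
        seed=seed,
    )


def _one_dstat(seed: int, mig_rate: float, block: int = 500_000):
    res = simulate(_dstat_config(seed, mig_rate=mig_rate))
    pm = res.popmap
    return d_statistic(
        res.genotypes,
        pm.samples_for(population="cultivar_L00"),
        pm.samples_for(population="weed0"),
        pm.samples_for(population="wild"),
        pm.samples_for(role="outgroup"),
        block=block,
    )


def dstat_null_calibration(seed: int, n_reps: int = 200) -> dict:
    """No-gene-flow replicates: fraction with |Z_D| < 3, plus SE calibration.

    Also reports the ratio of the mean jackknife SE to the empirical SD
    of D across replicates (should be near 1 if the block jackknife is
    calibrated for unlinked loci).
    """
    seeds = _child_seeds(seed, n_reps)
    zs, ds, ses = [], [], []
    for s in seeds:
        r = _one_dstat(int(s), mig_rate=0.0)
        zs.append(r.z)
        ds.append(r.d)
        ses.append(r.se)
    zs = np.asarray(zs)
    frac = float(np.mean(np.abs(zs) < 3.0))
    return {
        "frac_abs_z_lt3": frac,
        "mean_d": float(np.mean(ds)),
        "se_over_empirical_sd": float(np.mean(ses) / np.std(ds, ddof=1)),
        "n_reps": n_reps,
    }


def dstat_migration_power(seed: int, n_reps: int = 100, mig_rate: float = 0.1) -> dict:
    """Wild->weed migration replicates: fraction with D > 0 and Z > 3."""
    seeds = _child_seeds(seed + 1, n_reps)
    hits = 0
    ds = []
    for s in seeds:
        r = _one_dstat(int(s), mig_rate=mig_rate)
        ds.append(r.d)
        if r.d > 0 and r.z > 3:
            hits += 1
    return {"power": hits / n_reps, "mean_d": float(np.mean(ds)), "n_reps": n_reps}


# ---------------------------------------------------------------------------
# F_ST scan: sweep recovery and false positives


def _scan_config(seed: int, n_feral_in: int = 1, n_feral_out: int = 2,
                 s_feral: float = 0.1, dom_region_width: int = 300_000) -> SimConfig:
    # dense loci (~500 per 100-kb window; real panels are denser still)
    # so window F_ST averages over enough sites, on a genome large
    # enough that sweep footprints stay a small fraction of all windows
    # (the Z-outlier logic needs an intact background tail)
    return SimConfig(
        n_loci=90_000,
        n_chrom=3,
        chrom_length=6_000_000,
        n_dom_loci=4,
        n_feral_in=n_feral_in,
        n_feral_out=n_feral_out,
        s_feral=s_feral,
        T_feral=100,
        N_weed=500,
        N_lineage=200,
        T_lineage=20,
        dom_region_width=dom_region_width,
        n_lineages=2,
        weed_founders=(0,),
        n_crop_samples=15,
        n_weed_samples=25,
        seed=seed,
    )


def _scan_weed_vs_crop(res) -> pd.DataFrame:
    pm = res.popmap
    weed = pm.samples_for(population="weed0")
    crop = pm.samples_for(role="cultivated")
    table = fst_windows(res.genotypes, weed, crop, window=WINDOW, step=STEP)
    table = filter_informative_windows(table)
    table["z_fst"] = z_transform(table["fst"])
    return table


def region_recovery(seed: int, n_reps: int = 50, n_null: int = 40) -> dict:
    """Feralization-sweep recovery and neutral false-positive window rate.

    Recovery: fraction of implanted feralization loci (s = 0.1, 100
    generations) covered by a called Z > 3 region, over replicates.
    False positives: fraction of windows exceeding Z > 3 in fully
    neutral replicates, compared against three times the Gaussian upper
    tail P(Z > 3).
    """
    seeds = _child_seeds(seed + 2, n_reps)
    covered = total = 0
    for s in seeds:
        res = simulate(_scan_config(int(s)))
        table = _scan_weed_vs_crop(res)
        regions = call_candidate_regions(table, z_threshold=Z_THRESHOLD)
        truth = res.truth.loci
        feral = truth[truth["locus_class"].isin(["feralization_in", "feralization_out"])]
        inside = regions.intervals.contains(
            feral["chrom"].to_numpy(), feral["pos"].to_numpy() - 1
        )
        covered += int(inside.sum())
        total += len(feral)

    null_seeds = _child_seeds(seed + 3, n_null)
    n_sig = n_win = 0
    for s in null_seeds:
        res = simulate(
            _scan_config(int(s), n_feral_in=0, n_feral_out=0, s_feral=0.0)
        )
        table = _scan_weed_vs_crop(res)
        z = table["z_fst"].to_numpy()
        n_sig += int(np.sum(z > Z_THRESHOLD))
        n_win += int(np.sum(np.isfinite(z)))
    from scipy.stats import norm

    tail = float(norm.sf(Z_THRESHOLD))
    return {
        "recovery_rate": covered / total,
        "fp_window_rate": n_sig / n_win,
        "gaussian_tail_x3": 3 * tail,
        "n_reps": n_reps,
        "n_null_reps": n_null,
    }


def overlap_direction(seed: int, n_reps: int = 5) -> dict:
    """Overlap rate with feralization loci all outside vs all inside
    domestication regions (the directional logic of the overlap test)."""
    out_rates, in_rates = [], []
    for s in _child_seeds(seed + 4, n_reps):
        res = simulate(_scan_config(int(s), n_feral_in=0, n_feral_out=3))
        table = _scan_weed_vs_crop(res)
        regions = call_candidate_regions(table, z_threshold=Z_THRESHOLD)
        out_rates.append(overlap_rate(regions, res.dom_regions))
    for s in _child_seeds(seed + 5, n_reps):
        # wider regions so a called sweep region (sweep footprint plus
        # one window of slop on each side) sits fully inside
        res = simulate(
            _scan_config(int(s), n_feral_in=3, n_feral_out=0, dom_region_width=500_000)
        )
        table = _scan_weed_vs_crop(res)
        regions = call_candidate_regions(table, z_threshold=Z_THRESHOLD)
        in_rates.append(overlap_rate(regions, res.dom_regions))
    return {
        "rate_feral_outside": float(np.mean(out_rates)),
        "rate_feral_inside": float(np.mean(in_rates)),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# Kinship founder recovery


def founder_recovery(seed: int, founder: int = 7) -> dict:
    """Recover the founder lineage of a weed population by kinship.

    One weed population is founded from cultivar lineage ``founder``
    among 20 lineages; reports the fraction of weeds whose
    highest-kinship cultivar belongs to that lineage, and whether the
    hub detector's top cultivar does.
    """
    cfg = SimConfig(
        n_loci=2000,
        n_chrom=2,
        chrom_length=5_000_000,
        n_lineages=20,
        weed_founders=(founder,),
        n_crop_samples=5,
        n_weed_samples=30,
        T_lineage=40,
        T_feral=60,
        N_lineage=100,
        N_weed=200,
        n_dom_loci=4,
        n_feral_in=2,
        n_feral_out=3,
        seed=seed,
    )
    res = simulate(cfg)
    pm = res.popmap
    weeds = pm.samples_for(role="weedy")
    cultivars = pm.samples_for(role="cultivated")
    K = centered_ibd_kinship(res.genotypes, weeds + cultivars)
    assignments = assign_origins(K, weeds, cultivars)
    founder_label = res.truth.founders["weed0"]
    founder_samples = set(pm.samples_for(subgroup=founder_label))
    frac = float(np.mean(assignments["best_cultivar"].isin(founder_samples)))
    hubs = founder_hubs(assignments, min_count=2)
    top_is_founder = bool(len(hubs) and hubs.iloc[0]["cultivar"] in founder_samples)
    return {
        "frac_assigned_to_founder": frac,
        "hub_top_is_founder": top_is_founder,
        "n_weeds": len(weeds),
        "n_cultivars": len(cultivars),
    }


def nanjing_style_founder_fraction(n_to_founder: int = 27, n_total: int = 75) -> float:
    """Founder-share arithmetic on a tallied assignment table.

    Builds an assignment table in which ``n_to_founder`` of ``n_total``
    weeds point to one founder cultivar and the rest are spread over
    other cultivars, then computes the founder's share in percent.
    """
    rows = []
    for i in range(n_total):
        best = "founder_hub" if i < n_to_founder else f"cultivar_{i:03d}"
        rows.append({"weed": f"weed_{i:03d}", "best_cultivar": best})
    return founder_fraction(pd.DataFrame(rows), "founder_hub")


# ---------------------------------------------------------------------------
# DAF ratio shape


def daf_ratio_shape(seed: int, n_reps: int = 20) -> dict:
    """High-DAF enrichment inside domestication regions in the cultivated pool.

    For each replicate the cultivated panel's DAF spectrum is computed
    inside and outside the domestication regions; success means the
    in/out proportion ratio exceeds 1 in both of the top two DAF bins
    (the right arm of the U shape left by domestication sweeps).
    """
    seeds = _child_seeds(seed + 6, n_reps)
    hits = 0
    top_ratios = []
    for s in seeds:
        # many domestication sweeps with onsets staggered over the whole
        # domestication period, so in-transit sweeps populate the whole
        # right arm of the spectrum rather than piling up at fixation
        cfg = SimConfig(
            n_loci=8000,
            n_chrom=4,
            chrom_length=5_000_000,
            n_dom_loci=20,
            dom_region_width=300_000,
            n_feral_in=0,
            n_feral_out=0,
            s_dom=0.15,
            T_dom=200,
            dom_onset_spread=1.0,
            N_crop=500,
            n_lineages=2,
            weed_founders=(0,),
            n_crop_samples=25,
            seed=int(s),
        )
        res = simulate(cfg)
        pm = res.popmap
        G = res.genotypes
        pol = polarize(G, pm.samples_for(role="outgroup"), min_outgroup=8)
        freqs = site_freqs(G, pm.samples_for(role="cultivated"))
        dafs = derived_freq(freqs, pol)
        spec_dom, spec_non = daf_spectrum(dafs, G.sites, res.dom_regions, n_bins=20)
        ratio = daf_ratio(spec_dom, spec_non)
        top2 = ratio[-2:]
        top_ratios.append(top2)
        if np.all(np.isfinite(top2)) and np.all(top2 > 1.0):
            hits += 1
    return {
        "frac_u_shape": hits / n_reps,
        "mean_top_bin_ratio": float(np.nanmean([t[-1] for t in top_ratios])),
        "n_reps": n_reps,
    }
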