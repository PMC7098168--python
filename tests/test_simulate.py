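"""Forward simulator: determinism, layout, truth tables, HWE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from feralscan import SimConfig, simulate, write_vcf
from feralscan.simulate import SimConfigError, config_from_dict


def small_cfg(**kw):
    base = dict(
        n_loci=1500,
        n_chrom=2,
        chrom_length=2_000_000,
        n_dom_loci=2,
        n_feral_in=1,
        n_feral_out=2,
        n_lineages=2,
        weed_founders=(0,),
        n_wild_samples=10,
        n_crop_samples=5,
        n_weed_samples=10,
        seed=77,
    )
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_identical_seed_identical_output(self, tmp_path):
        r1, r2 = simulate(small_cfg()), simulate(small_cfg())
        np.testing.assert_array_equal(r1.genotypes.calls, r2.genotypes.calls)
        pd.testing.assert_frame_equal(r1.genotypes.sites, r2.genotypes.sites)
        pd.testing.assert_frame_equal(r1.truth.to_frame(), r2.truth.to_frame())
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(r1.genotypes, p1)
        write_vcf(r2.genotypes, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self):
        r1 = simulate(small_cfg())
        r2 = simulate(small_cfg(seed=78))
        assert not np.array_equal(r1.genotypes.calls, r2.genotypes.calls)


class TestLayoutAndTruth:
    def test_class_counts_match_config(self):
        res = simulate(small_cfg())
        counts = res.truth.loci["locus_class"].value_counts()
        assert counts["domestication"] == 2
        assert counts["feralization_in"] == 1
        assert counts["feralization_out"] == 2
        assert counts["neutral"] == 1500 - 5

    def test_positions_strictly_increasing(self):
        sites = simulate(small_cfg()).genotypes.sites
        for _, grp in sites.groupby("chrom"):
            assert (np.diff(grp["pos"]) > 0).all()

    def test_feralization_loci_placement(self):
        """feralization_in loci sit inside domestication regions;
        feralization_out loci keep the configured margin clear."""
        cfg = small_cfg(n_feral_in=2, n_feral_out=3, feral_margin=150_000)
        res = simulate(cfg)
        truth = res.truth.loci
        fin = truth[truth["locus_class"] == "feralization_in"]
        assert res.dom_regions.contains(
            fin["chrom"].to_numpy(), fin["pos"].to_numpy() - 1
        ).all()
        fout = truth[truth["locus_class"] == "feralization_out"]
        grown = res.dom_regions.df.assign(
            start=lambda d: (d["start"] - cfg.feral_margin + 1).clip(lower=0),
            end=lambda d: d["end"] + cfg.feral_margin - 1,
        )
        from feralscan import IntervalSet

        assert not IntervalSet(grown).normalize().contains(
            fout["chrom"].to_numpy(), fout["pos"].to_numpy() - 1
        ).any()

    def test_popmap_covers_all_samples(self):
        res = simulate(small_cfg())
        assert set(res.popmap.df["sample"]) == set(res.genotypes.samples)
        assert set(res.popmap.df["role"]) == {"wild", "cultivated", "weedy", "outgroup"}

    def test_founder_recorded(self):
        res = simulate(small_cfg(weed_founders=(1,)))
        assert res.truth.founders["weed0"] == "L01"

    def test_outgroup_fixed_per_site(self):
        """Outgroup samples are identical haplotypes (fixed per locus)."""
        res = simulate(small_cfg(missing_rate=0.0))
        og = res.popmap.samples_for(role="outgroup")
        calls = res.genotypes.calls[res.genotypes.sample_indices(og)]
        assert (calls == calls[0]).all()
        assert set(np.unique(calls)) <= {0, 2}


class TestConfigValidation:
    def test_feral_in_requires_dom_regions(self):
        with pytest.raises(SimConfigError, match="domestication region"):
            simulate(small_cfg(n_dom_loci=0, n_feral_in=1))

    def test_founder_index_range(self):
        with pytest.raises(SimConfigError, match="founder"):
            simulate(small_cfg(weed_founders=(5,)))

    def test_config_from_dict_requires_seed(self):
        with pytest.raises(SimConfigError, match="seed"):
            config_from_dict({"n_loci": 10})

    def test_config_from_dict_rejects_unknown_keys(self):
        with pytest.raises(SimConfigError, match="unknown"):
            config_from_dict({"seed": 1, "bogus": 2})


class TestGenotypeSampling:
    def test_hardy_weinberg_consistency(self):
        """Sampled genotype counts are HWE-consistent with the simulated
        population frequency at >=97% of testable loci (alpha 0.01)."""
        cfg = small_cfg(n_loci=2000, n_wild_samples=100, missing_rate=0.0)
        res = simulate(cfg)
        wild = res.popmap.samples_for(role="wild")
        calls = res.genotypes.calls[res.genotypes.sample_indices(wild)]
        p_wild = res.truth.freqs["p_wild"].to_numpy()
        derived_is_ref = res.truth.loci["derived_is_ref"].to_numpy()
        # calls count alt alleles; convert to derived-allele counts
        derived = np.where(derived_is_ref[None, :], 2 - calls, calls)
        n = len(wild)
        pvals = []
        for j in np.flatnonzero((p_wild > 0.1) & (p_wild < 0.9)):
            obs = np.bincount(derived[:, j], minlength=3)
            p = p_wild[j]
            exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            pvals.append(stats.chisquare(obs, exp).pvalue)
        pvals = np.asarray(pvals)
        assert len(pvals) > 200
        assert np.mean(pvals > 0.01) >= 0.97

    def test_missing_rate_applied(self):
        res = simulate(small_cfg(missing_rate=0.1))
        frac = np.mean(res.genotypes.calls == -1)
        assert 0.07 < frac < 0.13

    def test_truth_freqs_match_samples(self):
        """Sampled allele frequencies track the recorded truth frequencies."""
        res = simulate(small_cfg(n_weed_samples=50, missing_rate=0.0))
        weed = res.popmap.samples_for(population="weed0")
        calls = res.genotypes.calls[res.genotypes.sample_indices(weed)]
        derived_is_ref = res.truth.loci["derived_is_ref"].to_numpy()
        derived = np.where(derived_is_ref[None, :], 2 - calls, calls)
        sample_freq = derived.mean(axis=0) / 2
        truth_freq = res.truth.freqs["p_weed0"].to_numpy()
        assert np.corrcoef(sample_freq, truth_freq)[0, 1] > 0.98


def test_feral_sweep_differentiates_weed_from_crop():
    """Selection at feralization loci drives high weed-vs-crop
    differentiation while domestication loci stay shared."""
    from feralscan import wc_fst_site, site_freqs

    res = simulate(small_cfg(s_feral=0.1, T_feral=100, N_weed=500, seed=5))
    pm, G = res.popmap, res.genotypes
    fa = site_freqs(G, pm.samples_for(population="weed0"))
    fb = site_freqs(G, pm.samples_for(role="cultivated"))
    a, b, c = wc_fst_site(fa, fb)
    with np.errstate(invalid="ignore"):
        theta = a / (a + b + c)
    truth = res.truth.loci
    # average over the whole sweep footprint: any single designated
    # locus can lose its standing variation in the founding lineage
    feral = (truth["sel_feral_mult"].to_numpy() >= 0.8)
    dom = (truth["sel_dom_mult"].to_numpy() >= 0.8)
    assert feral.sum() > 10 and dom.sum() > 10
    assert np.nanmean(theta[feral]) > 0.25
    # domestication sweeps are shared by weed and crop, so those loci are
    # weakly differentiated or entirely uninformative (NaN theta)
    dom_theta = theta[dom]
    dom_mean = np.nanmean(dom_theta) if np.isfinite(dom_theta).any() else 0.0
    assert np.nanmean(theta[feral]) > dom_mean + 0.2
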