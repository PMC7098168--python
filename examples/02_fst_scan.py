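"""Windowed F_ST scan: find de-domestication regions in a weed genome.

Simulates a weed population carrying feralization sweeps, scans
weed-vs-cultivar F_ST in 100-kb windows (10-kb step), calls Z > 3
candidate regions, and reports their overlap with the known
domestication regions.
"""

from feralscan import call_candidate_regions, fst_windows, overlap_rate, simulate, SimConfig
from feralscan.scan import filter_informative_windows, z_transform

cfg = SimConfig(
    n_loci=30_000,
    n_chrom=2,
    chrom_length=6_000_000,
    n_dom_loci=2,
    n_feral_in=1,
    n_feral_out=2,
    N_weed=500,
    n_crop_samples=15,
    n_weed_samples=25,
    seed=3,
)
res = simulate(cfg)
pm = res.popmap

table = fst_windows(
    res.genotypes,
    pm.samples_for(population="weed0"),
    pm.samples_for(role="cultivated"),
    window=100_000,
    step=10_000,
)
table = filter_informative_windows(table)
table["z_fst"] = z_transform(table["fst"])
regions = call_candidate_regions(table, z_threshold=3.0)

print(f"scanned {len(table)} windows; called {len(regions)} candidate regions:")
print(regions.regions.to_string(index=False))
rate = overlap_rate(regions, res.dom_regions)
print(f"\noverlap with domestication regions: {rate:.1f}% of candidate bp")
truth = res.truth.loci
feral = truth[truth["locus_class"].str.startswith("feralization")]
hit = regions.intervals.contains(feral["chrom"].to_numpy(), feral["pos"].to_numpy() - 1)
print(f"implanted feralization loci covered: {hit.sum()}/{len(feral)}")
# A low overlap rate means weed adaptation targeted loci outside the
# domestication regions - the de-domestication signature.
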