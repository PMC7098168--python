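"""Generate a truth-known wild/cultivated/weedy/outgroup panel.

Builds a small synthetic panel with two cultivar lineages, one weed
population founded from the first lineage, designated domestication and
feralization loci, and a divergent outgroup, then prints what was made.
"""

from feralscan import SimConfig, simulate

cfg = SimConfig(
    n_loci=3000,
    n_chrom=2,
    chrom_length=3_000_000,
    n_dom_loci=3,
    n_feral_in=1,
    n_feral_out=2,
    n_lineages=2,
    weed_founders=(0,),
    seed=7,
)
res = simulate(cfg)

print(f"{res.genotypes.n_sites} SNPs x {res.genotypes.n_samples} samples")
print(res.popmap.df.groupby(["role", "population"]).size())
print("\ndomestication regions (bp):")
print(res.dom_regions.df.to_string(index=False))
print("\nlocus classes:")
print(res.truth.loci["locus_class"].value_counts().to_string())
# Each feralization locus is a sweep target in the weed branch only;
# domestication loci were swept before the weed split and are shared.
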