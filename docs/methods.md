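# Methods

This note documents the statistical procedures implemented in
`feralscan`, the forward simulator that backs its tests, and the design
choices made where conventions differ between tools. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Data model and conventions

Genotypes are diploid alt-allele dosages (0/1/2) with a missing
sentinel, for biallelic SNPs only; phasing is ignored (all statistics
are genotype- or frequency-based). Coordinates are 0-based half-open
internally and 1-based in VCF I/O and reports. Missing genotypes are
excluded from allele counts (complete-case within each population), so
the called haplotype number varies by site; the one exception is the
kinship matrix, which mean-imputes missing dosages (see below). Interval
sets (domestication regions, called candidate regions) are normalised to
sorted, non-overlapping intervals; overlapping or bookended intervals
merge.

## Diversity and differentiation

Per-site diversity is the mean pairwise difference among called
haplotypes, π = 2k(n−k)/(n(n−1)) for k alt alleles among n haplotypes.
Windowed π divides the sum of per-site values by the full window length
in bp (the VCFtools `--window-pi` convention), so monomorphic and
uncalled positions count as invariant sequence. Terminal windows are
truncated at the chromosome end, use their true length as divisor, and
are flagged.

F\_ST uses the two-population Weir–Cockerham (1984) variance components
a (among populations), b (among individuals within populations) and c
(within individuals), computed from called diploid counts, allele
frequencies and observed heterozygote fractions. Windowed F\_ST is the
ratio of sums Σa/Σ(a+b+c) over informative sites (VCFtools "weighted"
estimate). Sites fixed for the same allele in both populations have
a+b+c = 0 and are excluded with a logged count; negative per-site
components are retained, so near-zero windows can be slightly negative.
Sites with fewer than two called diploids in either population are
skipped.

### Candidate-region calling

Window F\_ST values are standardised with the population (n-denominator)
standard deviation over all finite windows of one comparison; windows
with Z > 3 (one-sided, elevated differentiation) are merged into
candidate de-domestication regions, recording each region's peak Z and
window count. Two filters keep the pooled Z-standardisation meaningful:

* `min_sites` (default 10): a ratio-of-sums over a handful of sites is
  wildly noisy, so sparse windows carry NaN.
* `filter_informative_windows` (used by the bundled studies): a window's
  sampling variance scales inversely with its informative-site count,
  and windows far below the typical count (sweep cores fixed in both
  populations, chromosome ends) otherwise dominate the upper tail of the
  pooled Z distribution as a variance mixture. Windows under 75% of the
  median informative count are masked.

The overlap rate is 100 × (candidate bp intersecting domestication
regions) / (candidate bp), with a window-count variant
(`window_overlap_rate`) for comparison. Empty candidate sets report 0%
with a warning.

## Outgroup polarization and DAF spectra

The ancestral allele at a site is the single allele carried by all
called outgroup genotypes, provided at least `min_outgroup` (default 8)
outgroup individuals are called; sites with a polymorphic or
under-called outgroup stay unassigned. A majority-rule alternative
(ancestral = outgroup major allele) is available behind a flag; the
strict rule is the deterministic default. DAF is the focal population's
frequency of the non-ancestral allele.

Spectra use B equal-width bins (default 20) indexed by floor(DAF·B),
with DAF = 1 clamped into the top bin and DAF = 0 sites excluded by
default (both behaviours are flags). Sites are split by membership in
the domestication-region interval set, and the per-bin ratio defaults to
normalised proportions rather than raw counts so unequal region sizes do
not dominate. Domestication sweeps concentrate in-region mass at high
DAF, which is what makes the ratio's right arm rise above 1.

## ABBA-BABA

With derived allele frequencies p₁…p₄ for (((P1, P2), P3), O), per-site
weights are ABBA = (1−p₁)p₂p₃(1−p₄) and BABA = p₁(1−p₂)p₃(1−p₄);
D = Σ(ABBA−BABA)/Σ(ABBA+BABA) over sites with all four frequencies
defined. Sites are oriented so that the outgroup **major** allele is
ancestral; an exact 50/50 outgroup tie cannot be oriented and is skipped
(logged). A polymorphic outgroup is otherwise retained and down-weighted
through the (1−p₄) factor. The standard error is a delete-one block
jackknife over genomic blocks (default 5 Mb, configurable; the bundled
studies use 500 kb so a desk-scale genome still yields ~20 blocks), with
se² = ((m−1)/m)·Σ(D₋ⱼ − mean)². Z = D/se. Fewer than two non-empty
blocks leaves the SE undefined with a warning. A per-chromosome grouping
option reports one row per chromosome plus the genome-wide row.

## Kinship and founder inference

The kinship matrix is the centred realised-relationship form
K = (X − 2p)(X − 2p)ᵀ / Σ 2p(1−p), with centering frequencies taken from
the combined panel supplied to the call (one joint run over weeds plus
candidate cultivars) and missing dosages replaced by 2p for this
computation only. Monomorphic sites drop out. Note the centering itself
induces a small negative expected off-diagonal of order −1/(n−1) in a
panel of n unrelated samples; it vanishes for large panels.

Each weed is assigned the cultivar maximising kinship; ties break toward
the lexicographically smaller cultivar id and are flagged, and the
runner-up and margin are reported so low-confidence assignments are
visible. Founder "hubs" are cultivars that are nearest kin to at least
`min_count` weeds, ranked by weed count; `founder_fraction` turns an
assignment table into the share of a regional panel traced to one
founder.

## The forward simulator

The generator is a frequency-based Wright–Fisher simulation of unlinked
loci, chosen over coalescent machinery because every statistic the
pipeline computes is frequency- or genotype-based and unlinked loci keep
analytic envelopes checkable. Per locus:

1. the ancestral derived frequency is drawn from a neutral-like spectrum
   (mass ∝ 1/i over derived counts i = 1…2N_wild−1);
2. the wild branch drifts for T_wild generations at size N_wild;
3. the crop branch starts from the same ancestral frequencies and runs
   T_dom generations of genic selection p′ = p(1+s)/(1+sp) at
   domestication loci (s_dom, favouring derived) plus drift at the
   bottlenecked N_crop; cultivar sub-lineages then drift independently
   for T_lineage generations at N_lineage;
4. each weed population is founded from one lineage's frequencies and
   runs T_feral generations with selection s_feral at feralization loci
   and drift at N_weed, optionally receiving wild migrants
   (p ← (1−m)p + m·p_wild) in the final mig_gens generations;
5. an optional admixed weed is the frequency mixture α·p_A + (1−α)·p_B;
6. diploid genotypes are Binomial(2, p) per individual — populations are
   Hardy–Weinberg by construction;
7. the outgroup is fixed ancestral except fixed derived at a random
   `outgroup_div` fraction of loci (realistic polarization error);
8. ref/alt labels are randomised per locus (so polarization is actually
   exercised) and calls are masked missing at `missing_rate`.

A single NumPy RNG keyed by `seed` drives everything; identical configs
give bit-identical outputs, including VCF bytes (fixed header).

Three design choices deserve emphasis:

* **Sweep footprints.** A hard sweep in real data drags linked variation
  across tens of kilobases. With strictly unlinked loci a sweep would
  touch exactly one site, which no 100-kb windowed scan could ever see.
  Each selected locus therefore projects a linearly decaying share of
  its selection coefficient onto loci within `sweep_footprint` bp
  (default 75 kb): full sweeps near the target, partial sweeps toward
  the edge. This is a deterministic stand-in for hitchhiking, not a
  recombination model.
* **Standing variation.** Loci designated as sweep targets are redrawn
  until their ancestral derived frequency is at least `sel_init_min`
  (default 0.05), emulating selection on standing variation rather than
  on alleles overwhelmingly lost to early drift. A designated target can
  still lose its variation in the founding lineage — the truth table
  records what actually happened.
* **Staggered domestication onsets.** `dom_onset_spread` staggers each
  domestication sweep's start uniformly over that fraction of T_dom
  (default 0: all start at the split). With simultaneous full-length
  sweeps every target reaches fixation and the DAF spectrum's in-region
  mass collapses onto the top bin; staggered onsets emulate protracted
  domestication and populate the whole high-DAF arm.

What the simulator does **not** emulate: linkage and recombination (so
no LD-based statistics can be tested), new mutation during the simulated
history, sequencing error beyond uniform missingness, selfing (real
weedy rice is highly selfing; genotypes here are HWE), and realistic
demographic trajectories — branch lengths and sizes are short, scaled
histories, not fits to any inferred N_e curve (the assumed real-data
mutation rate is carried as metadata only). Passing tests therefore
demonstrate the correctness and calibration of the statistics under a
clean frequency-drift model, not robustness to LD, inbreeding or
demographic misspecification in real data.

## Study conditions behind the reported numbers

The calibration/power studies in `feralscan.experiments` (shared by the
acceptance tests and `scripts/acceptance.py`) fix these desk-scale
conditions:

* **D-statistic studies**: 2000 unlinked loci on 4×2.5 Mb, pure drift
  (no sweeps), deep wild divergence (T_wild = 400 at N = 1000) matching
  the deep wild-vs-cultivated split of the motivating system, 20
  samples per population, 500-kb jackknife blocks (20 blocks); 200 null
  replicates and 100 migration replicates (m = 0.1 into the weed for
  its final 50 generations). Reported: the |Z| < 3 null rate, the
  jackknife-SE-to-empirical-SD ratio, and migration power.
* **Scan studies**: 90,000 loci on 3×6 Mb (~5 SNPs/kb — still far
  sparser than real resequencing panels), N_weed = 500, two cultivar
  lineages of 15 samples, 25 weed samples; sweeps s_feral = 0.1 for
  T_feral = 100 generations, one feralization locus inside and two
  outside the domestication regions; 50 sweep replicates and 40
  fully-neutral replicates for the false-positive rate, which is
  compared against 3× the Gaussian P(Z > 3) tail.
* **Overlap direction**: the same scan design with all feralization
  loci outside (expect ≈ 0% overlap) or all inside wider 500-kb
  domestication regions (expect ≈ 100%; the wider regions ensure a
  called region — sweep footprint plus one window of slop per side —
  fits inside its domestication region).
* **Founder recovery**: 20 cultivar lineages (T_lineage = 40 at
  N = 100) of 5 samples each, 30 weeds founded from lineage 7.
* **DAF ratio**: 20 replicates of 8000 loci on 4×5 Mb with 20
  domestication sweeps staggered over the whole T_dom = 200 at
  N_crop = 500; success is a ratio > 1 in both of the two highest DAF
  bins of the cultivated panel.

Replicate counts and genome sizes were chosen so each study finishes in
minutes on one CPU while leaving the binomial uncertainty of each
reported rate comfortably inside its stated band.

## Numerical details and degenerate inputs

Z-transformation requires at least two finite values and nonzero spread
(errors otherwise); NaN passes through. `z > threshold` is strict, so a
window exactly at the threshold is not called. Division-by-zero cases
(no informative sites in a window, empty spectrum bins, Σ(ABBA+BABA)=0,
single jackknife block, zero candidate bp) yield NaN/empty results or
explicit errors as documented on each function, never silent zeros —
except the overlap rate of an empty candidate set, which is defined as
0% with a warning. Kinship ties are broken deterministically; all
simulator sampling orders are fixed, so results are reproducible across
platforms for a given seed.
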