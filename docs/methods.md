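# Methods

This note documents the statistical procedures implemented in `polysweep`,
the assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that make results reproducible.

## Data model

Lines are assumed inbred (self-pollinated), so each line contributes one
haplotype per subgenome. Genotype calls are coded ref-homozygote /
alt-homozygote / heterozygote / missing; heterozygous calls are treated as
residual heterozygosity or error. Site filters keep variants called in at
least 46 of 62 lines (≥75%) with at most one heterozygous accession, recode
surviving heterozygous calls to missing, and then drop variants with minor
allele frequency ≤ 1.6% (strict inequality; with 62 lines this keeps
singletons at 1/62 ≈ 1.61%). All frequency computations use non-missing
homozygous calls only.

Genetic positions are interpolated piecewise-linearly between sparse
(chromosome, bp, cM) anchors; positions outside the anchored span are
clamped to the terminal anchor's cM, which keeps interpolated positions
monotone. Coordinates are 1-based bp internally (as in VCF); all window and
BED outputs are 0-based half-open, with windows anchored at multiples of
the step size starting at 0.

## Diversity statistics

*Per-site π* is the unbiased heterozygosity 2p(1−p)·n/(n−1) with n the
non-missing haplotype count. *Window π* (default 2 Mb windows, 1 Mb step)
is the sum of site values divided by the window's covered base pairs, so
windows with different coverage are comparable; windows under 10 kb of
coverage are reported but excluded from outlier calling. *Tajima's D* uses
the standard segregating-sites constants; because missing data make n vary
by site, each window uses the median non-missing sample size of its
segregating sites. D is undefined (NaN) for windows without segregating
sites.

*F*<sub>ST</sub> uses Hudson's estimator in the closed form
[(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)] / [p₁(1−p₂) + p₂(1−p₁)].
Per-SNP values retain negative estimates; window values are means of
per-SNP values. Note the per-SNP estimator is a ratio and its mean across
SNPs is slightly negatively biased even under no differentiation; for
genome-wide summaries `fst_overall` therefore uses the ratio-of-means
aggregate (numerators and denominators summed before dividing), which is
centred on zero under the null.

*LD* is haplotype r² = D²/(p_A q_A p_B q_B) over lines non-missing at both
sites — valid because inbred lines are phased by construction. Pairs are
restricted to MAF ≥ 0.05. The SNP-hiding probability asks, per distance
bin, whether a SNP has any partner with r² above a threshold (default 0.8);
the denominator counts SNPs with at least one neighbour in the bin.

*Outlier windows* are called per subgenome against empirical percentile
thresholds (default 2.5% tails) using the linear-interpolation (type-7)
quantile; ties at the threshold are flagged. Adjacent flagged windows are
merged into regions (gap tolerance configurable); merging is idempotent and
regions are disjoint.

*Donor-allele windows* report, per sliding window (default 3 Mb), the mean
frequency of a donor accession's allele among a line subset (typically
landraces), for mapping diverged introgression tracts.

## The PHS scan

For a pair of lines and a focal SNP, d_ijx is the cM length of the interval
bounded by the nearest discordant SNP strictly to the left and right of the
focal SNP, skipping sites where either line is missing (missing is never
treated as mismatch — depth-dependent missingness would otherwise shrink d
systematically). When no discordant SNP exists on a side, the boundary is
the chromosome's terminal SNP. Boundaries sit at the discordant SNP itself,
a deterministic and conservative convention. Pair means and SDs are pooled
over all focal SNPs of a subgenome (population SD, ddof 0); cross-subgenome
pooling is disallowed. Pairs informative at fewer than 10 SNPs, and pairs
with zero SD (clone-like duplicates), are excluded from the sums with the
denominators reduced accordingly.

PHS is computed for both alleles of every SNP with at least two carriers
and carrier frequency ≤ 0.95 (near-fixed alleles are uninformative and
inflate runtime); a derived-allele-only mode is available where ancestral
states are assigned. Thresholds are the empirical 97.5th percentile of PHS
within carrier-frequency classes of width 0.05; classes with fewer than 200
values fall back to the subgenome's pooled threshold. Outliers are strictly
above threshold, so a neutral panel flags ≈2.5% of alleles per class by
construction. Flagged SNPs are collapsed into 50-kb windows (each carrying
its maximum PHS and peak SNP/allele), and flagged windows within 1 Mb are
merged into sweep regions.

A caveat that matters for interpretation: a hard sweep spanning fraction f
of a subgenome's map contaminates its carriers' own d̄ and σ, which caps
the attainable Z near √((1−f)/f). Sweeps much wider than a few percent of
the map are therefore *harder* to flag, not easier. Scans flag both alleles;
in swept regions the complementary high-frequency allele can also exceed
its (compressed) frequency-class threshold, so carrier sets of region
outlier alleles are supersets of the selected haplotype's carriers.

## Homoeologous overlap and co-occurrence

Regions are projected between subgenomes via the nearest flanking anchors
of an ordered homoeolog-triplet map; the partner interval's endpoints are
sorted, which handles local orientation inversions, and regions outside the
anchored span do not project. Anchors breaking positional monotonicity in
order index are dropped with a warning.

The overlap test computes, for subgenomes X and Y, the proportion of X's
sweep windows whose projection intersects a sweep window of Y (both
directions are reported, since the one-directional proportions differ when
sweep-window counts differ). The null permutes sweep-window labels
uniformly over all genome-wide 50-kb windows of each subgenome, preserving
per-genome counts; the empirical P is (1 + #{permuted ≥ observed})/(1 +
n_perm), which is never zero. A circular-rotation null is a possible
alternative when LD clustering of windows is a concern; the uniform shuffle
is the stated baseline. Note that because single windows project to whole
inter-anchor intervals, scattered null windows can overlap *more* than
clustered observed regions; the test is calibrated (P uniform under null
placement) but conservative for clustered sweeps at coarse anchor spacing.

Per-line co-occurrence: for an overlapping pair of regions, a line
co-occurs if it carries an outlier-PHS allele at ≥1 SNP inside both
regions; the reported fraction is the share of scored pairs with no such
line. Because outlier alleles are carried by background lines as well as by
selected haplotypes, this fraction is an underestimate of the truly
disjoint fraction — in simulations with disjoint planted carrier sets, the
co-occurring lines are background carriers of shared ancestral alleles.

## Enrichment

All enrichment tests are Pearson χ² on 2×2 tables without continuity
correction (counts in intended applications are large; stated for
determinism), with fold = (tail proportion)/(background proportion).
Category scans apply Benjamini–Hochberg FDR across categories. GWAS-hit
enrichment first filters hits to MAF > 3% and association P < 10⁻³, then
compares the share of hits inside the tail with the tail's share of all
SNPs.

## QC arithmetic

Error and concordance rates compare homozygous, non-missing calls present
on both sides of a comparison, report percent rounded half-up to one
decimal, and retain raw counts. Depth-stratified rates accept bin edges or
a single depth cutoff. Capture-efficiency ratios are per-triplet log₂ depth
ratios for the three subgenome pairs; triplets with any non-positive depth
are excluded and counted.

## Variant effects

Gene models are single-transcript (one transcript per gene is assumed
throughout). SNPs in coding sequence are classified at codon level with the
standard nuclear code (stop-gain → PTC; stop-loss is folded into
non-synonymous); SNPs in the first or last two bases of an intron are
splice-site disruptions; exonic-non-CDS is UTR. Indels touching CDS are
frameshift or in-frame by length difference mod 3; indels spanning feature
boundaries take the most severe touched class. The per-variant label across
overlapping genes uses the fixed severity order PTC > SSD > frameshift >
non-synonymous > in-frame > synonymous > UTR > intronic > intergenic.
Ancestral states come from an outgroup allele table (state = ref/alt when
the outgroup allele matches, unknown otherwise); frequency spectra per
class use left-open/right-closed bins of width 0.05 and always sum to one
per class. The homoeolog-compensation fraction is, over disrupted genes
with a mapped triplet, the share whose triplet retains ≥1 non-disrupted
copy, reported to the nearest percent.

## Synthetic-data generator

The generator is an *emulation* of the statistical structure the analyses
assume, not a demographic simulation. Per subgenome, F founder haplotypes
(A/B: 16, D: 8) receive derived alleles whose founder counts follow the
neutral spectrum P(i) ∝ 1/i^skew (skew 1 for A/B; 1.5 for D, giving the
rare-allele excess); each of the 62 lines (26 landraces, 29 cultivars, 7
other; 13 winter-habit) is a mosaic of founders with Poisson breakpoints at
0.2 per cM along the genetic map, which yields LD blocks of realistic
extent at O(SNPs × lines) cost. Default chromosomes are 300 Mb / 150 cM
with 3,000 SNPs in A and B and 1,200 in D (the ~2.5× variant deficit).
Cultivars draw founders from Dirichlet-perturbed weights with concentration
(1−F)/F at F_drift = 0.02, giving weak landrace–cultivar differentiation;
missing calls (2%) and heterozygous calls (0.2%) are sprinkled uniformly.
Because lines draw founders independently, the per-site π estimator is
unbiased for the founder-spectrum expectation, which gives the generator
its closed-form calibration check.

Hard sweeps copy one line's haplotype over the specified interval into a
random carrier subset (optionally restricted to a metadata group);
introgression tracts define a donor haplotype as the reference haplotype
flipped to the alternate allele at the divergence rate, write only the
flipped sites into a recipient subset (so divergence 0 is exactly a no-op),
and record the donor allele per site. The genome-wide donor table uses the
reference (ancestral) allele outside tracts. Gene models for the effect
classifier are emitted separately as short synthetic genes (2–3 exons,
canonical GT/AG introns) on small random contigs, since the multi-Mb panel
chromosomes carry no stored sequence; panel SNPs receive effect labels from
configured class proportions instead. What the generator does *not*
emulate: bottlenecks and migration, forward-time selection dynamics,
recombination-rate heterogeneity along chromosomes, depth-correlated
missingness, and sequencing reads. Tests passing on this generator show the
statistics behave as designed under their stated assumptions, not that real
data meet those assumptions.

## Problem sizes and fixed analysis conditions

The calibration suites run at sizes chosen up front for statistical power:
sweep recall uses 20 replicate simulations of the default A subgenome
(3,000 SNPs, 300 Mb/150 cM) with a planted sweep of half-width 5 Mb
(2.5 cM) and carrier fraction 0.4 — inside the regime where the
contamination cap above still leaves the planted allele clearly separable;
neutral false-positive rates pool four neutral replicates. The permutation
calibration uses 200 replicates of 300 random sweep windows among 4,000
genome-wide windows with 199 permutations each, sized so the discrete
empirical-P atoms are small enough (largest atom ≈ 0.06) for a meaningful
Kolmogorov–Smirnov comparison with the uniform distribution at n = 200.
Enrichment calibration uses 1,000 label shuffles of a 5,000-SNP panel and a
planted four-fold category in a 20,000-SNP panel (background rate 5%, tail
rate 20%). The shipped demo configuration uses 120 Mb chromosomes with
1,200/1,200/480 SNPs and 500 permutations.

## Numerical conventions

Empirical quantiles are numpy's default linear interpolation (type 7).
Window-outlier ties at the threshold are flagged; PHS outliers are strictly
above threshold. Rates in QC reports round half-up. All stochastic steps
take explicit seeds; the simulator derives independent child streams from a
single seed, and the pipeline manifest (configuration, stage parameters,
SHA-256 of outputs, no timestamps) is byte-identical across repeated runs.

## Known limitations

Single-transcript gene models; no read-level evidence (the heterozygous-
call depth exception used with raw sequencing data cannot be applied, so
the ≤1-heterozygous-accession rule is applied unconditionally); haplotype
r² rather than genotype-correlation r²; projection resolution bounded by
homoeolog-anchor spacing; the overlap test's uniform-shuffle null ignores
LD clustering of sweep windows (rotation null left as an extension); PHS
power degrades for sweeps spanning a large fraction of a chromosome's map
and for carrier frequencies near fixation.
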