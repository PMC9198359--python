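# Methods

This note documents the models behind each component, the defaults and
why they were chosen, what the simulator does and does not emulate, and
the numerical conventions at the edges.

## The inference problem

In a cyclically parthenogenetic population, a field sample contains
three kinds of relatives that sexually reproducing models do not
distinguish: asexual copies of the same genotype (a clonal lineage),
selfed offspring (an intraclonal cross: the two "parents" are the same
clone), and outcrossed offspring. The package identifies lineages from
genome-wide IBS, classifies pair relationships from robust kinship and
IBS0, assembles a multi-year pedigree, and maps the genetic basis of
male production — the trait that controls investment in sex — two ways:
bulk-segregant analysis of male/female pools, and a mixed-model scan
over an F1 panel.

## Clonal assignment

Pairwise IBS is the mean over co-called sites of 1 − |dᵢ − dⱼ|/2 on
dosages. Singleton sites (minor-allele count 1 in the analysis sample)
are removed first — a singleton can only lower the IBS of pairs
involving its carrier and carries no lineage information — as are sites
with >15% missingness. Clonal lineages are single-linkage components of
the graph with edges at IBS ≥ 0.965. Single linkage operationalizes a
pair-threshold rule deterministically; its known failure mode (chaining
through an intermediate genotype, e.g. a selfed offspring bridging
parent and sibling lineages) is addressed by `flag_clone_outliers`,
which reports members whose median within-clone kinship falls below the
clonal bound (0.42) instead of silently removing them. Because IBS here
is computed over a polymorphism table, not the genome, `ibs_to_dxy`
rescales (1 − IBS) by n_SNPs / genome_bp for per-bp divergence.

Shannon diversity uses natural log. Per-individual heterozygosity is the
fraction of called sites heterozygous (optionally per-bp given a
callable genome length); it is a site-proportion summary, not a
hidden-state run-of-homozygosity estimate.

## Kinship, classification, pedigree

The kinship estimator is the within-family robust form
(N_het,het − 2·N_opp)/(N_het(i) + N_het(j)) over co-called sites with
sample MAF ≥ 0.05, with IBS0 = N_opp / N_co-called. Expectations for
non-inbred, unstructured parents: clonal pairs 0.5 exactly (identical
genotypes: N_het,het = H, denominator 2H), outcrossed parent–offspring
0.25, selfed parent–offspring 1/3 (at the parent's H het sites the
child is het with probability 1/2, so both-het = H/2 and the
denominator is H + H/2). Class boundaries default to the midpoints
(0.42 between 0.5 and 1/3; 0.29 between 1/3 and 0.25; PO requires
IBS0 < 0.002, a bound tolerant of ~1% genotype error), all
configurable.

Two caveats the tests make visible:

- *Realized-IBD variance.* A selfed offspring's heterozygosity is half
  the parent's only in expectation; the realized fraction varies with
  the number of independently segregating chromosome segments. With 12
  chromosomes at ~5 crossovers each the kinship SD is ~0.02 and the
  classes separate cleanly; with very few chromosomes a selfed
  offspring can stray toward the outcross boundary.
- *Structure bias.* With strongly diverged parental lineages the
  denominator inflates (the F1 is heterozygous at all fixed
  differences) and PO kinship drops below 0.25 (~0.21 at F_ST 0.3).
  The calibration suite therefore runs on panmictic founders; on
  structured data the boundaries should be adjusted or clusters
  inspected, as the estimator's own literature advises.

`verify_po` checks Mendelian consistency (trio-impossible dosages; duo
opposite homozygotes; for two parents, the fraction of child
heterozygous calls at parental fixed differences, which for a true F1
should be ≥0.97 even at 1% genotype error). `build_pedigree` averages
pair statistics over clone members, classifies clone pairs, and links
each clone to the best-supported parents among clones first observed no
later than itself; a single identified outcross parent gets an explicit
`unsampled_*` co-parent node, ties and conflicts are reported, and
cycle-creating edges are refused.

## Sliding-window IBS

Windows are 250 kb wide with a 10 kb step, starting at position 1; the
last partial window is kept if it holds ≥1,000 SNPs (defaults all
configurable). Samples with median depth <5 are dropped; singleton and
high-missingness sites are removed once from the whole analysis subset,
which makes the used-site-weighted mean of disjoint tiling windows equal
the global IBS exactly (conservation is tested to 1e-12). Clone-pair
values average all member-level cross pairs; a lone cross pair is used
as-is. The divergence ratio is IBS_focal / IBS_comparison per window,
averaged over windows where both are defined (unweighted by default;
a used-SNP-weighted option exists); values >1 mean the comparison pair
is more divergent than the focal pair.

## Within-clone pN/pS

Within a clonal lineage (up to 8 randomly chosen members), segregating
variants are binned by within-clone minor-allele frequency: "new"
mutations below 0.25 (private heterozygotes on one or a few copies) and
"shared" variants at 0.5 ± 0.05 (ancestral heterozygosity carried by
every copy, shielded from segregation). pN/pS is the nonsyn/syn count
ratio times an opportunity factor (default 1 — no site-opportunity
normalization), with a percentile bootstrap CI over variants (100
resamples). Zero synonymous counts yield a flagged undefined estimate.

## Bulk-segregant analysis

Pool-Seq counts carry two binomial stages: which individuals enter the
pool, then which reads sample the pool. The effective depth
C_eff = C·2N/(C + 2N) (C raw depth, N diploid pool size) is the
information-equivalent depth; counts are downsampled to it
(proportional by default, seeded hypergeometric optionally) before
testing, so that raw coverage 81 in a 50-female pool becomes effective
coverage 45. Sites are kept at combined-bulk MAF > 0.15 and total/
per-bulk depth ≥ 20. G is the 2×2 log-likelihood-ratio statistic with
zero cells contributing nothing; G′ is the tricube-weighted mean of G
over sites within a half-window (bandwidth 125 kb of the 250 kb
window), with edge weights renormalized rather than reflected. The null
is a normal fit to log G′ after Hampel-type trimming at median ±
5.2·MAD (the heavy right tail is QTL signal, not null); p-values are
one-sided and BH-corrected. Regions are maximal runs of q < 0.05 merged
across gaps ≤ 250 kb, peaked at max G′. Replicate pool pairings are
scanned and reported separately, never averaged.

Power analysis on the simulator shows the binding noise source is the
first sampling stage: with 35/50-individual pools the per-linkage-block
allele-frequency contrast has SD ≈ 0.05–0.08, independent of read
depth, against an expected QTL contrast of ~0.175 at a +1.5 log-odds
effect. A single pairing localizes the QTL to 250 kb in ~80% of runs
under study-matched conditions (divergent parents, ~5 SNP/kb); taking
the minimum-q site over both replicate pairings reaches ≥90%. Divergent
parents help twice: they supply dense informative markers, and parental
fixed-difference sites (pool frequency pinned at 0.5 regardless of
composition) contribute no composition noise to the null.

`validate_pools` checks that pools behave like an A×C F1 cohort: the
fraction of MAF>5% sites at which the parents differ (≈0.98 under the
divergent-founder model) and per parental-genotype-class mean pool
frequency against the F1 expectation (g_A + g_C)/4. `overlap_test`
counts set-1 regions touching any set-2 region and standardizes against
permutation null sets (z and add-one empirical p).

## F1 QTL mapping

Markers with identical dosage patterns across lines (up to a global
ref/alt flip; missingness pattern included) within a chromosome form one
linkage group represented by its smallest-position tag. The association
statistic per tag is a likelihood-ratio test from
y = μ + xβ + g + e with Var(g) = σ_g²K, fitted by ML on the eigenbasis
of K with heritability profiled on a 25-point grid; K is the standard
additive GRM ZZᵀ / 2Σp(1−p) rebuilt without the focal tag's linkage
group (leave-one-chromosome-out and global modes available — the
appropriate exclusion radius is a judgment call exposed as an option).
The phenotype is the observed male proportion; a totals-weighted
least-squares statistic is the fallback when the variance fit
degenerates, and permutation calibration makes either statistic valid.
Permutations (default 100) shuffle line labels, moving count pairs
together; the empirical FDR at threshold t is the mean permuted
exceedance count over the observed count, computed per chromosome and
made monotone step-up fashion. QTL boundaries come from exact
dynamic-programming 1-D segmentation of significant tag positions
(k = 1..10 per chromosome) scored by Gaussian BIC with a per-cluster SD
floor of 10 kb — without a floor, BIC degenerates to one zero-variance
cluster per point; 10 kb is the mapping resolution below which further
splitting is meaningless here.

The male⁺ allele at each QTL peak is the allele at higher frequency in
the male bulk; per-line male⁺ dosage summed over QTL is regressed on
male counts with a binomial GLM (IRLS via statsmodels), reported with a
likelihood-ratio test and a separation flag. The one-sample proportion
test is Yates-corrected: χ² = max(0, |x − np₀| − ½)² (1/np₀ +
1/n(1−p₀)), two-tailed from χ²₁ — e.g. 11 of 14 QTL younger than the
genome-wide average gives χ² = 3.5, p ≈ 0.061.

## The simulator

`SimConfig` defaults describe a desk-scale pond survey: 2 chromosomes of
5 Mb carrying 20,000 SNPs, 4 founder lineages, ancestral site
frequencies Beta(1,1) (a flat spectrum, appropriate for an ascertained
polymorphism table rather than a genome-wide mutation spectrum), and
optional Balding–Nichols drift per founder lineage
(`founder_divergence`, F_ST-like; 0 by default, ~0.7 reproduces
focal-pair divergence at 98% of MAF>5% sites). Founders are explicit
haplotype pairs; meiosis places Poisson(`crossover_rate`) crossovers
uniformly per chromosome without interference. The default of 5
crossovers per chromosome per meiosis is set so that an F1 panel's
ratio of distinct linkage-block patterns to markers matches the few
percent observed in real transmission-phased panels; treat it as a
genetic-map-preserving rescaling of a physically larger chromosome, not
a per-bp recombination rate. Clone copies receive
Poisson(`clonal_mutation_rate`, default 20 per copy ≈ 0.1% of sites)
private mutations, always heterozygous — an asexual lineage has no
segregation to expose them. Selfing draws two independent gametes from
one parent. F1 male-production probability is
invlogit(baseline + Σ effect·dosage) with binomial observed counts; at
each planted QTL parent A is forced homozygous reference and parent C
heterozygous, since a fixed difference would not segregate in the
panel. Pools draw individuals with replacement weighted by male
probability (male bulk) or its complement (female bulk) — a male is
genetically its parthenogenetic mother — then binomial reads at the raw
depth. All randomness flows through one `numpy` generator seeded from
`SimConfig.seed`; identical configs are byte-identical.

What the simulator does **not** emulate: genotyping error (tests inject
it explicitly where needed), depth heterogeneity along the genome
(site depth is uniform, so the depth-quantile filter is exercised by
hand-built fixtures), linked selection, seasonal pond dynamics,
coalescent-accurate founder haplotypes, and phasing. Passing tests
therefore demonstrate correctness of the estimators under their own
sampling assumptions, not robustness to alignment artifacts or
reference bias in real sequencing data.

## Numerical conventions and edge cases

- Coordinates are 1-based inclusive internally; BED files are converted
  at the boundary (0-based half-open on disk).
- Depth-quantile trim uses nearest-rank quantiles and removes
  depth ≤ q05 and depth > q95 (depths 1..100 → exactly 90 remain); a
  degenerate spread (q05 ≥ q95, e.g. constant depth) trims nothing.
- LD pruning is a greedy left-to-right scan per chromosome
  (|Δpos| ≤ window); r² uses pairwise-complete calls, with pairs sharing
  <10 calls or a zero-variance column treated as uncorrelated.
- Multi-allelic VCF records are dropped, not split; GQ < 10 calls are
  set missing at read time.
- Pairs with zero co-called sites get NaN IBS and are flagged; kinship
  with a zero denominator is NaN.
- G is clipped at 0 against floating-point residue; a site alone in its
  smoothing window keeps its raw G; chromosomes with <2 passing sites
  are skipped and named.
- Empty QTL region sets are valid results, not errors; an all-removing
  filter cascade raises `EmptyFilterResult`.

## Scale of the bundled analyses

The test and demo simulations are sized for a desk run: genomes of
2–12 chromosomes (≤10 Mb total), 2,000–60,000 SNPs, panels of 40
phenotyped lines with 200–400-line pool cohorts, 100 permutations, and
10–20 seeds per calibration, chosen to keep each property estimable
while the full suite completes in a few minutes. The same code paths
take full-scale inputs unchanged.
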