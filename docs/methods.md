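# Methods note

This note records the models, parameters, and numerical choices behind
`agoclip`, the scope of the synthetic generator, and known limitations.
All coordinates are 0-based half-open; midpoints are floored; RNA input
is normalized T→U on read.

## Consensus peaks

The Jaccard index of two intervals is |A ∩ B| / |A ∪ B| over base
positions; cross-chromosome or cross-strand pairs score 0. Peaks from the
same replicate never connect. The cross-replicate overlap graph links
peaks from different replicates sharing ≥ 1 bp; connected components
(union-find with a per-chromosome sweep) become candidate consensus peaks
with union footprint bounds. A component is retained at threshold *t*
under one of three aggregation modes:

- `any_pair` (default): some cross-replicate pair has J ≥ t;
- `all_pairs`: every overlapping cross-replicate pair has J ≥ t;
- `group`: the Jaccard of per-replicate footprints
  (intersection across replicates / union) is ≥ t.

`min_replicates` (default 2) additionally requires members from that many
distinct replicates, which excludes single-replicate peaks at any
threshold. Thresholds 0.2 / 0.4 / 0.8 are called J20 / J40 / J80;
since components are threshold-independent, J80 ⊆ J40 ⊆ J20 exactly.
The merge-method baseline pools all replicates' reads and calls peaks as
maximal coverage runs with `min_coverage` and `min_length`; it is
provided for comparison and is deliberately less selective.

Region annotation assigns each peak the region type with maximal base
overlap, ties resolved 3'UTR > 5'UTR > CDS > intron > ncRNA, else
`intergenic`.

## Heteroduplex model

The seed is miRNA positions 2–8 (7-mer default; 6/7/8-mer anchor types
supported). Anchors are exact Watson–Crick reverse-complement matches of
the seed in the target; every anchor is reported, including overlapping
ones. Around a forced anchor the duplex is extended on both sides by an
exact dynamic program over monotone pair sets with the additive energy
model GC = −3, AU = −2, GU = −1 (wobble allowed in extensions only, never
in the anchor), bulge = +3 per unpaired nt on one side, interior loop =
+2 per unpaired nt, and duplex initiation +4. The DP is O(n·m) using
running-minimum auxiliary arrays for bulge and loop transitions with full
traceback; it is validated exactly against exhaustive enumeration of all
monotone pair sets for short sequences. A duplex is reported only when
its total energy is negative. Units are kcal/mol-like model units; the
model is intentionally simple and monotone rather than a nearest-neighbor
thermodynamic parameter set — relative comparisons, not absolute folding
energies, are the design target. The scan window around an anchor is the
anchor ± (miRNA length + 15) nt.

External predictor output can be imported instead (`mirbshunter`,
`miranda`, `targetscan` dialects); TargetScan context scores are made
positive by absolute value. Imported sites carry no pairing mask and are
excluded from binding-mode profiles. `select_mirbshunter_params` maps a
dataset's peak count to recommended (min coverage, overlap fraction,
p-threshold) tiers: [0,100) → (3, 0.25, 0.0008); [100,1000) →
(5, 0.35, 0.0008); [1000,2000) → (7, 0.35, 0.0002); [2000,∞) →
(12, 0.35, 0.0002).

## Degree of occupancy

Duplexes within a peak are grouped into binding sites by transitive
≥ 1 bp overlap; within a site each miRNA contributes its best duplex
(lowest MFE, or highest imported score). The heteroduplex score is

β = mfe/min(MFE) + paired/len(miRNA) + seed-paired/len(seed)
  + motif-paired/len(motif) + (len(seed) − seed bulges)/len(seed),

each term in (0, 1], so β ∈ (0, 5]. min(MFE) is the dataset-wide minimum
by default (`min_mfe_scope="dataset"`); `per_mirna` scope normalizes each
miRNA by its own minimum. The energy term is written as mfe/min(MFE)
(a ratio of two negative numbers, hence positive and maximal for the
strongest duplex); this resolves an internal sign inconsistency in the
printed formula of the source method in favor of the bounded-term
interpretation. A site's worth is μ = ln(Σβ over its coalition) and the
peak's degree of occupancy is Δ = Σ μ over its sites. The natural
logarithm is a fixed convention; any other base rescales all Δ by a
constant and leaves quantile levels unchanged.

Stratification uses `numpy.quantile` (linear interpolation) boundaries at
k/n_levels and assigns level = 1 + Σ(value > boundary), so boundary ties
fall to the lower level; level 1 is lowest, 4 highest by default.
Stratification defaults to 3'UTR peaks; a simple site-count
stratification and single/multiple-site subsets are available as
baselines.

## Repression readout

Peaks map to genes by maximal base overlap (lexicographic tie-break;
unmapped peaks are dropped and counted). The background is every gene in
the expression table, targets included — a conservative choice that can
only dilute, never inflate, level-wise signal. Per level the two-sample
two-sided Kolmogorov–Smirnov test (asymptotic p, `scipy.stats.ks_2samp`)
compares the level's genes to the background; direction is reported as
the signed median shift. Genes reached at several levels count in each
level unless deduplication to the highest level is requested.

## Evaluation statistics

- Wilcoxon signed-rank (specificity protocol): zeros dropped, average
  ranks on |differences|; for n ≤ 25 the one-sided p is exact,
  P(W+ ≥ w), from the full null distribution computed by subset-sum
  counting over doubled (integer) ranks — correct in the presence of
  ties; larger n uses the normal approximation with tie-corrected
  variance and continuity correction. The standard upper-tail convention
  P(W+ ≥ w_obs) is used throughout (so the fully discordant direction
  gives p = 1, not 1 − 2⁻ⁿ).
- Spearman correlation uses average ranks (scipy), equal to the Pearson
  correlation of the rank vectors.
- Quantile normalization: the reference is the mean of the column order
  statistics; tied values within a column receive the mean of the
  reference values over the rank positions they jointly occupy.
- Precision is |site center − peak center| with floored midpoints;
  spacing is the median over peaks of the median center-to-center
  distance of non-overlapping sites within a peak.

## Binding-mode profiles

For each miRNA the pairing masks of its engine-computed duplexes are
summed per position and normalized by the row maximum (default; row-sum
optional), giving a miRNA × position matrix in [0, 1]. Rows are clustered
by complete-linkage hierarchical clustering on Euclidean distance
(`scipy`) cut into k flat clusters, and by seeded k-means (k-means++,
10 restarts, fixed `random_state`). With the default row-max
normalization the profile is invariant to each miRNA's site count.

## Synthetic generator

The generator's defaults are the study conditions: seed 17, 2,000
planted peaks, 2 replicates, peak length 80 nt, target cross-replicate
Jaccard cycling (0.9, 0.5, 0.25), 10 miRNAs of 22 nt (miR-1 and miR-2
share a seed, forming the family behind promiscuous sites), 1–4 sites
per peak with probabilities (0.4, 0.3, 0.2, 0.1), 14 nt site spacing,
6 nt of 3' complementary extension, promiscuity probability 0.2,
repression slope 0.15 log2fc units per true site, Gaussian noise
sd 0.4, 2,000 pure-noise background genes, and 50 single-replicate decoy
peaks.

Each gene occupies 550 nt (5'UTR 50, CDS 150, 3'UTR 250, spacer 100) on
one of four chromosomes; the planted peak sits 80 nt into the 3'UTR. The
replicate-2 interval is the base interval shifted by
d = round(L(1 − J)/(1 + J)) so each cross-replicate pair realizes its
target Jaccard within ±0.02. Sites are embedded as the DNA reverse
complement of miRNA positions 2 to 8+extension, centered symmetrically
around the peak center with ±2 nt jitter; promiscuous sites embed the
family seed so one locus matches two miRNAs. Expression is
log2fc = −slope·m + N(0, sd) for target genes and pure noise for
background genes. All randomness flows from a single `numpy` generator
seeded once per dataset, making every output byte-reproducible.

Scope and limitations: the generator plants only plus-strand,
3'UTR-resident, canonically seed-matched sites with uniform random
background sequence; it does not model read-level noise, crosslinking
biases, non-canonical (seedless or bulged-seed) sites, overlapping genes,
or expression-dependent detection. Chance seed matches in the random
background do occur (~6 × 10⁻⁵ per position per miRNA) and are left in
deliberately as realistic false-positive pressure. Decoy peaks appear in
one replicate only and therefore test the `min_replicates` filter, not
the Jaccard threshold.

## Problem sizes and runtime choices

All analysis sizes in the tests and the acceptance script (2,000-peak
study, 150-peak specificity datasets, 500-pair DP oracle checks,
100-seed null calibration) are this package's own choices, sized so the
full suite and the acceptance script each finish in well under a minute
on one CPU while keeping every statistical conclusion stable across
seeds. The duplex DP is exact, so shrinking or growing the oracle sample
changes runtime only.

## Open design decisions made here

- β energy term written as mfe/min(MFE) (see above).
- `any_pair` aggregation and `min_replicates=2` as consensus defaults.
- Natural log in μ; dataset-wide min(MFE) scope by default.
- Row-max normalization of binding profiles by default.
- Standard upper-tail convention for the exact signed-rank test.
- Background = all genes (targets included) in the repression readout.
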