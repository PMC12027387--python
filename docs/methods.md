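# Methods

## Scope and data model

The package analyzes a two-genotype (wild type vs Gsk-3-kinase deletion) by
two-growth-phase (exponential, EXP; early post-diauxic shift, PDS) design
with replicated, TMT-style log2 intensities. Three layers share one sample
naming scheme (`genotype_phase_replicate`): site-level phosphopeptide
records (one row per protein × 1-based residue position × multiplicity
class 1/2/3, with a phosphosite localization probability), protein-group
intensities and transcript abundances. Records with localization
probability < 0.75 are excluded at read time, the standard class-I site
filter. Absent intensities are empty fields / NaN, never zero: zero is a
measured floor, absence triggers imputation.

All contrasts are genotype comparisons within one phase, signed
log2(mutant/WT); the default is mck1del vs WT at PDS.

## Differential chain

1. **Median normalization.** Each sample is shifted so its median of
   present log2 values equals the median of the per-sample medians. This
   target makes the operation exactly idempotent; a constant shift applied
   to one sample is removed up to a single global constant, which cancels
   in every contrast. Assumption: most features are unchanged between
   samples. When a large fraction of one sample's features carry planted
   (or real) shifts comparable to the between-feature spread, the median
   itself moves and fold changes are attenuated — visible in simulations
   that perturb ≫10% of records, and a known property of median
   normalization generally.
2. **Imputation.** Missing values are drawn per sample from
   Normal(m − 1.8·sd, (0.3·sd)²), where m and sd are the sample's observed
   moments — the left-censoring ("downshifted normal") convention for
   label-based proteomics. Both factors are exposed; draws are seeded.
   Samples with fewer than 3 present values are rejected.
3. **Moderated test.** Per-feature pooled two-group variance s²ᵢ with
   d = n₁+n₂−2 df; prior (d₀, s₀²) by method of moments on log s²ᵢ under
   s²ᵢ ~ s₀²·F(d, d₀): matching the variance of log s²ᵢ gives d₀ via an
   inverse-trigamma Newton iteration, matching the mean gives s₀².
   Posterior variance (d₀s₀² + d s²ᵢ)/(d₀+d); t referred to t(d₀+d).
   Degenerate branches: if the spread of log variances does not exceed its
   sampling component, d₀ = ∞ and s₀² is the raw mean of s²ᵢ, so that a
   matrix in which every feature shows the same replicate variance yields
   exactly the ordinary t statistic. A feature with zero variance gets
   t = ±∞ when its group means differ (and p = 0), t = 0 otherwise; this
   makes the exact noise-free limit behave sensibly and is otherwise
   unreachable on continuous data.
4. **Permutation FDR.** Null statistics come from re-assigning genotype
   labels within the tested phase (all distinct balanced reassignments,
   excluding the observed one and its mirror; with 3 vs 3 replicates there
   are 9). For each observed |t| threshold,
   q = median over permutations of the count of null |t| at or above the
   threshold, divided by the observed count; q is then made non-increasing
   in |t| (BH-style suffix minimum) and clipped to [0, 1]. The median
   estimator is the SAM convention. Caveat: with very few distinct
   permutations the extreme tail is coarse — on complete-null data the
   single largest |t| receives q = 0 whenever more than half the
   permutations show no exceedance, so isolated single-feature discoveries
   at the very top should not be over-read. Across the whole matrix the
   procedure is well calibrated: on complete-null simulations (2,000
   features, 3 vs 3) the mean fraction of features with q < 0.05 is ~6·10⁻⁴.
5. **Calling.** reduced: log2FC ≤ −log2(fold) and q < 0.05; enhanced
   symmetric. Fold defaults are layer-specific: 2.0 for phosphopeptides,
   1.5 for transcripts and proteins.
6. **Clustering.** DE features are z-scored per row and clustered with
   Euclidean k-means (k = 4 default, 50 restarts, seeded); clusters are
   renumbered in decreasing size order and reported with group-mean
   z-profiles.

## Occupancy

Occupancy-level change is the ratio of ratios on the log2 scale:
site log2FC minus parent-protein log2FC. Parent matching is by protein id
(razor-style first protein). Sites without a quantified parent are kept and
flagged, never dropped. Occupancy statistics (t, p, q, call) are by default
recomputed on protein-normalized intensities (site minus parent per
sample); a threshold-only mode reuses the phospho q. True stoichiometry
estimation, which needs unmodified counterpart peptides, is out of scope.
The subtraction identity (occupancy + protein = phospho, to 1e-9) is
asserted on every record.

## Consensus scanning and priming

The scanner reports all (i, i+4) index pairs with S or T at both positions
— overlapping matches included, since cascades of 4-spaced phosphosites are
real; tyrosines never match. Differential evidence (by default the
phosphorylation-level calls, since protein-level changes rarely explain
phospho changes; occupancy-level evidence is a flag away) is attached per
match: reduced records at the first position, enhanced records at the +4
position. Classification: primed_pair (both), first_reduced_only,
plus4_only, none. A first site whose reduced evidence is confined to
multiplicity ≥ 2 records is flagged — the signature of a site that is only
observable on the doubly phosphorylated (primed) species.

Multiplicity statistics are computed over distinct first positions (for the
"only at multiplicity ≥ 2" fraction) and over enhanced +4 records (for the
monophospho fraction), with numerators and denominators reported; an empty
evidence set yields flagged-undefined fractions rather than silent NaNs.

Enrichment of first-site-phosphorylated consensus matches in a substrate
set over a background set is tested by shuffling residues within each
protein (composition preserved, phosphosite positions fixed);
p = (1 + #null ≥ observed)/(n_shuffles + 1).

## Integration

Layer correlation is Pearson r over genes significant in either layer and
quantified in both — the construction behind published transcript-protein
scatter plots. Note this union selection can bias r slightly relative to
the planted value when only a few dozen genes are selected. Quadrant
classes follow the per-layer calls; genes significant in both layers with
opposite signs get an explicit `discordant` class rather than a silent
mis-bin. Gene-set overlaps use the exact hypergeometric upper tail with a
configurable universe (default: all genes quantified in the relevant
layer).

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions used by the test suite and the acceptance script.

* **Sequences.** 400 proteins, Poisson lengths around 450 residues,
  residues drawn i.i.d. from a background with S and T upweighted to 8%
  each (so spurious consensus matches exist and specificity is
  measurable). 40 substrate proteins carry 3 planted, non-overlapping
  consensus pairs each — published substrate tables typically show
  clusters of several 4-spaced S/T sites per protein.
* **Planted phospho effects.** First sites lose 2.0 log2 units in the
  mutant (both phases); with probability 0.75 the first site is emitted
  only as a multiplicity-2 record, in which case the doubly phosphorylated
  species also reports (reduced) at the +4 position. The +4 site always
  gains a multiplicity-1 record up 1.0 log2 units in the mutant — the
  accumulating primed intermediate.
* **Noise and missingness.** Log2 noise s.d. = sqrt(ln(1+cv²))/ln 2 with
  cv = 0.2 (≈0.29 log2 units). Missingness (default rate 0.1) is
  left-censoring: the drop-out probability is a logistic function of
  intensity calibrated by root finding so the overall missing fraction
  equals the configured rate.
* **Expression layers and regulons.** Kinase-activated regulon genes
  (default 10% of non-substrate genes; a second regulon of 8% with half
  overlapping) carry correlated transcript/protein effects
  (mean −1.0, s.d. 1.0 log2, correlation 0.4 by default), applied in
  mutant PDS samples only — a starvation-induced program. 10% of
  substrates additionally change in parent-protein abundance (−1.0 log2),
  so occupancy normalization has protein-driven changes to remove. All
  phosphosites inherit their parent protein's abundance change.
* **Determinism.** One RNG stream per stage (effects, sequences, phospho,
  expression), split from the master seed, so changing one stage's
  parameters never perturbs another's draws; identical config + seed gives
  byte-identical outputs.
* **Replicates.** 3 per group (12 samples). The real design this emulates
  was an 11-plex with unstated per-group counts; 3 is the smallest
  replication at which the variance machinery is comfortable.

What the generator does **not** emulate: peptide digestion and shared
peptides, TMT ratio compression and reporter-ion interference, batch
structure, multi-protein peptide mappings, and intensity-dependent variance
(noise is homoscedastic on the log scale). Passing recovery tests therefore
demonstrates the inference chain's correctness under its stated
assumptions, not robustness to every artifact of real LC-MS/MS data.

## Packaged fixtures

`data/table1.tsv` and `data/table2.tsv` are manual transcriptions of two
printed result tables (kinase-activated genes with transcript/protein fold
changes; consensus-bearing phosphoproteins with per-site multiplicity
strings). They exist for worked-example tests and are transcriptions, not
machine-readable originals.

## Problem sizes

The test suite and the acceptance script run the full chain at the default
conditions (400 proteins, ~1,500 site records, 12 samples), null
calibration at 2,000 features × 200 seeds, and oracle equivalence on 100
random 1,000-residue sequences — sizes at which every property of interest
is measurable with comfortable margins while the whole suite stays fast.

## Known limitations

* With 3 vs 3 replicates only 9 distinct label permutations exist; q-value
  resolution is coarse and the extreme tail anti-conservative for isolated
  top features (see above).
* Median normalization assumes sparse perturbation; dense strong effects
  attenuate fold changes in every layer.
* The +4 priming gain (1.0 log2) sits exactly at the 2-fold call
  threshold, so single planted pairs are detected with ~50% probability;
  protein-level sensitivity comes from multiple pairs per substrate.
  Per-seed primed-pair sensitivity at the default conditions ranges
  roughly 0.75–0.90.
* Occupancy q-values inherit the protein layer's measurement noise; with a
  flat proteome the phospho- and occupancy-level call sets agree to
  Jaccard ≳ 0.9, not exactly.
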