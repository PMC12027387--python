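# phosphoprimer

Identifying the substrates of a kinase from quantitative phosphoproteomics
is a chain of inferences, not a single test: phosphopeptide intensities must
be normalized and imputed, differential sites called with honest error
control at tiny replicate numbers, site-level changes separated from
parent-protein abundance changes, and the surviving sites matched against
the kinase's sequence preference. `phosphoprimer` implements this chain for
Gsk-3-family kinases (modeled on the budding-yeast Gsk-3 kinase Mck1 in a
wild-type vs *mck1Δ*, exponential vs post-diauxic-shift design), together
with transcript/protein integration and gene-set overlap statistics, and a
synthetic-data generator with planted ground truth so every stage can be
benchmarked end to end without any external dataset.

It is aimed at computational biologists analyzing TMT-style site-level
phosphoproteomics (MaxQuant "Phospho (STY)Sites"-like tables) alongside
proteome and transcriptome matrices.

## The statistics at the core

**Moderated differential test.** For feature *i* with pooled residual
variance s²ᵢ on d degrees of freedom, variances are shrunk toward a prior
s₀² with d₀ prior degrees of freedom (estimated by the method of moments on
log s²ᵢ, assuming s²ᵢ ~ s₀²·F(d, d₀)):

    s̃²ᵢ = (d₀·s₀² + d·s²ᵢ) / (d₀ + d)
    tᵢ  = log2FCᵢ / sqrt(s̃²ᵢ·(1/n₁ + 1/n₂)),   tᵢ ~ t(d₀ + d) under H₀

With d₀ = 0 this is exactly the ordinary two-sample t-test. q-values come
from genotype-label permutations within the growth phase: for each observed
|t| threshold, q = median over permutations of the null exceedance count
divided by the observed exceedance count, monotonized in |t|.

**Occupancy normalization.** A site can lose signal because it was
dephosphorylated or because its protein became less abundant. On the log2
scale, occupancy-level change = site change − parent-protein change; the
statistics are recomputed on protein-normalized intensities.

**Consensus and priming.** Gsk-3 kinases phosphorylate the first S/T of the
(S/T)XXX(S/T) consensus after a separate "priming" kinase phosphorylates
the +4 S/T. The scanner reports every (i, i+4) S/T pair (overlaps included)
and classifies each against the differential evidence: a *primed pair* has
reduced first-site phosphorylation (typically observable only on
dual/multi-phosphopeptides, multiplicity ≥ 2) plus enhanced
monophosphorylation at the +4 site, where the primed intermediate
accumulates when the kinase is gone.

**Integration.** Pearson correlation of transcript vs protein log2 fold
changes over genes significant in either layer, seven-way quadrant
classification, and exact hypergeometric tests for regulon overlaps.

## Worked example

```sh
python examples/consensus_priming_scan.py
```

prints (seed 3):

```
proteins with >=1 consensus match carrying reduced first-site evidence: 43
proteins with a full primed pair (reduced first site + enhanced +4 site): 30
of the 40 planted substrates, 30 were recovered (75% sensitivity)
first-site phosphorylations seen only at multiplicity >= 2: 75% (91/122; the generator plants 75%)
enhanced +4 evidence that is monophosphorylated: 99%
```

The generated study plants 40 substrate proteins (of 400) with consensus
pairs whose first sites lose 2 log2 units in the mutant and whose +4 sites
gain a 1-log2-unit monophospho record; 75% of first sites are planted as
visible only at multiplicity ≥ 2. The scan recovers the substrates with no
false primed-pair calls among the 360 background proteins, and the
multiplicity statistic recovers the planted 75%. Other examples cover
differential calling (`simulate_and_call.py`), occupancy normalization
(`occupancy_normalization.py`) and multi-omic integration
(`integrate_layers.py`).

A thin CLI mirrors the pipeline stages:

```sh
phosphoprimer simulate --seed 1 --out-dir study/
phosphoprimer differential --matrix study/phospho_sites.tsv --layer phospho --out calls.tsv
phosphoprimer occupancy --phospho calls.tsv --protein prot_calls.tsv --out occ.tsv
```

## Layout

- `src/phosphoprimer/simulate.py` — synthetic study generator + ground truth
- `src/phosphoprimer/io_tables.py` — FASTA/TSV I/O, site-string parsing,
  packaged table fixtures (transcriptions of printed result tables)
- `src/phosphoprimer/differential.py` — normalization, imputation,
  moderated test, permutation FDR, calling, k-means profiles
- `src/phosphoprimer/occupancy.py` — proteome normalization, level overlaps
- `src/phosphoprimer/motif.py` — consensus scanning, priming classification,
  multiplicity statistics, shuffle-based enrichment
- `src/phosphoprimer/integrate.py` — correlation, quadrants, hypergeometric
  overlaps
- `docs/methods.md` — model assumptions, parameter choices, limitations
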