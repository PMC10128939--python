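# Methods

This note records the statistical model behind `exomatch`, the defaults it
ships with, what the synthetic-data generators do and do not emulate, and
the numerical and design choices made where the design was genuinely open.

## The case-only design

The unit of analysis is the gene. For a hypothesis set of genes of
interest (GOI), control genes are selected by similarity in an *external*
annotation space — ten gene-level metrics (three O/E ratios, their three
z-scores, pLI, genomic length, transcript length, exon count) — so the
matching never touches the case exomes. Conditional on the matching,
gene-of-interest status is regressed on the per-gene counts of qualifying
LOF/MIS/SYN variants observed in the cases:

    logit P(GOI_g = 1) = β0 + β_LOF·LOF_g + β_MIS·MIS_g + β_SYN·SYN_g

Key assumptions:

- The constraint metrics capture the gene properties (length, mutational
  target size, selective constraint) that drive baseline variant counts,
  so that within a cluster of interest (COI) the controls are exchangeable
  with the GOI under the null.
- Counts are aggregated across subjects, so relatedness among cases
  affects the sampling variability of the counts but not the validity of
  the gene-level comparison.
- The three models for nested GOI sets are non-independent; a Bonferroni
  division of the family level (0.05 / 3 ≈ 0.017) is used rather than a
  correlation-aware correction.

## Clustering

- **Normalization** is per-metric z-scoring across genes (sample SD).
  Min–max scaling was the plausible alternative; z-scoring is the
  conventional reading of "normalized" for correlation-based profile
  dissimilarities and is what this package does. A metric constant across
  the universe is an error, not silently dropped.
- **Dissimilarity** is `1 − |Pearson cor|` between two genes' 10-long
  normalized profiles (Spearman is not offered). The absolute value means
  strongly anti-correlated profiles are *similar*; the metric lives in
  [0, 1] by construction.
- **Cut heights are absolute** dissimilarity units on [0, 1], not
  fractions of the maximum merge height. This makes h = 1 exactly the
  whole-universe cluster and h = 0 all-singletons (given distinct
  profiles), and lets cut tables be compared across trees.
- **Linkage** is single linkage only. The implementation is
  `scipy.cluster.hierarchy.linkage(method="single")`; it is deterministic
  for identical input, and its merge heights are tie-invariant (they equal
  the minimum-spanning-tree edge weights, which the test suite verifies
  against brute-force oracles to 1e−10). No custom tie-breaking rule is
  layered on top.
- **Memory**: the condensed dissimilarity for p genes holds p(p−1)/2
  doubles — about 1.5 GB at p ≈ 19k. Tests and shipped fixtures run at
  p ≤ 5,000 (~100 MB).
- **Cut-height guidance** (keep COIs ≤ 20% of the universe; median COI
  size near 8) is surfaced in `height_scan` output and logs, never
  enforced: the right height is hypothesis- and universe-dependent.

## Variant counting

- SnpEff `ANN=` entries are restricted to transcripts present in the
  constraint table (version-stripped), and the most severe surviving
  consequence per record wins. LOF = {stop_gained, frameshift_variant,
  splice_acceptor_variant, splice_donor_variant} (high-confidence,
  LOFTEE-style); start_lost/stop_lost are excluded by default but the
  class sets are arguments.
- The MAF filter is exclusionary at the boundary (AF ≥ threshold is
  removed); a variant *missing* from the reference panel is retained —
  absence from a large reference is itself evidence of rarity.
- The counting unit is **distinct qualifying sites** observed in ≥ 1 case,
  not allele dosage: exome-wide class totals are naturally site counts, so
  gene-level predictors use the same unit. An allele-dosage mode
  (`unit="alleles"`) is available for sensitivity analyses.
- Upstream steps (alignment, calling, VQSR tranche filtering, indel
  normalization) are out of scope; the VCF is assumed already filtered
  and normalized.

## Association fitting

- Plain maximum likelihood via IRLS (Newton with step-halving),
  convergence at score norm < 1e−8, max 100 iterations. Wald SEs from the
  inverse observed information; OR = exp(estimate) and z = estimate/SE by
  construction.
- **Separation** is detected post-fit: if the fitted linear predictor
  perfectly orders GOI above controls (with non-degenerate spread), the
  MLE is infinite and the result is flagged `converged=False` with an
  explanatory diagnostic instead of returning a silently diverged
  estimate. A Firth (Jeffreys-prior) penalty is available as an option
  but is off by default — the reference analysis is plain logistic
  regression.
- Significance uses a **strict** `p < α` comparison against the adjusted
  level. Note the borderline case this creates: a p-value of 0.0169
  against α = 0.05/3 = 0.0167 is *not* flagged here, although an analysis
  rounding both to 0.017 would call it significant. The package applies
  the literal rule and leaves the judgment to the reader.

## Synthetic constraint universes

`simulate_constraints` draws a 10-dimensional Gaussian copula whose
intermediate correlations are calibrated per pair (monotone 1-D root
finding on the copula correlation map, tolerance 1e−4, common random
numbers from a fixed internal stream) so that the *output* Pearson
correlations match the published 10×10 gnomAD metric correlation matrix;
non-PSD targets are repaired to the nearest correlation matrix and
rejected if the repair moves any entry by more than 0.05. Marginal shapes
are free parameters of the problem and are chosen for plausibility:
scaled betas for the bounded O/E ratios, normals for z-scores, a
logit-normal for the U-shaped pLI, lognormals for the three size metrics
(exon counts rounded to integers ≥ 1 *inside* the quantile transform, so
calibration accounts for the discretization). At p = 10,000+ the sample
correlations reproduce every target to < 0.05.

What this generator does **not** emulate: the clumpy, multi-modal
geometry of the real constraint space. Real gene families produce tight
clusters; a Gaussian copula produces one elliptical cloud, on which
single linkage chains much faster. Consequently the synthetic tree's
cut-height table is *not* comparable row-for-row with a real universe's,
and passing tests on synthetic universes demonstrate correctness of the
machinery, not that any particular cut height is right for real data.

## The validation study

Defaults encode the study conditions the framework is validated under:

| quantity | default | origin |
| --- | --- | --- |
| class means (LOF, MIS, SYN) | 0.1218, 1.6231, 2.4097 | exome totals 2,328 / 31,015 / 46,046 over 19,108 genes |
| NB dispersion (size) | 1.5 per class | moderate overdispersion; no published value, config-exposed |
| count correlations | 0.166 / 0.257 / 0.688 | LOF–MIS / LOF–SYN / MIS–SYN targets |
| effect vectors | (−3, .75, .05, .1), (−5, 1.25, .1, .2), (−7, 1.75, .2, .3) | the three published effect levels |
| disturbance SD grid | 0.55, 1.00, 1.45 | three levels spanning the stated 0.55–1.45 range |
| iterations | 1,000 (CLI default) | full-scale study size |

Counts come from the same NORTA machinery with exact discrete NB quantile
functions. The response adds the Gaussian disturbance on the logit scale
*before* the inverse-logit, and GOI status is a Bernoulli draw from the
resulting probability — the minimal completion of "generate the GOI
probabilities" into binary labels. Simulated GOIs are drawn genome-wide
(not restricted to genes with pre-existing cluster structure).

The **null model** follows a three-step recipe: draw counts, draw the
response from them, then *re-draw the counts from a fresh stream* and fit
on the new counts. Response and predictors keep their marginal
distributions but are independent, so every rejection is a false
positive.

COI assignment uses a fixed partition of a synthetic universe. The
scaled-down study shipped in tests and `scripts/acceptance.py` uses
p = 5,000 genes, 200 iterations per scenario, and a cut height of 0.02;
at that height the synthetic tree yields one large cluster plus many
small ones covering ~25–30% of the universe, which exercises the COI
selection step (a height of 0.09 on the chain-prone synthetic tree would
sweep in ~95% of genes and make selection nearly vacuous). Because
control selection depends on the counts only through cluster membership —
and clusters derive from metrics generated independently of the counts —
slope estimates are approximately unbiased under any cut height; the
intercept absorbs the selection and is not a target of inference.
Iterations with zero GOIs, no COI controls, or non-converged fits are
excluded from summaries and counted.

Observed behavior at these sizes (recomputed, not asserted from memory):
mean MIS and SYN estimates fall within 2 SDs of their true values in all
nine scenarios (slopes attenuate mildly as the disturbance SD grows, as
expected for noise on the linear predictor), and null-model rejection
rates at |z| > 1.96 sit within Monte-Carlo error of 0.05 per term.

## Seeding and determinism

Every stochastic routine takes a seed or `numpy` Generator; scenario
grids spawn per-scenario and per-iteration substreams from one master
seed via `SeedSequence`, so any run is bit-reproducible. Copula
calibration uses its own fixed internal stream and is therefore a
deterministic function of marginals and targets alone — user seeds never
change the calibrated correlation structure.

## Known limitations

- The gnomAD v2.1.1 constraint dialect does not pin which columns supply
  genomic length / transcript length / exon count; the defaults
  (`gene_length`, `cds_length`, `num_coding_exons`) are overridable via
  `column_map`.
- Overlap counts between published GOI lists are computed from the actual
  lists supplied at run time, never hard-coded; published tallies that
  disagree with each other are left to the data.
- No covariates beyond the three count predictors; no mixed models; no
  alternative linkages; no ortholog mapping (model-organism lists must
  arrive as human symbols).
- Multi-allelic VCF records use the first ALT allele only (input is
  assumed decomposed/normalized).
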