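# Methods

This note documents the statistical models behind `cardioscreen`, the
defaults of the synthetic-data generators, the numerical choices, and what
the tests do and do not establish about real screen data.

## The screening model

The package analyzes a paired dropout design: a pooled library of barcoded
shRNAs is transduced into cardiomyocytes, the population is split into a
normoxic control arm and a hypoxia-reoxygenation arm, and barcode abundances
are sequenced at the end. shRNAs against genes whose loss favours survival
become enriched in the treated arm; shRNAs against pro-survival genes are
depleted. A drug-repurposing screen provides an orthogonal readout: the same
cells are exposed to a compound library at four concentrations (40, 200,
1000, 5000 nM) in both conditions with ATP-based luminescence (RLU) as the
viability readout.

## shRNA differential abundance

### Normalization

Raw counts are scaled to 2×10⁷ reads per sample (`normalize_to_depth`) and
divided by each shRNA's expected plasmid read count (`plasmid_normalize`),
giving a representation ratio that is invariant to sequencing depth and to
uneven plasmid pooling. Log-ratios use a pseudo-count of 0.5 on the
depth-normalized counts, since dropout screens produce true zeros.

### The three tests

*Quantile rank-score test* (`test_quantile`). The median-regression model
log-ratio ~ τ=0.5 intercept + gene indicator is tested with a rank-score
test. With Wilcoxon scores the statistic reduces to the standardized
rank-sum of the gene's shRNAs among all shRNAs, computed with tie-corrected
variance and a normal reference. Sign (pure median) scores were considered
and rejected: with ≤ 18 shRNAs per gene they give only a handful of
achievable p-values, which destroys rank aggregation and pushes the realized
test size far below nominal. Measured on 2000 null genes under default
conditions the test holds its level (type-I ≈ 0.043-0.05 at α = 0.05) and
its p-values are uniform (KS p ≈ 0.97).

*NB GLM Wald test* (`test_nb_wald`). Per gene, counts (one control and one
treated observation per shRNA) follow a negative-binomial GLM with log link:
intercept, condition effect, shRNA-identity covariates, and the log library
size as offset, so the condition coefficient is a log representation ratio.
The gene-wise dispersion is profiled out by maximizing a Cox-Reid-adjusted
likelihood (bounded search on log α in [10⁻⁸, 10], ~30 evaluations, IRLS
inner loop), with a method-of-moments fallback. The Wald statistic is
referred to a t distribution on the residual degrees of freedom (n_shRNA −
1), which protects calibration at the small replicate numbers typical here
(measured type-I ≈ 0.04-0.05). Genes with a single shRNA or an all-zero
condition carry no information for a gene-wise dispersion and are assigned
p = 1 with a logged count.

*NB exact-style test* (`test_nbp`). A library-wide mean-dispersion power law
Var = μ + φ μ^κ is fitted from the paired samples: with one pair per shRNA,
(c − t)²/2 is an unbiased single-pair variance estimate under equal means;
binned log-excess over the Poisson level is regressed on log mean (20
quantile bins). Each gene's pooled control/treatment split is then tested
conditionally on its total with both sides NB(μ, Var) — summing the
probabilities of all splits no more likely than the observed one over a
±15 SD window (negligible truncated mass), which keeps the test O(window)
per gene.

The original analyses used R packages for the second and third tests; these
are statistically equivalent re-implementations validated by calibration and
power simulation rather than bit-compatibility, so the published hit counts
(e.g. a 158/262 enriched/depleted split) are not reproduced verbatim.

### Consensus

Genes are ranked per test by ascending p with average ranks on ties — the
consensus is therefore invariant to any monotone transform of each test's
p-values — and the mean of the three ranks is thresholded at 500 (strict).
Direction comes from the pooled log₂ fold change of representation. On a
full-scale synthetic screen (4625 genes, 27,500 shRNAs, 400 genes spiked at
4-fold, dispersion 0.1, depth 2×10⁶) the consensus recovers ≈ 95% of spiked
genes with a false-call rate ≈ 1.6% among nulls.

## Drug screen scoring

Relative viability is RLU divided by a DMSO mean. Two references are
supported: the DMSO mean of the same condition (default; DMSO ≡ 1 per
condition) or the normoxic DMSO mean (which keeps the treated-control
deficit visible, e.g. 0.78 for a 22% drop). Protection calls are invariant
to the choice because every well of a condition scales by one constant, and
this invariance is tested.

The representative value picks, among concentrations observed in both
conditions, the one maximizing the treated/normoxic viability ratio (ties:
lowest concentration) and reports the treated relative viability there. A
drug is protective when the representative value exceeds mean + 1 sample SD
of the treated DMSO wells and the normoxic relative viability at the
representative concentration is no more than 1 SD below the normoxic DMSO
mean. The 1-SD normoxia tolerance is a package choice (the selection rule
itself only demands "not reducing viability in normoxia") and is
configurable via `sd_multiplier`. Note a deliberate property of the
ratio-maximizing selection: it favours concentrations whose normoxic well is
noisily low, so single protective drugs can fail the normoxia tolerance in a
given run; discrimination is still strong (a 1.5× treated boost is called
~2.6× as often as null drugs under default noise).

## Networks

Interaction-term categorization is an exact, case-insensitive match against
fixed agonist and antagonist vocabularies (whole-term matching, so "partial
agonist" resolves as agonist and "agonistic" matches nothing). Hit sets are
analyzed as induced subgraphs — only mutual interactions among hits count —
and ranked by degree, ties broken alphabetically for determinism. Four sets
are analyzed separately: shRNA-enriched, shRNA-depleted, antagonist targets
and agonist targets of protective drugs.

## Pathway analysis

Input values per gene and condition are the median depth-normalized counts
of the gene's shRNAs (shRNA screen; genes whose treated median is ≥ 1.3× the
control median are the hit set, boundary inclusive, zero-control genes
included and flagged) or the representative/normoxic viabilities of
protective drugs averaged per target (drug screen).

`mcml_reduce` treats members as points and conditions as classes: a
positive-semidefinite metric A is learned by projected gradient descent on
the convex MCML objective (minimizing the KL divergence between the
metric-induced soft-neighbour distribution and the ideal one that collapses
same-class points), the data are projected onto A's leading eigenvector
(sign fixed by its largest-magnitude component), and each condition's
reduced value is its projected centroid. With the scalar per-member values
used by both screens the input is one-dimensional; a 1-D metric cannot
change relative separations, so the reduced values are exactly the raw
condition centroids — this identity is exploited for the permutation nulls
and covered by a closed-form test, while the multi-dimensional optimizer is
tested separately. The pathway score is reduced(treated) − reduced(control);
the upper tail is significant for the shRNA screen, the lower tail for the
drug screen.

Null distributions use random same-length protein sets drawn without
replacement from the screen's data (default 10,000 per pathway length,
cached by length) and the occupancy-based fitness test draws set-of-hit-set-
size samples from the annotation universe (drug screen: all drug targets;
shRNA screen: all proteins in the pathway annotations; defaults 100 and 10
sets respectively, following the screen convention). Both p-values come from
the CDF of an Epanechnikov kernel density with Silverman's bandwidth
(0.9 min(SD, IQR/1.34) n^(−1/5)); no bandwidth was specified upstream and
Silverman's rule is the standard default. p-values are clamped to
[1/(n+1), 1] so smooth tails never report zero; degenerate (constant) nulls
fall back to direct comparison. At n = 10,000 the KDE CDF tracks the
empirical CDF within ±0.002 and pathway p-values are uniform under member
exchangeability (KS p > 0.2 over 200 synthetic pathways at n_perm = 1000).

The reported table filters on p-values rounded to three decimals (score p ≤
0.05, fitness p ≤ 0.1) and sorts ascending; an optional Benjamini-Hochberg
adjustment of the score p-values exists but is off by default, since no
multiplicity procedure is defined for these tables upstream.

## Validation statistics

Fisher's exact test is the standard two-sided hypergeometric sum (SciPy),
verified in tests against full enumeration; on the printed embryo-lethality
table (16/8 vs 9/12) it gives p = 0.1397 ≈ 0.14. Myocardium thickness
treats both ventricle outlines as circles of equal area, thickness =
√(A_out/π) − √(A_in/π), homogeneous of degree ½ in the areas. Group
comparisons offer both the nonparametric chain (Kruskal-Wallis + pairwise
Mann-Whitney U — exact for tie-free samples up to n = 20, else normal with
tie correction) and the parametric chain (one-way ANOVA + pairwise, optionally
paired, t tests), each with Benjamini-Hochberg adjustment within the family
of pairwise p-values. Dead embryos enter EF/HR comparisons with value 0, so
mortality folds into the contractility readout.

## Synthetic data: what it emulates, and what not

* **Library**: 1-18 shRNAs per gene with median 6 via a shifted binomial
  Bin(17, 0.291) + 1 — only the range and median of the real library are
  public, so the shape is a modeling choice; at 4625 genes it yields
  ≈ 27,500 shRNAs. Plasmid expectations are lognormal (CV 25%) around an
  even split of 2×10⁷ reads.
* **Counts**: gamma intensities (shape 1/dispersion, default dispersion 0.1)
  with one multinomial draw per sample at fixed depth: samples sum exactly
  to depth (matching the normalize-to-20-million workflow) while marginals
  keep Var ≈ μ + αμ² for libraries that are large relative to any one shRNA.
  A single sample per condition is generated, as the real screen pooled its
  transductions before sequencing.
* **Plates**: one well per drug/concentration/condition, 256 DMSO wells per
  condition (two control columns on each of ~8 384-well plates at full
  scale), treated controls centred at 0.78 of normoxic (a 22% drop), and
  lognormal multiplicative noise with CV 10% so luminescence stays positive.
* **Embryos**: group-wise normal EF (clipped at 0), Bernoulli deaths zeroing
  EF and HR, heart rate ~N(160, 15) bpm, ventricle areas from a circular
  cross-section (inner radius ~50 µm, myocardium ~15 µm).

Not emulated: sequencing-read level artifacts (FASTQ, demultiplexing), plate
spatial effects, dose-response shapes, batch structure, and any correlation
between a gene's shRNAs beyond their shared mean. Passing tests therefore
demonstrate that the statistical machinery is calibrated and recovers known
effects under the assumed generative model — not that real screens satisfy
those assumptions.

## Problem sizes and determinism

The test suite and the acceptance script run the heavy simulations at
deliberately chosen scales: calibration on 2000 null genes at depth 1.2×10⁶,
recovery on the full 4625-gene library at depth 2×10⁶ (a scaled-down
sequencing depth whose per-shRNA means, ~70 reads, retain ample power for
4-fold effects), pathway-null uniformity with 1000 permutations per pathway,
and KDE agreement at 10,000. Every generator and permutation consumes an
explicit seed (NumPy `SeedSequence` spawning), and identical configurations
produce bit-identical outputs, including the files written by `run_all`.

## Known limitations

* One sample per condition means all dispersion information comes from
  within-gene shRNA replication or library-wide trends; genes with a single
  shRNA are untestable in the NB GLM and get p = 1.
* The MCML reduction operates on scalar per-member values, where it
  coincides with class centroids; richer per-member profiles would exercise
  the metric learning fully but no such profiles exist in these screens.
* The fitness test with 10 random sets (shRNA convention) has very coarse
  resolution; its p-values should be read qualitatively.
* PSI-MITAB parsing resolves symbols from 'gene name' aliases or identifier
  text only; database-specific accession mapping is out of scope.
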