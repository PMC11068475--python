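# Methods

This note documents the models implemented in `gmebiome`, the calibration
of the synthetic-data generator, and the numerical choices made where the
design was genuinely open.

## The experiment being modelled

A cross-inoculation study: nine *Lotus* accessions (G) × four
soil-microbiome inoculants (M = two field extracts F5C/F5S, their 1:1
mixture MIX, and a noninoculated control NONE) × two environments (E =
100 mM salt vs control), with 72 combinations, two pots each (144 pots)
and six plants per pot.  Root microbiomes are profiled by UMI-tagged 16S
amplicon sequencing; phenotypes are shoot length (SL), root length (RL),
leaf and branch counts (NOL, NOB).  Community analyses exclude the
noninoculated group, so their factorial shape is 9 × 3 × 2 with degrees of
freedom 8/2/1/16/8/2/16 for G, M, E, G×M, G×E, M×E, G×M×E.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions the pipeline is exercised under.

**Reference collection.**  Taxa get independent random 320-base sequences
(pairwise identity ≈ 25%), so error-free top-hit assignment is
unambiguous; this deliberately removes the hard part of real taxonomy
(close homologs) because the operations under test are the tie-break and
bookkeeping rules, not alignment sensitivity.  A configurable fraction of
genus names (default 10%) is withheld from the accepted-names list to
exercise the NotAssigned rule.  A host "genome" decoy provides
plant-derived sequences for the exclusion rule.

**Communities.**  Per-sample taxon proportions are softmax of
`baseline + Σ term effects + noise`, with every factorial term's effects
drawn i.i.d. normal per (level combination, taxon) at a term-specific
log-scale standard deviation, and i.i.d. overdispersion noise per sample.
Softmax keeps proportions valid; effects on log-abundance are the standard
compositional device.  The default calibration

| term | G | M | E | G×M | G×E | M×E | G×M×E | overdispersion |
|------|---|---|---|-----|-----|-----|-------|----------------|
| sd   | 0.08 | 0.32 | 0.45 | 0.11 | 0.13 | 0.22 | 0.12 | 0.55 |

was chosen (once, before the acceptance runs were frozen) so that the
PERMANOVA partition of Morisita–Horn β-diversity under the default design
mirrors the study's pattern: M and E each explain ~15–35% of variance,
genotype and all interactions a few percent each, residual ~25–35%.  The
environment scale exceeds the inoculant scale because E has one degree of
freedom where M has two: equal per-level scales would give M roughly twice
E's sum of squares, whereas the study found them nearly equal.  The
baseline log-abundance spread (sd 0.5 over 60 taxa) keeps communities
uneven but not dominated by one taxon; stronger dominance makes the
realized variance partition unstable across effect draws.

**Reads.**  Each biological molecule receives a fresh UMI drawn from the
IUPAC pattern `NNNHNNNWNNNH` (12 bases) and is emitted `1 +
Poisson(mean_pcr_duplicates)` times; duplicates share the UMI but get
independent substitution errors.  The forward read begins at the UMI,
followed by the forward universal primer and the target; the reverse read
covers the amplicon 3′ end, so pairs overlap by well over the merger's
minimum at the default read length (230) and amplicon length (~370).
Illumina overhang adapters are not simulated: the real pipeline removes
them before the positional parse and they carry no information.  Indels,
chimeras and instrument-specific quality profiles are out of scope, so a
passing suite says nothing about denoising performance on real data.  A
JSON log records every molecule (taxon, UMI, copy count) as ground truth
for oracle tests.

**Phenotypes.**  SL is gamma-distributed with log-mean = log genotype mean
+ factor effects + pot intercept + a latent per-individual "vigor"; RL
shares the structure with rescaled M and G×M effects, and NOL/NOB are
rounded gamma transforms of the same vigor, which reproduces the
all-positive trait correlation structure.  Defaults: genotype means
10·exp(linspace(−0.35, 0.35)) mm (a large G effect, η² ≈ 0.3–0.45);
E effect ±0.12 with salt positive (this system's salt-adapted accessions
grow better under salt); inoculant main effects {−0.05, 0.04, 0, 0.08}
(small, η² ≈ 0.01) versus G×M effects of sd 0.09 (η² ≈ 0.04–0.05), so the
planted η²(G×M) is roughly five times η²(M) as in the study's phenotype
table; pot sd 0.12 (pot ICC ~10–15%); gamma shape 12; 9% of individuals
dropped as dead.  Interaction effect values are drawn once from a fixed
internal stream so the defaults are deterministic constants.

## Pipeline models and numerical choices

**UMI counting.**  `count(sample, target)` = number of distinct UMIs; PCR
duplicates collapse.  The optional MAUI-seq-style reassignment of a UMI
seen with several targets in one sample (credit the most frequent target)
is off by default, as is UMI-pattern filtering — the default pipeline
counts exactly what it sees.  The 0.05 mean-UMI filter is applied before
host exclusion, matching the order of operations in the original
workflow's description.  "More than 10 bp" overlap and "more than 300 bp"
total are strict inequalities.  The pair merger scores ungapped overlaps
by matches − mismatches (so a long, nearly exact overlap beats a short
chance-perfect one) and resolves disagreements by the higher-quality base;
exact reproduction of an external merger's scoring is out of scope.
Primer-region mismatches up to 2 are tolerated (positions are
length-based regardless).

**Taxonomy.**  The internal search is an ungapped sliding alignment
(identity = matching positions / query length, floor 70%); the synthetic
references are engineered to be separable without gaps, and what matters
downstream is the contract: maximal identity, then validly-named-genus,
then earliest reference ID under natural (numeric-aware) ordering.  A
query is host-derived iff its best host identity strictly exceeds its best
16S identity.  NotAssigned lineage bins stay distinct per parent lineage
during aggregation, and aggregation conserves count totals at every rank.

**Rarefaction and coverage.**  Expected richness uses the exact
hypergeometric form computed via log-gamma.  The endpoint slope
E[S_N] − E[S_{N−1}] equals f₁/N.  Coverage standardization takes the
largest endpoint slope across samples as the reference s\* (the
lowest-coverage sample) and subsamples every other sample, without
replacement and seeded, to the largest depth m with slope(m) ≥ s\*
(binary search; the slope is non-increasing in m, and slope(1) = 1
guarantees feasibility).  Whether the original analysis matched s\*
exactly or to the nearest attainable slope is unknowable from the text;
"largest m with slope ≥ s\*" is one consistent resolution.  Shannon
entropy uses natural log (base configurable).

**PERMANOVA.**  Sequential (Type I) SS in the order G, M, E, G×M, G×E,
M×E, G×M×E — the convention of the standard implementation and of the
study's printed table.  The Gower-centered matrix G = −½·C D∘²C gives
SS(total) = tr(G); term SS are tr-differences of cumulative hat-matrix
projections built by SVD (rank-tolerant to the deliberately redundant
cell-mean blocks).  Permutations jointly permute rows/columns of G,
unrestricted, with the add-one p-value convention.  Negative sequential SS
can occur for non-Euclidean dissimilarities (as in the reference
implementation) and are reported as-is.  A marginal-SS variant is not
provided; the sequential decomposition is what the acceptance checks
exercise.

**nMDS.**  Kruskal stress-1 minimized by iterative majorization (Guttman
transform) alternating with isotonic regression of embedded distances on
the dissimilarity order (primary tie treatment), best of `n_starts`
random starts (default 100).

**Gamma GLM and type II ANOVA.**  Fitting is IRLS (statsmodels), log
link.  Sums of squares are on the deviance scale: SS(T) is the deviance
drop when T enters the type II comparison (base model = all terms not
containing T), SS_resid is the full model's deviance, and
F = (SS/DF)/(SS_resid/DF_resid); η² = SS/(ΣSS + SS_resid).  This is the
standard GLM analogue of applying a linear-model effect-size routine, and
it reproduces the internal SS/F/DF relations of the study's phenotype
table.  On a balanced design the type II and sequential decompositions
agree exactly for the last term and to first order (within ~0.5% of the
total deviance) for the others — gamma deviance is not an exactly
orthogonal decomposition, which is why the equivalence test uses a
tolerance.  A constant response is handled as an explicit zero-deviance
degenerate fit.  Tukey–Kramer contrasts are single-step max-modulus
adjustments of link-scale marginal-mean differences, evaluated by a
seeded Monte-Carlo draw from the joint normal contrast distribution
(200 000 draws); with a single contrast the adjusted p equals the raw p
by construction.  The pot ICC uses one-way method-of-moments with
negative between-pot variance truncated to zero — likelihood fits are
fragile with two pots per group.

**Pot permutation.**  Exactly one pot per combination is selected
uniformly per iteration (asserted), the GLM/PERMANOVA is refit, and η²/R²
distributions are collected; ties η²(G×M) = η²(M) count as "not greater".
Inner PERMANOVA permutations default to 999 inside the outer loop — the
outer distribution, not the inner p-value, is the quantity of interest.

**Variance component.**  The kinship is the Morisita–Horn *similarity*
(1 − dissimilarity): a kinship must be a similarity, which resolves the
ambiguity in describing the matrix as "1 − the similarity index matrix".
The complementary reading would use the dissimilarity itself and is not a
valid covariance.  Negative eigenvalues are clipped to zero (minimal
perturbation, magnitude recorded) rather than ridge-inflated.  REML
profiles δ = σ²_e/σ²_g via one eigendecomposition of the
intercept-projected kinship, maximizes on a 100-point log grid over
10⁻⁵…10⁵ refined by bounded local search, and reports
σ²_g/(σ²_g + σ²_e).  When replicate communities exist per individual they
are averaged after rarefaction, before the kinship.

**Per-OTU smoother.**  For categorical factors the nominal reproducing
kernel k(a,b) = 1{a=b} − 1/L (tensor products for interactions) is
equivalent to ridge-penalized sum-to-zero level effects on centered
indicator blocks, one smoothing parameter per term, selected by GCV
(Nelder–Mead on log-λ in a bounded box; the lower bound is effectively
unpenalized, the upper effectively removes the term).  The equivalence to
the external package the study used is structural (same model class), not
numerical — "default settings" of an external optimizer are not a
specification.  Term F-tests compare the full fit to a refit without the
term (other λs held fixed), with effective-df differences (rounded to two
decimals) as numerator df.  OTU prevalence filtering is strict (> 6
individuals), with the threshold exposed.  Frequencies are analyzed on
the raw proportion scale; a logit flag exists.

## Problem sizes

Analyses at the composition/phenotype level run at the full printed design
(72 combinations; 216 community samples after excluding NONE; ~790
individuals).  Read-level end-to-end runs use reduced designs (8–12 taxa,
tens of molecules per sample): the read simulator and UMI pipeline are
exact bookkeeping, so their correctness is established by molecule-level
identity with the truth log, not by scale.  Calibration experiments use
1000 null simulations × 999 permutations (PERMANOVA type-I error), 200
seeds for REML recovery on a 10-block kinship of 300 individuals, and 200
pot-permutation iterations.

## Known limitations

* The reference search is ungapped and the synthetic references are far
  apart; assignment performance on real, closely related 16S sequences is
  not evaluated.
* Unique sequences are the unit of analysis (as in the original
  workflow); no denoising or chimera removal.
* The generator plants no coupling between community composition and
  phenotypes, so the variance-component machinery is validated by
  parameter recovery on constructed kinships, not by an emergent
  microbiome–phenotype signal.
* Gamma-deviance type II SS is one consistent bridge to η² for GLMs; other
  bridges (Pearson-scale, linear-model-on-link) would give slightly
  different effect sizes.
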