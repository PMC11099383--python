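# Methods

`gpcraxes` re-implements, as a reusable and fully tested pipeline, a
pan-cancer analysis of G-protein-coupled-receptor (GPCR) signaling
*axes*: a receptor paired with either its peptide-ligand precursor gene
or a biosynthetic enzyme producing its small-molecule ligand.  The
pipeline has five analysis stages — network construction, differential
expression, co-differential-regulation scoring, transcript–metabolite
pathway concordance, axis survival screening — plus a drug-activity
caller for pooled viability screens.  Every stage can run on synthetic
inputs with planted ground truth, so the statistical behavior of each
stage is testable without any external download.

## Axis network

Components are receptors (with G-protein coupling and family
annotations), ligands (peptide, metabolite, synthetic organic,
inorganic, natural product) and enzymes (with cellular-component and
class/domain annotations plus an optional literature evidence count).
Edges are typed: ligand→receptor (action mode), enzyme→ligand (reaction
direction LR/RL/UN), and derived receptor–enzyme edges that exist only
when a mediating ligand connects both endpoints and a
functional-interaction confidence score is ≥ 150 (inclusive; the
threshold is the lowest admitted value).

Enzyme filtering keeps an enzyme when at least one cellular-component
term is on the keep list (OR semantics) and no class/domain/name
annotation contains an excluded class (kinases, channels, transporters,
cytochromes …) as a case-insensitive substring; the exclusion is
substring-based because the class lists are plain-language labels drawn
from several annotation vocabularies.  Rate-limiting enzymes are chosen
per pathway as the member with the largest literature count, with ties
broken to the lexicographically smallest gene symbol so the choice is
deterministic.

## Differential expression

The pipeline's primary path is *importing* DE tables (gene, lfc,
pvalue, padj) computed by any engine.  The internal stage is a
deliberately simple stand-in so the pipeline is self-contained:
median-of-ratios size factors (reference genes = nonzero in all
samples; factor = median of count/geometric-mean ratios on the linear
scale), log2 transform with pseudocount 1, Welch t-test per gene, and
Benjamini–Hochberg adjustment per contrast (via statsmodels).  It does
no dispersion or fold-change shrinkage and is not a negative-binomial
model; downstream axis statistics, not the DE engine, are the point of
the package.  Significance uses the strict thresholds |LFC| > 1 and
adjusted p < 0.01 throughout.

One caveat the tests exercise: median-of-ratios assumes most genes are
unchanged.  When a large fraction of genes is shifted in one direction
(≫ a few percent), the estimated factors absorb part of the shift and
fold changes are biased toward zero; the synthetic cohorts plant ~1–2 %
of genes, where the effect is negligible.

## Co-differential regulation

Each axis gets an integer score per cancer subtype: ±2 when both genes
pass |LFC| > 1 in the same direction with both adjusted p < 0.01, ±1
when both pass the fold cut but only one is significant, else 0
(anti-regulation, sub-threshold fold change, both non-significant, or a
missing gene).  Axes are retained ("affected") when the score is
nonzero in at least 25 % of subtypes, inclusive.  The retained matrix
is Ward-clustered (scipy linkage on Euclidean row distances; a
Lance–Williams brute-force agglomerator serves as the test oracle).

Receptor-level summaries: ligand-wise similarity is the mean pairwise
Euclidean distance between a receptor's partner score vectors across
subtypes; tissue-wise similarity first averages subtype columns within
each tissue and then applies the same distance across tissues; the
up/down balance is the mean count of +2 minus −2 entries per partner.

Expression-correlation calls compare each axis pair's Pearson r against
a shared background of 1000 uniformly sampled gene pairs per subtype
(one background per subtype rather than per pair — cheaper and
statistically equivalent).  The background comparison is an outlier
test: a two-sided t tail probability of the standardized deviation
(r − mean_bg)/sd_bg with df = n_bg − 1.  Standardizing by the
background's standard deviation (not the standard error of its mean) is
essential — against the SE of the mean of 1000 pairs any |r| above
~0.02 would be "significant" and the test would carry no information.
A pair is called correlated when the BH-adjusted p is < 0.05 and
|r| > 0.25.

Mutation association ranks, per subtype, the top five mutated cancer
genes by the fraction of samples carrying ≥ 1 mutation (a sample counts
once; ties at rank five are all kept), then scores each gene by the
mean number of strongly co-regulated axes (|score| = 2) across the
subtypes where it ranked.

## Pathway abundance and concordance

The Pathway Abundance Score is PAS = (I − D)/S over a pathway's
members, where I counts members with LFC > 0, D those with LFC < 0 and
S = I + D (S = 1 when I + D = 0, so an unregulated pathway scores
exactly 0).  Zeros count toward neither side; the statistic is
sign-only, order-free and odd under negation.  All members with nonzero
LFC contribute by default; a significance-gated mode is available.
Enrichment scores (ES) are consumed from an input table, never
computed: gene-set enrichment is upstream tooling, not part of this
package.  The concordance code is +1 when ES and metabolite-level PAS
are both positive, −1 when both negative, else 0; ES significance
(adjusted p < 0.01) is reported alongside without gating the sign.

## Survival screening

Within one cohort, patients are split at the median expression of a
gene (high = strictly above; ties to low, a deterministic and
conservative rule) or jointly for an axis: both-high vs both-low, with
mixed patients excluded.  Contrasts use the two-group log-rank test and
univariate unadjusted Cox proportional-hazards regression (lifelines,
Efron ties) with the low group as reference.  We report standard
high-vs-low hazard ratios (HR > 1 = higher hazard in the high group);
an inverted labeling convention seen in some reports can be applied at
presentation time but is never silently assumed.

An axis passes the screen when HR_axis/HR_receptor and
HR_axis/HR_partner both fall outside (0.5, 2), the combined log-rank p
is < 0.05, and it is smaller than both single-gene log-rank p values;
q-values are BH-adjusted over tested axes within the cohort
(FDR < 0.1).

The combinatorial model forms a per-patient predictor
β_r·receptor_i + β_p·partner_i from the univariate Cox coefficients and
the binary high/low indicators (a continuous-expression mode exists
behind a flag; the indicator mode matches the median-cutoff derivation
of the betas).  Patients are re-split at the predictor's median so a
log-rank p is defined; the model is selected when its HR is ≥ 2-fold
(either direction) of both individual HRs with the combined log-rank p
below 0.05 and both individual p values.  Over selected models,
ordinary least squares regresses β_c on (β_r, β_partner).

A structural property worth knowing: when risk is elevated only in the
both-high cell (a pure interaction with multiplier m), the single-gene
high group is a ~50/50 mixture of both-high and mixed patients, so its
hazard ratio tends to (m + 1)/2 and the ratio HR_axis/HR_individual is
capped near 2m/(m + 1) < 2.  The strict 2-fold filter therefore admits
such axes only through estimation noise; it selects axes whose
*individual* associations are weak relative to the joint one (e.g.
compensating or anti-correlated marginals), not any interaction.  The
test suite documents this behavior on planted pure-interaction cohorts,
where recovery is accordingly low while the null false-pass rate stays
at zero.

## Drug-activity calling

A drug's profile is its log2 fold change in cell counts across cell
lines (negative = growth inhibition), with ≥ 2 replicates.  A drug is
active when the replicate–replicate Pearson correlation exceeds 0.2
(reproducibility) and Sarle's sample bimodality coefficient

    b = (g1² + 1) / (g2 + 3(n−1)²/((n−2)(n−3)))

exceeds 0.35 (both strict), with g1/g2 the bias-corrected sample
skewness and excess kurtosis.  b ≈ 1/3 for a normal sample, 5/9 for a
uniform one, → 1 for a balanced two-point mixture; it is invariant to
affine transforms.  The source screen does not print the formula; the
Sarle form is the one used by the pooled-screen resource the thresholds
come from.  A drug needs ≥ 4 scored cell lines; missing entries drop
pairwise.  Top inhibitors are ranked per cell line by ascending LFC
(ties to drug id), aggregated per tissue by mechanism of action and by
target, the latter optionally normalized by the tissue's cell
line–drug pair count.

## Synthetic data

The generator emits every pipeline input plus machine-readable truth
tables and is a pure function of (seed, config); per-generator streams
are seeded from the config seed plus fixed offsets, so outputs are
byte-identical across runs.

* Counts: negative binomial with per-gene mean drawn log-uniformly
  (default e³–e⁸ ≈ 20–3000) and variance μ + φμ², φ = 0.1 — typical of
  bulk RNA-seq.  Planted axis genes shift by LFC 2 in tumor samples of
  every subtype; pathway blocks shift ±2 by pathway direction; the rest
  are null.  Default scale: 2000 genes, 8 subtypes in 4 tissues, 400
  tumor + 100 normal samples per subtype.
* Survival: exponential event times (proportional hazards hold exactly,
  giving Cox a clean oracle) with per-patient hazard
  baseline × Π m_a^(both-high indicator of axis a), baseline 0.1,
  multiplier 3 on planted axes.  Censoring is independent exponential
  with its rate solved by bisection so the expected censored fraction
  matches the configured 0.3.
* Pathways/metabolites: concordant pathways get metabolite LFC signs
  and an ES sign matching their gene direction; discordant pathways get
  opposing metabolite signs (intended concordance 0).
* Drugs: active drugs draw true per-line LFC from a balanced mixture at
  0 and −3 (component sd 0.2); inactive drugs have *no* systematic
  cell-line effect, so their observed profiles are replicate noise
  (sd 0.1) and fail the reproducibility-correlation gate — which is
  precisely what that gate is for.  Unimodal-but-reproducible profiles
  would instead sit near the bimodality threshold (a normal sample's
  coefficient is 1/3 against a cutoff of 0.35), which is a real
  borderline regime of the published filter, not something the
  generator hides.

What the generator does not emulate: batch structure, tumor purity,
library-size extremes, subtype sample-size imbalance, correlated
expression between axis partners, non-proportional hazards, dose
dependence.  Passing tests demonstrate the pipeline's statistical
machinery under clean planted conditions; they do not certify behavior
on real cohorts.

## Numerical choices and degenerate inputs

BH adjustment ignores missing p values (not counted in m) and caps at
1.  Median splits put ties in the low group; constant vectors are
errors.  Cox non-convergence or separation yields a missing-flagged
record, not an exception; axes with a missing component propagate
missing through the screen.  All thresholds are strict inequalities as
printed in their sources.  Output tables are TSV with a commented
header line; floats are written with %.10g so runs diff cleanly.

## Problem sizes in the test suite

Simulation-heavy tests use scaled-down cohorts chosen to keep the suite
fast while leaving each statistical check well-powered: DE recovery at
2000 genes × 20 + 20 samples; correlation recovery at 300 genes × 50
samples over 20 seeds; the planted-axis screen at 100 axes × 400
patients over 20 seeds; drug recovery at 60 drugs × 100 lines over 20
seeds; the end-to-end determinism check at 200 genes × 2 subtypes.  The
acceptance script runs the full pipeline at the generator's default
scale.
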