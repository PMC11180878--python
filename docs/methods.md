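# Methods

`vasc_protnet` re-implements, as a tested pipeline, the co-expression network
analysis used for quantitative proteomics of isolated brain vasculature:
multi-batch isobaric-tag (TMT) data are batch-corrected against pooled
global-internal-standard (GIS) channels, cleaned of composition and nuisance
covariates with diagnosis effects protected, organised into signed
co-expression modules, and interrogated with preservation, trait,
differential-abundance and enrichment statistics, plus amyloid-beta peptide
ratio quantitation. A synthetic-study generator with full ground truth stands
in for the (confidential, ~300 GB) human cohort, so every stage is testable
offline.

## TAMPOR batch correction

Each TMT batch carries one or more GIS channels (a pooled mixture of all
samples). For protein *i* and channel *j* in batch *b* the denominator
`d_ib` is the median of the batch's GIS intensities (or of all non-GIS
channels with `use_all_non_gis`). The log2 ratios `log2(A_ij / d_ib)` are
then two-way median polished: protein-wise and sample-wise medians are
alternately subtracted (observed entries only) until the largest subtracted
median falls below `tol` (default 1e-8).

An *iteration* is the full cycle denominator → ratio → polish. With GIS-only
denominators the denominators never change, so the second cycle reproduces
the first bit-for-bit and the algorithm reports convergence at
`n_iterations = 2` (the confirming pass is counted). With `use_all_non_gis`
the denominators are re-derived from the partially corrected matrix each
cycle; divergence is possible in principle and is logged.

Because the polish drives every protein median to zero, multiplying the
ratio by a protein-wise central tendency before polishing provably cancels
from the centered output. The per-protein log2 median of the raw matrix is
therefore kept as a separate `row_scale` and added back only where an
abundance scale is needed (the Abeta ratio stage); this also makes the
output exactly invariant to per-batch rescaling of the linear input —
bit-exact for power-of-two factors, and to rounding error (~1e-12) for
arbitrary ones.

Median centering assumes most proteins are not differential. When a large,
asymmetric share of the proteome shifts with disease (as the generator
plants: ~23% of proteins), the sample-median subtraction compresses group
contrasts by roughly 5–10%; this is inherent to median normalization and is
quantified separately from regression protection (below).

## Cell-type proportions and outlier removal

Two estimators are averaged (and renormalized): **marker-score** — per cell
type, the mean of z-scored *linear* marker abundances, shifted nonnegative
per sample and normalized to sum 1; and **NNLS** — nonnegative least squares
of each sample's marker profile on the signature mean-profile basis, with
profiles taken relative to each marker's mean so all markers carry
comparable weight. Both estimators are proportion-calibrated only when cell
types are exchangeable in the cohort (the z-scores and mean profiles are
cohort-relative); the bundled deconvolution benchmark therefore uses a
symmetric-Dirichlet cohort, while the endothelial-dominant study uses the
ensemble for relative comparisons and outlier flagging only.

A sample is flagged as non-enriched when the robust z (median/MAD) of its
endothelial proportion is below −1.3 **and** the robust z of its neuron
proportion is above +4. The asymmetric defaults reflect the ensemble's
behaviour: estimated proportions are bounded below, so a non-enriched
sample's endothelial z saturates near −1.6 to −1.8 (it cannot reach −2 when
the MAD is set by the well-enriched majority), whereas the neuron excess of
contaminated samples (z ≥ 5.9 in simulation) is far above genuinely
neuron-rich but properly enriched preparations (z ≤ 3.1). Both thresholds
are configurable.

## Protected bootstrap regression

Per protein, the model intercept + neuron proportion + age + sex + PMI +
batch indicators (all centered) + AD/PSP indicators is fitted on `n_boot`
(default 1000) bootstrap resamples of the samples, via masked normal
equations so all proteins solve at once. The per-coefficient median over
fits is subtracted for the nuisance terms only:
`y' = y − Σ_c β̃_c (c − mean c)`; the diagnosis coefficients are estimated
but never subtracted, protecting disease contrasts. Rank-deficient resamples
(e.g. a protein absent from an entire batch makes that batch's centered
dummy collinear with the intercept) are solved by minimal-norm
pseudo-inverse; proteins with fewer than `min_obs` (10) observations or
unsolvable fits pass through unchanged with a warning.

Success criteria, verified in the tests: on noiseless data the coefficients
equal the planted values to 1e-6 and zero-effect proteins pass through
exactly; at default noise a planted age slope leaves a mean absolute
*partial* correlation with age (given diagnosis) below 0.05 — the partial
correlation is the right target because the protected diagnosis variation
deliberately remains in `y'` and is itself correlated with age in any finite
sample; and a planted +1 log2 AD effect is recovered within ±10% by the
regression step. Variance-partition tables (squared semi-partial
correlations, with categorical terms dropped as a block) document each
cleanup step; batch share falls from >20% to <1% after TAMPOR.

## Signed network and modules

Correlation is the biweight midcorrelation: with `m = median(x)`,
`u = (x−m)/(9·MAD)`, weights `w = (1−u²)²·1[|u|<1]` and `x̃ = (x−m)w`,
`r = Σx̃ỹ/√(Σx̃²Σỹ²)`, computed on pairwise-complete entries (weights from
each vector's own observed values; pairs with <5 shared samples are
missing; MAD = 0 falls back to Pearson). Adjacency is the signed transform
`a = ((1+r)/2)^β` with β = 9 (missing correlations contribute 0), and
similarity is topological overlap
`TOM_ij = (l_ij + a_ij)/(D_ij − a_ij + 1)` with the "mean" denominator
`D_ij = (k_i + k_j)/2`, validated against a brute-force triple loop.

Modules are branches of the average-linkage dendrogram of `1 − TOM`: a node
is a module candidate when it has ≥ `min_module_size` (20) members and its
height lies below the branch cut, and maximal such nodes are taken. The cut
is the smaller of (a) a `deep_split`-controlled fraction of the merge-height
range (`0.95 − 0.025·deep_split`; higher values demand tighter branches) and
(b) a low quantile (0.005) of the merge heights of a *permutation null* —
the same matrix with every protein's samples independently permuted — so no
branch that a co-expression-free dataset could produce is ever called a
module. The null rebuild is deterministic given `null_seed`. A PAM-like
stage then assigns leftover proteins to the nearest module by average
dissimilarity, restricted (when `pam_respects_dendro`) to modules under the
protein's nearest module-bearing ancestor. Exact replication of the
reference dynamic tree-cut heuristics is not attempted; the contract is the
stated procedure plus planted-module recovery (ARI ≥ 0.9).

Module eigenproteins are the leading right singular vector of the z-scored
member matrix (missing → 0 after scoring), sign-oriented to correlate
nonnegatively with the mean member profile; kME is the bicor of each protein
with each eigenprotein. Modules whose eigenproteins satisfy
`1 − cor(ME) < 0.07` are iteratively merged. Membership is then iterated to
a fixed point under three rules, applied per protein each pass after
recomputing MEs and kMEs: (3) unassign if all kME < 0.30; (2) assign an
unassigned protein to its arg-max module if any kME > 0.30; (1) reassign if
the best kME beats the current module's by more than 0.10 (ties toward the
lower module index). The loop stops at the first pass with no changes
(counted); an audit helper re-derives the kMEs and verifies the rules hold
exactly. At n = 62 samples rule 2 necessarily sweeps a few percent of null
proteins into modules (P(bicor > 0.30) ≈ 0.9% per module) — faithful
behaviour, which is why recovery is scored on planted members. With a large
null background this sweep can snowball for a small module (its eigenprotein
drifts as members join, letting further null proteins cross the 0.30 floor
on later passes), so convergence takes 3–11 iterations depending on the
realization and small modules can grow severalfold with absorbed background;
the fixed point still satisfies all three rules exactly and planted members
stay correctly grouped. A junk-heavy module of this kind also shows weak
self-preservation Z — the preservation statistic working as intended.

## Module preservation

For each template module, density statistics in the target (mean
intramodular adjacency, eigenprotein variance explained, mean |kME|) and
connectivity statistics comparing template and target (correlations of
intramodular connectivity, of kME, and of intramodular adjacency) are
normalized against `n_perm` random protein sets of equal size drawn from the
shared universe: `Z = (obs − mean_null)/sd_null`, `Z_density` and
`Z_connectivity` are the medians of their groups and `Z_summary` their mean.
`Z_summary > 1.96` marks moderate preservation (two-sided normal tail 0.05)
and `> 10` high preservation (tail < 1e-23). The default is 500
permutations; desk-scale runs (tests, acceptance script) use 100. Note that
with a self-target the connectivity correlations equal 1 for observed and
null sets alike, so their Z is 0 by the zero-variance guard and Z_summary is
carried by density; and for very homogeneous synthetic modules the
connectivity Z can be negative even when density preservation is strong,
because random (heterogeneous) sets correlate their connectivity across
networks almost perfectly.

## Differential abundance and trait statistics

Three-group comparisons use one-way ANOVA on observed entries and
Tukey-Kramer studentized-range p values (`q = |Δmean|/√(MSW/2·(1/n_a+1/n_b))`
with k = 3 and the pooled within df). Tukey p values below 1e-8.5 — where
the studentized-range tail is numerically imprecise — are replaced by
`min(1, 3 × Welch two-sided p)` (Bonferroni over the three comparisons
within a protein) with a provenance flag. Proteins with any group under 3
observations are skipped. Eigenprotein-trait association is bicor with the
Student t transform `t = r√((n−2)/(1−r²))`, two-sided, reported for n ≥ 5.
CAA severity is analysed as none (0) / mild (1) / moderate-severe (2–3).

Vascular/bulk enrichment is the mean over paired samples of
`log2(vascular) − log2(bulk)` on abundance-scale TAMPOR output, per protein
and per module; proteins absent from one fraction are flagged unique.
Classifier candidates are proteins unique to the vasculature or ≥ 3-fold
enriched there, with all three pairwise p < 0.05, sorted by ANOVA p.

## Enrichment

Set overrepresentation is the hypergeometric upper tail
`P(X ≥ overlap)` per (module, set) over a stated background, with
Haldane-corrected odds ratios and BH FDR within each analysis family (cell
types; each fluid × direction; GWAS) — corrections are not pooled across
families. BH is implemented in-package (missing p values propagate) and
cross-checked against statsmodels. GWAS risk enrichment maps gene symbols to
network proteins (case-insensitive, first match), scores each module as the
mean over member genes of `(−log10 p)·1[p < 0.05]`, and normalizes against
`n_perm` (default 10 000) random same-size draws from the mapped background:
`NES = (S − μ_null)/σ_null`, empirical `p = (1 + #{null ≥ S})/(n_perm + 1)`,
BH across modules with flags at 5% and 10% FDR. The statistic is the
package's declared reading of a permutation-normalized enrichment of
nominally significant gene-level hits.

## Abeta peptide quantitation

Strict-trypsin digestion cleaves after K/R except before P (missed
cleavages emit concatenations); digesting Abeta 1-40 and 1-42 yields the
distinguishing C-terminal peptides GAIIGLMVGGVV and GAIIGLMVGGVVIA.
Reporter intensities are loading-normalized by scaling every channel to the
maximum summed channel (all column sums equal afterwards), TAMPOR-corrected
per fraction with GIS-only denominators, and ratioed per sample on the
abundance scale (linear, with log2 alongside). Because the two fractions are
separate TMT experiments, their intensities carry an arbitrary relative
scale; it is anchored on the typical peptide (the median, over non-Abeta
shared peptides, of each peptide's median vascular/bulk ratio) before the
Abeta ratios are reported.

## The synthetic study

Defaults: 4 batches × 18 channels, one GIS per batch plus a second in the
last (5 GIS, 67 biological samples: 28 control / 21 AD / 18 PSP); 2000
proteins with planted modules of 300/150/80/40/20 members; log2 abundance
`μ_i + λ_i f_m(j) + covariate + diagnosis + batch_{i,b} + ε`,
with loadings λ ~ U(0.5, 1), factor scores standard normal shared within a
module, noise σ = 0.4 and per-protein per-batch effects
`log2 b ~ N(0, 0.6²)` (batch then explains >20% of per-protein variance
before correction). Factor scores are re-centered within each diagnosis
group so planted diagnosis contrasts equal the configured effects exactly —
otherwise the shared factor's random group imbalance (sd ≈ 0.29 at these
group sizes) would be confounded with the planted effect. Planted effects:
M1 +1.0 log2 in AD and +0.45 in PSP (its 30 vascular-enriched members mimic
strongly amyloid-associated proteins at +1.6/+0.8, so all three pairwise
contrasts separate); M2 −0.8 in AD (brain-down / plasma-up discordant
module); M4 +0.8 in PSP; age 0.05/yr on M3, sex 0.4 on M4, PMI 0.03/h on
M5. CAA score is built from the AD indicator and M1's factor, so the AD
module's eigenprotein correlates with CAA by construction. Five samples get
neuron-dominant (0.55), endothelium-poor (0.03) true proportions. Nine
15-marker cell-type blocks carry `log2(0.05 + 4·proportion)`; cell-type
*enrichment* lists additionally include 25 members of an associated module
(deconvolution signatures and enrichment lists are distinct families, as
with scRNA-derived lists). GIS channels carry the per-batch mean of the
biological channels plus N(0, 0.05) noise. Missingness is
missing-not-at-random — probability logistic in −(standardized log2
abundance), calibrated by bisection to a 10% overall rate. A paired bulk
matrix shares factors and effects but has independent noise/batch draws,
neuron-dominant marker composition, no M5 (zero loadings) and the planted
4-fold vascular enrichment subtracted. Peptide tables plant Abeta40 at 4.5×
vascular/bulk (the recovery check "median ≥ 4" is then meaningful),
Abeta42 at 1/4.5, and a 2.0× AD elevation of vascular Abeta40/Abeta42, with
per-channel loading factors to exercise the scaling step; 48 filler peptides
keep the planted folds from leaking into the channel totals.

What the generator does *not* emulate: peptide-to-protein rollup and search
artefacts, correlated missingness across proteins, isotope impurity
spillover, non-Gaussian heavy-tailed noise, and realistic proteome-wide
effect-size distributions. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated model, not
performance on real cohort data.

## Problem sizes and numerical choices

The default test/acceptance scale is the full synthetic design (2000
proteins × 67 channels), with 1000 bootstrap fits, 100 preservation
permutations, 10 000 GWAS permutations, and a 5000-protein null for ANOVA
calibration; the whole acceptance run takes a few minutes on one CPU.
Tolerances: TAMPOR `tol` 1e-8 (log2); TOM vs oracle 1e-12; bicor pairs need
≥ 5 shared samples; preservation Z with zero null variance reports 0;
ties in arg-max kME resolve toward the lower module index; recovery ARI is
computed over planted-module members (background proteins have no true
co-expression group). Every stochastic step takes an explicit seed and the
pipeline derives per-stage seeds from the master seed, so reruns are
byte-identical (verified via manifest digests).

## Known limitations

Single-block network construction only (no block-wise decomposition for
very large proteomes); no consensus networks across cohorts; the
dynamic-cut is a calibrated simplification of the reference tree-cut
heuristics; deconvolution is a two-estimator ensemble contracted on
recovery accuracy, not a re-implementation of the published multi-algorithm
ensembles; MAGMA gene-level statistics are consumed, never computed from
SNP data; and plotting is out of scope (all outputs are TSV).
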