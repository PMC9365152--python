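# Methods

`regmut` models regional somatic mutagenesis: the number of somatic
single-nucleotide variants (SNVs) that a cancer cohort accumulates in
fixed-size genomic windows, and how much of that regional variation is
explained by the chromatin state of the tissue the tumor arose from.

## Windows, tracks and burden

All analyses share one coordinate frame: non-overlapping windows of
equal length (1 Mbp by default; 100 kbp for gene-level work), 0-based
half-open, tiled per chromosome from position 0 with sub-window
remainders dropped. Windows whose uniquely-mappable fraction is at or
below 0.8 are removed (kept only when strictly above the threshold), as
are explicitly excluded windows — in lymphoid cohorts (CLL, B-NHL) the
two windows containing the immunoglobulin loci (chr2 at 89 Mbp, chr22
at 23 Mbp), where somatic hypermutation inflates local burden
independently of chromatin state.

Epigenome tracks — ATAC-seq chromatin accessibility (CA) of primary
cancers, normal tissues and cancer cell lines, and RepliSeq replication
timing (RT) in six cell-cycle phases — are reduced to the
length-weighted mean signal per window. Bases not covered by any
interval contribute signal 0 (the sparse bedGraph convention): absent
accessibility signal means no measured transposase insertion, not
missing data. Intervals running past the grid are clipped with a
warning. Strand is ignored throughout.

The response is the per-window SNV count per cohort. Hypermutated
genomes (strictly more than 90,000 SNVs, roughly 30 per Mbp) are
removed first; only cohorts with at least 25 genomes are analysed
individually, and a pan-cancer pseudo-cohort pooling every retained
genome is always produced. SNV positions are 1-based on input (VCF
convention) and mapped to the 0-based grid internally; indels and
sex-chromosome variants are rejected at parse time.

## Random-forest regression and the paired comparison

Burden is regressed on the track matrix with a random forest: 1000
trees, one third of predictors tried per split, terminal node size 5
(the regression default of the classic R implementation this model
family comes from). Accuracy is adjusted R² on held-out windows,

    adj.R² = 1 − (1 − R²)(n − 1)/(n − p − 1),

penalising the predictor count p; it is undefined (and raised as an
error) when the evaluation set has n ≤ p + 1 windows. Monte-Carlo
cross-validation draws 1000 random 80/20 window splits by default;
tests and the synthetic study use reduced splits and trees through the
same configuration type.

The cancer-vs-normal contrast trains two forests per split on an
identical window partition — one arm with the cancer-CA profiles, one
with the normal-CA profiles, both sharing the same RT profiles — and
evaluates Δadj.R² = adj.R²(cancer) − adj.R²(normal) on the identical
test windows. Reported per cohort: the median Δ, the 2.5/97.5
percentile interval of the per-split Δ distribution, and an empirical
p-value — the fraction of splits falling strictly on the opposite side
of zero from the median, with Δ = 0 counting one half (a continuity
choice; with no crossing splits the p-value is reported as below
1/n_splits). Because both arms share split seeds, swapping the arms
negates every Δ exactly. Arm sizes can be equalised by repeatedly
subsampling the larger arm without replacement (`downsample_arms`), so
a predictor-count imbalance cannot masquerade as a biological
difference.

Residuals for downstream analyses are observed minus out-of-bag (OOB)
predicted burden from a full-data fit: each window's expectation comes
only from trees that did not train on it, so residual variance is not
deflated by overfitting.

## Predictor significance and interpretation

Track importance is incMSE: the percent increase in OOB mean squared
error when one track's values are permuted, computed per tree across
that tree's OOB windows and averaged over permutation repeats. Because
raw incMSE has no calibrated null, significance comes from a
permutation-refit null: the burden vector is randomly reassigned across
windows (1000 times at full scale) and a forest refit to each permuted
response, recording per-track null incMSE. A track is significant only
when its observed incMSE strictly exceeds every null value (empirical
P < 0.001 at 1000 permutations); ties are non-significant, and nulls
are kept per track rather than pooled. Confidence intervals for incMSE
come from resampling windows with replacement and refitting; importance
is then measured on the windows left out of each resample, because
evaluating on the resample itself lets trees match duplicated windows
exactly and inflates the apparent importance even of pure-noise tracks.

Signed, per-window interpretation uses SHAP attributions computed with
the exact path-dependent tree algorithm (implemented in-package,
numba-accelerated, with an explicit traversal stack; validated in tests
against brute-force Shapley enumeration). Attributions satisfy local
accuracy exactly: base value plus the attribution row equals the model
prediction for every window. The headline diagnostic is the Spearman
correlation between a track's values and its own attribution column —
negative for accessibility (open chromatin depletes mutations),
positive for late-replication tracks, negative for early-replication
tracks.

## Mutational-signature burden

Each SNV carries a probability vector over single-base-substitution
(SBS) signatures (an input, e.g. consortium attributions; the package
does not infer exposures). The expected signature-specific burden of a
window sums those probabilities over its SNVs, so signature burdens
conserve the total count exactly. The alternative hard assignment gives
each SNV wholly to its argmax signature (lexicographic tie-break for
determinism); the rank agreement between the two per-window burdens is
a standard sanity check and is exercised by the acceptance suite.
Signatures with fewer than 20,000 expected SNVs genome-wide in a cohort
are filtered (inclusive at the boundary). Accuracy differences between
signature aetiology classes are tested by OLS ANOVA of adj.R² on class
plus a mean-burden covariate — the covariate is per (cohort, signature)
since the relevant burden scale is signature-specific — with an F-test
for the class term and pairwise contrasts.

## Hotspot windows

Windows whose observed burden exceeds the model expectation are scored
by Z-transforming the residuals per cohort (sample n−1 standard
deviation), converting to one-tailed upper normal P-values, and
adjusting by Benjamini-Hochberg across the cohort's windows. Genes
overlap a window when the half-open intervals intersect; a gene
inherits the minimum P over its windows, producing the gene-level table
downstream pathway tools consume. Enrichment of labelled genes (e.g. a
known cancer-gene list) among hits uses the one-sided hypergeometric
upper tail (the directional question "more than expected"); a two-sided
Fisher option is exposed. Hotspot analysis is intended for the 100-kbp
grid when gene-level interpretation matters; the synthetic study below
uses the 1-Mbp grid, where its planted effects are calibrated.

## The synthetic study

The generator (`regmut.synthdata`) emulates the structure of the real
inputs with every latent quantity recorded. Its defaults are the
package's standard study conditions and were chosen once, as follows:

- **Grid**: 500 windows of 1 Mbp (five 100-Mbp chromosomes);
  mappability drawn in [0.85, 1] so nothing is filtered by default (a
  `fraction_low_mappability` option plants filterable windows).
- **Latent fields**: accessibility L and replication timing R, i.i.d.
  standard normal per window.
- **Tracks**: 20 cancer CA (loading 1.0 on L), 20 normal CA (loading
  0.4), 6 RT (loading ±1.0 on R, late phases positive), optional
  pure-noise tracks; additive Gaussian track noise sd 1.0. The
  resulting per-track correlation with the latent field (~0.7 for
  cancer tracks) represents donor-to-donor heterogeneity plus assay
  noise; cancer and normal arms share the same latent field and differ
  by effect size, mirroring the finding that both correlate with
  burden but cancer epigenomes correlate more.
- **Burden**: log-mean b0 − 0.4·L + 0.25·R, normalised to 50 SNVs per
  window across 50 genomes; the log-sd of ~0.47 gives a ~6-fold central
  burden range, matching the megabase-scale variation of whole-genome
  cohorts. Counts are negative binomial (dispersion 2 per genome):
  regional burden is overdispersed, and Poisson noise alone would
  flatter the models.
- **Hotspots**: 10 windows multiplied by 3, drawn away from chromosome
  ends and only among windows with at least median baseline burden. A
  3-fold excess on a near-empty window carries too few mutations to be
  identifiable by any method at this depth, so planting there would
  measure the generator rather than the method.
- **Signatures**: three signatures (SBS1-, SBS5-, SBS13-like) with
  exposures 0.3/0.4/0.3, mild window-level modulation of exposures
  along L, and sharp category distributions over the six collapsed
  substitution classes. Sharpness is deliberate on two counts: real
  attributions use 96 trinucleotide channels and are far more
  discriminative than six classes would suggest, and the channel
  margins are wide enough that an SNV's argmax signature never depends
  on its window's exposure weights — otherwise the top-ranked burden
  becomes a discontinuous function of the window covariates and its
  rank agreement with the probabilistic burden degrades for reasons
  unrelated to either estimator. Emitted probability vectors are the
  exact posteriors under the generating mixture, so expected burdens
  are unbiased for the true label counts.
- **Genes**: one gene per sampled window (guaranteeing each hotspot
  window a gene — hotspots in the emulated biology arise at genes),
  lengths 0.2-0.6 of a window; cancer-gene flags drawn without
  replacement with weight 1 + hotspot_bias (default 50) on hotspot
  windows, so bias 0 makes flags independent of hotspots.

What the generator does **not** emulate: genome sequence and
trinucleotide context, spatial autocorrelation of chromatin along the
genome, copy-number and structural variation, inter-sample burden
heterogeneity beyond the negative binomial, and cohort-specific
signature catalogues. Passing tests therefore demonstrate that the
statistical machinery recovers planted structure under realistic noise,
not that the biological conclusions transfer to any particular cohort.

## Problem sizes and numerical choices

Tests and the acceptance script run the study at reduced but fixed
sizes chosen as the package's standard desk-scale configuration: 100
trees and 100–200 cross-validation splits for comparisons, 25–50 trees
for permutation-null calibration at 150–500 windows, 50 permutations
for reduced nulls, and a handful of generator replicates per property.
The full-scale defaults (1000 trees, 1000 splits, 1000 permutations)
remain the package defaults for real analyses.

Other numerical choices: forest determinism comes from per-split seeds
spawned from a master seed; the type-I calibration of the permutation
null is asserted through a one-sided exact binomial bound at the
1/n_perm rate (the expected flag rate under exchangeability is
1/(n_perm + 1), so a literal ≤ 1/n_perm comparison would fail by
sampling noise alone about half the time); Spearman correlations on
constant inputs are reported as missing rather than raised; and the
immunoglobulin exclusion list is a per-cohort configuration, not a
global filter.

## Known limitations

- Residual Z-scores assume approximately homoscedastic, symmetric model
  residuals; at very low counts per window (e.g. shallow cohorts on a
  100-kbp grid) the normal upper tail is anti-conservative. The
  acceptance analyses run at depths where this approximation holds.
- adjusted R² is undefined when the evaluation set is smaller than the
  predictor count plus one; the package raises rather than reporting a
  misleading value, which constrains very small grids with many tracks.
- Permutation-refit nulls are expensive (one forest per permutation);
  the reduced configurations trade null resolution (min attainable
  empirical P = 1/n_perm) for runtime.
- The SHAP implementation covers sklearn tree ensembles only (the model
  family the package fits); interventional (background-data) SHAP is
  not implemented.
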