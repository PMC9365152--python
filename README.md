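# regmut

Regional mutagenesis modelling for cancer genomics: predict
megabase-scale somatic mutation burden from chromatin accessibility
(CA) and replication timing (RT) profiles, compare cancer vs normal
epigenomes as predictors, identify the significant predictor profiles,
attribute predictions to individual tracks with SHAP, compute
probabilistic mutational-signature burden per window, and prioritise
genomic windows whose mutations exceed the epigenome-informed
expectation.

The package is aimed at computational cancer-genomics groups working
with whole-genome somatic variant calls (e.g. consortium SNV tables)
and genome-wide epigenome tracks (ATAC-seq, RepliSeq). A synthetic-data
module with planted ground truth makes every stage testable without any
external download.

## The model

The genome is tiled into non-overlapping windows (1 Mbp default,
100 kbp for gene-level work). For a cohort, the response is the SNV
count per window `y_w`; the predictors are per-window mean signals
`x_w` of hundreds of CA and RT profiles. A random forest (1000 trees,
p/3 predictors per split, node size 5) estimates `E[y | x]`, evaluated
by adjusted R² on held-out windows under Monte-Carlo cross-validation
(1000 random 80/20 splits):

    adj.R² = 1 − (1 − R²)(n − 1)/(n − p − 1)

Cancer and normal CA profiles are compared in a *paired* design: per
split, two forests train on identical windows — each arm with its own
CA profiles plus the same RT profiles — and

    Δadj.R² = adj.R²(M_cancer) − adj.R²(M_normal)

is evaluated on identical test windows, giving a median Δ, a 95%
percentile interval and an empirical p (the fraction of splits crossing
zero against the median). Predictor significance uses incMSE (percent
OOB-MSE increase under per-track permutation) against a
permutation-refit null: the burden vector is reassigned at random 1000
times with a forest refit each time, and a track is significant only if
its observed incMSE exceeds all null values (empirical P < 0.001).
Signed interpretation uses exact path-dependent tree SHAP. Windows with
unexplained excess burden are scored by Z-transformed residuals
(observed − out-of-bag prediction), one-tailed normal P, and BH FDR;
overlapping genes inherit the window's best P, and cancer-gene
enrichment among hits is a one-sided hypergeometric test.

## Worked example

Generate a synthetic cohort (500 × 1 Mbp windows, 20 cancer + 20
normal CA tracks, 6 RT tracks, 50 genomes, ~50 SNVs per window, 10
hotspot windows at 3× excess) and run the paired comparison and the
hotspot scan:

```python
import numpy as np
from regmut import ModelSpec, count_burden, fit_forest, mccv_compare, score_residuals
from regmut.burden import PAN_CANCER
from regmut.synthdata import default_scenario

scen = default_scenario(seed=1)
y = count_burden(scen["snvs"], scen["grid"], PAN_CANCER).counts
X, arms = scen["X"], scen["arms"]

res = mccv_compare(X[arms["cancer_CA"]], X[arms["normal_CA"]],
                   X[arms["RT"]], y, ModelSpec(n_trees=100, n_splits=100, seed=1))
print(f"median dAdjR2 = {res.median_delta:.3f} "
      f"[{res.ci_low:.3f}, {res.ci_high:.3f}], p {res.p_label}")
print(f"cancer arm adjR2 = {np.median(res.adj_r2_cancer):.3f}, "
      f"normal arm adjR2 = {np.median(res.adj_r2_normal):.3f}")

fit = fit_forest(X, y, ModelSpec(n_trees=100, seed=1))
hot = score_residuals(y, fit.oob_prediction, grid=scen["grid"])
called = set(hot.loc[hot.q < 0.05, "window"])
planted = set(scen["truth"].hotspot_windows.tolist())
print(f"hotspots: {len(called & planted)}/{len(planted)} planted recovered, "
      f"{len(called - planted)} extra calls")
```

prints

```
median dAdjR2 = 0.178 [0.035, 0.311], p 0.01
cancer arm adjR2 = 0.307, normal arm adjR2 = 0.152
hotspots: 8/10 planted recovered, 1 extra calls
```

The cancer-CA arm predicts regional burden better than the normal-CA
arm (positive median Δadj.R² with an empirical p of 0.01 over 100
splits), exactly the planted structure: cancer tracks load on the
latent accessibility field with strength 1.0 vs 0.4 for normal tracks.
Eight of the ten planted 3×-burden windows are recovered at FDR < 0.05
with one extra call.

The same stages are available from the shell:

```bash
regmut simulate --seed 1 --outdir data/
regmut run --config run.yaml --outdir results/
```

## Layout

- `src/regmut/grid.py` — window grid, mappability filter, track aggregation
- `src/regmut/burden.py` — cohort filters and per-window SNV counts
- `src/regmut/signatures.py` — probabilistic signature burden, class ANOVA
- `src/regmut/models.py` — forest regression, MCCV, paired comparison
- `src/regmut/importance.py` — incMSE, permutation null, bootstrap CIs, SHAP
- `src/regmut/treeshap.py` — exact path-dependent tree SHAP
- `src/regmut/hotspots.py` — residual Z / FDR scan, gene annotation, enrichment
- `src/regmut/synthdata.py` — planted-truth generator
- `src/regmut/cli.py` — `regmut` command-line interface
- `docs/methods.md` — model assumptions, generator design, limitations
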