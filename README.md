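# cecselect

Prioritizing contaminants of emerging concern (CECs) by how strongly they
covary with the metabolite profiles of caged sentinel animals.

## The problem

Rivers carry complex mixtures of pesticides, hormones, pharmaceuticals and
personal care products. Single-chemical toxicology cannot keep up with the
number of CECs detected in surface water, so monitoring programs need a way
to shortlist the contaminants most likely to elicit a biological response.
One field design for this: deploy caged filter feeders (e.g. freshwater
mussels) at several sites for a fixed period, measure a large targeted
contaminant panel in water samples over repeated events, profile the
animals' hemolymph metabolome, and ask which contaminants' site-to-site
concentration differences covary with site-to-site metabolite differences.

`cecselect` implements that analysis as a tested, reusable pipeline, plus a
synthetic-study generator with planted ground truth so every stage can be
validated at desk scale.

## The method

Let X be the n x K block of metabolite abundances (one row per animal,
median-normalized so each metabolite's median is 1, restricted to
metabolites that differ across sites by one-way ANOVA at p < 0.05) and Y
the n x M response block of per-site maximum contaminant concentrations
(below-detection-limit values set to 0; analytes never detected anywhere
dropped) plus maximum water temperature.

- **Multi-response PLS (NIPALS).** Both blocks are centered and scaled to
  unit variance; components t_a = X w_a are extracted to maximize
  covariance between the blocks' scores, with rank-one deflation of both
  blocks per component. R²X_a and R²Y_a are each component's share of the
  scaled blocks' variance.
- **Cross-validated assessment.** With site-stratified folds (default 7),
  scaling and the fit are redone inside every training fold. Per response
  j: PRESS_j (held-out squared error) against SS0_j (training-fold mean as
  predictor), Q²Y_j = 1 − PRESS_j/SS0_j, pooled
  Q²Cum = 1 − ΣPRESS/ΣSS0.
- **CV-ANOVA.** Per-response significance of the predictive gain,
  F_j = ((SS0_j − PRESS_j)/A) / (PRESS_j/(n − A − 1)) on (A, n − A − 1)
  degrees of freedom.
- **Selection.** Backward elimination: all responses with CV-ANOVA
  p > 0.05 are removed simultaneously each iteration until a fixed point
  (temperature is kept by force). Then every excluded contaminant is
  re-introduced one at a time (descending global-model Q²Y) and retained
  iff p < 0.05 **and** Q²Cum strictly increases. The full trace is
  recorded.
- **Biomarkers.** VIP_k = sqrt(K Σ_a SSY_a (w_ka/‖w_a‖)² / Σ_a SSY_a)
  (mean squared VIP = 1 by construction); VIP is recomputed on every
  training fold and a delete-one-fold jackknife tests H₀: VIP ≤ 1.

## Worked example

The numbered scripts under `analysis/` run the default synthetic study
(4 sites x 6 sampling events x 220 analytes, 8 animals per site x 186
metabolites, 15 factor-driven contaminants, 30 responsive metabolites):

```bash
python analysis/01_simulate_study.py --seed 17
python analysis/02_preprocess.py
python analysis/03_screen_metabolites.py
python analysis/04_fit_global_model.py --seed 17
python analysis/05_select_contaminants.py --seed 17
python analysis/06_rank_biomarkers.py --seed 17
```

which prints (abridged):

```
160 of 220 analytes were never detected at any site and were dropped; 60 remain
of 186 metabolites, 146 were not significantly different across sites (p >= 0.05); 40 screened in
global model: 2 components over 40 metabolites and 61 responses
variance explained in X per component: 41.0%, 22.0%
cross-validated Q2Cum of the global model: 0.968
elimination removed 45 of 60 contaminants over 1 iteration(s); re-introduction re-admitted 0
final model: water temperature and 15 contaminants; Q2Cum 0.968 (vs 0.968 for the global model)
strongest relationships (Q2Y): A122 (0.973), A184 (0.973), A028 (0.973), ...
10 of 40 screened metabolites have VIP >= 1 with VIP significantly greater than 1 (p < 0.05)
```

The 15 retained contaminants are exactly the planted active set
(`results/study/truth.json`), the 45 eliminated ones are the inert
detected analytes, and the VIP biomarkers are drawn from the planted
responsive metabolites. The same pipeline runs on real data from CSV files
(`cecselect run-all --config cfg.yaml`, or the `simulate | preprocess |
screen | fit | assess | select | report` subcommands; see `cecselect
--help`).

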