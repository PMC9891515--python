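# Methods

## Study design and data model

The pipeline models a caged-biomonitoring design: sentinel animals deployed
at `n_sites` river sites for a fixed window; surface water sampled at
`n_events_per_site` common dates and assayed against a targeted panel of
`n_analytes` contaminants (hormones / pesticides / PPCPs), each with a
per-analyte detection limit; hemolymph metabolomics once per animal
(`n_samples_per_site` per site, `n_metabolites` compounds), delivered in
run-day batches. Contaminant data are long-format event records
(`ContaminantPanel`); metabolite data are a wide sample x metabolite matrix
(`MetaboliteMatrix`). Units are carried opaquely (concentrations in
ppm-like units, temperature in deg C); nothing is converted.

## Preprocessing (fixed order, audited)

Contaminant side: **censor -> aggregate -> filter**. A value equal to or
above its detection limit counts as detected; smaller values are censored
and contribute **zero** to aggregation. Per (site, analyte) the response is
the **maximum over events** (wet-weight maxima); temperature is the per-site
maximum reading. Analytes whose maximum is zero at every site are dropped.
Zero-substitution below the limit is a known source of bias; it is used
here deliberately as the convention of the workflow this package
implements, and censored-likelihood alternatives are out of scope.

Metabolite side: **normalize -> impute**. Each metabolite is scaled so its
non-missing median equals 1 (block-wise when run-day blocks are recorded,
which removes multiplicative day effects; the pooled median still lands on
1 because each block's does). Missing cells are then imputed with the
per-metabolite minimum (`half-minimum` and `fail-on-missing` available);
parsers never silently turn missing or censored values into numbers.

The response block Y broadcasts each site's aggregate row to its samples
(site-constant rows by construction), with temperature as the last column,
flagged force-keep for selection.

## Metabolite screen

Per metabolite, one-way fixed-effects ANOVA across sites; the explanatory
block of the PLS model is the set with omnibus p < alpha (default 0.05, no
multiplicity correction — deliberately, matching the workflow; the screen's
null selection rate is therefore ~alpha). Abundances enter untransformed by
default (`log_transform` available). All site pairs are additionally
compared with Tukey-Kramer HSD (studentized-range distribution on the
within-group mean square; reduces to classic Tukey HSD for balanced
groups). Zero within-group variance is resolved by continuity: p = 0 for
unequal means, p = 1 for equal. Significant pairs can be rendered as
compact letter pairs (sites sharing a letter differ); letters are assigned
to pairs in a fixed site order, so the rendering is deterministic and
decodable back to the exact pair set.

## PLS engine

NIPALS with deflation of both blocks (full NIPALS-2): per component,
iterate w = X'u/|X'u|, t = Xw, c = Y't/t't, u = Yc/c'c until the relative
change of t falls below 1e-10 (at most 2000 sweeps — NIPALS converges
linearly at rate (sigma2/sigma1)^2 of the residual cross-covariance, so
near-tied spectra need well over 500), then deflate X and Y by the rank-one
term. Deterministic throughout: u starts at the residual-Y column of
largest variance, never at a random vector. Both blocks are autoscaled to
unit variance (sample sd, n-1 denominator; `center_only` and `pareto`
available); constant columns get scale 1 and a flag. Regression
coefficients B = W (P'W)^-1 C' act on the scaled spaces; predictions apply
the stored centering/scaling and its inverse. R2X_a = |t_a p_a'|^2_F /
|X_0|^2_F and analogously R2Y_a. Direct fits raise on true inner-loop
non-convergence; cross-validation training fits instead truncate to the
components that converged (a late component on an exhausted residual
carries no structure worth failing over) and, for a structureless first
component, keep the final iterate — near-tied directions are
prediction-equivalent.

The component count is chosen by cross-validated parsimony: add component a
while Q2Cum(a) − Q2Cum(a−1) >= 0.01, capped at min(n−1, K, 10) and the
training-fold rank limit; at least one component is always used. The
implementation deepens the CV horizon lazily (4 components at a time) —
decisions are identical to evaluating the full cap.

## Cross-validation, CV-ANOVA, VIP

Folds (default 7, the chemometrics convention) are assigned by seeded
site-stratified round-robin; assignment depends only on (n, folds, seed,
site labels), never on data values, and every fold must mix >=2 sites
(leave-one-out exempt). Scaling and the PLS fit are redone inside each
training fold — no leakage — and residuals are taken on the original Y
scale. PRESS_j sums held-out squared error; SS0_j uses the training-fold
mean as predictor; Q2Y_j = 1 − PRESS_j/SS0_j, Q2Cum = 1 − ΣPRESS/ΣSS0. A
response with SS0 = 0 (site-constant) gets Q2Y = 0 by convention and
CV-ANOVA p = 1: no variation, no predictive gain.

CV-ANOVA is applied per response: F_j = ((SS0_j − PRESS_j)/A) /
(PRESS_j/(n − A − 1)), clamped at 0 when the model does not beat the null,
with an upper F tail on (A, n − A − 1) degrees of freedom. This is a
per-response variant — the classical whole-model form pools responses, but
the selection algorithm needs per-contaminant p-values.

VIP_k = sqrt(K Σ_a SSY_a (w_ka/|w_a|)^2 / Σ_a SSY_a) with SSY_a the Y
variance explained by component a; mean squared VIP is 1 by construction.
Inference is a delete-one-fold jackknife: VIP recomputed on each training
fold, se from the jackknife formula over folds, one-sided t (df = folds−1)
of H0: VIP <= 1; se = 0 resolves to p = 0 if VIP > 1 else p = 1. Loading
signs are read off the full-model X loadings on components 1 and 2
(|loading| < 1e-10 maps to "0").

## Selection algorithm

Backward phase: cross-validate the model on the current response set
(components re-chosen after every change by default; a fixed count is
available), compute per-response CV-ANOVA p, remove **all** non-force-keep
responses with p > alpha simultaneously, repeat until none qualifies.
Simultaneous (not one-at-a-time) removal is the design choice: it gives the
small iteration counts this kind of workflow reports. Forward phase:
excluded responses are offered back one at a time in descending
global-model Q2Y (ties lexicographic — the order is recorded so
alternatives are auditable) and accepted iff p < alpha **and** Q2Cum
strictly increases; accepted candidates stay for later trials. The trace
records every decision, and three invariants are asserted on every run:
retained sets strictly shrink during elimination; every accepted
re-introduction satisfies the dual criterion; final Q2Cum >= post-
elimination Q2Cum. The ranked output sorts final responses by Q2Y
descending. Identical inputs and seed give identical traces.

## Synthetic-study generator

`SimulationConfig` defaults describe the default study: 4 sites x 6 events
x 220 analytes with 160 never detected (60 detected, 15 of them "active"),
8 animals per site x 186 metabolites (30 "responsive"), 2 latent factors,
effect size 2, animal-level noise sd 0.3 (log scale), block effect sd 0.2,
detection limits at the 0.25 quantile of each analyte's own values.

Generative model: site factor scores Z (sites x factors, standard normal)
represent latent exposure gradients. Active contaminants' log site means
are affine in Z; inert detected contaminants have site-constant means;
never-detected analytes get a limit above their largest value. Event-to-
event concentration noise (lognormal, sd 0.3) is **basin-wide**: sampling
events are common dates and flow/weather-driven fluctuation is shared by
all sites, so an inert analyte's max-aggregated site profile is exactly
site-constant while active analytes' profiles follow the factors.
Responsive metabolites are lognormal with log-means affine in the same Z,
scaled so site-driven sd / residual sd equals `effect_size`; others are
pure lognormal noise; multiplicative per-(block, metabolite) run-day
effects are applied to all metabolites (removed later by block-wise median
normalization). Temperature tracks the first factor (20 + 2 z1 deg C, 0.5
deg reading noise, per-site max). One seed sequence is split into
per-block sub-streams, so enlarging one block never perturbs another;
identical config + seed gives byte-identical CSV exports.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: real inert contaminants also vary between sites
for reasons unrelated to the biology (point sources, hydrology). Because
the responses are site-level constants and CV folds share sites, *any*
site variation in a response is partially predictable from metabolites
that encode site identity — with only 4 sites (3 centered dimensions),
a random site profile projects substantially onto any learnable 2-3
dimensional subspace, regardless of its magnitude. On real data the method
therefore retains more contaminants than the planted-truth recovery rates
here suggest; the recovery benchmarks quantify performance when "inert"
means "carries no site signal", which is what the planted truth defines.
Also not modelled: within-deployment time series, transport/pharmaco-
kinetics, metabolite-metabolite correlation beyond the shared factors.

## Problem sizes and tolerances used in the tests

Module tests run a reduced study (4 sites x 4 events x 40 analytes, 24
animals x 40 metabolites); the statistical acceptance checks use the
default full-size study over 20 seeds (planted recovery), 1000 null draws
(cross-validated Q2 calibration), 50 null selection runs (false-inclusion
rate), and 1000 simulated null metabolites (screen calibration). Numeric
equivalences are checked against independent references: a manual per-fold
refit loop for PRESS/Q2 (1e-10), scikit-learn's PLS for training
predictions (1e-8; the reference is run at a tight inner tolerance since
its `tol` compares a *squared* step norm), scipy's `f_oneway` and
`tukey_hsd` for the screen (1e-8), and closed forms for single-component
VIP and single-response weights. Exact identities (median = 1, mean
squared VIP = 1) are asserted to 1e-12/1e-10.

## Known limitations

- Zero-substitution of censored values and max-aggregation are the
  prescribed conventions, not statistical recommendations.
- The per-response CV-ANOVA df pair (A, n − A − 1) treats cross-validated
  residuals as if from an ordinary fit; with site-constant responses and
  shared-site folds its null is calibrated conservatively (verified by
  simulation), but it is not an exact test.
- Selection controls nothing family-wise across the elimination/
  re-introduction path.
- With 4 sites the response side has at most 3 informative dimensions; the
  discussion above about site-identity predictability applies to any
  analysis of this design, not just this implementation.
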