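# milemet

Early-life BMI trajectory milestones — the infancy BMI peak and the
childhood BMI rebound — predict metabolic risk in adolescence, but the
biological pathways linking early growth to later risk are poorly
understood. `milemet` implements a *meet-in-the-middle* screen that asks
which metabolite networks are associated with **both** the upstream
exposure (a BMI milestone) and the downstream outcome (a metabolic
syndrome z-score), sex-stratified throughout:

1. **Growth milestones.** A mixed-effects model with a natural cubic
   spline basis of age (sex × spline interactions as fixed effects,
   subject-level random coefficients) is fitted to longitudinal BMI.
   Per child, the infancy peak (t_p, B_p) and childhood rebound
   (t_r, B_r) are the interior maximum/minimum of the fitted curve where
   b′(t) = 0, located by bisection on the analytic spline derivative.
2. **Consensus metabolite networks.** Metabolite abundances are filtered
   to endogenous compounds, missing values imputed as ½ the minimum
   detected value, log10-transformed and Pareto-scaled. Signed weighted
   adjacency a_ij = ((1 + ρ_ij)/2)^β with Spearman ρ and β = 10 is
   transformed to a topological overlap matrix (TOM); per-sex TOMs are
   combined by quantile-calibrated element-wise minimum; modules come from
   average-linkage clustering of 1 − TOM with a dynamic tree cut
   (minimum module size 20). Each module is summarized per sample by its
   eigengene (first right-singular vector of the standardized module
   submatrix) and each metabolite by its kME (correlation with the
   eigengene).
3. **MetS z-score.** HOMA-IR = glucose [mg/dL] × insulin [µIU/mL] / 405;
   the composite is the mean of five externally standardized component
   z-scores (waist, mean of five SBP readings, HDL × (−1),
   triglycerides, HOMA-IR) against user-supplied sex/age(/height)
   mean/SD reference tables.
4. **Three-step screen.** Milestones (per within-sex SD) → MetS z
   (α = 0.05, carried forward); carried milestones → each module eigengene
   with Benjamini–Hochberg FDR at 5% per sex; FDR-significant modules →
   MetS z under nested covariate tiers (Model 1: age + race/ethnicity;
   Model 2: + pubertal status; Model 3: + maternal education,
   pre-pregnancy BMI, smoking), with an uncorrected per-component
   follow-up and a mutual-adjustment sensitivity analysis.

Because cohort data of this kind are not publicly distributable, the
package ships a first-class synthetic-cohort generator with exact ground
truth (planted milestones, planted metabolite modules, planted
exposure→module→outcome effects), so every stage is testable end to end.

## Worked example

```python
from milemet import (simulate_cohort, eligibility_filter, GrowthCurveModel,
                     MetabolitePreprocessor, ConsensusNetwork,
                     compute_mets_scores, run_screen, standardize_exposures)

ds = simulate_cohort(seed=1)                      # 300 children, 12 visits

model = GrowthCurveModel().fit(eligibility_filter(ds.anthropometry))
milestones = model.extract_all_milestones()
scaled, sds = standardize_exposures(milestones)
print(sds[sds.exposure == "age_rebound"])
#       sex     exposure        sd    n
# 2    male  age_rebound  3.647318  149
# 6  female  age_rebound  3.809509  148

processed = MetabolitePreprocessor().fit_transform(ds.metabolites,
                                                   ds.metabolite_meta)
net = ConsensusNetwork().fit(processed,
                             ds.covariates.set_index("subject_id")["sex"])
print(int(net.labels_.max()), "consensus modules")   # 5 consensus modules

mets = compute_mets_scores(ds.mets_components, ds.reference_tables)
results = run_screen(scaled, net.eigengenes_.eigengenes, mets,
                     ds.covariates)
print(results["carried_pairs"]["male"])
# [('age_rebound', 'ME2')]
```

The generator plants one causal path by default — an earlier childhood
rebound raises the module-2 metabolite factor in boys, which in turn
raises the MetS z-score — and the screen recovers exactly that
(milestone, module) pair: step 3 estimates 0.53 (95% CI 0.46, 0.61) MetS
z units per SD of the matched eigengene under Model 1. The reported SD of
the rebound age (≈3.6 mo here) is the per-SD unit of the step-1/step-2
effect estimates.

The same pipeline runs from a shell:

```bash
milemet simulate --out data --seed 1
milemet run --config config.yaml --out results --seed 1
```

where `config.yaml` holds either a `simulate:` block or an `inputs:` block
with paths to your own `anthropometry.csv`, `metabolites.csv`,
`metabolite_meta.csv`, `mets_components.csv`, `reference_tables.csv` and
`covariates.csv` (schemas in `milemet.io`).

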