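# lassobags

Knowledge-guided post-processing of (adaptive) lasso variable selection
for high-dimensional regression, built for settings like gene-expression
prediction of a continuous phenotype where P ≫ n **and** a domain expert
holds prior knowledge that is infeasible to elicit over thousands of
covariates.

The workflow shrinks the elicitation task to a shortlist. Data are split
into portions D1/D2/D3. On D1, a cross-validated lasso or adaptive lasso

&nbsp;&nbsp;&nbsp;&nbsp; β̂ = argmin<sub>β</sub> ‖y − Xβ‖² + λ ‖w ∘ β‖₁

selects a covariate set S. Around each j ∈ S a *bag* of potential
substitutes is built on D1:

- **B1** — the q covariates most correlated with j (default q = 20);
- **B2** — every covariate with Corr(X_j, X_k) ≥ a threshold (0.25);
- **B3** — the q covariates with the smallest residual MSE when swapped
  for j in the OLS of y on S.

The expert labels only the union of all bags (the shortlist) as
biologically relevant or not. Fixed rules then substitute: a relevant
selected covariate is kept; a single relevant bag member replaces its
owner; among several, the best-scoring one wins (largest correlation for
B1/B2, smallest replacement MSE for B3); with none, the owner stays.
Duplicates collapse, so the final model can only get sparser. The final
variable set is refit by OLS on D2 and validated on D3 via PMSE,
PRPMSE = 100·PMSE(substituted)/PMSE(baseline), a paired bootstrap 95 %
CI for the PMSE ratio, MISE, and the share of relevant variables.

A synthetic benchmark generator reproduces the method's simulation
design (n = 300, P = 1000, 20 generating covariates at β = 0.1, 60
biologically relevant covariates in four equicorrelated blocks at
ρ = 0.55–0.70, SNR-controlled Gaussian noise), so the whole study runs
without external data. See `docs/methods.md` for the model, conventions
and known reproduction caveats.

## Worked example

```python
from lassobags import (SimConfig, simulate_dataset, split_three_way,
                       initial_weights, fit_adaptive_lasso_cv,
                       bag_correlation_topq, apply_substitutions,
                       refit_ols, pmse, prpmse, selection_composition)

data, beta, relevance = simulate_dataset(SimConfig(seed=0))
split = split_three_way(data, seed=1)

w = initial_weights(split.d1, "lasso_init", seed=2)
sel = fit_adaptive_lasso_cv(split.d1, k=5, weights=w, seed=2)
n, k, pct = selection_composition(sel.selected, relevance)
print(f"adaptive lasso selected {n} covariates, {k} relevant ({pct:.1f}%)")

bags = bag_correlation_topq(sel, split.d1, q=20)
print(f"shortlist for the expert: {len(bags.shortlist())} of {data.p} covariates")

result = apply_substitutions(sel, bags, relevance)
n, k, pct = selection_composition(result.final_variables, relevance)
moved = sum(r.outcome in ("switched", "collapsed_duplicate") for r in result.records)
print(f"after B1 substitution: {n} covariates, {k} relevant ({pct:.1f}%), "
      f"{moved} substituted")

base = refit_ols(sel.selected, split.d2)
sub = refit_ols(result.final_variables, split.d2)
print(f"validation PMSE {pmse(sub, split.d3):.3f} vs baseline "
      f"{pmse(base, split.d3):.3f} (PRPMSE {prpmse(sub, base, split.d3):.1f}%)")
```

prints

```
adaptive lasso selected 18 covariates, 12 relevant (66.7%)
shortlist for the expert: 215 of 1000 covariates
after B1 substitution: 17 covariates, 12 relevant (70.6%), 1 substituted
validation PMSE 0.524 vs baseline 0.527 (PRPMSE 99.5%)
```

On this replicate the stage-1 model already contains 12 relevant
covariates; one non-relevant covariate resolves to a relevant variable
already in the model (a collapsed duplicate), so the final model is one
covariate sparser with a slightly better held-out PMSE (PRPMSE below
100 % means the substituted model predicts better). The expert had to
label 215 covariates instead of 1000.

The same steps are available from the shell for file-based data
(`X.tsv` samples × variables, one-column `y.csv`, and an elicitation
worksheet CSV the expert fills with 0/1):

```sh
lassobags simulate --seed 0 --out-dir run/
lassobags split --x run/X.tsv --y run/y.csv --out-dir run/
lassobags stage1 --out-dir run/ --method adaptive_lasso --seed 2
lassobags bags --out-dir run/ --rule B1 --q 20      # writes worksheet_B1.csv
# ... expert fills the 'relevant' column ...
lassobags substitute --out-dir run/ --rule B1 --worksheet run/worksheet_B1.csv
lassobags stage2 --out-dir run/ --variables run/substitution_B1.json
lassobags experiment --seed 1 --out-dir study/      # full replicated study
lassobags sweep --seed 1                            # q / threshold sensitivity
```

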