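# dmnage

Age-related change in default-mode-network (DMN) functional connectivity,
from ROI time series to group statistics.

Resting-state fMRI studies of depression ask whether the DMN's internal
coupling declines differently with age in patients than in controls. This
package implements that analysis for anyone holding per-subject ROI time
series (volumes × regions, TR = 2 s) and a phenotype table — it does not
touch raw images. It computes, per subject over a fixed 58-region DMN:

* **static FC strength** — the mean Pearson correlation over all
  58·57/2 = 1653 region pairs, and
* **dFC temporal variability** — sliding-window connectivity (width 100 s,
  step 6 s by default) summarized per region as
  `V_k = 1 − mean_{i<j} corr(F(i,k), F(j,k))`, where `F(i,k)` is region
  k's connectivity profile in window i, with the network statistic `V`
  the mean of `V_k` (range [0, 2]);

and, at the group level, the interaction regression

```
outcome ~ intercept + diagnosis + age + diagnosis×age
          + sex + education + site + mean FD
```

(diagnosis MDD = 0 / HC = 1, OLS, SPSS-style standardized betas), Fisher
r-to-z comparison of the within-group age correlations,
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`, clinical partial
correlations, a first-episode vs recurrent ANCOVA, heteroscedasticity
diagnostics with log refit, and a window-parameter validation grid. A
synthetic multi-site cohort generator with known age slopes makes the whole
pipeline testable end to end; see `docs/methods.md` for the model and its
limits.

## Worked example

```python
from dmnage import SimulationConfig, simulate_cohort, fit_interaction_model, \
    compare_independent_correlations
from dmnage.pipeline import qc_filter, compute_all_metrics

cfg = SimulationConfig(n_per_group=50, seed=42)
records, series = simulate_cohort(cfg)
retained, qc = qc_filter(records, series)
print(f"QC: retained {qc.n_retained}/{qc.n_input}")

table = compute_all_metrics(retained, series, width_s=100.0, step_s=6.0)
print(f"FC strength: mean {table['fc_strength'].mean():.3f}, "
      f"dFC variability: mean {table['dfc_variability'].mean():.3f}")

res = fit_interaction_model(table, "fc_strength")
for term in ("diagnosis", "age", "diagnosis_x_age"):
    print(f"{term}: b={res.coef(term):+.5f}, beta={res.beta(term):+.3f}, "
          f"t={res.tstat(term):+.3f}, p={res.pvalue(term):.4f}")
```

prints

```
QC: retained 100/100
FC strength: mean 0.393, dFC variability: mean 0.732
diagnosis: b=+0.01811, beta=+0.136, t=+1.581, p=0.1173
age: b=-0.00310, beta=-0.650, t=-5.239, p=0.0000
diagnosis_x_age: b=+0.00187, beta=+0.283, t=+2.291, p=0.0243
```

FC strength declines with age (negative age coefficient), and the positive
diagnosis×age coefficient says the decline is steeper in the patient group
(coded 0) than in controls (coded 1) — here t = 2.29, p = 0.024, recovering
the interaction the generator injected (true slope difference +0.0015 per
year). Comparing published within-group age correlations between two
independent groups works from summaries alone:

```python
c = compare_independent_correlations(-0.310, 971, -0.216, 902)
print(f"z = {c.z:.3f}, p = {c.p:.3f}")   # z = -2.182, p = 0.029
```

The same pipeline is scriptable from the shell: `dmnage simulate`,
`dmnage qc`, `dmnage metrics`, `dmnage analyze`, `dmnage validate`
(`--help` on each).

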