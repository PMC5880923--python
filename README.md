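# lgmsearch

Specification search for the growth trajectory in latent growth models
(LGM), with a Monte Carlo harness that measures how often a search
recovers the true trajectory.

## The problem

Longitudinal studies often have no theory for the *shape* of change —
is a score flat, linear, quadratic in time?  Under the LGM (latent
growth curve) framework the repeated measures of subject *i* follow

    y_i = Λ η_i + ε_i,        η_i = α + Γ w_i + ζ_i,

where Λ holds polynomial time codes (0, 1, …, t−1 and their powers),
η_i the subject's growth factors (intercept, slope, …) with means α,
between-subject covariance Ψ and optional time-invariant covariate
*w_i*, and ε_i the within-subject residuals with covariance Θ.  The
implied moments are μ = Λα and Σ = ΛΨΛ′ + Θ.

Practitioners search for the polynomial order by comparing adjacent
models — but from which *starting model*, and under which decision
rule?  `lgmsearch` implements the four canonical starting models
(simplest vs. most complex mean × identity vs. unstructured residual
covariance, giving step-up and top-down searches) and six decision
rules (likelihood-ratio test and differences in CFI, RMSEA, SRMR, AIC
and BIC with cutoffs 0.01 / 0.015 / 0.01 / 4 / 2), plus the simulation
machinery to measure hit rates across a 54-cell factorial design
(2 trajectories × 3 residual structures × 3 covariate effect sizes ×
3 sample sizes).

It is intended for methodologists studying model-building strategies
and for applied analysts who want a reproducible search/ladder workflow
on their own wide-format data.

## Worked example

```python
from lgmsearch import PopulationCondition, generate_dataset, run_search

data = generate_dataset(
    PopulationCondition("linear4", "UN1", 0.3, 210), seed=5
)
result = run_search(data, start=4, criterion="bic")
for step in result.trace:
    print(step.order_simple, "vs", step.order_complex,
          f"{step.statistic:.2f}", step.decision)
print("selected order:", result.selected_order)
```

prints

```
1 vs 2 -2.51 simpler
0 vs 1 152.68 complex
selected order: 1
```

The search starts from the most complex testable mean (quadratic for 4
waves) with an unstructured residual covariance.  Dropping the
quadratic term *improves* BIC (the complex model is worse by 2.51), so
the quadratic is discarded; dropping the linear term costs 152.68 BIC
points, so the linear model is kept — the true order for this
population.  The `examples/` directory has one short script per
capability (data generation, fitting and indices, search, the applied
ladder table, a small Monte Carlo run), and the `lgmsearch` command
exposes the same operations from the shell (`lgmsearch simulate`,
`fit`, `search`, `ladder`, `mc`, `report`).

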