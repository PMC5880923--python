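"""A small Monte Carlo hit-rate run over a slice of the design grid.

Runs the linear-growth (4-wave) third of the factorial design at 10
replications per cell, searching with starting models 1 (step-up, ID
residuals) and 4 (top-down, unstructured residuals) under the LRT and
Delta-BIC rules, and prints the per-criterion hit-rate table.
"""

from lgmsearch import aggregate, enumerate_design, run_design

design = enumerate_design(10, master_seed=0, trajectories=["linear4"])
records = run_design(design, starting_models=[1, 4], criteria=["lrt", "bic"])

table = aggregate(records, layout="table2")
print(table.round(1).to_string())
print(f"\n{len(records)} search records over {len(design)} datasets")
print("flagged (nonconverged-ladder) fraction:", records.flagged.mean())

# Each entry is the percentage of replications whose search recovered
# the true linear order (1) in that population cell.  The saturated
# start (model 4) with Delta-BIC should dominate the ID step-up start,
# especially when the true residual structure is not ID.
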