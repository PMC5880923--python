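"""Search for the growth trajectory from the fully saturated start.

Runs the top-down specification search (Model 4: highest-order
polynomial mean, unstructured residual covariance) under the Delta-BIC
rule on data whose true mean structure is linear, and prints the
comparison trace.
"""

from lgmsearch import PopulationCondition, generate_dataset, run_search

data = generate_dataset(
    PopulationCondition("linear4", "UN1", 0.3, 210), seed=5
)
result = run_search(data, start=4, criterion="bic")

print(f"criterion: {result.criterion}, starting model: {result.starting_model}")
for step in result.trace:
    print(
        f"  order {step.order_simple} vs {step.order_complex}: "
        f"BIC_simple - BIC_complex = {step.statistic:.2f} -> {step.decision}"
    )
print("selected order:", result.selected_order)

# Reading the trace: the complex model is retained only when its BIC
# improves on the simpler one by at least 2.  Starting from the
# quadratic (order t-2 = 2), the search should drop to the true linear
# order and stop there: the 0-vs-1 comparison favours "complex".
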